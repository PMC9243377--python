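"""Synthetic two-class multi-omics cohorts with planted pathway signal.

Each pathway is a block of genes sharing one latent factor: gene values are
sqrt(rho) * factor + sqrt(1 - rho) * noise, giving pairwise within-pathway
gene correlation rho.  Planted pathways shift the factor mean between the
outcome classes by the effect size delta (in pooled-SD units) in every
omics type, so the pathway's first principal component provably carries the
class signal.  An optional block structure makes groups of pathways share a
common factor, producing the between-pathway correlation that the ordering
stage is designed to exploit.  A numeric covariate emulating smoking age
(class-0 mean 30, SD 10, class-1 mean lowered by the covariate effect) is
attached to the annotations.

All randomness flows from a single required seed; the generator is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (ExpressionMatrix, PathwayCollection, SampleAnnotations,
                 write_expression_matrix, write_gene_sets,
                 write_sample_annotations)

__all__ = ["SyntheticCohortSpec", "SyntheticCohort",
           "generate_cohort", "generate_block_structure"]


@dataclass
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort; ``seed`` must be given explicitly."""

    seed: int
    n_samples: int = 120
    n_pathways: int = 100
    genes_per_pathway: tuple[int, int] = (8, 20)
    rho: float = 0.8                 # within-pathway gene correlation
    n_omics: int = 2
    n_planted: int = 5
    planted: tuple[int, ...] | None = None   # default: drawn from the seed
    effect_size: float = 1.5         # class mean shift of the factor, pooled-SD units
    class_proportion: float = 0.3    # fraction of positive samples
    covariate_effect: float = 1.0    # class shift of the covariate, in its SDs
    block_sizes: tuple[int, ...] = ()        # optional correlated pathway blocks
    block_weight: float = 0.0        # share of factor variance from the block factor

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect size must be non-negative")
        if not 0 < self.class_proportion < 1:
            raise ValueError("class proportion must be in (0, 1)")
        if self.planted is not None and any(
                not 0 <= i < self.n_pathways for i in self.planted):
            raise ValueError("planted indices out of range")
        if not 0 <= self.block_weight < 1:
            raise ValueError("block weight must be in [0, 1)")


@dataclass
class SyntheticCohort:
    """Generated expression matrices, annotations and the ground truth."""

    exprs: list[ExpressionMatrix]
    annotations: SampleAnnotations
    pathways: PathwayCollection
    ground_truth: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        """Write expression TSVs, a GMT and an annotations TSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for expr in self.exprs:
            write_expression_matrix(expr, out_dir / f"expr_{expr.omics_name}.tsv")
        write_gene_sets(self.pathways, out_dir / "pathways.gmt")
        # "pos" sorts after "neg", so the default lexicographic
        # positive-label rule recovers the same labels on re-read
        write_sample_annotations(self.annotations, out_dir / "annotations.tsv",
                                 class_names=("neg", "pos"))


def _blocks_from_spec(spec: SyntheticCohortSpec) -> list[list[int]]:
    """Interleave block members across the collection (block b gets indices
    b, b+k, b+2k, ...), so the file order scatters each block and the
    ordering stage has something to recover."""
    if not spec.block_sizes:
        return []
    if sum(spec.block_sizes) > spec.n_pathways:
        raise ValueError("block sizes exceed the pathway count")
    k = len(spec.block_sizes)
    blocks: list[list[int]] = [[] for _ in spec.block_sizes]
    idx = 0
    remaining = list(spec.block_sizes)
    while any(remaining):
        for b in range(k):
            if remaining[b]:
                blocks[b].append(idx)
                idx += 1
                remaining[b] -= 1
    return blocks


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Draw one cohort from the generative model described above."""
    rng = np.random.default_rng(spec.seed)
    n, P, C = spec.n_samples, spec.n_pathways, spec.n_omics

    n_pos = int(round(spec.class_proportion * n))
    if not 0 < n_pos < n:
        raise ValueError("class proportion leaves a class empty")
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n_pos]] = 1
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    if spec.planted is None:
        planted = tuple(sorted(rng.choice(P, size=spec.n_planted,
                                          replace=False).tolist()))
    else:
        planted = tuple(sorted(set(spec.planted)))
    planted_set = set(planted)

    blocks = _blocks_from_spec(spec)
    block_of = {}
    for b, members in enumerate(blocks):
        for i in members:
            if i in block_of:
                raise ValueError(f"pathway {i} appears in more than one block")
            block_of[i] = b

    lo, hi = spec.genes_per_pathway
    sizes = rng.integers(lo, hi + 1, size=P)
    pathway_defs = []
    gene_ids: list[str] = []
    for i in range(P):
        genes = [f"P{i:04d}_G{m:02d}" for m in range(sizes[i])]
        gene_ids.extend(genes)
        pathway_defs.append((f"PATHWAY_{i:04d}", frozenset(genes)))

    w = np.sqrt(spec.block_weight)
    u = np.sqrt(1.0 - spec.block_weight)
    lam = np.sqrt(spec.rho)
    noise_sd = np.sqrt(1.0 - spec.rho)

    exprs = []
    factors = np.zeros((C, P, n))
    for c in range(C):
        block_factors = rng.standard_normal((max(len(blocks), 1), n))
        values = np.empty((n, len(gene_ids)))
        col = 0
        for i in range(P):
            own = rng.standard_normal(n)
            if i in block_of:
                f = w * block_factors[block_of[i]] + u * own
            else:
                f = own
            if i in planted_set:
                f = f + spec.effect_size * labels
            factors[c, i] = f
            g = sizes[i]
            values[:, col:col + g] = (lam * f[:, None]
                                      + noise_sd * rng.standard_normal((n, g)))
            col += g
        exprs.append(ExpressionMatrix(sample_ids, list(gene_ids), values,
                                      omics_name=f"omics{c + 1}"))

    cov = 30.0 - 10.0 * spec.covariate_effect * labels \
        + 10.0 * rng.standard_normal(n)
    annotations = SampleAnnotations(
        sample_ids, labels,
        pd.DataFrame({"smoking_age": cov}), positive_label="case")
    ground_truth = {
        "planted": planted, "effect_size": spec.effect_size, "rho": spec.rho,
        "seed": spec.seed, "blocks": blocks, "block_weight": spec.block_weight,
        "factors": factors,
    }
    return SyntheticCohort(exprs, annotations,
                           PathwayCollection(pathway_defs), ground_truth)


def generate_block_structure(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Cohort with correlated pathway blocks (requires block_sizes set)."""
    if not spec.block_sizes:
        raise ValueError("spec.block_sizes must be non-empty")
    if spec.block_weight <= 0:
        raise ValueError("block_weight must be positive for block structure")
    return generate_cohort(spec)
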