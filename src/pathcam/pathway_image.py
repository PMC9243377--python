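"""Per-pathway PCA and assembly of per-sample pathway images.

Each gene set defines a sample x gene submatrix B (n x r_i).  A PCA fitted
on training samples reduces B to q principal-component scores per sample.
Stacking the q-score blocks over all P retained pathways and C omics types
yields, per sample, a C x P x q tensor — the "pathway image" fed to the
classifier.  Pixels are min-max scaled to [0, 1] with training-set
statistics; held-out samples are clipped into the same range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, PathwayCollection

logger = logging.getLogger("pathcam")

__all__ = [
    "PathwayProjection",
    "PathwayImageSet",
    "fit_pathway_projection",
    "transform_pathway",
    "fit_all_projections",
    "build_image_set",
    "merged_score_matrix",
]


@dataclass
class PathwayProjection:
    """A fitted per-pathway PCA: centering vector plus orthonormal loadings.

    ``usable`` is False when fewer than 2 pathway genes were present in the
    omics matrix; such a pathway contributes a constant pixel row (0.5 after
    scaling).
    """

    pathway_name: str
    omics_name: str
    gene_ids: list[str]
    center: np.ndarray          # (r_i,)
    loadings: np.ndarray        # (r_i, q); deficient columns zero-padded
    explained_variance: np.ndarray  # (q,) fractions of total variance
    usable: bool = True


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|entry| of each column positive."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        if col.any():
            k = int(np.argmax(np.abs(col)))
            if col[k] < 0:
                out[:, j] = -col
    return out


def fit_pathway_projection(
    expr: ExpressionMatrix,
    pathway: tuple[str, frozenset[str]],
    q: int,
) -> PathwayProjection:
    """Fit the top-q PCA of one pathway's gene submatrix.

    Loadings are eigenvectors of the gene-centered covariance; components
    beyond the matrix rank are zero-padded so the image stays rectangular.
    """
    name, genes = pathway
    present = [g for g in expr.gene_ids if g in genes]
    if len(present) < 2:
        logger.info("pathway %s unusable for omics %s (%d genes present)",
                    name, expr.omics_name, len(present))
        return PathwayProjection(
            name, expr.omics_name, present,
            center=np.zeros(len(present)),
            loadings=np.zeros((len(present), q)),
            explained_variance=np.zeros(q),
            usable=False,
        )
    B = expr.gene_submatrix(present)
    center = B.mean(axis=0)
    X = B - center
    # SVD of the centered matrix == eigendecomposition of the covariance
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    total = var.sum()
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    k = min(q, rank)
    loadings = np.zeros((len(present), q))
    evr = np.zeros(q)
    if k:
        loadings[:, :k] = vt[:k].T
        evr[:k] = var[:k] / total if total > 0 else 0.0
    return PathwayProjection(
        name, expr.omics_name, present, center,
        _fix_signs(loadings), evr, usable=True,
    )


def transform_pathway(expr: ExpressionMatrix, proj: PathwayProjection) -> np.ndarray:
    """Project samples onto a fitted pathway PCA; returns (n, q) scores."""
    if not proj.usable:
        return np.zeros((expr.n_samples, proj.loadings.shape[1]))
    B = expr.gene_submatrix(proj.gene_ids)
    return (B - proj.center) @ proj.loadings


def fit_all_projections(
    exprs: list[ExpressionMatrix],
    pathways: PathwayCollection,
    q: int,
) -> dict[tuple[str, str], PathwayProjection]:
    """Fit one projection per (pathway, omics) pair on the given samples."""
    return {
        (name, expr.omics_name): fit_pathway_projection(expr, (name, genes), q)
        for expr in exprs
        for name, genes in pathways.pathways
    }


@dataclass
class PathwayImageSet:
    """Per-sample pathway images: an n x C x P x q tensor in [0, 1]."""

    sample_ids: list[str]
    tensor: np.ndarray          # (n, C, P, q), scaled to [0, 1]
    pathway_order: list[str]
    omics_names: list[str]
    scale_min: np.ndarray       # (C, P, q) training minima
    scale_max: np.ndarray       # (C, P, q) training maxima

    def __post_init__(self) -> None:
        n, C, P, q = self.tensor.shape
        if len(self.sample_ids) != n or len(self.pathway_order) != P \
                or len(self.omics_names) != C:
            raise ValueError("tensor shape inconsistent with labels")
        if not np.all(np.isfinite(self.tensor)):
            raise ValueError("non-finite pixels")

    @property
    def n_samples(self) -> int:
        return self.tensor.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.tensor.shape

    def flat_images(self) -> np.ndarray:
        """(n, P, C*q) view: omics types as contiguous column blocks.

        Column c*q + k holds omics channel c, principal component k; this is
        the "P rows by C·q columns" display/classifier layout.
        """
        n, C, P, q = self.tensor.shape
        return self.tensor.transpose(0, 2, 1, 3).reshape(n, P, C * q)

    def subset_samples(self, idx) -> "PathwayImageSet":
        idx = list(idx)
        return PathwayImageSet(
            [self.sample_ids[i] for i in idx], self.tensor[idx],
            self.pathway_order, self.omics_names,
            self.scale_min, self.scale_max,
        )


def build_image_set(
    exprs: list[ExpressionMatrix],
    pathways: PathwayCollection,
    q: int,
    order: list[str] | None,
    projections: dict[tuple[str, str], PathwayProjection],
    scaling: tuple[np.ndarray, np.ndarray] | None = None,
) -> PathwayImageSet:
    """Assemble pathway images for the samples in ``exprs``.

    ``order`` gives the pathway row sequence (defaults to collection order).
    When ``scaling`` is None, per-pixel min/max are fitted on these samples
    (training use); otherwise the provided training statistics are applied
    and values are clipped to [0, 1] (held-out use).  Degenerate pixels
    (min == max) map to 0.5.
    """
    if not exprs:
        raise ValueError("no omics matrices given")
    sample_ids = list(exprs[0].sample_ids)
    for e in exprs[1:]:
        if list(e.sample_ids) != sample_ids:
            raise ValueError(
                f"sample IDs of omics {e.omics_name!r} do not match "
                f"{exprs[0].omics_name!r}"
            )
    order = list(order) if order is not None else pathways.names
    if sorted(order) != sorted(pathways.names):
        raise ValueError("order is not a permutation of the pathway collection")
    n = len(sample_ids)
    C, P = len(exprs), len(order)
    raw = np.zeros((n, C, P, q))
    unusable = np.zeros((C, P), dtype=bool)
    for c, expr in enumerate(exprs):
        for p, name in enumerate(order):
            proj = projections[(name, expr.omics_name)]
            raw[:, c, p, :] = transform_pathway(expr, proj)
            unusable[c, p] = not proj.usable
    if scaling is None:
        smin = raw.min(axis=0)
        smax = raw.max(axis=0)
    else:
        smin, smax = scaling
    span = smax - smin
    degenerate = span <= 0
    safe_span = np.where(degenerate, 1.0, span)
    scaled = (raw - smin[None]) / safe_span[None]
    scaled = np.where(degenerate[None], 0.5, scaled)
    scaled[:, unusable, :] = 0.5
    np.clip(scaled, 0.0, 1.0, out=scaled)
    return PathwayImageSet(sample_ids, scaled, order, [e.omics_name for e in exprs],
                           smin.copy(), smax.copy())


def merged_score_matrix(
    exprs: list[ExpressionMatrix],
    pathways: PathwayCollection,
    projections: dict[tuple[str, str], PathwayProjection],
    q: int,
) -> np.ndarray:
    """Unscaled merged score matrix, n x (P * C * q).

    Pathway p occupies the contiguous column block [p*C*q, (p+1)*C*q) — all
    omics types' PC scores for that pathway — as used by pathway ordering.
    """
    n = exprs[0].n_samples
    P, C = len(pathways), len(exprs)
    out = np.zeros((n, P * C * q))
    for p, (name, _) in enumerate(pathways.pathways):
        for c, expr in enumerate(exprs):
            scores = transform_pathway(expr, projections[(name, expr.omics_name)])
            out[:, (p * C + c) * q:(p * C + c + 1) * q] = scores
    return out
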