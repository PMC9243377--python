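"""Reading and writing of expression matrices, gene sets, annotations and
pathway-image containers.

All expression data are held samples-in-rows regardless of how the file on
disk is oriented.  Missing values are handled at read time: rows or columns
with more than half of their entries missing are dropped, and remaining gaps
are imputed with the gene's median across the observed samples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pathcam")

__all__ = [
    "ExpressionMatrix",
    "PathwayCollection",
    "SampleAnnotations",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "read_sample_annotations",
    "write_sample_annotations",
    "save_image_set",
    "load_image_set",
]


@dataclass
class ExpressionMatrix:
    """A sample x gene numeric matrix for one omics type."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray  # shape (n_samples, n_genes)
    omics_name: str = "expression"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, r = self.values.shape
        if len(self.sample_ids) != n or len(self.gene_ids) != r:
            raise ValueError(
                f"value matrix {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if len(set(self.gene_ids)) != r:
            raise ValueError("duplicate gene IDs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values after missing-value handling")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = list(idx)
        return ExpressionMatrix(
            [self.sample_ids[i] for i in idx],
            list(self.gene_ids),
            self.values[idx],
            self.omics_name,
        )

    def gene_submatrix(self, genes: Sequence[str]) -> np.ndarray:
        """Columns for the given genes, in the given order."""
        pos = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return self.values[:, [pos[g] for g in genes]]


@dataclass
class PathwayCollection:
    """An ordered list of named gene sets."""

    pathways: list[tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.pathways]
        if len(set(names)) != len(names):
            raise ValueError("duplicate pathway names")
        for name, genes in self.pathways:
            if not genes:
                raise ValueError(f"pathway {name!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.pathways)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.pathways]

    def genes_of(self, name: str) -> frozenset[str]:
        for n, g in self.pathways:
            if n == name:
                return g
        raise KeyError(name)


@dataclass
class SampleAnnotations:
    """Per-sample binary outcome label plus optional numeric covariates."""

    sample_ids: list[str]
    labels: np.ndarray  # 0/1 per sample
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    positive_label: str = "1"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels length mismatch")
        if not np.all(np.isin(self.labels, [0, 1])):
            raise ValueError("labels must be 0/1")
        if len(self.covariates) not in (0, len(self.sample_ids)):
            raise ValueError("covariate rows do not match samples")
        if len(self.covariates):
            self.covariates = self.covariates.astype(float)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def covariate_matrix(self) -> np.ndarray:
        if not len(self.covariates.columns):
            return np.zeros((self.n_samples, 0))
        return self.covariates.to_numpy(dtype=float)

    def subset(self, idx: Sequence[int]) -> "SampleAnnotations":
        idx = list(idx)
        cov = (
            self.covariates.iloc[idx].reset_index(drop=True)
            if len(self.covariates)
            else pd.DataFrame()
        )
        return SampleAnnotations(
            [self.sample_ids[i] for i in idx],
            self.labels[idx],
            cov,
            self.positive_label,
        )

    def aligned_to(self, sample_ids: Sequence[str]) -> "SampleAnnotations":
        """Reorder to the given sample IDs; every ID must be annotated."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValueError(f"samples without annotations: {missing[:5]}")
        return self.subset([pos[s] for s in sample_ids])


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_expression_matrix(
    path: str | Path,
    omics_name: str = "expression",
    orientation: str = "samples_in_rows",
) -> ExpressionMatrix:
    """Read a delimited expression matrix (IDs in the first row and column).

    ``orientation`` states how the *file* is laid out; the returned matrix is
    always samples-in-rows.  Rows/columns with >50% missing entries are
    dropped; remaining missing values are imputed with the gene median.
    """
    path = Path(path)
    if orientation not in ("samples_in_rows", "genes_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0,
                     float_precision="round_trip")
    if orientation == "genes_in_rows":
        df = df.T
    # now samples in rows
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs: {dupes[:5]}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        bad = df.apply(pd.to_numeric, errors="coerce")
        where = np.argwhere(bad.isna().to_numpy() & df.notna().to_numpy())
        if len(where):
            i, j = where[0]
            raise ValueError(
                f"malformed numeric cell at sample {df.index[i]!r}, "
                f"gene {df.columns[j]!r}: {df.iat[i, j]!r}"
            ) from exc
        raise
    miss = ~np.isfinite(values)
    keep_rows = miss.mean(axis=1) <= 0.5
    keep_cols = miss.mean(axis=0) <= 0.5
    if not keep_rows.all() or not keep_cols.all():
        logger.info(
            "%s: dropped %d samples and %d genes with >50%% missing values",
            path.name, int((~keep_rows).sum()), int((~keep_cols).sum()),
        )
    values = values[keep_rows][:, keep_cols]
    sample_ids = [str(s) for s in df.index[keep_rows]]
    gene_ids = [str(g) for g in df.columns[keep_cols]]
    miss = ~np.isfinite(values)
    if miss.any():
        medians = np.nanmedian(np.where(miss, np.nan, values), axis=0)
        values = np.where(miss, medians[None, :], values)
        logger.info("%s: imputed %d missing cells with gene medians",
                    path.name, int(miss.sum()))
    return ExpressionMatrix(sample_ids, gene_ids, values, omics_name)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write samples-in-rows TSV with an ID header row and column."""
    df = pd.DataFrame(expr.values, index=expr.sample_ids, columns=expr.gene_ids)
    df.to_csv(path, sep="\t", index_label="sample")


def read_gene_sets(
    path: str | Path,
    min_genes: int = 1,
    max_genes: int = 500,
    universe: set[str] | None = None,
) -> PathwayCollection:
    """Parse a GMT file, intersect with a gene universe and size-filter.

    GMT: one set per line, tab-separated fields — name, description
    (ignored), then member genes.  File order is preserved.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not any(line.strip() for line in lines):
        raise ValueError(f"empty GMT file: {path}")
    pathways: list[tuple[str, frozenset[str]]] = []
    for ln, line in enumerate(lines, 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            logger.warning("%s line %d: fewer than 3 fields, skipped", path.name, ln)
            continue
        name = fields[0]
        genes = {g for g in fields[2:] if g}
        if universe is not None:
            genes &= set(universe)
        if min_genes <= len(genes) <= max_genes:
            pathways.append((name, frozenset(genes)))
    return PathwayCollection(pathways)


def write_gene_sets(coll: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in coll.pathways:
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def read_sample_annotations(
    path: str | Path,
    sample_col: str = "sample",
    class_col: str = "label",
    positive_label: str | None = None,
) -> SampleAnnotations:
    """Read a sample table with a binary class column and numeric covariates.

    The positive class maps to 1; by default it is the lexicographically
    later of the two observed class values (always recorded on the result).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    for col in (sample_col, class_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path.name}")
    classes = sorted(df[class_col].astype(str).unique())
    if len(classes) != 2:
        raise ValueError(
            f"class column must have exactly 2 values, got {classes}"
        )
    if positive_label is None:
        positive_label = classes[-1]
        logger.info("positive class defaulted to %r (lexicographically later)",
                    positive_label)
    elif positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not in {classes}")
    labels = (df[class_col].astype(str) == positive_label).astype(int).to_numpy()
    cov_cols = [c for c in df.columns if c not in (sample_col, class_col)]
    cov = df[cov_cols].apply(pd.to_numeric, errors="raise") if cov_cols else pd.DataFrame()
    return SampleAnnotations(
        [str(s) for s in df[sample_col]], labels, cov, positive_label
    )


def write_sample_annotations(ann: SampleAnnotations, path: str | Path,
                             class_names: tuple[str, str] = ("neg", "pos")) -> None:
    df = pd.DataFrame({"sample": ann.sample_ids,
                       "label": [class_names[l] for l in ann.labels]})
    for col in ann.covariates.columns:
        df[col] = ann.covariates[col].to_numpy()
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pathway-image container: a directory holding one flat binary tensor file
# per array plus a JSON sidecar with names, order and scaling parameters.
# ---------------------------------------------------------------------------

def save_image_set(images, out_dir: str | Path) -> None:
    """Serialize a PathwayImageSet to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images.tensor.astype("<f8").tofile(out_dir / "tensor.bin")
    images.scale_min.astype("<f8").tofile(out_dir / "scale_min.bin")
    images.scale_max.astype("<f8").tofile(out_dir / "scale_max.bin")
    meta = {
        "shape": list(images.tensor.shape),
        "dims": ["sample", "omics", "pathway", "pc"],
        "sample_ids": images.sample_ids,
        "pathway_order": images.pathway_order,
        "omics_names": images.omics_names,
        "q": images.tensor.shape[3],
        "dtype": "<f8",
    }
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=2))


def load_image_set(in_dir: str | Path):
    from .pathway_image import PathwayImageSet  # circular at import time

    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "meta.json").read_text())
    shape = tuple(meta["shape"])
    tensor = np.fromfile(in_dir / "tensor.bin", dtype=meta["dtype"]).reshape(shape)
    smin = np.fromfile(in_dir / "scale_min.bin", dtype=meta["dtype"]).reshape(shape[1:])
    smax = np.fromfile(in_dir / "scale_max.bin", dtype=meta["dtype"]).reshape(shape[1:])
    return PathwayImageSet(
        sample_ids=meta["sample_ids"],
        tensor=tensor,
        pathway_order=meta["pathway_order"],
        omics_names=meta["omics_names"],
        scale_min=smin,
        scale_max=smax,
    )
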