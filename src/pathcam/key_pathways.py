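"""From class-activation maps to a ranked table of key pathways.

Every sample yields two activation maps (one per class); their absolute
difference D_i = |L_i^pos - L_i^neg| is the per-sample evidence map.  At
each pixel the D values of the two outcome groups are compared with a
two-sided Wilcoxon rank-sum test; p-values are Bonferroni-corrected over
all pixels, significant pixels are grouped into 4-connected hotspots per
omics channel, and pathways owning significant pixels are tabulated with
their adjusted p per (omics, PC) cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io import SampleAnnotations
from .pathway_image import PathwayImageSet
from .att_cnn import TrainedModel
from .xgradcam import (ActivationMap, compute_activation_maps,
                       normalize_pair_and_upsample)

__all__ = [
    "DifferenceMapSet",
    "Hotspot",
    "PixelTestResult",
    "difference_maps",
    "wilcoxon_rank_sum",
    "pixelwise_test",
    "bonferroni_adjust",
    "find_hotspots",
    "rank_pathways",
    "identify_key_pathways",
]

FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class DifferenceMapSet:
    """Per-sample |L^pos - L^neg| maps plus the outcome partition."""

    sample_ids: list[str]
    maps: np.ndarray        # (n, P, C*q) in [0, 1]
    labels: np.ndarray      # 0/1 per sample
    pathway_order: list[str]
    omics_names: list[str]
    q: int

    def __post_init__(self) -> None:
        if self.maps.shape[0] != len(self.labels):
            raise ValueError("map count does not match label count")

    def group(self, label: int) -> np.ndarray:
        return self.maps[self.labels == label]


def difference_maps(
    pos_maps: ActivationMap,
    neg_maps: ActivationMap,
    annotations: SampleAnnotations,
    pathway_order: list[str],
    omics_names: list[str],
    q: int,
    shared_scale: bool = True,
) -> DifferenceMapSet:
    """Elementwise |L^pos - L^neg| per sample, partitioned by true label.

    With ``shared_scale`` (default) the two raw class maps of each sample
    are min-max normalized on a common scale before differencing, so the
    relative activation of the two classes is preserved; otherwise the
    per-map normalized fields are differenced directly.
    """
    if pos_maps.normalized.shape != neg_maps.normalized.shape:
        raise ValueError("class map shapes differ")
    if pos_maps.sample_ids != neg_maps.sample_ids:
        raise ValueError("class maps cover different samples")
    ann = annotations.aligned_to(pos_maps.sample_ids)
    if shared_scale:
        target = pos_maps.normalized.shape[1:]
        L_pos, L_neg = normalize_pair_and_upsample(pos_maps.raw, neg_maps.raw,
                                                   target)
    else:
        L_pos, L_neg = pos_maps.normalized, neg_maps.normalized
    D = np.abs(L_pos - L_neg)
    return DifferenceMapSet(list(pos_maps.sample_ids), D, ann.labels,
                            pathway_order, omics_names, q)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration for combined n <= 12 without ties; otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return 1.0
    no_ties = len(np.unique(combined)) == combined.size
    method = "exact" if (combined.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


@dataclass
class Hotspot:
    """A 4-connected region of significant pixels within one omics channel."""

    omics_index: int
    pixels: list[tuple[int, int]]   # (pathway row, PC column) within channel

    @property
    def size(self) -> int:
        return len(self.pixels)


@dataclass
class PixelTestResult:
    """Per-pixel Wilcoxon statistics on the P x (C*q) difference-map grid."""

    raw_p: np.ndarray        # (P, C*q)
    adjusted_p: np.ndarray   # Bonferroni, capped at 1
    degenerate: np.ndarray   # pixels identical across both groups
    n_tests: int
    pathway_order: list[str]
    omics_names: list[str]
    q: int
    alpha: float = 0.001
    hotspots: list[Hotspot] = field(default_factory=list)
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def significance_mask(self) -> np.ndarray:
        return self.adjusted_p < self.alpha


def pixelwise_test(diffs: DifferenceMapSet) -> PixelTestResult:
    """One Wilcoxon rank-sum test per pixel, positive vs negative group."""
    pos = diffs.group(1)
    neg = diffs.group(0)
    if pos.shape[0] < 2 or neg.shape[0] < 2:
        raise ValueError("each outcome group needs at least 2 samples")
    n_comb = pos.shape[0] + neg.shape[0]
    P, W = diffs.maps.shape[1:]
    degenerate = np.ptp(diffs.maps, axis=0) == 0
    if n_comb <= 12:
        raw = np.ones((P, W))
        for i in range(P):
            for j in range(W):
                if not degenerate[i, j]:
                    raw[i, j] = wilcoxon_rank_sum(pos[:, i, j], neg[:, i, j])
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.mannwhitneyu(
                pos, neg, axis=0, alternative="two-sided",
                method="asymptotic", use_continuity=True)
        raw = np.where(degenerate | ~np.isfinite(res.pvalue), 1.0, res.pvalue)
    m = P * W
    return PixelTestResult(
        raw_p=raw, adjusted_p=bonferroni_adjust(raw, m), degenerate=degenerate,
        n_tests=m, pathway_order=diffs.pathway_order,
        omics_names=diffs.omics_names, q=diffs.q)


def bonferroni_adjust(raw: np.ndarray, m: int | None = None) -> np.ndarray:
    """Family-wise correction: adjusted = min(1, p * m), m = pixels tested."""
    raw = np.asarray(raw, dtype=float)
    if m is None:
        m = raw.size
    return np.minimum(1.0, raw * m)


def find_hotspots(adjusted: np.ndarray, alpha_sig: float, min_size: int,
                  q: int) -> list[Hotspot]:
    """4-connected components of significant pixels, per omics channel.

    ``adjusted`` is the P x (C*q) adjusted-p grid with omics channels as
    contiguous q-column blocks; components smaller than ``min_size`` are
    discarded.
    """
    if not 0 < alpha_sig < 1:
        raise ValueError("alpha_sig must be in (0, 1)")
    P, W = adjusted.shape
    C = W // q
    hotspots: list[Hotspot] = []
    for c in range(C):
        block = adjusted[:, c * q:(c + 1) * q] < alpha_sig
        labels, n_comp = ndimage.label(block, structure=FOUR_CONNECTED)
        for comp in range(1, n_comp + 1):
            rows, cols = np.nonzero(labels == comp)
            if len(rows) >= min_size:
                hotspots.append(Hotspot(c, list(zip(rows.tolist(), cols.tolist()))))
    return hotspots


def rank_pathways(result: PixelTestResult, alpha_sig: float | None = None) -> pd.DataFrame:
    """Tabulate pathways owning significant pixels, sorted by image row.

    One row per pathway with >= 1 significant pixel; one column per
    (omics, PC) cell holding the adjusted p where significant, blank (NaN)
    elsewhere.  ``row`` is the 1-based pathway-image row index.
    """
    alpha = result.alpha if alpha_sig is None else alpha_sig
    mask = result.adjusted_p < alpha
    q = result.q
    records = []
    for p_row in np.nonzero(mask.any(axis=1))[0]:
        rec: dict = {"row": int(p_row) + 1,
                     "pathway": result.pathway_order[p_row]}
        for c, omics in enumerate(result.omics_names):
            for k in range(q):
                col = c * q + k
                rec[f"{omics}_PC{k + 1}"] = (
                    result.adjusted_p[p_row, col] if mask[p_row, col] else np.nan)
        records.append(rec)
    cols = ["row", "pathway"] + [f"{o}_PC{k + 1}"
                                 for o in result.omics_names for k in range(q)]
    return pd.DataFrame.from_records(records, columns=cols)


def identify_key_pathways(
    trained: TrainedModel,
    images: PathwayImageSet,
    annotations: SampleAnnotations,
    alpha_sig: float = 0.001,
    min_size: int = 1,
    layer: str = "attended_input",
) -> tuple[DifferenceMapSet, PixelTestResult]:
    """Full interpretation stage: CAM pairs -> difference maps -> statistics.

    The supplied model should be the interpretation model trained on all
    samples; its output is used for attribution only, never for
    performance claims.  ``layer`` selects the CAM target: the default
    "attended_input" attributes at full pathway-image resolution, which
    keeps one pixel per (pathway, omics, PC) cell; "conv" uses the
    conventional conv-layer target.
    """
    ann = annotations.aligned_to(images.sample_ids)
    cov = ann.covariate_matrix() if trained.spec.n_covariates else None
    pos = compute_activation_maps(trained, images, cov, class_index=1, layer=layer)
    neg = compute_activation_maps(trained, images, cov, class_index=0, layer=layer)
    q = images.tensor.shape[3]
    diffs = difference_maps(pos, neg, ann, images.pathway_order,
                            images.omics_names, q)
    result = pixelwise_test(diffs)
    result.alpha = alpha_sig
    result.hotspots = find_hotspots(result.adjusted_p, alpha_sig, min_size, q)
    result.table = rank_pathways(result, alpha_sig)
    return diffs, result
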