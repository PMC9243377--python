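"""Greedy correlation-based pathway ordering.

Pathway images use one shared row sequence chosen so that correlated
pathways sit on adjacent rows, letting the convolutional classifier and the
class-activation maps exploit local structure.  Similarity between two
pathways is the mean absolute Pearson correlation over all pairs of their
PC score columns (PC signs are arbitrary, so the absolute value is used by
default); the order is a deterministic greedy chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PathwayOrder", "compute_pathway_similarity", "order_pathways"]


@dataclass
class PathwayOrder:
    """A permutation of pathway names plus the similarity matrix behind it."""

    ordered_names: list[str]
    similarity: np.ndarray  # (P, P), symmetric, unit diagonal

    def __post_init__(self) -> None:
        P = len(self.ordered_names)
        if self.similarity.shape != (P, P):
            raise ValueError("similarity shape does not match pathway count")


def compute_pathway_similarity(
    merged_scores: np.ndarray,
    block_width: int,
    absolute: bool = True,
) -> np.ndarray:
    """P x P pathway similarity from a merged n x (P*block_width) score matrix.

    Column block p holds pathway p's PC score columns (all omics types).
    similarity(a, b) = mean over all block-column pairs of |Pearson r|
    (signed r when ``absolute`` is False); zero-variance columns contribute
    0 to the mean.  Requires n >= 3 samples.
    """
    merged_scores = np.asarray(merged_scores, dtype=float)
    n, m = merged_scores.shape
    if n < 3:
        raise ValueError(f"need at least 3 samples for correlations, got {n}")
    if m % block_width:
        raise ValueError("column count is not a multiple of block_width")
    P = m // block_width
    sd = merged_scores.std(axis=0)
    nonzero = sd > 0
    X = merged_scores - merged_scores.mean(axis=0)
    X[:, nonzero] /= sd[nonzero] * np.sqrt(n)
    X[:, ~nonzero] = 0.0
    corr = X.T @ X  # zero-variance columns yield 0 rows/cols
    if absolute:
        corr = np.abs(corr)
    sim = corr.reshape(P, block_width, P, block_width).mean(axis=(1, 3))
    sim = (sim + sim.T) / 2
    np.fill_diagonal(sim, 1.0)
    return sim


def order_pathways(sim: np.ndarray, names: list[str] | None = None) -> PathwayOrder:
    """Deterministic greedy chain over a symmetric similarity matrix.

    Start at the pathway with the largest total off-diagonal similarity;
    repeatedly append the unselected pathway most similar to the most
    recently placed one.  All ties break to the lowest original index.
    """
    sim = np.asarray(sim, dtype=float)
    P = sim.shape[0]
    if sim.shape != (P, P) or not np.allclose(sim, sim.T, atol=1e-10):
        raise ValueError("similarity matrix must be square and symmetric")
    if names is None:
        names = [str(i) for i in range(P)]
    if len(names) != P:
        raise ValueError("names length does not match matrix")
    off = sim.copy()
    np.fill_diagonal(off, 0.0)
    totals = off.sum(axis=1)
    current = int(np.argmax(totals))  # argmax ties -> lowest index
    chain = [current]
    remaining = np.ones(P, dtype=bool)
    remaining[current] = False
    while remaining.any():
        cand = np.where(remaining, sim[current], -np.inf)
        current = int(np.argmax(cand))
        chain.append(current)
        remaining[current] = False
    return PathwayOrder([names[i] for i in chain], sim)
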