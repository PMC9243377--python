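"""Repeated stratified five-fold cross-validation with AUC scoring.

Every fold is leak-free: pathway projections, pixel scaling and the
pathway ordering are refitted on the fold's training samples only, a
stratified validation subset of the training portion drives early
stopping, and the held-out fold is scored with the training fold's frozen
transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .io import ExpressionMatrix, PathwayCollection, SampleAnnotations
from .att_cnn import ModelSpec, train_model, predict
from .ordering import compute_pathway_similarity, order_pathways
from .pathway_image import (build_image_set, fit_all_projections,
                            merged_score_matrix)

__all__ = ["CVResult", "stratified_kfold_split", "auc", "repeated_cv",
           "fit_fold_transforms"]

_SEED_MOD = 2**31 - 1


@dataclass
class CVResult:
    """Per-repeat, per-fold test AUCs and their summary."""

    aucs: np.ndarray          # (repeats, k)
    k: int
    repeats: int
    seed: int
    spec: ModelSpec

    @property
    def mean(self) -> float:
        return float(self.aucs.mean())

    @property
    def std(self) -> float:
        return float(self.aucs.std(ddof=1)) if self.aucs.size > 1 else 0.0


def stratified_kfold_split(labels: np.ndarray, k: int, seed: int,
                           val_fraction: float = 0.2):
    """Stratified k test folds, each with a validation subset of its train.

    Returns a list of (train_idx, val_idx, test_idx) triples; val is a
    stratified ``val_fraction`` share carved out of the non-test portion.
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"smallest class ({counts.min()}) has fewer members than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % _SEED_MOD)
    rng = np.random.default_rng(seed)
    folds = []
    for rest_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
        val: list[int] = []
        for cls in (0, 1):
            cls_idx = rest_idx[labels[rest_idx] == cls]
            cls_idx = cls_idx[rng.permutation(len(cls_idx))]
            n_val = max(1, int(round(val_fraction * len(cls_idx))))
            val.extend(cls_idx[:n_val].tolist())
        val_set = set(val)
        train = np.array([i for i in rest_idx if i not in val_set])
        folds.append((train, np.array(sorted(val)), test_idx))
    return folds


def auc(scores, labels) -> float:
    """Area under the ROC curve (Mann–Whitney with half-tie counting)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def fit_fold_transforms(
    exprs: list[ExpressionMatrix],
    pathways: PathwayCollection,
    q: int,
    train_idx: np.ndarray,
    frozen_order: list[str] | None = None,
):
    """Fit projections, pathway order and pixel scaling on training samples.

    Returns (projections, order_names, train_images); the image set carries
    the training scaling used to transform any other samples.
    """
    train_exprs = [e.subset_samples(train_idx) for e in exprs]
    projections = fit_all_projections(train_exprs, pathways, q)
    if frozen_order is None:
        merged = merged_score_matrix(train_exprs, pathways, projections, q)
        sim = compute_pathway_similarity(merged, block_width=len(exprs) * q)
        order_names = order_pathways(sim, pathways.names).ordered_names
    else:
        order_names = list(frozen_order)
    train_images = build_image_set(train_exprs, pathways, q, order_names,
                                   projections)
    return projections, order_names, train_images


def repeated_cv(
    exprs: list[ExpressionMatrix],
    pathways: PathwayCollection,
    annotations: SampleAnnotations,
    spec: ModelSpec,
    q: int,
    k: int = 5,
    repeats: int = 30,
    seed: int = 0,
    val_fraction: float = 0.2,
    frozen_order: list[str] | None = None,
) -> CVResult:
    """Repeat stratified k-fold CV of the full pipeline, scoring test AUC.

    Each fold refits projections/ordering/scaling on its training samples
    (unless ``frozen_order`` pins the row sequence) and trains a fresh
    model seeded from the fold's derived seed.
    """
    ann = annotations.aligned_to(exprs[0].sample_ids)
    y = ann.labels
    cov_all = ann.covariate_matrix()
    base = np.random.default_rng(seed)
    aucs = np.zeros((repeats, k))
    for rep in range(repeats):
        rep_seed = int(base.integers(_SEED_MOD))
        folds = stratified_kfold_split(y, k, rep_seed, val_fraction)
        for f, (tr, va, te) in enumerate(folds):
            fit_idx = np.concatenate([tr, va])
            projections, order_names, fit_images = fit_fold_transforms(
                exprs, pathways, q, fit_idx, frozen_order)
            fold_spec = replace(spec, seed=int(base.integers(_SEED_MOD)))
            pos = {s: i for i, s in enumerate(fit_images.sample_ids)}
            tr_local = np.array([pos[exprs[0].sample_ids[i]] for i in tr])
            va_local = np.array([pos[exprs[0].sample_ids[i]] for i in va])
            trained = train_model(fit_images, ann.subset(fit_idx), fold_spec,
                                  validation=(tr_local, va_local))
            test_exprs = [e.subset_samples(te) for e in exprs]
            test_images = build_image_set(
                test_exprs, pathways, q, order_names, projections,
                scaling=(fit_images.scale_min, fit_images.scale_max))
            probs = predict(trained, test_images,
                            cov_all[te] if spec.n_covariates else None)
            aucs[rep, f] = auc(probs[:, 1], y[te])
    return CVResult(aucs, k, repeats, seed, spec)
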