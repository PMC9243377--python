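"""X-Grad-CAM class-activation maps for the attention CNN.

For a class c and the conv activation F^l (K feature maps), each channel's
weight is the activation-normalized sum of logit gradients

    alpha_k = sum_{x,y} [ F_k(x,y) / sum_{x,y} F_k(x,y) ] * dS_c/dF_k(x,y)

and the raw map is the weighted channel sum M(x,y) = sum_k alpha_k F_k(x,y).
S_c is the pre-softmax logit.  The raw map is min-max normalized to [0, 1]
(a constant map becomes all zeros) and bilinearly upsampled to the input
pathway-image resolution P x (C*q), so each output pixel addresses one
(pathway row, omics type, PC) cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .att_cnn import TrainedModel
from .pathway_image import PathwayImageSet

__all__ = [
    "FeatureMapBundle",
    "ActivationMap",
    "extract_features_and_gradients",
    "xgrad_weights",
    "activation_map",
    "normalize_and_upsample",
    "normalize_pair_and_upsample",
    "compute_activation_maps",
]


@dataclass
class FeatureMapBundle:
    """Conv-layer activations, logit gradients and logits for one batch."""

    features: np.ndarray    # (n, K, H, W)
    gradients: np.ndarray   # (n, K, H, W): dS_c / dF
    logits: np.ndarray      # (n, 2)
    class_index: int

    def __post_init__(self) -> None:
        if self.features.shape != self.gradients.shape:
            raise ValueError("gradient tensor must match feature tensor shape")


@dataclass
class ActivationMap:
    """Per-sample class-activation maps at input resolution."""

    sample_ids: list[str]
    class_index: int
    weights: np.ndarray      # (n, K) channel weights alpha
    raw: np.ndarray          # (n, H, W) weighted channel sums
    normalized: np.ndarray   # (n, P, C*q) in [0, 1], upsampled


def extract_features_and_gradients(
    trained: TrainedModel,
    images: np.ndarray,
    covariates: np.ndarray | None,
    class_index: int,
    layer: str = "conv",
) -> FeatureMapBundle:
    """Forward + backward pass capturing F^l and dS_c/dF^l.

    ``layer`` selects the target activation: "conv" (the last convolutional
    activation, the conventional CAM target) or "attended_input" (the
    channel-attention output at full P x q resolution, which preserves
    pixel-level localization).  S_c is the pre-softmax logit for
    ``class_index``.
    """
    if class_index not in (0, 1):
        raise ValueError("class_index must be 0 or 1")
    feats, grads, logits = trained.model.features_and_logit_gradient(
        images, covariates, class_index, layer=layer)
    return FeatureMapBundle(feats, grads, logits, class_index)


def xgrad_weights(bundle: FeatureMapBundle) -> np.ndarray:
    """Channel weights alpha_k: activation-weighted gradient sums, (n, K).

    Channels whose activations sum to zero get alpha_k = 0 (the limit of a
    vanishing activation; avoids 0/0).
    """
    F, G = bundle.features, bundle.gradients
    denom = F.sum(axis=(2, 3))
    num = (F * G).sum(axis=(2, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(denom != 0, num / np.where(denom != 0, denom, 1.0), 0.0)
    return alpha


def activation_map(bundle: FeatureMapBundle, weights: np.ndarray) -> np.ndarray:
    """Raw maps M(x,y) = sum_k alpha_k F_k(x,y), (n, H, W); no rectification."""
    F = bundle.features
    if weights.shape != F.shape[:2]:
        raise ValueError(
            f"weights shape {weights.shape} does not match channels {F.shape[:2]}")
    return np.einsum("nk,nkhw->nhw", weights, F)


def _bilinear_upsample(M: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Align-corners bilinear interpolation of (n, h, w) maps to ``target``."""
    n, h, w = M.shape
    H, W = target

    def grid(src: int, dst: int) -> np.ndarray:
        if dst == 1 or src == 1:
            return np.zeros(dst)
        return np.linspace(0.0, src - 1.0, dst)

    gy, gx = grid(h, H), grid(w, W)
    y0 = np.clip(np.floor(gy).astype(int), 0, h - 1)
    x0 = np.clip(np.floor(gx).astype(int), 0, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    fy = (gy - y0)[None, :, None]
    fx = (gx - x0)[None, None, :]
    top = M[:, y0][:, :, x0] * (1 - fx) + M[:, y0][:, :, x1] * fx
    bot = M[:, y1][:, :, x0] * (1 - fx) + M[:, y1][:, :, x1] * fx
    return top * (1 - fy) + bot * fy


def normalize_and_upsample(M: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Min-max normalize each map to [0, 1], then bilinearly upsample.

    A constant map normalizes to all zeros.  ``M`` may be (h, w) or
    (n, h, w); the result matches with spatial shape ``target_shape``.
    """
    single = M.ndim == 2
    if single:
        M = M[None]
    lo = M.min(axis=(1, 2), keepdims=True)
    hi = M.max(axis=(1, 2), keepdims=True)
    span = hi - lo
    norm = np.where(span > 0, (M - lo) / np.where(span > 0, span, 1.0), 0.0)
    up = _bilinear_upsample(norm, target_shape)
    up = np.clip(up, 0.0, 1.0)
    return up[0] if single else up


def normalize_pair_and_upsample(
    M_pos: np.ndarray,
    M_neg: np.ndarray,
    target_shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a sample's two class maps on a shared [0, 1] scale.

    The min and max are taken over the union of both maps per sample, so
    "class 1 activates this pixel more than class 0" survives the
    normalization — the comparison the difference-map statistic relies on.
    Each map is then bilinearly upsampled to ``target_shape``.
    """
    if M_pos.shape != M_neg.shape:
        raise ValueError("class map shapes differ")
    lo = np.minimum(M_pos, M_neg).min(axis=(1, 2), keepdims=True)
    hi = np.maximum(M_pos, M_neg).max(axis=(1, 2), keepdims=True)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    L_pos = np.where(span > 0, (M_pos - lo) / safe, 0.0)
    L_neg = np.where(span > 0, (M_neg - lo) / safe, 0.0)
    return (np.clip(_bilinear_upsample(L_pos, target_shape), 0.0, 1.0),
            np.clip(_bilinear_upsample(L_neg, target_shape), 0.0, 1.0))


def compute_activation_maps(
    trained: TrainedModel,
    images: PathwayImageSet,
    covariates: np.ndarray | None,
    class_index: int,
    layer: str = "conv",
) -> ActivationMap:
    """Full X-Grad-CAM for every sample of an image set, one class."""
    cov = trained.standardize(covariates) if trained.spec.n_covariates else None
    bundle = extract_features_and_gradients(trained, images.tensor, cov,
                                            class_index, layer=layer)
    alpha = xgrad_weights(bundle)
    raw = activation_map(bundle, alpha)
    n, C, P, q = images.tensor.shape
    norm = normalize_and_upsample(raw, (P, C * q))
    return ActivationMap(list(images.sample_ids), class_index, alpha, raw, norm)
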