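"""Channel-attention CNN classifier for pathway images.

The model consumes per-sample pathway-image tensors (C omics channels x P
pathway rows x q PC columns) plus optional numeric covariates:

    input -> channel attention over the C omics channels
          -> channels laid out as column blocks of one P x (C*q) image
          -> dilated convolution (32 filters, 2x2 kernel, ReLU)
          -> 2x2 pooling (average and max branches, summed)
          -> dropout -> flatten -> concat standardized covariates
          -> dense 64 (ReLU) -> dropout -> dense 2 -> softmax

Channel attention pools each channel globally (average and max), passes
both descriptors through a shared two-layer perceptron and gates the
channels with the sigmoid of the summed outputs.  Training minimises
class-weighted cross-entropy with plain SGD, early-stopping on validation
AUC.

Forward and backward passes are written explicitly on NumPy arrays: every
gradient the training loop or the class-activation mapping needs is
computed in closed form, which keeps runs bit-reproducible for a fixed
seed and lets the interpretation stage read exact logit gradients at the
convolutional feature maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from sklearn.metrics import roc_auc_score

from .io import SampleAnnotations
from .pathway_image import PathwayImageSet

logger = logging.getLogger("pathcam")

__all__ = [
    "ModelSpec",
    "AttCnn",
    "TrainedModel",
    "build_model",
    "compute_class_weights",
    "train_model",
    "predict",
    "weighted_cross_entropy",
]


def _clamp_conv_geometry(size: int, kernel: int, dilation: int) -> tuple[int, int]:
    """Fit (kernel, dilation) into a spatial extent of ``size`` pixels.

    Dilation is reduced to 1 first, then the kernel is shrunk; narrow
    images (e.g. width 1 with a single omics type at q=1) therefore still
    admit a valid convolution.
    """
    if size < 1:
        raise ValueError(f"spatial size {size} < 1")
    if 1 + (kernel - 1) * dilation <= size:
        return kernel, dilation
    if kernel <= size:
        return kernel, 1
    return size, 1


@dataclass
class ModelSpec:
    """Hyperparameters of the attention CNN."""

    in_channels: int
    image_height: int           # P, pathway rows
    image_width: int            # q, PCs per omics channel
    n_covariates: int = 0
    r_att: int = 2              # channel-attention reduction ratio
    conv_filters: int = 32
    conv_kernel: tuple[int, int] = (2, 2)
    conv_dilation: int = 2
    dropout: float = 0.5
    dense_units: int = 64
    learning_rate: float = 0.001
    epochs: int = 200
    batch_size: int = 16
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if min(self.in_channels, self.image_height, self.image_width,
               self.conv_filters, self.dense_units) < 1:
            raise ValueError("model dimensions must be positive")
        kh, dh = _clamp_conv_geometry(self.image_height,
                                      self.conv_kernel[0], self.conv_dilation)
        W = self.in_channels * self.image_width
        kw, dw = _clamp_conv_geometry(W, self.conv_kernel[1], self.conv_dilation)
        if (kh, kw) != tuple(self.conv_kernel) or (dh, dw) != (self.conv_dilation,) * 2:
            logger.info(
                "conv geometry clamped to kernel (%d,%d), dilation (%d,%d) "
                "for image %dx%d", kh, kw, dh, dw, self.image_height, W)
        self._geometry = (kh, kw, dh, dw)

    @property
    def att_hidden(self) -> int:
        return max(1, self.in_channels // self.r_att)

    @property
    def conv_geometry(self) -> tuple[int, int, int, int]:
        """(kernel_h, kernel_w, dilation_h, dilation_w) actually used."""
        return self._geometry

    def feature_shape(self) -> tuple[int, int, int]:
        """(filters, H, W) of the conv activation (the CAM target layer)."""
        kh, kw, dh, dw = self._geometry
        H = self.image_height - (kh - 1) * dh
        W = self.in_channels * self.image_width - (kw - 1) * dw
        return self.conv_filters, H, W

    def pooled_shape(self) -> tuple[int, int, int]:
        F, H, W = self.feature_shape()
        return F, H // min(2, H), W // min(2, W)

    def flat_size(self) -> int:
        F, H, W = self.pooled_shape()
        return F * H * W


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class AttCnn:
    """The attention CNN with explicit parameter arrays and backprop."""

    PARAM_NAMES = ("att_W1", "att_b1", "att_W2", "att_b2",
                   "conv_W", "conv_b", "fc1_W", "fc1_b", "fc2_W", "fc2_b")

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        C, h = spec.in_channels, spec.att_hidden
        kh, kw, _, _ = spec.conv_geometry
        F = spec.conv_filters
        flat = spec.flat_size()
        d_in = flat + spec.n_covariates

        def glorot(fan_in, fan_out, shape):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, shape)

        self.params: dict[str, np.ndarray] = {
            "att_W1": glorot(C, h, (C, h)),
            "att_b1": np.zeros(h),
            "att_W2": glorot(h, C, (h, C)),
            "att_b2": np.zeros(C),
            "conv_W": rng.normal(0.0, np.sqrt(2.0 / (kh * kw)), (F, 1, kh, kw)),
            "conv_b": np.zeros(F),
            "fc1_W": rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, spec.dense_units)),
            "fc1_b": np.zeros(spec.dense_units),
            "fc2_W": glorot(spec.dense_units, 2, (spec.dense_units, 2)),
            "fc2_b": np.zeros(2),
        }

    # -- forward ----------------------------------------------------------

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def forward(self, images: np.ndarray, covariates: np.ndarray | None = None,
                train: bool = False, rng: np.random.Generator | None = None):
        """Run the network; returns (logits, cache) for backprop."""
        spec, P = self.params, self.spec
        x = np.asarray(images, dtype=float)
        if x.ndim != 4 or x.shape[1:] != (P.in_channels, P.image_height, P.image_width):
            raise ValueError(
                f"expected images (n, {P.in_channels}, {P.image_height}, "
                f"{P.image_width}), got {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite input image")
        n = x.shape[0]
        cov = np.zeros((n, 0)) if covariates is None else np.asarray(covariates, float)
        if cov.shape != (n, P.n_covariates):
            raise ValueError(
                f"expected covariates (n, {P.n_covariates}), got {cov.shape}")
        if train and rng is None:
            raise ValueError("training mode requires an rng for dropout")
        cache: dict = {"x": x, "cov": cov, "train": train}

        # channel attention
        avg = x.mean(axis=(2, 3))
        flat_sp = x.reshape(n, P.in_channels, -1)
        amax_idx = flat_sp.argmax(axis=2)
        mx = np.take_along_axis(flat_sp, amax_idx[:, :, None], axis=2)[:, :, 0]

        def mlp(v):
            pre = v @ spec["att_W1"] + spec["att_b1"]
            hid = np.maximum(pre, 0.0)
            return hid, hid @ spec["att_W2"] + spec["att_b2"]

        h_avg, o_avg = mlp(avg)
        h_max, o_max = mlp(mx)
        gate = _sigmoid(o_avg + o_max)
        att = x * gate[:, :, None, None]
        cache.update(avg=avg, mx=mx, amax_idx=amax_idx,
                     h_avg=h_avg, h_max=h_max, gate=gate, att=att)

        # channels -> column blocks of a single-channel image
        Wd = P.in_channels * P.image_width
        img = att.transpose(0, 2, 1, 3).reshape(n, 1, P.image_height, Wd)
        cache["img"] = img

        # dilated valid convolution
        kh, kw, dh, dw = P.conv_geometry
        F_, H, W = P.feature_shape()
        conv = np.broadcast_to(spec["conv_b"][None, :, None, None],
                               (n, F_, H, W)).copy()
        for ki in range(kh):
            for kj in range(kw):
                patch = img[:, :, ki * dh:ki * dh + H, kj * dw:kj * dw + W]
                conv += np.einsum("ncij,fc->nfij", patch,
                                  spec["conv_W"][:, :, ki, kj])
        relu = np.maximum(conv, 0.0)
        cache.update(conv=conv, relu=relu)

        # 2x2 pooling: average branch + max branch, summed
        ph, pw = min(2, H), min(2, W)
        Hp, Wp = H // ph, W // pw
        win = relu[:, :, :Hp * ph, :Wp * pw].reshape(n, F_, Hp, ph, Wp, pw)
        win = win.transpose(0, 1, 2, 4, 3, 5).reshape(n, F_, Hp, Wp, ph * pw)
        pool_avg = win.mean(axis=4)
        pmax_idx = win.argmax(axis=4)
        pool_max = np.take_along_axis(win, pmax_idx[..., None], axis=4)[..., 0]
        pooled = pool_avg + pool_max
        cache.update(pool_dims=(ph, pw, Hp, Wp), pmax_idx=pmax_idx, pooled=pooled)

        # dropout -> flatten -> covariates -> dense stack
        def dropout(v, key):
            if train and P.dropout > 0:
                mask = (rng.random(v.shape) >= P.dropout) / (1.0 - P.dropout)
            else:
                mask = None
            cache[key] = mask
            return v if mask is None else v * mask

        drop1 = dropout(pooled, "mask1").reshape(n, -1)
        u = np.concatenate([drop1, cov], axis=1)
        pre1 = u @ spec["fc1_W"] + spec["fc1_b"]
        hid1 = np.maximum(pre1, 0.0)
        drop2 = dropout(hid1, "mask2")
        logits = drop2 @ spec["fc2_W"] + spec["fc2_b"]
        cache.update(u=u, hid1=hid1, drop2=drop2, logits=logits)
        return logits, cache

    def predict_proba(self, images: np.ndarray,
                      covariates: np.ndarray | None = None) -> np.ndarray:
        logits, _ = self.forward(images, covariates, train=False)
        return softmax(logits)

    # -- backward ---------------------------------------------------------

    def backward(self, cache: dict, dlogits: np.ndarray):
        """Backprop from logit gradients.

        Returns (grads, d_feature) where ``grads`` maps parameter names to
        gradients and ``d_feature`` is the gradient at the conv activation
        (the CAM target layer).
        """
        spec, P = self.params, self.spec
        n = dlogits.shape[0]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}

        grads["fc2_W"] += cache["drop2"].T @ dlogits
        grads["fc2_b"] += dlogits.sum(axis=0)
        ddrop2 = dlogits @ spec["fc2_W"].T
        if cache["mask2"] is not None:
            ddrop2 = ddrop2 * cache["mask2"]
        dpre1 = ddrop2 * (cache["hid1"] > 0)
        grads["fc1_W"] += cache["u"].T @ dpre1
        grads["fc1_b"] += dpre1.sum(axis=0)
        du = dpre1 @ spec["fc1_W"].T
        flat = P.flat_size()
        ddrop1 = du[:, :flat].reshape(cache["pooled"].shape)
        if cache["mask1"] is not None:
            ddrop1 = ddrop1 * cache["mask1"]

        # pooling backward
        ph, pw, Hp, Wp = cache["pool_dims"]
        F_, H, W = P.feature_shape()
        dwin = np.broadcast_to(ddrop1[..., None] / (ph * pw),
                               (*ddrop1.shape, ph * pw)).copy()
        np.put_along_axis(
            dwin, cache["pmax_idx"][..., None],
            np.take_along_axis(dwin, cache["pmax_idx"][..., None], axis=4)
            + ddrop1[..., None], axis=4)
        drelu = np.zeros((n, F_, H, W))
        blocks = dwin.reshape(n, F_, Hp, Wp, ph, pw).transpose(0, 1, 2, 4, 3, 5)
        drelu[:, :, :Hp * ph, :Wp * pw] = blocks.reshape(n, F_, Hp * ph, Wp * pw)

        d_feature = drelu.copy()  # gradient at the conv activation
        dconv = drelu * (cache["conv"] > 0)

        # conv backward
        kh, kw, dh, dw = P.conv_geometry
        img = cache["img"]
        dimg = np.zeros_like(img)
        grads["conv_b"] += dconv.sum(axis=(0, 2, 3))
        for ki in range(kh):
            for kj in range(kw):
                patch = img[:, :, ki * dh:ki * dh + H, kj * dw:kj * dw + W]
                grads["conv_W"][:, :, ki, kj] += np.einsum(
                    "nfij,ncij->fc", dconv, patch)
                dimg[:, :, ki * dh:ki * dh + H, kj * dw:kj * dw + W] += \
                    np.einsum("nfij,fc->ncij", dconv, spec["conv_W"][:, :, ki, kj])

        # undo the channel -> column-block layout
        datt = dimg.reshape(n, P.image_height, P.in_channels,
                            P.image_width).transpose(0, 2, 1, 3)
        cache["d_att"] = datt  # gradient at the attention output

        # channel attention backward
        x, gate = cache["x"], cache["gate"]
        dgate = (datt * x).sum(axis=(2, 3))
        dx = datt * gate[:, :, None, None]
        ds = dgate * gate * (1.0 - gate)
        for v, hid in ((cache["avg"], cache["h_avg"]), (cache["mx"], cache["h_max"])):
            grads["att_W2"] += hid.T @ ds
            grads["att_b2"] += ds.sum(axis=0)
            dhid = (ds @ spec["att_W2"].T) * (hid > 0)
            grads["att_W1"] += v.T @ dhid
            grads["att_b1"] += dhid.sum(axis=0)
            dv = dhid @ spec["att_W1"].T
            if v is cache["avg"]:
                dx += dv[:, :, None, None] / (P.image_height * P.image_width)
            else:
                dflat = np.zeros((n, P.in_channels,
                                  P.image_height * P.image_width))
                np.put_along_axis(dflat, cache["amax_idx"][:, :, None],
                                  dv[:, :, None], axis=2)
                dx += dflat.reshape(x.shape)
        return grads, d_feature

    def features_and_logit_gradient(self, images: np.ndarray,
                                    covariates: np.ndarray | None,
                                    class_index: int,
                                    layer: str = "conv"):
        """Feature maps F^l and d(logit_c)/dF^l for every sample.

        ``layer`` selects the target activation: "conv" (the conv-layer
        ReLU output, K = conv_filters channels) or "attended_input" (the
        channel-attention output, K = C omics channels at full P x q
        resolution).
        """
        if layer not in ("conv", "attended_input"):
            raise ValueError(
                f"unknown layer {layer!r}; valid: conv, attended_input")
        logits, cache = self.forward(images, covariates, train=False)
        dlogits = np.zeros_like(logits)
        dlogits[:, class_index] = 1.0
        _, d_feature = self.backward(cache, dlogits)
        if layer == "conv":
            return cache["relu"], d_feature, logits
        return cache["att"], cache["d_att"], logits

    def clone_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}


def build_model(spec: ModelSpec) -> AttCnn:
    """Instantiate an untrained attention CNN from its hyperparameters."""
    return AttCnn(spec)


def compute_class_weights(labels: Iterable[int]) -> np.ndarray:
    """Per-class loss weights w_c = N / (2 n_c), equalizing class mass."""
    labels = np.asarray(list(labels), dtype=int)
    counts = np.bincount(labels, minlength=2)
    if (counts == 0).any():
        raise ValueError("both classes must be present to compute weights")
    return len(labels) / (2.0 * counts)


def weighted_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                           class_weights: np.ndarray):
    """Mean per-sample weighted CE and its logit gradient."""
    n = logits.shape[0]
    p = softmax(logits)
    w = class_weights[labels]
    eps = 1e-12
    loss = float(np.mean(-w * np.log(p[np.arange(n), labels] + eps)))
    dlogits = p * w[:, None]
    dlogits[np.arange(n), labels] -= w
    return loss, dlogits / n


@dataclass
class TrainedModel:
    """A fitted attention CNN plus everything needed to reuse it."""

    model: AttCnn
    spec: ModelSpec
    class_weights: np.ndarray
    cov_mean: np.ndarray
    cov_std: np.ndarray
    history: dict = field(default_factory=dict)

    def standardize(self, covariates: np.ndarray | None) -> np.ndarray:
        if covariates is None or self.spec.n_covariates == 0:
            return np.zeros((0, 0))
        cov = np.asarray(covariates, dtype=float)
        return (cov - self.cov_mean) / self.cov_std


def _stratified_holdout(labels: np.ndarray, fraction: float,
                        rng: np.random.Generator):
    """Deterministic stratified split; returns (train_idx, val_idx)."""
    val: list[int] = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        k = max(1, int(round(fraction * len(idx))))
        val.extend(idx[:k].tolist())
    val_set = set(val)
    train = [i for i in range(len(labels)) if i not in val_set]
    return np.array(train), np.array(sorted(val))


def train_model(
    images: PathwayImageSet,
    annotations: SampleAnnotations,
    spec: ModelSpec,
    validation: float | tuple[np.ndarray, np.ndarray] | None = 0.2,
) -> TrainedModel:
    """Train the attention CNN with SGD and early stopping on validation AUC.

    ``validation`` is either a fraction of samples carved out (stratified),
    an explicit (train_idx, val_idx) pair, or None.  With None every sample
    is used for fitting, no early stopping takes place and the final-epoch
    parameters are kept — the mode used for the interpretation model, which
    is trained on all samples and never scored.  Covariates are z-scored
    with training-set statistics; class weights follow w_c = N / (2 n_c).
    """
    ann = annotations.aligned_to(images.sample_ids)
    y = ann.labels
    X = images.tensor
    cov_raw = ann.covariate_matrix()
    if cov_raw.shape[1] != spec.n_covariates:
        raise ValueError(
            f"spec expects {spec.n_covariates} covariates, "
            f"annotations provide {cov_raw.shape[1]}")
    rng = np.random.default_rng(spec.seed)
    if validation is None:
        tr_idx, va_idx = np.arange(len(y)), np.zeros(0, dtype=int)
    elif isinstance(validation, tuple):
        tr_idx, va_idx = np.asarray(validation[0]), np.asarray(validation[1])
    else:
        tr_idx, va_idx = _stratified_holdout(y, float(validation), rng)
    if validation is not None and len(np.unique(y[va_idx])) < 2:
        raise ValueError("validation set lacks one of the classes")
    if len(np.unique(y[tr_idx])) < 2:
        raise ValueError("training set lacks one of the classes")

    if spec.n_covariates:
        cov_mean = cov_raw[tr_idx].mean(axis=0)
        cov_std = cov_raw[tr_idx].std(axis=0)
        cov_std = np.where(cov_std > 0, cov_std, 1.0)
        cov = (cov_raw - cov_mean) / cov_std
    else:
        cov_mean = np.zeros(0)
        cov_std = np.ones(0)
        cov = np.zeros((len(y), 0))

    weights = compute_class_weights(y[tr_idx])
    model = AttCnn(spec)
    lr = spec.learning_rate
    history = {"train_loss": [], "val_auc": []}
    best_auc, best_params, best_epoch, since_best = -np.inf, model.clone_params(), 0, 0

    for epoch in range(spec.epochs):
        order = tr_idx[rng.permutation(len(tr_idx))]
        losses, sizes = [], []
        for start in range(0, len(order), spec.batch_size):
            batch = order[start:start + spec.batch_size]
            logits, cache = model.forward(X[batch], cov[batch],
                                          train=True, rng=rng)
            loss, dlogits = weighted_cross_entropy(logits, y[batch], weights)
            grads, _ = model.backward(cache, dlogits)
            for k in model.params:
                model.params[k] -= lr * grads[k]
            losses.append(loss)
            sizes.append(len(batch))
        epoch_loss = float(np.average(losses, weights=sizes))
        history["train_loss"].append(epoch_loss)
        if validation is None:
            continue
        val_scores = model.predict_proba(X[va_idx], cov[va_idx])[:, 1]
        val_auc = float(roc_auc_score(y[va_idx], val_scores))
        history["val_auc"].append(val_auc)
        if val_auc > best_auc:
            best_auc, best_epoch, since_best = val_auc, epoch, 0
            best_params = model.clone_params()
        else:
            since_best += 1
            if since_best >= spec.patience:
                break
    if validation is not None:
        model.set_params(best_params)
        history["best_epoch"] = best_epoch
        history["best_val_auc"] = best_auc
    else:
        history["best_epoch"] = spec.epochs - 1
        history["best_val_auc"] = float("nan")
    return TrainedModel(model, spec, weights, cov_mean, cov_std, history)


def predict(trained: TrainedModel, images: PathwayImageSet | np.ndarray,
            covariates: np.ndarray | None = None) -> np.ndarray:
    """Class probabilities per sample (dropout disabled, deterministic)."""
    X = images.tensor if isinstance(images, PathwayImageSet) else np.asarray(images)
    if trained.spec.n_covariates:
        cov = trained.standardize(covariates)
    else:
        cov = np.zeros((X.shape[0], 0))
    return trained.model.predict_proba(X, cov)
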