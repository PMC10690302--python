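"""Super-resolution base learner, compartment-weighted loss, and training.

The base learner maps a low-resolution patch (3 velocity components +
magnitude, VENC-normalized) to the 3 super-resolved velocity components at
twice the resolution.  Architecture: stacked convolutional blocks
(residual, dense, or cross-stage-partial) on either side of a core
trilinear upsampling layer, with a global residual skip from the trilinearly
upsampled input velocities (the final conv is zero-initialized, so an
untrained model reproduces plain trilinear interpolation and training
learns the correction).

The optimization target splits the velocity matching MSE into fluid and
non-fluid regions, weights the fluid term per compartment so imbalanced
batches give every compartment equal influence, and adds an L2 penalty
(lambda = 5e-7) on the network weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._nn import Adam, Conv3D, LeakyReLU, Sequential, Upsample3D
from .synthesis import VelocityVolume

__all__ = [
    "BaseLearnerConfig",
    "LossTerms",
    "velocity_mse",
    "compartment_weights",
    "total_loss",
    "build_base_learner",
    "train_base_learner",
    "predict_patches",
    "predict_volume",
    "trilinear_predict_volume",
    "BaseLearner",
]

LAMBDA_L2 = 5e-7


@dataclass
class BaseLearnerConfig:
    block_type: str = "residual"  # residual | dense | csp
    n_pre_blocks: int = 2
    n_post_blocks: int = 2
    channels: int = 32
    upsample_factor: int = 2
    activation_alpha: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.upsample_factor != 2:
            raise ValueError("only the 1:2 super-resolution factor is supported")
        if self.channels < 4:
            raise ValueError("channels must be >= 4")
        if self.block_type not in _nn.BLOCK_TYPES:
            raise ValueError(f"invalid block_type {self.block_type!r}")


@dataclass
class LossTerms:
    """Decomposed value of the training loss for one batch."""

    l_fluid: float
    l_nonfluid: float
    w_c: dict[str, float]
    lam: float
    l_reg: float
    l_total: float


def velocity_mse(pred, target, mask) -> float:
    """Mean over masked voxels of the summed squared component errors.

    With N masked voxels: (1/N) * sum_masked (dvx^2 + dvy^2 + dvz^2).
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        warnings.warn("velocity_mse over an empty mask: returning 0")
        return 0.0
    d = np.asarray(pred, dtype=np.float64) - np.asarray(target, dtype=np.float64)
    return float((d**2).sum(axis=0)[mask].sum() / n)


def compartment_weights(batch_compartments) -> dict[str, float]:
    """Per-batch compartment weights w_c = Nc / (S_c * sum_i 1/S_i).

    Nc is the number of compartments present in the batch and S_c the
    sample count of compartment c, so S_c * w_c is the same for every
    compartment: each compartment contributes equally to the batch loss.
    """
    comps = list(batch_compartments)
    if not comps:
        raise ValueError("batch is empty")
    counts: dict[str, int] = {}
    for c in comps:
        counts[c] = counts.get(c, 0) + 1
    nc = len(counts)
    sum_k = sum(1.0 / s for s in counts.values())
    return {c: nc / (s * sum_k) for c, s in counts.items()}


def _network_weight_sq_sum(model) -> float:
    return float(
        sum((p.value.astype(np.float64) ** 2).sum()
            for p in model.params() if p.is_weight)
    )


def total_loss(
    pred,
    target,
    fluid_mask,
    compartments,
    network_weights_sq: float = 0.0,
    lam: float = LAMBDA_L2,
    return_grad: bool = False,
):
    """Compartment-weighted fluid/non-fluid velocity loss for a batch.

    ``pred``/``target``: (B, 3, d, d, d); ``fluid_mask``: (B, d, d, d).
    Per patch b: l_b = w_c(b) * MSE_fluid(b) + MSE_nonfluid(b); the batch
    loss is the mean of l_b plus lam * sum of squared network weights.
    """
    pred = np.asarray(pred)
    target = np.asarray(target)
    fluid_mask = np.asarray(fluid_mask, dtype=bool)
    if pred.shape != target.shape:
        raise ValueError("pred and target shapes differ")
    b = pred.shape[0]
    w_c = compartment_weights(compartments)
    w_b = np.array([w_c[c] for c in compartments])
    d = pred.astype(np.float64) - target.astype(np.float64)
    sq = (d**2).sum(axis=1)  # (B, n, n, n) summed over components
    nf = fluid_mask.sum(axis=(1, 2, 3)).astype(np.float64)
    nnf = fluid_mask[0].size - nf
    sf = np.where(fluid_mask, sq, 0.0).sum(axis=(1, 2, 3))
    snf = sq.sum(axis=(1, 2, 3)) - sf
    with np.errstate(invalid="ignore", divide="ignore"):
        lf_b = np.where(nf > 0, sf / np.maximum(nf, 1), 0.0)
        lnf_b = np.where(nnf > 0, snf / np.maximum(nnf, 1), 0.0)
    l_fluid = float((w_b * lf_b).mean())
    l_nonfluid = float(lnf_b.mean())
    grad = None
    if return_grad:
        coef = np.where(
            fluid_mask,
            (w_b / np.maximum(nf, 1))[:, None, None, None],
            (1.0 / np.maximum(nnf, 1))[:, None, None, None],
        )
        grad = (2.0 / b) * d * coef[:, None]
    l_reg = lam * network_weights_sq
    terms = LossTerms(
        l_fluid=l_fluid,
        l_nonfluid=l_nonfluid,
        w_c=w_c,
        lam=lam,
        l_reg=l_reg,
        l_total=l_fluid + l_nonfluid + l_reg,
    )
    if return_grad:
        return terms, grad
    return terms


class BaseLearner:
    """Patch super-resolution network with a global trilinear skip."""

    def __init__(self, config: BaseLearnerConfig, dtype=np.float32):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.channels
        block = _nn.BLOCK_TYPES[config.block_type]
        alpha = config.activation_alpha
        mk_blocks = lambda n: [block(c, 3, rng, alpha, dtype=dtype) for _ in range(n)]
        self.trunk = Sequential(
            Conv3D(4, c, 3, rng, dtype=dtype),
            LeakyReLU(alpha),
            *mk_blocks(config.n_pre_blocks),
            Upsample3D(config.upsample_factor),
            *mk_blocks(config.n_post_blocks),
            Conv3D(c, 3, 3, rng, zero_init=True, dtype=dtype),
        )
        self.skip = Upsample3D(config.upsample_factor)

    def params(self):
        return self.trunk.params()

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, 4, s, s, s) VENC-normalized LR input -> (N, 3, 2s, 2s, 2s)."""
        s = self.skip.forward(np.ascontiguousarray(x[:, :3]))
        return self.trunk.forward(x) + s

    def backward(self, g: np.ndarray) -> np.ndarray:
        gx = self.trunk.backward(g)
        gs = self.skip.backward(g)
        gx[:, :3] += gs
        return gx

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        if len(state) != len(params):
            raise ValueError("checkpoint does not match the architecture")
        for i, p in enumerate(params):
            p.value[...] = state[f"p{i}"]


def build_base_learner(config: BaseLearnerConfig, dtype=np.float32) -> BaseLearner:
    """Construct a seeded base learner; same config -> identical weights."""
    return BaseLearner(config, dtype=dtype)


def _eval_loss(model, lr, hr, mask, comps, lam, batch_size=16) -> LossTerms:
    """Validation loss (no augmentation, no gradient)."""
    w2 = _network_weight_sq_sum(model)
    totals = np.zeros(2)
    n = lr.shape[0]
    nb = 0
    for i in range(0, n, batch_size):
        sl = slice(i, min(i + batch_size, n))
        pred = model.forward(lr[sl])
        t = total_loss(pred, hr[sl], mask[sl], list(comps[sl]), 0.0, lam)
        k = sl.stop - sl.start
        totals += np.array([t.l_fluid, t.l_nonfluid]) * k
        nb += k
    lf, lnf = totals / nb
    return LossTerms(lf, lnf, {}, lam, lam * w2, lf + lnf + lam * w2)


def train_base_learner(
    dataset,
    config: BaseLearnerConfig,
    epochs: int = 5,
    lr: float = 1e-4,
    batch_size: int = 16,
    seed: int = 0,
    lam: float = LAMBDA_L2,
    indices=None,
    plateau_patience: int = 5,
    model: BaseLearner | None = None,
):
    """Adam training of a base learner on a PatchDataset.

    ``indices`` (optional) restricts the training split to a bootstrap
    resample.  The learning rate is halved when the validation loss fails
    to improve for ``plateau_patience`` epochs (learning-rate decay of 2).
    Returns ``(model, history)`` with per-epoch train/val losses.
    """
    lr_x, hr_x, mask_x, _, comps_x = dataset.stacked("train")
    if indices is not None:
        indices = np.asarray(indices)
        lr_x, hr_x, mask_x, comps_x = (
            lr_x[indices], hr_x[indices], mask_x[indices], comps_x[indices]
        )
    has_val = dataset.n("val") > 0
    if has_val:
        lr_v, hr_v, mask_v, _, comps_v = dataset.stacked("val")
    if model is None:
        model = build_base_learner(config)
    opt = Adam(model.params(), lr=lr)
    rng = np.random.default_rng(seed)
    n = lr_x.shape[0]
    history = []
    best_val = np.inf
    stall = 0
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        nb = 0
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            pred = model.forward(lr_x[idx])
            terms, grad = total_loss(
                pred, hr_x[idx], mask_x[idx], list(comps_x[idx]),
                _network_weight_sq_sum(model), lam, return_grad=True,
            )
            if not np.isfinite(terms.l_total):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            opt.zero_grad()
            model.backward(grad.astype(lr_x.dtype))
            for p in model.params():  # L2 penalty on weights
                if p.is_weight:
                    p.grad += (2.0 * lam) * p.value
            opt.step()
            epoch_loss += terms.l_total * len(idx)
            nb += len(idx)
        row = {"epoch": epoch, "lr": opt.lr, "train_loss": epoch_loss / nb}
        if has_val:
            vt = _eval_loss(model, lr_v, hr_v, mask_v, comps_v, lam, batch_size)
            row["val_loss"] = vt.l_total
            row["val_fluid"] = vt.l_fluid
            if vt.l_total < best_val - 1e-12:
                best_val = vt.l_total
                stall = 0
            else:
                stall += 1
                if stall >= plateau_patience:
                    opt.lr /= 2.0
                    stall = 0
        history.append(row)
    return model, history


def predict_patches(model, lr_batch: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Forward a batch of (N, 4, s, s, s) LR inputs through a model."""
    out = []
    for i in range(0, lr_batch.shape[0], batch_size):
        out.append(model.forward(lr_batch[i : i + batch_size]))
    return np.concatenate(out, axis=0)


def _patch_origins(n: int, size: int, stride: int) -> list[int]:
    """Tile positions covering [0, n); the last window is shifted flush."""
    if n <= size:
        return [0]
    xs = list(range(0, n - size + 1, stride))
    if xs[-1] != n - size:
        xs.append(n - size)
    return xs


def _stitch(predict_fn, lr_vel, lr_mag, venc, patch=12, stride=8, crop=2):
    """Overlapping-patch inference with border cropping and averaging.

    ``predict_fn`` maps (N,4,p,p,p) -> (N,3,2p,2p,2p).  ``crop`` LR voxels
    are trimmed from patch faces interior to the volume before averaging.
    """
    shape = lr_mag.shape
    if any(n < patch for n in shape):
        raise ValueError("LR volume smaller than the inference patch")
    out_shape = tuple(2 * n for n in shape)
    acc = np.zeros((3,) + out_shape, dtype=np.float64)
    wacc = np.zeros(out_shape, dtype=np.float64)
    origins = [
        (i, j, k)
        for i in _patch_origins(shape[0], patch, stride)
        for j in _patch_origins(shape[1], patch, stride)
        for k in _patch_origins(shape[2], patch, stride)
    ]
    batch = []
    for o in origins:
        sl = tuple(slice(a, a + patch) for a in o)
        x = np.concatenate(
            [lr_vel[(slice(None),) + sl] / venc, lr_mag[sl][None]], axis=0
        )
        batch.append(x.astype(np.float32))
    preds = predict_fn(np.stack(batch))
    for o, pr in zip(origins, preds):
        lo = [crop if a > 0 else 0 for a in o]
        hi = [
            crop if a + patch < n else 0
            for a, n in zip(o, shape)
        ]
        sl_p = tuple(
            slice(2 * l, 2 * patch - 2 * h) for l, h in zip(lo, hi)
        )
        sl_v = tuple(
            slice(2 * (a + l), 2 * (a + patch - h))
            for a, l, h in zip(o, lo, hi)
        )
        acc[(slice(None),) + sl_v] += pr[(slice(None),) + sl_p]
        wacc[sl_v] += 1.0
    if np.any(wacc == 0):
        raise RuntimeError("stitching left uncovered voxels")
    return (acc / wacc) * venc


def predict_volume(
    model_or_fn,
    lr_volume: VelocityVolume,
    patch: int = 12,
    stride: int = 8,
    crop: int = 2,
) -> VelocityVolume:
    """Super-resolve a whole LR volume by stitched patch inference.

    Output spacing is half the LR spacing; the magnitude image is carried
    over by trilinear upsampling and the mask re-thresholded from it.
    """
    predict_fn = (
        model_or_fn if callable(model_or_fn)
        else (lambda x: predict_patches(model_or_fn, x))
    )
    vel = _stitch(
        predict_fn, lr_volume.velocity, lr_volume.magnitude,
        lr_volume.venc_cms, patch, stride, crop,
    )
    from ._nn import upsample_trilinear
    from .synthesis import MAG_THRESHOLD

    mag = upsample_trilinear(lr_volume.magnitude.astype(np.float64))
    return VelocityVolume(
        velocity=vel,
        magnitude=mag,
        fluid_mask=mag > MAG_THRESHOLD,
        spacing_mm=lr_volume.spacing_mm / 2,
        venc_cms=lr_volume.venc_cms,
        frame_index=lr_volume.frame_index,
        snr_db=lr_volume.snr_db,
        compartment=lr_volume.compartment,
        sample_id=lr_volume.sample_id,
    )


def trilinear_predict_volume(lr_volume: VelocityVolume) -> VelocityVolume:
    """Plain trilinear interpolation to double resolution (baseline)."""
    from ._nn import upsample_trilinear
    from .synthesis import MAG_THRESHOLD

    vel = upsample_trilinear(lr_volume.velocity.astype(np.float64))
    mag = upsample_trilinear(lr_volume.magnitude.astype(np.float64))
    return VelocityVolume(
        velocity=vel,
        magnitude=mag,
        fluid_mask=mag > MAG_THRESHOLD,
        spacing_mm=lr_volume.spacing_mm / 2,
        venc_cms=lr_volume.venc_cms,
        frame_index=lr_volume.frame_index,
        snr_db=lr_volume.snr_db,
        compartment=lr_volume.compartment,
        sample_id=lr_volume.sample_id,
    )
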