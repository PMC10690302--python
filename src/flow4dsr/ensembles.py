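"""Bagging and stacking ensembles over super-resolution base learners.

Bagging trains base learners on bootstrap resamples (with replacement,
resample size equal to the original training-set size) and fuses them by
soft voting — an unweighted voxelwise mean.  Stacking fuses base-learner
outputs through a trained 8-layer convolutional feed-forward meta-learner
whose input/output resolution matches the base network's output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._nn import Adam, Conv3D, LeakyReLU, Sequential
from .models import (
    LAMBDA_L2,
    BaseLearner,
    BaseLearnerConfig,
    _network_weight_sq_sum,
    predict_patches,
    predict_volume,
    total_loss,
    train_base_learner,
)
from .synthesis import VelocityVolume

__all__ = [
    "EnsembleSpec",
    "MetaLearner",
    "Ensemble",
    "bootstrap_datasets",
    "bagging_predict",
    "build_meta_learner",
    "train_bagging",
    "train_stacking",
    "ensemble_predict",
]


@dataclass
class EnsembleSpec:
    kind: str  # bagging | stacking
    n_base: int
    base_configs: list[BaseLearnerConfig]
    meta_channels: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("bagging", "stacking"):
            raise ValueError(f"unknown ensemble kind {self.kind!r}")
        if self.n_base < 1 or self.n_base != len(self.base_configs):
            raise ValueError("n_base must equal len(base_configs) and be >= 1")


def bootstrap_datasets(n_or_dataset, n_base: int, seed: int = 0):
    """``n_base`` bootstrap index-sets of the training split.

    Each index-set has the full training size N, drawn with replacement;
    deterministic given the seed.
    """
    if hasattr(n_or_dataset, "n"):
        n = n_or_dataset.n("train")
    else:
        n = int(n_or_dataset)
    if n < 1:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(seed)
    return [rng.integers(0, n, size=n) for _ in range(n_base)]


def bagging_predict(models, lr_input: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Soft voting: voxelwise unweighted mean of member patch predictions."""
    if not models:
        raise ValueError("need at least one model")
    preds = [predict_patches(m, lr_input, batch_size) for m in models]
    shapes = {p.shape for p in preds}
    if len(shapes) != 1:
        raise ValueError("member prediction shapes differ")
    return np.mean(preds, axis=0)


class MetaLearner:
    """8-layer convolutional feed-forward fusion network.

    Input: concatenated base-learner SR outputs (3*n_base channels, 24^3);
    output: 3 fused SR velocity components at the same resolution.  The
    final conv is zero-initialized and a global skip carries the mean of
    the base outputs, so the untrained meta-learner reproduces soft voting.
    """

    N_CONV_LAYERS = 8

    def __init__(self, n_base: int, channels: int = 16, seed: int = 0,
                 dtype=np.float32):
        self.n_base = n_base
        rng = np.random.default_rng(seed)
        layers = [Conv3D(3 * n_base, channels, 3, rng, dtype=dtype), LeakyReLU()]
        for _ in range(self.N_CONV_LAYERS - 2):
            layers += [Conv3D(channels, channels, 3, rng, dtype=dtype), LeakyReLU()]
        layers.append(Conv3D(channels, 3, 3, rng, zero_init=True, dtype=dtype))
        self.net = Sequential(*layers)
        self.n_conv_layers = sum(
            isinstance(l, Conv3D) for l in self.net.layers
        )

    def params(self):
        return self.net.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        skip = x.reshape(n, self.n_base, 3, *x.shape[2:]).mean(axis=1)
        return self.net.forward(x) + skip

    def backward(self, g: np.ndarray) -> np.ndarray:
        gx = self.net.backward(g)
        n = g.shape[0]
        gskip = np.repeat(g[:, None] / self.n_base, self.n_base, axis=1)
        return gx + gskip.reshape(gx.shape)

    def state_dict(self):
        return {f"p{i}": p.value.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state):
        params = self.params()
        if len(state) != len(params):
            raise ValueError("checkpoint does not match the architecture")
        for i, p in enumerate(params):
            p.value[...] = state[f"p{i}"]


def build_meta_learner(n_base: int, channels: int = 16, seed: int = 0) -> MetaLearner:
    return MetaLearner(n_base, channels, seed)


@dataclass
class Ensemble:
    spec: EnsembleSpec
    members: list[BaseLearner]
    meta: MetaLearner | None = None
    trained: bool = False

    def predict_patches_fn(self):
        """Callable (N,4,s,s,s) -> (N,3,2s,2s,2s) fusing the members."""
        if not self.trained:
            raise RuntimeError("ensemble is not trained")
        if self.spec.kind == "bagging":
            return lambda x: bagging_predict(self.members, x)

        def stacked(x):
            base = np.concatenate(
                [predict_patches(m, x) for m in self.members], axis=1
            )
            return predict_patches(self.meta, base)

        return stacked

    def save_manifest(self, path, checkpoint_paths) -> None:
        manifest = {
            "kind": self.spec.kind,
            "n_base": self.spec.n_base,
            "seed": self.spec.seed,
            "base_configs": [asdict(c) for c in self.spec.base_configs],
            "members": [str(p) for p in checkpoint_paths],
        }
        Path(path).write_text(json.dumps(manifest, indent=2))


def train_bagging(
    dataset,
    spec: EnsembleSpec,
    epochs: int = 5,
    lr: float = 1e-4,
    batch_size: int = 16,
) -> tuple[Ensemble, list]:
    """Train ``n_base`` learners on bootstrap resamples; fuse by soft voting."""
    index_sets = bootstrap_datasets(dataset, spec.n_base, seed=spec.seed)
    members, histories = [], []
    for i, (cfg, idx) in enumerate(zip(spec.base_configs, index_sets)):
        model, hist = train_base_learner(
            dataset, cfg, epochs=epochs, lr=lr, batch_size=batch_size,
            seed=spec.seed + 1000 + i, indices=idx,
        )
        members.append(model)
        histories.append(hist)
    return Ensemble(spec, members, trained=True), histories


def train_stacking(
    base_models,
    dataset,
    spec: EnsembleSpec,
    epochs: int = 2,
    lr: float = 1e-4,
    batch_size: int = 8,
    lam: float = LAMBDA_L2,
    meta_split: str = "val",
) -> tuple[Ensemble, list]:
    """Train the stacking meta-learner on frozen base-model outputs.

    The meta-learner consumes base predictions on ``meta_split`` (the
    validation split by default, limiting leakage from base training data)
    and is optimized against the HR targets with the same
    compartment-weighted loss as the bases.  Base parameters are frozen.
    """
    lr_x, hr_x, mask_x, _, comps_x = dataset.stacked(meta_split)
    base_out = np.concatenate(
        [predict_patches(m, lr_x, batch_size) for m in base_models], axis=1
    ).astype(np.float32)
    meta = build_meta_learner(len(base_models), spec.meta_channels, spec.seed)
    opt = Adam(meta.params(), lr=lr)
    rng = np.random.default_rng(spec.seed + 77)
    n = base_out.shape[0]
    history = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        ep_loss, nb = 0.0, 0
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            pred = meta.forward(base_out[idx])
            terms, grad = total_loss(
                pred, hr_x[idx], mask_x[idx], list(comps_x[idx]),
                _network_weight_sq_sum(meta), lam, return_grad=True,
            )
            if not np.isfinite(terms.l_total):
                raise FloatingPointError("meta-learner training diverged")
            opt.zero_grad()
            meta.backward(grad.astype(np.float32))
            for p in meta.params():
                if p.is_weight:
                    p.grad += (2.0 * lam) * p.value
            opt.step()
            ep_loss += terms.l_total * len(idx)
            nb += len(idx)
        history.append({"epoch": epoch, "train_loss": ep_loss / nb})
    ens = Ensemble(spec, list(base_models), meta=meta, trained=True)
    return ens, history


def ensemble_predict(
    ensemble: Ensemble, lr_volume: VelocityVolume, **stitch_kw
) -> VelocityVolume:
    """Super-resolve a whole LR volume with a trained ensemble."""
    return predict_volume(ensemble.predict_patches_fn(), lr_volume, **stitch_kw)
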