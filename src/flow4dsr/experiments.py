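"""Desk-scale end-to-end experiment: phantoms -> pairs -> patches ->
base learners -> bagging/stacking -> downsample-and-recover evaluation.

The experiment generates seeded phantom suites for the three training
compartments (cardiac, aortic, cerebrovascular), builds a patch dataset
with model-wise 6:2:2 splitting and rotation augmentation, trains two tiny
base learners on bootstrap resamples, forms a Bagging-2 soft-voting
ensemble and a Stacking-2 ensemble with a convolutional meta-learner, and
evaluates everything on held-out phantoms (including the unseen two-lumen
"dissection" domain) against a trilinear-interpolation baseline.

Sizes are deliberately small — ~50 grids, a few hundred patches, networks
of ~10^4 parameters — so the full pipeline runs in minutes on one CPU.
Acceptance is directional: the ensembles must beat the trilinear baseline
in relative speed error and in regression slope, not match any particular
absolute error level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensembles import (
    EnsembleSpec,
    ensemble_predict,
    train_bagging,
    train_stacking,
)
from .metrics import EvalReport, downsample_recover
from .models import BaseLearnerConfig, trilinear_predict_volume
from .patches import build_dataset
from .phantoms import compartment_suite
from .synthesis import _even_crop, voxelize

__all__ = ["DeskConfig", "DeskResult", "reproduce_desk"]

TRAIN_COMPARTMENTS = ("cardiac", "aortic", "cerebro")


@dataclass
class DeskConfig:
    """Scaled-down study conditions for the single-CPU experiment."""

    n_samples: int = 5  # per training compartment (splits 3:1:1)
    n_frames: int = 3
    snr_db_eval: float = 15.0
    channels: int = 12
    n_pre_blocks: int = 2  # compute concentrated before upsampling
    n_post_blocks: int = 0
    n_base: int = 2
    epochs_base: int = 60
    epochs_meta: int = 8
    lr: float = 1e-3  # scaled up with the shortened schedule
    batch_size: int = 8
    block_type: str = "residual"


@dataclass
class DeskResult:
    reports: dict  # method -> list[EvalReport] on held-out phantoms
    dissection_reports: dict  # method -> list[EvalReport], unseen domain
    dataset_counts: dict
    histories: dict
    config: DeskConfig

    def summary(self) -> dict:
        """Aggregate metrics per method: mean RE (%), mean |k-1|, mean R^2."""
        out = {}
        for name, reps in self.reports.items():
            out[name] = _aggregate(reps)
        for name, reps in self.dissection_reports.items():
            out[name + "_dissection"] = _aggregate(reps)
        return out


def _aggregate(reports: list[EvalReport]) -> dict:
    res = np.array([r.re_percent for r in reports])
    ks = np.array([r.k for r in reports], dtype=float)
    r2s = np.array([r.r2 for r in reports], dtype=float)
    return {
        "re_percent": float(res.mean()),
        "k_dev": float(np.nanmean(np.abs(ks - 1.0))),
        "k_mean": float(np.nanmean(ks)),
        "r2_mean": float(np.nanmean(r2s)),
        "n_volumes": len(reports),
        "n_fluid_voxels": int(sum(r.n_fluid for r in reports)),
    }


def _systolic_frame(sample) -> int:
    return int(np.argmax(sample.waveform))


def reproduce_desk(seed: int = 0, config: DeskConfig | None = None):
    """Run the full scaled-down experiment; returns a :class:`DeskResult`.

    Deterministic given ``seed``.  The held-out evaluation uses the
    test-split phantom of each training compartment at its systolic frame,
    plus one dissection phantom never seen in training.
    """
    if config is None:
        config = DeskConfig()
    samples = []
    for comp in TRAIN_COMPARTMENTS:
        samples += compartment_suite(
            comp, config.n_samples, seed, n_frames=config.n_frames
        )
    ds = build_dataset(samples, seed=seed)
    test_ids = set(ds.manifest["splits"]["test"])
    test_samples = [s for s in samples if s.sample_id in test_ids]
    dissection = compartment_suite(
        "dissection", 1, seed + 1, n_frames=config.n_frames
    )

    base_configs = [
        BaseLearnerConfig(
            block_type=config.block_type,
            n_pre_blocks=config.n_pre_blocks,
            n_post_blocks=config.n_post_blocks,
            channels=config.channels,
            seed=seed + 10 + i,
        )
        for i in range(config.n_base)
    ]
    bag_spec = EnsembleSpec("bagging", config.n_base, base_configs, seed=seed)
    bagging, hist_base = train_bagging(
        ds, bag_spec, epochs=config.epochs_base, lr=config.lr,
        batch_size=config.batch_size,
    )
    stack_spec = EnsembleSpec(
        "stacking", config.n_base, base_configs,
        meta_channels=config.channels, seed=seed,
    )
    stacking, hist_meta = train_stacking(
        bagging.members, ds, stack_spec, epochs=config.epochs_meta,
        lr=config.lr,
    )

    methods = {
        "trilinear": trilinear_predict_volume,
        "bagging2": lambda v: ensemble_predict(bagging, v),
        "stacking2": lambda v: ensemble_predict(stacking, v),
    }
    rng = np.random.default_rng(seed + 999)

    def run(sample_list):
        reports: dict[str, list[EvalReport]] = {m: [] for m in methods}
        for sample in sample_list:
            frame = _systolic_frame(sample)
            native = _even_crop(voxelize(sample, frame))
            noise_seed = int(rng.integers(0, 2**31 - 1))
            for name, predictor in methods.items():
                reports[name].append(
                    downsample_recover(
                        native, predictor,
                        snr_db=config.snr_db_eval, seed=noise_seed,
                    )
                )
        return reports

    result = DeskResult(
        reports=run(test_samples),
        dissection_reports=run(dissection),
        dataset_counts=ds.manifest["counts"],
        histories={"base": hist_base, "meta": hist_meta},
        config=config,
    )
    return result
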