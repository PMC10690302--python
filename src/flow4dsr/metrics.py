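"""Hemodynamic evaluation metrics and the downsample-and-recover protocol.

Metrics follow the 4D-flow super-resolution evaluation convention:

* relative speed error  RE = mean over voxels of
  ``tanh(||V' - V|| / (||V|| + eps))`` (in percent), with ``eps = 1e-4``
  guarding zero-division and the tanh saturating the penalty at low
  reference speeds;
* per-component RMSE over the fluid region and over its complement;
* per-component linear regression of predicted on reference velocity
  (slope k, coefficient of determination R^2), after normalizing both by
  the shared max-|reference| scale onto [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthesis import (
    VelocityVolume,
    decode_velocity,
    encode_complex,
    kspace_downsample,
)

__all__ = [
    "EvalReport",
    "relative_error",
    "rmse_by_region",
    "regression_stats",
    "evaluate_pair",
    "downsample_recover",
    "compare_models",
]

EPS_RE = 1e-4


@dataclass
class EvalReport:
    """Per-volume evaluation summary."""

    re_percent: float
    rmse_fluid_cms: tuple[float, float, float]
    rmse_nonfluid_cms: tuple[float, float, float]
    k: tuple[float, float, float]
    r2: tuple[float, float, float]
    n_fluid: int
    n_nonfluid: int
    protocol: str = "insilico_pair"
    compartment: str = ""
    sample_id: str = ""

    def to_dict(self) -> dict:
        d = {
            "re_percent": self.re_percent,
            "n_fluid": self.n_fluid,
            "n_nonfluid": self.n_nonfluid,
            "protocol": self.protocol,
            "compartment": self.compartment,
            "sample_id": self.sample_id,
        }
        for name, tup in (
            ("rmse_fluid", self.rmse_fluid_cms),
            ("rmse_nonfluid", self.rmse_nonfluid_cms),
            ("k", self.k),
            ("r2", self.r2),
        ):
            for comp, v in zip("xyz", tup):
                d[f"{name}_{comp}"] = v
        return d


def relative_error(ref_velocity, pred_velocity, mask, eps: float = EPS_RE) -> float:
    """Relative speed error in percent over the masked voxels.

    ``tanh(||V'-V||_2 / (||V||_2 + eps))`` averaged over the mask, x100.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("relative_error requires a non-empty mask")
    ref = np.asarray(ref_velocity, dtype=np.float64)[:, mask]
    pred = np.asarray(pred_velocity, dtype=np.float64)[:, mask]
    err = np.sqrt(((pred - ref) ** 2).sum(axis=0))
    speed = np.sqrt((ref**2).sum(axis=0))
    return float(np.tanh(err / (speed + eps)).mean() * 100.0)


def rmse_by_region(ref, pred, fluid_mask):
    """Per-component RMSE (cm/s) over fluid voxels and over non-fluid voxels.

    An empty region yields NaN triples for that region.
    """
    ref = np.asarray(ref, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    fluid_mask = np.asarray(fluid_mask, dtype=bool)

    def _rmse(m):
        if not m.any():
            return (np.nan, np.nan, np.nan)
        d2 = (pred[:, m] - ref[:, m]) ** 2
        return tuple(np.sqrt(d2.mean(axis=1)))

    return _rmse(fluid_mask), _rmse(~fluid_mask)


def regression_stats(ref, pred, mask, normalize: bool = True):
    """Per-component OLS of predicted on reference velocity.

    Both fields are optionally normalized by the shared max-|ref| scale
    (mapping the reference onto [-1, 1]); the slope is scale-invariant but
    the fit is reported on the normalized axes.  Returns ``(k, r2)``
    triples; a constant reference component yields NaN for that component.
    """
    mask = np.asarray(mask, dtype=bool)
    ref = np.asarray(ref, dtype=np.float64)[:, mask]
    pred = np.asarray(pred, dtype=np.float64)[:, mask]
    if normalize:
        scale = np.abs(ref).max()
        if scale > 0:
            ref = ref / scale
            pred = pred / scale
    ks, r2s = [], []
    for c in range(3):
        x, y = ref[c], pred[c]
        if np.ptp(x) == 0:
            ks.append(np.nan)
            r2s.append(np.nan)
            continue
        res = stats.linregress(x, y)
        ks.append(float(res.slope))
        r2s.append(float(res.rvalue**2))
    return tuple(ks), tuple(r2s)


def evaluate_pair(
    ref: VelocityVolume,
    pred: VelocityVolume,
    mask=None,
    protocol: str = "insilico_pair",
) -> EvalReport:
    """Full metric report comparing a prediction to its reference volume."""
    if pred.velocity.shape != ref.velocity.shape:
        raise ValueError("reference and prediction grids differ")
    if mask is None:
        mask = ref.fluid_mask
    k, r2 = regression_stats(ref.velocity, pred.velocity, mask)
    rmse_f, rmse_nf = rmse_by_region(ref.velocity, pred.velocity, mask)
    return EvalReport(
        re_percent=relative_error(ref.velocity, pred.velocity, mask),
        rmse_fluid_cms=rmse_f,
        rmse_nonfluid_cms=rmse_nf,
        k=k,
        r2=r2,
        n_fluid=int(mask.sum()),
        n_nonfluid=int(mask.size - mask.sum()),
        protocol=protocol,
        compartment=ref.compartment,
        sample_id=ref.sample_id,
    )


def downsample_recover(
    native_volume: VelocityVolume,
    predictor,
    snr_db: float | None = None,
    seed: int = 0,
) -> EvalReport:
    """Downsample a native-resolution volume by two (k-space truncation),
    super-resolve back, and compare against the native data.

    ``predictor`` maps an LR :class:`VelocityVolume` to an SR one — a
    trained model/ensemble via the prediction helpers, or e.g. plain
    trilinear interpolation as baseline.
    """
    if any(n % 2 for n in native_volume.grid_shape):
        raise ValueError("native volume dimensions must be even")
    cset = encode_complex(native_volume)
    if snr_db is not None:
        from .synthesis import add_complex_noise

        cset = add_complex_noise(cset, snr_db, seed)
    lr = decode_velocity(
        kspace_downsample(cset, 2),
        frame_index=native_volume.frame_index,
        compartment=native_volume.compartment,
        sample_id=native_volume.sample_id,
    )
    sr = predictor(lr)
    return evaluate_pair(
        native_volume, sr, protocol="downsample_recover"
    )


def compare_models(reports: dict[str, EvalReport]) -> pd.DataFrame:
    """Long-format comparison table: model x compartment x metric.

    Flags the best model per (compartment, metric); lower is better except
    for R^2 and for k, which is best closest to 1.
    """
    if not reports:
        raise ValueError("need at least one report")
    rows = []
    for name, rep in reports.items():
        d = rep.to_dict()
        for metric in (
            "re_percent",
            "rmse_fluid_x", "rmse_fluid_y", "rmse_fluid_z",
            "rmse_nonfluid_x", "rmse_nonfluid_y", "rmse_nonfluid_z",
            "k_x", "k_y", "k_z",
            "r2_x", "r2_y", "r2_z",
        ):
            rows.append(
                {
                    "model": name,
                    "compartment": rep.compartment,
                    "metric": metric,
                    "value": d[metric],
                }
            )
    df = pd.DataFrame(rows)
    df["best"] = False
    for (comp, metric), grp in df.groupby(["compartment", "metric"]):
        vals = grp["value"].dropna()
        if vals.empty:
            continue
        if metric.startswith("r2"):
            idx = vals.idxmax()
        elif metric.startswith("k"):
            idx = (vals - 1.0).abs().idxmin()
        else:
            idx = vals.idxmin()
        df.loc[idx, "best"] = True
    return df
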