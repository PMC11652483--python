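"""Frame-intensity to MU conversion and frame-record assignment.

Each processed frame is reduced to an MU-equivalent scalar by dividing its
in-field intensity statistic by the frame's pixel scaling factor from the
acquisition log. Per-frame MU increments are then normalized so they sum to
the plan's total MU, and each frame is assigned a gantry angle by inverse
interpolation of the plan's cumulative-MU-versus-gantry polyline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .aperture import BinaryAperture
from .deconvolution import STAGE_PROCESSED, FluenceImage
from .epid_io import AcquisitionLog, VmatPlan


class MuCalibError(ValueError):
    pass


@dataclass
class FrameMU:
    frame_index: int
    mu_equiv: float
    cumulative_mu: float = 0.0


@dataclass
class LinearityReport:
    points: list[tuple[float, float]]
    slope: float
    intercept: float
    r_squared: float
    dose_rate_points: list[tuple[float, float]]
    max_rel_spread: float


def frame_mu(
    processed: FluenceImage,
    psf: float,
    field_mask: BinaryAperture,
    stat: str = "mean",
) -> float:
    """MU-equivalent of one frame: in-field intensity statistic / PSF."""
    if psf <= 0:
        raise MuCalibError(f"psf must be > 0, got {psf}")
    if processed.stage != STAGE_PROCESSED:
        raise MuCalibError(f"frame_mu expects a processed-stage image, got {processed.stage!r}")
    mask = field_mask.mask
    if not mask.any():
        warnings.warn("empty aperture: mu_equiv set to 0", stacklevel=2)
        return 0.0
    vals = processed.values[mask]
    agg = float(vals.sum()) if stat == "sum" else float(vals.mean())
    return agg / psf


def check_linearity(
    mu_points: list[tuple[float, float]],
    dose_rate_points: list[tuple[float, float]],
) -> LinearityReport:
    """Least-squares line through (delivered MU, measured MU-equivalent)
    pairs plus the relative spread of the fixed-MU dose-rate series."""
    if len(mu_points) < 3:
        raise MuCalibError(f"need >= 3 MU levels, got {len(mu_points)}")
    if len(dose_rate_points) < 2:
        raise MuCalibError(f"need >= 2 dose rates, got {len(dose_rate_points)}")
    x = np.array([p[0] for p in mu_points], dtype=float)
    y = np.array([p[1] for p in mu_points], dtype=float)
    fit = stats.linregress(x, y)
    dr = np.array([p[1] for p in dose_rate_points], dtype=float)
    spread = float((dr.max() - dr.min()) / dr.mean()) if dr.mean() != 0 else float("inf")
    return LinearityReport(
        points=list(mu_points),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        dose_rate_points=list(dose_rate_points),
        max_rel_spread=spread,
    )


def _unwrap_gantry(angles: list[float]) -> np.ndarray:
    """Unwrap a monotone arc so interpolation never crosses the 0/360 seam."""
    out = [float(angles[0])]
    for a in angles[1:]:
        d = (float(a) - out[-1] + 180.0) % 360.0 - 180.0
        out.append(out[-1] + d)
    return np.asarray(out)


@dataclass
class FrameRecord:
    frame_index: int
    time_s: float
    gantry_deg: float
    collimator_deg: float
    cumulative_mu: float


def assign_frame_records(
    frames: list[FrameMU],
    plan: VmatPlan,
    log: AcquisitionLog,
    angle_map: str = "mu",
) -> list[FrameRecord]:
    """Normalize per-frame MU to the plan total and assign machine angles.

    cumulative_mu_k = total_mu * (sum of mu_equiv up to k) / (sum over all);
    the gantry angle comes from inverse interpolation of the plan's
    cumulative-MU-vs-gantry polyline at cumulative_mu_k (``angle_map='mu'``)
    or from timestamp-proportional arc progress (``angle_map='time'``). The
    collimator angle is copied from the plan (constant per arc beam).
    """
    if len(frames) != log.n_frames:
        raise MuCalibError(f"{len(frames)} frame MUs but log declares {log.n_frames}")
    total_equiv = sum(f.mu_equiv for f in frames)
    if total_equiv <= 0:
        raise MuCalibError("total mu_equiv over frames is zero; cannot normalize")
    plan_cum = np.asarray([cp.cumulative_mu for cp in plan.control_points], dtype=float)
    if np.any(np.diff(plan_cum) <= 0):
        raise MuCalibError("plan cumulative MU must be strictly increasing for angle assignment")
    gantry_unwrapped = _unwrap_gantry([cp.gantry_angle for cp in plan.control_points])
    coll = plan.control_points[0].collimator_angle

    records = []
    running = 0.0
    for fr, t in zip(frames, log.frame_times):
        running += fr.mu_equiv
        cum = plan.total_mu * running / total_equiv
        if angle_map == "time":
            frac = (t - log.frame_times[0]) / max(log.frame_times[-1] - log.frame_times[0], 1e-12)
            g = float(np.interp(frac, [0.0, 1.0], [gantry_unwrapped[0], gantry_unwrapped[-1]]))
        else:
            g = float(np.interp(cum, plan_cum, gantry_unwrapped))
        fr.cumulative_mu = cum
        records.append(
            FrameRecord(
                frame_index=fr.frame_index,
                time_s=float(t),
                gantry_deg=g % 360.0,
                collimator_deg=coll,
                cumulative_mu=cum,
            )
        )
    # normalization is exact: force the last record onto the plan total
    records[-1].cumulative_mu = plan.total_mu
    return records
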