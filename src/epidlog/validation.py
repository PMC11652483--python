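"""Pipeline fidelity checks.

Three comparators: extraction-versus-truth recovery statistics for synthetic
acquisitions, a global 2D gamma index (the stand-in for the commercial
system's passing-rate computation), and the deterministic statistics of the
packaged 18-plan table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .complexity import spearman
from .config import DetectorGeometry
from .loggen import EpidLogFile
from .synthetic import SyntheticTruth


class ValidationError(ValueError):
    pass


@dataclass
class RecoveryReport:
    leaf_rmse_px: float
    leaf_max_err_px: float
    mu_rel_err: float  # max over frames of |increment error| / true increment
    gantry_max_err_deg: float
    n_frames: int


def recover(
    truth: SyntheticTruth, log: EpidLogFile, geometry: DetectorGeometry | None = None
) -> RecoveryReport:
    """Compare an extracted log against generator ground truth."""
    if geometry is None:
        geometry = DetectorGeometry()
    n = len(truth.frame_mu_increment)
    if len(log.records) != n:
        raise ValidationError(f"log has {len(log.records)} records, truth has {n} frames")
    errs = []
    for rec, ta, tb in zip(log.records, truth.frame_bank_a_mm, truth.frame_bank_b_mm):
        errs.extend(np.asarray(rec.bank_a_mm) - np.asarray(ta))
        errs.extend(np.asarray(rec.bank_b_mm) - np.asarray(tb))
    errs_px = np.asarray(errs) / geometry.pixel_mm
    cum = np.asarray([r.cumulative_mu for r in log.records])
    inc = np.diff(np.concatenate([[0.0], cum]))
    true_inc = np.asarray(truth.frame_mu_increment)
    mu_rel = float(np.max(np.abs(inc - true_inc) / true_inc))
    g_err = [
        abs((r.gantry_deg - tg + 180.0) % 360.0 - 180.0)
        for r, tg in zip(log.records, truth.frame_gantry_deg)
    ]
    return RecoveryReport(
        leaf_rmse_px=float(np.sqrt(np.mean(errs_px**2))),
        leaf_max_err_px=float(np.max(np.abs(errs_px))),
        mu_rel_err=mu_rel,
        gantry_max_err_deg=float(max(g_err)),
        n_frames=n,
    )


# ------------------------------------------------------------------ gamma


@dataclass
class GammaResult:
    gpr: float
    dd_percent: float
    dta_mm: float
    low_dose_cut: float
    n_evaluated: int


def gamma_2d(
    reference,
    evaluated,
    dd_percent: float = 3.0,
    dta_mm: float = 3.0,
    low_dose_cut: float = 0.10,
    pixel_mm: float = 0.5,
    step_px: float = 0.1,
    search_factor: float = 3.0,
) -> GammaResult:
    """Global-normalization gamma passing rate.

    The dose-difference criterion is dd% of the reference maximum; pixels
    below ``low_dose_cut`` of that maximum are excluded. The minimum gamma is
    searched exhaustively over bilinear sub-pixel shifts of the evaluated
    image on a ``step_px`` grid out to ``search_factor * dta``; samples
    falling outside the evaluated image do not contribute. Shifts are visited
    in order of increasing distance so the search stops as soon as the
    distance term alone exceeds every pixel's current minimum.
    """
    ref = np.asarray(getattr(reference, "values", reference), dtype=float)
    ev = np.asarray(getattr(evaluated, "values", evaluated), dtype=float)
    if ref.shape != ev.shape:
        raise ValidationError(f"shape mismatch: {ref.shape} vs {ev.shape}")
    norm = ref.max()
    if norm <= 0:
        raise ValidationError("reference image is empty")
    include = ref >= low_dose_cut * norm
    if not include.any():
        raise ValidationError("all pixels below the low-dose cutoff")
    delta = dd_percent / 100.0 * norm

    radius_px = search_factor * dta_mm / pixel_mm
    offsets = np.round(np.arange(-radius_px, radius_px + step_px / 2, step_px), 6)
    sy, sx = np.meshgrid(offsets, offsets, indexing="ij")
    d2_px = sy**2 + sx**2
    keep = d2_px <= radius_px**2 + 1e-9
    order = np.argsort(d2_px[keep])
    shifts = np.column_stack([sy[keep][order], sx[keep][order]])
    dist2_mm = d2_px[keep][order] * pixel_mm**2

    h, w = ev.shape
    pad = int(np.ceil(radius_px)) + 2
    padded = np.full((h + 2 * pad, w + 2 * pad), np.nan)
    padded[pad : pad + h, pad : pad + w] = ev

    def window(iy: int, ix: int) -> np.ndarray:
        return padded[pad + iy : pad + iy + h, pad + ix : pad + ix + w]

    gamma2 = np.full(ref.shape, np.inf)
    dta2 = dta_mm**2
    delta2 = delta**2
    for (shift_y, shift_x), d2 in zip(shifts, dist2_mm):
        current_max = np.max(gamma2[include])
        if d2 / dta2 >= current_max:
            break
        iy, fy = int(np.floor(shift_y)), shift_y - np.floor(shift_y)
        ix, fx = int(np.floor(shift_x)), shift_x - np.floor(shift_x)
        if fy < 1e-9 and fx < 1e-9:
            val = window(iy, ix)
        else:
            val = (
                (1 - fy) * (1 - fx) * window(iy, ix)
                + (1 - fy) * fx * window(iy, ix + 1)
                + fy * (1 - fx) * window(iy + 1, ix)
                + fy * fx * window(iy + 1, ix + 1)
            )
        term = d2 / dta2 + (val - ref) ** 2 / delta2
        gamma2 = np.fmin(gamma2, np.where(np.isnan(term), np.inf, term))

    passed = gamma2[include] <= 1.0 + 1e-9
    return GammaResult(
        gpr=100.0 * float(np.mean(passed)),
        dd_percent=dd_percent,
        dta_mm=dta_mm,
        low_dose_cut=low_dose_cut,
        n_evaluated=int(include.sum()),
    )


# ------------------------------------------------------------- table stats


def reproduce_table3_stats(df: pd.DataFrame) -> dict[str, float]:
    """Deterministic statistics of the 18-plan table: mean and sample SD of
    the proposed-method GPR, the count of plans below 90%, and the rank
    correlation with the machine-log GPR (all plans and 6 MV only)."""
    if len(df) != 18:
        raise ValidationError(f"expected 18 rows, got {len(df)}")
    gpr = df["gpr_prop"].to_numpy(dtype=float)
    mach = df["gpr_mach"].to_numpy(dtype=float)
    all_corr = spearman(gpr, mach)
    sub = df[df["beam"].astype(str).str.strip() == "6"]
    sub_corr = spearman(sub["gpr_prop"].to_numpy(dtype=float), sub["gpr_mach"].to_numpy(dtype=float))
    return {
        "mean_gpr": float(np.mean(gpr)),
        "sd_gpr": float(np.std(gpr, ddof=1)),
        "n_below_90": int(np.sum(gpr < 90.0)),
        "rho_all": all_corr.rho,
        "p_all": all_corr.p_value,
        "n_all": all_corr.n,
        "rho_6mv": sub_corr.rho,
        "p_6mv": sub_corr.p_value,
        "n_6mv": sub_corr.n,
    }
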