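"""Ground-truth generators for every input the pipeline consumes.

All generators are pure functions of their parameters and a seed: VMAT arc
plans with a sliding-window aperture, box-fluence calibration series,
full frame-sequence acquisitions (ideal aperture -> plateau scaling ->
Gaussian blur -> optional multiplicative noise -> detector-pose shift ->
16-bit intensity inversion), and pose-grid image sets with injected
imaging-center offsets.

Frame images are dose-normalized (constant plateau regardless of the frame's
MU share), and the per-frame pixel scaling factor is set so that dividing
the in-field mean of the processed image by it returns the frame's true MU
increment — mirroring how the acquisition log's scaling factor works.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .config import DetectorGeometry
from .deconvolution import (
    STAGE_DECONVOLVED,
    STAGE_IDEAL,
    FluenceImage,
    convolve,
    gaussian_kernel,
    raw_from_fluence,
)
from .epid_io import (
    AcquisitionLog,
    PlanControlPoint,
    RawFrame,
    RawFrameSequence,
    VmatPlan,
)

DEFAULT_PLATEAU = 40000.0


class SyntheticError(ValueError):
    pass


# ------------------------------------------------------------ rasterization


def rasterize_aperture(
    bank_a_mm: np.ndarray,
    bank_b_mm: np.ndarray,
    leaf_widths: list[float],
    geometry: DetectorGeometry,
) -> np.ndarray:
    """Binary aperture image: pixel on iff its center lies inside the
    half-open [left, right) leaf opening of its row's leaf band."""
    res = geometry.resolution
    img = np.zeros((res, res), dtype=float)
    bounds_mm = [-sum(leaf_widths) / 2.0]
    for w in leaf_widths:
        bounds_mm.append(bounds_mm[-1] + w)
    centers = np.array([geometry.pixel_center_mm(c) for c in range(res)])
    rows_mm = centers  # same convention on both axes
    for i, (b0, b1) in enumerate(zip(bounds_mm, bounds_mm[1:])):
        rows = np.flatnonzero((rows_mm >= b0) & (rows_mm < b1))
        if rows.size == 0:
            continue
        cols = (centers >= bank_a_mm[i]) & (centers < bank_b_mm[i])
        img[np.ix_(rows, np.flatnonzero(cols))] = 1.0
    return img


def ideal_box(size_cm: float, geometry: DetectorGeometry) -> np.ndarray:
    """Centered square field of the given nominal side, as a 0/1 image."""
    half = size_cm * 10.0 / 2.0
    res = geometry.resolution
    centers = np.array([geometry.pixel_center_mm(c) for c in range(res)])
    on = (centers >= -half) & (centers < half)
    if not on.any() or on.all():
        raise SyntheticError(f"{size_cm} cm box does not fit the {res}px detector")
    img = np.zeros((res, res), dtype=float)
    img[np.ix_(np.flatnonzero(on), np.flatnonzero(on))] = 1.0
    return img


def _blur(values: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return values.copy()
    return convolve(values, gaussian_kernel(sigma))


def gen_box_series(
    sizes_cm: list[float] | None = None,
    geometry: DetectorGeometry | None = None,
    blur_sigma: float = 2.0,
    plateau: float = DEFAULT_PLATEAU,
) -> tuple[dict[float, RawFrame], dict[float, FluenceImage]]:
    """Calibration box series: raw (blurred, inverted) frames plus the ideal
    fluences, keyed by nominal box side in cm."""
    if sizes_cm is None:
        sizes_cm = [5.0, 10.0, 15.0, 20.0]
    if geometry is None:
        geometry = DetectorGeometry()
    raws: dict[float, RawFrame] = {}
    ideals: dict[float, FluenceImage] = {}
    for k, size in enumerate(sizes_cm):
        ideal = ideal_box(size, geometry) * plateau
        blurred = _blur(ideal, blur_sigma)
        raws[size] = RawFrame(pixels=raw_from_fluence(blurred), frame_index=k, timestamp=0.3 * k)
        ideals[size] = FluenceImage(values=ideal, stage=STAGE_IDEAL)
    return raws, ideals


# -------------------------------------------------------------- arc plans


def _snap(mm: np.ndarray, geometry: DetectorGeometry) -> np.ndarray:
    return np.round(np.asarray(mm) / geometry.pixel_mm) * geometry.pixel_mm


def _aperture_waveform(
    progress: float,
    n_pairs: int,
    sweep_mm: float = 40.0,
    half_gap_mm: float = 20.0,
    wiggle_mm: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window aperture: window center sweeps across the field while
    each leaf pair adds a slowly rotating sinusoidal perturbation."""
    center = -sweep_mm / 2.0 + sweep_mm * progress
    idx = np.arange(n_pairs)
    phase = 2.0 * np.pi * idx / max(n_pairs, 1)
    left = center - half_gap_mm + wiggle_mm * np.sin(phase + 2.0 * np.pi * progress)
    right = center + half_gap_mm + wiggle_mm * np.cos(phase + 2.0 * np.pi * progress)
    return left, right


def make_arc_plan(
    plan_id: str = "synthetic-arc",
    total_mu: float = 200.0,
    n_cp: int = 90,
    n_leaf_pairs: int = 20,
    leaf_width_mm: float = 5.0,
    beam_energy: str = "6",
    gantry_start: float = 179.0,
    arc_span: float = -358.0,
    collimator: float = 0.0,
    geometry: DetectorGeometry | None = None,
    dose_rate: Callable[[float], float] | None = None,
) -> VmatPlan:
    """Sliding-window VMAT arc with leaf positions snapped to the pixel grid
    (so rasterization and edge extraction are exactly invertible)."""
    if geometry is None:
        geometry = DetectorGeometry()
    if n_cp < 2:
        raise SyntheticError("need >= 2 control points")
    if dose_rate is None:
        dose_rate = lambda t: 1.0 + 0.5 * np.sin(2.0 * np.pi * t)  # noqa: E731
    widths = [leaf_width_mm] * n_leaf_pairs
    ts = np.linspace(0.0, 1.0, n_cp)
    rates = np.array([dose_rate(float(t)) for t in ts[1:]])
    if np.any(rates <= 0) or rates.sum() <= 0:
        raise SyntheticError("dose-rate waveform must be positive")
    cum = np.concatenate([[0.0], np.cumsum(rates)])
    cum = cum / cum[-1] * total_mu
    cps = []
    for k, t in enumerate(ts):
        left, right = _aperture_waveform(float(t), n_leaf_pairs)
        cps.append(
            PlanControlPoint(
                index=k,
                gantry_angle=(gantry_start + arc_span * float(t)) % 360.0,
                collimator_angle=collimator,
                cumulative_mu=float(cum[k]),
                bank_A=list(_snap(left, geometry)),
                bank_B=list(_snap(right, geometry)),
            )
        )
    return VmatPlan(
        plan_id=plan_id,
        beam_energy=beam_energy,
        total_mu=total_mu,
        control_points=cps,
        n_leaf_pairs=n_leaf_pairs,
        leaf_widths=widths,
    )


# --------------------------------------------------------- acquisitions


@dataclass
class SyntheticTruth:
    plan: VmatPlan
    frame_bank_a_mm: list[list[float]]
    frame_bank_b_mm: list[list[float]]
    frame_mu_increment: list[float]
    frame_gantry_deg: list[float]
    blur_sigma: float
    noise_sd: float
    seed: int
    injected_shifts: list[tuple[float, float]] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "plan_id": self.plan.plan_id,
            "total_mu": self.plan.total_mu,
            "n_leaf_pairs": self.plan.n_leaf_pairs,
            "leaf_widths": self.plan.leaf_widths,
            "frame_bank_a_mm": self.frame_bank_a_mm,
            "frame_bank_b_mm": self.frame_bank_b_mm,
            "frame_mu_increment": self.frame_mu_increment,
            "frame_gantry_deg": self.frame_gantry_deg,
            "blur_sigma": self.blur_sigma,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "injected_shifts": [list(s) for s in self.injected_shifts],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @staticmethod
    def load_frames_json(path) -> dict:
        """Load just the per-frame truth arrays (no plan reconstruction)."""
        with open(path) as fh:
            return json.load(fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        """Rebuild the per-frame truth from JSON. The plan field is left
        unset (None): recovery statistics only need the frame arrays."""
        d = cls.load_frames_json(path)
        return cls(
            plan=None,
            frame_bank_a_mm=d["frame_bank_a_mm"],
            frame_bank_b_mm=d["frame_bank_b_mm"],
            frame_mu_increment=d["frame_mu_increment"],
            frame_gantry_deg=d["frame_gantry_deg"],
            blur_sigma=d["blur_sigma"],
            noise_sd=d["noise_sd"],
            seed=d["seed"],
            injected_shifts=[tuple(s) for s in d.get("injected_shifts", [])],
        )


def _gantry_at_mu(plan: VmatPlan, cumulative_mu: np.ndarray) -> np.ndarray:
    from .mu_calib import _unwrap_gantry  # local import to avoid cycle

    plan_cum = np.asarray([cp.cumulative_mu for cp in plan.control_points])
    unwrapped = _unwrap_gantry([cp.gantry_angle for cp in plan.control_points])
    return np.interp(cumulative_mu, plan_cum, unwrapped) % 360.0


def gen_vmat_acquisition(
    plan: VmatPlan | None = None,
    n_frames: int = 60,
    blur_sigma: float = 2.0,
    noise_sd: float = 0.0,
    shifts: list[tuple[int, int]] | None = None,
    seed: int = 0,
    geometry: DetectorGeometry | None = None,
    frame_period_s: float = 0.3,
    plateau: float = DEFAULT_PLATEAU,
    dose_rate: Callable[[float], float] | None = None,
) -> tuple[RawFrameSequence, SyntheticTruth]:
    """Full synthetic acquisition for an arc plan.

    ``shifts`` optionally injects a per-frame integer (dx, dy) detector
    offset (columns, rows). The per-frame dose waveform defaults to the
    plan-generation waveform; increments are normalized to the plan total.
    """
    if n_frames < 2:
        raise SyntheticError("need >= 2 frames")
    if geometry is None:
        geometry = DetectorGeometry()
    if plan is None:
        plan = make_arc_plan(geometry=geometry, dose_rate=dose_rate)
    if dose_rate is None:
        dose_rate = lambda t: 1.0 + 0.5 * np.sin(2.0 * np.pi * t)  # noqa: E731
    if shifts is not None and len(shifts) != n_frames:
        raise SyntheticError("shifts must have one (dx, dy) per frame")
    rng = np.random.default_rng(seed)

    mids = (np.arange(n_frames) + 0.5) / n_frames
    rates = np.array([dose_rate(float(t)) for t in mids])
    if np.any(rates <= 0) or rates.sum() <= 0:
        raise SyntheticError("dose waveform must be positive with nonzero total")
    mu_inc = rates / rates.sum() * plan.total_mu
    cum = np.cumsum(mu_inc)
    gantry = _gantry_at_mu(plan, cum)

    frames, psfs, times = [], [], []
    bank_a_all, bank_b_all = [], []
    for k in range(n_frames):
        left, right = _aperture_waveform(float(mids[k]), plan.n_leaf_pairs)
        left = _snap(left, geometry)
        right = _snap(right, geometry)
        bank_a_all.append([float(v) for v in left])
        bank_b_all.append([float(v) for v in right])
        mask = rasterize_aperture(left, right, plan.leaf_widths, geometry)
        fluence = _blur(mask * plateau, blur_sigma)
        if noise_sd > 0:
            fluence = fluence * (1.0 + noise_sd * rng.standard_normal(fluence.shape))
            fluence = np.clip(fluence, 0.0, None)
        if shifts is not None:
            dx, dy = shifts[k]
            fluence = np.roll(fluence, (int(dy), int(dx)), axis=(0, 1))
            mask = np.roll(mask, (int(dy), int(dx)), axis=(0, 1))
        raw = raw_from_fluence(fluence)
        processed = 65535.0 - raw.astype(float)
        infield = processed[mask > 0]
        psfs.append(float(infield.mean()) / float(mu_inc[k]))
        frames.append(RawFrame(pixels=raw, frame_index=k, timestamp=k * frame_period_s))
        times.append(k * frame_period_s)

    seq = RawFrameSequence(
        frames=frames,
        log=AcquisitionLog(n_frames=n_frames, frame_times=times, psf_values=psfs),
    )
    truth = SyntheticTruth(
        plan=plan,
        frame_bank_a_mm=bank_a_all,
        frame_bank_b_mm=bank_b_all,
        frame_mu_increment=[float(v) for v in mu_inc],
        frame_gantry_deg=[float(g) for g in gantry],
        blur_sigma=blur_sigma,
        noise_sd=noise_sd,
        seed=seed,
        injected_shifts=[(float(a), float(b)) for a, b in shifts] if shifts else [],
    )
    return seq, truth


# ------------------------------------------------------------ offset sets


def make_sinusoidal_shift_fn(
    amp_cross_px: float = 3.0, amp_in_px: float = 2.0, coll_gain_px: float = 0.0
) -> Callable[[float, float], tuple[int, int]]:
    """Injected pose-shift model: sinusoidal gantry sag plus a collimator
    term that vanishes at collimator 0, rounded to whole pixels."""

    def fn(gantry: float, coll: float) -> tuple[int, int]:
        g = np.deg2rad(gantry)
        dx = amp_cross_px * np.sin(g) + coll_gain_px * (coll / 90.0) * np.cos(g)
        dy = amp_in_px * (np.cos(g) - 1.0) / 2.0 + coll_gain_px * (coll / 90.0) * np.sin(g)
        return int(round(dx)), int(round(dy))

    return fn


def gen_offset_acquisition(
    shift_fn: Callable[[float, float], tuple[int, int]] | None = None,
    geometry: DetectorGeometry | None = None,
    sag_gantry_grid: list[float] | None = None,
    coll_gantry_grid: list[float] | None = None,
    coll_grid: list[float] | None = None,
    box_cm: float = 10.0,
    plateau: float = DEFAULT_PLATEAU,
) -> dict[tuple[float, float], FluenceImage]:
    """10x10 box images over the two pose grids, each rigidly shifted by the
    injected model at its pose. With the default zero shift all images are
    identical."""
    if geometry is None:
        geometry = DetectorGeometry()
    if shift_fn is None:
        shift_fn = lambda g, c: (0, 0)  # noqa: E731
    if sag_gantry_grid is None:
        sag_gantry_grid = [float(g) for g in range(0, 360, 10)]
    if coll_gantry_grid is None:
        coll_gantry_grid = [float(g) for g in range(0, 360, 30)]
    if coll_grid is None:
        coll_grid = [float(c) for c in range(-90, 91, 30)]
    base = ideal_box(box_cm, geometry) * plateau
    poses = [(g, 0.0) for g in sag_gantry_grid]
    poses += [(g, c) for g in coll_gantry_grid for c in coll_grid]
    out: dict[tuple[float, float], FluenceImage] = {}
    for g, c in poses:
        dx, dy = shift_fn(g, c)
        shifted = np.roll(base, (int(dy), int(dx)), axis=(0, 1))
        out[(g, c)] = FluenceImage(values=shifted, stage=STAGE_DECONVOLVED)
    return out


def write_truth_and_frames(directory, seq: RawFrameSequence, truth: SyntheticTruth) -> None:
    """Persist an acquisition: PNG frames + sidecar log + truth JSON."""
    from .epid_io import write_frame_sequence

    directory = Path(directory)
    write_frame_sequence(directory, seq)
    truth.to_json(directory / "truth.json")
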