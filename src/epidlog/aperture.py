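"""MLC aperture extraction from deconvolved frames.

Stages: binarization at a calibrated absolute threshold, per-leaf-band edge
localization (integer-pixel, half-open column runs), and correction of
detector-pose-dependent imaging-center offsets (gantry sag and collimator
shift).

Sign/axis conventions: a positive cross-plane offset means the imaged field
appears shifted toward higher column indices; correcting an aperture
therefore subtracts the offset from its edge positions. In-plane offsets are
handled before extraction, by shifting the leaf-row bands; cross-plane
offsets translate the extracted edge columns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import DetectorGeometry
from .deconvolution import STAGE_DECONVOLVED, FluenceImage


class ApertureError(ValueError):
    pass


@dataclass
class BinaryAperture:
    mask: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def binarize(image: FluenceImage, threshold: float) -> BinaryAperture:
    """mask = values >= threshold. Warns (not errors) on an empty mask."""
    if image.stage != STAGE_DECONVOLVED:
        raise ApertureError(f"binarize expects a deconvolved image, got stage {image.stage!r}")
    if threshold <= 0:
        raise ApertureError("threshold must be > 0")
    mask = image.values >= threshold
    if not mask.any():
        warnings.warn("empty aperture: no pixel reaches the threshold", stacklevel=2)
    return BinaryAperture(mask=mask, threshold_used=float(threshold))


# ------------------------------------------------------------- calibration


@dataclass
class ThresholdCalibration:
    candidate_thresholds: list[float]
    linearity_table: dict[float, list[float]]  # candidate -> ratios vs smallest box
    valid_range: tuple[float, float]
    chosen: float

    def to_json(self, path) -> None:
        payload = {
            "candidate_thresholds": self.candidate_thresholds,
            "linearity_table": {f"{k:g}": v for k, v in self.linearity_table.items()},
            "valid_range": list(self.valid_range),
            "chosen": self.chosen,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ThresholdCalibration":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            candidate_thresholds=d["candidate_thresholds"],
            linearity_table={float(k): v for k, v in d["linearity_table"].items()},
            valid_range=tuple(d["valid_range"]),
            chosen=d["chosen"],
        )


def _central_band_rows(resolution: int, half_rows: int) -> np.ndarray:
    center = (resolution - 1) / 2.0
    rows = np.arange(resolution)
    return rows[np.abs(rows - center) <= half_rows]


def cross_plane_count(mask: np.ndarray, half_rows: int = 5) -> float:
    """Mean number of open pixels per row over the central leaf band."""
    rows = _central_band_rows(mask.shape[0], half_rows)
    return float(mask[rows, :].sum(axis=1).mean())


def calibrate_threshold(
    box_images: dict[float, FluenceImage],
    grid_step: float = 100.0,
    tolerance: float = 0.02,
    band_half_rows: int = 5,
) -> ThresholdCalibration:
    """Sweep absolute thresholds over 40-60% of the maximum pixel value and
    keep the contiguous range where the binarized cross-plane pixel counts of
    the larger boxes scale linearly with nominal box size (ratios within
    ``tolerance`` of their integer targets). The chosen threshold is the
    midpoint of that range.

    ``box_images`` maps nominal box side (cm) to its deconvolved image; four
    distinct sizes (canonically 5/10/15/20) are required.
    """
    sizes = sorted(box_images)
    if len(sizes) != 4 or len(set(sizes)) != 4:
        raise ApertureError(f"need 4 distinct box sizes, got {sizes}")
    for s, img in box_images.items():
        if img.stage != STAGE_DECONVOLVED:
            raise ApertureError(f"box {s} cm: expected deconvolved stage, got {img.stage!r}")
    base = sizes[0]
    targets = [s / base for s in sizes[1:]]

    max_val = max(float(img.values.max()) for img in box_images.values())
    if max_val <= 0:
        raise ApertureError("box images are empty")
    lo, hi = 0.4 * max_val, 0.6 * max_val
    cands = grid_step * np.arange(np.ceil(lo / grid_step), np.floor(hi / grid_step) + 1)
    if len(cands) == 0:
        raise ApertureError("threshold grid is empty; decrease grid_step")

    table: dict[float, list[float]] = {}
    valid = np.zeros(len(cands), dtype=bool)
    for i, t in enumerate(cands):
        counts = [cross_plane_count(box_images[s].values >= t, band_half_rows) for s in sizes]
        if counts[0] <= 0:
            table[float(t)] = [float("inf")] * len(targets)
            continue
        ratios = [c / counts[0] for c in counts[1:]]
        table[float(t)] = ratios
        valid[i] = all(abs(r - tgt) <= tolerance for r, tgt in zip(ratios, targets))

    if not valid.any():
        best = min(table, key=lambda t: max(abs(r - tgt) for r, tgt in zip(table[t], targets)))
        raise ApertureError(
            f"no threshold in [{lo:.0f}, {hi:.0f}] satisfies linearity +/-{tolerance}; "
            f"best candidate {best:g} achieved ratios {table[best]}"
        )
    # maximal contiguous run of valid candidates
    best_run, run_start, n_run = (0, 0), None, 0
    for i, ok in enumerate(list(valid) + [False]):
        if ok:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start > n_run:
                n_run, best_run = i - run_start, (run_start, i - 1)
            run_start = None
    low, high = float(cands[best_run[0]]), float(cands[best_run[1]])
    return ThresholdCalibration(
        candidate_thresholds=[float(t) for t in cands],
        linearity_table=table,
        valid_range=(low, high),
        chosen=(low + high) / 2.0,
    )


# ---------------------------------------------------------- edge extraction


@dataclass
class LeafPair:
    leaf_index: int
    left_edge_mm: float
    right_edge_mm: float
    open: bool


@dataclass
class LeafAperture:
    frame_index: int
    pairs: list[LeafPair]


def leaf_band_rows(
    leaf_widths: list[float], geometry: DetectorGeometry, row_shift_px: int = 0
) -> list[tuple[int, int]]:
    """Half-open [row0, row1) detector-row bands, one per leaf pair, centered
    on the detector in-plane axis and optionally shifted by an in-plane
    offset."""
    bounds_mm = [-sum(leaf_widths) / 2.0]
    for w in leaf_widths:
        bounds_mm.append(bounds_mm[-1] + w)
    res = geometry.resolution
    bands = []
    for b0, b1 in zip(bounds_mm, bounds_mm[1:]):
        r0 = int(round(geometry.mm_to_boundary(b0))) + row_shift_px
        r1 = int(round(geometry.mm_to_boundary(b1))) + row_shift_px
        bands.append((max(0, min(res, r0)), max(0, min(res, r1))))
    return bands


def _longest_run(profile: np.ndarray) -> tuple[int, int, int]:
    """(start, stop_exclusive, n_runs) of the longest True run; (0,0,0) if none."""
    padded = np.concatenate([[False], profile, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    if len(starts) == 0:
        return 0, 0, 0
    lengths = stops - starts
    k = int(np.argmax(lengths))
    return int(starts[k]), int(stops[k]), len(starts)


def extract_leaf_edges(
    ap: BinaryAperture,
    geometry: DetectorGeometry,
    leaf_widths: list[float],
    frame_index: int = 0,
    row_shift_px: int = 0,
    park_mm: float = 0.0,
    park_gap_mm: float = 0.5,
) -> LeafAperture:
    """Per leaf-row band, take the longest open column run; its half-open
    [start, stop) span maps to left/right edge positions in mm at isocenter.
    Bands with no open pixels are reported closed at the park position."""
    bands = leaf_band_rows(leaf_widths, geometry, row_shift_px)
    pairs = []
    for i, (r0, r1) in enumerate(bands):
        if r1 <= r0:
            profile = np.zeros(ap.mask.shape[1], dtype=bool)
        else:
            profile = ap.mask[r0:r1, :].mean(axis=0) >= 0.5
        start, stop, n_runs = _longest_run(profile)
        if n_runs > 1:
            warnings.warn(
                f"leaf band {i}: {n_runs} disjoint open runs; keeping the longest (island artifact)",
                stacklevel=2,
            )
        if n_runs == 0:
            pairs.append(
                LeafPair(i, park_mm - park_gap_mm / 2.0, park_mm + park_gap_mm / 2.0, open=False)
            )
        else:
            pairs.append(
                LeafPair(
                    i,
                    geometry.boundary_to_mm(start),
                    geometry.boundary_to_mm(stop),
                    open=True,
                )
            )
    return LeafAperture(frame_index=frame_index, pairs=pairs)


# ------------------------------------------------------------ offset model


@dataclass
class OffsetModel:
    """Imaging-center offsets in pixels versus machine pose.

    ``sag_*`` tables are indexed by gantry angle (collimator 0); the
    ``coll_*`` tables hold the additional shift attributable to collimator
    rotation, i.e. pose measurement minus the same-gantry collimator-0
    measurement, on a (gantry x collimator) grid. All offsets are 0 at the
    reference pose by construction, and gantry interpolation is periodic.
    """

    sag_gantry: list[float]
    sag_cross_left: list[float]
    sag_cross_right: list[float]
    sag_in_upper: list[float]
    sag_in_lower: list[float]
    coll_gantry: list[float] = field(default_factory=list)
    coll_angles: list[float] = field(default_factory=list)
    coll_shift_cross: list[list[float]] = field(default_factory=list)
    coll_shift_in: list[list[float]] = field(default_factory=list)

    @classmethod
    def zero(cls) -> "OffsetModel":
        return cls([0.0], [0.0], [0.0], [0.0], [0.0])

    def _sag(self, table: list[float], gantry: float) -> float:
        xp = np.asarray(self.sag_gantry, dtype=float)
        fp = np.asarray(table, dtype=float)
        if len(xp) == 1:
            return float(fp[0])
        return float(np.interp(gantry % 360.0, xp, fp, period=360.0))

    def _coll(self, table: list[list[float]], gantry: float, coll: float) -> float:
        if not self.coll_gantry or not self.coll_angles:
            return 0.0
        ca = np.asarray(self.coll_angles, dtype=float)
        if coll < ca.min() - 1e-9 or coll > ca.max() + 1e-9:
            raise ApertureError(f"collimator angle {coll} outside calibrated grid [{ca.min()}, {ca.max()}]")
        arr = np.asarray(table, dtype=float)  # [gantry, coll]
        j = int(np.clip(np.searchsorted(ca, coll) - 1, 0, len(ca) - 2))
        t = 0.0 if ca[j + 1] == ca[j] else (coll - ca[j]) / (ca[j + 1] - ca[j])
        gp = np.asarray(self.coll_gantry, dtype=float)

        def along_gantry(col_idx: int) -> float:
            if len(gp) == 1:
                return float(arr[0, col_idx])
            return float(np.interp(gantry % 360.0, gp, arr[:, col_idx], period=360.0))

        return (1 - t) * along_gantry(j) + t * along_gantry(j + 1)

    def cross_offsets_px(self, gantry: float, collimator: float) -> tuple[float, float]:
        """(left-bank, right-bank) cross-plane offsets at a pose."""
        shift = self._coll(self.coll_shift_cross, gantry, collimator)
        return (
            self._sag(self.sag_cross_left, gantry) + shift,
            self._sag(self.sag_cross_right, gantry) + shift,
        )

    def inplane_offset_px(self, gantry: float, collimator: float) -> float:
        sag = 0.5 * (self._sag(self.sag_in_upper, gantry) + self._sag(self.sag_in_lower, gantry))
        return sag + self._coll(self.coll_shift_in, gantry, collimator)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "OffsetModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def _box_metrics(values: np.ndarray, band_half: int = 5) -> tuple[float, float, float, float]:
    """(left_col, right_col_exclusive, top_row, bottom_row_exclusive) of a
    box field, measured on central-band majority profiles at half maximum."""
    threshold = 0.5 * values.max()
    mask = values >= threshold
    rows = _central_band_rows(mask.shape[0], band_half)
    col_profile = mask[rows, :].mean(axis=0) >= 0.5
    c0, c1, _ = _longest_run(col_profile)
    cols = _central_band_rows(mask.shape[1], band_half)
    row_profile = mask[:, cols].mean(axis=1) >= 0.5
    r0, r1, _ = _longest_run(row_profile)
    if c1 <= c0 or r1 <= r0:
        raise ApertureError("box field not detected in offset-calibration image")
    return float(c0), float(c1), float(r0), float(r1)


def _norm_pose(g: float, c: float) -> tuple[float, float]:
    return (round(float(g) % 360.0, 3), round(float(c), 3))


def measure_center_offsets(
    images: dict[tuple[float, float], FluenceImage],
    sag_gantry_grid: list[float] | None = None,
    coll_gantry_grid: list[float] | None = None,
    coll_grid: list[float] | None = None,
    band_half_rows: int = 5,
) -> OffsetModel:
    """Tabulate imaging-center offsets from 10x10 box images acquired over
    the pose grids: gantry-only (10 deg steps, collimator 0) for the sag
    tables and a (30 deg x 30 deg) gantry-collimator grid for the additional
    collimator-rotation shift. A missing pose is a hard error naming it."""
    if sag_gantry_grid is None:
        sag_gantry_grid = [float(g) for g in range(0, 360, 10)]
    if coll_gantry_grid is None:
        coll_gantry_grid = [float(g) for g in range(0, 360, 30)]
    if coll_grid is None:
        coll_grid = [float(c) for c in range(-90, 91, 30)]

    lut = {_norm_pose(g, c): img for (g, c), img in images.items()}

    def metrics(g: float, c: float):
        key = _norm_pose(g, c)
        if key not in lut:
            raise ApertureError(f"missing calibration image at pose gantry={g}, collimator={c}")
        return _box_metrics(lut[key].values, band_half_rows)

    ref_l, ref_r, ref_t, ref_b = metrics(0.0, 0.0)
    sag_l, sag_r, sag_t, sag_b = [], [], [], []
    for g in sag_gantry_grid:
        l, r, t, b = metrics(g, 0.0)
        sag_l.append(l - ref_l)
        sag_r.append(r - ref_r)
        sag_t.append(t - ref_t)
        sag_b.append(b - ref_b)

    shift_cross, shift_in = [], []
    for g in coll_gantry_grid:
        l0, r0, t0, b0 = metrics(g, 0.0)
        row_x, row_y = [], []
        for c in coll_grid:
            l, r, t, b = metrics(g, c)
            row_x.append(((l + r) - (l0 + r0)) / 2.0)
            row_y.append(((t + b) - (t0 + b0)) / 2.0)
        shift_cross.append(row_x)
        shift_in.append(row_y)

    return OffsetModel(
        sag_gantry=list(sag_gantry_grid),
        sag_cross_left=sag_l,
        sag_cross_right=sag_r,
        sag_in_upper=sag_t,
        sag_in_lower=sag_b,
        coll_gantry=list(coll_gantry_grid),
        coll_angles=list(coll_grid),
        coll_shift_cross=shift_cross,
        coll_shift_in=shift_in,
    )


def apply_offset_correction(
    ap: LeafAperture,
    gantry: float,
    collimator: float,
    model: OffsetModel,
    geometry: DetectorGeometry,
) -> LeafAperture:
    """Shift extracted edges by minus the pose-interpolated cross-plane
    offsets (left bank by the left table, right bank by the right one)."""
    off_l, off_r = model.cross_offsets_px(gantry, collimator)
    pairs = []
    for p in ap.pairs:
        if not p.open:
            pairs.append(LeafPair(p.leaf_index, p.left_edge_mm, p.right_edge_mm, False))
        else:
            pairs.append(
                LeafPair(
                    p.leaf_index,
                    p.left_edge_mm - off_l * geometry.pixel_mm,
                    p.right_edge_mm - off_r * geometry.pixel_mm,
                    True,
                )
            )
    return LeafAperture(frame_index=ap.frame_index, pairs=pairs)
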