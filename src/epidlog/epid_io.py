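"""Readers and writers for external artifacts.

Covers the four artifact families the pipeline touches:

* EPID frame sequences — 16-bit grayscale PNG files plus a plain-text
  acquisition-log sidecar (``acquisition.log``, dialect ``EPIDACQ/1.0``:
  one line per frame with ``index  time_s  psf``).
* DICOM RT-Plan arc beams (read and write, explicit VR little endian).
* The packaged 18-plan gamma-passing-rate / complexity-index table.

Coordinate conventions (used throughout the package): row 0 is the top of
the detector, column 0 the left; the image center sits at pixel coordinate
((N-1)/2, (N-1)/2); cross-plane (leaf travel, X) runs along columns,
in-plane (leaf stacking, Y) along rows. Pixel spans are 0-based and
half-open, and leaf positions are millimetres at the isocenter plane,
signed about the beam axis (negative = bank A side).
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import _dicom

ACQ_LOG_NAME = "acquisition.log"
ACQ_MAGIC = "EPIDACQ/1.0"
_FRAME_RE = re.compile(r"^frame_(\d+)\.png$")


class EpidIOError(ValueError):
    """Raised for any malformed or inconsistent external artifact."""


# ------------------------------------------------------------------ types


@dataclass
class RawFrame:
    """One inverted-intensity 16-bit EPID frame."""

    pixels: np.ndarray  # uint16, square
    frame_index: int
    timestamp: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise EpidIOError(f"frame {self.frame_index}: pixels must be square 2D, got {self.pixels.shape}")
        if self.pixels.dtype != np.uint16:
            if np.any(self.pixels < 0) or np.any(self.pixels > 65535):
                raise EpidIOError(f"frame {self.frame_index}: pixel values outside [0, 65535]")
            self.pixels = self.pixels.astype(np.uint16)
        if self.frame_index < 0:
            raise EpidIOError("frame_index must be >= 0")


@dataclass
class AcquisitionLog:
    n_frames: int
    frame_times: list[float]
    psf_values: list[float]

    def __post_init__(self) -> None:
        if not (len(self.frame_times) == len(self.psf_values) == self.n_frames):
            raise EpidIOError(
                f"acquisition log inconsistent: n_frames={self.n_frames}, "
                f"{len(self.frame_times)} times, {len(self.psf_values)} psf values"
            )
        if any(t1 <= t0 for t0, t1 in zip(self.frame_times, self.frame_times[1:])):
            raise EpidIOError("frame_times must be strictly increasing")
        if any(p <= 0 for p in self.psf_values):
            raise EpidIOError("psf_values must be positive")


@dataclass
class RawFrameSequence:
    frames: list[RawFrame]
    log: AcquisitionLog
    degraded: bool = False  # set when 8-bit shim scaling was applied

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class PlanControlPoint:
    index: int
    gantry_angle: float  # degrees, [0, 360)
    collimator_angle: float  # degrees, [-180, 180)
    cumulative_mu: float
    bank_A: list[float]  # mm at isocenter, left edges
    bank_B: list[float]  # mm at isocenter, right edges

    def __post_init__(self) -> None:
        if len(self.bank_A) != len(self.bank_B):
            raise EpidIOError(f"control point {self.index}: bank lengths differ")
        for a, b in zip(self.bank_A, self.bank_B):
            if b < a - 1e-9:
                raise EpidIOError(f"control point {self.index}: bank B edge {b} < bank A edge {a}")


@dataclass
class VmatPlan:
    plan_id: str
    beam_energy: str
    total_mu: float
    control_points: list[PlanControlPoint]
    n_leaf_pairs: int
    leaf_widths: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.control_points) < 2:
            raise EpidIOError("a VMAT plan needs at least 2 control points")
        cum = [cp.cumulative_mu for cp in self.control_points]
        if any(c1 < c0 - 1e-9 for c0, c1 in zip(cum, cum[1:])):
            raise EpidIOError("cumulative MU must be non-decreasing over control points")
        if abs(cum[-1] - self.total_mu) > 1e-6:
            raise EpidIOError(f"total_mu {self.total_mu} != final cumulative MU {cum[-1]}")
        if not self.leaf_widths:
            self.leaf_widths = [5.0] * self.n_leaf_pairs
        if len(self.leaf_widths) != self.n_leaf_pairs:
            raise EpidIOError("leaf_widths length must equal n_leaf_pairs")


# --------------------------------------------------------- frame sequence


def write_acquisition_log(path, log: AcquisitionLog) -> None:
    lines = [ACQ_MAGIC]
    for i, (t, p) in enumerate(zip(log.frame_times, log.psf_values)):
        lines.append(f"{i}\t{t:.6f}\t{p:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_acquisition_log(path) -> AcquisitionLog:
    path = Path(path)
    if not path.exists():
        raise EpidIOError(f"missing acquisition log: {path}")
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or lines[0] != ACQ_MAGIC:
        raise EpidIOError(f"{path}: not an {ACQ_MAGIC} sidecar")
    times, psfs = [], []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != 3:
            raise EpidIOError(f"{path}: malformed log line {ln!r}")
        times.append(float(parts[1]))
        psfs.append(float(parts[2]))
    return AcquisitionLog(n_frames=len(times), frame_times=times, psf_values=psfs)


def write_frame_sequence(directory, seq: RawFrameSequence) -> None:
    """Write frames as frame_<index>.png (16-bit grayscale) + sidecar log."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for fr in seq.frames:
        img = Image.fromarray(fr.pixels.astype(np.uint16), mode="I;16")
        img.save(directory / f"frame_{fr.frame_index:05d}.png")
    write_acquisition_log(directory / ACQ_LOG_NAME, seq.log)


def _load_png(path) -> tuple[np.ndarray, bool]:
    img = Image.open(path)
    if img.mode in ("I;16", "I;16B", "I"):
        arr = np.asarray(img, dtype=np.uint32)
        if arr.max() > 65535:
            raise EpidIOError(f"{path}: pixel values exceed 16-bit range")
        return arr.astype(np.uint16), False
    if img.mode == "L":
        # degraded-shim: accept 8-bit by scaling x257 onto the 16-bit range
        return (np.asarray(img, dtype=np.uint16) * 257), True
    raise EpidIOError(f"{path}: unsupported image mode {img.mode!r} (need 16-bit grayscale)")


def read_frame_sequence(directory, config=None) -> RawFrameSequence:
    """Read a directory of frame_*.png plus its acquisition-log sidecar.

    Frames are ordered by the index in their file name; the count must match
    the log. A ``config`` with a ``detector.resolution`` field overrides the
    default 512-pixel side check.
    """
    directory = Path(directory)
    log = read_acquisition_log(directory / ACQ_LOG_NAME)
    entries = []
    for p in directory.iterdir():
        m = _FRAME_RE.match(p.name)
        if m:
            entries.append((int(m.group(1)), p))
    if not entries:
        raise EpidIOError(f"no frames found in {directory}")
    entries.sort()
    if len(entries) != log.n_frames:
        raise EpidIOError(
            f"frame count mismatch in {directory}: found {len(entries)} frame files "
            f"but acquisition log declares n_frames={log.n_frames}"
        )
    resolution = 512
    if config is not None:
        resolution = config.detector.resolution
    frames, degraded = [], False
    for (idx, path), t in zip(entries, log.frame_times):
        arr, was_8bit = _load_png(path)
        degraded = degraded or was_8bit
        if arr.shape != (resolution, resolution):
            raise EpidIOError(f"{path}: expected {resolution}x{resolution}, got {arr.shape}")
        frames.append(RawFrame(pixels=arr, frame_index=idx, timestamp=t))
    return RawFrameSequence(frames=frames, log=log, degraded=degraded)


# --------------------------------------------------------------- RT plan


def _energy_parts(label: str) -> tuple[float, str]:
    m = re.match(r"^\s*([0-9.]+)\s*(.*)$", label)
    if not m:
        return 6.0, label
    return float(m.group(1)), m.group(2).strip()


def _stable_uid(seed_text: str) -> str:
    digest = int(hashlib.sha1(seed_text.encode()).hexdigest()[:30], 16)
    return f"2.25.{digest}"


def write_rtplan(path, plans: VmatPlan | list[VmatPlan]) -> None:
    """Serialize one or more arc beams into a DICOM RT-Plan file.

    Meterset weights are stored normalized (cumulative_mu / total_mu) with
    BeamMeterset carrying the absolute total, the usual RT-Plan convention.
    Collimator angles are mapped from [-180, 180) to DICOM's [0, 360).
    """
    if isinstance(plans, VmatPlan):
        plans = [plans]
    root = _dicom.Dataset()
    sop_uid = _stable_uid("|".join(p.plan_id for p in plans))
    root.put(0x0008, 0x0016, "UI", _dicom.RTPLAN_SOP_CLASS)
    root.put(0x0008, 0x0018, "UI", sop_uid)
    root.put(0x0008, 0x0060, "CS", "RTPLAN")
    root.put(0x300A, 0x0002, "SH", plans[0].plan_id[:16])

    ref_items = []
    beam_items = []
    for bi, plan in enumerate(plans, start=1):
        ref = _dicom.Dataset()
        ref.put(0x300A, 0x0086, "DS", plan.total_mu)
        ref.put(0x300C, 0x0006, "IS", bi)
        ref_items.append(ref)

        beam = _dicom.Dataset()
        beam.put(0x300A, 0x00C0, "IS", bi)
        beam.put(0x300A, 0x00C2, "LO", plan.plan_id)
        beam.put(0x300A, 0x00C3, "LO", plan.beam_energy)  # energy label incl. FFF suffix
        beam.put(0x300A, 0x00C4, "CS", "DYNAMIC")
        beam.put(0x300A, 0x00C6, "CS", "PHOTON")
        bld = _dicom.Dataset()
        bld.put(0x300A, 0x00B8, "CS", "MLCX")
        bld.put(0x300A, 0x00BC, "IS", plan.n_leaf_pairs)
        span = sum(plan.leaf_widths)
        bounds = [-span / 2.0]
        for w in plan.leaf_widths:
            bounds.append(bounds[-1] + w)
        bld.put(0x300A, 0x00BE, "DS", bounds)
        beam.put(0x300A, 0x00B6, "SQ", [bld])
        beam.put(0x300A, 0x010E, "DS", 1.0)
        beam.put(0x300A, 0x0110, "IS", len(plan.control_points))

        cp_items = []
        energy_mv, _ = _energy_parts(plan.beam_energy)
        for cp in plan.control_points:
            item = _dicom.Dataset()
            item.put(0x300A, 0x0112, "IS", cp.index)
            if cp.index == 0:
                item.put(0x300A, 0x0114, "DS", energy_mv)
            item.put(0x300A, 0x011E, "DS", cp.gantry_angle % 360.0)
            item.put(0x300A, 0x0120, "DS", cp.collimator_angle % 360.0)
            item.put(0x300A, 0x0134, "DS", cp.cumulative_mu / plan.total_mu if plan.total_mu else 0.0)
            pos = _dicom.Dataset()
            pos.put(0x300A, 0x00B8, "CS", "MLCX")
            pos.put(0x300A, 0x011C, "DS", list(cp.bank_A) + list(cp.bank_B))
            item.put(0x300A, 0x011A, "SQ", [pos])
            cp_items.append(item)
        beam.put(0x300A, 0x0111, "SQ", cp_items)
        beam_items.append(beam)

    fg = _dicom.Dataset()
    fg.put(0x300A, 0x0078, "IS", 1)
    fg.put(0x300A, 0x0080, "IS", len(plans))
    fg.put(0x300C, 0x0004, "SQ", ref_items)
    root.put(0x300A, 0x0070, "SQ", [fg])
    root.put(0x300A, 0x00B0, "SQ", beam_items)
    _dicom.write_file(path, root, _dicom.RTPLAN_SOP_CLASS, sop_uid)


def _as_list(v) -> list:
    return list(v) if isinstance(v, (list, tuple)) else [v]


def read_rtplan(path, beam: int = 0) -> VmatPlan:
    """Read one arc beam of a DICOM RT-Plan as a VmatPlan.

    ``beam`` is the 0-based index into the plan's beam sequence; frames are
    associated to a beam explicitly by the caller, never guessed.
    """
    try:
        ds = _dicom.read_file(path)
    except _dicom.DicomError as exc:
        raise EpidIOError(str(exc)) from exc
    if ds.get(0x0008, 0x0016) != _dicom.RTPLAN_SOP_CLASS:
        raise EpidIOError(f"{path}: not an RT-Plan DICOM file (SOP class {ds.get(0x0008, 0x0016)!r})")

    beams = ds.require(0x300A, 0x00B0, "BeamSequence")
    if not 0 <= beam < len(beams):
        raise EpidIOError(f"beam index {beam} out of range: plan has {len(beams)} beam(s)")
    bds = beams[beam]

    metersets = {}
    for fg in ds.get(0x300A, 0x0070, []):
        for ref in fg.get(0x300C, 0x0004, []):
            metersets[int(ref.get(0x300C, 0x0006, 0))] = float(ref.require(0x300A, 0x0086, "BeamMeterset"))
    beam_number = int(bds.get(0x300A, 0x00C0, beam + 1))
    if beam_number not in metersets:
        raise EpidIOError(f"no BeamMeterset for beam number {beam_number}")
    total_mu = metersets[beam_number]

    n_pairs, leaf_widths = None, []
    for dev in bds.get(0x300A, 0x00B6, []):
        if dev.get(0x300A, 0x00B8) in ("MLCX", "MLCY"):
            n_pairs = int(dev.require(0x300A, 0x00BC, "NumberOfLeafJawPairs"))
            bounds = _as_list(dev.get(0x300A, 0x00BE, []))
            leaf_widths = [b1 - b0 for b0, b1 in zip(bounds, bounds[1:])]
    if n_pairs is None:
        raise EpidIOError(f"{path}: beam {beam} has no MLC device description")

    cps_ds = bds.require(0x300A, 0x0111, "ControlPointSequence")
    if len(cps_ds) < 2:
        raise EpidIOError(f"{path}: beam {beam} is static ({len(cps_ds)} control point)")

    cps: list[PlanControlPoint] = []
    gantry = coll = 0.0
    banks: tuple[list[float], list[float]] = ([0.0] * n_pairs, [0.0] * n_pairs)
    for item in cps_ds:
        idx = int(item.require(0x300A, 0x0112, "ControlPointIndex"))
        if item.get(0x300A, 0x011E) is not None:
            gantry = float(item.get(0x300A, 0x011E)) % 360.0
        if item.get(0x300A, 0x0120) is not None:
            c = float(item.get(0x300A, 0x0120)) % 360.0
            coll = c - 360.0 if c >= 180.0 else c
        for pos in item.get(0x300A, 0x011A, []):
            if pos.get(0x300A, 0x00B8) in ("MLCX", "MLCY"):
                vals = _as_list(pos.require(0x300A, 0x011C, "LeafJawPositions"))
                if len(vals) != 2 * n_pairs:
                    raise EpidIOError(f"control point {idx}: expected {2 * n_pairs} leaf positions, got {len(vals)}")
                banks = ([float(v) for v in vals[:n_pairs]], [float(v) for v in vals[n_pairs:]])
        weight = float(item.require(0x300A, 0x0134, "CumulativeMetersetWeight"))
        cps.append(
            PlanControlPoint(
                index=idx,
                gantry_angle=gantry,
                collimator_angle=coll,
                cumulative_mu=weight * total_mu,
                bank_A=list(banks[0]),
                bank_B=list(banks[1]),
            )
        )

    energy = bds.get(0x300A, 0x00C3)
    if energy is None:
        ev = cps_ds[0].get(0x300A, 0x0114, 6.0)
        energy = f"{ev:g}"
    return VmatPlan(
        plan_id=str(bds.get(0x300A, 0x00C2, ds.get(0x300A, 0x0002, "plan"))),
        beam_energy=str(energy),
        total_mu=total_mu,
        control_points=cps,
        n_leaf_pairs=n_pairs,
        leaf_widths=leaf_widths or [],
    )


# ---------------------------------------------------------------- table 3

TABLE3_COLUMNS = [
    "site", "beam", "mu", "gpr_prop", "gpr_mach",
    "sas", "mcsv", "lt", "ltmcs", "aav", "lsv",
    "mlc_mn", "mlc_sn", "mlc_mx", "mlc_sx", "mu_mean", "mu_std",
]


def read_table3(path=None) -> pd.DataFrame:
    """Load the 18-plan GPR / complexity-index table (packaged CSV by default).

    Percent columns are on the 0-100 scale. Any missing cell or a row count
    other than 18 is a hard error.
    """
    if path is None:
        with resources.as_file(resources.files("epidlog.data") / "table3.csv") as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    missing = [c for c in TABLE3_COLUMNS if c not in df.columns]
    if missing:
        raise EpidIOError(f"table3 fixture missing columns: {missing}")
    if len(df) != 18:
        raise EpidIOError(f"table3 fixture must have 18 rows, got {len(df)}")
    numeric = [c for c in TABLE3_COLUMNS if c not in ("site", "beam")]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise EpidIOError(f"table3 fixture: missing or non-numeric cell at row {row}, column {col!r}")
        df[col] = vals.astype(float)
    return df[TABLE3_COLUMNS]
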