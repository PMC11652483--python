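"""End-to-end run: frames + plan -> machine-log file.

Stage order per frame: invert -> deconvolve -> binarize -> extract leaf
edges -> offset-correct -> MU conversion; then frame records are assigned
cumulative MU and gantry angles and serialized as EPIDLOG/1.0. Errors are
re-raised with the failing stage name prefixed.

Because the pose-dependent offset correction needs each frame's gantry
angle, which itself comes from the MU bookkeeping, extraction runs twice
when an offset model is supplied: a first pass without correction fixes the
MU/angle assignment (in-field means are shift-invariant), a second pass
re-extracts with in-plane band re-indexing and cross-plane edge correction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .aperture import (
    LeafAperture,
    OffsetModel,
    ThresholdCalibration,
    apply_offset_correction,
    binarize,
    extract_leaf_edges,
)
from .config import PipelineConfig
from .deconvolution import gaussian_kernel, invert_raw, iterative_deconvolve
from .epid_io import RawFrameSequence, VmatPlan, read_frame_sequence, read_rtplan
from .loggen import EpidLogFile, LogRecord, write_epid_log
from .mu_calib import FrameMU, assign_frame_records, frame_mu


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineResult:
    log: EpidLogFile
    manifest: dict


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def run_pipeline(
    frames_dir,
    plan_path,
    config: PipelineConfig | None = None,
    beam: int = 0,
    threshold: ThresholdCalibration | float | None = None,
    offsets: OffsetModel | None = None,
    out_path=None,
) -> PipelineResult:
    if config is None:
        config = PipelineConfig()
    geometry = config.detector

    with _stage("read"):
        seq: RawFrameSequence = read_frame_sequence(frames_dir, config)
        plan: VmatPlan = read_rtplan(plan_path, beam=beam)

    with _stage("deconvolve"):
        kernel = gaussian_kernel(config.deconv.sigma)
        deconvolved = [
            iterative_deconvolve(
                invert_raw(fr), kernel, tol=config.deconv.tol, max_iter=config.deconv.max_iter
            ).image
            for fr in seq.frames
        ]

    with _stage("binarize"):
        if threshold is None:
            thr = 0.5 * max(img.values.max() for img in deconvolved)
        elif isinstance(threshold, ThresholdCalibration):
            thr = threshold.chosen
        else:
            thr = float(threshold)
        masks = [binarize(img, thr) for img in deconvolved]

    with _stage("mu"):
        frame_mus = [
            FrameMU(frame_index=fr.frame_index, mu_equiv=frame_mu(invert_raw(fr), psf, mask, stat=config.mu.stat))
            for fr, psf, mask in zip(seq.frames, seq.log.psf_values, masks)
        ]
        records = assign_frame_records(frame_mus, plan, seq.log, angle_map=config.mu.angle_map)

    with _stage("extract"):
        apertures: list[LeafAperture] = []
        for mask, rec in zip(masks, records):
            row_shift = 0
            if offsets is not None:
                row_shift = int(round(offsets.inplane_offset_px(rec.gantry_deg, rec.collimator_deg)))
            ap = extract_leaf_edges(
                mask, geometry, plan.leaf_widths, frame_index=rec.frame_index, row_shift_px=row_shift
            )
            if offsets is not None:
                ap = apply_offset_correction(ap, rec.gantry_deg, rec.collimator_deg, offsets, geometry)
            apertures.append(ap)

    with _stage("serialize"):
        header = {
            "plan_id": plan.plan_id,
            "beam_energy": plan.beam_energy,
            "n_leaf_pairs": str(plan.n_leaf_pairs),
            "total_mu": f"{plan.total_mu:.4f}",
            "frame_period_s": f"{_median_period(seq):.3f}",
            "axes": "cross-plane mm at isocenter, bank A negative side",
            "generator": f"epidlog/{__version__}",
        }
        log = EpidLogFile(header=header, records=[])
        for rec, ap in zip(records, apertures):
            log.records.append(
                LogRecord(
                    frame_index=rec.frame_index,
                    time_s=rec.time_s,
                    gantry_deg=rec.gantry_deg,
                    collimator_deg=rec.collimator_deg,
                    cumulative_mu=rec.cumulative_mu,
                    bank_a_mm=[p.left_edge_mm for p in ap.pairs],
                    bank_b_mm=[p.right_edge_mm for p in ap.pairs],
                )
            )
        log.validate()
        if out_path is not None:
            write_epid_log(out_path, log)

    config_text = config.to_toml_text()
    manifest = {
        "epidlog_version": __version__,
        "n_frames": len(seq.frames),
        "plan_id": plan.plan_id,
        "beam": beam,
        "threshold": thr,
        "offsets_applied": offsets is not None,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "config": config.to_dict(),
    }
    if out_path is not None:
        out_path = Path(out_path)
        out_path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=1))
        out_path.with_suffix(".config.toml").write_text(config_text)
    return PipelineResult(log=log, manifest=manifest)


def _median_period(seq: RawFrameSequence) -> float:
    times = seq.log.frame_times
    if len(times) < 2:
        return 0.0
    diffs = sorted(t1 - t0 for t0, t1 in zip(times, times[1:]))
    return diffs[len(diffs) // 2]
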