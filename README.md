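# epidlog

Control-point-specific VMAT QA from sequential EPID frames.

A linac's portal imager, read out frame by frame during an arc delivery,
carries enough information to reconstruct what the machine actually did:
where every MLC leaf was and how much dose had been delivered at each time
step. `epidlog` turns a time-ordered sequence of 16-bit EPID frames plus the
treatment plan into a machine-log file — per-frame MLC banks, gantry angle
and cumulative MU — via

1. **intensity inversion** (frames are stored inverse to dose),
2. **iterative deconvolution** with a Gaussian scatter kernel (additive
   van-Cittert-style updates until the re-blur residual saturates),
3. **calibrated binarization** — the threshold is chosen by requiring that
   binarized 5/10/15/20 cm box fields keep their 2/3/4 cross-plane
   pixel-count ratios over a 40–60 %-of-maximum sweep,
4. **per-leaf edge extraction** on leaf-row bands (integer-pixel, half-open
   column runs),
5. **imaging-center offset correction** for gantry sag and collimator
   rotation, interpolated from a pose-grid calibration,
6. **MU conversion** through the acquisition log's per-frame pixel scaling
   factor, normalized to the plan total, with gantry angles assigned by
   inverse interpolation of the plan's cumulative-MU-vs-gantry polyline.

Around the pipeline sit plan-complexity analytics (SAS, LT, MCSv, LTMCS,
AAV, LSV plus six control-point transition metrics, with Spearman
correlation against gamma passing rates), a global 2D gamma comparator, a
synthetic-data module that generates every input with known ground truth,
and a packaged 18-plan GPR/complexity table used by the deterministic
statistics.

## CLI

```sh
# synthetic inputs with ground truth
epidlog simulate --preset arc     --out runs/arc --frames 60 --seed 1
epidlog simulate --preset boxes   --out runs/boxes
epidlog simulate --preset offsets --out runs/poses --amp-cross 3 --amp-in 2

# machine calibration (reusable JSON artifacts)
epidlog calibrate-threshold runs/boxes --out threshold.json
epidlog calibrate-offsets   runs/poses --out offsets.json

# frames + RT-Plan -> EPIDLOG/1.0 machine log (+ manifest, resolved config)
epidlog convert runs/arc runs/arc/plan.dcm --out run.epidlog \
    --threshold threshold.json --offsets offsets.json

# fidelity and analytics
epidlog validate --truth runs/arc/truth.json --log run.epidlog
epidlog complexity runs/arc/plan.dcm
epidlog correlate            # packaged 18-plan table by default
epidlog table3-stats
```

All stages are deterministic given inputs, config and seed; `convert`
writes a manifest (config hash, versions) next to its output.

## File formats

* **Frames** — `frame_<index>.png`, 16-bit grayscale, plus an
  `acquisition.log` sidecar (`EPIDACQ/1.0`: one line per frame with index,
  time in seconds, pixel scaling factor).
* **Plans** — DICOM RT-Plan, one `VmatPlan` per arc beam; leaf positions in
  mm at the isocenter plane.
* **Logs** — `EPIDLOG/1.0`, a versioned tab-separated text dialect
  (documented in `epidlog/loggen.py`): header block, then one record per
  frame with angles, cumulative MU and both MLC banks. Parsing and
  re-serializing is byte-identical.

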