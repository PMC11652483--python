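import warnings

import pytest

from epidlog.aperture import calibrate_threshold
from epidlog.config import DetectorGeometry, PipelineConfig
from epidlog.deconvolution import gaussian_kernel, invert_raw, iterative_deconvolve
from epidlog.epid_io import write_frame_sequence, write_rtplan
from epidlog.pipeline import run_pipeline
from epidlog.synthetic import gen_box_series, gen_vmat_acquisition


@pytest.fixture
def small_geometry() -> DetectorGeometry:
    """256 px detector at 0.5 mm/px keeps unit tests fast; the default arc
    aperture (edges within +-46 mm) fits its +-64 mm field of view."""
    return DetectorGeometry(resolution=256, pixel_mm=0.5)


@pytest.fixture(scope="session")
def box_calibration_512():
    """Full-procedure threshold calibration on the default 512 px detector:
    ideal 5/10/15/20 cm boxes, sigma=2 blur, iterative deconvolution, sweep
    of 40-60% absolute thresholds. Shared with the acceptance tests."""
    raws, ideals = gen_box_series(blur_sigma=2.0)
    kernel = gaussian_kernel(2.0)
    deconv = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for size, frame in raws.items():
            deconv[size] = iterative_deconvolve(invert_raw(frame), kernel).image
    calibration = calibrate_threshold(deconv)
    return {"raws": raws, "ideals": ideals, "deconvolved": deconv, "calibration": calibration}


@pytest.fixture(scope="session")
def arc_run_60(tmp_path_factory):
    """The 60-frame sliding-window arc preset, run end to end through the
    pipeline at the calibrated-threshold scale. Shared with acceptance."""
    seq, truth = gen_vmat_acquisition(n_frames=60, blur_sigma=2.0, seed=1)
    d = tmp_path_factory.mktemp("arc60")
    write_frame_sequence(d, seq)
    write_rtplan(d / "plan.dcm", truth.plan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(
            d, d / "plan.dcm", PipelineConfig(), threshold=20000.0, out_path=d / "run.epidlog"
        )
    return {"dir": d, "seq": seq, "truth": truth, "result": result}
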