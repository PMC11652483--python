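"""Scatter-blur removal by additive iterative deconvolution.

The acquisition model is ``processed = true * K`` with a normalized Gaussian
kernel K. Starting from the processed image itself, the estimate of the
unblurred image is refined by adding back the mismatch between the re-blurred
estimate and the measurement:

    blurred_n  = estimate_n * K
    estimate_{n+1} = estimate_n + processed - blurred_n

Iteration stops when the L2 mismatch between ``blurred_n`` and the measured
image saturates (relative change below ``tol``) or at ``max_iter``.
Intermediate estimates may go negative; output is clipped to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

STAGE_PROCESSED = "processed"
STAGE_DECONVOLVED = "deconvolved"
STAGE_IDEAL = "ideal"

MAX_RAW = 65535


class DeconvolutionError(ValueError):
    pass


@dataclass
class FluenceImage:
    """A dose-proportional 2D image at a known processing stage."""

    values: np.ndarray
    stage: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DeconvolutionError("FluenceImage must be 2D")
        if self.stage not in (STAGE_PROCESSED, STAGE_DECONVOLVED, STAGE_IDEAL):
            raise DeconvolutionError(f"unknown stage {self.stage!r}")
        if np.any(self.values < 0):
            raise DeconvolutionError("FluenceImage values must be >= 0")


@dataclass
class BlurKernel:
    sigma: float
    half_width: int
    weights: np.ndarray = field(init=False)
    profile: np.ndarray = field(init=False)  # 1-D separable factor

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise DeconvolutionError(f"kernel sigma must be > 0, got {self.sigma}")
        if self.half_width < 1:
            raise DeconvolutionError("kernel half_width must be >= 1")
        x = np.arange(-self.half_width, self.half_width + 1, dtype=float)
        prof = np.exp(-0.5 * (x / self.sigma) ** 2)
        prof /= prof.sum()
        self.profile = prof
        self.weights = np.outer(prof, prof)


def gaussian_kernel(sigma: float, half_width: int | None = None) -> BlurKernel:
    """Sampled 2D Gaussian, truncated at ``half_width`` (default ceil(4*sigma))
    and renormalized to unit sum."""
    if half_width is None:
        half_width = max(1, int(np.ceil(4.0 * sigma)))
    return BlurKernel(sigma=sigma, half_width=half_width)


def convolve(values: np.ndarray, kernel: BlurKernel) -> np.ndarray:
    """Separable convolution with reflective boundary handling."""
    if min(values.shape) < 2 * kernel.half_width + 1:
        raise DeconvolutionError(
            f"kernel ({2 * kernel.half_width + 1} px) larger than image {values.shape}"
        )
    tmp = ndimage.convolve1d(np.asarray(values, dtype=float), kernel.profile, axis=0, mode="reflect")
    return ndimage.convolve1d(tmp, kernel.profile, axis=1, mode="reflect")


def invert_raw(frame) -> FluenceImage:
    """Map an inverted-intensity raw frame (RawFrame or bare array) to a
    dose-proportional image (value -> 65535 - value)."""
    pix = np.asarray(getattr(frame, "pixels", frame))
    if np.any(pix < 0) or np.any(pix > MAX_RAW):
        raise DeconvolutionError("raw pixel values outside [0, 65535]")
    return FluenceImage(values=(MAX_RAW - pix).astype(float), stage=STAGE_PROCESSED)


def raw_from_fluence(values: np.ndarray) -> np.ndarray:
    """Inverse of invert_raw for synthetic generation: clip+round to uint16."""
    clipped = np.clip(np.rint(values), 0, MAX_RAW)
    return (MAX_RAW - clipped).astype(np.uint16)


@dataclass
class DeconvolutionResult:
    image: FluenceImage  # negative ringing clipped to 0 for downstream use
    n_iterations: int
    residual_history: list[float]
    estimate: np.ndarray = None  # raw unclipped iterate; satisfies the re-blur identity


def iterative_deconvolve(
    image: FluenceImage,
    kernel: BlurKernel,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> DeconvolutionResult:
    if image.stage != STAGE_PROCESSED:
        raise DeconvolutionError(f"expected a processed-stage image, got {image.stage!r}")
    if tol <= 0:
        raise DeconvolutionError("tol must be > 0")
    processed = image.values
    if not np.all(np.isfinite(processed)):
        raise DeconvolutionError("non-finite values in input image")

    estimate = processed.copy()
    residuals: list[float] = []
    n = 0
    for n in range(1, max_iter + 1):
        blurred = convolve(estimate, kernel)
        if not np.all(np.isfinite(blurred)):
            raise DeconvolutionError(f"non-finite values at iteration {n}")
        residual = float(np.linalg.norm(blurred - processed))
        residuals.append(residual)
        if residuals[0] == 0.0:  # already a fixed point (e.g. delta kernel)
            estimate = estimate + processed - blurred
            break
        if n > 1 and abs(residuals[-1] - residuals[-2]) / residuals[0] < tol:
            break
        estimate = estimate + processed - blurred
        if n >= max_iter:
            warnings.warn(f"deconvolution hit max_iter={max_iter} before saturating", stacklevel=2)

    out = FluenceImage(values=np.clip(estimate, 0.0, None), stage=STAGE_DECONVOLVED)
    return DeconvolutionResult(image=out, n_iterations=n, residual_history=residuals, estimate=estimate)
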