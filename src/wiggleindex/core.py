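"""Core Wiggle Index computation.

The Wiggle Index (WI) turns a short video of a single well into one scalar
that summarizes total larval motility.  The chain is:

1. spatial Gaussian blur of every frame (suppresses compression artefacts),
2. per pixel, the population standard deviation of intensity within each
   rolling window of ``F`` consecutive frames (sigma_FW),
3. per pixel, the population standard deviation of its series of sigma_FW
   values across all windows (sigma_S) — high where the *variability* of a
   pixel varies, i.e. where animals start and stop moving,
4. the mean of all sigma_S values at or above a cut-off threshold ``T``
   (the WI value); the threshold removes spatially global disturbances such
   as illumination flicker or plate drift, which raise every pixel's
   sigma_S by the same small amount.

All arithmetic is done in 64-bit floats on the native 8-bit intensity scale
(0–255); the default threshold ``T = 30`` is calibrated to that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import AssayMetadata, FrameStack

__all__ = [
    "WIParams",
    "SigmaFWStack",
    "MotilityField",
    "WIRecord",
    "gaussian_blur",
    "rolling_window_sd",
    "sigma_s",
    "wiggle_index",
    "compute_wi",
]


@dataclass(frozen=True)
class WIParams:
    """Parameters of the Wiggle Index pipeline.

    Attributes
    ----------
    blur_sigma
        Standard deviation, in pixels, of the per-frame 2-D Gaussian blur
        (the ImageJ "Gaussian Blur" sigma convention).  0 disables blurring.
    window_size
        Rolling frame-window length ``F``; with the 250-frame, 10 s default
        videos the default of 150 frames corresponds to a 6 s window.
    threshold
        Cut-off ``T`` applied to the sigma_S map, in intensity-SD units on
        the 8-bit scale.
    frame_rate
        Frames per second of the source video.
    sample_sd
        If True use the sample standard deviation (divisor ``n - 1``)
        instead of the population one (divisor ``n``) in both SD passes.
        The defining formulas divide by ``F`` and ``W``, so population SD
        is the default; the flag exists for sensitivity checks only.
    denominator
        How the above-threshold sigma_S sum is averaged — ``"all"`` (total
        pixel count; extensive total-motility reading, the default) or
        ``"above"`` (above-threshold count TA).  See :func:`wiggle_index`.
    """

    blur_sigma: float = 2.0
    window_size: int = 150
    threshold: float = 30.0
    frame_rate: float = 25.0
    sample_sd: bool = False
    denominator: str = "all"

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError(f"blur_sigma must be >= 0, got {self.blur_sigma}")
        if self.window_size < 2:
            raise ValueError(f"window_size must be >= 2, got {self.window_size}")
        if self.threshold < 0:
            raise ValueError(f"threshold must be >= 0, got {self.threshold}")
        if self.denominator not in ("all", "above"):
            raise ValueError(
                f"denominator must be 'all' or 'above', got {self.denominator!r}"
            )


@dataclass
class SigmaFWStack:
    """Rolling-window SDs for one well.

    ``values[w, r, c]`` is sigma_FW of pixel ``(r, c)`` in window ``w``
    (windows advance one frame at a time, so a stack of ``N`` frames yields
    ``W = N - F + 1`` windows).  ``window_means`` retains the per-window
    pixel means (mu_W) for testing and diagnostics.
    """

    values: np.ndarray
    window_means: np.ndarray
    window_size: int

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


@dataclass
class MotilityField:
    """Per-pixel sigma_S map for one well at one time point."""

    sigma_s: np.ndarray
    source_id: str = ""
    well_id: str = ""
    params: WIParams | None = None


@dataclass
class WIRecord:
    """Scalar Wiggle Index for one well at one time point.

    ``wi_value`` is the mean of the above-threshold sigma_S values; if no
    pixel reaches the threshold the well is considered motionless and the
    WI is 0 with ``ta_count`` 0 (rather than undefined), so time courses of
    immobilized larvae remain plottable.
    """

    wi_value: float
    ta_count: int
    metadata: AssayMetadata | None = None
    params: WIParams | None = None


def gaussian_blur(stack: FrameStack, sigma: float) -> FrameStack:
    """Blur every frame independently with a 2-D Gaussian of SD ``sigma`` px.

    Blurring is purely spatial — frames never mix — and uses reflect
    boundary handling, so a spatially constant frame is a fixed point and
    total intensity is conserved up to boundary effects.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return stack
    blurred = ndimage.gaussian_filter(
        stack.frames, sigma=(0.0, sigma, sigma), mode="reflect"
    )
    return replace(stack, frames=blurred)


def _window_stats(frames: np.ndarray, F: int, ddof: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-pass rolling mean/SD along axis 0 with step 1.

    The stack is first re-centred by subtracting frame 0 from every frame
    (per pixel).  Standard deviations are invariant to a per-pixel constant
    shift, and on integer-valued 8-bit input the centring keeps a uniform
    intensity offset bit-exactly irrelevant, which makes the global-offset
    invariance of the index testable to machine precision.
    """
    n = frames.shape[0]
    W = n - F + 1
    y = frames - frames[:1]
    sds = np.empty((W,) + frames.shape[1:], dtype=np.float64)
    means = np.empty_like(sds)
    for w in range(W):
        win = y[w : w + F]
        mu = win.mean(axis=0)
        var = ((win - mu) ** 2).sum(axis=0) / (F - ddof)
        means[w] = mu + frames[0]
        sds[w] = np.sqrt(var)
    return sds, means


def rolling_window_sd(stack: FrameStack, window_size: int, *, sample_sd: bool = False) -> SigmaFWStack:
    """Per-pixel SD of intensity in every rolling window of ``window_size`` frames.

    A stack of ``N`` frames yields ``W = N - F + 1`` windows: the first
    spans frames 1..F, the last frames ``N-F+1``..``N`` (1-based).  The
    population SD (divisor ``F``) is used unless ``sample_sd``.
    """
    F = int(window_size)
    if F < 2:
        raise ValueError(f"window_size must be >= 2, got {F}")
    n = stack.n_frames
    if n < F:
        raise ValueError(
            f"stack has {n} frames but the rolling window needs at least {F}"
        )
    sds, means = _window_stats(stack.frames, F, ddof=1 if sample_sd else 0)
    return SigmaFWStack(values=sds, window_means=means, window_size=F)


def sigma_s(sfw: SigmaFWStack, *, sample_sd: bool = False) -> MotilityField:
    """Per-pixel SD of the sigma_FW series across windows.

    With a single window the series has no dispersion and sigma_S is 0
    everywhere.  Population SD (divisor ``W``) unless ``sample_sd``.
    """
    vals = sfw.values
    W = vals.shape[0]
    if W == 1:
        return MotilityField(sigma_s=np.zeros(vals.shape[1:], dtype=np.float64))
    mu = vals.mean(axis=0)
    var = ((vals - mu) ** 2).sum(axis=0) / (W - (1 if sample_sd else 0))
    return MotilityField(sigma_s=np.sqrt(var))


def wiggle_index(
    field: MotilityField, threshold: float, denominator: str = "all"
) -> WIRecord:
    """Threshold-filtered average of the sigma_S map.

    The sum of all sigma_S values at or above ``threshold`` is divided by

    * ``denominator="all"`` (default): the total pixel count of the well —
      an extensive measure of *total* motility that grows as more of the
      well is active, can take any value down to 0, and is the reading
      consistent with observed WI magnitudes and smoothly decaying
      relative-motility curves;
    * ``denominator="above"``: the above-threshold pixel count TA — the
      plain mean of the surviving sigma_S values, which is confined to
      {0} ∪ [threshold, sigma_S_max] and provided for sensitivity checks.

    ``ta_count`` records TA either way.  An empty above-threshold set
    yields WI = 0, ta_count = 0 (a motionless well, not a missing value).
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    if denominator not in ("all", "above"):
        raise ValueError(f"denominator must be 'all' or 'above', got {denominator!r}")
    sig = np.asarray(field.sigma_s, dtype=np.float64)
    mask = sig >= threshold
    ta = int(mask.sum())
    if ta == 0:
        wi = 0.0
    elif denominator == "above":
        wi = float(sig[mask].mean())
    else:
        wi = float(sig[mask].sum() / sig.size)
    return WIRecord(wi_value=wi, ta_count=ta)


def compute_wi(
    well: FrameStack,
    params: WIParams | None = None,
    metadata: AssayMetadata | None = None,
) -> tuple[WIRecord, MotilityField]:
    """Full pipeline for one well: blur → rolling SD → sigma_S → threshold mean.

    Returns both the scalar :class:`WIRecord` and the :class:`MotilityField`
    so the sigma_S map can be exported as a heat map.
    """
    params = params or WIParams()
    blurred = gaussian_blur(well, params.blur_sigma)
    sfw = rolling_window_sd(blurred, params.window_size, sample_sd=params.sample_sd)
    fld = sigma_s(sfw, sample_sd=params.sample_sd)
    fld.source_id = well.source_id
    fld.well_id = metadata.well_id if metadata is not None else ""
    fld.params = params
    rec = wiggle_index(fld, params.threshold, denominator=params.denominator)
    rec.metadata = metadata
    rec.params = params
    return rec, fld
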