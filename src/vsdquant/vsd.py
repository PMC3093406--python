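"""VSD quantification chain: smoothing, baseline statistics, amplitude maps,
activated-pixel detection, multi-site pooling and pair normalization.

The readout follows standard practice in photostimulation response mapping:

1. Movies are smoothed with a small truncated Gaussian in space (3x3 px,
   sigma 1 px) and time (3 frames, sigma 1 frame).
2. For every pixel, the mean and SD of its baseline activity are computed
   over the 50 frames preceding photostimulation.
3. Signal amplitude is expressed per pixel in SD-above-baseline units (or
   alternatively as dI/I %).
4. A pixel is *activated* when its amplitude is >= 1 SD above its baseline
   mean; the *activation size* of a frame is the fraction of activated
   pixels as a percentage of the frame.
5. A slice's evoked response is a scalar reduction of the post-stimulus
   activation (peak activation size by default), and a treated slice is
   expressed as a percentage of its litter-matched control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import (
    AcquisitionSpec,
    IncompatibleInputsError,
    InsufficientDataError,
    InvalidParameterError,
    OutOfBoundsError,
    VSDMovie,
    pixel_grid,
)
from . import stats as _stats

__all__ = [
    "BaselineStats",
    "AmplitudeMovie",
    "ActivationResult",
    "SliceResponse",
    "PairSummary",
    "DEFAULT_THRESHOLD_SD",
    "DISPLAY_THRESHOLD_SD",
    "smooth_movie",
    "baseline_stats",
    "amplitude_map",
    "delta_i_over_i",
    "activated_pixels",
    "activation_trace",
    "response_amplitude",
    "pool_sites",
    "normalize_pair",
    "summarize_pairs",
    "average_trials",
]

#: Quantification threshold in baseline-SD units.
DEFAULT_THRESHOLD_SD = 1.0
#: Display threshold used when plotting amplitude maps.
DISPLAY_THRESHOLD_SD = 1.1

#: Reduction methods accepted by :func:`response_amplitude`.
REDUCTIONS = ("peak_activation_size", "mean_activation_size", "peak_mean_amplitude")


@dataclass
class BaselineStats:
    """Per-pixel mean and SD maps over a pre-stimulus window.

    ``window`` is the half-open frame interval ``[first, last)`` the maps were
    computed from. SDs use the sample (ddof=1) estimator.
    """

    mean_map: np.ndarray
    sd_map: np.ndarray
    window: Tuple[int, int]

    def __post_init__(self) -> None:
        if self.mean_map.shape != self.sd_map.shape:
            raise IncompatibleInputsError("mean and SD maps must share a shape")
        if self.window[1] - self.window[0] < 2:
            raise InsufficientDataError("baseline window must span >= 2 frames")
        if np.any(self.sd_map < 0):
            raise InvalidParameterError("sd_map must be non-negative")


@dataclass
class AmplitudeMovie:
    """Per-pixel, per-frame response in SD units (or dI/I %).

    ``units`` is ``'sd'`` or ``'dii_percent'``; ``baseline_window`` echoes the
    window of the :class:`BaselineStats` used; ``floored_mask`` marks pixels
    whose baseline SD was floored to avoid division blow-up.
    """

    values: np.ndarray
    spec: AcquisitionSpec
    units: str = "sd"
    baseline_window: Optional[Tuple[int, int]] = None
    stim_site: Optional[Tuple[int, int]] = None
    floored_mask: Optional[np.ndarray] = None
    pooling: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.values.shape != self.spec.shape:
            raise IncompatibleInputsError(
                f"values shape {self.values.shape} does not match spec {self.spec.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("amplitude values must be finite")


@dataclass
class ActivationResult:
    """Activated-pixel mask and activation size for one frame or window."""

    mask: np.ndarray
    activation_size: float  # percent of frame
    threshold_sd: float
    frame_or_window: Tuple[int, int]


@dataclass
class SliceResponse:
    """Scalar summary of one slice's evoked activation."""

    slice_id: str
    response: float
    condition: str = "control"  # {control, treated}
    method: str = "peak_activation_size"
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.response < 0:
            raise InvalidParameterError("response must be >= 0")


@dataclass
class PairSummary:
    """Mean +/- SE of normalized pair responses plus the group test."""

    normalized_responses: List[float]
    mean: float
    se: float
    test: Optional[_stats.GroupComparison] = None


def _require_odd(name: str, k: int) -> None:
    if k < 1 or k % 2 == 0:
        raise InvalidParameterError(f"{name} must be odd and >= 1, got {k}")


def smooth_movie(
    movie: VSDMovie,
    spatial_kernel_px: int = 3,
    spatial_sigma_px: float = 1.0,
    temporal_kernel_frames: int = 3,
    temporal_sigma_frames: float = 1.0,
) -> VSDMovie:
    """Gaussian smoothing in space then time with truncated, renormalized kernels.

    Each frame is convolved with a ``spatial_kernel_px`` square Gaussian
    kernel (weights ``exp(-d^2/2 sigma^2)`` renormalized to sum 1), then each
    pixel's time series with the analogous 1-D temporal kernel. Boundaries use
    nearest-edge replication so border pixels are not dimmed. Output shape is
    unchanged.
    """
    _require_odd("spatial_kernel_px", spatial_kernel_px)
    _require_odd("temporal_kernel_frames", temporal_kernel_frames)
    if spatial_sigma_px <= 0 or temporal_sigma_frames <= 0:
        raise InvalidParameterError("sigmas must be > 0")
    r_s = (spatial_kernel_px - 1) // 2
    r_t = (temporal_kernel_frames - 1) // 2
    out = ndimage.gaussian_filter(
        movie.frames,
        sigma=(0.0, spatial_sigma_px, spatial_sigma_px),
        radius=(0, r_s, r_s),
        mode="nearest",
    )
    out = ndimage.gaussian_filter1d(
        out, sigma=temporal_sigma_frames, axis=0, mode="nearest", radius=r_t
    )
    return movie.with_frames(out)


def baseline_stats(movie: VSDMovie, n_frames: int = 50) -> BaselineStats:
    """Per-pixel mean and sample SD over the ``n_frames`` preceding stimulation.

    The window is the half-open interval ``[stim_frame - n_frames,
    stim_frame)``.
    """
    stim = movie.spec.stim_frame
    if n_frames < 2:
        raise InsufficientDataError("need >= 2 baseline frames")
    if stim < n_frames:
        raise InsufficientDataError(
            f"only {stim} pre-stimulus frames available, {n_frames} requested"
        )
    window = (stim - n_frames, stim)
    block = movie.frames[window[0] : window[1]]
    return BaselineStats(
        mean_map=block.mean(axis=0), sd_map=block.std(axis=0, ddof=1), window=window
    )


def amplitude_map(
    movie: VSDMovie, baseline: BaselineStats, sd_floor_rel: float = 1e-6
) -> AmplitudeMovie:
    """Express the movie in SD-above-baseline units per pixel.

    ``value(t, p) = (frame(t, p) - mean(p)) / max(sd(p), floor)`` where the
    floor is ``sd_floor_rel`` times the global mean baseline intensity,
    guarding against zero-variance (synthetic noiseless) pixels; floored
    pixels are flagged in ``floored_mask``.
    """
    if baseline.mean_map.shape != movie.frames.shape[1:]:
        raise IncompatibleInputsError("baseline maps do not match movie frames")
    floor = sd_floor_rel * float(np.abs(baseline.mean_map).mean())
    floor = max(floor, np.finfo(np.float64).tiny)
    floored = baseline.sd_map < floor
    sd = np.where(floored, floor, baseline.sd_map)
    values = (movie.frames - baseline.mean_map) / sd
    return AmplitudeMovie(
        values=values,
        spec=movie.spec,
        units="sd",
        baseline_window=baseline.window,
        stim_site=movie.stim_site,
        floored_mask=floored,
    )


def delta_i_over_i(movie: VSDMovie, baseline: BaselineStats) -> AmplitudeMovie:
    """Fractional change of signal relative to baseline intensity, in percent.

    ``100 * (frame - mean) / mean`` per pixel; requires a strictly positive
    baseline mean everywhere.
    """
    if baseline.mean_map.shape != movie.frames.shape[1:]:
        raise IncompatibleInputsError("baseline maps do not match movie frames")
    if np.any(baseline.mean_map <= 0):
        raise InvalidParameterError("baseline mean must be > 0 everywhere for dI/I")
    values = 100.0 * (movie.frames - baseline.mean_map) / baseline.mean_map
    return AmplitudeMovie(
        values=values,
        spec=movie.spec,
        units="dii_percent",
        baseline_window=baseline.window,
        stim_site=movie.stim_site,
    )


def activated_pixels(
    amp: AmplitudeMovie,
    frame: int,
    threshold_sd: float = DEFAULT_THRESHOLD_SD,
    exclusion_mask: Optional[np.ndarray] = None,
) -> ActivationResult:
    """Activated-pixel mask and activation size of one frame.

    A pixel is activated when its amplitude is >= ``threshold_sd``; excluded
    pixels (e.g. the laser-artifact disc) never count as activated but still
    count in the frame size, so the activation size remains a percentage of
    the full frame.
    """
    if threshold_sd <= 0:
        raise InvalidParameterError("threshold_sd must be > 0")
    if not (0 <= frame < amp.values.shape[0]):
        raise OutOfBoundsError(f"frame {frame} outside movie of {amp.values.shape[0]} frames")
    mask = amp.values[frame] >= threshold_sd
    if exclusion_mask is not None:
        if exclusion_mask.shape != mask.shape:
            raise IncompatibleInputsError("exclusion mask shape mismatch")
        mask = mask & ~exclusion_mask
    size = 100.0 * np.count_nonzero(mask) / mask.size
    return ActivationResult(
        mask=mask, activation_size=size, threshold_sd=threshold_sd, frame_or_window=(frame, frame + 1)
    )


def _artifact_masks(
    spec: AcquisitionSpec,
    site: Optional[Tuple[int, int]],
    radius: float,
    n_frames: int,
) -> dict:
    """Per-frame exclusion masks for the first post-stimulus frames."""
    if site is None or n_frames <= 0:
        return {}
    rows, cols = pixel_grid(spec.frame_height, spec.frame_width)
    disc = (rows - site[0]) ** 2 + (cols - site[1]) ** 2 <= radius**2
    return {spec.stim_frame + k: disc for k in range(n_frames)}


def activation_trace(
    amp: AmplitudeMovie,
    threshold_sd: float = DEFAULT_THRESHOLD_SD,
    artifact_radius: float = 3.0,
    artifact_frames: int = 3,
) -> np.ndarray:
    """Per-frame activation size (%) with the stimulation artifact excluded.

    The artifact exclusion is a disc of ``artifact_radius`` pixels around the
    movie's stimulation site, applied to the first ``artifact_frames``
    post-stimulus frames.
    """
    masks = _artifact_masks(amp.spec, amp.stim_site, artifact_radius, artifact_frames)
    trace = np.empty(amp.values.shape[0])
    for t in range(amp.values.shape[0]):
        trace[t] = activated_pixels(
            amp, t, threshold_sd=threshold_sd, exclusion_mask=masks.get(t)
        ).activation_size
    return trace


def response_amplitude(
    amp: AmplitudeMovie,
    post_window_frames: int = 100,
    threshold_sd: float = DEFAULT_THRESHOLD_SD,
    artifact_radius: float = 3.0,
    artifact_frames: int = 3,
    reduction: str = "peak_activation_size",
    slice_id: str = "slice",
    condition: str = "control",
) -> SliceResponse:
    """Reduce the post-stimulus window to one scalar evoked response.

    Reductions (recorded in the output):

    ``peak_activation_size`` (default)
        Maximum over the window of the per-frame activation size (%).
    ``mean_activation_size``
        Mean activation size over the window (%).
    ``peak_mean_amplitude``
        Maximum over the window of the frame-mean amplitude (SD units, floored
        at 0); linear in signal amplitude, hence the natural choice when a
        treated/control amplitude ratio is the quantity of interest.

    The first ``artifact_frames`` post-stimulus frames exclude a disc of
    ``artifact_radius`` pixels around the stimulation site.
    """
    spec = amp.spec
    stim = spec.stim_frame
    if post_window_frames < 1 or stim + post_window_frames > spec.n_frames:
        raise InvalidParameterError(
            f"post-stimulus window [{stim}, {stim + post_window_frames}) outside movie"
        )
    if reduction not in REDUCTIONS:
        raise InvalidParameterError(f"unknown reduction {reduction!r}; choose from {REDUCTIONS}")
    window = (stim, stim + post_window_frames)
    masks = _artifact_masks(spec, amp.stim_site, artifact_radius, artifact_frames)
    if reduction in ("peak_activation_size", "mean_activation_size"):
        per_frame = np.array(
            [
                activated_pixels(
                    amp, t, threshold_sd=threshold_sd, exclusion_mask=masks.get(t)
                ).activation_size
                for t in range(*window)
            ]
        )
        value = per_frame.max() if reduction == "peak_activation_size" else per_frame.mean()
    else:  # peak_mean_amplitude
        per_frame = np.empty(post_window_frames)
        for i, t in enumerate(range(*window)):
            frame = amp.values[t]
            excl = masks.get(t)
            per_frame[i] = frame[~excl].mean() if excl is not None else frame.mean()
        value = max(per_frame.max(), 0.0)
    return SliceResponse(
        slice_id=slice_id,
        response=float(value),
        condition=condition,
        method=reduction,
        details={
            "post_window": window,
            "threshold_sd": threshold_sd,
            "artifact_radius": artifact_radius,
            "artifact_frames": artifact_frames,
        },
    )


def pool_sites(per_site_amps: Sequence[AmplitudeMovie], method: str = "mean") -> AmplitudeMovie:
    """Combine amplitude movies from multiple photostimulation sites.

    Pixel-wise mean by default; ``method='max'`` takes the element-wise
    maximum. All inputs must share shape, units and timing; the output
    metadata records the method and site count.
    """
    if not per_site_amps:
        raise InvalidParameterError("need at least one site")
    first = per_site_amps[0]
    for a in per_site_amps[1:]:
        if a.values.shape != first.values.shape or a.units != first.units:
            raise IncompatibleInputsError("pooled movies must share shape and units")
        if a.spec.stim_frame != first.spec.stim_frame:
            raise IncompatibleInputsError("pooled movies must share stimulation timing")
    stack = np.stack([a.values for a in per_site_amps])
    if method == "mean":
        values = stack.mean(axis=0)
    elif method == "max":
        values = stack.max(axis=0)
    else:
        raise InvalidParameterError(f"unknown pooling method {method!r}")
    return AmplitudeMovie(
        values=values,
        spec=first.spec,
        units=first.units,
        baseline_window=first.baseline_window,
        pooling={"method": method, "n_sites": len(per_site_amps)},
    )


def normalize_pair(treated: SliceResponse, control: SliceResponse) -> float:
    """Treated response as a percentage of its matched control response."""
    if control.response <= 0:
        raise InvalidParameterError("control response must be > 0 to normalize")
    return 100.0 * treated.response / control.response


def summarize_pairs(
    pairs: Sequence[float],
    test: str = "mann_whitney",
    treated_responses: Optional[Sequence[float]] = None,
    control_responses: Optional[Sequence[float]] = None,
) -> PairSummary:
    """Mean and SE of normalized pair responses, plus the group comparison.

    ``pairs`` are per-pair normalized responses in percent. The SE is the
    sample SD divided by sqrt(n). When the raw treated and control responses
    are supplied, the selected two-sided test (``'mann_whitney'``, ``'t'``)
    compares them; otherwise only the descriptive summary is returned.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.size < 2:
        raise InsufficientDataError("need >= 2 pairs to summarize")
    mean = float(pairs.mean())
    se = _stats.sem(pairs)
    comparison = None
    if treated_responses is not None and control_responses is not None:
        if test == "mann_whitney":
            comparison = _stats.mann_whitney_u(treated_responses, control_responses)
        elif test == "t":
            comparison = _stats.students_t(treated_responses, control_responses)
        else:
            raise InvalidParameterError(f"unknown test {test!r}")
    return PairSummary(normalized_responses=list(map(float, pairs)), mean=mean, se=se, test=comparison)


def average_trials(trials: Sequence[VSDMovie]) -> VSDMovie:
    """Frame-wise average of repeated trials from one photostimulation site."""
    if not trials:
        raise InvalidParameterError("need at least one trial")
    first = trials[0]
    for t in trials[1:]:
        if t.frames.shape != first.frames.shape:
            raise IncompatibleInputsError("trials must share shape")
    mean = np.mean([t.frames for t in trials], axis=0)
    return first.with_frames(mean)
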