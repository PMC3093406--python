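"""Ground-truth simulators for VSD movies and fluorescence micrographs.

Every generator is deterministic given its parameters and a seed, and returns
the ground truth needed to check downstream recovery exactly:

* :func:`make_baseline_movie` — per-pixel baseline noise around a resting
  fluorescence level (independent Gaussian by default; a Student-t option
  gives heavier tails).
* :func:`inject_stimulus_artifact` — the focal laser-excitation artifact seen
  as a bright disc at the uncaging site in the initial post-stimulus frame(s).
* :func:`inject_activation` — a spatially spreading evoked depolarisation:
  a separable signal ``peak_amplitude * noise_sd * G(||p-center||; sigma) *
  r(t)`` with a unit-peak Gaussian spatial profile and a unit-peak
  difference-of-exponentials time course.
* :func:`make_slice_pair` — a treated/control slice pair with a known
  response-amplitude ratio and independent noise realisations.
* :func:`make_fluor_image` — confocal-like puncta of known total signal on a
  diffuse noisy background.

Signal amplitudes are parameterised in baseline-SD units so ground truth
aligns with the SD-unit readout of the analysis pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .core import (
    AcquisitionSpec,
    InvalidParameterError,
    OutOfBoundsError,
    VSDMovie,
    pixel_grid,
)

__all__ = [
    "ActivationGroundTruth",
    "PairGroundTruth",
    "FluorGroundTruth",
    "make_baseline_movie",
    "inject_stimulus_artifact",
    "inject_activation",
    "make_slice_pair",
    "make_fluor_image",
    "temporal_profile",
    "spatial_profile",
]

#: Default resting fluorescence level (arbitrary camera units).
DEFAULT_BASELINE_MEAN = 1000.0
#: Default per-pixel baseline noise SD (camera units); ~0.8% of resting level.
DEFAULT_NOISE_SD = 8.0


@dataclass
class ActivationGroundTruth:
    """Parameters of one injected evoked response, in analysis-ready units.

    ``peak_amplitude`` is the noiseless peak at the response centre in
    baseline-SD units; ``spatial_sigma`` the Gaussian footprint SD in pixels;
    ``rise_tau``/``decay_tau`` the time constants of the difference-of-
    exponentials time course in frames. ``true_active_fraction`` (percent of
    the frame whose noiseless peak signal is >= 1 baseline SD) is filled in by
    :func:`inject_activation`.
    """

    center: Tuple[float, float]
    onset_frame: int
    peak_amplitude: float
    spatial_sigma: float
    rise_tau: float = 5.0
    decay_tau: float = 30.0
    true_active_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.peak_amplitude < 0:
            raise InvalidParameterError("peak_amplitude must be >= 0")
        if self.spatial_sigma < 0:
            raise InvalidParameterError("spatial_sigma must be >= 0")
        if self.rise_tau < 0 or self.decay_tau <= 0:
            raise InvalidParameterError("time constants must be positive")
        if self.true_active_fraction is not None and not (
            0.0 <= self.true_active_fraction <= 100.0
        ):
            raise InvalidParameterError("true_active_fraction must be in [0, 100]")


@dataclass
class PairGroundTruth:
    """Ground truth of a treated/control slice pair."""

    response_ratio: float
    control_truth: ActivationGroundTruth
    treated_truth: ActivationGroundTruth

    def __post_init__(self) -> None:
        if self.response_ratio <= 0:
            raise InvalidParameterError("response_ratio must be > 0")


@dataclass
class FluorGroundTruth:
    """Ground truth of a simulated puncta image."""

    positions: np.ndarray  # (n, 2) row/col centres
    punctum_intensity: float  # peak amplitude per punctum
    punctum_sigma: float
    background_mean: float
    total_injected_signal: float  # sum of the in-frame signal field


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def spatial_profile(
    height: int, width: int, center: Tuple[float, float], sigma: float
) -> np.ndarray:
    """Unit-peak Gaussian footprint ``exp(-d^2 / 2 sigma^2)`` on the pixel grid.

    ``sigma == 0`` degenerates to a single-pixel point source at the rounded
    centre.
    """
    rows, cols = pixel_grid(height, width)
    if sigma == 0:
        g = np.zeros((height, width))
        r0, c0 = int(round(center[0])), int(round(center[1]))
        if not (0 <= r0 < height and 0 <= c0 < width):
            raise OutOfBoundsError(f"center {center} outside frame")
        g[r0, c0] = 1.0
        return g
    d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    return np.exp(-d2 / (2.0 * sigma**2))


def temporal_profile(
    n_frames: int, onset_frame: int, rise_tau: float, decay_tau: float
) -> np.ndarray:
    """Unit-peak rise-then-decay time course sampled at frame indices.

    For ``t >= onset``: ``h(u) = exp(-u/decay) - exp(-u/rise)`` with
    ``u = t - onset``, normalised by its continuous-time maximum so the peak
    equals 1. A zero ``rise_tau`` gives an instantaneous-rise exponential
    decay.
    """
    t = np.arange(n_frames, dtype=np.float64)
    u = t - onset_frame
    r = np.zeros(n_frames)
    on = u >= 0
    if rise_tau == 0:
        r[on] = np.exp(-u[on] / decay_tau)
        return r
    if rise_tau >= decay_tau:
        raise InvalidParameterError("rise_tau must be < decay_tau")
    # continuous-time peak location and height of the difference of exponentials
    u_peak = (
        math.log(decay_tau / rise_tau) * rise_tau * decay_tau / (decay_tau - rise_tau)
    )
    h_peak = math.exp(-u_peak / decay_tau) - math.exp(-u_peak / rise_tau)
    r[on] = (np.exp(-u[on] / decay_tau) - np.exp(-u[on] / rise_tau)) / h_peak
    return r


def make_baseline_movie(
    spec: AcquisitionSpec,
    baseline_mean: float = DEFAULT_BASELINE_MEAN,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    noise: str = "gaussian",
    t_df: float = 5.0,
    bleach_tau_frames: Optional[float] = None,
) -> VSDMovie:
    """Pre/post-stimulus acquisition with pure per-pixel baseline noise.

    Each pixel time series is independent noise around ``baseline_mean`` with
    standard deviation ``noise_sd``. ``noise='student_t'`` draws from a
    Student-t with ``t_df`` degrees of freedom rescaled to the same SD.
    ``bleach_tau_frames`` optionally applies a multiplicative exponential
    dye-bleaching drift to the mean level.
    """
    if baseline_mean <= 0:
        raise InvalidParameterError("baseline_mean must be > 0")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    rng = _rng(seed)
    if noise == "gaussian":
        eps = rng.standard_normal(spec.shape)
    elif noise == "student_t":
        if t_df <= 2:
            raise InvalidParameterError("t_df must exceed 2 for finite variance")
        eps = rng.standard_t(t_df, spec.shape) / math.sqrt(t_df / (t_df - 2.0))
    else:
        raise InvalidParameterError(f"unknown noise model {noise!r}")
    mean = np.full(spec.n_frames, baseline_mean)
    if bleach_tau_frames is not None:
        mean = mean * np.exp(-np.arange(spec.n_frames) / bleach_tau_frames)
    frames = mean[:, None, None] + noise_sd * eps
    return VSDMovie(frames=frames, spec=spec)


def inject_stimulus_artifact(
    movie: VSDMovie,
    site: Tuple[int, int],
    radius: float = 2.0,
    amplitude: float = 200.0,
    n_frames: int = 1,
) -> VSDMovie:
    """Add the focal laser-excitation artifact at the uncaging site.

    A disc of Euclidean ``radius`` (pixels) around ``site`` is offset by
    ``amplitude`` in the first ``n_frames`` post-stimulus frames; all other
    pixels are untouched. The returned movie records ``site`` as its
    stimulation site.
    """
    spec = movie.spec
    r0, c0 = site
    if not (0 <= r0 < spec.frame_height and 0 <= c0 < spec.frame_width):
        raise OutOfBoundsError(f"site {site} outside {spec.frame_height}x{spec.frame_width} frame")
    if radius < 0:
        raise InvalidParameterError("radius must be >= 0")
    if n_frames < 1 or spec.stim_frame + n_frames > spec.n_frames:
        raise InvalidParameterError("artifact frames must fit after stim_frame")
    rows, cols = pixel_grid(spec.frame_height, spec.frame_width)
    disc = (rows - r0) ** 2 + (cols - c0) ** 2 <= radius**2
    frames = movie.frames.copy()
    frames[spec.stim_frame : spec.stim_frame + n_frames] += amplitude * disc
    return VSDMovie(frames=frames, spec=spec, stim_site=(r0, c0))


def activation_signal(
    spec: AcquisitionSpec, truth: ActivationGroundTruth, baseline_noise_sd: float
) -> np.ndarray:
    """Noiseless evoked-signal field (T, H, W) in camera intensity units."""
    g = spatial_profile(spec.frame_height, spec.frame_width, truth.center, truth.spatial_sigma)
    r = temporal_profile(spec.n_frames, truth.onset_frame, truth.rise_tau, truth.decay_tau)
    return truth.peak_amplitude * baseline_noise_sd * r[:, None, None] * g[None, :, :]


def inject_activation(
    movie: VSDMovie,
    truth: ActivationGroundTruth,
    baseline_noise_sd: float,
) -> Tuple[VSDMovie, ActivationGroundTruth]:
    """Add a spreading evoked depolarisation and report its true footprint.

    The signal is separable: ``peak_amplitude * noise_sd * G(p) * r(t)`` with
    unit-peak spatial and temporal profiles (see :func:`spatial_profile`,
    :func:`temporal_profile`). Returns a copy of ``truth`` with
    ``true_active_fraction`` filled in — the percentage of frame pixels whose
    noiseless peak signal over the sampled frames is >= 1 x
    ``baseline_noise_sd``, computed by exact enumeration of the closed form.
    """
    spec = movie.spec
    if baseline_noise_sd <= 0:
        raise InvalidParameterError("baseline_noise_sd must be > 0")
    if truth.onset_frame < spec.stim_frame:
        raise InvalidParameterError(
            f"onset_frame {truth.onset_frame} precedes stim_frame {spec.stim_frame}"
        )
    signal = activation_signal(spec, truth, baseline_noise_sd)
    peak_map = signal.max(axis=0)
    n_active = int(np.count_nonzero(peak_map >= baseline_noise_sd))
    fraction = 100.0 * n_active / spec.n_pixels
    out_truth = replace(truth, true_active_fraction=fraction)
    return movie.with_frames(movie.frames + signal), out_truth


def make_slice_pair(
    spec: AcquisitionSpec,
    control_truth: ActivationGroundTruth,
    response_ratio: float,
    seed: int = 0,
    baseline_mean: float = DEFAULT_BASELINE_MEAN,
    noise_sd: float = DEFAULT_NOISE_SD,
    artifact: bool = True,
    artifact_radius: float = 2.0,
    artifact_amplitude_sd: float = 25.0,
) -> Tuple[VSDMovie, VSDMovie, PairGroundTruth]:
    """Treated/control movie pair with a known response-amplitude ratio.

    Both movies share the acquisition spec and noise statistics but have
    independent noise realisations; the treated movie's injected peak
    amplitude is ``control_truth.peak_amplitude * response_ratio``. When
    ``artifact`` is true a stimulation artifact
    (``artifact_amplitude_sd`` baseline SDs) is placed at the response centre
    of each movie.

    Returns ``(control_movie, treated_movie, PairGroundTruth)``.
    """
    if response_ratio <= 0:
        raise InvalidParameterError("response_ratio must be > 0")
    treated_truth = replace(
        control_truth,
        peak_amplitude=control_truth.peak_amplitude * response_ratio,
        true_active_fraction=None,
    )
    rng = _rng(seed)
    # sub-seeds below 2**31 so callers can reproduce each slice independently
    seeds = rng.integers(0, 2**31 - 1, size=2)
    movies = []
    truths = []
    for sub_seed, truth in zip(seeds, (control_truth, treated_truth)):
        m = make_baseline_movie(spec, baseline_mean, noise_sd, seed=int(sub_seed))
        site = (int(round(truth.center[0])), int(round(truth.center[1])))
        if artifact:
            m = inject_stimulus_artifact(
                m, site, radius=artifact_radius, amplitude=artifact_amplitude_sd * noise_sd
            )
        else:
            m = VSDMovie(frames=m.frames, spec=spec, stim_site=site)
        m, filled = inject_activation(m, truth, baseline_noise_sd=noise_sd)
        movies.append(m)
        truths.append(filled)
    pair = PairGroundTruth(
        response_ratio=response_ratio, control_truth=truths[0], treated_truth=truths[1]
    )
    return movies[0], movies[1], pair


def make_fluor_image(
    height: int,
    width: int,
    n_puncta: int,
    punctum_intensity: float = 100.0,
    punctum_sigma: float = 1.5,
    background_mean: float = 20.0,
    background_sd: float = 4.0,
    seed: int = 0,
) -> Tuple[np.ndarray, FluorGroundTruth]:
    """Confocal-like image: Gaussian puncta on a diffuse noisy background.

    Puncta are unit-peak Gaussians of amplitude ``punctum_intensity`` and SD
    ``punctum_sigma`` placed at ``n_puncta`` distinct pixel positions drawn
    uniformly. The ground truth records positions and the total injected
    signal (sum of the in-frame signal field). Negative noise excursions are
    clipped at zero, as in an unsigned camera image.
    """
    if min(height, width) <= 0:
        raise InvalidParameterError("image dimensions must be positive")
    if n_puncta < 0 or punctum_intensity < 0 or background_mean < 0 or background_sd < 0:
        raise InvalidParameterError("counts and intensities must be >= 0")
    if n_puncta > height * width:
        raise InvalidParameterError("more puncta than pixels")
    rng = _rng(seed)
    flat = rng.choice(height * width, size=n_puncta, replace=False)
    positions = np.column_stack(np.unravel_index(flat, (height, width))).astype(float)
    signal = np.zeros((height, width))
    for r0, c0 in positions:
        signal += punctum_intensity * spatial_profile(height, width, (r0, c0), punctum_sigma)
    image = background_mean + background_sd * rng.standard_normal((height, width)) + signal
    np.clip(image, 0.0, None, out=image)
    truth = FluorGroundTruth(
        positions=positions,
        punctum_intensity=punctum_intensity,
        punctum_sigma=punctum_sigma,
        background_mean=background_mean,
        total_injected_signal=float(signal.sum()),
    )
    return image, truth
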