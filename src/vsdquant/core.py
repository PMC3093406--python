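"""Core containers and error types shared across the package.

The central object is :class:`VSDMovie`, a time-ordered stack of grayscale
frames from a voltage-sensitive-dye (VSD) recording of a brain slice, together
with the acquisition parameters (:class:`AcquisitionSpec`) needed to interpret
it: frame interval, stimulation frame, baseline length and physical pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "AcquisitionSpec",
    "VSDMovie",
    "VSDQuantError",
    "InvalidSpecError",
    "InvalidParameterError",
    "OutOfBoundsError",
    "IncompatibleInputsError",
    "InsufficientDataError",
    "DegenerateDataError",
    "NoSignalError",
    "CorruptInputError",
    "MetadataMissingError",
]


class VSDQuantError(ValueError):
    """Base class for all package-specific errors."""


class InvalidSpecError(VSDQuantError):
    """An acquisition spec violates its invariants."""


class InvalidParameterError(VSDQuantError):
    """A parameter is outside its valid domain (e.g. even kernel size)."""


class OutOfBoundsError(VSDQuantError):
    """A pixel site or frame index lies outside the movie."""


class IncompatibleInputsError(VSDQuantError):
    """Two inputs that must share a shape or timing do not."""


class InsufficientDataError(VSDQuantError):
    """Too few frames or samples for the requested statistic."""


class DegenerateDataError(VSDQuantError):
    """Data admit no meaningful statistic (e.g. zero variance everywhere)."""


class NoSignalError(VSDQuantError):
    """An all-zero image where signal is required."""


class CorruptInputError(VSDQuantError):
    """Stored data and sidecar metadata disagree."""


class MetadataMissingError(VSDQuantError):
    """A movie file has no sidecar metadata."""


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition geometry and timing of a VSD recording.

    Defaults reproduce a fast CCD voltage-imaging configuration: 88 (w) x
    60 (h) pixel frames at 2.2 ms/frame, 1000 frames per trial, photo-
    stimulation delivered after a 50-frame baseline, 14.6 x 17.9 um pixels
    under a 4x objective.

    Parameters
    ----------
    frame_height, frame_width : int
        Frame size in pixels (rows, columns).
    n_frames : int
        Frames per trial.
    frame_interval_ms : float
        Sampling interval in milliseconds.
    stim_frame : int
        Index (0-based) of the first post-stimulus frame.
    n_baseline_frames : int
        Length of the pre-stimulus window used for baseline statistics.
    pixel_size_x_um, pixel_size_y_um : float
        Physical pixel size (width, height) in micrometres. Pixels may be
        non-square; this affects only physical-area reporting, never the
        pixel-fraction statistics.
    """

    frame_height: int = 60
    frame_width: int = 88
    n_frames: int = 1000
    frame_interval_ms: float = 2.2
    stim_frame: int = 50
    n_baseline_frames: int = 50
    pixel_size_x_um: float = 14.6
    pixel_size_y_um: float = 17.9

    def __post_init__(self) -> None:
        if min(self.frame_height, self.frame_width, self.n_frames) <= 0:
            raise InvalidSpecError("frame dimensions and frame count must be positive")
        if self.frame_interval_ms <= 0:
            raise InvalidSpecError("frame interval must be positive")
        if min(self.pixel_size_x_um, self.pixel_size_y_um) <= 0:
            raise InvalidSpecError("pixel sizes must be positive")
        if not (0 < self.n_baseline_frames <= self.stim_frame < self.n_frames):
            raise InvalidSpecError(
                "need n_baseline_frames <= stim_frame < n_frames "
                f"(got {self.n_baseline_frames}, {self.stim_frame}, {self.n_frames})"
            )

    @property
    def shape(self) -> Tuple[int, int, int]:
        """Movie array shape ``(n_frames, frame_height, frame_width)``."""
        return (self.n_frames, self.frame_height, self.frame_width)

    @property
    def n_pixels(self) -> int:
        return self.frame_height * self.frame_width

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_x_um * self.pixel_size_y_um

    def to_dict(self) -> dict:
        return {
            "frame_height": self.frame_height,
            "frame_width": self.frame_width,
            "n_frames": self.n_frames,
            "frame_interval_ms": self.frame_interval_ms,
            "stim_frame": self.stim_frame,
            "n_baseline_frames": self.n_baseline_frames,
            "pixel_size_x_um": self.pixel_size_x_um,
            "pixel_size_y_um": self.pixel_size_y_um,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionSpec":
        return cls(**{k: d[k] for k in cls().to_dict()})


@dataclass
class VSDMovie:
    """A VSD trial: ``frames`` of shape ``(T, H, W)`` plus acquisition metadata.

    ``stim_site`` is the (row, col) photostimulation location when known.
    """

    frames: np.ndarray
    spec: AcquisitionSpec
    stim_site: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.shape != self.spec.shape:
            raise IncompatibleInputsError(
                f"frames shape {self.frames.shape} does not match spec {self.spec.shape}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise CorruptInputError("movie contains non-finite values")
        if self.stim_site is not None:
            r, c = self.stim_site
            if not (0 <= r < self.spec.frame_height and 0 <= c < self.spec.frame_width):
                raise OutOfBoundsError(f"stim_site {self.stim_site} outside frame")

    def with_frames(self, frames: np.ndarray) -> "VSDMovie":
        """Copy of this movie with replaced frame data."""
        return VSDMovie(frames=frames, spec=self.spec, stim_site=self.stim_site)


def pixel_grid(height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column index grids of shape ``(height, width)``."""
    return np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
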