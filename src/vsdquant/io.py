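"""Readers and writers: multi-page TIFF movies with JSON sidecar metadata,
TIFF images and masks, CSV tables, and YAML analysis manifests.

Acquisition metadata travels in a JSON sidecar next to the TIFF (same stem,
``.json`` suffix) rather than in TIFF tags, for format portability. A
manifest plus its inputs fully determines all outputs bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import (
    AcquisitionSpec,
    CorruptInputError,
    MetadataMissingError,
    VSDMovie,
)

__all__ = [
    "write_movie",
    "read_movie",
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
    "save_manifest",
    "load_manifest",
    "sidecar_path",
]

PathLike = Union[str, Path]


def sidecar_path(movie_path: PathLike) -> Path:
    return Path(movie_path).with_suffix(".json")


def write_movie(movie: VSDMovie, path: PathLike) -> Path:
    """Write a movie as multi-page float32 TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, movie.frames.astype(np.float64), photometric="minisblack")
    meta = movie.spec.to_dict()
    meta["stim_site"] = list(movie.stim_site) if movie.stim_site is not None else None
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_movie(path: PathLike) -> VSDMovie:
    """Read a movie written by :func:`write_movie`, validating the sidecar.

    Raises :class:`MetadataMissingError` when the sidecar is absent and
    :class:`CorruptInputError` when the sidecar and the TIFF disagree or the
    sidecar violates the acquisition invariants.
    """
    path = Path(path)
    sidecar = sidecar_path(path)
    if not sidecar.exists():
        raise MetadataMissingError(f"no metadata sidecar at {sidecar}")
    meta = json.loads(sidecar.read_text())
    try:
        spec = AcquisitionSpec.from_dict(meta)
    except Exception as exc:  # invalid sidecar values
        raise CorruptInputError(f"invalid sidecar metadata: {exc}") from exc
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape != spec.shape:
        raise CorruptInputError(
            f"TIFF shape {frames.shape} does not match sidecar spec {spec.shape}"
        )
    stim_site = meta.get("stim_site")
    return VSDMovie(
        frames=np.asarray(frames, dtype=np.float64),
        spec=spec,
        stim_site=tuple(stim_site) if stim_site is not None else None,
    )


def write_image(image: np.ndarray, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float64))
    return path


def read_image(path: PathLike) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float64)


def write_mask(mask: np.ndarray, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8))
    return path


def read_mask(path: PathLike) -> np.ndarray:
    return np.asarray(tifffile.imread(path)) > 0


def save_manifest(manifest: dict, path: PathLike) -> Path:
    """Write an analysis manifest as YAML (keys sorted for stable output)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path


def load_manifest(path: PathLike) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_table(df: pd.DataFrame, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
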