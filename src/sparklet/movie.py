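"""Fluorescence time-lapse container and TIFF input/output.

A :class:`MovieStack` is the in-memory form of an en face endothelial
recording: a (t, y, x) grayscale intensity array, the pixel size in
micrometres, per-frame timestamps in seconds, and free-form acquisition
metadata (condition labels, bath pO2, pH, drugs).

On disk a movie is a multi-page 16-bit grayscale TIFF (ImageJ-compatible
t, y, x axis order) accompanied by a JSON sidecar ``<name>.tif.json``
carrying the pixel size, frame rate and metadata.  The sidecar is the
authoritative source on read; the ImageJ ``finterval`` tag is used as a
fallback for frame timing when only a bare TIFF is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["MovieStack", "read_movie", "write_movie"]


@dataclass
class MovieStack:
    """A time-ordered series of grayscale fluorescence frames.

    Parameters
    ----------
    frames
        Intensity array of shape ``(t, y, x)``; non-negative and finite.
    pixel_um
        Side of one (square) pixel in micrometres.
    timestamps
        Frame acquisition times in seconds, strictly increasing,
        one per frame.
    metadata
        Free-form acquisition metadata (condition, pO2 in mmHg, pH, ...).
    """

    frames: np.ndarray
    pixel_um: float
    timestamps: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (t, y, x); got shape {self.frames.shape}")
        if self.timestamps.shape != (self.frames.shape[0],):
            raise ValueError(
                f"{self.timestamps.size} timestamps for {self.frames.shape[0]} frames"
            )
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if not (np.isfinite(self.pixel_um) and self.pixel_um > 0):
            raise ValueError(f"pixel_um must be positive, got {self.pixel_um}")

    # -- derived geometry -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def frame_rate_hz(self) -> float:
        """Median sampling rate; constant-rate movies have exact rates."""
        if self.n_frames < 2:
            raise ValueError("frame rate undefined for a single-frame movie")
        return 1.0 / float(np.median(np.diff(self.timestamps)))

    @property
    def duration_s(self) -> float:
        """Total recorded time, counting each frame as one sample interval."""
        return self.n_frames / self.frame_rate_hz

    @property
    def fov_um(self) -> tuple[float, float]:
        ny, nx = self.frame_shape
        return (ny * self.pixel_um, nx * self.pixel_um)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_movie(movie: MovieStack, path: str | Path) -> Path:
    """Write a movie as 16-bit ImageJ TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    frames = movie.frames
    if not np.issubdtype(frames.dtype, np.integer):
        frames = np.clip(np.rint(frames), 0, np.iinfo(np.uint16).max)
    frames = frames.astype(np.uint16)
    dt = float(np.median(np.diff(movie.timestamps))) if movie.n_frames > 1 else 0.0
    tifffile.imwrite(
        path,
        frames,
        imagej=True,
        resolution=(1.0 / movie.pixel_um, 1.0 / movie.pixel_um),
        metadata={"axes": "TYX", "unit": "um", "finterval": dt},
    )
    sidecar = {
        "pixel_um": movie.pixel_um,
        "timestamps_s": movie.timestamps.tolist(),
        "metadata": movie.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_movie(path: str | Path, pixel_um: float | None = None) -> MovieStack:
    """Read a multi-page grayscale TIFF movie.

    The pixel size must come from the JSON sidecar, the ``pixel_um``
    argument, or (last resort) the TIFF resolution tags; if none is
    available the read fails rather than assuming a default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray()
            ij = tif.imagej_metadata or {}
    except Exception as exc:  # unreadable/corrupt container
        raise ValueError(f"could not read TIFF movie {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(
            f"{path}: expected a single-channel (t, y, x) stack, got shape {frames.shape}"
        )

    timestamps = None
    metadata: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        try:
            info = json.loads(sidecar.read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed movie sidecar {sidecar}: {exc}") from exc
        pixel_um = pixel_um if pixel_um is not None else info.get("pixel_um")
        ts = info.get("timestamps_s")
        if ts is not None:
            timestamps = np.asarray(ts, dtype=float)
        metadata = info.get("metadata", {})
    if pixel_um is None:
        raise ValueError(
            f"{path}: pixel size unknown; provide pixel_um or a metadata sidecar"
        )
    if timestamps is None:
        dt = float(ij.get("finterval", 0.0) or 0.0)
        if dt <= 0:
            raise ValueError(
                f"{path}: frame interval unknown; provide a metadata sidecar"
            )
        timestamps = np.arange(frames.shape[0]) * dt
    return MovieStack(frames=frames, pixel_um=float(pixel_um), timestamps=timestamps, metadata=metadata)
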