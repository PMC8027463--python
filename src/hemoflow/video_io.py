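"""Frame-stack I/O and calibration.

Videos of the conjunctival microcirculation are handled internally as a
``FrameStack``: a T x H x W float array of intensities in [0, 1] plus a
:class:`CalibrationProfile` carrying the spatial scale (μm per pixel) and
the frame rate.  Color sources are reduced to a single analysis channel —
by default the green channel, where hemoglobin absorption gives the
strongest erythrocyte contrast.

Supported on-disk formats: multi-page TIFF (preferred archival format),
directories of numbered PNG/TIFF frames, and MP4 when an ffmpeg-capable
imageio backend is installed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import tifffile

__all__ = ["CalibrationProfile", "FrameStack", "load_stack", "save_stack"]

_CHANNELS = ("green", "luma")
# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class CalibrationProfile:
    """Spatial and temporal calibration of an acquisition.

    Parameters
    ----------
    pixel_scale_um : float
        Micrometres per pixel. There is deliberately no default: the value
        depends on the slit-lamp magnification and camera and must be
        supplied explicitly.
    frame_rate_fps : float
        Frames per second of the source video.
    roi : tuple of int, optional
        ``(row0, col0, height, width)`` crop applied at load time.
    """

    pixel_scale_um: float
    frame_rate_fps: float
    roi: Optional[Tuple[int, int, int, int]] = None

    def __post_init__(self) -> None:
        if not self.pixel_scale_um > 0:
            raise ValueError(f"pixel_scale_um must be > 0, got {self.pixel_scale_um}")
        if not self.frame_rate_fps > 0:
            raise ValueError(f"frame_rate_fps must be > 0, got {self.frame_rate_fps}")
        if self.roi is not None:
            r0, c0, h, w = self.roi
            if h <= 0 or w <= 0 or r0 < 0 or c0 < 0:
                raise ValueError(f"invalid roi {self.roi}")

    @property
    def dt_s(self) -> float:
        """Seconds per frame."""
        return 1.0 / self.frame_rate_fps

    @classmethod
    def from_json(cls, path) -> "CalibrationProfile":
        with open(path) as fh:
            d = json.load(fh)
        roi = tuple(d["roi"]) if d.get("roi") else None
        return cls(float(d["pixel_scale_um"]), float(d["frame_rate_fps"]), roi)

    def to_json(self, path) -> None:
        d = {"pixel_scale_um": self.pixel_scale_um, "frame_rate_fps": self.frame_rate_fps}
        if self.roi is not None:
            d["roi"] = list(self.roi)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


@dataclass
class FrameStack:
    """A calibrated T x H x W intensity sequence in [0, 1]."""

    frames: np.ndarray
    calibration: CalibrationProfile
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError(f"a FrameStack needs at least 2 frames, got {self.frames.shape[0]}")
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"intensities must lie in [0, 1], got range [{lo}, {hi}]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.frames.shape  # type: ignore[return-value]


def _normalize(arr: np.ndarray) -> np.ndarray:
    """Rescale integer intensities by the dtype's full scale; pass floats through."""
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def _to_channel(frames: np.ndarray, channel: str) -> np.ndarray:
    if frames.ndim == 3:
        return frames  # already single channel
    if frames.ndim == 4 and frames.shape[-1] in (3, 4):
        rgb = frames[..., :3]
        if channel == "green":
            return rgb[..., 1]
        return rgb @ _LUMA
    raise ValueError(f"unsupported frame array shape {frames.shape}")


_num_re = re.compile(r"(\d+)")


def _natural_key(p: Path):
    return [int(tok) if tok.isdigit() else tok for tok in _num_re.split(p.name)]


def _read_frame_dir(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    files = sorted(
        (p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")),
        key=_natural_key,
    )
    if not files:
        raise IOError(f"no PNG/TIFF frames found in {path}")
    frames = [np.asarray(iio.imread(f)) for f in files]
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"mixed frame sizes in {path}: {sorted(shapes)}")
    return np.stack(frames)


def load_stack(path, calibration: CalibrationProfile, channel: str = "green") -> FrameStack:
    """Read a video into a :class:`FrameStack`.

    Parameters
    ----------
    path : path-like
        Multi-page TIFF, MP4, or a directory of numbered PNG/TIFF frames
        (sorted by natural numeric order).
    calibration : CalibrationProfile
        Spatial/temporal calibration; its ``roi``, if set, is cropped here.
    channel : {'green', 'luma'}
        Channel extracted from color sources. Grayscale sources pass
        through unchanged.
    """
    if channel not in _CHANNELS:
        raise ValueError(f"channel must be one of {_CHANNELS}, got {channel!r}")
    path = Path(path)
    if path.is_dir():
        raw = _read_frame_dir(path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        try:
            raw = tifffile.imread(path)
        except (FileNotFoundError, tifffile.TiffFileError) as exc:
            raise IOError(f"cannot read TIFF {path}: {exc}") from exc
    elif path.suffix.lower() in (".mp4", ".mov", ".avi"):
        try:
            import imageio.v3 as iio

            raw = np.asarray(iio.imread(path, plugin="pyav"))
        except ImportError as exc:
            raise IOError(
                f"cannot read {path}: MP4 decoding requires an ffmpeg-capable "
                f"imageio backend (pip install imageio[pyav])"
            ) from exc
    elif not path.exists():
        raise IOError(f"no such file: {path}")
    else:
        raise IOError(f"unsupported video format: {path.suffix!r}")

    raw = np.asarray(raw)
    if raw.ndim == 2:
        raise ValueError(f"{path} holds a single frame; a stack needs at least 2")
    frames = _to_channel(_normalize(raw), channel)
    if calibration.roi is not None:
        r0, c0, h, w = calibration.roi
        if r0 + h > frames.shape[1] or c0 + w > frames.shape[2]:
            raise ValueError(f"roi {calibration.roi} exceeds frame bounds {frames.shape[1:]}")
        frames = frames[:, r0 : r0 + h, c0 : c0 + w]
    return FrameStack(frames, calibration, source_id=path.stem)


def save_stack(stack: FrameStack, path) -> None:
    """Write a stack as a 16-bit multi-page TIFF.

    Round-trip through :func:`load_stack` preserves shape exactly and
    intensity to 16-bit quantization (1/65535 per pixel).
    """
    path = Path(path)
    data = np.round(np.clip(stack.frames, 0, 1) * 65535).astype(np.uint16)
    try:
        tifffile.imwrite(path, data, photometric="minisblack")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
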