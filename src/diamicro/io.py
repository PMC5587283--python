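"""Calibrated images and TIFF / JSON sidecar I/O.

A :class:`CalibratedImage` couples a pixel array with its spatial
calibration (micrometres per pixel) and, for multi-channel stacks, a map
from biological channel role (``laminin``, ``nuclei``, ``cd68``) to plane
index.  Images round-trip through single-file TIFFs with the calibration
and channel map stored in the ImageDescription tag as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import CalibrationError, RegistrationError

__all__ = ["CalibratedImage", "read_image", "write_image", "write_ground_truth", "read_ground_truth"]


@dataclass
class CalibratedImage:
    """Pixel data plus spatial calibration.

    Parameters
    ----------
    data :
        ``(rows, cols)`` grayscale or ``(channels, rows, cols)`` stack,
        float or integer. Row-major, 0-based pixel coordinates.
    pixel_size_um :
        Edge length of one pixel in micrometres (isotropic).
    channels :
        Optional role -> plane-index map for multi-channel stacks,
        e.g. ``{"laminin": 0, "nuclei": 1, "cd68": 2}``.
    """

    data: np.ndarray
    pixel_size_um: float
    channels: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.pixel_size_um <= 0:
            raise CalibrationError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        if self.data.ndim not in (2, 3):
            raise RegistrationError(f"expected 2D or 3D array, got ndim={self.data.ndim}")
        if self.channels is not None:
            nplanes = 1 if self.data.ndim == 2 else self.data.shape[0]
            for role, idx in self.channels.items():
                if not (0 <= idx < nplanes):
                    raise RegistrationError(f"channel {role!r} index {idx} out of range for {nplanes} planes")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(rows, cols) of one plane."""
        return self.data.shape[-2:]

    @property
    def field_area_um2(self) -> float:
        r, c = self.frame_shape
        return r * c * self.pixel_size_um**2

    @property
    def field_area_mm2(self) -> float:
        return self.field_area_um2 / 1e6

    def channel(self, role: str) -> np.ndarray:
        """Return the 2D plane for a channel role."""
        if self.data.ndim == 2:
            return self.data
        if self.channels is None or role not in self.channels:
            raise RegistrationError(f"no channel map entry for role {role!r}")
        return self.data[self.channels[role]]


def write_image(path: str | Path, image: CalibratedImage) -> Path:
    """Write a CalibratedImage to TIFF with JSON metadata in the description."""
    path = Path(path)
    meta = {"pixel_size_um": image.pixel_size_um, "channels": image.channels}
    tifffile.imwrite(path, image.data, description=json.dumps(meta))
    return path


def read_image(path: str | Path, pixel_size_um: float | None = None,
               channels: dict[str, int] | None = None) -> CalibratedImage:
    """Read a TIFF written by :func:`write_image` (or any plain TIFF).

    Explicit ``pixel_size_um`` / ``channels`` arguments override embedded
    metadata; for plain TIFFs without metadata they are required.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise CalibrationError(f"{path}: no pixel size in metadata and none supplied")
    ch = channels if channels is not None else meta.get("channels")
    if ch is not None:
        ch = {k: int(v) for k, v in ch.items()}
    return CalibratedImage(data=data, pixel_size_um=float(px), channels=ch)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def write_ground_truth(path: str | Path, truth) -> Path:
    """Write a ground-truth dataclass as a JSON sidecar (arrays -> lists).

    Large raster fields (label masks) are dropped from the sidecar; they
    are reproducible from the generating spec and seed.
    """
    path = Path(path)
    d = dataclasses.asdict(truth)
    d = {k: _jsonable(v) for k, v in d.items() if not isinstance(v, np.ndarray) or v.ndim < 2}
    path.write_text(json.dumps(d, indent=1))
    return path


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
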