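"""Raster image and transform I/O.

Conventions used throughout the package
---------------------------------------
* Pixel coordinates are 0-based ``(x, y)`` with the origin at the top-left
  corner of the displayed image; ``y`` increases downward.  Arrays are stored
  ``pixels[row, col] == pixels[y, x]``.
* Shifts are reported as ``(dx, dy)`` = (columns, rows).
* Angles are in degrees, counter-clockwise positive in the displayed image.
* TIFF output is uncompressed; PNG is 8-bit only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import FormatError

MODALITIES = ("brightfield", "backscatter", "fluorescence", "sem", "binary")

#: Objective magnification -> camera pixel size in nm (2,048 px sensor,
#: 6.5 um pixel pitch).
MAGNIFICATION_TABLE: dict[int, float] = {
    100: 65.0,
    60: 108.0,
    40: 162.5,
    20: 325.0,
    10: 650.0,
    4: 1625.0,
}

_ALLOWED_DTYPES = (np.uint8, np.uint16, np.float32, np.float64)


def _binary_max(pixels: np.ndarray) -> float:
    if pixels.dtype == np.uint8:
        return 255
    if pixels.dtype == np.uint16:
        return 65535
    return 1.0


@dataclass
class RasterImage:
    """A 2-D intensity grid with optional physical pixel size and modality tag.

    Parameters
    ----------
    pixels
        2-D array, ``uint8``, ``uint16`` or unit-interval float.
    pixel_size_nm
        Physical edge length of one pixel in nanometres; strictly positive
        when given.
    modality
        One of :data:`MODALITIES`.  ``binary`` images may only contain the
        values ``{0, max}`` of their dtype.
    """

    pixels: np.ndarray
    pixel_size_nm: float | None = None
    modality: str = "brightfield"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got ndim={self.pixels.ndim}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have positive width and height")
        if self.pixels.dtype not in _ALLOWED_DTYPES:
            raise FormatError(
                f"unsupported bit depth {self.pixels.dtype}; "
                "use uint8, uint16 or float"
            )
        if self.pixel_size_nm is not None:
            if not (self.pixel_size_nm > 0):
                raise ValueError("pixel_size_nm must be strictly positive")
            self.pixel_size_nm = float(self.pixel_size_nm)
        if self.modality not in MODALITIES:
            raise ValueError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        if self.modality == "binary":
            hi = _binary_max(self.pixels)
            if not np.isin(self.pixels, (0, hi)).all():
                raise ValueError(
                    f"binary modality may only contain values {{0, {hi}}}"
                )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def astype_float(self) -> np.ndarray:
        """Return the pixel grid as float64 without rescaling."""
        return self.pixels.astype(np.float64)


def pixel_size_for_magnification(magnification: int) -> float:
    """Camera pixel size in nm for the given objective magnification."""
    try:
        return MAGNIFICATION_TABLE[int(magnification)]
    except KeyError:
        raise KeyError(
            f"no pixel size tabulated for magnification {magnification}x"
        ) from None


def read_raster(
    path: str | Path,
    pixel_size_nm: float | None = None,
    modality: str = "brightfield",
    channel: int | None = None,
) -> RasterImage:
    """Read a single-plane TIFF or PNG into a :class:`RasterImage`.

    Multi-channel inputs require ``channel``: for ``(H, W, C)`` layouts the
    last axis is indexed, for ``(C, H, W)`` stacks the first.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = iio.imread(path)
    else:
        raise FormatError(f"unsupported raster format: {suffix!r}")
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if channel is None:
            raise FormatError(
                f"{path} has {arr.shape} planes; pass a channel index"
            )
        if arr.shape[-1] in (2, 3, 4):
            arr = arr[..., channel]
        else:
            arr = arr[channel]
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected 2-D data, got shape {arr.shape}")
    if arr.dtype.kind in "iu" and arr.dtype.itemsize > 2:
        raise FormatError(
            f"unsupported bit depth {arr.dtype.itemsize * 8}-bit integer in {path}"
        )
    return RasterImage(arr, pixel_size_nm=pixel_size_nm, modality=modality)


def write_raster(image: RasterImage, path: str | Path) -> None:
    """Write a raster losslessly (uncompressed TIFF, or 8-bit PNG)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    elif suffix == ".png":
        if image.pixels.dtype != np.uint8:
            raise FormatError("PNG output supports 8-bit images only")
        iio.imwrite(path, image.pixels)
    else:
        raise FormatError(f"unsupported raster format: {suffix!r}")


@dataclass
class SimilarityTransform:
    """Scale + rotation + translation mapping between two pixel frames.

    Maps a point ``p = (x, y)`` to ``s * R(theta) @ p + (tx, ty)``, where the
    rotation is counter-clockwise positive in the displayed image (y down),
    i.e. ``R = [[cos, sin], [-sin, cos]]`` in (x, y) coordinates.
    """

    scale: float = 1.0
    rotation_deg: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    score: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise ValueError("scale must be strictly positive")

    @property
    def rotation_matrix(self) -> np.ndarray:
        th = math.radians(self.rotation_deg)
        c, s = math.cos(th), math.sin(th)
        return np.array([[c, s], [-s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an ``(N, 2)`` array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = self.scale * pts @ self.rotation_matrix.T
        out[:, 0] += self.tx
        out[:, 1] += self.ty
        return out

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        inv_rot = -self.rotation_deg
        t = -inv_scale * (
            SimilarityTransform(1.0, inv_rot).rotation_matrix @ np.array([self.tx, self.ty])
        )
        return SimilarityTransform(inv_scale, inv_rot, t[0], t[1])

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        rot = self.rotation_deg + other.rotation_deg
        scale = self.scale * other.scale
        t = self.apply(np.array([[other.tx, other.ty]]))[0]
        return SimilarityTransform(scale, rot, t[0], t[1])


def write_transform(transform: SimilarityTransform, path: str | Path) -> None:
    """Write a transform as a JSON record.

    Values round-trip exactly through ``repr`` floats (>= 12 significant
    digits).  Non-finite fields are rejected.
    """
    fields = {
        "scale": transform.scale,
        "rotation_deg": transform.rotation_deg,
        "tx_px": transform.tx,
        "ty_px": transform.ty,
        "score": transform.score,
    }
    for name, value in fields.items():
        if name != "score" and not math.isfinite(value):
            raise ValueError(f"transform field {name!r} is not finite: {value}")
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2)
        fh.write("\n")


def read_transform(path: str | Path) -> SimilarityTransform:
    with open(path) as fh:
        rec = json.load(fh)
    return SimilarityTransform(
        scale=rec["scale"],
        rotation_deg=rec["rotation_deg"],
        tx=rec["tx_px"],
        ty=rec["ty_px"],
        score=rec.get("score", float("nan")),
    )
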