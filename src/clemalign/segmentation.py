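"""Segmentation of gold micro-islands and island morphometrics.

Foreground always means gold.  Bright-field images show gold dark on bright
glass; back-scatter electron images show gold bright on dark glass, so the
``auto`` polarity flips with the modality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import EmptyDistributionError
from .raster_io import RasterImage

DEFAULT_MIN_AREA_PX = 20

ISLAND_COLUMNS = (
    "label",
    "pixel_count",
    "area_um2",
    "perimeter_px",
    "circularity",
    "centroid_x",
    "centroid_y",
)


@dataclass
class PatternMask:
    """Binary foreground (gold) mask with threshold provenance."""

    mask: np.ndarray
    modality: str = "binary"
    threshold: float | None = None
    polarity: str | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def to_raster(self) -> RasterImage:
        return RasterImage(
            self.mask.astype(np.uint8) * 255, modality="binary"
        )


@dataclass
class Island:
    """One labelled micro-pattern fiducial."""

    label: int
    pixel_count: int
    area_um2: float
    perimeter_px: float
    circularity: float
    centroid_x: float
    centroid_y: float


@dataclass
class IslandTable:
    """Ordered collection of islands; labels run 1..n by decreasing area."""

    islands: list[Island] = field(default_factory=list)
    pixel_size_nm: float | None = None
    source_mask: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.islands)

    def __iter__(self):
        return iter(self.islands)

    def __getitem__(self, i: int) -> Island:
        return self.islands[i]

    def centroids(self) -> np.ndarray:
        """(N, 2) array of (x, y) centroids."""
        return np.array([(i.centroid_x, i.centroid_y) for i in self.islands]).reshape(-1, 2)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[getattr(i, c) for c in ISLAND_COLUMNS] for i in self.islands],
            columns=list(ISLAND_COLUMNS),
        )


_AUTO_POLARITY = {
    "brightfield": "dark_foreground",
    "backscatter": "bright_foreground",
    "sem": "bright_foreground",
    "fluorescence": "bright_foreground",
    "binary": "bright_foreground",
}


def segment_pattern(image: RasterImage, polarity: str = "auto") -> PatternMask:
    """Segment gold foreground from glass background.

    The threshold is the two-class variance-maximizing (Otsu) criterion;
    ``auto`` polarity resolves from the image modality.  A constant image
    yields an empty mask with a warning flag rather than an exception.
    Binary-modality images pass through unchanged (idempotence).
    """
    if polarity not in ("auto", "dark_foreground", "bright_foreground"):
        raise ValueError(f"unknown polarity {polarity!r}")
    px = image.pixels
    if polarity == "auto":
        polarity = _AUTO_POLARITY[image.modality]

    if image.modality == "binary":
        return PatternMask(px > 0, modality="binary", polarity="bright_foreground")

    if px.min() == px.max():
        return PatternMask(
            np.zeros(px.shape, dtype=bool),
            modality=image.modality,
            polarity=polarity,
            warning="constant image: no contrast to segment",
        )

    thr = float(threshold_otsu(px))
    if polarity == "dark_foreground":
        mask = px <= thr
    else:
        mask = px > thr
    return PatternMask(mask, modality=image.modality, threshold=thr, polarity=polarity)


def label_islands(
    mask,
    pixel_size_nm: float,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    exclude_border: bool = False,
) -> IslandTable:
    """Extract 8-connected islands with morphometrics.

    Islands smaller than ``min_area_px`` are dropped; with
    ``exclude_border`` islands touching the frame edge are also dropped.
    Labels are reassigned 1..n ordered by decreasing area, ties broken by
    the top-left-most centroid.  The perimeter is the Crofton (projection)
    estimate, which is unbiased on rasterized disks; circularity
    ``4*pi*A/P**2`` is clipped at 1.0 since discretization can still push a
    disk above 1.
    """
    if not (pixel_size_nm > 0):
        raise ValueError("pixel_size_nm must be strictly positive")
    arr = mask.mask if isinstance(mask, PatternMask) else np.asarray(mask) > 0
    labels = cc_label(arr, connectivity=2)
    h, w = arr.shape
    rows = []
    for rp in regionprops(labels):
        if rp.area < max(min_area_px, 1):
            continue
        if exclude_border:
            r0, c0, r1, c1 = rp.bbox
            if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
                continue
        perim = float(rp.perimeter_crofton)
        if perim > 0:
            circ = min(1.0, 4.0 * np.pi * rp.area / perim**2)
        else:
            circ = 1.0  # degenerate 1-px island
        cy, cx = rp.centroid
        rows.append(
            Island(
                label=0,
                pixel_count=int(rp.area),
                area_um2=float(rp.area) * (pixel_size_nm / 1000.0) ** 2,
                perimeter_px=perim,
                circularity=circ,
                centroid_x=float(cx),
                centroid_y=float(cy),
            )
        )
    rows.sort(key=lambda i: (-i.pixel_count, i.centroid_y, i.centroid_x))
    for n, isl in enumerate(rows, start=1):
        isl.label = n
    return IslandTable(rows, pixel_size_nm=pixel_size_nm, source_mask=arr)


def island_statistics(table: IslandTable) -> dict:
    """Cumulative distributions of island area and circularity.

    Returns sorted values with their cumulative fractions (final value
    exactly 1) and (min, median, max) summary quantiles for both measures.
    """
    if len(table) == 0:
        raise EmptyDistributionError("island table is empty")
    out = {}
    for key, values in (
        ("area_um2", [i.area_um2 for i in table]),
        ("circularity", [i.circularity for i in table]),
    ):
        v = np.sort(np.asarray(values, dtype=float))
        cum = np.arange(1, len(v) + 1) / len(v)
        out[key] = {
            "values": v,
            "cumulative_fraction": cum,
            "min": float(v[0]),
            "median": float(np.median(v)),
            "max": float(v[-1]),
        }
    return out
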