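"""Translation registration and mosaicking.

Provides the spectral translation estimator shared by stitching, the
rotational aligner and the synthetic benchmark; grid stitching of
bright-field tiles into a global map; and scale-aware embedding of
high-resolution tiles into a lower-resolution base image.

Shift convention: ``phase_correlate(a, b)`` returns ``(dx, dy)`` such that
``b`` equals ``a`` cyclically shifted by ``(dx, dy)`` (columns, rows), i.e.
``b[y, x] == a[y - dy, x - dx]`` up to wrap-around.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import tukey
from skimage.feature import match_template
from skimage.transform import resize

from .errors import DegenerateInputError, PlacementNotFoundError
from .raster_io import RasterImage, SimilarityTransform

DEFAULT_OVERLAP = 0.30
SCORE_FLOOR = 0.05


def _as_array(image) -> np.ndarray:
    if isinstance(image, RasterImage):
        return image.astype_float()
    return np.asarray(image, dtype=np.float64)


@dataclass
class ShiftEstimate:
    """Integer pixel shift with a normalized correlation score in [0, 1]."""

    dx: int
    dy: int
    score: float
    sub_dx: float = 0.0
    sub_dy: float = 0.0

    @property
    def shift(self) -> tuple[int, int]:
        return (self.dx, self.dy)


def _taper(shape: tuple[int, int], alpha: float = 0.25) -> np.ndarray:
    wy = tukey(shape[0], alpha)
    wx = tukey(shape[1], alpha)
    return np.outer(wy, wx)


def _wrap_index(idx: int, n: int) -> int:
    # map FFT bin to signed shift in (-n/2, n/2]
    return idx - n if idx > n // 2 else idx


def phase_correlate(
    a,
    b,
    *,
    window: bool = True,
    max_shift: tuple[int, int] | None = None,
    subpixel: bool = False,
    lowpass: float | None = None,
) -> ShiftEstimate:
    """Estimate the integer translation between two equal-shape images.

    The estimator maximizes the inverse transform of the normalized
    cross-power spectrum (spectral whitening) of the mean-subtracted,
    optionally edge-tapered images; the peak amplitude is the phase-coherence
    score in [0, 1].  Ties are broken by smallest ``dx**2 + dy**2``, then
    smallest ``dy``, then smallest ``dx``.

    Parameters
    ----------
    max_shift
        Optional ``(mx, my)`` limiting the search to ``|dx| <= mx`` and
        ``|dy| <= my``.
    subpixel
        When true, add a parabolic refinement of the correlation peak in
        ``sub_dx``/``sub_dy`` (default off: integer-grid estimation is the
        contract the downstream accuracy analysis is built on).
    lowpass
        Optional spectral cutoff in cycles per pixel (Nyquist is 0.5).
        Frequencies above it are rolled off with a raised cosine before the
        inverse transform.  Images upsampled from a coarser grid carry only
        aliasing replicas above the coarse grid's Nyquist, and whitening
        amplifies them into pure noise; the cutoff removes that noise.
    """
    fa = _as_array(a)
    fb = _as_array(b)
    if fa.shape != fb.shape:
        raise ValueError(f"shape mismatch: {fa.shape} vs {fb.shape}")
    if fa.std() == 0 or fb.std() == 0:
        raise DegenerateInputError("constant image has no registrable content")

    fa = fa - fa.mean()
    fb = fb - fb.mean()
    if window:
        w = _taper(fa.shape)
        fa = fa * w
        fb = fb * w
        fa -= fa.mean()
        fb -= fb.mean()

    if np.linalg.norm(fa) == 0 or np.linalg.norm(fb) == 0:
        raise DegenerateInputError("image is constant after tapering")

    # normalized cross-power spectrum: corr[dy, dx] peaks where b = roll(a, d)
    # with unit amplitude for a perfect cyclic copy (phase coherence in [0,1])
    cross = np.conj(np.fft.rfft2(fa)) * np.fft.rfft2(fb)
    mag = np.abs(cross)
    cross /= mag + 1e-12 * mag.max() + 1e-300
    if lowpass is not None:
        fy = np.fft.fftfreq(fa.shape[0])[:, None]
        fx = np.fft.rfftfreq(fa.shape[1])[None, :]
        freq = np.hypot(fy, fx)
        cross *= 0.5 * (1.0 + np.cos(np.pi * np.clip(freq / lowpass, 0.0, 1.0)))
    corr = np.fft.irfft2(cross, s=fa.shape)

    h, wd = corr.shape
    dy_axis = np.array([_wrap_index(i, h) for i in range(h)])
    dx_axis = np.array([_wrap_index(i, wd) for i in range(wd)])
    if max_shift is not None:
        mx, my = max_shift
        mask = (np.abs(dy_axis)[:, None] > my) | (np.abs(dx_axis)[None, :] > mx)
        corr = np.where(mask, -np.inf, corr)

    peak = corr.max()
    if not np.isfinite(peak):
        raise DegenerateInputError("no admissible shift inside max_shift window")
    # collect near-exact ties and apply the deterministic tie-break
    ties = np.argwhere(corr >= peak - 1e-9 * abs(peak) - 1e-30)
    cands = [(dx_axis[j], dy_axis[i], i, j) for i, j in ties]
    cands.sort(key=lambda t: (t[0] ** 2 + t[1] ** 2, t[1], t[0]))
    dx, dy, iy, ix = cands[0]

    score = float(np.clip(corr[iy, ix], 0.0, 1.0))

    sub_dx = sub_dy = 0.0
    if subpixel:
        sub_dy = _parabolic_offset(
            corr[(iy - 1) % h, ix], corr[iy, ix], corr[(iy + 1) % h, ix]
        )
        sub_dx = _parabolic_offset(
            corr[iy, (ix - 1) % wd], corr[iy, ix], corr[iy, (ix + 1) % wd]
        )
    return ShiftEstimate(int(dx), int(dy), score, sub_dx, sub_dy)


def _parabolic_offset(left: float, mid: float, right: float) -> float:
    if not (np.isfinite(left) and np.isfinite(mid) and np.isfinite(right)):
        return 0.0
    denom = left - 2.0 * mid + right
    if denom == 0:
        return 0.0
    off = 0.5 * (left - right) / denom
    return float(np.clip(off, -0.5, 0.5))


@dataclass
class TileSet:
    """Tiles laid out on a nominal rectangular grid.

    ``tiles[r][c]`` is the tile at grid row ``r``, column ``c``; all tiles
    share one shape.  Nominal positions follow from the overlap fraction.
    """

    tiles: list
    grid_shape: tuple[int, int]
    overlap_fraction: float = DEFAULT_OVERLAP

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if len(self.tiles) != rows * cols:
            raise ValueError(
                f"grid {rows}x{cols} needs {rows * cols} tiles, got {len(self.tiles)}"
            )
        if not (0 < self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must lie in (0, 1)")
        self._arrays = [_as_array(t) for t in self.tiles]
        shapes = {arr.shape for arr in self._arrays}
        if len(shapes) != 1:
            raise ValueError(f"tiles must share one shape, got {shapes}")

    @property
    def tile_shape(self) -> tuple[int, int]:
        return self._arrays[0].shape

    def array(self, r: int, c: int) -> np.ndarray:
        return self._arrays[r * self.grid_shape[1] + c]

    def nominal_offset(self, r: int, c: int) -> tuple[int, int]:
        h, w = self.tile_shape
        step_x = int(round(w * (1 - self.overlap_fraction)))
        step_y = int(round(h * (1 - self.overlap_fraction)))
        return (c * step_x, r * step_y)


@dataclass
class GlobalMap:
    """A stitched mosaic plus the resolved per-tile offsets."""

    image: np.ndarray
    offsets: list  # rows: (tile_id, nominal_x, nominal_y, resolved_x, resolved_y, score)
    warnings: list = field(default_factory=list)


def _link_shift(
    tiles: TileSet, a: tuple[int, int], b: tuple[int, int]
) -> tuple[tuple[int, int], float]:
    """Correction to B's nominal offset relative to A, from the overlap strips."""
    h, w = tiles.tile_shape
    ov = tiles.overlap_fraction
    ta = tiles.array(*a)
    tb = tiles.array(*b)
    if b[1] == a[1] + 1:  # horizontal neighbour
        ow = max(4, int(round(w * ov)))
        strip_a, strip_b = ta[:, w - ow:], tb[:, :ow]
        search = (max(1, ow // 4), max(1, h // 4))
    elif b[0] == a[0] + 1:  # vertical neighbour
        oh = max(4, int(round(h * ov)))
        strip_a, strip_b = ta[h - oh:, :], tb[:oh, :]
        search = (max(1, w // 4), max(1, oh // 4))
    else:
        raise ValueError(f"tiles {a} and {b} are not grid neighbours")
    try:
        est = phase_correlate(strip_a, strip_b, max_shift=search)
    except DegenerateInputError:
        return (0, 0), 0.0
    # strip_b = roll(strip_a, t) => B sits at nominal - t
    return (-est.dx, -est.dy), est.score


def stitch_grid(tiles: TileSet, overlap_fraction: float | None = None) -> GlobalMap:
    """Stitch a grid of tiles into a global map.

    Pairwise shifts are estimated on the nominal overlap strips; a maximum
    spanning tree over link scores fixes a consistent global placement.
    Links scoring below :data:`SCORE_FLOOR` fall back to nominal placement
    with a warning.  Overlapping pixels are resolved last-writer-wins in
    row-major grid order.
    """
    if overlap_fraction is not None:
        tiles = TileSet(tiles.tiles, tiles.grid_shape, overlap_fraction)
    rows, cols = tiles.grid_shape
    warnings: list[str] = []

    links = []  # (score, tie_id, node_a, node_b, correction)
    for r in range(rows):
        for c in range(cols):
            for nb in ((r, c + 1), (r + 1, c)):
                if nb[0] >= rows or nb[1] >= cols:
                    continue
                corr, score = _link_shift(tiles, (r, c), nb)
                if score < SCORE_FLOOR:
                    warnings.append(
                        f"link {(r, c)}->{nb}: score {score:.3f} below floor, "
                        "using nominal placement"
                    )
                    corr = (0, 0)
                links.append((score, len(links), (r, c), nb, corr))

    # maximum spanning tree (Kruskal on -score); deterministic tie order
    parent: dict[tuple[int, int], tuple[int, int]] = {
        (r, c): (r, c) for r in range(rows) for c in range(cols)
    }

    def find(n):
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    adj: dict[tuple[int, int], list] = {n: [] for n in parent}
    for score, _, a, b, corr in sorted(links, key=lambda t: (-t[0], t[1])):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            # edge offset in the a -> b direction, fixed at insertion time
            na = tiles.nominal_offset(*a)
            nb = tiles.nominal_offset(*b)
            rel = (nb[0] - na[0] + corr[0], nb[1] - na[1] + corr[1])
            adj[a].append((b, rel, score, +1))
            adj[b].append((a, rel, score, -1))

    # accumulate resolved offsets from the anchor tile
    offsets: dict[tuple[int, int], tuple[int, int]] = {(0, 0): (0, 0)}
    link_score: dict[tuple[int, int], float] = {(0, 0): 1.0}
    stack = [(0, 0)]
    while stack:
        node = stack.pop()
        for other, rel, score, sign in adj[node]:
            if other in offsets:
                continue
            ox, oy = offsets[node]
            offsets[other] = (ox + sign * rel[0], oy + sign * rel[1])
            link_score[other] = score
            stack.append(other)

    h, w = tiles.tile_shape
    min_x = min(o[0] for o in offsets.values())
    min_y = min(o[1] for o in offsets.values())
    offsets = {k: (v[0] - min_x, v[1] - min_y) for k, v in offsets.items()}
    canvas_w = max(o[0] for o in offsets.values()) + w
    canvas_h = max(o[1] for o in offsets.values()) + h

    canvas = np.zeros((canvas_h, canvas_w))
    rows_out = []
    for r in range(rows):
        for c in range(cols):
            ox, oy = offsets[(r, c)]
            canvas[oy:oy + h, ox:ox + w] = tiles.array(r, c)
            nx, ny = tiles.nominal_offset(r, c)
            rows_out.append(
                (r * cols + c, nx - min_x, ny - min_y, ox, oy, link_score[(r, c)])
            )
    return GlobalMap(canvas, rows_out, warnings)


def embed_highres(
    base,
    tile,
    scale_ratio: float | str = "auto",
    *,
    score_floor: float = 0.3,
    output_scale: float | None = None,
) -> tuple[SimilarityTransform, np.ndarray]:
    """Place a high-resolution tile inside a lower-resolution base image.

    The tile is downscaled by ``scale_ratio`` (= base pixel size / tile pixel
    size; resolved from metadata when ``"auto"``), located by normalized
    cross-correlation, and composited into an enhanced image rendered at
    ``output_scale`` times the base resolution (default: ``scale_ratio``, so
    the tile is pasted at native resolution).

    Returns the tile->base :class:`SimilarityTransform` (rotation fixed at 0)
    and the composited image.
    """
    base_arr = _as_array(base)
    tile_arr = _as_array(tile)
    if scale_ratio == "auto":
        if not (
            isinstance(base, RasterImage)
            and isinstance(tile, RasterImage)
            and base.pixel_size_nm
            and tile.pixel_size_nm
        ):
            raise ValueError("scale_ratio='auto' requires pixel sizes on both images")
        scale_ratio = base.pixel_size_nm / tile.pixel_size_nm
    scale_ratio = float(scale_ratio)
    if scale_ratio <= 0:
        raise ValueError("scale_ratio must be positive")

    if scale_ratio != 1.0:
        small_shape = (
            max(1, int(round(tile_arr.shape[0] / scale_ratio))),
            max(1, int(round(tile_arr.shape[1] / scale_ratio))),
        )
        small = resize(
            tile_arr, small_shape, order=1, anti_aliasing=scale_ratio > 1,
            preserve_range=True,
        )
    else:
        small = tile_arr
    if small.shape[0] > base_arr.shape[0] or small.shape[1] > base_arr.shape[1]:
        raise ValueError("downscaled tile exceeds base field of view")

    ncc = match_template(base_arr, small, pad_input=False)
    iy, ix = np.unravel_index(np.argmax(ncc), ncc.shape)
    score = float(ncc[iy, ix])
    if score < score_floor:
        raise PlacementNotFoundError(
            f"best placement score {score:.3f} below floor {score_floor}"
        )
    placement = SimilarityTransform(
        scale=1.0 / scale_ratio, rotation_deg=0.0, tx=float(ix), ty=float(iy),
        score=score,
    )

    out_scale = scale_ratio if output_scale is None else float(output_scale)
    out_shape = (
        int(round(base_arr.shape[0] * out_scale)),
        int(round(base_arr.shape[1] * out_scale)),
    )
    enhanced = resize(base_arr, out_shape, order=1, preserve_range=True)
    tile_out = resize(
        tile_arr,
        (
            max(1, int(round(small.shape[0] * out_scale))),
            max(1, int(round(small.shape[1] * out_scale))),
        ),
        order=1,
        preserve_range=True,
    ) if out_scale != scale_ratio else tile_arr
    py, px = int(round(iy * out_scale)), int(round(ix * out_scale))
    th = min(tile_out.shape[0], out_shape[0] - py)
    tw = min(tile_out.shape[1], out_shape[1] - px)
    enhanced[py:py + th, px:px + tw] = tile_out[:th, :tw]
    return placement, enhanced
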