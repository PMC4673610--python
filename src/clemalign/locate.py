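"""ROI localization on the global map.

Finds the field of view around one cell on the stitched global map under
unknown translation, rotation and scale, by scale-space blob keypoints on
the binary micro-pattern masks (bright-field and back-scatter contrast are
opposite, masks make them comparable), nearest-neighbour descriptor
matching with a ratio test, and robust two-point similarity consensus.
Sparse patterns can be augmented with Voronoi edges drawn between island
centroids to add matchable structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import Voronoi
from scipy.spatial.distance import cdist
from shapely.geometry import LineString, box

from .errors import (
    DegenerateGeometryError,
    InsufficientCorrespondenceError,
)
from .raster_io import RasterImage, SimilarityTransform
from .segmentation import IslandTable, PatternMask, segment_pattern

DEFAULT_RATIO = 0.8
DEFAULT_INLIER_TOL = 3.0
DEFAULT_MIN_INLIERS = 8

_DESC_RINGS = 4          # descriptor log-polar grid: rings
_DESC_SECTORS = 12       # ... and angular sectors -> 48-d descriptor
_DESC_RADIUS_SIGMA = 8.0  # descriptor support radius in units of sigma
_ORI_BINS = 36           # orientation histogram resolution (10 deg)
_PYRAMID_SIGMA = 16.0    # sigmas above this run on a 4x-reduced image


@dataclass
class Keypoint:
    """Scale-space blob keypoint with a unit-norm local-context descriptor."""

    x: float
    y: float
    scale: float
    orientation_deg: float
    descriptor: np.ndarray

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class LocalizationResult:
    transform: SimilarityTransform | None
    inlier_count: int
    match_count: int
    status: str  # located | ambiguous | failed


def _to_float_image(image) -> np.ndarray:
    if isinstance(image, PatternMask):
        return image.mask.astype(np.float64)
    if isinstance(image, RasterImage):
        return image.astype_float()
    return np.asarray(image, dtype=np.float64)


def _sigma_series(min_sigma: float, max_sigma: float, per_octave: int = 3):
    ratio = 2.0 ** (1.0 / per_octave)
    sigmas = [min_sigma]
    while sigmas[-1] * ratio <= max_sigma:
        sigmas.append(sigmas[-1] * ratio)
    return np.array(sigmas)


def detect_keypoints(
    image,
    *,
    min_sigma: float = 1.6,
    max_sigma: float | None = None,
    threshold_rel: float = 0.03,
    max_keypoints: int = 3000,
) -> list[Keypoint]:
    """Detect multi-scale blob keypoints with orientation and descriptor.

    Scale-normalized Laplacian-of-Gaussian responses are computed over a
    geometric sigma series spanning at least four octaves (image size
    permitting); 3-D local extrema of either sign above
    ``threshold_rel * max|response|`` become keypoints.

    Orientation candidates come from the angular distribution of the
    surrounding pattern mass (up to four histogram peaks within 80% of the
    maximum; one keypoint copy per candidate, standard multi-orientation
    practice).  On radially symmetric fiducials the gradient direction
    itself is isotropic, so context — the direction of neighbouring islands
    — is what orients the keypoint.  The descriptor is a log-polar grid
    (4 rings x 12 sectors, 48-d, unit norm) of smoothed pattern intensity
    in the keypoint frame.

    A constant image returns an empty list.
    """
    arr = _to_float_image(image)
    if arr.std() == 0:
        return []
    if max_sigma is None:
        max_sigma = max(min_sigma * 2, min(arr.shape) / 8.0)
    sigmas = _sigma_series(min_sigma, max_sigma)

    # two-level pyramid: sigmas above _PYRAMID_SIGMA run on a 4x-reduced
    # image (scale-normalized LoG magnitude is invariant to the resampling)
    reduce = 4
    levels: list[tuple[np.ndarray, float, np.ndarray]] = []  # (image, factor, sigmas)
    small_sigmas = sigmas[sigmas <= _PYRAMID_SIGMA]
    large_sigmas = sigmas[sigmas > _PYRAMID_SIGMA]
    if len(small_sigmas):
        levels.append((arr, 1.0, small_sigmas))
    if len(large_sigmas) and min(arr.shape) >= 4 * reduce:
        h, w = arr.shape
        reduced = (
            arr[: h - h % reduce, : w - w % reduce]
            .reshape(h // reduce, reduce, w // reduce, reduce)
            .mean(axis=(1, 3))
        )
        levels.append((reduced, float(reduce), large_sigmas))

    found = []  # (response, x, y, sigma) in full-res coordinates
    per_level = []
    for img, factor, sigs in levels:
        stack = np.empty((len(sigs),) + img.shape)
        for i, s in enumerate(sigs):
            sl = s / factor
            # scale-normalized LoG; negated so bright blobs peak positive
            stack[i] = -(sl**2) * ndimage.gaussian_laplace(img, sl)
        per_level.append((img, factor, sigs, stack))
    global_max = max(np.abs(st).max() for _, _, _, st in per_level)
    thr = threshold_rel * global_max
    for img, factor, sigs, stack in per_level:
        for resp in (stack, -stack):
            peaks = (resp == ndimage.maximum_filter(resp, size=3)) & (resp > thr)
            for si, yi, xi in np.argwhere(peaks):
                s = sigs[si]
                m = int(math.ceil(s / factor))
                if (
                    yi < m or xi < m
                    or yi >= img.shape[0] - m or xi >= img.shape[1] - m
                ):
                    continue
                x = xi * factor + (factor - 1) / 2.0
                y = yi * factor + (factor - 1) / 2.0
                found.append((float(resp[si, yi, xi]), x, y, float(s), factor))
    if not found:
        return []
    found.sort(key=lambda t: -t[0])
    found = found[:max_keypoints]

    # batch orientation/descriptor extraction per (sigma, pyramid level)
    level_image = {factor: img for img, factor, _, _ in per_level}
    keypoints: list[Keypoint] = []
    by_sigma: dict[tuple[float, float], list[tuple[float, float]]] = {}
    for _, x, y, s, factor in found:
        by_sigma.setdefault((s, factor), []).append((x, y))
    for (s, factor), positions in by_sigma.items():
        img = level_image[factor]
        sl = s / factor
        smooth = ndimage.gaussian_filter(img, max(0.5, sl / 2.0))
        xs = np.array([p[0] for p in positions])
        ys = np.array([p[1] for p in positions])
        # sample in level coordinates
        lx = (xs - (factor - 1) / 2.0) / factor
        ly = (ys - (factor - 1) / 2.0) / factor
        candidates = _orientation_candidates_batch(smooth, lx, ly, sl)
        fx, fy, flx, fly, fth = [], [], [], [], []
        for x, y, px, py, cands in zip(xs, ys, lx, ly, candidates):
            for th in cands:
                fx.append(x); fy.append(y)
                flx.append(px); fly.append(py); fth.append(th)
        descs = _descriptor_batch(
            smooth, np.array(flx), np.array(fly), sl, np.array(fth)
        )
        for x, y, th, d in zip(fx, fy, fth, descs):
            if d is not None:
                keypoints.append(Keypoint(float(x), float(y), float(s), float(th), d))
    return keypoints


def _orientation_candidates_batch(
    smooth, xs, ys, sigma, max_peaks: int = 4
) -> list[list[float]]:
    """Context orientation candidates per point (degrees, display convention).

    Histogram of smoothed pattern intensity over the position angle of
    samples in the annulus ``(1.5 sigma, 8 sigma]``; every peak within 80%
    of the (circularly smoothed) maximum becomes a candidate, with
    parabolic sub-bin refinement.  On a radially symmetric fiducial the
    local gradient direction is isotropic, so the direction of the
    surrounding islands is what orients the keypoint.
    """
    r = _DESC_RADIUS_SIGMA * sigma
    n = 15
    offs = np.linspace(-r, r, n)
    ox, oy = np.meshgrid(offs, offs)
    rad = np.hypot(ox, oy).ravel()
    sel = (rad > 1.5 * sigma) & (rad <= r)
    pxs, pys = ox.ravel()[sel], oy.ravel()[sel]
    sx = xs[:, None] + pxs[None, :]
    sy = ys[:, None] + pys[None, :]
    coords = np.vstack([sy.ravel(), sx.ravel()])
    v = ndimage.map_coordinates(
        smooth, coords, order=1, mode="nearest"
    ).reshape(sx.shape)
    ab = (
        (np.arctan2(pys, pxs) + np.pi) / (2 * np.pi) * _ORI_BINS
    ).astype(int) % _ORI_BINS
    hist = np.zeros((len(xs), _ORI_BINS))
    np.add.at(
        hist,
        (np.repeat(np.arange(len(xs)), len(pxs)), np.tile(ab, (len(xs), 1)).ravel()),
        v.ravel(),
    )
    kernel = np.array([1.0, 4.0, 6.0, 4.0, 1.0])
    kernel /= kernel.sum()
    ext = np.concatenate([hist[:, -2:], hist, hist[:, :2]], axis=1)
    hist = np.apply_along_axis(
        lambda h: np.convolve(h, kernel, mode="same"), 1, ext
    )[:, 2:-2]

    out: list[list[float]] = []
    for hi in hist:
        mx = hi.max()
        if mx <= 0:
            out.append([0.0])
            continue
        peaks = []
        for b in range(_ORI_BINS):
            left = hi[(b - 1) % _ORI_BINS]
            mid = hi[b]
            right = hi[(b + 1) % _ORI_BINS]
            if mid >= left and mid > right and mid >= 0.8 * mx:
                den = left - 2 * mid + right
                off = 0.0 if den == 0 else float(
                    np.clip(0.5 * (left - right) / den, -0.5, 0.5)
                )
                peaks.append(
                    (
                        mid,
                        math.degrees(
                            ((b + 0.5 + off) / _ORI_BINS) * 2 * np.pi - np.pi
                        ),
                    )
                )
        peaks.sort(key=lambda t: -t[0])
        out.append([p[1] for p in peaks[:max_peaks]] if peaks else [0.0])
    return out


def _polar_sample_grid():
    """Fixed polar sample offsets (unit radius) with their cell index."""
    ring_edges = np.linspace(0.0, 1.0, _DESC_RINGS + 1)
    rs, angs, cell = [], [], []
    for i in range(_DESC_RINGS):
        for j in range(_DESC_SECTORS):
            for a in range(3):
                for b in range(3):
                    rs.append(
                        ring_edges[i]
                        + (ring_edges[i + 1] - ring_edges[i]) * (a + 0.5) / 3
                    )
                    angs.append(2 * np.pi * (j + (b + 0.5) / 3) / _DESC_SECTORS)
                    cell.append(i * _DESC_SECTORS + j)
    return np.array(rs), np.array(angs), np.array(cell)


_POLAR_RS, _POLAR_ANGS, _POLAR_CELL = _polar_sample_grid()


def _descriptor_batch(smooth, xs, ys, sigma, thetas_deg) -> list:
    """Polar-grid pattern-intensity descriptors in each keypoint frame."""
    if len(xs) == 0:
        return []
    radius = _DESC_RADIUS_SIGMA * sigma
    th = np.radians(np.asarray(thetas_deg))
    c, s = np.cos(th)[:, None], np.sin(th)[:, None]
    px = radius * _POLAR_RS * np.cos(_POLAR_ANGS)
    py = radius * _POLAR_RS * np.sin(_POLAR_ANGS)
    # display convention: +theta rotates CCW on screen (y down)
    sx = xs[:, None] + c * px[None, :] - s * py[None, :]
    sy = ys[:, None] + s * px[None, :] + c * py[None, :]
    coords = np.vstack([sy.ravel(), sx.ravel()])
    v = ndimage.map_coordinates(
        smooth, coords, order=1, mode="nearest"
    ).reshape(sx.shape)
    k = len(xs)
    ncell = _DESC_RINGS * _DESC_SECTORS
    desc = np.zeros((k, ncell))
    np.add.at(
        desc,
        (np.repeat(np.arange(k), v.shape[1]), np.tile(_POLAR_CELL, (k, 1)).ravel()),
        v.ravel(),
    )
    out: list = []
    for d in desc:
        d = d - d.mean()
        norm = np.linalg.norm(d)
        out.append(d / norm if norm > 1e-9 else None)
    return out


def match_descriptors(
    query: list[Keypoint],
    reference: list[Keypoint],
    ratio: float = DEFAULT_RATIO,
    *,
    position_eps: float = 3.0,
) -> list[tuple[int, int, float]]:
    """Ratio-test descriptor matching, one match per physical keypoint.

    Returns ``(query_index, reference_index, distance)`` triples.  The
    second-nearest distance for the ratio test is taken over references at
    a *different* position than the nearest one, so orientation duplicates
    of the same blob cannot veto their own match.  Matches are made
    one-to-one per rounded keypoint position, best distance first.
    """
    if not query or not reference:
        raise ValueError("both keypoint sets must be non-empty")
    if not (0 < ratio <= 1):
        raise ValueError("ratio must lie in (0, 1]")
    dq = np.array([k.descriptor for k in query])
    dr = np.array([k.descriptor for k in reference])
    pos_r = np.array([[k.x, k.y] for k in reference])
    dist = cdist(dq, dr)
    nn = np.argmin(dist, axis=1)
    candidates = []
    for qi, ri in enumerate(nn):
        d1 = dist[qi, ri]
        dxy = pos_r - pos_r[ri]
        far = np.hypot(dxy[:, 0], dxy[:, 1]) > position_eps
        if far.any():
            d2 = dist[qi, far].min()
            if d2 <= 0 or d1 / d2 >= ratio:
                continue
        candidates.append((float(d1), qi, int(ri)))
    candidates.sort()
    used_q: set = set()
    used_r: set = set()
    matches = []
    for d1, qi, ri in candidates:
        qkey = (round(query[qi].x), round(query[qi].y))
        rkey = (round(reference[ri].x), round(reference[ri].y))
        if qkey in used_q or rkey in used_r:
            continue
        used_q.add(qkey)
        used_r.add(rkey)
        matches.append((qi, ri, d1))
    return matches


def _solve_two_point(z1, z2, w1, w2):
    """Closed-form similarity through two complex point pairs."""
    dz = z2 - z1
    if dz == 0:
        return None
    m = (w2 - w1) / dz
    t = w1 - m * z1
    return m, t


def _transform_from_complex(m: complex, t: complex) -> SimilarityTransform:
    # apply() uses R = [[c, s], [-s, c]] so the complex multiplier is
    # s * exp(-i * theta_display)
    scale = abs(m)
    rot = -math.degrees(math.atan2(m.imag, m.real))
    return SimilarityTransform(scale, rot, t.real, t.imag)


def estimate_similarity(
    src_points,
    dst_points,
    inlier_tol_px: float = DEFAULT_INLIER_TOL,
    seed: int = 0,
    max_iters: int | None = None,
) -> tuple[SimilarityTransform, np.ndarray]:
    """Robust similarity from point correspondences (2-point consensus).

    Repeatedly samples two matches, solves the closed-form two-point
    similarity, counts correspondences with reprojection error below
    ``inlier_tol_px`` and refits least-squares on the best inlier set.  The
    default iteration count keeps the consensus reliable down to inlier
    rates of a few percent.

    Returns the transform and a boolean inlier mask; raises
    :class:`InsufficientCorrespondenceError` for fewer than two matches.
    """
    src = np.atleast_2d(np.asarray(src_points, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_points, dtype=float))
    n = len(src)
    if n != len(dst):
        raise ValueError("src and dst must have equal length")
    if n < 2:
        raise InsufficientCorrespondenceError(
            f"need at least 2 correspondences, got {n}"
        )
    z = src[:, 0] + 1j * src[:, 1]
    w = dst[:, 0] + 1j * dst[:, 1]

    if n == 2:
        sol = _solve_two_point(z[0], z[1], w[0], w[1])
        if sol is None:
            raise DegenerateGeometryError("coincident source points")
        tf = _transform_from_complex(*sol)
        return tf, np.array([True, True])

    if max_iters is None:
        # >99.9% confidence of one all-inlier sample down to ~6% inlier rate
        max_iters = 2000
    rng = np.random.default_rng(seed)
    best = None  # (count, -err_sum, m, t, mask)
    for _ in range(max_iters):
        i, j = rng.choice(n, size=2, replace=False)
        sol = _solve_two_point(z[i], z[j], w[i], w[j])
        if sol is None:
            continue
        m, t = sol
        err = np.abs(m * z + t - w)
        mask = err < inlier_tol_px
        count = int(mask.sum())
        key = (count, -float(err[mask].sum()))
        if best is None or key > best[0]:
            best = (key, m, t, mask)
    if best is None:
        raise DegenerateGeometryError("all sampled point pairs were degenerate")
    _, m, t, mask = best

    # least-squares refit on the inlier set
    zi, wi = z[mask], w[mask]
    if len(zi) >= 2 and np.ptp(zi.real) + np.ptp(zi.imag) > 0:
        zc, wc = zi - zi.mean(), wi - wi.mean()
        denom = np.vdot(zc, zc).real
        if denom > 0:
            m = np.vdot(zc, wc) / denom  # sum(conj(zc) * wc) / sum(|zc|^2)
            t = wi.mean() - m * zi.mean()
            err = np.abs(m * z + t - w)
            mask = err < inlier_tol_px
    return _transform_from_complex(m, t), mask


def _ransac_candidates(
    src: np.ndarray,
    dst: np.ndarray,
    inlier_tol_px: float,
    seed: int,
    max_iters: int = 2000,
    top_k: int = 8,
) -> list[tuple[int, SimilarityTransform]]:
    """Top-K distinct 2-point RANSAC hypotheses, each refit on its inliers.

    The true consensus in a heavily contaminated match set can be smaller
    than a spurious one, so the single best-count hypothesis is not enough;
    the caller disambiguates the survivors by pattern-overlap verification.
    """
    n = len(src)
    if n < 2:
        return []
    z = src[:, 0] + 1j * src[:, 1]
    w = dst[:, 0] + 1j * dst[:, 1]
    rng = np.random.default_rng(seed)
    hyps = []  # (count, m, t, mask)
    for _ in range(max_iters):
        i, j = rng.choice(n, size=2, replace=False)
        sol = _solve_two_point(z[i], z[j], w[i], w[j])
        if sol is None:
            continue
        m, t = sol
        err = np.abs(m * z + t - w)
        mask = err < inlier_tol_px
        count = int(mask.sum())
        if count >= 3:
            hyps.append((count, m, t, mask))
    hyps.sort(key=lambda h: -h[0])
    out: list[tuple[int, SimilarityTransform]] = []
    kept_params: list[tuple[complex, complex]] = []
    for count, m, t, mask in hyps:
        # refit least squares on the hypothesis' inliers
        zi, wi = z[mask], w[mask]
        zc, wc = zi - zi.mean(), wi - wi.mean()
        denom = np.vdot(zc, zc).real
        if denom > 0:
            m = np.vdot(zc, wc) / denom
            t = wi.mean() - m * zi.mean()
        duplicate = any(
            abs(m - m0) <= 0.02 * abs(m0) + 1e-12 and abs(t - t0) < 3.0
            for m0, t0 in kept_params
        )
        if duplicate:
            continue
        kept_params.append((m, t))
        out.append((count, _transform_from_complex(m, t)))
        if len(out) >= top_k:
            break
    return out


def _to_mask_array(obj) -> np.ndarray:
    from .mosaic import GlobalMap

    if isinstance(obj, PatternMask):
        return obj.mask.astype(np.float64)
    if isinstance(obj, GlobalMap):
        obj = RasterImage(
            np.clip(obj.image, 0, 255).astype(np.uint8), modality="brightfield"
        )
    if isinstance(obj, RasterImage):
        if obj.modality == "binary":
            return (obj.pixels > 0).astype(np.float64)
        return segment_pattern(obj).mask.astype(np.float64)
    arr = np.asarray(obj, dtype=np.float64)
    uniq = np.unique(arr)
    if len(uniq) <= 2:
        return (arr > arr.min()).astype(np.float64)
    return segment_pattern(
        RasterImage(arr.astype(np.float64) / max(arr.max(), 1e-12))
    ).mask.astype(np.float64)


def _guided_inliers(
    kp_q: list[Keypoint],
    kp_r: list[Keypoint],
    tf: SimilarityTransform,
    tol: float,
    iterations: int = 5,
):
    """Grow the consensus by geometric matching of keypoint positions.

    Projects every (deduplicated) query keypoint through ``tf``, pairs it
    one-to-one with the nearest reference keypoint within a tightened
    tolerance and refits the transform on the pairs, iterating a few times.
    The grown consensus must stay close to the initial transform (no
    iterative-closest-point drift) and must exceed three times the count
    expected from chance proximity alone.  Returns ``(transform, count,
    src_points, dst_points)`` or ``None``.
    """
    from scipy.spatial import cKDTree

    tol_g = min(tol, max(1.5, tol / 2.0))
    init = tf
    pq = np.unique(np.round([[k.x, k.y] for k in kp_q], 1), axis=0)
    pr = np.unique(np.round([[k.x, k.y] for k in kp_r], 1), axis=0)
    area_r = max(np.ptp(pr[:, 0]), 1.0) * max(np.ptp(pr[:, 1]), 1.0)
    expected_by_chance = len(pq) * math.pi * tol_g**2 * len(pr) / area_r
    tree = cKDTree(pr)
    best = None
    # annealed tolerance: latch on at the caller's tolerance, then tighten
    schedule = [tol] * max(1, iterations - 1) + [tol_g]
    for tol_it in schedule:
        proj = tf.apply(pq)
        dist, idx = tree.query(proj)
        order = np.argsort(dist)
        used: set[int] = set()
        pairs = []
        for i in order:
            if dist[i] >= tol_it:
                break
            if idx[i] in used:
                continue
            used.add(int(idx[i]))
            pairs.append((pq[i], pr[idx[i]]))
        if len(pairs) < 2:
            return best
        src = np.array([p[0] for p in pairs])
        dst = np.array([p[1] for p in pairs])
        z = src[:, 0] + 1j * src[:, 1]
        w = dst[:, 0] + 1j * dst[:, 1]
        zc, wc = z - z.mean(), w - w.mean()
        denom = np.vdot(zc, zc).real
        if denom <= 0:
            return best
        m = np.vdot(zc, wc) / denom
        t = w.mean() - m * z.mean()
        refit = _transform_from_complex(m, t)
        # a collapsing or exploding scale signals a bogus consensus
        if not (0.25 < refit.scale / init.scale < 4.0):
            return best
        tf = refit
        if tol_it <= tol_g and len(pairs) >= 3.0 * expected_by_chance:
            best = (tf, len(pairs), src, dst)
    return best


def _hough_filter(
    kp_q: list[Keypoint],
    kp_r: list[Keypoint],
    matches: list[tuple[int, int, float]],
    top_k: int = 6,
    min_size: int = 4,
    expand: bool = True,
) -> list[list[tuple[int, int, float]]]:
    """Group matches into (scale-ratio, rotation)-consistent clusters.

    Each match predicts the transform's scale (reference/query detection
    scale) and rotation (orientation difference); true correspondences agree
    on both, mismatches scatter.  A coarse 2-D histogram vote (half-octave x
    20 degrees, with +/-1-bin tolerance) proposes up to ``top_k`` candidate
    subsets; the caller verifies every candidate against the pattern
    overlap, so proposing too many is cheap and proposing too few is fatal.
    """
    if len(matches) < 4:
        return [matches]
    dlog = np.array(
        [math.log2(kp_r[ri].scale / kp_q[qi].scale) for qi, ri, _ in matches]
    )
    dth = np.array(
        [(kp_r[ri].orientation_deg - kp_q[qi].orientation_deg) % 360.0
         for qi, ri, _ in matches]
    )
    lbin = np.round(dlog / 0.5).astype(int)
    tbin = (np.round(dth / 20.0).astype(int)) % 18
    votes: dict[tuple[int, int], int] = {}
    for lb, tb in zip(lbin, tbin):
        votes[(lb, tb)] = votes.get((lb, tb), 0) + 1
    pools = []
    for (bl, bt), _count in sorted(votes.items(), key=lambda kv: -kv[1])[:top_k]:
        if expand:
            keep = [
                m
                for m, lb, tb in zip(matches, lbin, tbin)
                if abs(lb - bl) <= 1 and min((tb - bt) % 18, (bt - tb) % 18) <= 1
            ]
        else:
            keep = [
                m for m, lb, tb in zip(matches, lbin, tbin)
                if lb == bl and tb == bt
            ]
        if len(keep) >= min_size:
            pools.append(keep)
    return pools


def _verify_overlap(roi_mask: np.ndarray, map_mask: np.ndarray, tf) -> float:
    """Dice overlap between the transformed ROI pattern and the map pattern.

    The decisive check for a candidate transform: keypoint consensus can be
    fooled by chance coincidences, but warping the whole ROI mask onto the
    map and measuring foreground agreement cannot.  Returns the Dice
    coefficient over the warped ROI support (0 = no agreement).
    """
    from scipy import ndimage as _ndi

    inv = tf.inverse()
    rinv = inv.rotation_matrix * inv.scale
    # (row, col) order for ndimage: input = M @ output + offset
    m = np.array([[rinv[1, 1], rinv[1, 0]], [rinv[0, 1], rinv[0, 0]]])
    off = np.array([inv.ty, inv.tx])
    warped = _ndi.affine_transform(
        roi_mask.astype(np.float32), m, offset=off, order=1,
        mode="constant", cval=-1.0, output_shape=map_mask.shape,
    )
    support = warped >= 0.0
    n_support = int(support.sum())
    if n_support < 64:
        return 0.0
    a = warped > 0.5
    b = (map_mask > 0.5) & support
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    dice = 2.0 * float((a & b).sum()) / float(denom)
    # penalize transforms that push most of the ROI off the map: agreement
    # over a sliver of the pattern is not evidence
    expected = roi_mask.size * tf.scale**2
    frac = n_support / max(expected, 1.0)
    if frac < 0.4:
        dice *= frac / 0.4
    return dice


def _bin_seeded_candidates(
    kp_q: list[Keypoint],
    kp_r: list[Keypoint],
    matches: list[tuple[int, int, float]],
    pools: list[list[tuple[int, int, float]]],
    roi_mask: np.ndarray,
    map_mask: np.ndarray,
) -> list[SimilarityTransform]:
    """Transform hypotheses from each match cluster's pose vote.

    Each Hough pool votes a scale and rotation (median over its matches);
    warping the ROI by that pose and phase-correlating against the map
    yields the translation in a single spectral registration — no minimal
    sampling involved, so a handful of correct matches suffices.
    """
    from .mosaic import phase_correlate
    from scipy import ndimage as _ndi

    h, w = map_mask.shape
    out = []
    for pool in pools:
        if not pool:
            continue
        # direct trimmed least-squares on the bin members: exact bins are
        # often nearly pure, which pins down the full transform at once
        if len(pool) >= 3:
            z = np.array([complex(*kp_q[qi].position) for qi, _, _ in pool])
            wv = np.array([complex(*kp_r[ri].position) for _, ri, _ in pool])
            keep = np.ones(len(z), dtype=bool)
            fit = None
            for _ in range(3):
                zc, wc = z[keep] - z[keep].mean(), wv[keep] - wv[keep].mean()
                denom = np.vdot(zc, zc).real
                if denom <= 0:
                    break
                mm = np.vdot(zc, wc) / denom
                tt = wv[keep].mean() - mm * z[keep].mean()
                if abs(mm) > 0:
                    fit = (mm, tt)
                res = np.abs(mm * z + tt - wv)
                new_keep = res < max(3.0, 2.5 * float(np.median(res[keep])))
                if new_keep.sum() < 3 or (new_keep == keep).all():
                    break
                keep = new_keep
            if fit is not None:
                out.append(_transform_from_complex(*fit))
        s_est = 2.0 ** float(
            np.median([math.log2(kp_r[ri].scale / kp_q[qi].scale) for qi, ri, _ in pool])
        )
        ths = np.radians(
            [(kp_r[ri].orientation_deg - kp_q[qi].orientation_deg) for qi, ri, _ in pool]
        )
        # orientation deltas vote the transform rotation with opposite sign
        # (keypoint frames rotate against the content)
        th_est = -math.degrees(
            math.atan2(float(np.mean(np.sin(ths))), float(np.mean(np.cos(ths))))
        )
        if not (0.05 < s_est < 20):
            continue
        pose = SimilarityTransform(s_est, th_est, 0.0, 0.0)
        inv = pose.inverse()
        rinv = inv.rotation_matrix * inv.scale
        m = np.array([[rinv[1, 1], rinv[1, 0]], [rinv[0, 1], rinv[0, 0]]])
        warped = _ndi.affine_transform(
            roi_mask.astype(np.float32), m, offset=0.0, order=1,
            mode="constant", cval=0.0, output_shape=(h, w),
        )
        if warped.std() == 0:
            continue
        try:
            est = phase_correlate(warped, map_mask.astype(np.float32))
        except Exception:
            continue
        dx, dy = est.dx % w, est.dy % h
        out.append(SimilarityTransform(s_est, th_est, float(dx), float(dy)))
    return out


def _perturb_about(tf: SimilarityTransform, center_map, dtheta: float, dscale: float):
    """Compose a small rotation/scale about a fixed map-frame point."""
    adj = SimilarityTransform(1.0 + dscale, dtheta, 0.0, 0.0)
    c = np.asarray(center_map, dtype=float)
    shift = c - adj.apply(c[None, :])[0]
    adj = SimilarityTransform(1.0 + dscale, dtheta, shift[0], shift[1])
    return adj.compose(tf)


def _polish_candidate(
    tf: SimilarityTransform,
    roi_mask: np.ndarray,
    map_mask: np.ndarray,
    kp_roi: list[Keypoint],
    kp_map: list[Keypoint],
    tol: float,
):
    """Local pose refinement maximizing pattern overlap.

    Alternates coarse-to-fine sweeps of rotation and scale (about the
    mapped ROI centre, where the overlap score is most sensitive) with a
    guided geometric refit.  Keypoint consensus can stall a couple of
    degrees off the optimum; the overlap objective does not.
    """
    from .mosaic import phase_correlate
    from scipy import ndimage as _ndi

    def correct_translation(cand: SimilarityTransform) -> SimilarityTransform:
        inv = cand.inverse()
        rinv = inv.rotation_matrix * inv.scale
        m = np.array([[rinv[1, 1], rinv[1, 0]], [rinv[0, 1], rinv[0, 0]]])
        warped = _ndi.affine_transform(
            roi_mask.astype(np.float32), m, offset=np.array([inv.ty, inv.tx]),
            order=1, mode="constant", cval=0.0, output_shape=map_mask.shape,
        )
        if warped.std() == 0:
            return cand
        try:
            est = phase_correlate(
                warped, map_mask.astype(np.float32), max_shift=(16, 16),
                subpixel=True,
            )
        except Exception:
            return cand
        return SimilarityTransform(
            cand.scale, cand.rotation_deg,
            cand.tx + est.dx + est.sub_dx, cand.ty + est.dy + est.sub_dy,
        )

    rc = np.array([(roi_mask.shape[1] - 1) / 2.0, (roi_mask.shape[0] - 1) / 2.0])
    best_score = _verify_overlap(roi_mask, map_mask, tf)
    best_tf = tf
    for step_th, step_sc in ((3.0, 0.04), (1.0, 0.01), (0.25, 0.0025)):
        cand = correct_translation(best_tf)
        sc = _verify_overlap(roi_mask, map_mask, cand)
        if sc > best_score:
            best_score, best_tf = sc, cand
        center = best_tf.apply(rc[None, :])[0]
        for dth in np.arange(-3 * step_th, 3 * step_th + 1e-9, step_th):
            if dth == 0:
                continue
            cand = _perturb_about(best_tf, center, float(dth), 0.0)
            sc = _verify_overlap(roi_mask, map_mask, cand)
            if sc > best_score:
                best_score, best_tf = sc, cand
        center = best_tf.apply(rc[None, :])[0]
        for dsc in np.arange(-3 * step_sc, 3 * step_sc + 1e-9, step_sc):
            if dsc == 0:
                continue
            cand = _perturb_about(best_tf, center, 0.0, float(dsc))
            sc = _verify_overlap(roi_mask, map_mask, cand)
            if sc > best_score:
                best_score, best_tf = sc, cand
        grown = _guided_inliers(kp_roi, kp_map, best_tf, tol)
        if grown is not None:
            sc = _verify_overlap(roi_mask, map_mask, grown[0])
            if sc > best_score:
                best_score, best_tf = sc, grown[0]
    grown = _guided_inliers(kp_roi, kp_map, best_tf, tol)
    return best_tf, best_score, grown


def locate_roi(
    roi,
    global_map,
    *,
    ratio: float = DEFAULT_RATIO,
    inlier_tol_px: float = DEFAULT_INLIER_TOL,
    min_inliers: int = DEFAULT_MIN_INLIERS,
    min_overlap: float = 0.5,
    seed: int = 0,
) -> LocalizationResult:
    """Locate a ROI snapshot on the global map.

    Pipeline: detect keypoints on both patterns, match descriptors,
    propose transforms from scale/rotation-consistent match clusters,
    refine each by guided geometric re-matching, and pick the candidate
    whose warped ROI pattern best overlaps the map pattern (Dice).  The
    returned transform maps ROI pixel coordinates onto map pixel
    coordinates.  A low-confidence result is reported as status
    ``ambiguous`` or ``failed`` rather than asserting a transform.
    """
    roi_mask = _to_mask_array(roi)
    map_mask = _to_mask_array(global_map)
    kp_roi = detect_keypoints(roi_mask)
    kp_map = detect_keypoints(map_mask)
    if not kp_roi or not kp_map:
        return LocalizationResult(None, 0, 0, "failed")
    matches = match_descriptors(kp_roi, kp_map, ratio)
    if len(matches) < 2:
        return LocalizationResult(None, 0, len(matches), "failed")
    src_all = np.array([kp_roi[qi].position for qi, _, _ in matches])
    dst_all = np.array([kp_map[ri].position for _, ri, _ in matches])

    # candidate transforms from the Hough-consistent pools and the full set;
    # overlap verification is cheap and decisive, so propose generously
    pools = _hough_filter(kp_roi, kp_map, matches) + [matches]
    candidates = []  # (overlap, count, tf, inlier_src, inlier_dst)

    def consider(tf: SimilarityTransform) -> None:
        proj = tf.apply(src_all)
        err = np.hypot(proj[:, 0] - dst_all[:, 0], proj[:, 1] - dst_all[:, 1])
        mask = err < inlier_tol_px
        count = int(mask.sum())
        inlier_src, inlier_dst = src_all[mask], dst_all[mask]
        # guided geometric re-matching refines the transform and grows the
        # consensus over all detected keypoint positions
        if count >= 2:
            grown = _guided_inliers(kp_roi, kp_map, tf, inlier_tol_px)
            if grown is not None and grown[1] > count:
                tf, count, inlier_src, inlier_dst = grown
        if not (0.05 < tf.scale < 20):
            return
        overlap = _verify_overlap(roi_mask, map_mask, tf)
        candidates.append((overlap, count, tf, inlier_src, inlier_dst))

    for pi, pool in enumerate(pools):
        idx = [matches.index(m) for m in pool]
        for _count0, tf in _ransac_candidates(
            src_all[idx], dst_all[idx], inlier_tol_px, seed + pi
        ):
            consider(tf)
    # pose-vote hypotheses: robust when correct matches are too few for
    # minimal-sample consensus; seeded from every bin with a minimal vote,
    # because the correct cluster can be badly outvoted by spurious ones
    seed_pools = _hough_filter(
        kp_roi, kp_map, matches, top_k=24, min_size=3, expand=False
    )
    for tf in _bin_seeded_candidates(
        kp_roi, kp_map, matches, seed_pools, roi_mask, map_mask
    ):
        consider(tf)

    if not candidates:
        return LocalizationResult(None, 0, len(matches), "failed")

    # polish the leading candidates (overlap-driven local pose refinement)
    candidates.sort(key=lambda c: (c[0], c[1]), reverse=True)
    overlap, count, best_tf, inlier_src, inlier_dst = candidates[0]
    for cand_overlap, cand_count, tf, c_src, c_dst in candidates[:3]:
        if cand_overlap <= 0.1:
            continue
        polished, pol_score, grown = _polish_candidate(
            tf, roi_mask, map_mask, kp_roi, kp_map, inlier_tol_px
        )
        if pol_score > overlap:
            best_tf, overlap = polished, pol_score
            count, inlier_src, inlier_dst = cand_count, c_src, c_dst
            if grown is not None and grown[1] > count:
                _, count, inlier_src, inlier_dst = grown

    # guards: inliers must span an area (no point-collapse consensus) and
    # the warped pattern must actually coincide with the map pattern
    spread_ok = (
        count >= 2
        and np.ptp(inlier_src, axis=0).max() > 4 * inlier_tol_px
        and np.ptp(inlier_dst, axis=0).max() > 4 * inlier_tol_px
    )
    if count >= min_inliers and spread_ok and overlap >= min_overlap:
        return LocalizationResult(best_tf, count, len(matches), "located")
    if count >= max(4, min_inliers // 2) and spread_ok and overlap >= 0.5 * min_overlap:
        return LocalizationResult(None, count, len(matches), "ambiguous")
    return LocalizationResult(None, count, len(matches), "failed")


def voronoi_augment(
    islands: IslandTable,
    frame_shape: tuple[int, int],
    mask: np.ndarray | None = None,
) -> tuple[list[tuple[tuple[float, float], tuple[float, float]]], np.ndarray]:
    """Voronoi tessellation of island centroids, rasterized into the mask.

    Returns the clipped edge segments ``((x1, y1), (x2, y2))`` and the
    augmented binary mask: 1-px-wide Voronoi edges unioned with the island
    mask (or with ``islands.source_mask`` when ``mask`` is omitted).
    """
    from skimage.draw import line as draw_line

    pts = islands.centroids()
    if len(pts) == 0:
        raise ValueError("island table has no centroids")
    if mask is None:
        mask = islands.source_mask
    if mask is None:
        mask = np.zeros(frame_shape, dtype=bool)
    out = np.asarray(mask).astype(bool).copy()
    if out.shape != tuple(frame_shape):
        raise ValueError("mask shape does not match frame_shape")

    if len(pts) == 1:
        return [], out

    if np.ptp(pts, axis=0).max() < 1e-9:
        raise DegenerateGeometryError("all centroids coincide")

    h, w = frame_shape
    frame = box(0, 0, w - 1, h - 1)
    diag = float(np.hypot(h, w)) * 2

    segments = []
    if len(pts) == 2 or _collinear(pts):
        order = np.argsort(pts @ _principal_direction(pts))
        p = pts[order]
        for a, b in zip(p[:-1], p[1:]):
            segments.append(_bisector_segment(a, b, diag))
    else:
        vor = Voronoi(pts)
        center = pts.mean(axis=0)
        for (p1, p2), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
            if v1 >= 0 and v2 >= 0:
                segments.append((vor.vertices[v1], vor.vertices[v2]))
            else:
                vfin = vor.vertices[max(v1, v2)]
                t = pts[p2] - pts[p1]
                t = t / np.linalg.norm(t)
                nrm = np.array([-t[1], t[0]])
                mid = pts[[p1, p2]].mean(axis=0)
                if np.dot(mid - center, nrm) < 0:
                    nrm = -nrm
                segments.append((vfin, vfin + nrm * diag))

    edges = []
    for a, b in segments:
        seg = LineString([tuple(a), tuple(b)]).intersection(frame)
        if seg.is_empty or seg.geom_type != "LineString":
            continue
        (x1, y1), (x2, y2) = seg.coords[0], seg.coords[-1]
        edges.append(((x1, y1), (x2, y2)))
        rr, cc = draw_line(
            int(round(y1)), int(round(x1)), int(round(y2)), int(round(x2))
        )
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        out[rr[keep], cc[keep]] = True
    return edges, out


def _collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    if len(pts) < 3:
        return True
    d = pts - pts.mean(axis=0)
    _, sv, _ = np.linalg.svd(d, full_matrices=False)
    return sv[-1] <= tol * max(sv[0], 1.0)


def _principal_direction(pts: np.ndarray) -> np.ndarray:
    d = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    return vt[0]


def _bisector_segment(a: np.ndarray, b: np.ndarray, length: float):
    mid = (a + b) / 2.0
    d = b - a
    d = d / np.linalg.norm(d)
    perp = np.array([-d[1], d[0]])
    return (mid - perp * length, mid + perp * length)
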