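"""Rotation + translation alignment between the two micro-pattern images,
and fusion of the accompanying fluorescence / SEM channels.

The result convention is "rotate then translate": pattern B is pattern A
rotated by ``rotation_deg`` about the image centre (counter-clockwise
positive as displayed) and then shifted by ``(dx, dy)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import AlignmentFailedError, DegenerateInputError, GeometryError
from .mosaic import phase_correlate
from .raster_io import RasterImage, SimilarityTransform
from .segmentation import PatternMask

DEFAULT_COARSE_STEP = 2.0
DEFAULT_REFINE_STEP = 0.1
DEFAULT_SCORE_FLOOR = 0.05


@dataclass
class AlignmentResult:
    """Best rotation/shift plus the full score-vs-angle profile."""

    rotation_deg: float
    dx: float
    dy: float
    score: float
    profile: list  # (angle_deg, score) over the evaluated sweep

    @property
    def shift(self) -> tuple[float, float]:
        return (self.dx, self.dy)


def _as_float(pattern) -> np.ndarray:
    if isinstance(pattern, PatternMask):
        return pattern.mask.astype(np.float64)
    if isinstance(pattern, RasterImage):
        return pattern.astype_float()
    return np.asarray(pattern, dtype=np.float64)


def _rotation_matrix_display(theta_deg: float) -> np.ndarray:
    """(x, y) rotation matrix, CCW positive as displayed (y down)."""
    th = math.radians(theta_deg)
    c, s = math.cos(th), math.sin(th)
    return np.array([[c, s], [-s, c]])


def apply_rigid(
    image,
    theta_deg: float,
    shift: tuple[float, float] = (0.0, 0.0),
    *,
    scale: float = 1.0,
    center: tuple[float, float] | None = None,
    order: int = 1,
    output_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Warp: scale+rotate about ``center`` (default image centre), then shift.

    A point ``p`` of the input lands at
    ``scale * R(theta) @ (p - c) + c + shift`` in the output.  Bilinear
    interpolation by default, zero background.
    """
    arr = _as_float(image)
    if center is None:
        center = ((arr.shape[1] - 1) / 2.0, (arr.shape[0] - 1) / 2.0)
    cx, cy = center
    dx, dy = shift
    # inverse map: p_in = R(-theta)/scale @ (p_out - shift - c) + c
    rinv = _rotation_matrix_display(-theta_deg) / scale
    # in (row, col) = (y, x) order for ndimage
    m = np.array([[rinv[1, 1], rinv[1, 0]], [rinv[0, 1], rinv[0, 0]]])
    off = np.array(
        [
            cy - m[0, 0] * (cy + dy) - m[0, 1] * (cx + dx),
            cx - m[1, 0] * (cy + dy) - m[1, 1] * (cx + dx),
        ]
    )
    return ndimage.affine_transform(
        arr, m, offset=off, order=order, mode="constant", cval=0.0,
        output_shape=output_shape or arr.shape,
    )


def rotational_align(
    pattern_a,
    pattern_b,
    coarse_step_deg: float = DEFAULT_COARSE_STEP,
    refine_step_deg: float = DEFAULT_REFINE_STEP,
    *,
    score_floor: float = DEFAULT_SCORE_FLOOR,
) -> AlignmentResult:
    """Full-circle rotation sweep with per-angle translation registration.

    For each angle on the coarse grid ``[0, 360)`` pattern B is rotated back
    about its centre and registered against pattern A by phase correlation;
    the best-scoring angle is refined at ``refine_step_deg`` over one coarse
    step on either side.  Ties are broken toward the smaller angle, making
    the result deterministic for symmetric patterns.  The coarse sweep runs
    on a 2x-reduced rendering of large patterns (angle selection only; the
    refinement and the reported shift use full resolution).
    """
    if coarse_step_deg <= 0 or refine_step_deg <= 0:
        raise ValueError("angle steps must be positive")
    a = _as_float(pattern_a)
    b = _as_float(pattern_b)
    if a.std() == 0 or b.std() == 0 or a.max() == 0 or b.max() == 0:
        raise DegenerateInputError("empty or constant pattern")

    def reduce2(img):
        h, w = img.shape
        return (
            img[: h - h % 2, : w - w % 2]
            .reshape(h // 2, 2, w // 2, 2)
            .mean(axis=(1, 3))
        )

    use_pyramid = min(a.shape) >= 256 and a.shape == b.shape
    a_c, b_c = (reduce2(a), reduce2(b)) if use_pyramid else (a, b)

    def evaluate(theta: float, coarse: bool):
        ref, mov = (a_c, b_c) if coarse else (a, b)
        rb = apply_rigid(mov, -theta, order=1)
        if rb.std() == 0:
            return None
        return phase_correlate(ref, rb)

    profile: list[tuple[float, float]] = []
    best = None  # (score, angle)
    for theta in np.arange(0.0, 360.0, coarse_step_deg):
        est = evaluate(float(theta), coarse=True)
        score = est.score if est is not None else 0.0
        profile.append((float(theta), score))
        # strict > keeps the smaller angle on ties
        if est is not None and (best is None or score > best[0] + 1e-12):
            best = (score, float(theta))
    if best is None or best[0] < score_floor:
        raise AlignmentFailedError(
            f"best rotation score {0 if best is None else best[0]:.4f} "
            f"below floor {score_floor}"
        )

    # full-resolution refinement around the winning coarse angle
    lo = best[1] - coarse_step_deg
    hi = best[1] + coarse_step_deg
    best = None  # (score, angle, est) at full resolution
    for theta in np.arange(lo, hi + refine_step_deg / 2, refine_step_deg):
        th = round(float(theta) % 360.0, 9)
        est = evaluate(th, coarse=False)
        if est is None:
            continue
        profile.append((th, est.score))
        if (
            best is None
            or est.score > best[0] + 1e-12
            or (est.score > best[0] - 1e-12 and th < best[1])
        ):
            best = (est.score, th, est)
    if best is None or best[0] < score_floor:
        raise AlignmentFailedError(
            f"refined rotation score below floor {score_floor}"
        )

    score, theta, est = best
    # phase_correlate on (a, rot_b) measures R(-theta) @ t; undo the rotation
    m = np.array([est.dx, est.dy], dtype=float)
    t = _rotation_matrix_display(theta) @ m
    return AlignmentResult(theta, float(t[0]), float(t[1]), score, profile)


def _result_params(result) -> tuple[float, float, tuple[float, float], bool]:
    """(scale, theta, shift, center_anchored) from either result type."""
    if isinstance(result, AlignmentResult):
        return 1.0, result.rotation_deg, (result.dx, result.dy), True
    if isinstance(result, SimilarityTransform):
        return result.scale, result.rotation_deg, (result.tx, result.ty), False
    raise TypeError(f"unsupported transform type {type(result).__name__}")


def fuse_channels(
    light_channels: list,
    em_image,
    result,
    *,
    order: int = 1,
) -> np.ndarray:
    """Fuse light-microscope channels with an EM image.

    Each light channel is warped into EM coordinates with the alignment
    parameters (rotate then translate; bilinear interpolation, zero
    background) and stacked with the EM image as the last channel of a
    ``(n_channels + 1, H, W)`` float array sized to the EM image.
    """
    em = _as_float(em_image)
    arrays = [_as_float(ch) for ch in light_channels]
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise GeometryError(f"light channels disagree in shape: {shapes}")
    scale, theta, shift, anchored = _result_params(result)
    out = []
    for arr in arrays:
        center = (
            ((arr.shape[1] - 1) / 2.0, (arr.shape[0] - 1) / 2.0)
            if anchored
            else (0.0, 0.0)
        )
        out.append(
            apply_rigid(
                arr, theta, shift, scale=scale, center=center,
                order=order, output_shape=em.shape,
            )
        )
    out.append(em)
    return np.stack(out)
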