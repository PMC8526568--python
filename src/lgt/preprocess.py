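"""Image corrections and segmentation applied to raw stacks.

The correction chain mirrors standard ratiometric-biosensor practice:

1. dark-current subtraction (images acquired without excitation),
2. shading correction (division by a unit-mean uniform-dye reference),
3. channel registration from fluorescent-bead fiducials,
4. per-frame background subtraction from a cell-free region,
5. Otsu-based segmentation on the donor channel (highest SNR),
6. exclusion of pixels in the background range in *any* channel.

All operations return new stacks; the input is never mutated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from .stack import BackgroundRegion, CorrectionBundle, MaskStack, RawStack

__all__ = [
    "AffineTransform",
    "subtract_dark",
    "shading_correct",
    "estimate_affine_from_fiducials",
    "apply_affine",
    "subtract_background",
    "segment_cells",
    "background_range_mask",
]


@dataclass(frozen=True)
class AffineTransform:
    """2-D affine map ``dst = A @ src + b`` on (row, col) coordinates.

    ``matrix`` is the 2×3 block ``[A | b]``.  ``residual_rms`` records the
    fit residual when the transform was estimated from point pairs.
    """

    matrix: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {m.shape}")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise ValueError("affine linear part is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def from_translation(cls, dr: float, dc: float) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, dr], [0.0, 1.0, dc]]))

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def offset(self) -> np.ndarray:
        return self.matrix[:, 2]

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return points @ self.linear.T + self.offset

    def inverse(self) -> "AffineTransform":
        inv_lin = np.linalg.inv(self.linear)
        inv_off = -inv_lin @ self.offset
        return AffineTransform(np.hstack([inv_lin, inv_off[:, None]]))

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(np.allclose(self.matrix, AffineTransform.identity().matrix, atol=tol))


def subtract_dark(stack: RawStack, bundle: CorrectionBundle, *, clip: bool = True) -> RawStack:
    """Subtract each channel's dark frame; negatives are clipped to zero.

    Clipping keeps downstream ratio images stable when read noise drives
    near-zero pixels negative.
    """
    out = stack.copy()
    for c, role in enumerate(stack.channel_roles):
        if role not in bundle.dark:
            raise KeyError(f"no dark frame for channel {role!r}")
        dark = np.asarray(bundle.dark[role], dtype=float)
        if dark.shape != stack.frame_shape:
            raise ValueError(f"dark frame shape {dark.shape} != frame {stack.frame_shape}")
        out.data[:, c] -= dark
    if clip:
        np.clip(out.data, 0.0, None, out=out.data)
    return out


def shading_correct(stack: RawStack, bundle: CorrectionBundle) -> RawStack:
    """Divide each channel by its unit-mean shading reference."""
    out = stack.copy()
    for c, role in enumerate(stack.channel_roles):
        if role not in bundle.shading:
            raise KeyError(f"no shading reference for channel {role!r}")
        ref = bundle.shading[role]
        if ref.shape != stack.frame_shape:
            raise ValueError(f"shading shape {ref.shape} != frame {stack.frame_shape}")
        out.data[:, c] /= ref
    return out


def estimate_affine_from_fiducials(
    points_src: np.ndarray, points_dst: np.ndarray
) -> AffineTransform:
    """Least-squares affine mapping bead coordinates src -> dst.

    Requires at least three non-collinear pairs; the RMS residual of the
    fit is stored on the returned transform.
    """
    src = np.atleast_2d(np.asarray(points_src, dtype=float))
    dst = np.atleast_2d(np.asarray(points_dst, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ValueError("point sets must both be (N, 2)")
    n = src.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 point pairs, got {n}")
    # collinearity check: rank of centred src must be 2
    centred = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(src).max())) < 2:
        raise ValueError("fiducial points are collinear; affine is under-determined")
    design = np.hstack([src, np.ones((n, 1))])
    coef, _, _, _ = np.linalg.lstsq(design, dst, rcond=None)  # (3, 2)
    matrix = coef.T  # (2, 3)
    resid = design @ coef - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineTransform(matrix, residual_rms=rms)


def apply_affine(
    stack: RawStack,
    transform: AffineTransform,
    channels: tuple[str, ...] | list[str],
) -> tuple[RawStack, np.ndarray]:
    """Resample the named channels into the reference frame.

    ``transform`` maps moving-camera coordinates onto the reference frame;
    resampling is bilinear.  Returns the new stack and a 2-D validity mask
    that is False where the resampled value fell outside the moving image.
    """
    out = stack.copy()
    inv = transform.inverse()
    h, w = stack.frame_shape
    valid = np.ones((h, w), dtype=bool)
    if transform.is_identity() or not channels:
        return out, valid
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords_ref = np.stack([rr.ravel(), cc.ravel()], axis=1)
    coords_mov = inv.apply_points(coords_ref)
    sample = coords_mov.T.reshape(2, h, w)
    inside = (
        (sample[0] >= 0) & (sample[0] <= h - 1) & (sample[1] >= 0) & (sample[1] <= w - 1)
    )
    valid &= inside
    for role in channels:
        c = stack.channel_index(role)
        for t in range(stack.n_frames):
            warped = ndimage.map_coordinates(
                stack.data[t, c], sample, order=1, mode="constant", cval=0.0
            )
            warped[~inside] = 0.0
            out.data[t, c] = warped
    return out, valid


def subtract_background(
    stack: RawStack,
    region: BackgroundRegion,
    cell_masks: np.ndarray | None = None,
) -> tuple[RawStack, np.ndarray, np.ndarray]:
    """Subtract the per-frame, per-channel mean of a cell-free region.

    Returns ``(corrected, levels, sds)`` where ``levels`` and ``sds`` are
    (T, C) arrays of the region mean and standard deviation — the latter
    feeds the background-range pixel exclusion.
    """
    if region.n_pixels < 25:
        raise ValueError("background region must contain at least 25 pixels")
    if cell_masks is not None:
        rmask = region.mask(stack.frame_shape)
        if np.any(np.asarray(cell_masks, dtype=bool) & rmask):
            warnings.warn(
                "background region overlaps the cell mask; proceeding anyway",
                stacklevel=2,
            )
    rs, cs = region.slices()
    patch = stack.data[:, :, rs, cs]  # (T, C, h, w)
    levels = patch.mean(axis=(2, 3))
    sds = patch.std(axis=(2, 3))
    out = stack.copy()
    out.data -= levels[:, :, None, None]
    return out, levels, sds


def segment_cells(
    stack: RawStack,
    role: str = "donor",
    *,
    smooth_window: int = 5,
    keep_largest: bool = True,
) -> MaskStack:
    """Per-frame Otsu segmentation on one channel (donor by default).

    The per-frame Otsu thresholds are optionally smoothed with a temporal
    running median (odd window, truncated at the series edges) to suppress
    frame-to-frame threshold jitter, after which the largest connected
    component is retained.  Degenerate (constant) frames yield an empty
    mask with a warning.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    chan = stack.channel(role)
    n = stack.n_frames
    thresholds = np.empty(n)
    degenerate = np.zeros(n, dtype=bool)
    for t in range(n):
        frame = chan[t]
        if np.ptp(frame) == 0:
            warnings.warn(f"frame {t} is constant; empty mask produced", stacklevel=2)
            degenerate[t] = True
            thresholds[t] = float(frame.flat[0])
            continue
        thresholds[t] = threshold_otsu(frame)
    if smooth_window > 1 and n > 1:
        half = smooth_window // 2
        smoothed = np.array(
            [np.median(thresholds[max(0, t - half) : min(n, t + half + 1)]) for t in range(n)]
        )
    else:
        smoothed = thresholds.copy()
    masks = np.zeros((n,) + stack.frame_shape, dtype=bool)
    for t in range(n):
        if degenerate[t]:
            continue
        m = chan[t] > smoothed[t]
        if keep_largest and m.any():
            lab = label(m)
            counts = np.bincount(lab.ravel())
            counts[0] = 0
            m = lab == counts.argmax()
        masks[t] = m
    return MaskStack(masks=masks, thresholds=smoothed)


def background_range_mask(
    stack: RawStack,
    levels: np.ndarray,
    sds: np.ndarray,
    k: float = 2.0,
) -> np.ndarray:
    """Validity mask excluding pixels in the background range of any channel.

    A pixel is valid only if, in every channel, its intensity exceeds the
    background level plus ``k`` background standard deviations; failing the
    test in any single channel invalidates it (ratio images are unstable
    wherever any constituent channel carries no signal).
    """
    levels = np.asarray(levels, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if levels.shape != (stack.n_frames, len(stack.channel_roles)):
        raise ValueError("levels must be (T, C)")
    cut = levels + k * sds  # (T, C)
    above = stack.data > cut[:, :, None, None]
    return np.all(above, axis=1)  # (T, H, W)
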