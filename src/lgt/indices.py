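"""Per-pixel biosensor indices from corrected channel stacks.

Two indices are produced:

* the FRET index, a proxy for RAC1 activity:
  ``R = (FRET − α·Donor − β·Acceptor) / Donor`` with bleed-through
  fractions α (donor into FRET) and β (directly excited acceptor into
  FRET) estimated from single-fluorophore control cells;
* the GTP index, a proxy for free GTP: the ratio of the GTP-sensor
  fluorescence excited at 409 nm to that excited at 494 nm.

A double-exponential photobleach correction fitted to the whole-cell mean
rescales each frame; because the rescaling is a per-frame scalar it leaves
within-frame spatial patterns (and hence pixel-wise correlations) intact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu

from .stack import MaskStack, RawStack

__all__ = [
    "IndexStack",
    "DisplayScale",
    "estimate_bleedthrough",
    "compute_fret_index",
    "compute_gtp_index",
    "photobleach_correct",
    "display_scale",
]


@dataclass
class IndexStack:
    """Per-frame real-valued index maps plus a per-pixel validity mask.

    ``values`` is (T, H, W) with NaN wherever ``valid`` is False;
    ``kind`` is ``"fret"`` or ``"gtp"``.
    """

    values: np.ndarray
    valid: np.ndarray
    kind: str
    frame_interval: float = 1.0
    photobleach_corrected: bool = False
    bleach_params: Optional[dict] = None
    bleach_warning: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape or self.values.ndim != 3:
            raise ValueError("values and valid must be matching (T, H, W) arrays")
        if self.kind not in ("fret", "gtp"):
            raise ValueError(f"kind must be 'fret' or 'gtp', got {self.kind!r}")
        bad = self.valid & ~np.isfinite(self.values)
        if np.any(bad):
            # non-finite values are never valid
            self.valid = self.valid & np.isfinite(self.values)
        self.values = np.where(self.valid, self.values, np.nan)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.frame_interval


def _expressing_pixels(channel: np.ndarray) -> np.ndarray:
    """Boolean mask of fluorophore-expressing pixels in a control stack.

    Otsu on the pooled intensities separates expressing cells from the
    (background-subtracted) empty field.
    """
    finite = channel[np.isfinite(channel)]
    if finite.size == 0 or np.ptp(finite) == 0:
        return np.zeros(channel.shape, dtype=bool)
    thr = threshold_otsu(finite)
    return channel > thr


def estimate_bleedthrough(
    donor_only: RawStack,
    acceptor_only: RawStack,
    min_pixels: int = 500,
) -> tuple[float, float]:
    """Bleed-through fractions from single-fluorophore control stacks.

    Both stacks must already be dark-, shading- and background-corrected.
    α is the zero-intercept regression slope of FRET-channel on
    donor-channel intensity over donor-expressing pixels; β likewise from
    the acceptor-only stack.  Raises if fewer than ``min_pixels``
    expressing pixels are found or a slope falls outside [0, 1).
    """

    def _slope(stack: RawStack, predictor: str) -> float:
        x = stack.channel(predictor)
        y = stack.channel("fret")
        sel = _expressing_pixels(x)
        n = int(sel.sum())
        if n < min_pixels:
            raise ValueError(
                f"only {n} {predictor}-expressing pixels; need >= {min_pixels}"
            )
        xv, yv = x[sel], y[sel]
        slope = float(xv @ yv / (xv @ xv))
        # a slope a hair below 0 is sampling noise around a true 0
        if slope < -0.01 or slope >= 1.0:
            raise ValueError(
                f"implausible bleed-through slope {slope:.4f} from {predictor}-only stack"
            )
        return max(slope, 0.0)

    alpha = _slope(donor_only, "donor")
    beta = _slope(acceptor_only, "acceptor")
    return alpha, beta


def _as_stack3d(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected (H, W) or (T, H, W), got shape {arr.shape}")
    return arr


def compute_fret_index(
    fret: np.ndarray,
    donor: np.ndarray,
    acceptor: np.ndarray,
    alpha: float = 0.0,
    beta: float = 0.0,
    valid: Optional[np.ndarray] = None,
    *,
    frame_interval: float = 1.0,
    eps_frac: float = 1e-6,
) -> IndexStack:
    """Bleed-through-corrected FRET index R = (FRET − αD − βA) / D.

    Pixels whose donor intensity falls below ``eps_frac`` of the frame
    maximum are invalidated (the ratio is unstable there).
    """
    fret, donor, acceptor = map(_as_stack3d, (fret, donor, acceptor))
    if not (fret.shape == donor.shape == acceptor.shape):
        raise ValueError("channel maps must share a shape")
    v = np.ones(fret.shape, dtype=bool) if valid is None else _as_stack3d(valid).astype(bool)
    if v.shape != fret.shape:
        raise ValueError("validity mask shape mismatch")
    eps = eps_frac * np.nanmax(donor, axis=(1, 2), keepdims=True)
    v = v & (donor > eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (fret - alpha * donor - beta * acceptor) / donor
    return IndexStack(values=np.where(v, r, np.nan), valid=v, kind="fret",
                      frame_interval=frame_interval)


def compute_gtp_index(
    ex409: np.ndarray,
    ex494: np.ndarray,
    valid: Optional[np.ndarray] = None,
    *,
    frame_interval: float = 1.0,
    eps_frac: float = 1e-6,
) -> IndexStack:
    """GTP index: ratio of the 409-nm to the 494-nm excitation image."""
    ex409, ex494 = map(_as_stack3d, (ex409, ex494))
    if ex409.shape != ex494.shape:
        raise ValueError("channel maps must share a shape")
    v = np.ones(ex409.shape, dtype=bool) if valid is None else _as_stack3d(valid).astype(bool)
    if v.shape != ex409.shape:
        raise ValueError("validity mask shape mismatch")
    eps = eps_frac * np.nanmax(ex494, axis=(1, 2), keepdims=True)
    v = v & (ex494 > eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = ex409 / ex494
    return IndexStack(values=np.where(v, r, np.nan), valid=v, kind="gtp",
                      frame_interval=frame_interval)


def _double_exp(t, a1, k1, a2, k2):
    return a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)


def _single_exp(t, a, k):
    return a * np.exp(-k * t)


def _fit_double_exponential(t: np.ndarray, m: np.ndarray) -> tuple[np.ndarray, dict]:
    """Multi-start bounded double-exponential fit of a whole-cell mean series.

    Rates are initialized on a log-spaced grid over [1e-4, 1] per minute
    and the lowest-SSE converged fit wins; falls back to a single
    exponential, then to no correction, when fitting fails.
    """
    m0 = m[0]
    best = None
    k_grid = np.logspace(-4, 0, 5)
    for k1 in k_grid:
        for k2 in k_grid:
            if k2 > k1:
                continue
            try:
                popt, _ = curve_fit(
                    _double_exp, t, m,
                    p0=[m0 / 2, k1, m0 / 2, k2],
                    bounds=([0, 0, 0, 0], [np.inf, 10.0, np.inf, 10.0]),
                    maxfev=5000,
                )
            except (RuntimeError, ValueError):
                continue
            sse = float(np.sum((_double_exp(t, *popt) - m) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt)
    if best is not None and _double_exp(t, *best[1]).min() > 0:
        a1, k1, a2, k2 = best[1]
        return _double_exp(t, *best[1]), {
            "model": "double_exponential", "a1": a1, "k1": k1, "a2": a2, "k2": k2,
            "sse": best[0],
        }
    # fall back to a single exponential
    for k in k_grid:
        try:
            popt, _ = curve_fit(
                _single_exp, t, m, p0=[m0, k],
                bounds=([0, 0], [np.inf, 10.0]), maxfev=5000,
            )
        except (RuntimeError, ValueError):
            continue
        if _single_exp(t, *popt).min() > 0:
            warnings.warn("double-exponential fit failed; using single exponential",
                          stacklevel=3)
            return _single_exp(t, *popt), {
                "model": "single_exponential", "a": popt[0], "k": popt[1],
            }
    raise RuntimeError("photobleach fit did not converge")


def photobleach_correct(
    index: IndexStack, masks: MaskStack | np.ndarray, min_frames: int = 6
) -> IndexStack:
    """Fit-and-divide photobleach correction of an index stack.

    The in-mask whole-cell mean index per frame is fitted to
    ``m(t) = a1·e^(−k1·t) + a2·e^(−k2·t)`` and every frame is divided by
    ``m(t)/m(0)``.  The correction multiplies each frame by a scalar, so
    spatial patterns within frames are preserved exactly.
    """
    if index.n_frames < min_frames:
        raise ValueError(
            f"need >= {min_frames} frames to fit 4 parameters, got {index.n_frames}"
        )
    mask_arr = masks.masks if isinstance(masks, MaskStack) else np.asarray(masks, dtype=bool)
    if mask_arr.ndim == 2:
        mask_arr = np.broadcast_to(mask_arr, index.values.shape)
    if mask_arr.shape != index.values.shape:
        raise ValueError("mask shape mismatch")
    sel = mask_arr & index.valid
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.array([
            np.nanmean(np.where(sel[t], index.values[t], np.nan))
            for t in range(index.n_frames)
        ])
    if np.any(~np.isfinite(m)) or np.any(m <= 0):
        return IndexStack(
            index.values.copy(), index.valid.copy(), index.kind,
            frame_interval=index.frame_interval, photobleach_corrected=False,
            bleach_warning="non-positive or undefined whole-cell mean; not corrected",
        )
    t = index.times
    try:
        curve, params = _fit_double_exponential(t, m)
    except RuntimeError:
        warnings.warn("photobleach correction skipped: fit did not converge", stacklevel=2)
        return IndexStack(
            index.values.copy(), index.valid.copy(), index.kind,
            frame_interval=index.frame_interval, photobleach_corrected=False,
            bleach_warning="fit non-convergence; returned uncorrected",
        )
    factor = curve / curve[0]
    corrected = index.values / factor[:, None, None]
    return IndexStack(
        corrected, index.valid.copy(), index.kind,
        frame_interval=index.frame_interval, photobleach_corrected=True,
        bleach_params=params,
    )


@dataclass(frozen=True)
class DisplayScale:
    """Rendering bounds for pseudocolour display (never fed into statistics).

    ``lo_raw``/``hi_raw`` are the low/high percentile values of the index;
    ``lo``/``hi`` are the same bounds shifted so the low end maps to 1.
    """

    lo_raw: float
    hi_raw: float
    shift: float
    degenerate: bool = False

    @property
    def lo(self) -> float:
        return self.lo_raw + self.shift

    @property
    def hi(self) -> float:
        return self.hi_raw + self.shift


def display_scale(
    index: IndexStack,
    low_q: float = 0.05,
    high_q: float = 0.95,
    null_index: Optional[IndexStack] = None,
    min_pixels: int = 100,
) -> DisplayScale:
    """Percentile display bounds excluding the extreme tails.

    The lowest/highest ``low_q``/``1 − high_q`` of ratio values are
    discarded as spurious and the scale is shifted so its low end is 1.
    For the GTP sensor the low bound may be taken from a Null-sensor
    stack (``null_index``) while the high bound comes from this stack.
    """
    vals = index.values[index.valid]
    if vals.size < min_pixels:
        raise ValueError(f"need >= {min_pixels} valid pixels, got {vals.size}")
    lo_src = vals if null_index is None else null_index.values[null_index.valid]
    if lo_src.size < min_pixels:
        raise ValueError("null-sensor stack has too few valid pixels")
    lo = float(np.percentile(lo_src, 100 * low_q))
    hi = float(np.percentile(vals, 100 * high_q))
    degenerate = not (hi > lo)
    return DisplayScale(lo_raw=lo, hi_raw=hi, shift=1.0 - lo, degenerate=degenerate)
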