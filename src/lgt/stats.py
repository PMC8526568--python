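"""Correlation and group statistics for dual-biosensor series.

The correlation unit is the frame: one pixel-wise Pearson r between the
RAC1 activity (FRET) index and the GTP index per image, computed over the
jointly valid pixels.  Per-cell records aggregate the frame series
(mean, median, quartiles — the bar-and-whiskers summary); group-level
comparisons of per-cell mean r use the Mann–Whitney test, and the paired /
unpaired two-tailed t-tests serve the cell-body vs cell-protrusion ratio
comparisons.

The Mann–Whitney implementation enumerates the exact conditional (midrank)
distribution for small samples and uses the tie-corrected normal
approximation otherwise; identical samples therefore give p = 1 rather
than an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .indices import IndexStack

__all__ = [
    "CellCorrelationRecord",
    "GroupComparison",
    "framewise_pearson",
    "pearson_series",
    "summarize_cell",
    "mann_whitney",
    "paired_t",
    "unpaired_t",
]

#: frames with fewer jointly valid pixels than this are skipped
DEFAULT_MIN_PIXELS = 100


def framewise_pearson(
    index_a: np.ndarray,
    index_b: np.ndarray,
    valid: Optional[np.ndarray] = None,
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> tuple[float, int]:
    """Pixel-wise Pearson r between two index maps of one frame.

    Returns ``(r, n)`` where n is the number of jointly valid pixels;
    ``r`` is NaN (with a warning) when n < ``min_pixels`` or either map
    has zero variance over the valid pixels.
    """
    a = np.asarray(index_a, dtype=float)
    b = np.asarray(index_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("index maps must share a shape")
    v = np.isfinite(a) & np.isfinite(b)
    if valid is not None:
        v &= np.asarray(valid, dtype=bool)
    n = int(v.sum())
    if n < min_pixels:
        warnings.warn(f"frame skipped: {n} valid pixels < {min_pixels}", stacklevel=2)
        return float("nan"), n
    av, bv = a[v], b[v]
    if av.std() == 0 or bv.std() == 0:
        warnings.warn("frame skipped: zero variance in an index", stacklevel=2)
        return float("nan"), n
    r, _ = sps.pearsonr(av, bv)
    return float(r), n


def pearson_series(
    fret: IndexStack,
    gtp: IndexStack,
    extra_valid: Optional[np.ndarray] = None,
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame Pearson r series between a FRET and a GTP index stack."""
    if fret.values.shape != gtp.values.shape:
        raise ValueError("index stacks must share a shape")
    n_frames = fret.n_frames
    r = np.empty(n_frames)
    n = np.empty(n_frames, dtype=int)
    for t in range(n_frames):
        v = fret.valid[t] & gtp.valid[t]
        if extra_valid is not None:
            v = v & np.asarray(extra_valid[t] if extra_valid.ndim == 3 else extra_valid,
                               dtype=bool)
        r[t], n[t] = framewise_pearson(fret.values[t], gtp.values[t], v, min_pixels)
    return r, n


@dataclass
class CellCorrelationRecord:
    """Per-frame r series for one cell plus its bar-and-whiskers summary."""

    r_values: np.ndarray
    pixel_counts: np.ndarray
    mean: float = field(init=False)
    median: float = field(init=False)
    q1: float = field(init=False)
    q3: float = field(init=False)
    r_min: float = field(init=False)
    r_max: float = field(init=False)
    n_frames_retained: int = field(init=False)
    insufficient: bool = field(init=False)

    def __post_init__(self) -> None:
        self.r_values = np.asarray(self.r_values, dtype=float)
        self.pixel_counts = np.asarray(self.pixel_counts, dtype=int)
        kept = self.r_values[np.isfinite(self.r_values)]
        if kept.size and (np.any(kept < -1) or np.any(kept > 1)):
            raise ValueError("Pearson r values must lie in [-1, 1]")
        self.n_frames_retained = int(kept.size)
        self.insufficient = self.n_frames_retained < 5
        if kept.size:
            self.mean = float(kept.mean())
            self.median = float(np.median(kept))
            self.q1 = float(np.percentile(kept, 25))
            self.q3 = float(np.percentile(kept, 75))
            self.r_min = float(kept.min())
            self.r_max = float(kept.max())
        else:
            self.mean = self.median = self.q1 = self.q3 = float("nan")
            self.r_min = self.r_max = float("nan")


def summarize_cell(
    r_values: Sequence[float], pixel_counts: Optional[Sequence[int]] = None
) -> CellCorrelationRecord:
    """Bar-and-whiskers summary (mean, median, quartiles) of a frame series.

    Frames skipped upstream appear as NaN and are excluded; a record with
    fewer than 5 retained frames is flagged ``insufficient``.
    """
    r_values = np.asarray(r_values, dtype=float)
    if pixel_counts is None:
        pixel_counts = np.zeros(r_values.shape, dtype=int)
    rec = CellCorrelationRecord(r_values=r_values, pixel_counts=np.asarray(pixel_counts))
    if rec.insufficient:
        warnings.warn(
            f"only {rec.n_frames_retained} retained frames; record flagged insufficient",
            stacklevel=2,
        )
    return rec


@dataclass
class GroupComparison:
    """Outcome of a two-group test on per-cell summary values."""

    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    group_labels: tuple[str, str] = ("a", "b")
    degenerate: bool = False
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.degenerate and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


def _mw_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact conditional Mann–Whitney with midranks.

    Enumerates all assignments of the pooled midranks to group A and
    compares the observed U against that permutation distribution;
    two-sided p = 2·min(P(U ≤ u), P(U ≥ u)), capped at 1.
    """
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    n_low = n_high = total = 0
    for idx in combinations(range(na + nb), na):
        u = ranks[list(idx)].sum() - na * (na + 1) / 2
        total += 1
        if u <= u_obs + 1e-12:
            n_low += 1
        if u >= u_obs - 1e-12:
            n_high += 1
    p = min(1.0, 2.0 * min(n_low, n_high) / total)
    return float(u_obs), p


def _mw_normal(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """Tie-corrected normal approximation with continuity correction."""
    na, nb = len(a), len(b)
    n = na + nb
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u = ranks[:na].sum() - na * (na + 1) / 2
    mean = na * nb / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return float(u), 1.0, True
    z = (u - mean - 0.5 * np.sign(u - mean)) / np.sqrt(var)
    return float(u), float(2.0 * sps.norm.sf(abs(z))), False


def mann_whitney(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    exact_max: int = 8,
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided Mann–Whitney U comparison of two independent samples.

    Exact midrank enumeration when both samples have at most ``exact_max``
    observations, tie-corrected normal approximation (with continuity
    correction) otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    if a.size <= exact_max and b.size <= exact_max:
        u, p = _mw_exact(a, b)
        method, degenerate = "exact", False
    else:
        u, p, degenerate = _mw_normal(a, b)
        method = "normal_tie_corrected"
    return GroupComparison(
        test="mann_whitney", statistic=u, p_value=p, n_a=a.size, n_b=b.size,
        group_labels=labels, degenerate=degenerate, detail={"method": method},
    )


def paired_t(
    cb_values: Sequence[float],
    cp_values: Sequence[float],
    labels: tuple[str, str] = ("cb", "cp"),
) -> GroupComparison:
    """Two-tailed paired Student's t-test on matched samples.

    Zero-variance differences (e.g. identical pairs) make t undefined;
    the comparison is then returned flagged ``degenerate`` with NaN p.
    """
    a = np.asarray(cb_values, dtype=float)
    b = np.asarray(cp_values, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = b - a
    if np.std(d, ddof=1) == 0:
        return GroupComparison(
            test="paired_t", statistic=float("nan"), p_value=float("nan"),
            n_a=a.size, n_b=b.size, group_labels=labels, degenerate=True,
            detail={"reason": "zero variance of differences"},
        )
    res = sps.ttest_rel(b, a)
    return GroupComparison(
        test="paired_t", statistic=float(res.statistic), p_value=float(res.pvalue),
        n_a=a.size, n_b=b.size, group_labels=labels,
        detail={"df": a.size - 1, "mean_difference": float(d.mean())},
    )


def unpaired_t(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
    equal_var: bool = False,
) -> GroupComparison:
    """Two-tailed unpaired t-test (Welch's unequal-variance form by default)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        return GroupComparison(
            test="unpaired_t", statistic=float("nan"), p_value=float("nan"),
            n_a=a.size, n_b=b.size, group_labels=labels, degenerate=True,
            detail={"reason": "zero variance in both samples"},
        )
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        test="unpaired_t", statistic=float(res.statistic), p_value=float(res.pvalue),
        n_a=a.size, n_b=b.size, group_labels=labels,
        detail={"welch": not equal_var},
    )
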