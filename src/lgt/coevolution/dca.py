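"""Direct-coupling analysis of a concatenated two-protein alignment.

Couplings between alignment columns are estimated either by the mean-field
approximation (inverse of the pseudocount-regularized pairwise frequency
covariance matrix) or by pseudolikelihood maximization.  Per column pair
the coupling strength is the Frobenius norm of the 20×20 amino-acid
coupling submatrix (gap state excluded) in the zero-sum gauge, with the
average-product correction (APC) removing background conservation and
phylogenetic signal.  Only the inter-protein block of the score matrix is
reported; a 2-D Gaussian convolution of that block pools evidence from
neighbouring residue pairs into interface-level signal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.special import logsumexp

from .msa import N_STATES, ConcatenatedMSA

__all__ = [
    "CouplingMap",
    "sequence_weights",
    "compute_couplings",
    "gaussian_convolve",
    "top_fraction_threshold",
    "top_pairs",
    "precision_at_k",
]

_Q = N_STATES  # 21 states, gap = 0


@dataclass
class CouplingMap:
    """Inter-protein coupling scores (raw, and convolved when computed).

    ``raw[r, c]`` couples protein-A column ``cols_a[r]`` with protein-B
    column ``cols_b[c]`` (original alignment positions; columns dropped by
    the gap filter are absent).
    """

    raw: np.ndarray
    cols_a: np.ndarray
    cols_b: np.ndarray
    method: str
    convolved: Optional[np.ndarray] = None
    sigma: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if not np.all(np.isfinite(self.raw)):
            raise ValueError("coupling scores must be finite")
        if self.raw.shape != (len(self.cols_a), len(self.cols_b)):
            raise ValueError("score block shape does not match column index arrays")
        if self.convolved is not None and self.convolved.shape != self.raw.shape:
            raise ValueError("convolved map must match the raw block shape")

    @property
    def scores(self) -> np.ndarray:
        """Convolved scores when available, raw otherwise."""
        return self.raw if self.convolved is None else self.convolved


def sequence_weights(matrix: np.ndarray, identity_threshold: float = 0.8) -> np.ndarray:
    """Inverse-neighbourhood sequence weights.

    A sequence's weight is 1 over the number of alignment rows (itself
    included) with fractional identity >= ``identity_threshold`` to it.
    """
    m = np.asarray(matrix)
    n, length = m.shape
    counts = np.zeros(n, dtype=np.int64)
    chunk = max(1, int(2e7) // max(1, n * length))
    for start in range(0, n, chunk):
        block = m[start : start + chunk]  # (c, L)
        ident = (block[:, None, :] == m[None, :, :]).mean(axis=2)
        counts[start : start + chunk] = (ident >= identity_threshold).sum(axis=1)
    return 1.0 / counts


def _weighted_frequencies(
    m: np.ndarray, w: np.ndarray, pseudocount: float
) -> tuple[np.ndarray, np.ndarray]:
    """Single- and pairwise weighted state frequencies with pseudocount.

    ``fi`` is (L, q); ``fij`` is (L, q, L, q).  The pseudocount mixes the
    empirical frequencies with the uniform distribution:
    ``f = (1 − pc)·f_data + pc/q`` (and ``pc/q²`` pairwise).
    """
    n, length = m.shape
    x = np.zeros((n, length, _Q))
    x[np.arange(n)[:, None], np.arange(length)[None, :], m] = 1.0
    xf = x.reshape(n, length * _Q)
    wsum = w.sum()
    fi = (w[:, None, None] * x).sum(axis=0) / wsum  # (L, q)
    fij = (xf.T * w) @ xf / wsum  # (L*q, L*q)
    fij = fij.reshape(length, _Q, length, _Q)
    pc = pseudocount
    fi = (1 - pc) * fi + pc / _Q
    fij = (1 - pc) * fij + pc / (_Q * _Q)
    # the diagonal blocks must stay consistent with fi
    for i in range(length):
        fij[i, :, i, :] = np.diag(fi[i])
    return fi, fij


def _zero_sum_gauge(j: np.ndarray) -> np.ndarray:
    """Shift a (…, s, s) coupling block into the zero-sum gauge."""
    row = j.mean(axis=-1, keepdims=True)
    col = j.mean(axis=-2, keepdims=True)
    tot = j.mean(axis=(-2, -1), keepdims=True)
    return j - row - col + tot


def _frobenius_apc(j4: np.ndarray) -> np.ndarray:
    """Zero-sum gauge → Frobenius norm over non-gap states → APC.

    ``j4`` is (L, L, q, q); the returned score matrix is (L, L) with zero
    diagonal.  APC uses off-diagonal row/column means over the full map.
    """
    length = j4.shape[0]
    jg = _zero_sum_gauge(j4[:, :, 1:, 1:])  # drop the gap state
    fn = np.sqrt((jg**2).sum(axis=(-2, -1)))
    np.fill_diagonal(fn, 0.0)
    off = ~np.eye(length, dtype=bool)
    row_mean = (fn * off).sum(axis=1) / (length - 1)
    total_mean = (fn * off).sum() / (length * (length - 1))
    if total_mean > 0:
        apc = np.outer(row_mean, row_mean) / total_mean
        fn = fn - apc
    np.fill_diagonal(fn, 0.0)
    return fn


def _mean_field_couplings(m: np.ndarray, w: np.ndarray, pseudocount: float) -> np.ndarray:
    """Couplings from the inverse covariance matrix (non-gap states)."""
    n, length = m.shape
    fi, fij = _weighted_frequencies(m, w, pseudocount)
    s = _Q - 1  # non-gap states, gap is the reference
    c = (
        fij[:, 1:, :, 1:]
        - fi[:, 1:, None, None] * fi[None, None, :, 1:]
    )  # (L, s, L, s)
    cmat = c.transpose(0, 1, 2, 3).reshape(length * s, length * s)
    try:
        inv = np.linalg.inv(cmat)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance; increasing pseudocount to 0.7", stacklevel=3)
        fi, fij = _weighted_frequencies(m, w, max(pseudocount, 0.7))
        c = fij[:, 1:, :, 1:] - fi[:, 1:, None, None] * fi[None, None, :, 1:]
        inv = np.linalg.inv(c.reshape(length * s, length * s))
    j = -inv.reshape(length, s, length, s).transpose(0, 2, 1, 3)  # (L, L, s, s)
    j4 = np.zeros((length, length, _Q, _Q))
    j4[:, :, 1:, 1:] = j
    return j4


def _plm_couplings(
    m: np.ndarray, w: np.ndarray, l2: float = 0.01, maxiter: int = 100
) -> np.ndarray:
    """Pseudolikelihood-maximization couplings (conjugate-gradient).

    Each column's conditional distribution given the rest of the row is a
    softmax regression fitted by nonlinear conjugate gradient with an L2
    penalty; site-pair couplings are averaged over the two conditionals.
    """
    n, length = m.shape
    x = np.zeros((n, length, _Q))
    x[np.arange(n)[:, None], np.arange(length)[None, :], m] = 1.0
    xf = x.reshape(n, length * _Q)
    wn = w / w.sum()
    j_dir = np.zeros((length, length, _Q, _Q))

    for r in range(length):
        y = m[:, r]
        xr = xf.copy()
        xr[:, r * _Q : (r + 1) * _Q] = 0.0  # exclude the site itself

        def negloglik(theta: np.ndarray):
            h = theta[:_Q]
            jr = theta[_Q:].reshape(_Q, length * _Q)
            logits = h[None, :] + xr @ jr.T  # (n, q)
            lse = logsumexp(logits, axis=1)
            nll = -(wn * (logits[np.arange(n), y] - lse)).sum()
            p = np.exp(logits - lse[:, None])
            resid = p.copy()
            resid[np.arange(n), y] -= 1.0
            resid *= wn[:, None]
            grad_h = resid.sum(axis=0)
            grad_j = resid.T @ xr + 2.0 * l2 * jr
            nll += l2 * (jr**2).sum()
            return nll, np.concatenate([grad_h, grad_j.ravel()])

        theta0 = np.zeros(_Q + _Q * length * _Q)
        res = minimize(negloglik, theta0, jac=True, method="CG",
                       options={"maxiter": maxiter})
        jr = res.x[_Q:].reshape(_Q, length, _Q)
        j_dir[r] = jr.transpose(1, 0, 2)  # (L, q_r, q_j) -> [j, a_r, a_j]

    j4 = 0.5 * (j_dir + j_dir.transpose(1, 0, 3, 2))
    for i in range(length):
        j4[i, i] = 0.0
    return j4


def compute_couplings(
    cmsa: ConcatenatedMSA,
    method: str = "mean_field",
    *,
    pseudocount: float = 0.5,
    reweight_identity: float = 0.8,
    max_gap_fraction: float = 0.5,
    plm_l2: float = 0.01,
) -> CouplingMap:
    """Raw inter-protein coupling scores for a concatenated alignment.

    Columns with more than ``max_gap_fraction`` (weighted) gaps are
    removed before estimation and reported via ``cols_a``/``cols_b``.
    Scores are Frobenius norms of the non-gap coupling blocks with APC.
    """
    if method not in ("mean_field", "pseudolikelihood"):
        raise ValueError(f"unknown method {method!r}")
    m = cmsa.matrix
    if cmsa.n_rows < 50:
        warnings.warn(
            f"only {cmsa.n_rows} rows; coupling estimates will be noisy", stacklevel=2
        )
    w = sequence_weights(m, reweight_identity)
    gap_frac = (w[:, None] * (m == 0)).sum(axis=0) / w.sum()
    keep = gap_frac <= max_gap_fraction
    if not keep.all():
        warnings.warn(f"removed {int((~keep).sum())} gap-rich columns", stacklevel=2)
    kept_idx = np.flatnonzero(keep)
    mk = m[:, keep]
    if method == "mean_field":
        j4 = _mean_field_couplings(mk, w, pseudocount)
    else:
        j4 = _plm_couplings(mk, w, l2=plm_l2)
    scores = _frobenius_apc(j4)

    in_a = kept_idx < cmsa.boundary
    rows = np.flatnonzero(in_a)
    cols = np.flatnonzero(~in_a)
    inter = scores[np.ix_(rows, cols)]
    return CouplingMap(
        raw=inter,
        cols_a=kept_idx[in_a],
        cols_b=kept_idx[~in_a] - cmsa.boundary,
        method=method,
        meta={
            "pseudocount": pseudocount,
            "reweight_identity": reweight_identity,
            "n_rows": cmsa.n_rows,
            "m_eff": float(w.sum()),
            "removed_columns": int((~keep).sum()),
        },
    )


def gaussian_convolve(coupling_map: CouplingMap, sigma: float = 2.0) -> CouplingMap:
    """Gaussian-smooth the inter-protein block (reflective boundary).

    Pools coupling evidence from neighbouring residue pairs, suppressing
    isolated false positives while reinforcing contiguous interface
    patches.  ``sigma`` is in alignment columns.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    conv = ndimage.gaussian_filter(coupling_map.raw, sigma, mode="reflect")
    return CouplingMap(
        raw=coupling_map.raw,
        cols_a=coupling_map.cols_a,
        cols_b=coupling_map.cols_b,
        method=coupling_map.method,
        convolved=conv,
        sigma=sigma,
        meta=dict(coupling_map.meta),
    )


def top_fraction_threshold(scores: np.ndarray, fraction: float = 0.05) -> float:
    """Minimum score of the top ``fraction`` of all scores.

    With N scores the top set holds ``ceil(fraction · N)`` values; the
    threshold is the smallest of them (ties at the boundary share it).
    """
    flat = np.asarray(scores, dtype=float).ravel()
    if flat.size < 20:
        raise ValueError(f"need at least 20 scores, got {flat.size}")
    m = math.ceil(fraction * flat.size)
    if m < 1:
        raise ValueError("fraction too small: the top set would be empty")
    return float(np.partition(flat, -m)[-m])


def top_pairs(
    coupling_map: CouplingMap,
    k: int,
    min_separation: int = 0,
    use_convolved: bool = True,
) -> list[tuple[int, int]]:
    """Top-k predicted contacts (original column indices, A then B).

    Cells are taken in decreasing score order; with ``min_separation`` > 0
    a greedy non-maximum suppression skips cells within that Chebyshev
    distance of an already selected one — appropriate for convolved maps,
    where one interface patch spans many neighbouring cells.
    """
    mat = coupling_map.scores if use_convolved else coupling_map.raw
    order = np.argsort(mat, axis=None)[::-1]
    picked: list[tuple[int, int]] = []
    picked_rc: list[tuple[int, int]] = []
    for flat in order:
        r, c = divmod(int(flat), mat.shape[1])
        if min_separation > 0 and any(
            max(abs(r - pr), abs(c - pc)) < min_separation for pr, pc in picked_rc
        ):
            continue
        picked_rc.append((r, c))
        picked.append((int(coupling_map.cols_a[r]), int(coupling_map.cols_b[c])))
        if len(picked) == k:
            break
    return picked


def precision_at_k(
    predicted: Sequence[tuple[int, int]],
    true_pairs: Sequence[tuple[int, int]],
    tol: int = 0,
) -> float:
    """Fraction of predicted pairs within Chebyshev distance ``tol`` of truth."""
    if not predicted:
        return 0.0
    hits = 0
    for pi, pj in predicted:
        if any(max(abs(pi - ti), abs(pj - tj)) <= tol for ti, tj in true_pairs):
            hits += 1
    return hits / len(predicted)
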