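"""Species-shuffle randomization test for interface significance.

Randomly reassigning one protein's orthologs to species destroys the
shared phylogeny and hence any genuine inter-protein coevolution, while
preserving both alignments' column statistics.  Repeating the full
coupling + convolution computation on many such shuffles yields a null
distribution for the inter-protein signal; the p-value is the fraction of
replicates whose exceedance statistic clears the threshold set by the top
fraction of the original signal (p = exceedances / replicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dca import compute_couplings, gaussian_convolve, top_fraction_threshold
from .msa import ConcatenatedMSA, OrthologSet, concat_by_species

__all__ = ["RandomizationOutcome", "randomization_test", "outcome_from_counts"]

_STATISTICS = ("max", "count", "top_fraction_min")


@dataclass
class RandomizationOutcome:
    """Result of the species-shuffle randomization test.

    ``p_value`` follows the plain k/N counting convention; the
    add-one estimate (k+1)/(N+1) is reported alongside as
    ``p_value_add_one``.
    """

    n_replicates: int
    threshold: float
    statistic: str
    replicate_values: np.ndarray
    exceed_count: int
    original_value: float = float("nan")
    seed: int | None = None
    p_value: float = field(init=False)
    p_value_add_one: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")
        if not 0 <= self.exceed_count <= self.n_replicates:
            raise ValueError("exceed_count out of range")
        if self.statistic not in _STATISTICS:
            raise ValueError(f"statistic must be one of {_STATISTICS}")
        self.replicate_values = np.asarray(self.replicate_values, dtype=float)
        self.p_value = self.exceed_count / self.n_replicates
        self.p_value_add_one = (self.exceed_count + 1) / (self.n_replicates + 1)


def outcome_from_counts(
    exceed_count: int, n_replicates: int, threshold: float = float("nan"),
    statistic: str = "max",
) -> RandomizationOutcome:
    """Construct an outcome from counts alone (e.g. 3 of 100 → p = 0.03)."""
    return RandomizationOutcome(
        n_replicates=n_replicates,
        threshold=threshold,
        statistic=statistic,
        replicate_values=np.full(n_replicates, np.nan),
        exceed_count=exceed_count,
    )


def _evaluate(conv_scores: np.ndarray, threshold: float, statistic: str,
              fraction: float) -> tuple[float, bool]:
    """Replicate exceedance value and verdict under the chosen statistic."""
    if statistic == "max":
        v = float(conv_scores.max())
        return v, v > threshold
    if statistic == "count":
        n_above = int((conv_scores > threshold).sum())
        top_set = int(np.ceil(fraction * conv_scores.size))
        return float(n_above), n_above >= top_set
    if statistic == "top_fraction_min":
        v = top_fraction_threshold(conv_scores, fraction)
        return v, v > threshold
    raise ValueError(statistic)


def randomization_test(
    set_a: OrthologSet,
    set_b: OrthologSet,
    n_replicates: int = 100,
    sigma: float = 2.0,
    fraction: float = 0.05,
    seed: int = 0,
    *,
    statistic: str = "max",
    method: str = "mean_field",
    **coupling_kwargs,
) -> RandomizationOutcome:
    """Species-shuffle significance test of the inter-protein signal.

    The threshold is the minimum of the top ``fraction`` of the original
    convolved inter-protein scores.  For each replicate, protein-A
    sequences are randomly reassigned to species (protein B untouched),
    the cMSA rebuilt and the couplings and convolution recomputed; the
    replicate counts as an exceedance according to ``statistic``:

    * ``"max"`` (default): its convolved maximum exceeds the threshold;
    * ``"count"``: at least as many cells exceed the threshold as the
      size of the original top set;
    * ``"top_fraction_min"``: the minimum of its own top-``fraction`` set
      exceeds the threshold.
    """
    if n_replicates < 1:
        raise ValueError("need at least 1 replicate")
    rng = np.random.default_rng(seed)
    original = gaussian_convolve(
        compute_couplings(concat_by_species(set_a, set_b), method, **coupling_kwargs),
        sigma,
    )
    threshold = top_fraction_threshold(original.scores, fraction)
    original_value, _ = _evaluate(original.scores, threshold, statistic, fraction)

    values = np.empty(n_replicates)
    exceed = 0
    for rep in range(n_replicates):
        shuffled = set_a.reassigned(rng)
        conv = gaussian_convolve(
            compute_couplings(concat_by_species(shuffled, set_b), method,
                              **coupling_kwargs),
            sigma,
        )
        values[rep], hit = _evaluate(conv.scores, threshold, statistic, fraction)
        exceed += int(hit)
    return RandomizationOutcome(
        n_replicates=n_replicates,
        threshold=threshold,
        statistic=statistic,
        replicate_values=values,
        exceed_count=exceed,
        original_value=original_value,
        seed=seed,
    )
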