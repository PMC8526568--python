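"""End-to-end pipeline runners for the imaging and coevolution arms.

The imaging runner executes the correction chain in its fixed order
(dark → shading → registration → background → segmentation → validity →
indices → photobleach → correlation → summary) on one or many cells and
compares groups of per-cell mean correlations.  The coevolution runner
wires alignment concatenation, coupling estimation, convolution and the
species-shuffle randomization test.  Every stage appends to a stage log
recorded in the run manifest, and all randomness flows from a single seed.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .indices import IndexStack, compute_fret_index, compute_gtp_index, \
    estimate_bleedthrough, photobleach_correct
from .preprocess import (
    apply_affine,
    background_range_mask,
    estimate_affine_from_fiducials,
    segment_cells,
    shading_correct,
    subtract_background,
    subtract_dark,
)
from .sensors import GEVAL30, GEVAL_NULL
from .stack import CorrectionBundle, MaskStack, RawStack
from .stats import (
    CellCorrelationRecord,
    GroupComparison,
    mann_whitney,
    paired_t,
    pearson_series,
    summarize_cell,
    unpaired_t,
)
from .synthetic import SceneConfig, generate_cbcp_dataset, simulate_scene

__all__ = [
    "CorrectionToggles",
    "CellAnalysis",
    "analyze_cell",
    "ImagingRunConfig",
    "ImagingRunResult",
    "run_imaging_pipeline",
    "CoevolutionRunConfig",
    "run_coevolution_pipeline",
    "cbcp_quantification",
    "derive_seed",
]

#: canonical correction order; the runner asserts this sequence
STAGE_ORDER = (
    "dark", "shading", "registration", "background", "segmentation",
    "validity", "indices", "photobleach", "correlation", "summary",
)


def derive_seed(base: int, index: int) -> int:
    """Deterministic per-cell seed below 2**31."""
    return (base * 100_003 + 17 * index + 1) % (2**31 - 1)


@dataclass(frozen=True)
class CorrectionToggles:
    """On/off switches for each correction stage (all on by default)."""

    dark: bool = True
    shading: bool = True
    registration: bool = True
    background: bool = True
    bleedthrough: bool = True
    photobleach: bool = True

    def all_off(self) -> "CorrectionToggles":
        return CorrectionToggles(False, False, False, False, False, False)


@dataclass
class CellAnalysis:
    """Everything the imaging pipeline produced for one cell."""

    record: CellCorrelationRecord
    fret_index: IndexStack
    gtp_index: IndexStack
    masks: MaskStack
    alpha: float
    beta: float
    stage_log: list[str]
    r_series: np.ndarray
    pixel_counts: np.ndarray


def _preprocess_control(ctrl: RawStack, bundle: CorrectionBundle,
                        toggles: CorrectionToggles) -> RawStack:
    out = ctrl
    if toggles.dark:
        out = subtract_dark(out, bundle)
    if toggles.shading:
        out = shading_correct(out, bundle)
    if toggles.background and bundle.background is not None:
        out, _, _ = subtract_background(out, bundle.background)
    return out


def analyze_cell(
    stack: RawStack,
    bundle: CorrectionBundle,
    *,
    toggles: CorrectionToggles = CorrectionToggles(),
    min_pixels: int = 100,
    background_k: float = 2.0,
    stage_log: Optional[list[str]] = None,
) -> CellAnalysis:
    """Run the full correction + index + correlation chain on one cell.

    Stages run in the canonical order; disabled stages are skipped but the
    order of the executed ones is preserved (and asserted).
    """
    log: list[str] = [] if stage_log is None else stage_log
    levels = sds = None

    if toggles.dark:
        stack = subtract_dark(stack, bundle)
        log.append("dark")
    if toggles.shading:
        stack = shading_correct(stack, bundle)
        log.append("shading")
    reg_valid = np.ones(stack.frame_shape, dtype=bool)
    if toggles.registration and bundle.fiducials_src is not None:
        transform = estimate_affine_from_fiducials(
            bundle.fiducials_src, bundle.fiducials_dst
        )
        stack, reg_valid = apply_affine(stack, transform, ("ex409", "ex494"))
        log.append("registration")
    if toggles.background:
        if bundle.background is None:
            raise ValueError("background correction enabled but no region in bundle")
        stack, levels, sds = subtract_background(stack, bundle.background)
        log.append("background")

    masks = segment_cells(stack, "donor")
    log.append("segmentation")

    validity = masks.masks & reg_valid[None]
    if toggles.background and sds is not None:
        validity &= background_range_mask(
            stack, np.zeros_like(levels), sds, k=background_k
        )
    log.append("validity")

    alpha = beta = 0.0
    if toggles.bleedthrough:
        if bundle.alpha is not None and bundle.beta is not None:
            alpha, beta = bundle.alpha, bundle.beta
        elif bundle.donor_only is not None and bundle.acceptor_only is not None:
            alpha, beta = estimate_bleedthrough(
                _preprocess_control(bundle.donor_only, bundle, toggles),
                _preprocess_control(bundle.acceptor_only, bundle, toggles),
            )
        else:
            raise ValueError(
                "bleed-through correction enabled but bundle has neither "
                "coefficients nor control stacks"
            )

    fret = compute_fret_index(
        stack.channel("fret"), stack.channel("donor"), stack.channel("acceptor"),
        alpha, beta, validity, frame_interval=stack.frame_interval,
    )
    gtp = compute_gtp_index(
        stack.channel("ex409"), stack.channel("ex494"), validity,
        frame_interval=stack.frame_interval,
    )
    log.append("indices")

    if toggles.photobleach:
        fret = photobleach_correct(fret, masks)
        gtp = photobleach_correct(gtp, masks)
        log.append("photobleach")

    r, n = pearson_series(fret, gtp, min_pixels=min_pixels)
    log.append("correlation")
    record = summarize_cell(r, n)
    log.append("summary")

    executed = [s for s in STAGE_ORDER if s in log]
    if log != executed:
        raise RuntimeError(f"stage order violated: {log}")
    return CellAnalysis(
        record=record, fret_index=fret, gtp_index=gtp, masks=masks,
        alpha=alpha, beta=beta, stage_log=log, r_series=r, pixel_counts=n,
    )


_SENSORS = {"geval30": GEVAL30, "null": GEVAL_NULL}


@dataclass
class ImagingRunConfig:
    """Configuration of a multi-cell synthetic imaging run."""

    n_cells: int = 10
    scene: SceneConfig = field(default_factory=SceneConfig)
    sensor: str = "geval30"  # "geval30" | "null"
    toggles: CorrectionToggles = field(default_factory=CorrectionToggles)
    min_pixels: int = 100
    background_k: float = 2.0
    seed: int = 0


@dataclass
class ImagingRunResult:
    """Per-cell correlation records of one group plus run metadata."""

    records: list[CellCorrelationRecord]
    analyses: list[CellAnalysis]
    config: ImagingRunConfig
    manifest: dict

    @property
    def mean_r_per_cell(self) -> np.ndarray:
        return np.array([rec.mean for rec in self.records])

    @property
    def grand_mean_r(self) -> float:
        return float(np.nanmean(self.mean_r_per_cell))


def run_imaging_pipeline(
    config: ImagingRunConfig, keep_analyses: bool = False
) -> ImagingRunResult:
    """Simulate and analyze ``n_cells`` scenes under one sensor/condition."""
    if config.sensor not in _SENSORS:
        raise ValueError(f"sensor must be one of {sorted(_SENSORS)}")
    sensor = _SENSORS[config.sensor]
    records, analyses, logs = [], [], []
    t0 = time.time()
    for i in range(config.n_cells):
        scene = replace(config.scene, seed=derive_seed(config.seed, i))
        stack, bundle, _ = simulate_scene(scene, sensor)
        ana = analyze_cell(
            stack, bundle, toggles=config.toggles,
            min_pixels=config.min_pixels, background_k=config.background_k,
        )
        records.append(ana.record)
        logs.append(ana.stage_log)
        if keep_analyses:
            analyses.append(ana)
    manifest = {
        "arm": "imaging",
        "version": __version__,
        "seed": config.seed,
        "sensor": config.sensor,
        "n_cells": config.n_cells,
        "toggles": asdict(config.toggles),
        "min_pixels": config.min_pixels,
        "background_k": config.background_k,
        "stage_logs": logs,
        "elapsed_s": round(time.time() - t0, 3),
    }
    return ImagingRunResult(records=records, analyses=analyses, config=config,
                            manifest=manifest)


def compare_sensor_groups(
    result_a: ImagingRunResult, result_b: ImagingRunResult,
    labels: tuple[str, str] = ("geval30", "null"),
) -> GroupComparison:
    """Mann–Whitney comparison of per-cell mean correlations of two groups."""
    return mann_whitney(result_a.mean_r_per_cell, result_b.mean_r_per_cell,
                        labels=labels)


def cbcp_quantification(
    table: Optional[pd.DataFrame] = None,
    test: str = "paired",
    *,
    n_cells: int = 30,
    offset: float = 0.15,
    seed: int = 0,
) -> GroupComparison:
    """Compare sensor ratios between cell bodies (CB) and protrusions (CP).

    ``table`` needs ``cb`` and ``cp`` columns (one row per cell); when
    omitted, a synthetic paired table is generated.  ``test`` selects the
    two-tailed paired or unpaired (Welch) t-test.
    """
    if table is None:
        table = generate_cbcp_dataset(n_cells=n_cells, offset=offset, seed=seed)
    if not {"cb", "cp"} <= set(table.columns):
        raise ValueError("table must have 'cb' and 'cp' columns")
    cb = table["cb"].to_numpy(dtype=float)
    cp = table["cp"].to_numpy(dtype=float)
    if test == "paired":
        if np.any(~np.isfinite(cb)) or np.any(~np.isfinite(cp)):
            raise ValueError("paired test requires complete pairs")
        return paired_t(cb, cp, labels=("cb", "cp"))
    if test == "unpaired":
        return unpaired_t(cb[np.isfinite(cb)], cp[np.isfinite(cp)], labels=("cb", "cp"))
    raise ValueError("test must be 'paired' or 'unpaired'")


@dataclass
class CoevolutionRunConfig:
    """Configuration of a simulate-and-test coevolution run."""

    len_a: int = 60
    len_b: int = 60
    n_species: int = 500
    planted_pairs: int = 5
    coupling_strength: float = 0.9
    mutation_rate: float = 0.2
    method: str = "mean_field"
    sigma: float = 2.0
    fraction: float = 0.05
    n_replicates: int = 100
    statistic: str = "max"
    seed: int = 0


def run_coevolution_pipeline(config: CoevolutionRunConfig):
    """Simulate coevolving ortholog sets, score couplings, run the test.

    Returns ``(coupling_map, outcome, truth)`` — the convolved coupling
    map of the original alignment, the randomization outcome, and the
    generator's planted-pair ground truth.
    """
    from .coevolution import (
        compute_couplings, concat_by_species, gaussian_convolve,
        generate_coevolving_msa, randomization_test,
    )

    set_a, set_b, truth = generate_coevolving_msa(
        config.len_a, config.len_b, config.n_species, config.planted_pairs,
        config.coupling_strength, config.mutation_rate, config.seed,
    )
    cmap = gaussian_convolve(
        compute_couplings(concat_by_species(set_a, set_b), config.method),
        config.sigma,
    )
    outcome = randomization_test(
        set_a, set_b, n_replicates=config.n_replicates, sigma=config.sigma,
        fraction=config.fraction, seed=config.seed, statistic=config.statistic,
        method=config.method,
    )
    return cmap, outcome, truth
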