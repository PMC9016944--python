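"""Simulation studies over the full pipeline.

These drive generate -> binarize -> test end-to-end, repeatedly, to measure
the operating characteristics of the association layer: raw type-I error on
null cohorts, and recovery of a planted state effect. They are used by the
calibration tests and the acceptance script; cohort sizes are arguments, so
callers choose the scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .assoc import associate_all
from .presence import binarize_by_participant
from .synth import CohortConfig, generate_cohort, independent_genus_pool


@dataclass
class NullCalibration:
    n_cohorts: int
    n_tests: int
    type_one_error: float  # fraction of raw p < alpha
    alpha: float
    p_values: np.ndarray


def null_cohort_config(
    n_per_state: int = 60,
    n_genes: int = 20,
    mean_mags: float = 3.0,
    seed: int = 0,
) -> CohortConfig:
    """A null cohort: no state effects, independent per-MAG carriage.

    Per-gene carriage probabilities are spread over [0.08, 0.35] so that
    participant-level carriage stays away from 0 and 1 and expected
    contingency cells stay moderate.
    """
    genes = [f"gene{i:02d}" for i in range(n_genes)]
    probs = {g: 0.08 + 0.27 * i / max(n_genes - 1, 1) for i, g in enumerate(genes)}
    from .synth import MagCountDistribution

    return CohortConfig(
        n_per_state={"healthy": n_per_state, "adenoma": n_per_state, "carcinoma": n_per_state},
        mags_per_participant=MagCountDistribution("negative_binomial", mean_mags, 4.0),
        genus_pool=independent_genus_pool(genes, probs),
        effects={},
        seed=seed,
    )


def run_null_calibration(
    n_cohorts: int = 2000,
    alpha: float = 0.05,
    n_per_state: int = 60,
    n_genes: int = 20,
    seed: int = 0,
) -> NullCalibration:
    """Raw type-I error of the state chi-squared test over null cohorts."""
    base = null_cohort_config(n_per_state=n_per_state, n_genes=n_genes, seed=seed)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_cohorts)
    p_values = []
    genes = base.genes
    for s in seeds:
        cohort = generate_cohort(replace(base, seed=int(s)))
        profiles = binarize_by_participant(cohort.matrix, cohort.records)
        results = associate_all(profiles, genes)
        p_values.extend(r.p_raw for r in results if not r.degenerate)
    p = np.asarray(p_values)
    return NullCalibration(
        n_cohorts=n_cohorts,
        n_tests=len(p),
        type_one_error=float((p < alpha).mean()),
        alpha=alpha,
        p_values=p,
    )


@dataclass
class PlantedRecovery:
    n_runs: int
    recovery_rate: float  # planted gene attains min p_adj with correct direction
    direction_rate: float  # correct direction among all runs


def planted_cohort_config(
    n_per_state: int = 200,
    n_genes: int = 10,
    odds: float = 3.0,
    target_state: str = "carcinoma",
    seed: int = 0,
) -> CohortConfig:
    """One gene gets carriage odds scaled in ``target_state``; rest are null."""
    base = null_cohort_config(n_per_state=n_per_state, n_genes=n_genes, seed=seed)
    planted = base.genes[0]
    return replace(base, effects={planted: {target_state: odds}})


def run_planted_recovery(
    n_runs: int = 200,
    n_per_state: int = 200,
    odds: float = 3.0,
    target_state: str = "carcinoma",
    seed: int = 0,
) -> PlantedRecovery:
    """How often the planted gene attains the minimum adjusted p-value with
    the correct direction, over independent cohort draws."""
    base = planted_cohort_config(
        n_per_state=n_per_state, odds=odds, target_state=target_state, seed=seed
    )
    planted = base.genes[0]
    rng = np.random.default_rng(seed + 1)
    seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    hits = 0
    direction_hits = 0
    for s in seeds:
        cohort = generate_cohort(replace(base, seed=int(s)))
        profiles = binarize_by_participant(cohort.matrix, cohort.records)
        results = associate_all(profiles, base.genes)
        by_gene = {r.feature: r for r in results}
        target = by_gene[planted]
        min_p_adj = min(r.p_adj for r in results)
        correct_direction = target.direction == target_state
        if correct_direction:
            direction_hits += 1
        if target.p_adj == min_p_adj and correct_direction:
            hits += 1
    return PlantedRecovery(
        n_runs=n_runs,
        recovery_rate=hits / n_runs,
        direction_rate=direction_hits / n_runs,
    )
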