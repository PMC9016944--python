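"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes: participants with a
disease state (and, for carcinoma, a stage), each contributing a set of MAGs;
each MAG drawn from a genus pool; gene carriage sampled per MAG from its genus
profile, with optional disease-state effects applied on the odds scale so that
the logistic alternative of the stage trend test is literally realizable.
Outputs are written in the pipeline's own input formats (metadata TSV,
presence-table TSV, hmmsearch tblout), so the generator doubles as the
fixture factory for round-trip tests.

Default sizes mirror the published cohort scale: 265/112/290 participants per
state and a negative-binomial MAG count with mean ~25.4 per participant
(16,936 MAGs over 667 participants). Simulation studies use reduced sizes.

What the generator does NOT emulate: sequence content, assembly/binning
artifacts, within-genus phylogenetic structure, study-level batch effects,
or abundance; carriage is exchangeable across participants given state and
genus composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .catalog import GeneCatalog, default_catalog
from .errors import ValidationError
from .ingest import MagRecord
from .presence import DISEASE_STATES, PresenceMatrix

_GENUS_POOL_SEED = 20180815  # fixed: the default pool is a study condition


@dataclass(frozen=True)
class GenusProfile:
    """A genus with a sampling weight and per-gene carriage probabilities."""

    name: str
    weight: float
    carriage: dict[str, float]

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValidationError(f"genus {self.name!r} has negative weight")
        for gene, p in self.carriage.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(
                    f"carriage probability for {gene!r} in {self.name!r} "
                    f"outside [0, 1]: {p}"
                )


@dataclass(frozen=True)
class MagCountDistribution:
    """Distribution of MAGs per participant.

    Families: ``negative_binomial`` (params mean, shape), ``poisson``
    (param mean), ``fixed`` (param mean, rounded).
    """

    family: str = "negative_binomial"
    mean: float = 16936 / 667  # ~25.4, the published MAGs-per-participant scale
    shape: float = 2.0

    def __post_init__(self) -> None:
        if self.family not in {"negative_binomial", "poisson", "fixed"}:
            raise ValidationError(f"unknown distribution family {self.family!r}")
        if self.mean <= 0 or (self.family == "negative_binomial" and self.shape <= 0):
            raise ValidationError("distribution parameters must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "fixed":
            return np.full(n, int(round(self.mean)), dtype=np.int64)
        if self.family == "poisson":
            return rng.poisson(self.mean, size=n).astype(np.int64)
        p = self.shape / (self.shape + self.mean)
        return rng.negative_binomial(self.shape, p, size=n).astype(np.int64)


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort.

    ``effects`` maps gene -> disease state -> multiplicative odds applied to
    the genus carriage probability for MAGs of participants in that state
    (1.0 everywhere = null cohort).
    """

    n_per_state: dict[str, int] = field(
        default_factory=lambda: {"healthy": 265, "adenoma": 112, "carcinoma": 290}
    )
    mags_per_participant: MagCountDistribution = field(
        default_factory=MagCountDistribution
    )
    genus_pool: list[GenusProfile] = field(default_factory=list)
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    stage_distribution: dict[str, float] = field(
        default_factory=lambda: {"I": 0.2, "II": 0.3, "III": 0.3, "IV": 0.2}
    )
    copy_number_lambda: float = 0.25  # extra copies per present gene (Poisson)
    study: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genus_pool:
            self.genus_pool = default_genus_pool()
        total_weight = sum(g.weight for g in self.genus_pool)
        if total_weight <= 0:
            raise ValidationError("genus pool weights must not all be zero")
        for state, n in self.n_per_state.items():
            if state not in DISEASE_STATES or n < 0:
                raise ValidationError(f"bad n_per_state entry {state!r}: {n}")
        for gene, per_state in self.effects.items():
            for state, odds in per_state.items():
                if odds <= 0:
                    raise ValidationError(
                        f"effect odds for {gene!r} in {state!r} must be > 0"
                    )
        probs = np.array(list(self.stage_distribution.values()), dtype=float)
        if (probs < 0).any() or probs.sum() <= 0:
            raise ValidationError("stage distribution must be non-negative")

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.genus_pool:
            for sym in g.carriage:
                seen.setdefault(sym)
        return list(seen)


def default_genus_pool(
    genes: Sequence[str] | None = None,
    n_genera: int = 20,
) -> list[GenusProfile]:
    """Class-structured default genus pool.

    Genes travel with genera: cysteine/methionine genes are carried by most
    genera at high within-genus probability, inorganic sulfur-reduction genes
    by few genera, taurine genes by an intermediate fraction — mirroring the
    observed prevalence structure. Built with a fixed internal generator so
    the default pool is identical across runs; pass your own pool (or use
    ``independent_genus_pool``) for statistical experiments.
    """
    if genes is None:
        catalog = default_catalog()
        class_of = {g.symbol: g.substrate_class for g in catalog}
        genes = catalog.symbols
    else:
        class_of = {}
    rng = np.random.default_rng(_GENUS_POOL_SEED)
    fractions = {
        "inorganic": (0.12, 0.7),
        "organic_cys_met": (0.55, 0.8),
        "organic_taurine": (0.25, 0.7),
        "accessory": (0.4, 0.6),
    }
    weights = rng.dirichlet(np.full(n_genera, 1.5)) * n_genera
    pool = []
    for i in range(n_genera):
        carriage = {}
        for sym in genes:
            frac, within = fractions.get(class_of.get(sym, "accessory"), (0.3, 0.6))
            if rng.random() < frac:
                carriage[sym] = within * float(rng.uniform(0.6, 1.0))
            else:
                carriage[sym] = 0.0
        pool.append(
            GenusProfile(name=f"Genus{i + 1:02d}", weight=float(weights[i]), carriage=carriage)
        )
    return pool


def independent_genus_pool(
    genes: Sequence[str], carriage: float | Mapping[str, float] = 0.2
) -> list[GenusProfile]:
    """Single-genus pool giving independent per-MAG coin flips per gene.

    Removes the genus structure so that participant-level carriage is an
    exchangeable Bernoulli process — the setting for calibration studies.
    """
    if isinstance(carriage, Mapping):
        probs = {g: float(carriage[g]) for g in genes}
    else:
        probs = {g: float(carriage) for g in genes}
    return [GenusProfile(name="GenusA", weight=1.0, carriage=probs)]


def apply_odds(p: np.ndarray, odds: np.ndarray) -> np.ndarray:
    """Adjust probabilities by a multiplicative odds factor."""
    return p * odds / (1.0 - p + p * odds)


@dataclass
class Cohort:
    """A realized synthetic cohort with its generating truth."""

    records: list[MagRecord]
    matrix: PresenceMatrix
    config: CohortConfig


def generate_cohort(config: CohortConfig) -> Cohort:
    """Sample a cohort; deterministic given ``config.seed``.

    Per-MAG gene presence is Bernoulli with the genus carriage probability
    adjusted on the odds scale by the participant's state effect; per-copy
    counts are 1 + Poisson(copy_number_lambda) where present.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.genes
    n_genes = len(genes)
    gene_idx = {g: j for j, g in enumerate(genes)}

    pool = config.genus_pool
    weights = np.array([g.weight for g in pool], dtype=float)
    weights = weights / weights.sum()
    base = np.array(
        [[g.carriage.get(sym, 0.0) for sym in genes] for g in pool], dtype=float
    )

    odds = np.ones((len(DISEASE_STATES), n_genes), dtype=float)
    for gene, per_state in config.effects.items():
        if gene not in gene_idx:
            continue
        for s, o in per_state.items():
            odds[DISEASE_STATES.index(s), gene_idx[gene]] = o

    stages = list(config.stage_distribution)
    stage_p = np.array([config.stage_distribution[s] for s in stages], dtype=float)
    stage_p = stage_p / stage_p.sum()

    participant_state: list[tuple[str, str, str | None]] = []
    pid = 0
    for state in DISEASE_STATES:
        for _ in range(config.n_per_state.get(state, 0)):
            pid += 1
            stage = (
                stages[rng.choice(len(stages), p=stage_p)]
                if state == "carcinoma"
                else None
            )
            participant_state.append((f"P{pid:04d}", state, stage))

    n_participants = len(participant_state)
    mag_counts = config.mags_per_participant.sample(rng, n_participants)

    # flat MAG arrays for vectorized sampling
    part_idx = np.repeat(np.arange(n_participants), mag_counts)
    n_mags = len(part_idx)
    state_idx = np.array(
        [DISEASE_STATES.index(participant_state[i][1]) for i in part_idx],
        dtype=np.int64,
    )
    genus_idx = rng.choice(len(pool), size=n_mags, p=weights)
    probs = apply_odds(base[genus_idx], odds[state_idx])
    present = rng.random((n_mags, n_genes)) < probs
    counts = np.where(
        present, 1 + rng.poisson(config.copy_number_lambda, (n_mags, n_genes)), 0
    ).astype(np.int64)

    completeness = rng.uniform(55.0, 99.0, n_mags)
    contamination = rng.uniform(0.0, 4.9, n_mags)
    heterogeneity = rng.uniform(0.0, 0.49, n_mags)

    records = []
    mag_ids = []
    for k in range(n_mags):
        p_id, state, stage = participant_state[part_idx[k]]
        mag_id = f"MAG{k + 1:05d}"
        mag_ids.append(mag_id)
        records.append(
            MagRecord(
                mag_id=mag_id,
                participant_id=p_id,
                study=config.study,
                disease_state=state,
                stage=stage,
                genus_label=pool[genus_idx[k]].name,
                completeness=float(completeness[k]),
                contamination=float(contamination[k]),
                strain_heterogeneity=float(heterogeneity[k]),
            )
        )
    matrix = PresenceMatrix(mag_ids, list(genes), counts)
    return Cohort(records=records, matrix=matrix, config=config)


def participants_without_mags(cohort: Cohort) -> list[tuple[str, str, str | None]]:
    """Participants whose sampled MAG count was zero (still cohort members)."""
    with_mags = {r.participant_id for r in cohort.records}
    seen = {}
    for r in cohort.records:
        seen[r.participant_id] = None
    # reconstruct from config ordering: ids are P0001..P{n}
    out = []
    pid = 0
    for state in DISEASE_STATES:
        for _ in range(cohort.config.n_per_state.get(state, 0)):
            pid += 1
            name = f"P{pid:04d}"
            if name not in with_mags:
                out.append((name, state, None))
    return out


def planted_effect_truth(config: CohortConfig) -> pd.DataFrame:
    """Closed-form per-gene, per-state MAG-level carriage probabilities.

    Marginalizes the genus pool: p(state, gene) = sum_genus w_genus *
    odds-adjusted carriage. Serves as the recovery target for simulation
    studies.
    """
    genes = config.genes
    pool = config.genus_pool
    weights = np.array([g.weight for g in pool], dtype=float)
    weights = weights / weights.sum()
    base = np.array(
        [[g.carriage.get(sym, 0.0) for sym in genes] for g in pool], dtype=float
    )
    rows = {}
    for si, state in enumerate(DISEASE_STATES):
        odds = np.ones(len(genes))
        for gene, per_state in config.effects.items():
            if gene in genes and state in per_state:
                odds[genes.index(gene)] = per_state[state]
        rows[state] = weights @ apply_odds(base, odds[None, :])
    return pd.DataFrame(rows, index=genes)


def write_tblout_fixture(
    cohort: Cohort,
    catalog: GeneCatalog,
    path: str | Path,
    n_decoys: int = 0,
    decoy_offset: float = 0.1,
    decoy_seed: int = 1,
) -> None:
    """Write the cohort's hits as a valid hmmsearch tblout file.

    Present genes receive scores 5 bits above their trusted cutoff (100 bits
    for genes without one); optional decoy rows score ``decoy_offset`` below
    cutoff and must be removed by trusted-cutoff filtering. Parsing and
    filtering the file reproduces the cohort's presence matrix exactly.
    """
    matrix = cohort.matrix
    lines = [
        "#                                                               --- full sequence ---- --- best 1 domain ---- --- domain number estimation ----",
        "# target name        accession  query name           accession    E-value  score  bias   E-value  score  bias   exp reg clu  ov env dom rep inc description of target",
        "#------------------- ---------- -------------------- ---------- --------- ------ ----- --------- ------ -----   --- --- --- --- --- --- --- --- ---------------------",
    ]
    orf_counter = {m: 0 for m in matrix.mag_ids}

    def row(mag: str, symbol: str, score: float) -> str:
        orf_counter[mag] += 1
        target = f"{mag}_{orf_counter[mag]}"
        hmm = catalog[symbol].hmm_id
        return (
            f"{target:<20} -          {hmm:<20} -          "
            f"{1e-30:9.1e} {score:6.1f}   0.0 {1e-30:9.1e} {score:6.1f}   0.0   "
            f"1.0   1   0   0   1   1   1   1 {symbol}"
        )

    for i, mag in enumerate(matrix.mag_ids):
        for j, symbol in enumerate(matrix.gene_symbols):
            c = int(matrix.counts[i, j])
            if c == 0:
                continue
            cutoff = catalog[symbol].trusted_cutoff
            score = (cutoff + 5.0) if cutoff is not None else 100.0
            for _ in range(c):
                lines.append(row(mag, symbol, score))

    if n_decoys > 0:
        rng = np.random.default_rng(decoy_seed)
        with_cutoff = [
            s for s in matrix.gene_symbols if catalog[s].trusted_cutoff is not None
        ]
        if not with_cutoff:
            raise ValidationError("decoys require at least one gene with a cutoff")
        for _ in range(n_decoys):
            mag = matrix.mag_ids[rng.integers(len(matrix.mag_ids))]
            symbol = with_cutoff[rng.integers(len(with_cutoff))]
            lines.append(
                row(mag, symbol, catalog[symbol].trusted_cutoff - decoy_offset)
            )
    lines.append("#")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def config_from_yaml(path: str | Path) -> CohortConfig:
    """Load a cohort configuration from YAML."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "n_per_state" in raw:
        kwargs["n_per_state"] = {k: int(v) for k, v in raw["n_per_state"].items()}
    if "mags_per_participant" in raw:
        kwargs["mags_per_participant"] = MagCountDistribution(**raw["mags_per_participant"])
    if "genus_pool" in raw:
        kwargs["genus_pool"] = [
            GenusProfile(
                name=g["name"],
                weight=float(g.get("weight", 1.0)),
                carriage={k: float(v) for k, v in g.get("carriage", {}).items()},
            )
            for g in raw["genus_pool"]
        ]
    for key in ("effects", "stage_distribution", "copy_number_lambda", "study", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    return CohortConfig(**kwargs)
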