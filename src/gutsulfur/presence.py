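"""MAG x gene presence structures and participant-level summaries.

The unit of detection is a hit count per (MAG, gene); the unit of inference is
the participant. A participant "carries" a gene when at least one of their MAGs
has at least one retained hit for it. Dot-plot summaries report, per gene and
disease state, the fraction of participants carrying the gene and the mean
number of carrier MAGs among carriers only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .catalog import GeneCatalog
    from .ingest import HmmHit, MagRecord

DISEASE_STATES = ("healthy", "adenoma", "carcinoma")


@dataclass
class PresenceMatrix:
    """Non-negative hit counts per MAG (rows) and gene symbol (columns)."""

    mag_ids: list[str]
    gene_symbols: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.mag_ids), len(self.gene_symbols)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.mag_ids)} MAGs x {len(self.gene_symbols)} genes"
            )
        if (self.counts < 0).any():
            raise ValidationError("hit counts must be non-negative")

    @property
    def presence(self) -> np.ndarray:
        """Boolean presence (count >= 1)."""
        return self.counts >= 1

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.mag_ids, columns=self.gene_symbols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PresenceMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def gene_sets(self) -> dict[str, set[str]]:
        """Per-MAG set of present gene symbols."""
        genes = np.asarray(self.gene_symbols, dtype=object)
        return {
            mag: set(genes[self.presence[i]]) for i, mag in enumerate(self.mag_ids)
        }


@dataclass
class ParticipantProfile:
    """Binarized gene carriage for one participant."""

    participant_id: str
    disease_state: str
    stage: str | None
    gene_presence: dict[str, bool]
    mags_with_gene: dict[str, int]
    n_mags: int

    def __post_init__(self) -> None:
        for gene, present in self.gene_presence.items():
            n = self.mags_with_gene.get(gene, 0)
            if present != (n >= 1) or n > self.n_mags:
                raise ValidationError(
                    f"inconsistent carriage for participant "
                    f"{self.participant_id!r}, gene {gene!r}"
                )


@dataclass(frozen=True)
class DotplotCell:
    """One gene x disease-state summary cell."""

    gene: str
    disease_state: str
    prop_participants: float
    mean_mags_carriers: float | None
    n_carriers: int
    n_state: int


def build_presence_matrix(
    hits: Iterable["HmmHit"],
    gene_symbols: Sequence[str],
    mag_ids: Sequence[str] | None = None,
) -> PresenceMatrix:
    """Tally retained hits into a MAG x gene count matrix.

    ``mag_ids`` may declare MAGs with zero hits (e.g. every MAG that survived
    quality filtering) so they appear as all-zero rows.
    """
    hits = list(hits)
    symbols = list(gene_symbols)
    sym_index = {s: j for j, s in enumerate(symbols)}
    mags = list(mag_ids) if mag_ids is not None else []
    mag_index = {m: i for i, m in enumerate(mags)}
    for h in hits:
        if h.mag_id not in mag_index:
            if mag_ids is not None:
                raise ValidationError(
                    f"hit references MAG {h.mag_id!r} not in declared mag_ids"
                )
            mag_index[h.mag_id] = len(mags)
            mags.append(h.mag_id)
    counts = np.zeros((len(mags), len(symbols)), dtype=np.int64)
    for h in hits:
        if h.gene_symbol not in sym_index:
            raise ValidationError(
                f"hit references undeclared gene symbol {h.gene_symbol!r}"
            )
        counts[mag_index[h.mag_id], sym_index[h.gene_symbol]] += 1
    return PresenceMatrix(mags, symbols, counts)


def binarize_by_participant(
    matrix: PresenceMatrix, records: Iterable["MagRecord"]
) -> list[ParticipantProfile]:
    """Collapse MAG-level counts to participant-level presence.

    A gene is present for a participant iff at least one of their MAGs carries
    at least one copy; ``mags_with_gene`` counts carrier MAGs, not copies.
    Participants listed in the metadata whose MAGs all fell out of the matrix
    (or who have no MAGs) still receive an all-absent profile, so they stay in
    downstream denominators. Every MAG in the matrix must have metadata.
    """
    records = list(records)
    by_mag = {r.mag_id: r for r in records}
    orphans = [m for m in matrix.mag_ids if m not in by_mag]
    if orphans:
        raise ValidationError(
            "MAG(s) in presence matrix lack metadata: " + ", ".join(sorted(orphans))
        )

    participants: dict[str, dict] = {}
    for r in records:
        p = participants.setdefault(
            r.participant_id,
            {"state": r.disease_state, "stage": r.stage, "rows": [], "n_mags": 0},
        )
        p["n_mags"] += 1
        if r.stage is not None and p["stage"] is None:
            p["stage"] = r.stage

    presence = matrix.presence
    for i, mag in enumerate(matrix.mag_ids):
        participants[by_mag[mag].participant_id]["rows"].append(i)

    profiles = []
    genes = matrix.gene_symbols
    for pid, info in participants.items():
        if info["rows"]:
            mags_with = presence[info["rows"], :].sum(axis=0)
        else:
            mags_with = np.zeros(len(genes), dtype=np.int64)
        profiles.append(
            ParticipantProfile(
                participant_id=pid,
                disease_state=info["state"],
                stage=info["stage"],
                gene_presence={g: bool(mags_with[j] >= 1) for j, g in enumerate(genes)},
                mags_with_gene={g: int(mags_with[j]) for j, g in enumerate(genes)},
                n_mags=info["n_mags"],
            )
        )
    return profiles


def dotplot_summary(
    profiles: Sequence[ParticipantProfile],
    genes: Sequence[str],
    states: Sequence[str] = DISEASE_STATES,
) -> list[DotplotCell]:
    """Per gene x disease state: carrier proportion and mean carrier-MAG count.

    The proportion denominator is every participant in the state (including
    those with zero surviving MAGs); the mean is over carriers only and is
    ``None`` for states with no carriers.
    """
    cells = []
    for state in states:
        members = [p for p in profiles if p.disease_state == state]
        for gene in genes:
            carriers = [p for p in members if p.gene_presence.get(gene, False)]
            prop = len(carriers) / len(members) if members else 0.0
            mean = (
                float(np.mean([p.mags_with_gene[gene] for p in carriers]))
                if carriers
                else None
            )
            cells.append(
                DotplotCell(
                    gene=gene,
                    disease_state=state,
                    prop_participants=prop,
                    mean_mags_carriers=mean,
                    n_carriers=len(carriers),
                    n_state=len(members),
                )
            )
    return cells


def dotplot_table(cells: Sequence[DotplotCell]) -> pd.DataFrame:
    """Tidy TSV-ready frame of dot-plot statistics."""
    return pd.DataFrame(
        [
            {
                "gene": c.gene,
                "state": c.disease_state,
                "prop_participants": c.prop_participants,
                "mean_mags_carriers": (
                    np.nan if c.mean_mags_carriers is None else c.mean_mags_carriers
                ),
                "n_carriers": c.n_carriers,
                "n_state": c.n_state,
            }
            for c in cells
        ]
    )


@dataclass
class GenusSummary:
    """Genus x gene carrier-MAG counts plus the sulfidogenic-genus rollup."""

    table: pd.DataFrame
    n_genera_with_sulfidogenic: int


def genus_gene_summary(
    matrix: PresenceMatrix,
    records: Iterable["MagRecord"],
    catalog: "GeneCatalog",
) -> GenusSummary:
    """Count carrier MAGs per genus per gene; roll up sulfidogenic genera.

    MAGs without a genus label fall into an "unclassified" bucket. The rollup
    is the number of distinct genera with at least one MAG carrying at least
    one sulfidogenic gene.
    """
    by_mag = {r.mag_id: r for r in records}
    genus = [
        (by_mag[m].genus_label or "unclassified") if m in by_mag else "unclassified"
        for m in matrix.mag_ids
    ]
    df = pd.DataFrame(
        matrix.presence.astype(int), index=genus, columns=matrix.gene_symbols
    )
    table = df.groupby(level=0).sum().rename_axis("genus")
    sulfidogenic = [s for s in matrix.gene_symbols if s in catalog and catalog[s].sulfidogenic]
    if sulfidogenic:
        rollup = int((table[sulfidogenic].sum(axis=1) >= 1).sum())
    else:
        rollup = 0
    return GenusSummary(table=table, n_genera_with_sulfidogenic=rollup)


def published_cohort_overview() -> pd.DataFrame:
    """The shipped per-study participant/MAG counts for the five public CRC
    cohorts (study, country, disease_state, n_participants, n_mags)."""
    from importlib import resources

    ref = resources.files("gutsulfur.data").joinpath("cohort_overview.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def records_from_overview(overview: pd.DataFrame) -> list["MagRecord"]:
    """Expand a per-study count table into placeholder MAG records.

    Participants and MAGs get synthetic ids; MAGs are spread round-robin over
    the cell's participants. Used to exercise cohort accounting against
    printed per-study totals.
    """
    from .ingest import MagRecord

    records = []
    pid_counter = 0
    mag_counter = 0
    for row in overview.itertuples(index=False):
        n_p, n_m = int(row.n_participants), int(row.n_mags)
        if n_p == 0:
            continue
        pids = []
        for _ in range(n_p):
            pid_counter += 1
            pids.append(f"P{pid_counter:05d}")
        for k in range(n_m):
            mag_counter += 1
            records.append(
                MagRecord(
                    mag_id=f"MAG{mag_counter:06d}",
                    participant_id=pids[k % n_p],
                    study=row.study,
                    disease_state=row.disease_state,
                    completeness=95.0,
                    contamination=1.0,
                    strain_heterogeneity=0.1,
                )
            )
    return records


@dataclass
class CohortAccounting:
    """Participant and MAG totals per study x disease state with grand totals."""

    table: pd.DataFrame
    total_participants: int
    total_mags: int
    participants_by_state: dict[str, int]
    mags_by_state: dict[str, int]


def cohort_accounting(records: Iterable["MagRecord"]) -> CohortAccounting:
    """Tally participants and MAGs per study x disease state.

    Totals are invariant to record order; a participant is counted within the
    (study, state) cell their MAGs annotate.
    """
    records = list(records)
    if not records:
        empty = pd.DataFrame(
            columns=["study", "disease_state", "n_participants", "n_mags"]
        )
        return CohortAccounting(empty, 0, 0, {}, {})
    df = pd.DataFrame(
        {
            "study": [r.study for r in records],
            "disease_state": [r.disease_state for r in records],
            "participant_id": [r.participant_id for r in records],
            "mag_id": [r.mag_id for r in records],
        }
    )
    table = (
        df.groupby(["study", "disease_state"], sort=True)
        .agg(
            n_participants=("participant_id", "nunique"),
            n_mags=("mag_id", "nunique"),
        )
        .reset_index()
    )
    by_state = df.groupby("disease_state")
    return CohortAccounting(
        table=table,
        total_participants=int(df["participant_id"].nunique()),
        total_mags=int(df["mag_id"].nunique()),
        participants_by_state=by_state["participant_id"].nunique().to_dict(),
        mags_by_state=by_state["mag_id"].nunique().to_dict(),
    )
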