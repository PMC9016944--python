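"""Parsers and filters for homology-search output and MAG metadata.

Covers the hmmsearch per-target table (tblout), BLAST tabular output
(outfmt 6), the MAG metadata table, the wide presence-table dialect
(cell = gene symbol if present, ``N/A`` if absent), trusted-cutoff and
identity/coverage hit filters, MAG quality-tier filtering, and the
TNM -> stage lookup.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import math

import numpy as np
import pandas as pd

from .catalog import GeneCatalog
from .errors import FormatError, ValidationError
from .presence import DISEASE_STATES, PresenceMatrix

#: Default rule deriving a MAG id from a Prodigal-style protein id:
#: strip a trailing ``_<orf-number>``.
DEFAULT_MAG_ID_PATTERN = r"_\d+$"

_STATE_SYNONYMS = {
    "healthy": "healthy",
    "control": "healthy",
    "control/healthy": "healthy",
    "h": "healthy",
    "adenoma": "adenoma",
    "carcinoma": "carcinoma",
    "crc": "carcinoma",
    "cancer": "carcinoma",
}

STAGES = ("I", "II", "III", "IV")
UNSTAGED = "unstaged"


@dataclass(frozen=True)
class HmmHit:
    mag_id: str
    protein_id: str
    profile_id: str
    gene_symbol: str
    full_seq_score: float
    full_seq_evalue: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.full_seq_score):
            raise ValidationError(
                f"non-finite bit score for hit {self.protein_id!r}"
            )
        if self.full_seq_evalue < 0:
            raise ValidationError(f"negative E-value for hit {self.protein_id!r}")


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    pct_identity: float
    align_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValidationError(
                f"percent identity {self.pct_identity} outside [0, 100]"
            )
        if self.align_length < 0:
            raise ValidationError("alignment length must be >= 0")


@dataclass(frozen=True)
class MagRecord:
    mag_id: str
    participant_id: str
    study: str
    disease_state: str
    stage: str | None = None
    tnm: tuple[str, str, str] | None = None
    genus_label: str = ""
    completeness: float = float("nan")
    contamination: float = float("nan")
    strain_heterogeneity: float | None = None

    def __post_init__(self) -> None:
        if self.disease_state not in DISEASE_STATES:
            raise ValidationError(
                f"disease_state {self.disease_state!r} not in {DISEASE_STATES}"
            )


class TbloutResult(NamedTuple):
    hits: list[HmmHit]
    skipped: list[tuple[int, str]]  # (line number, unresolvable profile id)


def parse_hmmsearch_tblout(
    path: str | Path,
    profile_to_symbol: Mapping[str, str],
    mag_id_pattern: str = DEFAULT_MAG_ID_PATTERN,
) -> TbloutResult:
    """Parse an hmmsearch per-target table (tblout dialect).

    One hit per non-comment row whose query profile resolves through
    ``profile_to_symbol``; rows with unresolvable profiles are collected into
    the skipped report rather than raising. The MAG id is derived from the
    target (protein) name by deleting the first match of ``mag_id_pattern``.
    """
    path = Path(path)
    rx = re.compile(mag_id_pattern)
    hits: list[HmmHit] = []
    skipped: list[tuple[int, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(maxsplit=18)
            if len(fields) < 18:
                raise FormatError(
                    f"{path}:{lineno}: malformed tblout row "
                    f"({len(fields)} fields, expected >= 18)"
                )
            target, _tacc, query = fields[0], fields[1], fields[2]
            evalue, score = float(fields[4]), float(fields[5])
            symbol = profile_to_symbol.get(query)
            if symbol is None:
                skipped.append((lineno, query))
                continue
            hits.append(
                HmmHit(
                    mag_id=rx.sub("", target, count=1),
                    protein_id=target,
                    profile_id=query,
                    gene_symbol=symbol,
                    full_seq_score=score,
                    full_seq_evalue=evalue,
                )
            )
    return TbloutResult(hits, skipped)


def filter_hits_trusted_cutoff(
    hits: Iterable[HmmHit],
    catalog: GeneCatalog,
    return_flagged: bool = False,
):
    """Retain hits scoring at or above their gene's trusted cutoff.

    The comparison is inclusive (``score >= cutoff``), following the HMMER
    trusted-cutoff convention. Hits to genes without a cutoff are retained;
    with ``return_flagged=True`` those are additionally returned so callers
    can report them. Input order is preserved.
    """
    kept: list[HmmHit] = []
    flagged: list[HmmHit] = []
    for h in hits:
        cutoff = catalog[h.gene_symbol].trusted_cutoff
        if cutoff is None:
            kept.append(h)
            flagged.append(h)
        elif h.full_seq_score >= cutoff:
            kept.append(h)
    if return_flagged:
        return kept, flagged
    return kept


def parse_blast_outfmt6(path: str | Path) -> list[BlastHit]:
    """Parse BLAST tabular output (outfmt 6, 12 standard columns)."""
    path = Path(path)
    hits = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: outfmt-6 row has {len(fields)} columns, "
                    "expected 12"
                )
            hits.append(
                BlastHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    align_length=int(fields[3]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
    return hits


def filter_blast_hits(
    hits: Iterable[BlastHit],
    min_identity: float = 60.0,
    min_align_len: int = 40,
) -> list[BlastHit]:
    """Identity/coverage filter for the genomic survey.

    Retains alignments with identity strictly greater than ``min_identity``
    percent and alignment length of at least ``min_align_len`` amino acids.
    """
    return [
        h
        for h in hits
        if h.pct_identity > min_identity and h.align_length >= min_align_len
    ]


def filter_mags_by_quality(
    records: Iterable[MagRecord],
    tiers: Sequence[str] = ("high", "medium"),
) -> list[MagRecord]:
    """Keep MAGs satisfying any requested quality tier.

    high:   completeness > 90, contamination < 5, strain heterogeneity < 0.5
            (records without a strain-heterogeneity value cannot be high tier);
    medium: completeness > 50, contamination < 5.
    All inequalities are strict.
    """
    unknown = set(tiers) - {"high", "medium"}
    if unknown:
        raise ValidationError(f"unknown quality tier(s): {sorted(unknown)}")

    def is_high(r: MagRecord) -> bool:
        return (
            r.completeness > 90
            and r.contamination < 5
            and r.strain_heterogeneity is not None
            and r.strain_heterogeneity < 0.5
        )

    def is_medium(r: MagRecord) -> bool:
        return r.completeness > 50 and r.contamination < 5

    checks = {"high": is_high, "medium": is_medium}
    active = [checks[t] for t in tiers]
    return [r for r in records if any(c(r) for c in active)]


def read_presence_table(path: str | Path) -> PresenceMatrix:
    """Read a wide presence table (first column MAG id; cell = column's gene
    symbol when present, ``N/A`` when absent) into a binary matrix."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    mag_col = df.columns[0]
    genes = list(df.columns[1:])
    counts = np.zeros((len(df), len(genes)), dtype=np.int64)
    for j, gene in enumerate(genes):
        col = df[gene]
        bad = ~col.isin([gene, "N/A"])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: row {row + 2}, column {gene!r}: cell "
                f"{col.iloc[row]!r} must be {gene!r} or 'N/A'"
            )
        counts[:, j] = (col == gene).to_numpy()
    return PresenceMatrix(df[mag_col].tolist(), genes, counts)


def write_presence_table(matrix: PresenceMatrix, path: str | Path) -> None:
    """Write the presence-table dialect; counts are binarized on write."""
    presence = matrix.presence
    data = {"mag_id": matrix.mag_ids}
    for j, gene in enumerate(matrix.gene_symbols):
        data[gene] = np.where(presence[:, j], gene, "N/A")
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def normalize_disease_state(token: str) -> str:
    state = _STATE_SYNONYMS.get(token.strip().lower())
    if state is None:
        raise ValidationError(f"unknown disease state token {token!r}")
    return state


def read_mag_metadata(path: str | Path) -> list[MagRecord]:
    """Read the MAG metadata TSV into validated records.

    Required columns: mag_id, participant_id, study, disease_state,
    completeness, contamination. Optional: stage, t/n/m, genus_label,
    strain_heterogeneity. Disease-state synonyms (control, CRC, ...) are
    normalized; unknown tokens are collected and reported together.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    required = ["mag_id", "participant_id", "study", "disease_state"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"metadata file {path} missing required column(s): {', '.join(missing)}"
        )
    empty_pid = df["participant_id"].str.strip() == ""
    if empty_pid.any():
        raise ValidationError(
            f"{path}: {int(empty_pid.sum())} row(s) missing participant_id"
        )
    bad_states = sorted(
        {
            tok
            for tok in df["disease_state"]
            if tok.strip().lower() not in _STATE_SYNONYMS
        }
    )
    if bad_states:
        raise ValidationError(
            f"unknown disease state value(s): {', '.join(map(repr, bad_states))}"
        )
    dupes = df["mag_id"][df["mag_id"].duplicated()].unique()
    if len(dupes):
        raise ValidationError(
            "duplicate mag_id(s): " + ", ".join(map(repr, dupes[:10]))
        )

    def opt_float(row, col) -> float | None:
        if col in df.columns and str(getattr(row, col)).strip():
            return float(getattr(row, col))
        return None

    records = []
    for row in df.itertuples(index=False):
        stage = getattr(row, "stage", "").strip() or None
        tnm = None
        if all(hasattr(row, c) for c in ("t", "n", "m")):
            t, n, m = row.t.strip(), row.n.strip(), row.m.strip()
            if t or n or m:
                tnm = (t, n, m)
        records.append(
            MagRecord(
                mag_id=row.mag_id,
                participant_id=row.participant_id,
                study=row.study,
                disease_state=normalize_disease_state(row.disease_state),
                stage=stage if stage in STAGES else None,
                tnm=tnm,
                genus_label=getattr(row, "genus_label", "").strip(),
                completeness=(
                    c if (c := opt_float(row, "completeness")) is not None else float("nan")
                ),
                contamination=(
                    c if (c := opt_float(row, "contamination")) is not None else float("nan")
                ),
                strain_heterogeneity=opt_float(row, "strain_heterogeneity"),
            )
        )
    return records


def write_mag_metadata(records: Iterable[MagRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "mag_id": r.mag_id,
                "participant_id": r.participant_id,
                "study": r.study,
                "disease_state": r.disease_state,
                "stage": r.stage or "",
                "t": r.tnm[0] if r.tnm else "",
                "n": r.tnm[1] if r.tnm else "",
                "m": r.tnm[2] if r.tnm else "",
                "genus_label": r.genus_label,
                "completeness": r.completeness,
                "contamination": r.contamination,
                "strain_heterogeneity": (
                    "" if r.strain_heterogeneity is None else r.strain_heterogeneity
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- TNM -> stage -----------------------------------------------------------

_TOKEN_RX = re.compile(r"^[pcy]*([TNM])([0-9isx]+)[a-c]?$", re.IGNORECASE)


def _normalize_tnm_token(token: str, axis: str) -> str:
    """Normalize a TNM token: strip p/c/y prefixes and a/b/c subletters."""
    m = _TOKEN_RX.match(token.strip())
    if not m or m.group(1).upper() != axis:
        raise ValidationError(f"malformed {axis} token {token!r}")
    return f"{axis}{m.group(2).lower()}"


def load_tnm_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the TNM -> stage lookup (shipped simplified colorectal mapping by
    default); rows match top-to-bottom, '*' is a wildcard."""
    if path is None:
        ref = resources.files("gutsulfur.data").joinpath("tnm_stage_map.tsv")
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t", comment="#", dtype=str)
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def tnm_to_stage(
    t: str, n: str, m: str, table: pd.DataFrame | None = None
) -> str:
    """Map a (T, N, M) triple to stage I-IV via the lookup table.

    Unmatched triples (e.g. Tx/Nx/Mx) return ``"unstaged"`` — never a guess.
    """
    if table is None:
        table = load_tnm_table()
    try:
        nt = _normalize_tnm_token(t, "T")
        nn = _normalize_tnm_token(n, "N")
        nm = _normalize_tnm_token(m, "M")
    except ValidationError:
        raise
    for row in table.itertuples(index=False):
        if (
            (row.t == "*" or row.t.lower() == nt.lower())
            and (row.n == "*" or row.n.lower() == nn.lower())
            and (row.m == "*" or row.m.lower() == nm.lower())
        ):
            return row.stage
    return UNSTAGED


def annotate_stages(
    records: Iterable[MagRecord], table: pd.DataFrame | None = None
) -> list[MagRecord]:
    """Fill missing stages from TNM triples where available."""
    if table is None:
        table = load_tnm_table()
    out = []
    for r in records:
        if r.stage is None and r.tnm is not None:
            try:
                stage = tnm_to_stage(*r.tnm, table=table)
            except ValidationError:
                stage = UNSTAGED
            out.append(replace(r, stage=stage if stage in STAGES else None))
        else:
            out.append(r)
    return out
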