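"""Sulfur-metabolism gene catalog.

The catalog is the controlled vocabulary of the pipeline: every gene symbol used
by the homology-search filters, the pathway grammars, and the association layer
must resolve here. Each entry records the substrate class of the reaction
(inorganic sulfur species, cysteine/methionine-derived organic sulfur, taurine
and other sulfonates, or accessory machinery), whether the encoded reaction
directly yields hydrogen sulfide ("sulfidogenic"), the HMM profile used for
detection, and its trusted bit-score cutoff.

The shipped default catalog (``data/sulfur_catalog.tsv``) holds 79 entries: the
genes named in the primary gut sulfur-cycle literature plus representative
members of standard sulfur-cycle families. HMM ids and cutoffs for entries
beyond the named set are representative placeholders; supply your own catalog
TSV (same columns) for production annotation runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError, ResolutionError, ValidationError

SUBSTRATE_CLASSES = frozenset(
    {"inorganic", "organic_cys_met", "organic_taurine", "accessory"}
)

#: Symbols whose field-conventional capitalization is not all-lowercase.
#: Used to normalize case-insensitive matches onto the canonical spelling.
_CASED_SYMBOLS = ("CBS", "3MST",)

_CATALOG_COLUMNS = (
    "symbol",
    "full_name",
    "substrate_class",
    "sulfidogenic",
    "hmm_id",
    "trusted_cutoff",
    "reaction",
)


@dataclass(frozen=True)
class GeneDefinition:
    """One catalog entry.

    ``trusted_cutoff`` is the profile-specific bit-score threshold above which
    a hit is accepted without curation; ``None`` marks profiles (typically
    custom HMMs) that ship without one — hits to those are retained but
    flagged by the trusted-cutoff filter.
    """

    symbol: str
    full_name: str
    substrate_class: str
    sulfidogenic: bool
    hmm_id: str
    trusted_cutoff: float | None = None
    reaction: str = ""

    def __post_init__(self) -> None:
        if self.substrate_class not in SUBSTRATE_CLASSES:
            raise ValidationError(
                f"unknown substrate_class {self.substrate_class!r} for "
                f"{self.symbol!r}; expected one of {sorted(SUBSTRATE_CLASSES)}"
            )
        if self.trusted_cutoff is not None:
            if not math.isfinite(self.trusted_cutoff) or self.trusted_cutoff < 0:
                raise ValidationError(
                    f"trusted_cutoff for {self.symbol!r} must be finite and >= 0, "
                    f"got {self.trusted_cutoff!r}"
                )


@dataclass
class GeneCatalog:
    """Collection of :class:`GeneDefinition` keyed by symbol."""

    entries: dict[str, GeneDefinition] = field(default_factory=dict)
    version: str = ""

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("catalog must be non-empty")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: object) -> bool:
        return symbol in self.entries

    def __getitem__(self, symbol: str) -> GeneDefinition:
        try:
            return self.entries[symbol]
        except KeyError:
            raise ResolutionError(
                f"gene symbol {symbol!r} does not resolve in catalog"
            ) from None

    def __iter__(self):
        return iter(self.entries.values())

    @property
    def symbols(self) -> list[str]:
        return list(self.entries)

    def resolve(self, name: str) -> str:
        """Map a possibly mis-cased symbol onto its canonical catalog spelling."""
        if name in self.entries:
            return name
        lowered = name.lower()
        for sym in self.entries:
            if sym.lower() == lowered:
                return sym
        raise ResolutionError(f"gene symbol {name!r} does not resolve in catalog")

    def sulfidogenic_symbols(self) -> set[str]:
        return {g.symbol for g in self if g.sulfidogenic}

    def hmm_to_symbol(self) -> dict[str, str]:
        """Mapping from HMM profile id to gene symbol, for tblout resolution."""
        return {g.hmm_id: g.symbol for g in self}


def _parse_bool(value: object) -> bool:
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise FormatError(f"cannot interpret {value!r} as a boolean")


def load_catalog(path: str | Path, version: str | None = None) -> GeneCatalog:
    """Load and validate a catalog TSV.

    The file is UTF-8 TSV with columns ``symbol``, ``full_name``,
    ``substrate_class``, ``sulfidogenic``, ``hmm_id``, ``trusted_cutoff``,
    ``reaction``; ``#`` lines are comments. Duplicate symbols and unknown
    substrate classes are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in _CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"catalog file {path} is missing required column(s): {', '.join(missing)}"
        )
    symbols = df["symbol"].tolist()
    dupes = sorted({s for s in symbols if symbols.count(s) > 1})
    if dupes:
        raise ValidationError(f"duplicate gene symbol(s) in catalog: {', '.join(dupes)}")
    entries: dict[str, GeneDefinition] = {}
    for row in df.itertuples(index=False):
        cutoff_text = row.trusted_cutoff.strip()
        cutoff = float(cutoff_text) if cutoff_text else None
        entry = GeneDefinition(
            symbol=row.symbol.strip(),
            full_name=row.full_name.strip(),
            substrate_class=row.substrate_class.strip(),
            sulfidogenic=_parse_bool(row.sulfidogenic),
            hmm_id=row.hmm_id.strip(),
            trusted_cutoff=cutoff,
            reaction=row.reaction.strip(),
        )
        entries[entry.symbol] = entry
    return GeneCatalog(entries=entries, version=version or path.stem)


def write_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    """Write a catalog in the same TSV dialect ``load_catalog`` reads."""
    rows = []
    for g in catalog:
        rows.append(
            {
                "symbol": g.symbol,
                "full_name": g.full_name,
                "substrate_class": g.substrate_class,
                "sulfidogenic": "true" if g.sulfidogenic else "false",
                "hmm_id": g.hmm_id,
                "trusted_cutoff": "" if g.trusted_cutoff is None else repr(g.trusted_cutoff),
                "reaction": g.reaction,
            }
        )
    pd.DataFrame(rows, columns=list(_CATALOG_COLUMNS)).to_csv(path, sep="\t", index=False)


def default_catalog() -> GeneCatalog:
    """The shipped 79-gene default catalog."""
    ref = resources.files("gutsulfur.data").joinpath("sulfur_catalog.tsv")
    with resources.as_file(ref) as path:
        return load_catalog(path, version="default")


def classify_substrate(
    catalog: GeneCatalog, symbols: Iterable[str]
) -> dict[str, set[str]]:
    """Partition ``symbols`` by substrate class.

    Returns a mapping from substrate class to the subset of input symbols in
    that class; classes with no members are omitted, so the union of the
    returned sets equals the input exactly and the sets are disjoint.
    """
    partition: dict[str, set[str]] = {}
    for sym in symbols:
        entry = catalog[sym]
        partition.setdefault(entry.substrate_class, set()).add(sym)
    return partition
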