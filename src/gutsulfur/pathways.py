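"""Pathway grammars and completeness calls.

A pathway is an ordered list of steps; each step is satisfied by any one of a
set of alternative gene requirements, where a requirement is an AND-set of
subunit symbols (e.g. the terminal sulfite-reduction step is satisfied by
{dsrA, dsrB} or by {asrA, asrB, asrC}). Completeness is called on the pooled
gene set of a unit — a single MAG, all MAGs of a genus, or all MAGs of a
participant. A participant whose pooled set completes a pathway that no single
one of their MAGs completes is a metabolic-cooperation candidate.

Status vocabulary:

``complete``
    every step satisfied;
``near_complete``
    exactly one step missing;
``first_and_last_only``
    first and last steps satisfied, at least one interior step missing (for
    3-step grammars this takes precedence over ``near_complete``, since the
    single interior step is then the missing one);
``absent``
    anything else.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .catalog import GeneCatalog
from .errors import ValidationError
from .ingest import MagRecord
from .presence import PresenceMatrix

#: Completion order used by the monotonicity contract.
STATUS_ORDER = ("absent", "first_and_last_only", "near_complete", "complete")


@dataclass(frozen=True)
class PathwayStep:
    label: str
    alternatives: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise ValidationError(f"step {self.label!r} has no alternatives")
        if any(not alt for alt in self.alternatives):
            raise ValidationError(f"step {self.label!r} has an empty AND-set")

    def satisfied_by(self, genes: frozenset[str] | set[str]) -> bool:
        return any(alt <= genes for alt in self.alternatives)


@dataclass(frozen=True)
class PathwayDefinition:
    name: str
    steps: tuple[PathwayStep, ...]
    excluded_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.steps) < 2:
            raise ValidationError(f"pathway {self.name!r} needs >= 2 steps")

    @property
    def n_variants(self) -> int:
        n = 1
        for s in self.steps:
            n *= len(s.alternatives)
        return n


@dataclass(frozen=True)
class PathwayCall:
    unit_id: str
    unit_level: str  # mag | genus | participant
    pathway: str
    variant: tuple[tuple[str, ...], ...]
    status: str
    missing_steps: tuple[str, ...]
    cooperation_candidate: bool = False


def _step_from_config(entry: dict, catalog: GeneCatalog | None) -> PathwayStep:
    alts = []
    for alt in entry.get("alternatives", []):
        symbols = tuple(alt)
        if catalog is not None:
            for s in symbols:
                if s not in catalog:
                    raise ValidationError(
                        f"pathway step {entry.get('label')!r} references symbol "
                        f"{s!r} not in catalog"
                    )
        alts.append(frozenset(symbols))
    return PathwayStep(label=entry.get("label", ""), alternatives=tuple(alts))


def load_pathway_grammar(
    path: str | Path, catalog: GeneCatalog | None = None
) -> list[PathwayDefinition]:
    """Load pathway definitions from a YAML grammar file.

    When a catalog is given, every referenced symbol must resolve in it.
    """
    with open(path, encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    definitions = []
    for p in config.get("pathways", []):
        steps = tuple(_step_from_config(s, catalog) for s in p.get("steps", []))
        definitions.append(
            PathwayDefinition(
                name=p["name"],
                steps=steps,
                excluded_genes=frozenset(p.get("excluded_genes", []) or []),
            )
        )
    if not definitions:
        raise ValidationError(f"no pathways defined in {path}")
    return definitions


def default_pathway_grammar(
    catalog: GeneCatalog | None = None,
) -> list[PathwayDefinition]:
    """The shipped taurine-reduction grammars (3-step and 4-step families)."""
    ref = resources.files("gutsulfur.data").joinpath("taurine_pathways.yaml")
    with resources.as_file(ref) as path:
        return load_pathway_grammar(path, catalog)


def enumerate_variants(
    definition: PathwayDefinition,
) -> list[tuple[tuple[str, ...], ...]]:
    """Cartesian product of per-step alternatives in lexicographic order.

    Each variant is a tuple with one sorted AND-set (as a tuple) per step.
    """
    per_step = [
        sorted(tuple(sorted(alt)) for alt in step.alternatives)
        for step in definition.steps
    ]
    return [tuple(combo) for combo in itertools.product(*per_step)]


def call_pathway(
    gene_set: Iterable[str],
    definition: PathwayDefinition,
    unit_id: str = "",
    unit_level: str = "mag",
) -> PathwayCall:
    """Call completeness of one pathway on one pooled gene set.

    A step is satisfied iff some alternative's AND-set is a subset of the gene
    set. The reported variant maximizes the number of satisfied steps, ties
    broken lexicographically.
    """
    genes = frozenset(gene_set)
    satisfied = [step.satisfied_by(genes) for step in definition.steps]
    missing = tuple(
        step.label for step, ok in zip(definition.steps, satisfied) if not ok
    )
    n_missing = len(missing)
    interior_missing = any(not ok for ok in satisfied[1:-1])
    if n_missing == 0:
        status = "complete"
    elif satisfied[0] and satisfied[-1] and interior_missing and (
        n_missing > 1 or len(definition.steps) == 3
    ):
        status = "first_and_last_only"
    elif n_missing == 1:
        status = "near_complete"
    else:
        status = "absent"

    best = None
    best_count = -1
    for variant in enumerate_variants(definition):
        count = sum(1 for req in variant if set(req) <= genes)
        if count > best_count:
            best, best_count = variant, count
    return PathwayCall(
        unit_id=unit_id,
        unit_level=unit_level,
        pathway=definition.name,
        variant=best,
        status=status,
        missing_steps=missing,
    )


def _pooled_gene_sets(
    matrix: PresenceMatrix,
    records: Sequence[MagRecord],
    level: str,
) -> dict[str, set[str]]:
    per_mag = matrix.gene_sets()
    if level == "mag":
        return per_mag
    by_mag = {r.mag_id: r for r in records}
    missing = [m for m in matrix.mag_ids if m not in by_mag]
    if missing:
        raise ValidationError(
            "MAG(s) lack metadata for pooling: " + ", ".join(sorted(missing))
        )
    pooled: dict[str, set[str]] = {}
    for mag, genes in per_mag.items():
        r = by_mag[mag]
        if level == "genus":
            key = r.genus_label or "unclassified"
        elif level == "participant":
            key = r.participant_id
        else:
            raise ValidationError(f"unknown pooling level {level!r}")
        pooled.setdefault(key, set()).update(genes)
    return pooled


def call_pathways_at_level(
    matrix: PresenceMatrix,
    records: Sequence[MagRecord],
    definitions: Sequence[PathwayDefinition],
    level: str,
) -> list[PathwayCall]:
    """Pool gene sets at the requested level and call every pathway.

    At participant level, a complete call with no single complete MAG among
    that participant's MAGs is flagged as a cooperation candidate.
    """
    pooled = _pooled_gene_sets(matrix, records, level)
    per_mag = matrix.gene_sets() if level == "participant" else None
    mags_of: dict[str, list[str]] = {}
    if level == "participant":
        for r in records:
            if r.mag_id in per_mag:
                mags_of.setdefault(r.participant_id, []).append(r.mag_id)

    calls = []
    for unit_id in sorted(pooled):
        genes = pooled[unit_id]
        for definition in definitions:
            call = call_pathway(genes, definition, unit_id=unit_id, unit_level=level)
            if level == "participant" and call.status == "complete":
                any_mag_complete = any(
                    call_pathway(per_mag[m], definition).status == "complete"
                    for m in mags_of.get(unit_id, [])
                )
                if not any_mag_complete:
                    call = PathwayCall(
                        **{**call.__dict__, "cooperation_candidate": True}
                    )
            calls.append(call)
    return calls


@dataclass(frozen=True)
class CooccurrenceTable:
    """2x2 MAG tally for a pair of genes."""

    symbol_a: str
    symbol_b: str
    both: int
    a_only: int
    b_only: int
    neither: int

    @property
    def total(self) -> int:
        return self.both + self.a_only + self.b_only + self.neither


def cooccurrence_table(
    matrix: PresenceMatrix, symbol_a: str, symbol_b: str
) -> CooccurrenceTable:
    """Tally MAGs by joint carriage of two genes."""
    for s in (symbol_a, symbol_b):
        if s not in matrix.gene_symbols:
            raise ValidationError(f"symbol {s!r} not in presence matrix")
    ia = matrix.gene_symbols.index(symbol_a)
    ib = matrix.gene_symbols.index(symbol_b)
    a = matrix.presence[:, ia]
    b = matrix.presence[:, ib]
    return CooccurrenceTable(
        symbol_a=symbol_a,
        symbol_b=symbol_b,
        both=int((a & b).sum()),
        a_only=int((a & ~b).sum()),
        b_only=int((~a & b).sum()),
        neither=int((~a & ~b).sum()),
    )


def calls_table(calls: Sequence[PathwayCall]):
    """Tidy frame of pathway calls (unit, level, pathway, variant, status)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "unit_id": c.unit_id,
                "level": c.unit_level,
                "pathway": c.pathway,
                "variant": ";".join("+".join(req) for req in c.variant),
                "status": c.status,
                "missing_steps": ";".join(c.missing_steps),
                "cooperation_candidate": c.cooperation_candidate,
            }
            for c in calls
        ]
    )
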