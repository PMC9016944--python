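"""Association statistics for gene carriage vs disease state and CRC stage.

Per gene, participants are binarized (carrier / non-carrier) and tallied into
a 2 x 3 contingency table over disease states (healthy, adenoma, carcinoma).
A Pearson chi-squared test (df = 2, no continuity correction) asks whether
carriage is distributed non-randomly across states; p-values are adjusted
across all tested features in one batch with the Benjamini-Hochberg step-up
procedure. For the subset with cancer staging, a Rao score test on a binomial
logistic regression of carriage against stage (coded 1-4) tests for a stage
trend. Evaluated at the intercept-only fit, the efficient score statistic has
the closed form

    U = sum_i x_i (y_i - ybar),   V = ybar (1 - ybar) sum_i (x_i - xbar)^2,
    chi2_1 = U^2 / V,

which is what ``stage_score_test`` computes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .presence import DISEASE_STATES, ParticipantProfile

_STATE_ADVANCEMENT = {s: i for i, s in enumerate(DISEASE_STATES)}
_STAGE_CODES = {"I": 1, "II": 2, "III": 3, "IV": 4}


@dataclass
class ContingencyTable:
    """2 x 3 presence/absence x disease-state counts."""

    states: tuple[str, ...]
    presence: np.ndarray  # carriers per state
    absence: np.ndarray  # non-carriers per state

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=np.int64)
        self.absence = np.asarray(self.absence, dtype=np.int64)
        if self.presence.shape != self.absence.shape or len(self.presence) != len(
            self.states
        ):
            raise ValidationError("contingency rows must match the state columns")
        if (self.presence < 0).any() or (self.absence < 0).any():
            raise ValidationError("contingency counts must be non-negative")

    @property
    def counts(self) -> np.ndarray:
        return np.vstack([self.presence, self.absence])

    @property
    def column_totals(self) -> np.ndarray:
        return self.presence + self.absence


@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    df: int
    p_raw: float
    expected_min: float
    degenerate: bool = False


@dataclass(frozen=True)
class ScoreTestResult:
    statistic: float
    df: int
    p_raw: float
    degenerate: bool = False


@dataclass(frozen=True)
class AssociationResult:
    feature: str
    statistic: float
    df: int
    p_raw: float
    p_adj: float
    direction: str
    expected_min: float
    degenerate: bool


@dataclass(frozen=True)
class StageProfile:
    gene: str
    proportions: dict[str, float]  # carriers / stage total, per observed stage
    n_per_stage: dict[str, int]


def build_contingency(
    profiles: Sequence[ParticipantProfile],
    gene: str,
    states: Sequence[str] = DISEASE_STATES,
) -> ContingencyTable:
    """Tally carriers and non-carriers of ``gene`` per disease state."""
    presence = []
    absence = []
    for state in states:
        members = [p for p in profiles if p.disease_state == state]
        if not members:
            raise ValidationError(
                f"disease state {state!r} has zero participants; the "
                "state-association test is undefined"
            )
        carriers = sum(1 for p in members if p.gene_presence.get(gene, False))
        presence.append(carriers)
        absence.append(len(members) - carriers)
    return ContingencyTable(tuple(states), np.array(presence), np.array(absence))


def chi_squared_test(table: ContingencyTable) -> ChiSquaredResult:
    """Pearson chi-squared test of independence on a 2 x k table.

    No continuity correction. df = k - 1. A zero row margin (gene absent
    everywhere, or present in everyone) makes the test degenerate: the result
    is statistic 0, p 1, with the degenerate flag set. The smallest expected
    cell count is reported so callers can judge the asymptotic approximation.
    """
    counts = table.counts.astype(float)
    col_tot = counts.sum(axis=0)
    if (col_tot <= 0).any() or counts.sum() <= 0:
        raise ValidationError("every state column must have a positive total")
    row_tot = counts.sum(axis=1)
    df = len(table.states) - 1
    if (row_tot == 0).any():
        return ChiSquaredResult(0.0, df, 1.0, 0.0, degenerate=True)
    expected = np.outer(row_tot, col_tot) / counts.sum()
    statistic = float(((counts - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df))
    return ChiSquaredResult(statistic, df, p, float(expected.min()))


def benjamini_hochberg(p_raw: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_raw), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def stage_score_test(
    presence: Sequence[bool], stage: Sequence[int | str]
) -> ScoreTestResult:
    """Rao score test for a carriage trend across stages.

    ``stage`` accepts integer codes or stage labels I-IV (coded 1-4). The
    statistic is the efficient score U^2/V at the intercept-only binomial
    logistic fit; p from chi-squared with 1 df. All-carrier or no-carrier
    input is degenerate (statistic 0, p 1).
    """
    y = np.asarray(presence, dtype=float)
    x = np.asarray([_STAGE_CODES.get(s, s) for s in stage], dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValidationError("presence and stage vectors must align")
    if len(np.unique(x)) < 2:
        raise ValidationError("need >= 2 distinct stages for a trend test")
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        return ScoreTestResult(0.0, 1, 1.0, degenerate=True)
    u = float(np.sum(x * (y - ybar)))
    v = float(ybar * (1 - ybar) * np.sum((x - x.mean()) ** 2))
    statistic = u * u / v
    return ScoreTestResult(statistic, 1, float(stats.chi2.sf(statistic, 1)))


def stage_profile(
    profiles: Sequence[ParticipantProfile],
    gene: str,
    states: Sequence[str] = ("carcinoma",),
) -> StageProfile:
    """Carrier proportion per stage, over staged participants in ``states``.

    Unstaged participants are excluded from denominators; stages with zero
    participants are omitted rather than reported as zero.
    """
    staged = [
        p
        for p in profiles
        if p.disease_state in states and p.stage in _STAGE_CODES
    ]
    proportions: dict[str, float] = {}
    n_per_stage: dict[str, int] = {}
    for stage_label in _STAGE_CODES:
        members = [p for p in staged if p.stage == stage_label]
        if not members:
            continue
        carriers = sum(1 for p in members if p.gene_presence.get(gene, False))
        n_per_stage[stage_label] = len(members)
        proportions[stage_label] = carriers / len(members)
    return StageProfile(gene=gene, proportions=proportions, n_per_stage=n_per_stage)


def _direction(table: ContingencyTable) -> str:
    props = np.where(
        table.column_totals > 0, table.presence / table.column_totals, 0.0
    )
    best = props.max()
    candidates = [s for s, p in zip(table.states, props) if p == best]
    # ties break toward the more advanced disease state
    return max(candidates, key=lambda s: _STATE_ADVANCEMENT.get(s, -1))


def associate_all(
    profiles: Sequence[ParticipantProfile],
    genes: Sequence[str],
    extra_features: Mapping[str, Mapping[str, bool]] | None = None,
    states: Sequence[str] = DISEASE_STATES,
) -> list[AssociationResult]:
    """Chi-squared state association for every feature, BH-adjusted in one batch.

    ``extra_features`` maps a feature name (e.g. a pathway) to per-participant
    presence, letting pathway-completeness calls join the same BH family as
    the genes. Direction is the state with maximal carrier proportion.
    """
    features: list[tuple[str, ContingencyTable]] = []
    for gene in genes:
        features.append((gene, build_contingency(profiles, gene, states)))
    if extra_features:
        state_of = {p.participant_id: p.disease_state for p in profiles}
        for name, presence_map in extra_features.items():
            pres = np.zeros(len(states), dtype=np.int64)
            absn = np.zeros(len(states), dtype=np.int64)
            idx = {s: i for i, s in enumerate(states)}
            for p in profiles:
                i = idx[state_of[p.participant_id]]
                if presence_map.get(p.participant_id, False):
                    pres[i] += 1
                else:
                    absn[i] += 1
            features.append((name, ContingencyTable(tuple(states), pres, absn)))

    if not features:
        return []
    tests = [(name, chi_squared_test(t), t) for name, t in features]
    p_adj = benjamini_hochberg([r.p_raw for _, r, _ in tests])
    return [
        AssociationResult(
            feature=name,
            statistic=r.statistic,
            df=r.df,
            p_raw=r.p_raw,
            p_adj=float(q),
            direction=_direction(t),
            expected_min=r.expected_min,
            degenerate=r.degenerate,
        )
        for (name, r, t), q in zip(tests, p_adj)
    ]


def significance_marker(p_adj: float) -> str:
    """Asterisk markers at the conventional 0.05 / 0.01 / 0.001 levels."""
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return ""


def association_table(results: Sequence[AssociationResult]):
    """Tidy TSV-ready frame of association results with asterisk markers."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "statistic": r.statistic,
                "df": r.df,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "direction": r.direction,
                "expected_min": r.expected_min,
                "degenerate": r.degenerate,
                "significance": significance_marker(r.p_adj),
            }
            for r in results
        ]
    )
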