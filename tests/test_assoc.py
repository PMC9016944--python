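"""Association statistics: chi-squared, BH, Rao score test, stage profiles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from gutsulfur.assoc import (
    ContingencyTable,
    associate_all,
    benjamini_hochberg,
    build_contingency,
    chi_squared_test,
    significance_marker,
    stage_profile,
    stage_score_test,
)
from gutsulfur.errors import ValidationError
from gutsulfur.presence import ParticipantProfile


def profile(pid, state, present, stage=None, gene="mgl"):
    return ParticipantProfile(
        participant_id=pid,
        disease_state=state,
        stage=stage,
        gene_presence={gene: present},
        mags_with_gene={gene: int(present)},
        n_mags=1,
    )


def table(presence, absence):
    return ContingencyTable(
        ("healthy", "adenoma", "carcinoma"), np.array(presence), np.array(absence)
    )


def permutation_pvalue(presence, states, n_per_state, rng, n_shuffles=100_000):
    """Monte-Carlo permutation p for the 2x3 Pearson statistic: shuffle the
    carrier labels across participants with state margins fixed."""
    y = np.asarray(presence, dtype=float)
    n_tot = len(y)
    onehot = np.eye(3)[states]
    row1 = y.sum()
    col = np.full(3, float(n_per_state))
    e1 = row1 * col / n_tot
    e0 = (n_tot - row1) * col / n_tot
    pres = np.array([int(y[states == s].sum()) for s in range(3)])
    observed = chi_squared_test(table(list(pres), list(n_per_state - pres)))
    exceed = 0
    chunk = 20_000
    for start in range(0, n_shuffles, chunk):
        size = min(chunk, n_shuffles - start)
        perm = rng.permuted(np.tile(y, (size, 1)), axis=1)
        o1 = perm @ onehot
        o0 = n_per_state - o1
        null = (((o1 - e1) ** 2) / e1 + ((o0 - e0) ** 2) / e0).sum(axis=1)
        exceed += int((null >= observed.statistic - 1e-9).sum())
    return exceed / n_shuffles


class TestContingency:
    def test_tally(self):
        profiles = [
            profile("p1", "healthy", True),
            profile("p2", "adenoma", True),
            profile("p3", "carcinoma", True),
        ]
        t = build_contingency(profiles, "mgl")
        assert list(t.presence) == [1, 1, 1]
        assert list(t.absence) == [0, 0, 0]

    def test_no_carriers(self):
        profiles = [profile(f"p{i}", s, False) for i, s in
                    enumerate(["healthy", "adenoma", "carcinoma"])]
        assert list(build_contingency(profiles, "mgl").presence) == [0, 0, 0]

    def test_empty_state_is_error(self):
        profiles = [profile("p1", "healthy", True), profile("p2", "adenoma", False)]
        with pytest.raises(ValidationError, match="carcinoma"):
            build_contingency(profiles, "mgl")

    def test_matches_brute_force_scan(self, rng):
        states = ["healthy", "adenoma", "carcinoma"]
        profiles = [
            profile(f"p{i}", states[int(rng.integers(3))], bool(rng.integers(2)))
            for i in range(120)
        ]
        t = build_contingency(profiles, "mgl")
        for j, s in enumerate(states):
            carriers = sum(
                1 for p in profiles if p.disease_state == s and p.gene_presence["mgl"]
            )
            n = sum(1 for p in profiles if p.disease_state == s)
            assert t.presence[j] == carriers
            assert t.column_totals[j] == n


class TestChiSquared:
    def test_perfect_independence(self):
        r = chi_squared_test(table([10, 10, 10], [20, 20, 20]))
        assert r.statistic == pytest.approx(0.0)
        assert r.p_raw == pytest.approx(1.0)

    def test_derived_example_statistic_21(self):
        r = chi_squared_test(table([20, 30, 50], [80, 70, 50]))
        assert r.statistic == pytest.approx(21.0)
        assert r.df == 2
        assert r.p_raw == pytest.approx(np.exp(-10.5), rel=1e-12)
        assert r.expected_min == pytest.approx(100 * 100 / 300)

    def test_zero_row_margin_degenerate(self):
        r = chi_squared_test(table([0, 0, 0], [10, 10, 10]))
        assert r.degenerate
        assert r.statistic == 0.0 and r.p_raw == 1.0

    def test_zero_column_total_raises(self):
        with pytest.raises(ValidationError):
            chi_squared_test(table([0, 5, 5], [0, 5, 5]))

    def test_column_permutation_invariance(self, rng):
        pres = rng.integers(1, 30, 3)
        absn = rng.integers(1, 30, 3)
        r1 = chi_squared_test(table(list(pres), list(absn)))
        perm = [2, 0, 1]
        r2 = chi_squared_test(table(list(pres[perm]), list(absn[perm])))
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_matches_scipy_chi2_contingency(self, rng):
        for _ in range(50):
            pres = rng.integers(1, 40, 3)
            absn = rng.integers(1, 40, 3)
            r = chi_squared_test(table(list(pres), list(absn)))
            ref = stats.chi2_contingency(np.vstack([pres, absn]), correction=False)
            assert r.statistic == pytest.approx(ref.statistic)
            assert r.p_raw == pytest.approx(ref.pvalue)

    def test_matches_permutation_oracle(self, rng):
        """Chi-squared tail agrees with a label-permutation null within
        Monte-Carlo + asymptotic-approximation error."""
        n_per_state = 100
        states = np.repeat(np.arange(3), n_per_state)
        rates = np.array([0.4, 0.5, 0.6])
        presence = rng.random(3 * n_per_state) < rates[states]
        pres = [int(presence[states == s].sum()) for s in range(3)]
        absn = [n_per_state - p for p in pres]
        observed = chi_squared_test(table(pres, absn))
        p_perm = permutation_pvalue(presence, states, n_per_state, rng)
        assert abs(p_perm - observed.p_raw) < 0.02


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.03]) == pytest.approx([0.03])

    def test_hand_derived_example(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.04, 0.05])
        assert adj == pytest.approx([0.04, 0.04, 0.05, 0.05])

    def test_all_equal_unchanged(self):
        assert benjamini_hochberg([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.5, 1.5])

    @given(st.integers(0, 2**32 - 1))
    def test_order_invariance_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 50))
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        perm = rng.permutation(len(p))
        assert benjamini_hochberg(p[perm]) == pytest.approx(adj[perm])

    def test_step_up_definition_oracle(self, rng):
        """Matches q_i = min_{j>=i} m p_(j)/j computed by hand."""
        for _ in range(200):
            p = rng.random(rng.integers(1, 20))
            m = len(p)
            order = np.argsort(p)
            q_sorted = np.minimum.accumulate(
                (m * p[order] / np.arange(1, m + 1))[::-1]
            )[::-1]
            expected = np.empty(m)
            expected[order] = np.clip(q_sorted, 0, 1)
            assert benjamini_hochberg(p) == pytest.approx(expected)


class TestStageScoreTest:
    def test_derived_example_statistic_8(self):
        presence, stage = [], []
        for s, carriers in zip([1, 2, 3, 4], [2, 4, 6, 8]):
            presence += [True] * carriers + [False] * (10 - carriers)
            stage += [s] * 10
        r = stage_score_test(presence, stage)
        assert r.statistic == pytest.approx(8.0)
        assert r.df == 1
        assert r.p_raw == pytest.approx(0.004677, abs=1e-5)

    def test_equal_carriage_statistic_zero(self):
        presence = [True, False] * 4
        stage = [1, 1, 2, 2, 3, 3, 4, 4]
        r = stage_score_test(presence, stage)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_raw == pytest.approx(1.0)

    def test_all_identical_presence_degenerate(self):
        r = stage_score_test([True] * 8, [1, 1, 2, 2, 3, 3, 4, 4])
        assert r.degenerate and r.p_raw == 1.0

    def test_stage_labels_accepted(self):
        r1 = stage_score_test([True, False, True, False], ["I", "II", "III", "IV"])
        r2 = stage_score_test([True, False, True, False], [1, 2, 3, 4])
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_single_stage_rejected(self):
        with pytest.raises(ValidationError):
            stage_score_test([True, False], [2, 2])

    def test_matches_statsmodels_score_oracle(self, rng):
        """Closed form agrees with the GLM likelihood-based score test."""
        import statsmodels.api as sm

        for _ in range(100):
            n = int(rng.integers(20, 80))
            x = rng.integers(1, 5, size=n).astype(float)
            if len(np.unique(x)) < 2:
                continue
            logit_p = -0.5 + 0.0 * x
            y = (rng.random(n) < 1 / (1 + np.exp(-logit_p))).astype(float)
            if y.mean() in (0.0, 1.0):
                continue
            r = stage_score_test(y.astype(bool), x.astype(int))
            null_fit = sm.GLM(y, np.ones((n, 1)), family=sm.families.Binomial()).fit()
            stat, _pval, _df = null_fit.score_test(exog_extra=x.reshape(-1, 1))
            assert r.statistic == pytest.approx(float(np.ravel(stat)[0]), abs=1e-6)


class TestStageProfile:
    def test_proportion_per_stage(self):
        profiles = [
            profile(f"p{i}", "carcinoma", i < 3, stage="II") for i in range(6)
        ]
        sp = stage_profile(profiles, "mgl")
        assert sp.proportions["II"] == pytest.approx(0.5)
        assert sp.n_per_stage["II"] == 6

    def test_empty_stage_omitted_not_zero(self):
        profiles = [profile("p1", "carcinoma", True, stage="I")]
        sp = stage_profile(profiles, "mgl")
        assert "IV" not in sp.proportions

    def test_unstaged_excluded_from_denominator(self):
        profiles = [
            profile("p1", "carcinoma", True, stage="I"),
            profile("p2", "carcinoma", False, stage=None),
        ]
        sp = stage_profile(profiles, "mgl")
        assert sp.n_per_stage["I"] == 1


class TestAssociateAll:
    def make_cohort(self, rng, n=60, rate=0.4):
        states = ["healthy", "adenoma", "carcinoma"]
        return [
            profile(f"p{i}", states[i % 3], bool(rng.random() < rate))
            for i in range(n)
        ]

    def test_empty_feature_list(self):
        assert associate_all([], []) == []

    def test_bh_applied_in_single_batch(self, rng):
        profiles = []
        states = ["healthy", "adenoma", "carcinoma"]
        genes = [f"g{j}" for j in range(5)]
        for i in range(90):
            presence = {g: bool(rng.random() < 0.4) for g in genes}
            profiles.append(
                ParticipantProfile(
                    participant_id=f"p{i}",
                    disease_state=states[i % 3],
                    stage=None,
                    gene_presence=presence,
                    mags_with_gene={g: int(v) for g, v in presence.items()},
                    n_mags=1,
                )
            )
        results = associate_all(profiles, genes)
        expected = benjamini_hochberg([r.p_raw for r in results])
        assert [r.p_adj for r in results] == pytest.approx(list(expected))
        assert all(r.p_adj >= r.p_raw - 1e-12 for r in results)

    def test_direction_is_max_proportion_state(self):
        profiles = (
            [profile(f"h{i}", "healthy", i < 1) for i in range(10)]
            + [profile(f"a{i}", "adenoma", i < 2) for i in range(10)]
            + [profile(f"c{i}", "carcinoma", i < 8) for i in range(10)]
        )
        (r,) = associate_all(profiles, ["mgl"])
        assert r.direction == "carcinoma"

    def test_direction_tie_breaks_toward_advanced_state(self):
        profiles = (
            [profile(f"h{i}", "healthy", i < 5) for i in range(10)]
            + [profile(f"a{i}", "adenoma", i < 5) for i in range(10)]
            + [profile(f"c{i}", "carcinoma", i < 5) for i in range(10)]
        )
        (r,) = associate_all(profiles, ["mgl"])
        assert r.direction == "carcinoma"

    def test_significance_markers(self):
        assert significance_marker(0.04) == "*"
        assert significance_marker(0.005) == "**"
        assert significance_marker(5e-4) == "***"
        assert significance_marker(0.2) == ""
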