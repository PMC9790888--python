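"""Scores, rank tests and the Mann-Whitney test for equivalence."""

import numpy as np
import pytest
from scipy import stats as sps

from extenderopt.equivstats import (
    EquivalenceConfig,
    build_score_table,
    dunn_posthoc,
    equivalence_decision,
    fligner_killeen,
    generation_summary,
    kruskal_wallis,
    mann_whitney_equivalence,
    percent_improvement,
    relative_total_motility,
    w_plus,
)
from extenderopt.exceptions import DataError
from extenderopt.virtual_lab import make_study_fixture

# ---------------------------------------------------------------------------
# independent textbook-formula oracles (kept free of scipy's implementations)
# ---------------------------------------------------------------------------


def _ranks(pooled):
    """Average ranks via argsort only (independent of scipy.rankdata)."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def oracle_kruskal(groups):
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = _ranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    return h / correction


def oracle_fligner(x, y):
    centered = [np.abs(np.asarray(g) - np.median(g)) for g in (x, y)]
    pooled = np.concatenate(centered)
    n_total = len(pooled)
    ranks = _ranks(pooled)
    a = sps.norm.ppf(0.5 + ranks / (2.0 * (n_total + 1)))
    abar = a.mean()
    v = np.sum((a - abar) ** 2) / (n_total - 1)
    stat, start = 0.0, 0
    for g in centered:
        ai = a[start : start + len(g)]
        stat += len(g) * (ai.mean() - abar) ** 2
        start += len(g)
    return stat / v


def oracle_w_plus(x, y):
    total = 0.0
    for xi in x:
        for yj in y:
            total += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
    return total / (len(x) * len(y))


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------


class TestScores:
    @pytest.mark.parametrize(
        "treatment,control,expected",
        [(60.0, 60.0, 1.0), (68.3, 65.3, 68.3 / 65.3)],
    )
    def test_relative_total_motility(self, treatment, control, expected):
        assert relative_total_motility(treatment, control) == pytest.approx(expected)

    def test_zero_control_is_an_error(self):
        with pytest.raises(DataError):
            relative_total_motility(50.0, 0.0)

    def test_percent_improvement_from_validation_means(self):
        assert percent_improvement(31.9, 25.2) == pytest.approx(26.6, abs=0.05)
        assert percent_improvement(50.0, 50.0) == 0.0

    def test_score_table_aggregates_replicates(self):
        _, motility = make_study_fixture(2, seed=1)
        table = build_score_table(motility, metric="relative")
        assert len(table) == 2 * 8 * 4
        first = table.iloc[0]
        assert first["relative_total_motility"] == pytest.approx(
            first["total_motility"] / first["control_motility"]
        )

    def test_generation_summary_median_and_sd(self):
        import pandas as pd

        records = pd.DataFrame(
            {
                "generation": [1, 1, 1, 2],
                "formulation_id": ["a", "b", "c", "d"],
                "bull_id": ["x", "x", "x", "x"],
                "replicate": [1, 1, 1, 1],
                "total_motility": [40.0, 50.0, 60.0, 55.0],
                "control_motility": [60.0] * 4,
            }
        )
        out = generation_summary(records, metric="total")
        g1 = out[out["generation"] == 1].iloc[0]
        assert g1["median"] == 50.0
        assert g1["sd"] == pytest.approx(np.std([40, 50, 60], ddof=1))
        g2 = out[out["generation"] == 2].iloc[0]
        assert (g2["median"], g2["sd"]) == (55.0, 0.0)

    def test_summary_matches_sort_based_median_on_random_fixtures(self, rng):
        _, motility = make_study_fixture(3, seed=8)
        table = build_score_table(motility, metric="total")
        out = generation_summary(motility, metric="total")
        for g in (1, 2, 3):
            values = np.sort(table[table["generation"] == g]["score"].to_numpy())
            mid = len(values) // 2
            manual = (
                values[mid]
                if len(values) % 2
                else 0.5 * (values[mid - 1] + values[mid])
            )
            assert float(
                out.loc[out["generation"] == g, "median"].iloc[0]
            ) == pytest.approx(manual)


# ---------------------------------------------------------------------------
# rank tests vs oracles
# ---------------------------------------------------------------------------


class TestRankTests:
    def test_identical_groups_are_null(self):
        g = np.array([50.0, 55.0, 60.0])
        result = kruskal_wallis([g, g.copy()])
        assert result.statistic == 0.0 and result.p_value == 1.0

    def test_three_groups_report_df_2(self, rng):
        result = kruskal_wallis([rng.normal(size=10) for _ in range(3)])
        assert result.df == 2

    def test_kruskal_matches_textbook_formula(self, rng):
        for _ in range(100):
            groups = [
                np.round(rng.uniform(0, 100, rng.integers(3, 12)), 1)
                for _ in range(rng.integers(2, 5))
            ]
            if all(np.ptp(np.concatenate(groups)) == 0 for _ in [0]):
                continue
            result = kruskal_wallis(groups)
            assert result.statistic == pytest.approx(
                oracle_kruskal(groups), abs=1e-10
            )

    def test_fligner_matches_textbook_formula(self, rng):
        for _ in range(100):
            x = rng.normal(0, 1, rng.integers(5, 20))
            y = rng.normal(0, rng.uniform(0.5, 3), rng.integers(5, 20))
            result = fligner_killeen(x, y)
            assert result.df == 1
            assert result.statistic == pytest.approx(oracle_fligner(x, y), abs=1e-10)

    def test_fligner_null_case_rejects_at_nominal_rate(self, rng):
        """Equal spreads (location shift only): rejections stay near 5 %."""
        rejections = sum(
            fligner_killeen(rng.normal(50, 5, 40), rng.normal(60, 5, 40)).p_value
            < 0.05
            for _ in range(60)
        )
        assert rejections <= 9  # 3 expected under the null

    def test_fligner_detects_scale_ratio_five(self, rng):
        """Power check: sd ratio 5 at n=32 per group is detected reliably."""
        detected = sum(
            fligner_killeen(
                rng.normal(50, 2, 32), rng.normal(50, 10, 32)
            ).p_value
            < 0.05
            for _ in range(50)
        )
        assert detected >= 45

    def test_constant_samples_rejected(self):
        with pytest.raises(DataError):
            fligner_killeen(np.ones(5), np.ones(5))

    def test_dunn_identical_groups_near_one(self):
        g = np.arange(10.0)
        results = dunn_posthoc([g, g.copy(), g.copy()])
        assert len(results) == 3  # all pairs of 3 groups
        assert all(r.p_value > 0.99 for r in results)

    def test_dunn_matches_independent_formula(self, rng):
        """z_ij from mean ranks with the pooled tie correction, re-derived."""
        for _ in range(100):
            groups = [
                np.round(rng.uniform(0, 50, rng.integers(4, 10)), 0)
                for _ in range(3)
            ]
            pooled = np.concatenate(groups)
            ranks = _ranks(pooled)
            n_total = len(pooled)
            _, counts = np.unique(pooled, return_counts=True)
            tie = np.sum(counts**3 - counts) / (12.0 * (n_total - 1))
            base = n_total * (n_total + 1) / 12.0 - tie
            sizes = [len(g) for g in groups]
            means, start = [], 0
            for g in groups:
                means.append(ranks[start : start + len(g)].mean())
                start += len(g)
            expected = []
            for i in range(3):
                for j in range(i + 1, 3):
                    z = (means[i] - means[j]) / np.sqrt(
                        base * (1 / sizes[i] + 1 / sizes[j])
                    )
                    expected.append(z**2)
            got = [r.statistic for r in dunn_posthoc(groups, adjust="none")]
            assert got == pytest.approx(expected, abs=1e-10)

    def test_dunn_holm_adjustment_monotone(self, rng):
        groups = [rng.normal(loc, 1, 12) for loc in (0, 0.5, 3)]
        raw = dunn_posthoc(groups, adjust="none")
        holm = dunn_posthoc(groups, adjust="holm")
        for r, h in zip(raw, holm):
            assert h.p_value >= r.p_value - 1e-15


# ---------------------------------------------------------------------------
# Mann-Whitney equivalence
# ---------------------------------------------------------------------------


class TestWPlus:
    def test_complete_separation(self):
        assert w_plus([10, 11, 12], [1, 2, 3]) == 1.0

    def test_interleaved_example(self):
        assert w_plus([1, 3], [2, 4]) == 0.25

    def test_matches_pair_enumeration_on_random_fixtures(self, rng):
        for _ in range(200):
            m, n = rng.integers(2, 15, size=2)
            x = np.round(rng.uniform(0, 10, m), 0)  # force ties
            y = np.round(rng.uniform(0, 10, n), 0)
            assert w_plus(x, y) == pytest.approx(oracle_w_plus(x, y), abs=1e-12)

    def test_antisymmetry_without_ties(self, rng):
        for _ in range(50):
            x = rng.normal(size=8)
            y = rng.normal(size=11)
            assert w_plus(x, y) + w_plus(y, x) == pytest.approx(1.0, abs=1e-12)


# every (W+, sigma-hat, CRIT, eps) tuple reported for the campaign's
# generation-level comparisons; the decision rule must return REJ = 0 for all
REPORTED_TUPLES = [
    (0.56, 0.08, 0.31, 0.15),  # gen 6: experimental vs network
    (0.63, 0.07, 0.57, 0.10),  # gen 6: experimental vs GP
    (0.61, 0.08, 0.31, 0.10),  # gen 6: network vs GP
    (0.30, 0.15, 0.10, 0.15),  # gen 17 vs control
    (0.73, 0.07, 0.44, 0.15),  # gen 21 vs control
    (0.44, 0.07, 0.52, 0.15),  # gen 19 vs gen 20
    (0.43, 0.07, 0.51, 0.10),  # gen 20 vs gen 21
    (0.34, 0.07, 0.63, 0.15),  # gen 19 vs gen 21
    (0.60, 0.07, 0.10, 0.15),  # total vs relative metric
]


class TestEquivalence:
    @pytest.mark.parametrize("w,sigma,crit,eps", REPORTED_TUPLES)
    def test_reported_summaries_all_fail_to_establish_equivalence(
        self, w, sigma, crit, eps
    ):
        assert equivalence_decision(w, sigma, crit, eps, eps) == 0

    def test_decision_rejects_inside_band(self):
        assert equivalence_decision(0.51, 0.08, 0.31) == 1

    def test_well_separated_samples_never_equivalent(self, rng):
        x = rng.normal(60, 8, 20)
        y = rng.normal(45, 8, 20)
        result = mann_whitney_equivalence(x, y)
        assert result.W_plus > 0.8 and result.REJ == 0

    def test_complete_separation_is_degenerate(self, rng):
        """W+ = 1 exactly leaves no variance to standardize against."""
        with pytest.raises(DataError):
            mann_whitney_equivalence([10.0, 11.0, 12.0], [1.0, 2.0, 3.0])

    def test_sigma_matches_u_statistic_bruteforce(self, rng):
        """Variance estimate vs direct enumeration of the covariance pieces."""
        x = rng.normal(50, 10, 9)
        y = rng.normal(52, 10, 7)
        m, n = len(x), len(y)
        h = lambda a, b: 1.0 if a > b else (0.5 if a == b else 0.0)
        w = np.mean([[h(a, b) for b in y] for a in x])
        pi_xyy = np.mean(
            [
                h(a, y[j]) * h(a, y[jp])
                for a in x
                for j in range(n)
                for jp in range(n)
                if j != jp
            ]
        )
        pi_xxy = np.mean(
            [
                h(x[i], b) * h(x[ip], b)
                for b in y
                for i in range(m)
                for ip in range(m)
                if i != ip
            ]
        )
        var = (
            w * (1 - w) + (n - 1) * (pi_xyy - w**2) + (m - 1) * (pi_xxy - w**2)
        ) / (m * n)
        result = mann_whitney_equivalence(x, y)
        assert result.W_plus == pytest.approx(w, abs=1e-12)
        assert result.sigma_hat == pytest.approx(np.sqrt(var), abs=1e-12)

    def test_crit_is_noncentral_chi_square_quantile(self, rng):
        x = rng.normal(50, 8, 32)
        y = rng.normal(50, 8, 32)
        result = mann_whitney_equivalence(x, y)
        nc = (0.15 / result.sigma_hat) ** 2
        assert result.CRIT == pytest.approx(
            np.sqrt(sps.ncx2.ppf(0.05, 1, nc)), abs=1e-12
        )

    def test_equivalent_samples_are_detected(self, rng):
        """Two draws from one distribution at n=64 usually establish equivalence."""
        hits = sum(
            mann_whitney_equivalence(
                rng.normal(60, 5, 64), rng.normal(60, 5, 64)
            ).REJ
            for _ in range(40)
        )
        assert hits >= 20

    def test_type_one_error_at_margin(self, rng):
        """At P(X>Y) = 0.65 (the margin) the rejection rate stays near alpha."""
        n_sims = 2000
        delta = np.sqrt(2.0) * sps.norm.ppf(0.65)
        rejections = 0
        for _ in range(n_sims):
            x = rng.normal(delta, 1.0, 32)
            y = rng.normal(0.0, 1.0, 32)
            rejections += mann_whitney_equivalence(x, y).REJ
        rate = rejections / n_sims
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sims)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(DataError):
            mann_whitney_equivalence([5.0, 5.0, 5.0], [1.0, 1.0, 1.0])

    def test_margin_config_validation(self):
        with pytest.raises(DataError):
            EquivalenceConfig(eps1=0.6)
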