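"""Median split, KM, logrank, univariate Cox and batch association."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from luadsig.simulate import SimulationConfig, gen_survival_cohort
from luadsig.survival import (
    SurvivalAssociation,
    SurvivalError,
    batch_associate,
    cox_univariate,
    km_estimate,
    logrank_test,
    median_split,
    summarize_probes,
)


class TestMedianSplit:
    def test_symmetric(self):
        high, low = median_split({"a": 1, "b": 2, "c": 3, "d": 4})
        assert set(low) == {"a", "b"} and set(high) == {"c", "d"}

    def test_ties_go_low(self):
        high, low = median_split({"a": 1, "b": 2, "c": 2, "d": 3})
        assert set(low) == {"a", "b", "c"} and set(high) == {"d"}

    def test_two_patients(self):
        high, low = median_split({"a": 5, "b": 9})
        assert low == ["a"] and high == ["b"]

    def test_degenerate_identical_values(self):
        with pytest.raises(SurvivalError, match="identical"):
            median_split({"a": 1.0, "b": 1.0, "c": 1.0})

    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=2,
                    max_size=30, unique=True))
    def test_distinct_values_split_near_evenly(self, values):
        ids = [f"p{i}" for i in range(len(values))]
        high, low = median_split(dict(zip(ids, values)))
        assert abs(len(high) - len(low)) <= 1
        assert set(high) | set(low) == set(ids)


class TestKaplanMeier:
    def test_two_events_product_limit(self):
        km = km_estimate([1, 2], [True, True])
        assert km.at(0.5) == 1.0
        assert km.at(1) == pytest.approx(0.5)
        assert km.at(2) == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        km = km_estimate([1, 2, 3], [False, False, False])
        assert km.at(3) == 1.0

    def test_censoring_leaves_risk_set(self):
        # event at 3 among 2 at risk; the censored subject never events
        km = km_estimate([3, 5], [True, False])
        assert km.at(3) == pytest.approx(0.5)
        assert km.at(4.9) == pytest.approx(0.5)

    def test_empty_errors(self):
        with pytest.raises(SurvivalError):
            km_estimate([], [])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, size=40)
        km = km_estimate(t, np.ones(40, bool))
        for q in np.quantile(t, [0.2, 0.5, 0.8]):
            assert km.at(q) == pytest.approx(np.mean(t > q), abs=1e-12)

    def test_non_increasing(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, size=60)
        e = rng.random(60) < 0.7
        km = km_estimate(t, e)
        assert np.all(np.diff(km.survival) <= 1e-12)


def _lr_stat(t, e, g):
    """Brute-force O/E/V logrank table (hypergeometric moments)."""
    o_minus_e = v = 0.0
    for tj in np.unique(t[e]):
        at = t >= tj
        d = e & (t == tj)
        n, n1 = at.sum(), (at & (g == 1)).sum()
        dj, d1 = d.sum(), (d & (g == 1)).sum()
        o_minus_e += d1 - dj * n1 / n
        if n > 1:
            v += dj * (n - dj) / (n - 1) * n1 * (n - n1) / n**2
    return o_minus_e**2 / v


class TestLogrank:
    def test_identical_groups_stat_zero_p_one(self):
        t, e = [1, 2, 3], [1, 1, 0]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_table(self):
        # A: events at 1, 2; B: events at 3, 4; O_A - E_A = 7/6, V = 17/36
        stat, p = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert stat == pytest.approx((7 / 6) ** 2 / (17 / 36), rel=1e-9)
        assert p == pytest.approx(0.08955, abs=1e-4)

    def test_matches_bruteforce_moment_table(self):
        rng = np.random.default_rng(4)
        t = np.ceil(rng.exponential(8, 30))
        e = rng.random(30) < 0.8
        g = rng.integers(0, 2, 30)
        stat, _ = logrank_test(t[g == 1], e[g == 1], t[g == 0], e[g == 0])
        assert stat == pytest.approx(_lr_stat(t, e, g), rel=1e-9)

    def test_label_swap_invariant(self):
        a = ([1, 4, 6], [1, 1, 0])
        b = ([2, 3, 9], [1, 0, 1])
        assert logrank_test(*a, *b) == pytest.approx(logrank_test(*b, *a))

    def test_no_events_errors(self):
        with pytest.raises(SurvivalError, match="no events"):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])

    def test_p_within_monte_carlo_error_of_permutation_null(self):
        # 12-patient toy; 10^4 label permutations, fixed seed; tolerance
        # covers MC error plus the chi-square approximation at this n
        t = np.array([2, 4, 5, 7, 8, 9, 11, 13, 14, 16, 18, 21], float)
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 1, 1, 0], bool)
        g = np.array([0, 0, 1, 0, 1, 0, 1, 1, 0, 1, 1, 1])
        stat0, p0 = logrank_test(t[g == 1], e[g == 1], t[g == 0], e[g == 0])
        rng = np.random.default_rng(5)
        exceed = sum(
            _lr_stat(t, e, rng.permutation(g)) >= stat0 - 1e-12 for _ in range(10_000)
        )
        assert abs(p0 - exceed / 10_000) < 0.06


class TestCoxUnivariate:
    def test_three_patient_closed_form(self):
        # score equation reduces to 2 x^2 = 1 with x = hr; no ties so
        # Efron and Breslow agree exactly
        for ties in ("efron", "breslow"):
            r = cox_univariate([1, 0, 1], [1, 2, 3], [1, 1, 1], ties=ties)
            assert r.hr == pytest.approx(1 / np.sqrt(2), rel=1e-8)
            assert r.ci_low < r.hr < r.ci_high

    def test_label_permutation_of_one_sample_gives_hr_near_one(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(10, 400)
        g = np.zeros(400, int)
        g[rng.permutation(400)[:200]] = 1  # labels carry no information
        r = cox_univariate(g, t, np.ones(400, bool))
        # null logHR has SE ~= sqrt(4/400) = 0.1; 3 sigma band around 0
        assert abs(np.log(r.hr)) < 0.3

    def test_label_swap_reciprocal(self):
        rng = np.random.default_rng(7)
        t = np.ceil(rng.exponential(10, 120))
        e = rng.random(120) < 0.8
        g = rng.integers(0, 2, 120)
        r = cox_univariate(g, t, e)
        r_swap = cox_univariate(1 - g, t, e)
        assert r_swap.hr == pytest.approx(1 / r.hr, rel=1e-6)

    def test_matches_lifelines_efron(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n = 120
        g = rng.integers(0, 2, n)
        t = np.ceil(rng.exponential(10 * np.exp(-0.5 * g)))
        e = rng.random(n) < 0.8
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e.astype(int), "z": g}), "t", "e"
        )
        r = cox_univariate(g, t, e)
        assert r.beta == pytest.approx(float(cph.params_["z"]), abs=1e-6)
        assert r.se == pytest.approx(float(cph.standard_errors_["z"]), abs=1e-6)

    def test_breslow_close_to_efron_with_light_ties(self):
        rng = np.random.default_rng(8)
        t = np.ceil(rng.exponential(5, 150))
        e = rng.random(150) < 0.9
        g = rng.integers(0, 2, 150)
        be = cox_univariate(g, t, e, ties="breslow")
        ef = cox_univariate(g, t, e, ties="efron")
        assert be.hr == pytest.approx(ef.hr, rel=0.1)
        assert be.hr != ef.hr  # tie corrections do differ

    def test_monotone_likelihood_flagged_with_unbounded_ci(self):
        r = cox_univariate([1, 0], [1, 2], [1, 1])
        assert r.monotone
        assert (r.ci_low, r.ci_high) == (0.0, np.inf)

    def test_group_without_events_errors(self):
        with pytest.raises(SurvivalError, match="at least one event"):
            cox_univariate([0, 0, 1], [1, 2, 3], [1, 1, 0])

    def test_planted_hr_recovered(self):
        cfg = SimulationConfig(
            seed=11, n_patients=2000, n_panel_genes=1, n_harmful=1, harmful_hr=2.0
        )
        cohort, _, _ = gen_survival_cohort(cfg)
        cohort = cohort.set_index("patient_id")
        expr = cohort["SURV001"]
        high = (expr > expr.median()).astype(int)
        r = cox_univariate(high, cohort["time_months"], cohort["event"].astype(bool))
        assert 1.8 <= r.hr <= 2.2


def _assoc(gene, hr, p=0.01, probe=None):
    return SurvivalAssociation(
        gene=gene, subgroup="all", n=100, hr=hr, ci_low=hr * 0.8, ci_high=hr * 1.2,
        logrank_p=p, significant=p < 0.05, probe=probe,
    )


class TestSummarizeProbes:
    def test_odd_count_median(self):
        got = summarize_probes([_assoc("g", h) for h in (1.2, 1.5, 2.0)])
        assert got.hr == 1.5

    def test_single_probe_identity(self):
        a = _assoc("g", 1.7, probe="p1")
        assert summarize_probes([a]) == a

    def test_even_count_lower_median_supplies_ci(self):
        probes = [_assoc("g", h, probe=f"p{h}") for h in (1.0, 1.2, 1.6, 2.0)]
        got = summarize_probes(probes)
        assert got.hr == 1.2 and got.probe == "p1.2"
        assert (got.ci_low, got.ci_high) == (1.2 * 0.8, 1.2 * 1.2)

    def test_empty_errors(self):
        with pytest.raises(SurvivalError):
            summarize_probes([])


@pytest.fixture(scope="module")
def cohort():
    cfg = SimulationConfig(
        seed=13, n_patients=1000, n_panel_genes=50, n_harmful=5, harmful_hr=2.0
    )
    df, truth, _ = gen_survival_cohort(cfg)
    return df.set_index("patient_id"), truth


class TestBatchAssociate:
    def test_empty_panel_gives_empty_table(self, cohort):
        table, counts = batch_associate(cohort[0], [], subgroups=["all"])
        assert table.empty and counts["all"]["n_significant"] == 0

    def test_single_gene_equals_direct_composition(self, cohort):
        df, _ = cohort
        table, _ = batch_associate(df, ["SURV001"], subgroups=["all"])
        expr = df["SURV001"]
        high = (expr > expr.median()).astype(int)
        t, e = df["time_months"], df["event"].astype(bool)
        r = cox_univariate(high, t, e)
        _, p = logrank_test(t[high == 1], e[high == 1], t[high == 0], e[high == 0])
        row = table.iloc[0]
        assert row["hr"] == pytest.approx(r.hr)
        assert row["logrank_p"] == pytest.approx(p)
        assert row["n"] == len(df)

    def test_small_subgroup_skipped_with_warning(self, cohort):
        df, _ = cohort
        tiny = df.copy()
        tiny.loc[tiny.index[:5], "subgroup"] = "radio"
        tiny = pd.concat([tiny[tiny.subgroup == "radio"], df.iloc[5:50]])
        with pytest.warns(UserWarning, match="radio"):
            table, counts = batch_associate(tiny, ["SURV001"])
        assert "radio" not in counts

    def test_planted_harmful_genes_recovered(self, cohort):
        df, truth = cohort
        table, counts = batch_associate(df, truth["gene"].tolist(), subgroups=["all"])
        merged = table.merge(truth, on="gene")
        planted = merged[merged.harmful]
        assert planted["significant"].all()
        assert (planted["hr"] > 1.4).all()
        # decoy false positives at alpha = 0.05: binomial(45, 0.05) stays
        # below 8 with probability > 0.998
        fp = merged[~merged.harmful]["significant"].sum()
        assert fp <= 7

    def test_multiprobe_summary_uses_real_probe(self):
        cfg = SimulationConfig(
            seed=17, n_patients=400, n_panel_genes=6, n_harmful=2,
            harmful_hr=2.0, n_multiprobe=2,
        )
        cohort, truth, probe_map = gen_survival_cohort(cfg)
        cohort = cohort.set_index("patient_id")
        table, _ = batch_associate(
            cohort, truth["gene"].tolist(), subgroups=["all"], probe_map=probe_map
        )
        for g in ("SURV001", "SURV002"):
            probe = table.loc[table.gene == g, "probe"].item()
            assert probe in probe_map and probe_map[probe] == g

    def test_null_significance_rate_near_alpha(self):
        cfg = SimulationConfig(
            seed=19, n_patients=400, n_panel_genes=200, n_harmful=0,
            censoring_fraction=0.2,
        )
        cohort, truth, _ = gen_survival_cohort(cfg)
        cohort = cohort.set_index("patient_id")
        table, counts = batch_associate(cohort, truth["gene"].tolist(), subgroups=["all"])
        rate = counts["all"]["n_significant"] / 200
        # binomial(200, 0.05): 3 sigma band around 5%
        assert 0.005 <= rate <= 0.10
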