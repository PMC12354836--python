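"""Log-rank, maxstat cutpoint, binary Cox, Kaplan-Meier, the expression
screen and the differential-expression ranking — each checked against an
independent oracle (hand computation, lifelines, or direct enumeration)."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from editscan.config import PipelineConfig
from editscan.simulate import _survival_draw, simulate_screen_cohorts
from editscan.survival import (
    cox_hr_binary,
    de_rank,
    km_curve,
    logrank,
    logrank_z,
    maxstat_cutpoint,
    pearson_screen,
)


def random_survival(rng, n, lam=0.2, censor=0.3):
    t = rng.exponential(1 / lam, n)
    c = rng.uniform(0, np.quantile(t, 1 - censor) * 2, n)
    return np.minimum(t, c), (t <= c).astype(int)


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        chi2, p = logrank(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_worked_example(self):
        """A: events at 1,2,3; B: events at 4,5,6. The hypergeometric
        increments give O-E = -1.85 and V = 0.6775 for group B, hence
        chi-square = 1.85^2 / 0.6775 = 5.05166."""
        chi2, p = logrank([1, 2, 3], [1, 1, 1], [4, 5, 6], [1, 1, 1])
        assert chi2 == pytest.approx(1.85**2 / 0.6775, rel=1e-12)

    def test_matches_lifelines_on_random_datasets(self, rng):
        from lifelines.statistics import logrank_test

        for _ in range(25):
            n1, n2 = rng.integers(5, 40, size=2)
            t1, e1 = random_survival(rng, n1)
            t2, e2 = random_survival(rng, n2)
            if e1.sum() + e2.sum() == 0:
                continue
            chi2, p = logrank(t1, e1, t2, e2)
            ref = logrank_test(t1, t2, e1, e2)
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
            assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_symmetric_in_group_labels(self, rng):
        t1, e1 = random_survival(rng, 20)
        t2, e2 = random_survival(rng, 25)
        assert logrank(t1, e1, t2, e2)[0] == pytest.approx(logrank(t2, e2, t1, e1)[0])

    def test_null_rejection_rate_is_nominal(self):
        hits, total = 0, 400
        for ss in np.random.SeedSequence(31).spawn(total):
            g = np.random.default_rng(ss)
            t1, e1 = random_survival(g, 20)
            t2, e2 = random_survival(g, 20)
            if e1.sum() + e2.sum() == 0:
                total -= 1
                continue
            hits += logrank(t1, e1, t2, e2)[1] < 0.05
        assert 0.02 <= hits / total <= 0.09

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([], [], [1.0], [1])


class TestMaxstat:
    def test_statistic_equals_exhaustive_maximum(self, cfg, rng):
        """Returned maximum must equal the brute-force maximum over every
        admissible split, computed independently with lifelines."""
        from lifelines.statistics import logrank_test

        for _ in range(15):
            n = int(rng.integers(12, 31))
            x = rng.uniform(0, 10, n)
            t, e = random_survival(rng, n)
            if e.sum() < 2:
                continue
            cut = maxstat_cutpoint(x, t, e, cfg)
            best_z, best_v = -1.0, None
            for v in np.sort(np.unique(x))[:-1]:
                if not (0.1 <= (x <= v).mean() <= 0.9):
                    continue
                m = x <= v
                z = np.sqrt(logrank_test(t[m], t[~m], e[m], e[~m]).test_statistic)
                if z > best_z + 1e-12:
                    best_z, best_v = z, v
            assert cut.max_std_logrank == pytest.approx(best_z, rel=1e-9)
            assert cut.cutoff == best_v

    def test_two_distinct_values_select_the_lower(self, cfg):
        x = [1.0] * 5 + [2.0] * 5
        t = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        e = [1] * 10
        cut = maxstat_cutpoint(x, np.array(t, float), np.array(e), cfg)
        assert cut.cutoff == 1.0

    def test_constant_covariate_rejected(self, cfg):
        with pytest.raises(ValueError, match="no admissible cutpoint"):
            maxstat_cutpoint([3.0] * 10, np.arange(1.0, 11.0), np.ones(10, int), cfg)

    def test_selection_inflates_naive_type_one_error(self, cfg):
        """Quoting the unadjusted log-rank p at the maxstat-selected
        cutpoint is anti-conservative: the null rejection rate must
        exceed the nominal 5% clearly (known selection bias)."""
        hits = 0
        n_sims = 150
        for ss in np.random.SeedSequence(55).spawn(n_sims):
            g = np.random.default_rng(ss)
            x = g.uniform(0, 1, 40)
            t, e = random_survival(g, 40)
            cut = maxstat_cutpoint(x, t, e, cfg)
            hits += cut.logrank_p < 0.05
        assert hits / n_sims > 0.10


class TestCox:
    def test_null_hr_near_one_with_nominal_ci_coverage(self):
        covered, hrs = 0, []
        n_seeds = 100
        for ss in np.random.SeedSequence(17).spawn(n_seeds):
            g = np.random.default_rng(ss)
            t, e = random_survival(g, 200)
            grp = (g.random(200) < 0.5).astype(int)
            hr, (lo, hi), p = cox_hr_binary(grp, t, e)
            hrs.append(hr)
            covered += lo <= 1.0 <= hi
        assert abs(np.mean(np.log(hrs))) < 0.05
        assert covered >= 89

    def test_planted_hr_recovered(self):
        target = 3.0
        betas = []
        for ss in np.random.SeedSequence(23).spawn(60):
            g = np.random.default_rng(ss)
            grp = (g.random(200) < 0.5).astype(int)
            lam = np.where(grp == 1, 0.3, 0.1)
            t_ev = g.exponential(1 / lam)
            c = g.uniform(0, 18, 200)
            t, e = np.minimum(t_ev, c), (t_ev <= c).astype(int)
            hr, _, _ = cox_hr_binary(grp, t, e)
            betas.append(np.log(hr))
        assert np.exp(np.mean(betas)) == pytest.approx(target, rel=0.10)

    def test_matches_lifelines_without_ties(self, rng):
        from lifelines import CoxPHFitter

        for _ in range(10):
            n = 80
            grp = (rng.random(n) < 0.5).astype(int)
            t, e = random_survival(rng, n)
            if e[grp == 1].sum() == 0 or e[grp == 0].sum() == 0:
                continue
            hr, _, _ = cox_hr_binary(grp, t, e)
            df = pd.DataFrame({"T": t, "E": e, "x": grp})
            cph = CoxPHFitter().fit(df, "T", "E")
            assert np.log(hr) == pytest.approx(cph.params_["x"], abs=1e-3)

    def test_all_events_in_one_group_flagged_non_estimable(self):
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.array([1, 1, 1, 0, 0, 0])
        grp = np.array([1, 1, 1, 0, 0, 0])
        hr, ci, p = cox_hr_binary(grp, t, e)
        assert hr is None and ci == (None, None)

    def test_sign_agrees_with_logrank(self, rng):
        for _ in range(20):
            n = 60
            grp = (rng.random(n) < 0.5).astype(int)
            lam = np.where(grp == 1, rng.uniform(0.1, 0.5), rng.uniform(0.1, 0.5))
            t = rng.exponential(1 / lam)
            e = (rng.random(n) < 0.8).astype(int)
            if e[grp == 1].sum() == 0 or e[grp == 0].sum() == 0:
                continue
            hr, _, _ = cox_hr_binary(grp, t, e)
            if hr is None:
                continue
            z = logrank_z(t, e, grp.astype(bool))
            if abs(z) > 1e-9 and abs(np.log(hr)) > 1e-9:
                assert np.sign(np.log(hr)) == np.sign(z)


class TestKaplanMeier:
    def test_four_distinct_events_step_by_quarters(self):
        times, surv = km_curve([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        assert list(surv) == pytest.approx([1.0, 0.75, 0.5, 0.25, 0.0])

    def test_all_censored_stays_flat(self):
        _, surv = km_curve([1.0, 2.0, 3.0], [0, 0, 0])
        assert all(s == 1.0 for s in surv)

    def test_matches_direct_product_limit_on_random_data(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 40))
            t, e = random_survival(rng, n)
            times, surv = km_curve(t, e)
            # independent product-limit computation
            s = 1.0
            expected = {}
            for ti in sorted(set(t)):
                at_risk = (t >= ti).sum()
                d = ((t == ti) & (e == 1)).sum()
                s *= 1 - d / at_risk
                expected[ti] = s
            for ti, si in zip(times, surv):
                if ti in expected:
                    assert si == pytest.approx(expected[ti], rel=1e-9)


class TestPearsonScreen:
    def test_planted_regulator_ranks_first(self):
        cohorts, regulator = simulate_screen_cohorts(123)
        ranked = pearson_screen(cohorts)
        assert ranked.index[0] == regulator
        assert int(ranked.loc[regulator, "rank"]) == 1

    def test_constant_gene_excluded_from_head(self):
        rng = np.random.default_rng(1)
        ed = rng.uniform(0, 30, 20)
        expr = pd.DataFrame(
            {"flat": np.ones(20), "noise": rng.normal(size=20)}
        )
        ranked = pearson_screen([(ed, expr)])
        assert np.isnan(ranked.loc["flat", "mean_r"])
        assert ranked.index[-1] == "flat"

    def test_permuted_editing_breaks_the_coupling(self):
        rs = []
        for ss in np.random.SeedSequence(9).spawn(40):
            g = np.random.default_rng(ss)
            cohorts, regulator = simulate_screen_cohorts(ss, n_cohorts=1, n_genes=20)
            ed, expr = cohorts[0]
            ranked = pearson_screen([(g.permutation(ed), expr)])
            rs.append(ranked.loc[regulator, "mean_r"])
        assert abs(np.mean(rs)) < 0.1


class TestDeRank:
    def test_score_arithmetic_and_ordering(self):
        table = pd.DataFrame(
            {"logfc": [2.0, -2.0, 0.5], "p": [0.01, 0.01, 0.5]},
            index=["up", "down", "weak"],
        )
        ranked = de_rank(table)
        assert ranked.loc["up", "score"] == pytest.approx(4.0)
        assert ranked.loc["down", "score"] == pytest.approx(-4.0)
        assert list(ranked.index) == ["up", "weak", "down"]

    def test_zero_p_clamped_and_flagged(self):
        ranked = de_rank(pd.DataFrame({"logfc": [1.0], "p": [0.0]}, index=["g"]))
        assert bool(ranked.loc["g", "p_clamped"])
        assert np.isfinite(ranked.loc["g", "score"])

    def test_input_permutation_permutes_output(self, rng):
        table = pd.DataFrame(
            {"logfc": rng.normal(size=10), "p": rng.uniform(1e-6, 1, 10)},
            index=[f"g{i}" for i in range(10)],
        )
        a = de_rank(table)
        b = de_rank(table.sample(frac=1, random_state=3))
        assert list(a.index) == list(b.index)
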