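import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from satblot.cohort_stats import (
    compare_groups,
    descriptive,
    ecdf,
    ks_two_sample,
    mann_whitney,
    paired_therapy_analysis,
    panss_association,
    stratify_by_birth_year,
)
from satblot.synthetic_data import CohortSpec, TherapySpec, make_cohort, make_paired_therapy


def exact_mw_oracle(x, y):
    """Independent enumeration oracle: count pairwise wins over every
    reassignment of the pooled values (valid without ties)."""
    pooled = list(x) + list(y)
    n = len(x)
    idx = range(len(pooled))

    def u_of(subset):
        xs = [pooled[i] for i in subset]
        ys = [pooled[i] for i in idx if i not in subset]
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = sum(1 for a in x for b in y if a > b)
    us = [u_of(set(c)) for c in combinations(idx, n)]
    p_le = sum(1 for u in us if u <= u_obs) / len(us)
    p_ge = sum(1 for u in us if u >= u_obs) / len(us)
    return min(1.0, 2 * min(p_le, p_ge))


def ks_scan_oracle(x, y):
    """Signed ECDF difference at the argmax of |F_x - F_y| over pooled points."""
    best = 0.0
    for t in sorted(set(x) | set(y)):
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        if abs(fx - fy) > abs(best):
            best = fx - fy
    return best


class TestDescriptive:
    def test_control_row_cv(self):
        # published control moments: mean 22.0, SD 6.7 -> CV reported 0.30
        assert round(6.7 / 22.0, 2) == 0.30

    def test_hand_arithmetic(self):
        d = descriptive([10, 20, 30])
        assert d.mean == 20
        assert d.sd == pytest.approx(10.0)
        assert d.median == 20
        assert d.cv == pytest.approx(0.5)
        assert (d.min, d.max) == (10, 30)

    def test_constant_vector(self):
        d = descriptive([7.0, 7.0, 7.0])
        assert d.sd == 0.0
        assert d.cv == 0.0

    def test_single_value(self):
        d = descriptive([5.0])
        assert d.n == 1 and d.sd == 0.0 and d.cv == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            descriptive([])

    def test_rounding_only_at_report_time(self):
        d = descriptive([22.0 - 6.7, 22.0, 22.0 + 6.7])
        assert d.cv != round(d.cv, 2)  # internal value unrounded
        assert d.rounded()["cv"] == round(d.cv, 2)


class TestMannWhitney:
    def test_complete_separation_small(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.U == 0
        assert res.p == pytest.approx(0.10)
        assert not res.significant

    def test_identical_samples(self):
        res = mann_whitney([5, 5, 5, 5], [5, 5, 5, 5])
        assert res.p == pytest.approx(1.0)

    def test_symmetry(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=40)
        assert mann_whitney(x, y).p == pytest.approx(mann_whitney(y, x).p)

    def test_exact_path_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            n, m = rng.integers(2, 8, size=2)
            pooled = rng.permutation(np.arange(1.0, n + m + 1))  # distinct values
            x, y = pooled[:n], pooled[n:]
            assert mann_whitney(x, y).p == pytest.approx(exact_mw_oracle(x, y))

    def test_asymptotic_matches_scipy(self, rng):
        x = rng.normal(0, 1, 50)
        y = rng.normal(0.5, 1, 60)
        ours = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_ties_handled_with_midranks(self, rng):
        x = rng.integers(0, 5, 40).astype(float)
        y = rng.integers(1, 6, 45).astype(float)
        ours = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(0.3, 1, size=30)
        assert mann_whitney(np.exp(x), np.exp(y)).p == pytest.approx(mann_whitney(x, y).p)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKolmogorovSmirnov:
    def test_complete_separation(self):
        res = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert res.D == pytest.approx(1.0)

    def test_identical_samples(self):
        res = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert res.D == 0.0
        assert res.alpha == pytest.approx(1.0)

    def test_sign_convention_first_minus_second(self):
        # x stochastically smaller: F_x >= F_y, so D > 0; swapping flips it
        x, y = [1, 2, 3, 4], [3, 4, 5, 6]
        assert ks_two_sample(x, y).D > 0
        assert ks_two_sample(y, x).D == pytest.approx(-ks_two_sample(x, y).D)

    def test_scan_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(3, 12)))
            y = rng.normal(0.4, 1.2, size=int(rng.integers(3, 12)))
            res = ks_two_sample(x, y)
            assert res.D == pytest.approx(ks_scan_oracle(list(x), list(y)))

    def test_statistic_matches_scipy(self, rng):
        x = rng.normal(size=80)
        y = rng.normal(0.3, 1, size=90)
        res = ks_two_sample(x, y)
        ref = stats.ks_2samp(x, y)
        assert abs(res.D) == pytest.approx(ref.statistic)

    def test_alpha_is_kolmogorov_tail(self):
        x = list(range(100))
        y = [v + 10 for v in range(110)]
        res = ks_two_sample(x, y)
        n, m = 100, 110
        expected = stats.kstwobign.sf(abs(res.D) * math.sqrt(n * m / (n + m)))
        assert res.alpha == pytest.approx(expected, rel=1e-6)


class TestCompareGroups:
    def _cohort(self, seed=0):
        hc = make_cohort(CohortSpec("HC", n=401, mean_content=22.0, sd_content=6.7), seed=seed)
        nh = make_cohort(
            CohortSpec("NH_SZ_Mplus", n=143, mean_content=14.7, sd_content=3.0), seed=seed + 1
        )
        return pd.concat([hc, nh], ignore_index=True)

    def test_headline_separation_is_huge(self):
        # control vs non-hypoxia medicated group at published moments
        report = compare_groups(self._cohort(seed=3), [("HC", "NH_SZ_Mplus")])
        pair = report.pairs[0]
        assert pair["mann_whitney"]["p"] < 1e-20
        assert pair["mann_whitney"]["significant"]
        assert pair["ks"]["D"] != 0

    def test_group_against_itself(self):
        cohort = self._cohort()
        report = compare_groups(cohort, [("HC", "HC")])
        assert report.pairs[0]["mann_whitney"]["p"] == pytest.approx(1.0)
        assert report.pairs[0]["ks"]["D"] == 0.0

    def test_type_one_error_control(self):
        # two cohorts from the same spec: p > 0.01 in >= 90% of 100 seeds
        hits = 0
        for seed in range(100):
            a = make_cohort(CohortSpec("HC", n=60, mean_content=20, sd_content=5), seed=seed)
            b = make_cohort(
                CohortSpec("NH_SZ_Mplus", n=60, mean_content=20, sd_content=5), seed=seed + 1000
            )
            cohort = pd.concat([a, b], ignore_index=True)
            p = compare_groups(cohort, [("HC", "NH_SZ_Mplus")]).pairs[0]["mann_whitney"]["p"]
            hits += p > 0.01
        assert hits >= 90

    def test_unknown_group_raises(self):
        with pytest.raises(KeyError):
            compare_groups(self._cohort(), [("HC", "nope")])


class TestStratifyAndEcdf:
    def test_boundary_years(self):
        df = pd.DataFrame({"birth_year": [1989, 1990], "content": [1.0, 2.0]})
        older, younger = stratify_by_birth_year(df)
        assert len(older) == 1 and len(younger) == 1
        assert older["birth_year"].iloc[0] == 1989

    def test_empty_younger_stratum(self):
        df = pd.DataFrame({"birth_year": [1950, 1960, 1970], "content": [1, 2, 3]})
        older, younger = stratify_by_birth_year(df)
        assert len(older) == 3 and len(younger) == 0

    def test_partition_is_exhaustive(self, rng):
        df = pd.DataFrame({"birth_year": rng.integers(1935, 2002, 200), "content": 1.0})
        older, younger = stratify_by_birth_year(df)
        assert len(older) + len(younger) == 200
        assert set(older.index).isdisjoint(younger.index)

    def test_missing_years_raise(self):
        df = pd.DataFrame({"birth_year": [1950, np.nan], "content": [1, 2]})
        with pytest.raises(ValueError):
            stratify_by_birth_year(df)

    def test_ecdf_singleton(self):
        e = ecdf([5.0])
        assert e.values.tolist() == [[5.0, 1.0]]

    def test_ecdf_with_ties(self):
        e = ecdf([1, 1, 2])
        assert e["value"].tolist() == [1, 2]
        assert e["cumulative_fraction"].tolist() == pytest.approx([2 / 3, 1.0])

    def test_ecdf_rank_oracle(self, rng):
        values = rng.normal(size=50)
        e = ecdf(values)
        s = np.sort(values)
        for v, f in zip(e["value"], e["cumulative_fraction"]):
            assert f == pytest.approx(np.searchsorted(s, v, side="right") / 50)
        assert e["cumulative_fraction"].iloc[-1] == 1.0


class TestPairedTherapy:
    def test_no_change(self):
        pre = np.array([8.0, 10.0, 15.0, 20.0, 28.0])
        rep = paired_therapy_analysis(pre, pre)
        assert rep.delta_on_pre_slope == pytest.approx(0.0, abs=1e-12)
        assert rep.cv_pre == rep.cv_post
        assert rep.low_baseline_delta_mean == 0.0
        assert rep.high_baseline_delta_mean == 0.0

    def test_exact_shrinkage_closed_form(self, rng):
        pre = rng.normal(20, 6, 200)
        mu = pre.mean()
        post = mu + 0.5 * (pre - mu)
        rep = paired_therapy_analysis(pre, post)
        assert rep.delta_on_pre_slope == pytest.approx(-0.5, abs=1e-9)
        assert rep.cv_post == pytest.approx(rep.cv_pre / 2, rel=1e-9)

    def test_generator_shrinkage_recovers_published_cv_band(self):
        spec = TherapySpec(n=93, pre_mean=17.0, pre_sd=5.27, setpoint_mu=17.0,
                           kappa=0.45, eps_sd=0.94, seed=123)
        df = make_paired_therapy(spec)
        rep = paired_therapy_analysis(df["content_pre"], df["content_post"])
        assert 0.13 <= rep.cv_post <= 0.17
        assert rep.low_baseline_delta_mean > 0 > rep.high_baseline_delta_mean
        # the overall occasion comparison stays non-significant
        assert rep.mw.p > 0.01

    def test_kappa_recovery_within_analytic_ci(self):
        spec = TherapySpec(n=500, pre_mean=17.0, pre_sd=5.27, setpoint_mu=17.0,
                           kappa=0.45, eps_sd=0.94, seed=11)
        df = make_paired_therapy(spec)
        pre = df["content_pre"].to_numpy()
        delta = (df["content_post"] - df["content_pre"]).to_numpy()
        rep = paired_therapy_analysis(df["content_pre"], df["content_post"])
        kappa_hat = 1.0 + rep.delta_on_pre_slope
        resid = delta - np.polyval(np.polyfit(pre, delta, 1), pre)
        se = math.sqrt((resid**2).sum() / (len(pre) - 2) / ((pre - pre.mean()) ** 2).sum())
        assert abs(kappa_hat - 0.45) < 3 * se

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_therapy_analysis([1, 2, 3], [1, 2])


class TestPanssAssociation:
    def test_exact_linear_relation(self):
        content = np.array([5.0, 10.0, 15.0, 25.0, 30.0])
        panss = -2.0 * content + 100.0
        rep = panss_association(content, panss)
        assert rep.ols_slope == pytest.approx(-2.0)
        assert rep.ols_intercept == pytest.approx(100.0)
        assert rep.pearson_r == pytest.approx(-1.0)

    def test_null_association_small_r(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            content = rng.uniform(6, 40, 500)
            panss = rng.normal(90, 20, 500)
            if abs(panss_association(content, panss).pearson_r) < 0.1:
                hits += 1
        assert hits >= int(0.95 * n_seeds) - 1

    def test_negative_generator_slope_orders_subgroups(self):
        spec = CohortSpec("SZ_Mminus", n=400, mean_content=18.0, sd_content=5.9,
                          panss_beta0=118.0, panss_beta1=-1.0, panss_sd=10.0)
        df = make_cohort(spec, seed=2)
        rep = panss_association(df["content"], df["panss"])
        # low-content subgroup ("I") scores higher, as published
        assert rep.subgroup_low_desc.mean > rep.subgroup_high_desc.mean
        assert rep.ols_slope < 0

    def test_zero_variance_content_raises(self):
        with pytest.raises(ValueError):
            panss_association([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
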