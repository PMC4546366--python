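"""Statistical battery: contrast ANOVAs, Holm, sector t-tests, power, log-rank."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rfackit import (
    PowerSpec,
    helmert_anova,
    holm_adjust,
    km_logrank,
    rm_anova_holm,
    sectorwise_tests,
    treatment_anova,
    two_sample_power,
)

LEVELS = ("sham", "MI", "MI+Val")


def three_groups(vals_by_group):
    values = np.concatenate([np.asarray(v, float) for v in vals_by_group])
    groups = np.concatenate(
        [np.full(len(v), lab) for v, lab in zip(vals_by_group, LEVELS)]
    )
    return values, groups


class TestHelmert:
    def test_identical_group_distributions_give_null_contrasts(self):
        v, g = three_groups([[1.0, 2, 3], [1, 2, 3], [1, 2, 3]])
        res = helmert_anova(v, g)
        assert np.allclose(res.contrasts["t"], 0.0)
        assert np.allclose(res.contrasts["p"], 1.0)
        assert res.f_overall == pytest.approx(0.0)

    def test_all_constant_flagged_degenerate(self):
        v, g = three_groups([[5.0, 5], [5, 5], [5, 5]])
        res = helmert_anova(v, g)
        assert res.degenerate and np.isnan(res.contrasts["p"]).all()

    def test_constructed_null_on_randomization_contrast(self):
        rng = np.random.default_rng(0)
        eps = rng.normal(0, 1e-3, 6)
        v, g = three_groups([[10 + eps[0], 10 + eps[1]],
                             [eps[2], eps[3]], [eps[4], eps[5]]])
        res = helmert_anova(v, g)
        assert res.contrasts.loc["surgery", "p"] < 1e-6
        assert res.contrasts.loc["randomization", "p"] > 0.2

    def test_matches_hand_computed_sums_of_squares(self):
        data = [[3.0, 5, 4, 6], [8, 7, 9, 10], [2, 3, 1, 2]]
        v, g = three_groups(data)
        res = helmert_anova(v, g)
        # textbook oracle: contrast t = c.m / sqrt(MSE * sum(c_i^2/n_i))
        means = np.array([np.mean(d) for d in data])
        ns = np.array([len(d) for d in data])
        sse = sum(((np.array(d) - np.mean(d)) ** 2).sum() for d in data)
        mse = sse / (sum(ns) - 3)
        for name, c in [("surgery", np.array([1.0, -0.5, -0.5])),
                        ("randomization", np.array([0.0, 1.0, -1.0]))]:
            t = c @ means / np.sqrt(mse * np.sum(c**2 / ns))
            p = 2 * sps.t.sf(abs(t), sum(ns) - 3)
            assert res.contrasts.loc[name, "t"] == pytest.approx(t)
            assert res.contrasts.loc[name, "p"] == pytest.approx(p)
            assert res.contrasts.loc[name, "F"] == pytest.approx(t**2)

    def test_randomization_contrast_invariant_to_sham_shift(self):
        rng = np.random.default_rng(1)
        data = [rng.normal(5, 1, 5), rng.normal(3, 1, 5), rng.normal(4, 1, 5)]
        v, g = three_groups(data)
        base = helmert_anova(v, g).contrasts.loc["randomization"]
        v2 = v.copy()
        v2[g == "sham"] += 100.0
        shifted = helmert_anova(v2, g).contrasts.loc["randomization"]
        assert shifted["t"] == pytest.approx(base["t"])
        assert shifted["p"] == pytest.approx(base["p"])


class TestTreatment:
    def test_all_equal_groups(self):
        v, g = three_groups([[1.0, 2], [1, 2], [1, 2]])
        res = treatment_anova(v, g)
        assert np.allclose(res.contrasts["p"], 1.0)

    def test_large_shift_both_significant(self):
        rng = np.random.default_rng(2)
        v, g = three_groups([rng.normal(0, 0.1, 6),
                             rng.normal(10, 0.1, 6),
                             rng.normal(0, 0.1, 6)])
        res = treatment_anova(v, g, reference="MI")
        assert (res.contrasts["p"] < 1e-6).all()

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        data = [rng.normal(5, 2, 4), rng.normal(7, 2, 5), rng.normal(6, 2, 6)]
        v, g = three_groups(data)
        res = treatment_anova(v, g, reference="MI")
        # oracle: cell-means fit by normal equations, contrast on coefficients
        X = np.column_stack([(g == lab).astype(float) for lab in LEVELS])
        beta = np.linalg.solve(X.T @ X, X.T @ v)
        resid = v - X @ beta
        mse = resid @ resid / (len(v) - 3)
        for name, c in [("MI vs sham", np.array([-1.0, 1.0, 0.0])),
                        ("MI vs MI+Val", np.array([0.0, 1.0, -1.0]))]:
            se = np.sqrt(mse * c @ np.linalg.inv(X.T @ X) @ c)
            t = c @ beta / se
            assert res.contrasts.loc[name, "t"] == pytest.approx(t)


class TestRepeatedMeasures:
    def make_df(self, matrix):
        n_s, n_t = matrix.shape
        return pd.DataFrame({
            "subject": np.repeat([f"s{i}" for i in range(n_s)], n_t),
            "timepoint": [f"t{j}" for j in range(n_t)] * n_s,
            "value": matrix.ravel(),
        })

    def test_time_constant_data_high_p(self):
        rng = np.random.default_rng(4)
        base = rng.normal(50, 5, 8)
        matrix = base[:, None] + rng.normal(0, 1e-6, (8, 4))
        p, _ = rm_anova_holm(self.make_df(matrix))
        assert p > 0.3

    def test_holm_hand_values(self):
        assert holm_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.04, 0.04])

    def test_holm_monotone_and_never_below_raw(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 12)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_two_timepoints_reduce_to_paired_t(self):
        rng = np.random.default_rng(6)
        matrix = rng.normal(0, 1, (9, 2))
        _, pw = rm_anova_holm(self.make_df(matrix))
        t_ref, p_ref = sps.ttest_rel(matrix[:, 0], matrix[:, 1])
        assert pw.loc[0, "t"] == pytest.approx(t_ref)
        assert pw.loc[0, "p_raw"] == pytest.approx(p_ref)
        assert pw.loc[0, "p_holm"] == pytest.approx(p_ref)  # single comparison

    def test_missing_cells_rejected(self):
        df = self.make_df(np.zeros((3, 3))).iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova_holm(df)


class TestSectorwise:
    def test_identical_groups_p_one(self):
        maps = np.tile(np.arange(60.0).reshape(10, 6), (4, 1, 1))
        res = sectorwise_tests(maps + 0, maps + 0)
        # zero variance in both groups -> t undefined -> NaN, but equal-mean
        # cells with variance give p = 1; use a jittered copy for that
        rng = np.random.default_rng(7)
        jit = rng.normal(0, 1, (4, 10, 6))
        res = sectorwise_tests(maps + jit, maps + jit)
        assert np.allclose(res.p_value, 1.0)

    def test_single_shifted_cell_detected(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, (6, 10, 6))
        b = rng.normal(0, 1, (6, 10, 6))
        b[:, 4, 2] += 10.0
        res = sectorwise_tests(a, b)
        assert res.p_value[4, 2] < 0.01
        others = np.delete(res.p_value.ravel(), 4 * 6 + 2)
        assert np.median(others) > 0.2

    def test_matches_hand_computed_pooled_t(self):
        a = np.array([3.0, 5, 4, 6])
        b = np.array([7.0, 9, 6, 8, 10])
        A = np.zeros((4, 1, 1)); A[:, 0, 0] = a
        B = np.zeros((5, 1, 1)); B[:, 0, 0] = b
        res = sectorwise_tests(A, B)
        sp = np.sqrt(((3 * a.var(ddof=1) + 4 * b.var(ddof=1)) / 7))
        t = (a.mean() - b.mean()) / (sp * np.sqrt(1 / 4 + 1 / 5))
        assert res.t_stat[0, 0] == pytest.approx(t)
        assert res.p_value[0, 0] == pytest.approx(2 * sps.t.sf(abs(t), 7))

    def test_thin_cells_missing(self):
        a = np.full((1, 2, 6), 1.0)
        b = np.full((3, 2, 6), 2.0)
        res = sectorwise_tests(a, b)
        assert np.isnan(res.p_value).all()


class TestPower:
    def test_null_delta_gives_alpha(self):
        spec = PowerSpec(n_per_group=12, delta=0.0, sd1=10.0, sd2=10.0, alpha=0.05)
        assert two_sample_power(spec) == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_n_and_delta(self):
        base = dict(delta=10.0, sd1=10.0, sd2=10.0, alpha=0.05)
        powers_n = [two_sample_power(PowerSpec(n_per_group=n, **base)) for n in (4, 8, 16, 32)]
        assert (np.diff(powers_n) > 0).all()
        powers_d = [two_sample_power(PowerSpec(n_per_group=12, delta=d, sd1=10, sd2=10))
                    for d in (2, 6, 10, 14)]
        assert (np.diff(powers_d) > 0).all()

    def test_one_sided_exceeds_two_sided(self):
        two = two_sample_power(PowerSpec(12, 14.0, 10.4, 17.3, sides=2))
        one = two_sample_power(PowerSpec(12, 14.0, 10.4, 17.3, sides=1))
        assert one > two

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(1, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            PowerSpec(5, 1.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            PowerSpec(5, 1.0, 1.0, 1.0, alpha=1.5)


class TestKMLogrank:
    def test_identical_groups_chi2_zero(self):
        t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        g = np.array(["A"] * 4 + ["B"] * 4)
        _, chi2, p, flag = km_logrank(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert not flag

    def test_no_events_flagged(self):
        t = np.full(8, 4.0)
        e = np.zeros(8, int)
        g = np.array(["A"] * 4 + ["B"] * 4)
        fitters, chi2, p, flag = km_logrank(t, e, g)
        assert flag and np.isnan(chi2)
        assert np.allclose(fitters["A"].survival_function_.to_numpy(), 1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            km_logrank([1.0, 2.0], [1, 1], ["A", "A"])

    def test_textbook_two_group_oracle(self):
        # classic toy data, no censoring; oracle builds the O-E table by hand
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.ones(6, int)
        g = np.array(["A", "A", "A", "B", "B", "B"])
        _, chi2, p, flag = km_logrank(t, e, g)
        event_times = np.unique(t)
        o_a = ex_a = var = 0.0
        for et in event_times:
            at_risk = t >= et
            n = at_risk.sum()
            n_a = (at_risk & (g == "A")).sum()
            d = ((t == et) & (e == 1)).sum()
            d_a = ((t == et) & (e == 1) & (g == "A")).sum()
            o_a += d_a
            ex_a += d * n_a / n
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        chi2_ref = (o_a - ex_a) ** 2 / var
        assert chi2 == pytest.approx(chi2_ref)
        assert p == pytest.approx(sps.chi2.sf(chi2_ref, 1))
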