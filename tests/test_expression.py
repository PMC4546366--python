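"""Expression screens: probe filtering, permutation FDP control, FC gates."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rfackit import (
    ExpressionMatrix,
    ExpressionModel,
    filter_probes,
    generate_expression,
    multivariate_permutation_f,
    pairwise_fc_filter,
    quantitative_trait_corr,
    read_series_matrix,
)


def matrix_from_array(x, classes, genes=None, trait=None):
    x = np.asarray(x, dtype=float)
    probes = [f"P{i}" for i in range(x.shape[0])]
    samples = [f"S{j}" for j in range(x.shape[1])]
    return ExpressionMatrix(
        intensity=pd.DataFrame(x, index=probes, columns=samples),
        genes=pd.Series(genes if genes is not None else probes, index=probes),
        classes=pd.Series(classes, index=samples),
        trait=None if trait is None else pd.Series(trait, index=samples),
    )


class TestFilter:
    def base_matrix(self, extra_rows, extra_genes=None):
        rng = np.random.default_rng(0)
        x = np.exp(rng.normal(np.log(500), 1.0, (50, 12)))
        genes = [f"G{i}" for i in range(50)]
        if extra_rows is not None:
            x = np.vstack([x, extra_rows])
            genes = genes + (extra_genes or [f"X{i}" for i in range(len(extra_rows))])
        return matrix_from_array(x, ["a"] * 6 + ["b"] * 6, genes=genes)

    def test_constant_probe_excluded_by_variance_rule(self):
        m = self.base_matrix(np.full((1, 12), 200.0))
        out, audit = filter_probes(m)
        assert "P50" in audit.dropped_variance
        assert "P50" not in out.intensity.index

    def test_intensity_percentile_boundary(self):
        # 33rd percentile just below 125 -> rule (a) drops it
        row = np.full(12, 124.9)
        m = self.base_matrix(row[None, :])
        _, audit = filter_probes(m)
        assert "P50" in audit.dropped_intensity
        # just above the cut passes rule (a)
        m2 = self.base_matrix(np.full((1, 12), 125.0))
        _, audit2 = filter_probes(m2)
        assert "P50" not in audit2.dropped_intensity

    def test_collapse_keeps_max_iqr_probe(self):
        rng = np.random.default_rng(1)
        base = np.exp(rng.normal(np.log(500), 1.2, (30, 12)))
        spread = rng.normal(0, 1, 12)
        dup_a = 500.0 * np.exp(1.0 * spread)   # IQR smaller
        dup_b = 500.0 * np.exp(2.5 * spread)   # IQR larger -> kept
        x = np.vstack([base, dup_a, dup_b])
        genes = [f"G{i}" for i in range(30)] + ["GDUP", "GDUP"]
        m = matrix_from_array(x, ["a"] * 6 + ["b"] * 6, genes=genes)
        out, _ = filter_probes(m)
        kept = out.intensity.index[out.genes.loc[out.intensity.index] == "GDUP"]
        assert list(kept) == ["P31"]

    def test_idempotent_with_recorded_null_variance(self):
        m = self.base_matrix(None)
        once, audit = filter_probes(m)
        twice, _ = filter_probes(once, sigma0=audit.sigma0)
        assert list(once.intensity.index) == list(twice.intensity.index)

    def test_negative_intensities_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            matrix_from_array([[-1.0, 2.0]], ["a", "b"])


class TestSeriesMatrix:
    def test_reads_geo_dialect(self, tmp_path):
        path = tmp_path / "series.txt"
        path.write_text(
            "!Series_title\t\"synthetic\"\n"
            "!series_matrix_table_begin\n"
            "ID_REF\tS1\tS2\tS3\tS4\n"
            "P1\t10\t20\t30\t40\n"
            "P2\t5\t5\t5\t5\n"
            "!series_matrix_table_end\n"
        )
        m = read_series_matrix(path, classes=pd.Series(["a", "a", "b", "b"],
                                                       index=["S1", "S2", "S3", "S4"]))
        assert m.intensity.shape == (2, 4)
        assert m.intensity.loc["P1", "S3"] == 30


class TestClassScreen:
    def test_separable_limit_returns_exactly_the_affected_genes(self):
        rng = np.random.default_rng(2)
        x = np.exp(rng.normal(np.log(500), 0.001, (100, 6)))
        x[:5, 3:] *= 8.0  # strong effect in genes 0-4
        m = matrix_from_array(x, ["a"] * 3 + ["b"] * 3)
        res = multivariate_permutation_f(m, n_perm=1000, seed=0)
        assert sorted(res.genes) == [f"P{i}" for i in range(5)]

    def test_tiny_instance_equals_full_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        x = np.exp(rng.normal(np.log(300), 0.5, (10, 6)))
        x[0, :2] *= 5.0
        labels = ["a", "a", "b", "b", "c", "c"]
        m = matrix_from_array(x, labels)
        res = multivariate_permutation_f(m, fdr=0.10, conf=0.80, n_perm=1000, seed=0)
        assert res.exhaustive
        # independent oracle: plain loops over every distinct labelling
        logx = np.log2(x)

        def f_pvals(lab):
            from scipy import stats as sps
            lab = np.asarray(lab)
            ps = []
            for row in logx:
                groups = [row[lab == g] for g in ("a", "b", "c")]
                ps.append(sps.f_oneway(*groups).pvalue)
            return np.array(ps)

        p_obs = f_pvals(labels)
        perms = sorted(set(itertools.permutations(labels)))
        perm_p = np.array([f_pvals(list(pp)) for pp in perms])
        order = np.argsort(p_obs, kind="mergesort")
        k_star = 0
        for k in range(len(p_obs), 0, -1):
            cutoff = p_obs[order[k - 1]]
            fd = (perm_p <= cutoff + 1e-12).sum(axis=1)
            if np.mean(fd <= 0.10 * k) >= 0.80:
                k_star = k
                break
        assert res.k == k_star
        assert res.genes == [f"P{i}" for i in order[:k_star]]

    def test_nested_in_fdr_and_confidence(self):
        rng = np.random.default_rng(4)
        x = np.exp(rng.normal(np.log(400), 0.4, (60, 12)))
        x[:8, 6:] *= 2.0
        m = matrix_from_array(x, ["a"] * 6 + ["b"] * 6)
        k_tight = multivariate_permutation_f(m, fdr=0.05, conf=0.9, n_perm=400, seed=1).k
        k_mid = multivariate_permutation_f(m, fdr=0.10, conf=0.9, n_perm=400, seed=1).k
        k_loose = multivariate_permutation_f(m, fdr=0.10, conf=0.7, n_perm=400, seed=1).k
        assert k_tight <= k_mid <= k_loose

    def test_degenerate_classes_rejected(self):
        m = matrix_from_array(np.ones((5, 4)), ["a"] * 4)
        with pytest.raises(ValueError):
            multivariate_permutation_f(m)


class TestPairwiseFC:
    def test_identical_means_empty(self):
        rng = np.random.default_rng(5)
        x = np.exp(rng.normal(np.log(300), 0.001, (20, 18)))
        m = matrix_from_array(x, ["sham"] * 6 + ["MI"] * 6 + ["MI+Val"] * 6)
        out = pairwise_fc_filter(m)
        assert not out["significant"].any()

    def test_fc_gate_excludes_small_fold_changes(self):
        x = np.full((1, 18), 1000.0)
        x[0, 6:12] = 1190.0  # MI 1.19-fold vs others: p tiny, FC below gate
        rng = np.random.default_rng(6)
        x = x * np.exp(rng.normal(0, 1e-4, x.shape))
        m = matrix_from_array(x, ["sham"] * 6 + ["MI"] * 6 + ["MI+Val"] * 6)
        out = pairwise_fc_filter(m, alpha=0.01, fc=1.2)
        assert out["p MI vs sham"].iloc[0] < 0.01
        assert abs(out["FC MI vs sham"].iloc[0]) < 1.2
        assert not out["significant"].iloc[0]

    def test_toy_matrix_matches_hand_gates(self):
        from scipy import stats as sps
        rng = np.random.default_rng(7)
        x = np.exp(rng.normal(np.log(400), 0.3, (40, 18)))
        x[:6, 6:12] *= rng.uniform(1.1, 2.5, (6, 1))
        labels = np.array(["sham"] * 6 + ["MI"] * 6 + ["MI+Val"] * 6)
        m = matrix_from_array(x, labels)
        out = pairwise_fc_filter(m, alpha=0.01, fc=1.2)
        logx = np.log2(x)
        for i in range(40):
            ok = False
            for a, b in (("MI", "sham"), ("MI", "MI+Val")):
                p = sps.ttest_ind(logx[i, labels == a], logx[i, labels == b]).pvalue
                ratio = x[i, labels == a].mean() / x[i, labels == b].mean()
                fc = ratio if ratio >= 1 else -1 / ratio
                ok |= (p < 0.01) and (abs(fc) >= 1.2)
            assert out["significant"].iloc[i] == ok

    def test_fc_below_one_rejected(self):
        m = matrix_from_array(np.ones((2, 4)), ["a", "a", "b", "b"])
        with pytest.raises(ValueError):
            pairwise_fc_filter(m, comparisons=[("a", "b")], fc=0.9)


class TestTraitScreen:
    def test_exact_linear_gene_always_selected(self):
        rng = np.random.default_rng(8)
        trait = rng.uniform(20, 80, 10)
        x = np.exp(rng.normal(np.log(300), 0.3, (30, 10)))
        x[0] = 1000.0 * np.exp(-0.05 * trait)  # exact monotone function
        m = matrix_from_array(x, ["a"] * 5 + ["b"] * 5, trait=trait)
        res = quantitative_trait_corr(m, n_perm=500, seed=0)
        assert "P0" in res.genes
        assert res.stats.loc["P0", "r"] == pytest.approx(-1.0, abs=1e-6)

    def test_same_seed_identical_output(self):
        rng = np.random.default_rng(9)
        trait = rng.uniform(20, 80, 12)
        x = np.exp(rng.normal(np.log(300), 0.5, (40, 12)))
        m = matrix_from_array(x, ["a"] * 6 + ["b"] * 6, trait=trait)
        r1 = quantitative_trait_corr(m, n_perm=300, seed=5)
        r2 = quantitative_trait_corr(m, n_perm=300, seed=5)
        assert r1.genes == r2.genes and r1.k == r2.k

    def test_zero_variance_trait_rejected(self):
        m = matrix_from_array(np.ones((5, 6)), ["a"] * 3 + ["b"] * 3,
                              trait=np.full(6, 1.0))
        with pytest.raises(ValueError, match="variance"):
            quantitative_trait_corr(m)

    def test_exhaustive_for_small_sample_counts(self):
        rng = np.random.default_rng(10)
        trait = rng.uniform(0, 1, 5)
        x = np.exp(rng.normal(np.log(300), 0.5, (10, 5)))
        m = matrix_from_array(x, ["a"] * 2 + ["b"] * 3, trait=trait)
        res = quantitative_trait_corr(m, n_perm=1000, seed=0)
        assert res.exhaustive and res.n_perm_used == 120


class TestGeneratorScreenIntegration:
    def test_trait_coupled_genes_recovered_from_generator(self):
        rng = np.random.default_rng(11)
        trait = np.concatenate([rng.normal(72, 3, 6), rng.normal(20, 4, 6),
                                rng.normal(34, 5, 6)])
        classes = np.array(["sham"] * 6 + ["MI"] * 6 + ["MI+Val"] * 6)
        model = ExpressionModel(n_genes=300, n_class_affected=30, n_trait_coupled=20)
        m = generate_expression(trait, classes, model=model, seed=12)
        mf, _ = filter_probes(m)
        res = quantitative_trait_corr(mf, n_perm=500, seed=13)
        coupled = m.metadata["coupled_genes"]
        recovered = sum(g in coupled for g in res.genes)
        assert recovered >= 0.5 * len(coupled & set(mf.genes))
        # the coupling is negative: selected truly-coupled genes have r < 0
        sel = res.stats[res.stats["gene"].isin(coupled)].loc[
            [p for p in res.stats.index
             if res.stats.loc[p, "gene"] in coupled and res.stats.loc[p, "gene"] in res.genes]
        ]
        assert (sel["r"] < 0).all()
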