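"""TPM, expression filtering, time-course selection, clustering and links."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retroscape import synthetic_data as sd
from retroscape import te_expression as tx
from retroscape.io_formats import CountMatrix, GeneModel

from conftest import make_te


def small_counts(counts, lengths=None, meta=None):
    counts = np.asarray(counts)
    nf, ns = counts.shape
    if lengths is None:
        lengths = np.full(nf, 1000)
    if meta is None:
        meta = pd.DataFrame(
            {
                "tissue": ["dorsal"] * ns,
                "stage": ["I"] * ns,
                "replicate": range(1, ns + 1),
            },
            index=[f"s{i}" for i in range(ns)],
        )
    return CountMatrix(
        feature_ids=[f"f{i}" for i in range(nf)],
        feature_lengths=np.asarray(lengths),
        sample_ids=list(meta.index),
        counts=counts,
        sample_meta=meta,
    )


class TestLocation:
    GENES = [
        GeneModel("g", "chr1", "+", 50_000, 60_000, exons=[(50_000, 52_000), (55_000, 60_000)])
    ]

    def test_distance_classes(self):
        far = make_te("far", "chr1", 70_000, 70_100)
        prox = make_te("prox", "chr1", 63_000, 63_100)
        assert tx.classify_te_location([far], self.GENES)["far"] == "intergenic"
        assert tx.classify_te_location([prox], self.GENES)["prox"] == "proximal"

    def test_exonic_and_intronic_by_midpoint(self):
        ex = make_te("ex", "chr1", 55_500, 55_700)
        intr = make_te("in", "chr1", 53_000, 53_200)
        out = tx.classify_te_location([ex, intr], self.GENES)
        assert out["ex"] == "exonic" and out["in"] == "intronic"


class TestTPM:
    def test_worked_example(self):
        cm = small_counts([[10], [40]], lengths=[1000, 2000])
        t = tx.tpm(cm)
        assert t.iloc[0, 0] == pytest.approx(1e6 / 3)
        assert t.iloc[1, 0] == pytest.approx(2e6 / 3)

    def test_single_feature_is_million(self):
        t = tx.tpm(small_counts([[7, 3]]))
        assert (t.to_numpy() == 1e6).all()

    def test_columns_sum_to_million(self, rng):
        cm = small_counts(rng.integers(1, 500, size=(40, 6)), lengths=rng.integers(200, 5000, 40))
        t = tx.tpm(cm)
        np.testing.assert_allclose(t.sum(axis=0), 1e6, atol=1e-6)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty library"):
            tx.tpm(small_counts([[0, 5], [0, 5]]))


class TestFilter:
    def test_zero_feature_dropped(self):
        cm = small_counts([[0, 0, 0], [100, 100, 100]])
        kept = tx.filter_expressed(cm, groups=["a", "a", "b"])
        assert kept == ["f1"]

    def test_cpm_cutoff_from_median_library(self):
        # libraries ~1e4 -> cutoff = 10/median(lib)*1e6 = 1000 CPM ~ 10 counts
        counts = np.array([[10, 10, 0], [5, 5, 5]])
        cm = small_counts(np.vstack([counts, [[9980, 9985, 9995]]]))
        kept = tx.filter_expressed(cm, groups=["a", "a", "b"], min_total=15)
        # f0 reaches cutoff in exactly 2 samples = smallest group size, total 20
        assert "f0" in kept and "f1" not in kept


class TestTimecourseDE:
    def design(self):
        rows = []
        for tissue in ("dorsal", "abdominal"):
            for stage in ("I", "II", "III"):
                for rep in (1, 2, 3):
                    rows.append((f"{tissue}_{stage}_{rep}", tissue, stage, rep))
        return pd.DataFrame(
            [(t, s, r) for _, t, s, r in rows],
            columns=["tissue", "stage", "replicate"],
            index=[n for n, *_ in rows],
        )

    def test_perfect_linear_fit_selected(self):
        design = self.design()
        t = design["stage"].map({"I": 0, "II": 1, "III": 2}).to_numpy()
        y = 2.0 ** (1.0 + t) - 1.0  # log2(y+1) exactly linear in t
        expr = pd.DataFrame([y], index=["f0"], columns=design.index)
        (res,) = tx.timecourse_de(expr, design)
        assert res.R_squared == pytest.approx(1.0)
        assert res.selected

    def test_f_test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        design = self.design()
        expr = pd.DataFrame(
            rng.random((5, 18)) * 100, index=[f"f{i}" for i in range(5)],
            columns=design.index,
        )
        results = tx.timecourse_de(expr, design)
        t = design["stage"].map({"I": 0, "II": 1, "III": 2}).to_numpy().astype(float)
        g = (design["tissue"] == "abdominal").to_numpy().astype(float)
        X = sm.add_constant(np.column_stack([t, t**2, g, g * t, g * t**2]))
        for r, (_, y) in zip(results, expr.iterrows()):
            fit = sm.OLS(np.log2(y.to_numpy() + 1), X).fit()
            assert r.F_stat == pytest.approx(fit.fvalue, abs=1e-10)
            assert r.p == pytest.approx(fit.f_pvalue, abs=1e-10)
            assert r.R_squared == pytest.approx(fit.rsquared, abs=1e-10)

    def test_selection_monotone_in_thresholds(self, rng):
        cm, _ = sd.simulate_counts(sd.ExprSimConfig(n_features=300, n_planted=30, seed=3))
        expr = tx.tpm(cm)
        loose = {r.feature_id for r in tx.timecourse_de(expr, cm.sample_meta, alpha=0.05, r2_min=0.6) if r.selected}
        tight_alpha = {r.feature_id for r in tx.timecourse_de(expr, cm.sample_meta, alpha=0.01, r2_min=0.6) if r.selected}
        tight_r2 = {r.feature_id for r in tx.timecourse_de(expr, cm.sample_meta, alpha=0.05, r2_min=0.8) if r.selected}
        assert tight_alpha <= loose and tight_r2 <= loose

    def test_rank_deficient_design_rejected(self):
        design = self.design()
        design["stage"] = "I"  # single stage aliases t and t^2
        expr = pd.DataFrame(np.ones((2, 18)), index=["a", "b"], columns=design.index)
        with pytest.raises(ValueError):
            tx.timecourse_de(expr, design)

    def test_null_pvalues_uniform(self):
        cfg = sd.ExprSimConfig(n_features=1000, n_planted=0, seed=8)
        cm, _ = sd.simulate_counts(cfg)
        expr = tx.tpm(cm)
        res = tx.timecourse_de(expr, cm.sample_meta)
        pv = np.array([r.p for r in res])
        assert stats.kstest(pv, "uniform").pvalue > 0.01


class TestClustering:
    def test_two_planted_groups_k2(self, rng):
        base_a = np.sin(np.linspace(0, 3, 12))
        base_b = np.cos(np.linspace(0, 3, 12))
        rows = [base_a + rng.normal(0, 0.05, 12) for _ in range(10)]
        rows += [base_b + rng.normal(0, 0.05, 12) for _ in range(10)]
        expr = pd.DataFrame(rows, index=[f"f{i}" for i in range(20)])
        res = tx.cluster_profiles(expr, k_range=range(2, 8))
        assert res.k == 2
        first = {res.labels[f"f{i}"] for i in range(10)}
        second = {res.labels[f"f{i}"] for i in range(10, 20)}
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_three_orthogonal_profiles_k3(self, rng):
        t = np.linspace(0, 2 * np.pi, 12)
        bases = [np.sin(t), np.cos(t), np.sin(2 * t)]
        rows = [b + rng.normal(0, 0.05, 12) for b in bases for _ in range(8)]
        expr = pd.DataFrame(rows)
        res = tx.cluster_profiles(expr, k_range=range(2, 8))
        assert res.k == 3

    def test_identical_profiles_degenerate(self):
        expr = pd.DataFrame(np.tile(np.arange(6.0), (5, 1)))
        res = tx.cluster_profiles(expr)
        assert res.degenerate


class TestLinks:
    def test_nearest_deg_beyond_minimum_distance(self):
        te = make_te("TE_1", "chr1", 100_000, 100_500)
        near = GeneModel("gNear", "chr1", "+", 102_000, 104_000)  # 1.5 kb: too close
        far = GeneModel("gFar", "chr1", "+", 120_000, 125_000, annotation_label="DSG4")
        expr = pd.DataFrame(
            [[1, 2, 3, 4], [2, 4, 6, 8], [9, 7, 5, 3]],
            index=["TE_1", "gFar", "gNear"],
            columns=list("abcd"),
        )
        (link,) = tx.te_gene_links([te], [near, far], expr)
        assert link.gene_id == "gFar" and link.gene_label == "DSG4"
        assert link.distance_bp == 19_500

    def test_identical_profiles_r_one(self):
        te = make_te("TE_1", "chr1", 0, 100)
        g = GeneModel("g", "chr1", "+", 50_000, 60_000)
        expr = pd.DataFrame(
            [[1, 5, 9], [1, 5, 9]], index=["TE_1", "g"], columns=list("abc")
        )
        (link,) = tx.te_gene_links([te], [g], expr)
        assert link.pearson_r == pytest.approx(1.0)

    def test_anticorrelated_pair_negative_r(self):
        te = make_te("TE_1", "chr1", 0, 100)
        g = GeneModel("g", "chr1", "+", 50_000, 60_000)
        expr = pd.DataFrame(
            [[1, 5, 9], [9, 5, 1]], index=["TE_1", "g"], columns=list("abc")
        )
        (link,) = tx.te_gene_links([te], [g], expr)
        assert link.pearson_r < 0
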