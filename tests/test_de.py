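"""miRNA fold-change calls, signed-rank exactness, clustering, concordance,
and the empirical-Bayes moderated t."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nucmir import (
    ConfigurationError,
    DegeneratePriorError,
    ExpressionMatrix,
    InsufficientDataError,
    SampleMeta,
    cluster_high_expressers,
    cross_species_concordance,
    de_entities,
    mirna_differential,
    moderated_t_de,
    wilcoxon_delta_ct,
)
from nucmir.de import estimate_variance_prior

from conftest import make_ct


def _call(calls, entity, comparison):
    return next(
        c for c in calls if c.entity == entity and c.comparison == comparison
    )


class TestMirnaDifferential:
    def test_fold_and_direction(self, whole_cell_collapsed):
        calls = mirna_differential(whole_cell_collapsed)
        c = _call(calls, "mirA", ("granulocyte", "promyelocyte"))
        assert c.fold == pytest.approx(0.25)  # CT 26 vs 24 -> 2**-2
        assert c.direction == "down" and c.passes

    def test_undetectable_never_passes(self, whole_cell_collapsed):
        calls = mirna_differential(whole_cell_collapsed)
        assert not any(c.passes for c in calls if c.entity == "mirB")

    def test_twofold_inclusive(self):
        metas = [
            SampleMeta("a", "promyelocyte", "whole", 1),
            SampleMeta("b", "granulocyte", "whole", 1),
        ]
        m = make_ct({"a": [25.0], "b": [24.0]}, metas, ["mir1"])
        c = _call(
            mirna_differential(m), "mir1", ("granulocyte", "promyelocyte")
        )
        assert c.fold == 2.0 and c.passes  # "2-fold or more" is inclusive

    def test_reciprocal_folds(self, whole_cell_collapsed):
        calls = mirna_differential(whole_cell_collapsed)
        for a, b in itertools.combinations(
            whole_cell_collapsed.cell_types(), 2
        ):
            for e in ["mirA", "mirD"]:
                f1 = _call(calls, e, (a, b)).fold
                f2 = _call(calls, e, (b, a)).fold
                assert f1 * f2 == pytest.approx(1.0)

    def test_needs_two_cell_types(self):
        metas = [SampleMeta("a", "LSK", "whole", 1)]
        m = make_ct({"a": [24.0]}, metas, ["mir1"])
        with pytest.raises(ConfigurationError):
            mirna_differential(m)

    def test_de_entities_summary(self, whole_cell_collapsed):
        calls = mirna_differential(whole_cell_collapsed)
        assert "mirA" in de_entities(calls)
        assert "mirB" not in de_entities(calls)


class TestWilcoxon:
    def test_n5_all_positive_exact(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [0.0] * 5
        assert wilcoxon_delta_ct(a, b) == pytest.approx(0.0625)

    def test_n6_all_positive_exact(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        b = [0.0] * 6
        assert wilcoxon_delta_ct(a, b) == pytest.approx(0.03125)

    def test_no_signal(self):
        a = [1.0, 2.0, 3.0]
        with pytest.warns(UserWarning):
            assert wilcoxon_delta_ct(a, a) == 1.0

    @pytest.mark.parametrize("n", range(4, 11))
    def test_enumeration_oracle(self, n, rng):
        """Exact p agrees with explicit enumeration of all 2^n sign flips."""
        d = rng.normal(0.5, 1.0, size=n)
        d[d == 0] += 0.1
        p_impl = wilcoxon_delta_ct(d, np.zeros(n))
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        mean_w = n * (n + 1) / 4.0
        ws = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=n)
        ]
        dev = abs(w_obs - mean_w) - 1e-9
        p_oracle = sum(1 for w in ws if abs(w - mean_w) >= dev) / 2**n
        assert p_impl == pytest.approx(p_oracle)

    def test_matches_scipy_exact_on_tie_free_input(self, rng):
        d = rng.normal(0.3, 1.0, size=12)
        p_impl = wilcoxon_delta_ct(d, np.zeros(12))
        p_scipy = stats.wilcoxon(d, method="exact").pvalue
        assert p_impl == pytest.approx(p_scipy)

    def test_normal_approximation_large_n(self, rng):
        d = rng.normal(0.2, 1.0, size=60)
        p_impl = wilcoxon_delta_ct(d, np.zeros(60))
        p_scipy = stats.wilcoxon(d, method="approx", correction=True).pvalue
        assert p_impl == pytest.approx(p_scipy, rel=0.02)

    def test_unequal_lengths_rejected(self):
        from nucmir import ValidationError

        with pytest.raises(ValidationError):
            wilcoxon_delta_ct([1.0, 2.0], [1.0])


class TestClustering:
    def _matrix_with_groups(self):
        stages = ["LSK", "promyelocyte", "myelocyte", "granulocyte"]
        metas = [SampleMeta(f"{s}:whole", s, "whole", 1) for s in stages]
        # two "rising" assays (identical profiles), two "falling"
        rows = {
            "up1": [24.0, 23.0, 22.0, 21.0],
            "up2": [25.0, 24.0, 23.0, 22.0],
            "down1": [21.0, 22.0, 23.0, 24.0],
            "down2": [22.0, 23.0, 24.0, 25.0],
        }
        vals = {m.sample_id: [rows[a][i] for a in rows] for i, m in enumerate(metas)}
        return make_ct(vals, metas, list(rows))

    def test_groups_separate_in_leaf_order(self):
        m = self._matrix_with_groups()
        calls = mirna_differential(m)
        res = cluster_high_expressers(m, calls)
        order = res.entities
        ups = {order.index("up1"), order.index("up2")}
        downs = {order.index("down1"), order.index("down2")}
        assert max(ups) < min(downs) or max(downs) < min(ups)

    def test_identical_profiles_merge_at_zero(self):
        m = self._matrix_with_groups()
        calls = mirna_differential(m)
        res = cluster_high_expressers(m, calls)
        assert res.linkage[:, 2].min() == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(res.linkage[:, 2]) >= -1e-12)  # monotone heights

    def test_ct25_boundary_excluded(self):
        stages = ["promyelocyte", "granulocyte"]
        metas = [SampleMeta(f"{s}:whole", s, "whole", 1) for s in stages]
        m = make_ct(
            {"promyelocyte:whole": [25.0, 24.0], "granulocyte:whole": [27.0, 26.0]},
            metas,
            ["boundary", "high"],
        )
        calls = mirna_differential(m)
        with pytest.warns(UserWarning):  # only one assay survives the cut
            res = cluster_high_expressers(m, calls, ct_high=25.0)
        assert "boundary" not in res.selected and "high" in res.selected

    def test_too_few_selected_warns_empty(self, whole_cell_collapsed):
        calls = mirna_differential(whole_cell_collapsed, min_fold=100.0)
        with pytest.warns(UserWarning):
            res = cluster_high_expressers(whole_cell_collapsed, calls)
        assert res.empty


class TestConcordance:
    def test_monotone_transform_gives_unit_rho(self):
        a = {f"mir{i}": v for i, v in enumerate([-2.0, -1.0, 0.5, 1.0, 3.0])}
        b = {k: 2 * v for k, v in a.items()}
        res = cross_species_concordance(a, b)
        assert res.rho == pytest.approx(1.0)
        res2 = cross_species_concordance(a, {k: v**3 for k, v in a.items()})
        assert res2.rho == pytest.approx(1.0)  # rank-invariant

    def test_sign_flip_gives_minus_one(self):
        a = {f"mir{i}": float(v) for i, v in enumerate([-2, -1, 1, 2, 3])}
        res = cross_species_concordance(a, {k: -v for k, v in a.items()})
        assert res.rho == pytest.approx(-1.0)

    def test_species_prefix_mapping(self):
        a = {"mmu-miR-223": 2.0, "mmu-miR-16": -1.0, "mmu-miR-29a": 1.0}
        b = {"hsa-miR-223": 1.5, "hsa-miR-16": -0.5, "hsa-miR-29a": 0.7}
        res = cross_species_concordance(a, b)
        assert res.n_common == 3
        # all three pass |log2 fold| >= 1 in A; directions agree everywhere
        assert res.table == {"up_up": 2, "up_down": 0, "down_up": 0, "down_down": 1}

    def test_seeded_copula_recovery(self):
        # bivariate normal with Pearson rho 0.8 -> Spearman 6/pi*asin(rho/2)
        rng = np.random.default_rng(2024)
        rho = 0.8
        n = 64
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        a = {f"m{i}": z[i, 0] for i in range(n)}
        b = {f"m{i}": z[i, 1] for i in range(n)}
        expected = 6 / math.pi * math.asin(rho / 2)
        res = cross_species_concordance(a, b)
        assert res.rho == pytest.approx(expected, abs=0.1)

    def test_insufficient_overlap(self):
        with pytest.raises(InsufficientDataError):
            cross_species_concordance({"a": 1.0, "b": 2.0}, {"a": 1.0, "c": 2.0})


def _expr_matrix(data, groups):
    metas = [
        SampleMeta(f"s{i}", g, "whole", 1) for i, g in enumerate(groups)
    ]
    df = pd.DataFrame(
        data, index=[f"g{i}" for i in range(len(data))],
        columns=[m.sample_id for m in metas],
    )
    return ExpressionMatrix(df, metas), {m.sample_id: m.cell_type for m in metas}


class TestModeratedT:
    def test_matches_independent_recomputation(self, rng):
        """Step-by-step oracle: moment estimators and shrinkage recomputed from
        scratch (different code path) on a 20-gene 3v3 toy matrix."""
        from scipy.special import digamma, polygamma

        data = rng.normal(8.0, 1.0, size=(20, 6))
        data[:5, :3] += 2.0
        x, groups = _expr_matrix(data, ["A"] * 3 + ["B"] * 3)
        fit = moderated_t_de(x, groups, comparison=("A", "B"))

        # oracle
        g1, g2 = data[:, :3], data[:, 3:]
        lfc = g1.mean(1) - g2.mean(1)
        df = 4
        s2 = (
            ((g1 - g1.mean(1, keepdims=True)) ** 2).sum(1)
            + ((g2 - g2.mean(1, keepdims=True)) ** 2).sum(1)
        ) / df
        e = np.log(s2) - digamma(df / 2) + np.log(df / 2)
        var_e = e.var(ddof=1)
        excess = var_e - polygamma(1, df / 2)
        assert excess > 0  # heterogeneous toy data
        # invert trigamma by bisection (independent of the package's Newton)
        lo, hi = 1e-6, 1e6
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if polygamma(1, mid) > excess:
                lo = mid
            else:
                hi = mid
        d0 = 2 * lo
        s0 = math.exp(e.mean() + digamma(d0 / 2) - math.log(d0 / 2))
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        t_oracle = lfc / np.sqrt(s2_post * (2 / 3))
        p_oracle = 2 * stats.t.sf(np.abs(t_oracle), d0 + df)

        assert fit.d_prior == pytest.approx(d0, rel=1e-4)
        assert fit.s2_prior == pytest.approx(s0, rel=1e-4)
        got_t = np.array([r.t_moderated for r in fit.results])
        got_p = np.array([r.p_moderated for r in fit.results])
        np.testing.assert_allclose(got_t, t_oracle, rtol=1e-4)
        np.testing.assert_allclose(got_p, p_oracle, rtol=1e-3)

    def test_prior_df_zero_is_ordinary_t(self, rng):
        data = rng.normal(0.0, 1.0, size=(50, 6))
        x, groups = _expr_matrix(data, ["A"] * 3 + ["B"] * 3)
        fit = moderated_t_de(x, groups, comparison=("A", "B"), prior_df=0)
        t_ref, p_ref = stats.ttest_ind(data[:, :3], data[:, 3:], axis=1)
        np.testing.assert_allclose(
            [r.t_moderated for r in fit.results], t_ref, rtol=1e-9
        )
        np.testing.assert_allclose(
            [r.p_moderated for r in fit.results], p_ref, rtol=1e-9
        )

    def test_equal_variances_shrink_to_point(self, rng):
        """With no variance heterogeneity the prior absorbs everything and the
        moderated t uses the common variance for every gene."""
        n_genes = 400
        data = rng.normal(0.0, 1.0, size=(n_genes, 6))
        # force all gene variances identical by standardising residuals
        for i in range(n_genes):
            for block in (slice(0, 3), slice(3, 6)):
                v = data[i, block]
                data[i, block] = (v - v.mean()) / v.std(ddof=1)
        x, groups = _expr_matrix(data, ["A"] * 3 + ["B"] * 3)
        fit = moderated_t_de(x, groups, comparison=("A", "B"))
        assert math.isinf(fit.d_prior)
        post = {r.s2_posterior for r in fit.results}
        assert all(v == pytest.approx(fit.s2_prior) for v in post)

    def test_posterior_variance_between_prior_and_gene(self, rng):
        data = rng.normal(0, 1, size=(200, 6))
        data *= rng.uniform(0.3, 3.0, size=(200, 1))  # heterogeneous variances
        x, groups = _expr_matrix(data, ["A"] * 3 + ["B"] * 3)
        fit = moderated_t_de(x, groups, comparison=("A", "B"))
        for r in fit.results:
            lo, hi = sorted((fit.s2_prior, r.s2_gene))
            assert lo - 1e-12 <= r.s2_posterior <= hi + 1e-12

    def test_large_prior_df_converges_to_prior(self, rng):
        data = rng.normal(0, 1, size=(100, 6))
        data *= rng.uniform(0.3, 3.0, size=(100, 1))
        x, groups = _expr_matrix(data, ["A"] * 3 + ["B"] * 3)
        fit = moderated_t_de(x, groups, comparison=("A", "B"), prior_df=1e9)
        for r in fit.results:
            assert r.s2_posterior == pytest.approx(fit.s2_prior, rel=1e-6)

    def test_all_zero_variance_degenerate(self):
        data = np.tile(np.arange(6.0), (5, 1))  # zero within-group variance
        data[:, :3] = 1.0
        data[:, 3:] = 2.0
        x, groups = _expr_matrix(data, ["A"] * 3 + ["B"] * 3)
        with pytest.raises(DegeneratePriorError):
            moderated_t_de(x, groups, comparison=("A", "B"))

    def test_significance_requires_both_filters(self, rng):
        data = rng.normal(8.0, 0.1, size=(10, 6))
        data[0, :3] += 2.0  # large fold, tiny variance -> significant
        data[1, :3] += 0.2  # significant p possible but fold < 2
        x, groups = _expr_matrix(data, ["A"] * 3 + ["B"] * 3)
        fit = moderated_t_de(x, groups, comparison=("A", "B"))
        by_gene = {r.gene: r for r in fit.results}
        assert by_gene["g0"].significant
        assert not by_gene["g1"].significant  # |lfc| < 1


def test_matches_limma_on_toy_matrix(tmp_path, rng):
    """Cross-check the moderated t against the canonical R implementation."""
    import shutil
    import subprocess

    rscript = shutil.which("Rscript")
    if rscript is None:
        pytest.skip("Rscript not available")
    data = rng.normal(8.0, 1.0, size=(40, 6)) * rng.uniform(0.5, 2.0, size=(40, 1))
    data[:8, :3] += rng.uniform(1.0, 3.0, size=(8, 3))
    csv = tmp_path / "x.csv"
    np.savetxt(csv, data, delimiter=",")
    script = tmp_path / "limma.R"
    script.write_text(
        """
suppressMessages(library(limma))
x <- as.matrix(read.csv(commandArgs(TRUE)[1], header=FALSE))
design <- cbind(ref=1, test=c(1,1,1,0,0,0))
fit <- eBayes(lmFit(x, design))
out <- data.frame(t=fit$t[,"test"], p=fit$p.value[,"test"],
                  d0=fit$df.prior, s02=fit$s2.prior)
write.csv(out, commandArgs(TRUE)[2], row.names=FALSE)
"""
    )
    out_csv = tmp_path / "limma_out.csv"
    subprocess.run(
        [rscript, str(script), str(csv), str(out_csv)], check=True,
        capture_output=True,
    )
    ref = pd.read_csv(out_csv)
    x, groups = _expr_matrix(data, ["A"] * 3 + ["B"] * 3)
    fit = moderated_t_de(x, groups, comparison=("A", "B"))
    assert fit.d_prior == pytest.approx(ref["d0"][0], rel=1e-3)
    assert fit.s2_prior == pytest.approx(ref["s02"][0], rel=1e-3)
    np.testing.assert_allclose(
        [r.t_moderated for r in fit.results], ref["t"], rtol=1e-3
    )
    np.testing.assert_allclose(
        [r.p_moderated for r in fit.results], ref["p"], rtol=1e-3
    )
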