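"""Normalisation, FDR, NB GLM and the classifiers, against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from outronscan.diff_stats import (
    bh_adjust,
    call_22g_targets,
    classify_interaction,
    classify_small_rna,
    fit_nb_glm,
    interaction_design,
    nb_wald_de,
    size_factors_median_ratio,
)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = np.tile(np.array([[10], [40], [7]]), (1, 2))
        np.testing.assert_allclose(size_factors_median_ratio(counts), [1.0, 1.0])

    def test_doubled_sample_closed_form(self):
        rng = np.random.default_rng(0)
        base = rng.integers(5, 500, size=200)
        counts = np.column_stack([base, 2 * base])
        np.testing.assert_allclose(
            size_factors_median_ratio(counts), [2**-0.5, 2**0.5], atol=1e-6
        )

    def test_gene_with_zero_excluded_from_reference(self):
        # the zero-containing gene would otherwise drag sample 2's factor down
        counts = np.array([[10, 10], [0, 1000]])
        np.testing.assert_allclose(size_factors_median_ratio(counts), [1.0, 1.0])

    def test_no_all_positive_gene_raises(self):
        with pytest.raises(ValueError):
            size_factors_median_ratio(np.array([[0, 1], [1, 0]]))

    def test_scale_equivariance_of_relative_factors(self):
        # scaling one sample by c multiplies its factor relative to any other
        # sample by c (the geometric-mean reference absorbs a c^(1/n) term)
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 300, size=(100, 4)).astype(float)
        f0 = size_factors_median_ratio(counts)
        scaled = counts.copy()
        scaled[:, 2] *= 3.0
        f1 = size_factors_median_ratio(scaled)
        assert f1[2] / f1[0] == pytest.approx(3.0 * f0[2] / f0[0], rel=1e-9)
        assert f1[1] / f1[0] == pytest.approx(f0[1] / f0[0], rel=1e-9)


class TestBhAdjust:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_all_ones_stay_one(self):
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == 0.123

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_matches_statsmodels_oracle(self, pvals):
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(pvals), expected, atol=1e-12)

    def test_monotone_and_order_preserving(self):
        rng = np.random.default_rng(3)
        p = rng.random(200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj >= p)


class TestNbWaldGlm:
    def test_flat_counts_give_null_result(self):
        counts = pd.DataFrame([[50] * 6], index=["g"])
        res = nb_wald_de(counts, np.array(["a"] * 3 + ["b"] * 3), "a",
                         size_factors=np.ones(6))
        assert res.log2fc.iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert res.wald_p.iloc[0] > 0.9

    def test_single_gene_matches_statsmodels_nb_fit(self):
        """IRLS coefficients agree with statsmodels GLM at the same dispersion."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        n = 8
        X = np.column_stack([np.ones(2 * n), [0] * n + [1] * n]).astype(float)
        r = 1 / 0.08
        y = np.concatenate([
            rng.negative_binomial(r, r / (r + 80.0), n),
            rng.negative_binomial(r, r / (r + 240.0), n),
        ]).astype(float)
        fit = fit_nb_glm(y, X, np.ones(2 * n))
        oracle = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=fit.dispersion)
        ).fit()
        np.testing.assert_allclose(fit.coef, oracle.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, oracle.bse, rtol=1e-4)

    def test_size_factor_offsets_recover_depth_free_lfc(self):
        rng = np.random.default_rng(13)
        sf = np.array([0.5, 1.0, 2.0, 0.5, 1.0, 2.0])
        r = 1 / 0.02
        mu = np.concatenate([100 * sf[:3], 400 * sf[3:]])
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu), size=(200, 6)), columns=list("abcdef")
        )
        res = nb_wald_de(counts, np.array(["c"] * 3 + ["t"] * 3), "c",
                         size_factors=sf)
        assert res.log2fc.mean() == pytest.approx(2.0, abs=0.1)

    def test_all_zero_gene_flagged_not_significant(self):
        counts = pd.DataFrame([[0] * 6, [30, 31, 29, 60, 61, 62]], index=["z", "g"])
        res = nb_wald_de(counts, np.array(["a"] * 3 + ["b"] * 3), "a",
                         size_factors=np.ones(6))
        assert not res.loc["z", "converged"]
        assert res.loc["z", "wald_p"] == 1.0


class TestInteractionDesign:
    def test_reference_levels_wt_control(self):
        sheet = pd.DataFrame(
            {
                "genotype": ["wt", "wt", "mutant", "mutant"],
                "treatment": ["control", "rnai", "control", "rnai"],
            }
        )
        X = interaction_design(sheet)
        np.testing.assert_array_equal(
            X,
            [[1, 0, 0, 0], [1, 0, 1, 0], [1, 1, 0, 0], [1, 1, 1, 1]],
        )


class TestClassifySmallRna:
    @pytest.mark.parametrize(
        "length,nt,rel,biotype,expected",
        [
            (22, "G", "antisense", "protein_coding", "22G"),
            (21, "G", "antisense", "protein_coding", "22G"),
            (23, "G", "antisense", "protein_coding", "22G"),
            (22, "A", "antisense", "protein_coding", "other"),
            (20, "G", "antisense", "protein_coding", "other"),
            (22, "G", "sense", "protein_coding", "other"),
            (22, "G", "sense", "miRNA", "miRNA"),
            (22, "A", "sense", "miRNA", "miRNA"),
        ],
    )
    def test_rule_table(self, length, nt, rel, biotype, expected):
        assert classify_small_rna(length, nt, rel, biotype) == expected

    def test_mirna_priority_over_22g(self):
        assert classify_small_rna(22, "G", "sense", "miRNA") == "miRNA"


class TestCall22gTargets:
    @staticmethod
    def _de(genes, lfcs, padjs):
        return pd.DataFrame({"log2fc": lfcs, "padj": padjs}, index=genes)

    def test_quadrant_rule(self):
        sm = self._de(["g1", "g2"], [1.2, 2.0], [0.003, 0.001])
        mr = self._de(["g1", "g2"], [-1.5, 1.0], [0.001, 0.001])
        out = call_22g_targets(sm, mr)
        assert bool(out.loc["g1", "candidate"]) is True
        assert bool(out.loc["g2", "candidate"]) is False  # mRNA up

    def test_non_significant_side_blocks_candidacy(self):
        sm = self._de(["g"], [1.2], [0.2])
        mr = self._de(["g"], [-1.5], [0.001])
        assert not call_22g_targets(sm, mr)["candidate"].any()

    def test_gene_missing_on_one_side_skipped(self):
        sm = self._de(["g1", "g2"], [1.0, 1.0], [0.01, 0.01])
        mr = self._de(["g1"], [-1.0], [0.01])
        out = call_22g_targets(sm, mr)
        assert list(out.index) == ["g1"]


class TestClassifyInteraction:
    @staticmethod
    def _model(beta_t, beta_i, padj_t, padj_i):
        return pd.DataFrame(
            {
                "beta_treatment": [beta_t],
                "beta_interaction": [beta_i],
                "padj_treatment": [padj_t],
                "padj_interaction": [padj_i],
            },
            index=["g"],
        )

    @pytest.mark.parametrize(
        "beta_t,beta_i,padj_i,expected",
        [
            (-1.0, 1.5, 0.01, "reversed"),     # combined +0.5
            (-1.0, 0.6, 0.01, "attenuated"),   # combined -0.4
            (-1.0, 0.6, 0.2, "unchanged"),     # interaction not significant
            (-0.2, 1.5, 0.01, "not_candidate"),  # wt effect too weak
        ],
    )
    def test_rule_table(self, beta_t, beta_i, padj_i, expected):
        out = classify_interaction(self._model(beta_t, beta_i, 0.001, padj_i))
        assert out["class"].iloc[0] == expected

    def test_pure_function_same_input_same_output(self):
        model = self._model(-1.0, 1.5, 0.001, 0.01)
        a = classify_interaction(model)
        b = classify_interaction(model)
        pd.testing.assert_frame_equal(a, b)
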