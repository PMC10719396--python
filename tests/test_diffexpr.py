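"""NB differential-expression core: normalization, dispersion, Wald, shrinkage, BH."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syncom_metatx.datatypes import CountMatrix
from syncom_metatx.diffexpr import (
    NegativeBinomialDE,
    StrainIneligibleError,
    bh_adjust,
    de_pipeline,
    estimate_dispersions,
    nb_wald_test,
    run_per_strain_de,
    shrink_lfc,
    size_factors,
)

COND6 = ["matrix"] * 3 + ["root"] * 3
X6 = np.array([0, 0, 0, 1, 1, 1], dtype=float)


def _nb_counts(rng, mu_matrix, alpha):
    n = (1.0 / alpha)[:, None]
    return rng.negative_binomial(n, n / (n + mu_matrix))


class TestSizeFactors:
    def test_median_of_ratios_by_hand(self):
        counts = pd.DataFrame({"s1": [2.0, 8.0], "s2": [4.0, 16.0]})
        sf = size_factors(counts, min_ref_genes=2)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2), abs=1e-4)
        assert sf["s2"] == pytest.approx(np.sqrt(2), abs=1e-4)

    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5.0, 9.0, 3.0]})
        counts["b"] = counts["a"]
        assert (size_factors(counts, min_ref_genes=3) == 1.0).all()

    def test_single_sample_unit_factor(self):
        assert (size_factors(pd.DataFrame({"a": [5.0, 2.0]})) == 1.0).all()

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, (100, 6)) + 1, columns=list("abcdef"))
        sf = size_factors(counts)
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_reference_genes_is_ineligible(self):
        counts = pd.DataFrame({"a": [0.0, 5.0], "b": [3.0, 0.0]})
        with pytest.raises(StrainIneligibleError):
            size_factors(counts, min_ref_genes=1)


class TestDispersions:
    def test_moments_formula_by_hand(self):
        # two samples with mean 10 and ddof-1 variance 30 -> raw = 20/100
        dev = np.sqrt(15.0)
        counts = pd.DataFrame({"a": [10 - dev], "b": [10 + dev]})
        sf = pd.Series([1.0, 1.0], index=["a", "b"])
        disp = estimate_dispersions(counts, sf)
        assert disp.loc[0, "raw"] == pytest.approx(0.2)

    def test_poisson_gene_hits_floor(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(200, (300, 6)), columns=list("abcdef"))
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersions(counts, sf, condition=X6)
        # Poisson data: most raw values are at the floor or tiny
        assert np.nanmedian(disp["raw"]) < 0.01

    def test_known_dispersion_recovered_at_n50(self):
        rng = np.random.default_rng(2)
        mu = np.full(500, 100.0)
        alpha = np.full(500, 0.1)
        counts = pd.DataFrame(_nb_counts(rng, np.tile(mu[:, None], (1, 50)), alpha))
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersions(counts, sf)
        assert 0.05 <= np.nanmedian(disp["final"]) <= 0.2

    def test_all_zero_gene_untracked(self):
        counts = pd.DataFrame({"a": [0.0, 5.0], "b": [0.0, 7.0]})
        sf = pd.Series(1.0, index=counts.columns)
        disp = estimate_dispersions(counts, sf)
        assert np.isnan(disp.loc[0, "final"])


class TestWald:
    def test_flat_gene_has_zero_lfc_and_p_one(self):
        counts = pd.DataFrame(np.full((1, 6), 25.0), columns=list("abcdef"))
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.DataFrame({"final": [0.05]}, index=counts.index)
        res = nb_wald_test(counts, sf, disp, COND6)
        assert res.loc[0, "log2FC_mle"] == pytest.approx(0.0, abs=1e-8)
        assert res.loc[0, "pvalue"] == pytest.approx(1.0)

    def test_fourfold_change_gives_lfc_two(self):
        counts = pd.DataFrame(
            [[10.0, 10.0, 10.0, 40.0, 40.0, 40.0]], columns=list("abcdef")
        )
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.DataFrame({"final": [1e-8]}, index=counts.index)
        res = nb_wald_test(counts, sf, disp, COND6)
        assert res.loc[0, "log2FC_mle"] == pytest.approx(2.0, abs=1e-6)

    def test_poisson_limit_matches_mean_ratio(self):
        rng = np.random.default_rng(3)
        mu = rng.uniform(500, 2000, 50)
        lfc = rng.normal(0, 1, 50)
        mu_mat = mu[:, None] * np.power(2.0, lfc[:, None] * X6[None, :])
        counts = pd.DataFrame(rng.poisson(mu_mat), columns=list("abcdef"))
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.DataFrame({"final": np.full(50, 1e-8)}, index=counts.index)
        res = nb_wald_test(counts, sf, disp, COND6)
        expected = np.log2(counts.iloc[:, 3:].mean(axis=1) / counts.iloc[:, :3].mean(axis=1))
        np.testing.assert_allclose(res["log2FC_mle"], expected, atol=1e-3)

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as smapi

        rng = np.random.default_rng(4)
        mu = rng.lognormal(4, 1, 15)
        alpha = np.full(15, 0.08)
        lfc = rng.normal(0, 1, 15)
        mu_mat = mu[:, None] * np.power(2.0, lfc[:, None] * X6[None, :])
        y = _nb_counts(rng, mu_mat, alpha)
        counts = pd.DataFrame(y, columns=list("abcdef"))
        sf = pd.Series([0.8, 1.0, 1.25, 0.9, 1.1, 1.01], index=counts.columns)
        sf = sf / np.exp(np.log(sf).mean())
        disp = pd.DataFrame({"final": alpha}, index=counts.index)
        mine = nb_wald_test(counts, sf, disp, COND6)
        design = smapi.add_constant(X6)
        for i in range(15):
            ref = smapi.GLM(
                y[i], design,
                family=smapi.families.NegativeBinomial(alpha=alpha[i]),
                offset=np.log(sf.to_numpy()),
            ).fit()
            assert mine.loc[i, "log2FC_mle"] == pytest.approx(ref.params[1] / np.log(2), abs=1e-4)
            assert mine.loc[i, "SE"] == pytest.approx(ref.bse[1] / np.log(2), abs=1e-4)

    def test_deg_set_invariant_to_relabeling_within_compartment(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.poisson(60, (200, 6)), columns=list("abcdef"))
        res1 = de_pipeline(counts, COND6, min_ref_genes=5)
        shuffled = counts[["b", "c", "a", "f", "d", "e"]]
        res2 = de_pipeline(shuffled, COND6, min_ref_genes=5)
        set1 = set(res1.index[(res1["padj"] < 0.05).fillna(False)])
        set2 = set(res2.index[(res2["padj"] < 0.05).fillna(False)])
        assert set1 == set2


class TestShrinkage:
    def _frame(self, mle, se):
        return pd.DataFrame(
            {
                "baseMean": np.full(len(mle), 50.0),
                "log2FC_mle": mle,
                "SE": se,
                "pvalue": np.full(len(mle), 0.5),
                "tested": True,
            }
        )

    def test_tiny_se_keeps_mle(self):
        de = self._frame([2.0] * 10 + [0.5] * 10, [1e-6] * 20)
        out = shrink_lfc(de)
        assert out.loc[0, "log2FC_shrunk"] == pytest.approx(2.0, abs=1e-6)

    def test_huge_se_shrinks_to_zero(self):
        de = self._frame([2.0] * 19 + [3.0], [0.1] * 19 + [1e6])
        out = shrink_lfc(de)
        assert abs(out.loc[19, "log2FC_shrunk"]) < 1e-6

    def test_never_exceeds_mle_magnitude(self):
        rng = np.random.default_rng(6)
        de = self._frame(rng.normal(0, 2, 100), rng.uniform(0.01, 3, 100))
        out = shrink_lfc(de)
        assert (out["log2FC_shrunk"].abs() <= out["log2FC_mle"].abs() + 1e-12).all()

    def test_degenerate_all_infinite_se(self):
        de = self._frame([1.0, -1.0], [np.inf, np.inf])
        out = shrink_lfc(de)
        assert (out["log2FC_shrunk"] == 0.0).all()


class TestBH:
    def test_hand_example(self):
        got = bh_adjust(pd.Series([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_adjust(pd.Series([0.3]))[0] == pytest.approx(0.3)
        assert (bh_adjust(pd.Series([1.0, 1.0, 1.0])) == 1.0).all()

    def test_nan_passthrough(self):
        got = bh_adjust(pd.Series([0.01, np.nan, 0.04]))
        assert np.isnan(got[1])
        assert got.notna().sum() == 2

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(pd.Series([0.5, 1.5]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_brute_force_definition(self, pvals):
        got = bh_adjust(pd.Series(pvals)).to_numpy()
        m = len(pvals)
        order = np.argsort(pvals, kind="stable")
        expected = np.empty(m)
        for rank_pos, i in enumerate(order):
            candidates = [
                min(1.0, m * pvals[j] / (list(order).index(j) + 1))
                for j in order[rank_pos:]
            ]
            expected[i] = min(candidates)
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestPerStrain:
    def _matrix(self, rng, eligible=True):
        feats = pd.DataFrame(
            {
                "strain_id": ["A"] * 50 + ["B"] * 20,
                "kingdom": "bacteria",
                "orthogroup_id": [f"og{i}" for i in range(70)],
                "length": 200,
                "cog_category": "C",
            },
            index=[f"g{i}" for i in range(70)],
        )
        samples = pd.DataFrame(
            {"compartment": COND6, "replicate": [1, 2, 3, 1, 2, 3]},
            index=list("abcdef"),
        )
        counts = pd.DataFrame(
            rng.poisson(40, (70, 6)).astype(float), index=feats.index, columns=samples.index
        )
        counts.iloc[50:, :] = 0.0  # strain B: nothing detected in all samples
        counts.iloc[50:, 0] = 1.0
        return CountMatrix(counts=counts, samples=samples, features=feats)

    def test_ineligible_strain_reported_with_reason(self):
        cm = self._matrix(np.random.default_rng(7))
        out = run_per_strain_de(cm)
        assert out["A"].tested
        assert not out["B"].tested
        assert "cannot normalize" in out["B"].status

    def test_housekeeping_qc_flags(self):
        rng = np.random.default_rng(8)
        cm = self._matrix(rng)
        out = run_per_strain_de(cm, housekeeping={"A": ["g0", "g1"]})
        assert set(out["A"].housekeeping_flags) == {"g0", "g1"}

    def test_missing_compartment_errors(self):
        cm = self._matrix(np.random.default_rng(9))
        only_root = CountMatrix(
            counts=cm.counts[["d", "e", "f"]],
            samples=cm.samples.loc[["d", "e", "f"]],
            features=cm.features,
        )
        with pytest.raises(ValueError, match="matrix"):
            run_per_strain_de(only_root)


class TestEstimator:
    def test_sklearn_surface(self):
        rng = np.random.default_rng(10)
        counts = pd.DataFrame(
            rng.poisson(50, (6, 40)), columns=[f"g{i}" for i in range(40)], index=list("abcdef")
        )
        est = NegativeBinomialDE(min_ref_genes=5)
        assert est.get_params()["min_ref_genes"] == 5
        est.fit(counts, COND6)
        assert est.results_.shape[0] == 40
        assert (est.size_factors_ > 0).all()
        calls = est.predict()
        assert calls.dtype == bool
        with pytest.raises(ValueError):
            est.set_params(bogus=1)
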