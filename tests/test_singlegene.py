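"""SGLQ identifiability, forest importance, fail-both logic, AIC selection."""

import numpy as np
import pandas as pd
import pytest

import radiosig.singlegene as sg
from radiosig.exceptions import InsufficientDataError


class TestSGLQ:
    @pytest.mark.parametrize(
        "alpha,beta", [(0.2, 0.3), (-0.15, 0.05), (0.0, 0.4), (0.3, -0.1)]
    )
    def test_noise_free_recovery_is_exact(self, alpha, beta):
        """Linear-in-parameters on the log scale: exact identifiability."""
        E = np.linspace(-1.5, 1.5, 7)
        sf = np.exp(alpha * E - beta * E**2)
        sf = np.minimum(sf, 10.0)  # keep positive, no clipping needed here
        reg = sg.SGLQRegressor().fit(E, sf)
        assert reg.alpha_ == pytest.approx(alpha, abs=1e-10)
        assert reg.beta_ == pytest.approx(beta, abs=1e-10)
        np.testing.assert_allclose(reg.predict(E), sf, atol=1e-10)

    def test_prediction_at_zero_expression_is_one(self):
        reg = sg.SGLQRegressor().fit(
            np.array([-1.0, 0.5, 1, 2]), np.array([0.5, 0.9, 0.7, 0.4])
        )
        assert reg.predict([0.0])[0] == pytest.approx(1.0)

    def test_sf2_identically_one_gives_null_fit(self):
        reg = sg.SGLQRegressor().fit(np.array([-1.0, 0, 1, 2]), np.ones(4))
        assert (reg.alpha_, reg.beta_) == (0.0, 0.0)
        assert not reg.pass_

    def test_constant_expression_is_rank_deficient(self):
        reg = sg.SGLQRegressor().fit(np.ones(5), np.full(5, 0.5))
        assert reg.rank_deficient_ and not reg.pass_

    def test_nonpositive_sf_rejected(self):
        with pytest.raises(ValueError):
            sg.SGLQRegressor().fit(np.arange(4.0), np.array([0.5, 0.2, 0.0, 0.1]))

    def test_fit_sglq_aligns_cell_lines(self):
        E = pd.Series([0.1, 0.7, -0.5, 1.2], index=list("ABCD"), name="g1")
        sf2 = pd.Series([0.8, 0.5, 0.9, 0.45], index=list("DCBA"))
        fit = sg.fit_sglq(E, sf2)
        ref = sg.SGLQRegressor().fit(
            E.to_numpy(), sf2[list("ABCD")].to_numpy()
        )
        assert fit.alpha == pytest.approx(ref.alpha_)
        with pytest.raises(InsufficientDataError):
            sg.fit_sglq(E.iloc[:2], sf2)


class TestForest:
    def _signal_data(self, seed=0, n=40, noise_genes=50):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, noise_genes + 1))
        y = np.exp(-np.abs(X[:, 0])) * 0.8 + rng.normal(0, 0.02, n)
        return X, y

    def test_single_signal_gene_ranks_first(self):
        X, y = self._signal_data()
        forest = sg.RadiosensitivityForest(n_trees=150, random_state=1).fit(X, y)
        assert int(np.argmax(forest.importances_)) == 0
        assert forest.importances_[0] > 0

    def test_constant_target_gives_no_positive_importance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 10))
        forest = sg.RadiosensitivityForest(n_trees=50, random_state=3).fit(
            X, np.full(30, 0.5)
        )
        assert (forest.importances_ <= 0).all()

    def test_same_seed_is_bit_reproducible(self):
        X, y = self._signal_data(seed=5, noise_genes=10)
        a = sg.RadiosensitivityForest(n_trees=60, random_state=9).fit(X, y)
        b = sg.RadiosensitivityForest(n_trees=60, random_state=9).fit(X, y)
        np.testing.assert_array_equal(a.importances_, b.importances_)

    def test_rf_importance_wrapper_shapes(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(
            rng.normal(size=(6, 10)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"L{i}" for i in range(10)],
        )
        sf2 = pd.Series(rng.uniform(0.2, 0.9, 10), index=expr.columns)
        out = sg.rf_importance(expr, sf2, n_trees=30, seed=0)
        assert list(out.index) == list(expr.index)
        assert set(out.columns) == {"rf_importance", "rf_pass"}

    def test_invalid_tree_count(self):
        with pytest.raises(ValueError):
            sg.RadiosensitivityForest(n_trees=0).fit(
                np.zeros((6, 2)), np.zeros(6)
            )


class TestFailBoth:
    def _inputs(self):
        imp = pd.DataFrame(
            {"rf_importance": [0.5, -0.1, -0.2], "rf_pass": [True, False, False]},
            index=["a", "b", "c"],
        )
        fits = {
            "a": sg.SGLQFit("a", 0.1, 0.1, 0.5, 0.001, sglq_pass=True),
            "b": sg.SGLQFit("b", 0.1, 0.1, 0.5, 0.01, sglq_pass=True),
            "c": sg.SGLQFit("c", 0.0, 0.0, 0.0, 0.9, sglq_pass=False),
        }
        return imp, fits

    def test_or_logic_retains_single_pass_genes(self):
        imp, fits = self._inputs()
        retained, report = sg.fail_both_filter(imp, fits)
        assert retained == ["a", "b"]  # b passes only SGLQ
        assert report.excluded == ["c"]

    def test_never_excludes_a_passing_gene(self):
        imp, fits = self._inputs()
        retained, _ = sg.fail_both_filter(imp, fits)
        for g in retained:
            assert bool(imp.loc[g, "rf_pass"]) or fits[g].sglq_pass

    def test_gene_set_mismatch_raises(self):
        imp, fits = self._inputs()
        del fits["c"]
        with pytest.raises(KeyError):
            sg.fail_both_filter(imp, fits)

    def test_report_percentages_match_printed_arithmetic(self):
        report = sg.ExclusionReport(n_total=832, n_excluded=289, excluded=[])
        assert report.pct_excluded == 34.7
        assert report.pct_retained == 65.3
        assert report.n_retained == 543


class TestDoseLinearity:
    def test_exact_linear_selects_degree_one_with_floor(self):
        doses = np.array([0.0, 2, 5, 6, 7])
        Y = pd.DataFrame((2.0 * doses + 1.0)[None, :], index=["g"])
        with pytest.warns(UserWarning, match="floor"):
            best = sg.dose_linearity_aic(doses, Y)
        assert best["g"] == 1

    def test_strong_cubic_curvature_selects_degree_three(self):
        doses = np.repeat([0.0, 2, 5, 6, 7], 10)
        rng = np.random.default_rng(0)
        Y = pd.DataFrame(((doses - 3) ** 3 + rng.normal(0, 0.5, doses.size))[None, :])
        assert sg.dose_linearity_aic(doses, Y).iloc[0] == 3

    def test_underdetermined_degrees_are_skipped(self):
        doses = np.array([0.0, 2, 5, 6])  # 4 levels: degree 4 not estimable
        Y = pd.DataFrame((doses * 1.5)[None, :])
        with pytest.warns(UserWarning, match="floor"):
            best = sg.dose_linearity_aic(doses, Y, degrees=(1, 4))
        assert best.iloc[0] == 1
        with pytest.raises(InsufficientDataError):
            sg.dose_linearity_aic(doses, Y, degrees=(4,))

    def test_too_few_dose_levels(self):
        with pytest.raises(InsufficientDataError):
            sg.dose_linearity_aic(
                np.array([0.0, 1, 2]), pd.DataFrame(np.zeros((1, 3)))
            )
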