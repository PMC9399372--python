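"""ANOVA filter, profile library and permutation-significance behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import radiosig.timecourse as tc
from radiosig.exceptions import InsufficientDataError


def _experiment(values, lines, hours, genes=None):
    cols = pd.MultiIndex.from_tuples(
        [(l, h) for l in lines for h in hours], names=["cell_line", "hour"]
    )
    genes = genes or [f"g{i}" for i in range(len(values))]
    return tc.TimeCourseExperiment(
        values=pd.DataFrame(values, index=genes, columns=cols)
    )


class TestAnova:
    def test_textbook_two_group_f_statistic(self):
        # groups {1,2} and {3,4}: SSB=4 (df 1), SSW=1 (df 2) -> F=8
        F, p = tc.oneway_anova(np.array([[1.0, 2, 3, 4]]), np.array([0, 0, 1, 1]))
        assert F[0] == pytest.approx(8.0)
        from scipy import stats

        assert p[0] == pytest.approx(stats.f.sf(8.0, 1, 2))

    def test_constant_gene_is_p_one_and_filtered(self):
        expr = _experiment(
            np.vstack([np.full(8, 3.0), np.arange(8, dtype=float)]),
            lines=["A", "B"],
            hours=[0, 2, 4, 8],
        )
        F, p = tc.oneway_anova(expr.values.to_numpy(), expr.sample_hours())
        assert p[0] == 1.0 and F[0] == 0.0
        retained = tc.anova_filter(expr, alpha=0.05)
        assert "g0" not in retained.index

    def test_zero_within_variance_with_signal_is_p_zero(self):
        X = np.array([[1.0, 1.0, 5.0, 5.0]])
        F, p = tc.oneway_anova(X, np.array([0, 0, 1, 1]))
        assert p[0] == 0.0 and np.isinf(F[0])

    def test_requires_replicates_per_timepoint(self):
        with pytest.raises(InsufficientDataError):
            tc.oneway_anova(np.ones((1, 3)), np.array([0, 1, 2]))

    def test_selector_matches_filter(self):
        rng = np.random.default_rng(0)
        expr = _experiment(
            rng.normal(size=(50, 12)), lines=["A", "B", "C"], hours=[0, 2, 8, 24]
        )
        sel = tc.TimepointAnovaSelector(alpha=0.2).fit(
            expr.values.T.to_numpy(), expr.sample_hours()
        )
        retained = tc.anova_filter(expr, alpha=0.2)
        assert list(expr.genes[sel.get_support()]) == list(retained.index)


class TestProfileLibrary:
    def test_enumeration_count_t3_c1(self):
        lib = tc.build_profile_library(3, c=1, m=8)
        assert lib.n_candidates == 9  # (2c+1)^(T-1)
        assert lib.n_profiles == 8  # flat profile excluded

    def test_full_selection_is_whole_enumeration(self):
        lib = tc.build_profile_library(4, c=1, m=26)
        assert lib.n_profiles == 26
        assert not (lib.changes == 0).all(axis=1).any()

    def test_deterministic(self):
        a = tc.build_profile_library(6, c=2, m=50, seed=1)
        b = tc.build_profile_library(6, c=2, m=50, seed=2)
        np.testing.assert_array_equal(a.changes, b.changes)

    def test_m_out_of_range(self):
        with pytest.raises(ValueError):
            tc.build_profile_library(3, c=1, m=9)


class TestAssignment:
    def test_exact_profile_match_has_correlation_one(self):
        lib = tc.build_profile_library(4, c=1, m=26)
        series = pd.DataFrame(lib.series[[3]], index=["g0"])
        out = tc.assign_genes(series, lib)
        assert out.labels["g0"] == 3
        assert out.correlations["g0"] == pytest.approx(1.0)

    def test_negated_profile_assigns_to_its_mirror(self):
        lib = tc.build_profile_library(4, c=1, m=26)
        k = 5
        neg = -lib.series[k]
        series = pd.DataFrame([neg], index=["g0"])
        out = tc.assign_genes(series, lib)
        chosen = lib.series[out.labels["g0"]]
        np.testing.assert_allclose(chosen, -lib.series[k])

    def test_matches_brute_force_correlation_argmax(self):
        rng = np.random.default_rng(42)
        lib = tc.build_profile_library(4, c=1, m=10)
        S = rng.normal(size=(5, 4))
        out = tc.assign_genes(pd.DataFrame(S), lib)
        # independent oracle: full correlation matrix, explicit argmax
        X = S - S[:, [0]]
        for i in range(5):
            cors = [np.corrcoef(X[i], prof)[0, 1] for prof in lib.series]
            assert out.labels[i] == int(np.argmax(cors))

    def test_zero_variance_after_transform_reported_unassigned(self):
        lib = tc.build_profile_library(4, c=1, m=10)
        series = pd.DataFrame([[2.0, 2.0, 2.0, 2.0]], index=["flatg"])
        out = tc.assign_genes(series, lib)
        assert out.unassigned == ["flatg"]
        assert len(out.labels) == 0

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        shift=st.floats(-50, 50, allow_nan=False),
        seed=st.integers(0, 1000),
    )
    def test_assignment_invariant_to_level_shift(self, shift, seed):
        rng = np.random.default_rng(seed)
        lib = tc.build_profile_library(5, c=1, m=20)
        S = rng.normal(size=(4, 5))
        base = tc.assign_genes(pd.DataFrame(S), lib)
        shifted = tc.assign_genes(pd.DataFrame(S + shift), lib)
        pd.testing.assert_series_equal(base.labels, shifted.labels)


class TestSignificance:
    def _planted(self, n_genes=30, seed=0):
        lib = tc.build_profile_library(5, c=1, m=20)
        S = pd.DataFrame(np.tile(lib.series[2], (n_genes, 1)))
        return tc.assign_genes(S, lib)

    def test_extreme_enrichment_hits_empirical_floor(self):
        out = tc.profile_significance(
            self._planted(), n_perm=199, method="empirical", seed=1
        )
        k = 2
        assert out.pvalues[k] == pytest.approx(1.0 / 200.0)
        assert out.pvalues.min() >= 1.0 / 200.0
        assert out.pvalues.max() <= 1.0

    def test_extreme_enrichment_significant_under_binomial(self):
        out = tc.profile_significance(self._planted(), n_perm=300, seed=1)
        assert out.significant[2]
        assert out.qvalues[2] < 1e-6

    def test_null_series_yield_no_significant_profile(self):
        rng = np.random.default_rng(3)
        lib = tc.build_profile_library(6, c=2, m=50)
        S = pd.DataFrame(rng.normal(size=(120, 6)))
        out = tc.profile_significance(
            tc.assign_genes(S, lib), n_perm=500, q_threshold=0.01, seed=3
        )
        assert not out.significant.any()

    def test_small_n_perm_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            tc.profile_significance(self._planted(), n_perm=50, seed=0)

    def test_sizes_sum_to_assigned_genes(self):
        out = self._planted()
        assert out.sizes.sum() == len(out.labels)


class TestProfileClusterer:
    def test_estimator_agrees_with_functions(self):
        rng = np.random.default_rng(7)
        S = rng.normal(size=(40, 5))
        est = tc.ProfileClusterer(c=1, m=20, n_perm=200, random_state=5).fit(S)
        lib = tc.build_profile_library(5, c=1, m=20)
        manual = tc.assign_genes(pd.DataFrame(S), lib)
        np.testing.assert_array_equal(
            est.labels_[est.labels_ >= 0], manual.labels.to_numpy()
        )
        assert est.predict(S[:5]).tolist() == est.labels_[:5].tolist()

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        est = tc.ProfileClusterer(c=1, m=10, n_perm=150, random_state=2)
        assert clone(est).get_params() == est.get_params()
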