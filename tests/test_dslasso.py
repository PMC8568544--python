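"""Candidate pool, adaptive lasso, and the double-selection procedure."""

import numpy as np
import pandas as pd
import pytest

from oadcompare.dslasso import (adaptive_lasso_select, build_candidate_pool,
                                double_select, post_selection_fit)
from oadcompare.margins import fit_outcome_model, predictive_margins


@pytest.fixture(scope="module")
def pool69(sim_frames):
    X, _, _ = sim_frames
    return build_candidate_pool(X)


class TestCandidatePool:
    def test_full_schema_yields_69_columns(self, pool69):
        assert pool69.shape[1] == 69
        prov = pool69.attrs["provenance"]
        assert sum(v == "main" for v in prov.values()) == 35
        assert sum(v == "interaction" for v in prov.values()) == 34

    def test_minimal_schema(self):
        df = pd.DataFrame({"A": [0, 1, 0, 1], "hba1c_ctrl_bl": [0, 0, 1, 1]})
        pool = build_candidate_pool(df)
        assert list(pool.columns) == ["A", "hba1c_ctrl_bl",
                                      "A_x_hba1c_ctrl_bl"]

    def test_anchor_never_self_interacts(self, pool69):
        assert "hba1c_ctrl_bl_x_hba1c_ctrl_bl" not in pool69.columns

    def test_duplicate_columns_dropped(self):
        df = pd.DataFrame({"A": [0, 1, 0, 1], "B": [0, 1, 0, 1],
                           "hba1c_ctrl_bl": [0, 0, 1, 1]})
        pool = build_candidate_pool(df)
        # B duplicates A exactly, as does its interaction
        assert "B" not in pool.columns
        assert pool.shape[1] == 3

    def test_non_binary_column_rejected(self):
        df = pd.DataFrame({"A": [0.0, 0.5, 1.0],
                           "hba1c_ctrl_bl": [0, 1, 0]})
        with pytest.raises(ValueError, match="non-binary"):
            build_candidate_pool(df)

    def test_constant_columns_dropped(self):
        df = pd.DataFrame({"A": [1, 1, 1, 1], "B": [0, 1, 0, 1],
                           "hba1c_ctrl_bl": [0, 0, 1, 1]})
        pool = build_candidate_pool(df)
        assert "A" not in pool.columns


def orthonormal_design(n, p, rng):
    """Columns with mean 0 and X'X = n I (exactly), via QR of centered noise."""
    A = rng.normal(size=(n, p + 1))
    A[:, 0] = 1.0
    Q, _ = np.linalg.qr(A)
    X = Q[:, 1:] * np.sqrt(n)        # orthogonal to the constant => mean 0
    return X


class TestAdaptiveLasso:
    def test_orthonormal_matches_soft_threshold_closed_form(self):
        """On an orthonormal design the whole adaptive-lasso path equals
        coordinate-free soft-thresholding of the OLS coefficients at the
        adaptive thresholds."""
        rng = np.random.default_rng(21)
        n, p = 128, 6
        X = orthonormal_design(n, p, rng)
        beta = np.array([1.2, -0.8, 0.5, 0.0, 0.0, 0.0])
        y = X @ beta + rng.normal(0, 0.5, n)
        pool = pd.DataFrame(X, columns=[f"c{j}" for j in range(p)])
        res = adaptive_lasso_select(y, pool, gamma=1.0)

        # independent closed form on the internally standardized problem
        sd = X.std(axis=0)
        y_sd = y.std()
        Xs = (X - X.mean(0)) / sd
        yc = (y - y.mean()) / y_sd
        bhat = Xs.T @ yc / n                      # OLS under orthonormality
        w = np.abs(bhat) ** -1.0
        for ai, alpha in enumerate(res.alphas):
            # lasso on Xw = Xs/w decouples: column norms are n/w_j^2, so the
            # solution is b_j = w_j * S(bhat_j, alpha * w_j) with S the
            # soft-threshold operator
            bw = bhat * w
            thr = alpha * w ** 2
            soft = np.sign(bw) * np.maximum(np.abs(bw) - thr, 0.0)
            orig = soft / w * (y_sd / sd)
            np.testing.assert_allclose(res.coefs.iloc[:, ai].to_numpy(),
                                       orig, atol=1e-6)
        # BIC-selected support is the true support for this strong signal
        assert set(res.selected) == {"c0", "c1", "c2"}

    def test_zero_penalty_limit_selects_everything(self):
        rng = np.random.default_rng(22)
        n, p = 200, 5
        X = rng.integers(0, 2, (n, p)).astype(float)
        y = X @ np.array([1.0, 0.8, -0.9, 0.7, 1.1]) + rng.normal(0, 0.1, n)
        pool = pd.DataFrame(X, columns=[f"c{j}" for j in range(p)])
        res = adaptive_lasso_select(y, pool, eps=1e-6)
        assert np.count_nonzero(res.coefs.iloc[:, -1]) == p

    def test_infinite_penalty_limit_selects_nothing(self):
        rng = np.random.default_rng(23)
        X = rng.integers(0, 2, (100, 4)).astype(float)
        y = rng.normal(size=100)
        pool = pd.DataFrame(X, columns=list("abcd"))
        res = adaptive_lasso_select(y, pool)
        # the path starts at alpha_max, where every coefficient is zero
        assert np.count_nonzero(res.coefs.iloc[:, 0]) == 0

    def test_selection_invariant_to_column_order(self, sim_frames, pool69):
        _, _, Y = sim_frames
        y = Y["hba1c_control"]
        res1 = adaptive_lasso_select(y, pool69)
        shuffled = pool69[list(pool69.columns[::-1])]
        res2 = adaptive_lasso_select(y, shuffled)
        assert set(res1.selected) == set(res2.selected)

    def test_selection_invariant_to_response_rescaling(self, sim_frames,
                                                       pool69):
        _, _, Y = sim_frames
        y = Y["cost_total"]
        res1 = adaptive_lasso_select(y, pool69)
        res2 = adaptive_lasso_select(1000.0 * y + 17.0, pool69)
        assert set(res1.selected) == set(res2.selected)

    def test_ridge_fallback_on_rank_deficient_pool(self):
        rng = np.random.default_rng(24)
        X = rng.integers(0, 2, (50, 3)).astype(float)
        pool = pd.DataFrame(np.column_stack([X, X[:, 0]]),
                            columns=["a", "b", "c", "a_dup"])
        y = X[:, 0] + rng.normal(0, 0.2, 50)
        with pytest.warns(UserWarning, match="ridge"):
            res = adaptive_lasso_select(y, pool)
        assert res.ridge_fallback

    def test_constant_column_rejected(self):
        pool = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.0, 1.0, 0.0]})
        with pytest.raises(ValueError, match="constant"):
            adaptive_lasso_select([1.0, 2.0, 3.0], pool)


class TestDoubleSelect:
    def test_union_covers_every_equation(self, sim_frames, pool69):
        _, arms, Y = sim_frames
        sel = double_select(Y["hba1c_control"], arms, pool69)
        union = set(sel.union)
        assert set(sel.outcome_selected) <= union
        for s in sel.treatment_selected.values():
            assert set(s) <= union
        assert union <= set(pool69.columns)
        assert sel.union == [c for c in pool69.columns if c in union]

    def test_confounder_and_prognostic_variable_both_selected(self,
                                                              sim_frames,
                                                              pool69):
        """City (assignment-only) and baseline control (assignment and
        outcome) both enter the union — the whole point of selecting on the
        treatment equations as well."""
        _, arms, Y = sim_frames
        sel = double_select(Y["hba1c_control"], arms, pool69)
        assert "city_shenyang" in sel.union       # drives assignment only
        assert "hba1c_ctrl_bl" in sel.union       # drives both

    def test_full_union_reproduces_fully_adjusted_model(self, sim_frames,
                                                        pool69):
        _, arms, Y = sim_frames
        y = Y["eq5d"]
        fit_full = fit_outcome_model(y, arms, covariates=pool69)
        marg_full = predictive_margins(fit_full, covariates=pool69,
                                       letters=False)
        _, marg_ds = post_selection_fit(y, arms, pool69,
                                        list(pool69.columns))
        np.testing.assert_allclose(marg_ds["margin"], marg_full["margin"],
                                   atol=1e-10)

    def test_empty_union_margins_equal_subgroup_means(self, sim_frames,
                                                      pool69):
        _, arms, Y = sim_frames
        y = Y["hypo_incidence"].astype(float)
        _, marg = post_selection_fit(y, arms, pool69, [])
        means = y.groupby(arms, observed=True).mean()
        for a in marg.index:
            assert marg.loc[a, "margin"] == pytest.approx(means[a],
                                                          abs=1e-10)

    def test_bic_paths_and_penalties_reported(self, sim_frames, pool69):
        _, arms, Y = sim_frames
        sel = double_select(Y["hba1c_control"], arms, pool69)
        assert "outcome" in sel.penalties
        assert len(sel.bic_paths["outcome"]) == 80
        assert all(np.isfinite(sel.bic_paths["outcome"]))
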