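import numpy as np
import pandas as pd
import pytest

from islandbeta.models import (
    backward_stepwise,
    candidate_terms,
    deviance_by_term,
    fit_gaussian_glm,
    hierarchical_submodels,
    mantel_pvalues,
    term_label,
)


def synth_pairs(seed, n=200, coef=None, noise=1.0):
    """Pair table with independent predictors and a known linear response."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "island_a": [f"a{i}" for i in range(n)],
            "island_b": [f"b{i}" for i in range(n)],
            "pred_area": rng.normal(size=n),
            "pred_dni": rng.normal(size=n),
            "pred_dm": rng.normal(size=n),
        }
    )
    y = rng.normal(0.0, noise, n)
    for term, b in (coef or {}).items():
        col = np.ones(n)
        for v in term:
            col = col * df[v].to_numpy()
        y = y + b * col
    df["beta_j"] = y
    return df


class TestGaussianGLM:
    def test_noiseless_linear_recovered_exactly(self):
        df = synth_pairs(0, n=50, noise=0.0, coef={("pred_area",): 2.0})
        df["beta_j"] += 3.0
        res = fit_gaussian_glm(df, "beta_j", [("pred_area",)])
        assert res.params["intercept"] == pytest.approx(3.0, abs=1e-8)
        assert res.params["area"] == pytest.approx(2.0, abs=1e-8)
        assert res.resid_deviance == pytest.approx(0.0, abs=1e-16)
        assert res.deviance_explained_pct == pytest.approx(100.0)

    def test_matches_normal_equations_oracle(self):
        """Coefficients agree with an explicit (X'X)^-1 X'y solve on a small table."""
        df = synth_pairs(1, n=12, coef={("pred_area",): 1.0, ("pred_dm",): -0.5})
        terms = [("pred_area",), ("pred_dni",), ("pred_dm",)]
        X = np.column_stack(
            [np.ones(12)] + [df[t[0]].to_numpy() for t in terms]
        )
        y = df["beta_j"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        res = fit_gaussian_glm(df, "beta_j", terms)
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-10)

    def test_intercept_only_noise_explains_nothing(self):
        df = synth_pairs(2, n=400)
        res = fit_gaussian_glm(df, "beta_j", [])
        assert res.deviance_explained_pct == pytest.approx(0.0, abs=1e-9)

    def test_rank_deficiency_names_collinear_terms(self):
        df = synth_pairs(3, n=40)
        df["pred_dni"] = 2.0 * df["pred_area"]
        with pytest.raises(ValueError, match="collinear"):
            fit_gaussian_glm(df, "beta_j", [("pred_area",), ("pred_dni",)])

    def test_too_few_pairs_rejected(self):
        df = synth_pairs(4, n=5)
        with pytest.raises(ValueError, match="at least 10"):
            fit_gaussian_glm(df, "beta_j", [])

    def test_undefined_responses_dropped_and_counted(self):
        df = synth_pairs(5, n=30)
        df.loc[:4, "beta_j"] = np.nan
        res = fit_gaussian_glm(df, "beta_j", [("pred_area",)])
        assert res.n_obs == 25
        assert res.n_dropped == 5


class TestBackwardStepwise:
    def test_strong_single_signal_selected(self):
        df = synth_pairs(10, n=400, coef={("pred_area",): 2.0}, noise=0.5)
        res = backward_stepwise(df, "beta_j")
        assert res.terms == [("pred_area",)]

    def test_pure_noise_keeps_little(self):
        # AIC is a liberal criterion: it retains a noise term with prob ~0.16
        # each, so intercept-only is not guaranteed -- but whatever survives
        # explains essentially nothing, and selection never worsens the
        # starting AIC.
        for s in range(10):
            df = synth_pairs(100 + s, n=400)
            res = backward_stepwise(df, "beta_j")
            assert res.deviance_explained_pct < 5.0
            full = fit_gaussian_glm(df, "beta_j")
            assert res.aic <= full.aic + 1e-9

    def test_matches_exhaustive_enumeration(self):
        for s in range(5):
            df = synth_pairs(200 + s, n=150, coef={("pred_area",): 1.0, ("pred_area", "pred_dm"): 0.8, ("pred_dm",): 0.6})
            step = backward_stepwise(df, "beta_j")
            best = min(
                (fit_gaussian_glm(df, "beta_j", list(sub)).aic for sub in hierarchical_submodels()),
            )
            assert step.aic == pytest.approx(best, abs=1e-9)

    def test_selected_aic_bounded_by_full_and_null(self):
        df = synth_pairs(30, n=200, coef={("pred_dni",): 1.0})
        res = backward_stepwise(df, "beta_j")
        full = fit_gaussian_glm(df, "beta_j")
        null = fit_gaussian_glm(df, "beta_j", [])
        assert res.aic <= full.aic + 1e-9
        assert res.aic <= null.aic + 1e-9

    def test_hierarchy_keeps_mains_under_retained_interaction(self):
        df = synth_pairs(31, n=300, coef={("pred_area", "pred_dm"): 1.5}, noise=0.3)
        res = backward_stepwise(df, "beta_j", hierarchy=True)
        if ("pred_area", "pred_dm") in res.terms:
            assert ("pred_area",) in res.terms and ("pred_dm",) in res.terms

    def test_no_hierarchy_can_orphan_interactions(self):
        df = synth_pairs(32, n=300, coef={("pred_area", "pred_dm"): 1.5}, noise=0.3)
        res = backward_stepwise(df, "beta_j", hierarchy=False)
        assert ("pred_area", "pred_dm") in res.terms
        assert ("pred_dni",) not in res.terms


class TestDevianceByTerm:
    def test_single_term_share_equals_model_r2(self):
        df = synth_pairs(40, n=200, coef={("pred_area",): 1.0})
        res = backward_stepwise(df, "beta_j")
        shares = deviance_by_term(res, df)
        assert shares["sequential_pct"].sum() == pytest.approx(res.deviance_explained_pct)

    def test_sequential_shares_telescope(self):
        df = synth_pairs(
            41, n=300, coef={("pred_area",): 1.0, ("pred_dm",): 0.7, ("pred_area", "pred_dm"): 0.5}
        )
        res = fit_gaussian_glm(
            df, "beta_j", [("pred_area",), ("pred_dm",), ("pred_area", "pred_dm")]
        )
        shares = deviance_by_term(res, df)
        assert shares["sequential_pct"].sum() == pytest.approx(res.deviance_explained_pct, abs=1e-9)
        assert (shares["sequential_pct"] > -1e-9).all()

    def test_orthogonal_predictors_sequential_equals_drop_one(self):
        n = 64
        df = pd.DataFrame(
            {
                "island_a": [f"a{i}" for i in range(n)],
                "island_b": [f"b{i}" for i in range(n)],
                # exactly orthogonal, mean-zero design
                "pred_area": np.tile([1.0, -1.0], n // 2),
                "pred_dni": np.repeat([1.0, -1.0], n // 2),
                "pred_dm": np.tile([1.0, 1.0, -1.0, -1.0], n // 4),
            }
        )
        rng = np.random.default_rng(6)
        df["beta_j"] = (
            1.2 * df["pred_area"] - 0.8 * df["pred_dni"] + rng.normal(0, 0.2, n)
        )
        res = fit_gaussian_glm(df, "beta_j", [("pred_area",), ("pred_dni",)])
        shares = deviance_by_term(res, df)
        np.testing.assert_allclose(
            shares["sequential_pct"], shares["drop_one_pct"], atol=1e-9
        )


def test_mantel_permutation_pvalues_behave():
    # response mapped from a genuine pairwise structure over 12 islands
    rng = np.random.default_rng(7)
    islands = [f"i{k}" for k in range(12)]
    area = {i: rng.uniform(0, 2) for i in islands}
    rows = []
    for a_i in range(12):
        for b_i in range(a_i + 1, 12):
            a, b = islands[a_i], islands[b_i]
            d = abs(area[a] - area[b])
            rows.append(
                {
                    "island_a": a,
                    "island_b": b,
                    "pred_area": d,
                    "pred_dni": rng.normal(),
                    "pred_dm": rng.normal(),
                    "beta_j": 2.0 * d + rng.normal(0, 0.1),
                }
            )
    df = pd.DataFrame(rows)
    res = fit_gaussian_glm(df, "beta_j", [("pred_area",)])
    p = mantel_pvalues(df, res, n_perm=199, seed=1)
    assert 0 < p["area"] <= 0.05
    assert (p > 0).all() and (p <= 1).all()


def test_candidate_set_and_labels():
    terms = candidate_terms()
    assert len(terms) == 7
    assert term_label(("pred_area", "pred_dni", "pred_dm")) == "area x dni x dm"
    assert len(hierarchical_submodels()) == 19
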