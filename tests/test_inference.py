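"""Correlation, linear-model, LMG, subset-importance and mixed-model checks."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import lmg_by_permutations, ols_r2
from estuarsens.inference import (
    Term,
    all_subsets_importance,
    build_design,
    drop_aliased,
    fit_linear_model,
    lmg_importance,
    pearson_matrix,
    transform_table,
)
from estuarsens.mixed import MixedFit, RandomInterceptML, fit_mixed_model, r2_mixed


# ---------------------------------------------------------------------------
# transforms & correlations


def test_transform_table_basics():
    df = pd.DataFrame(
        {
            "zeros": [0.0, 0.0, 0.0],
            "area": [0.0, np.e - 1, np.e**2 - 1],
            "tidal_regime": ["microtidal", "mesotidal", "macrotidal"],
        }
    )
    out, dropped = transform_table(df, log_columns=["zeros", "area"])
    assert (out["zeros"] == 0).all()
    assert np.allclose(out["area"], [0, 1, 2])
    assert list(out["tidal_regime"]) == [1, 2, 3]
    assert dropped == 0
    with pytest.raises(KeyError):
        transform_table(df, log_columns=["nope"])


def test_transform_drops_incomplete_rows():
    df = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [1.0, 2.0, 3.0]})
    out, dropped = transform_table(df, required=["a", "b"])
    assert dropped == 1 and len(out) == 2


def test_pearson_exact_cases():
    df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [3.0, 5, 7, 9], "z": [2.0, 1, 4, 3]})
    m = pearson_matrix(df, rows=["x", "y", "z"])
    assert m.r.loc["x", "y"] == pytest.approx(1.0)
    # hand evaluation of the product-moment formula for (1,2,3,4),(2,1,4,3)
    assert m.r.loc["x", "z"] == pytest.approx(0.6)
    assert m.r.loc["x", "x"] == 1.0
    assert (m.r.to_numpy() == m.r.to_numpy().T).all()


def test_pearson_orthogonal_and_duplication():
    df = pd.DataFrame({"x": [-1.0, 0, 1, 0], "y": [0.0, -1, 0, 1], "w": [1.0, 2, 2, 1]})
    m = pearson_matrix(df, rows=["x", "y"])
    assert m.r.loc["x", "y"] == pytest.approx(0.0, abs=1e-12)
    doubled = pearson_matrix(pd.concat([df, df], ignore_index=True), rows=["x", "w"])
    single = pearson_matrix(df, rows=["x", "w"])
    assert doubled.r.loc["x", "w"] == pytest.approx(single.r.loc["x", "w"])
    assert doubled.p.loc["x", "w"] < single.p.loc["x", "w"]  # p changes with n


def test_pearson_ns_mask():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
    m = pearson_matrix(df, alpha=0.05)
    assert bool(m.ns.loc["a", "b"]) == bool(m.p.loc["a", "b"] >= 0.05)


# ---------------------------------------------------------------------------
# linear models


def test_ols_exact_recovery():
    x = np.arange(10.0)
    y = 2.0 * x + 1.0
    fit = fit_linear_model(y, pd.DataFrame({"x": x}))
    assert fit.r2 == pytest.approx(1.0)
    assert fit.params["x"] == pytest.approx(2.0)
    assert fit.params["Intercept"] == pytest.approx(1.0)


def test_ols_intercept_only():
    y = np.array([1.0, 2, 3, 4])
    fit = fit_linear_model(y, pd.DataFrame(index=range(4)))
    assert fit.r2 == pytest.approx(0.0)


def test_ols_matches_normal_equations_oracle():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
    y = rng.normal(size=40)
    fit = fit_linear_model(y, X)
    M = np.column_stack([np.ones(40), X.to_numpy()])
    beta = np.linalg.solve(M.T @ M, M.T @ y)
    assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)


def test_ols_aliased_column_dropped():
    rng = np.random.default_rng(4)
    X = pd.DataFrame({"a": rng.normal(size=20)})
    X["b"] = 2 * X["a"]
    fit = fit_linear_model(np.arange(20.0), X)
    assert "b" not in fit.params.index


def test_drop_aliased_catches_intercept_collinearity():
    X = pd.DataFrame({"const2": np.full(10, 2.0), "x": np.arange(10.0)})
    kept, dropped = drop_aliased(X)
    assert dropped == ["const2"]


# ---------------------------------------------------------------------------
# LMG


def test_lmg_single_predictor_equals_r2():
    rng = np.random.default_rng(0)
    x = rng.normal(size=50)
    y = x + rng.normal(size=50)
    X = pd.DataFrame({"x": x})
    shares = lmg_importance(y, X, [Term("x", ("x",))])
    assert shares["x"] == pytest.approx(ols_r2(y, [x]))


def test_lmg_orthogonal_predictors():
    rng = np.random.default_rng(1)
    a = np.tile([1.0, -1.0], 30)
    b = np.repeat([1.0, -1.0], 30)  # exactly orthogonal, both centered
    y = a + 0.5 * b + rng.normal(0, 0.5, 60)
    X = pd.DataFrame({"a": a, "b": b})
    shares = lmg_importance(y, X, [Term("a", ("a",)), Term("b", ("b",))])
    assert shares["a"] == pytest.approx(ols_r2(y, [a]), abs=1e-10)
    assert shares["b"] == pytest.approx(ols_r2(y, [b]), abs=1e-10)


def test_lmg_matches_permutation_oracle_and_sums_to_r2():
    rng = np.random.default_rng(2)
    n = 50
    z = rng.normal(size=n)
    X = pd.DataFrame(
        {
            "a": z + rng.normal(0, 0.5, n),
            "b": z + rng.normal(0, 0.5, n),
            "c": rng.normal(size=n),
        }
    )
    y = X["a"] + 0.5 * X["b"] - X["c"] + rng.normal(size=n)
    groups = [Term(c, (c,)) for c in "abc"]
    shares = lmg_importance(y, X, groups)
    oracle = lmg_by_permutations(y, {c: [X[c]] for c in "abc"})
    for c in "abc":
        assert shares[c] == pytest.approx(oracle[c], abs=1e-10)
        assert shares[c] >= 0
    assert shares.sum() == pytest.approx(ols_r2(y, [X[c] for c in "abc"]), abs=1e-8)


def test_lmg_group_cap():
    X = pd.DataFrame(np.zeros((10, 16)), columns=[f"c{i}" for i in range(16)])
    with pytest.raises(ValueError):
        lmg_importance(np.zeros(10), X, [Term(c, (c,)) for c in X.columns])


# ---------------------------------------------------------------------------
# all-subsets importance


def _aicc(y, cols):
    y = np.asarray(y)
    df = pd.DataFrame({f"c{i}": c for i, c in enumerate(cols)}, index=range(len(y)))
    fit = fit_linear_model(y, df)
    return fit.aicc


def test_subsets_single_candidate_closed_form():
    rng = np.random.default_rng(5)
    x = rng.normal(size=40)
    y = 0.5 * x + rng.normal(size=40)
    X = pd.DataFrame({"x": x})
    res = all_subsets_importance(y, X, [Term("x", ("x",))])
    a0 = _aicc(y, [])
    a1 = _aicc(y, [x])
    w1 = np.exp(-0.5 * (a1 - min(a0, a1)))
    w0 = np.exp(-0.5 * (a0 - min(a0, a1)))
    assert res.importance["x"] == pytest.approx(w1 / (w0 + w1), abs=1e-10)


def test_subsets_forced_term_importance_one():
    rng = np.random.default_rng(6)
    X = pd.DataFrame({"f": rng.normal(size=30), "x": rng.normal(size=30)})
    y = rng.normal(size=30)
    res = all_subsets_importance(
        y, X, [Term("x", ("x",))], forced=[Term("f", ("f",))]
    )
    assert res.importance["f"] == 1.0


def test_subsets_match_exhaustive_enumeration():
    rng = np.random.default_rng(7)
    n = 50
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["f", "a", "b"])
    y = 0.3 * X["f"] + 0.8 * X["a"] + rng.normal(size=n)
    res = all_subsets_importance(
        y, X, [Term("a", ("a",)), Term("b", ("b",))], forced=[Term("f", ("f",))]
    )
    # independent enumeration of the 4 models
    models = {
        (): ["f"],
        ("a",): ["f", "a"],
        ("b",): ["f", "b"],
        ("a", "b"): ["f", "a", "b"],
    }
    aiccs = {}
    coefs = {}
    for key, cols in models.items():
        fit = fit_linear_model(y, X[cols])
        aiccs[key] = fit.aicc
        coefs[key] = fit.params
    best = min(aiccs.values())
    ws = {k: np.exp(-0.5 * (v - best)) for k, v in aiccs.items()}
    z = sum(ws.values())
    ws = {k: v / z for k, v in ws.items()}
    for name in ("a", "b"):
        expected = sum(w for k, w in ws.items() if name in k)
        assert res.importance[name] == pytest.approx(expected, abs=1e-10)
        avg = sum(ws[k] * coefs[k][name] for k in ws if name in k) / sum(
            ws[k] for k in ws if name in k
        )
        assert res.coef_avg[name] == pytest.approx(avg, abs=1e-10)


def test_subsets_importance_monotone_in_effect_size():
    rng = np.random.default_rng(8)
    n = 60
    x = rng.normal(size=n)
    noise = rng.normal(size=n)
    X = pd.DataFrame({"x": x})
    weak = all_subsets_importance(0.1 * x + noise, X, [Term("x", ("x",))])
    strong = all_subsets_importance(0.8 * x + noise, X, [Term("x", ("x",))])
    assert strong.importance["x"] > weak.importance["x"]


def test_subsets_candidate_cap():
    X = pd.DataFrame(np.zeros((5, 16)), columns=[f"c{i}" for i in range(16)])
    with pytest.raises(ValueError):
        all_subsets_importance(
            np.zeros(5), X, [Term(c, (c,)) for c in X.columns]
        )


# ---------------------------------------------------------------------------
# mixed models


def _grouped_data(seed, n_groups=60, reps=4, sigma_u=1.0, sigma_e=0.5, beta=1.0):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), reps)
    u = rng.normal(0, sigma_u, n_groups)[g]
    x = rng.normal(size=len(g))
    y = beta * x + u + rng.normal(0, sigma_e, len(g))
    X = pd.DataFrame({"Intercept": np.ones(len(g)), "x": x})
    return y, X, g


def test_mixed_matches_statsmodels_ml():
    y, X, g = _grouped_data(seed=0)
    sm_fit = fit_mixed_model(y, X, g, reml=False)
    engine = RandomInterceptML(y, X, g)
    own = engine.fit_subset()
    assert own.llf == pytest.approx(sm_fit.llf, abs=1e-4)
    assert np.allclose(own.params.to_numpy(), sm_fit.params.to_numpy(), atol=1e-4)
    assert own.sigma2_intercept == pytest.approx(sm_fit.sigma2_intercept, rel=1e-2)
    assert own.sigma2_residual == pytest.approx(sm_fit.sigma2_residual, rel=1e-2)


def test_mixed_reml_matches_statsmodels():
    y, X, g = _grouped_data(seed=1)
    sm_fit = fit_mixed_model(y, X, g, reml=True)
    own = RandomInterceptML(y, X, g).fit_subset(reml=True)
    assert np.allclose(own.params.to_numpy(), sm_fit.params.to_numpy(), atol=1e-4)
    assert own.sigma2_intercept == pytest.approx(sm_fit.sigma2_intercept, rel=1e-2)
    assert own.sigma2_residual == pytest.approx(sm_fit.sigma2_residual, rel=1e-2)


def test_mixed_zero_group_variance():
    rng = np.random.default_rng(2)
    g = np.repeat(np.arange(40), 3)
    x = rng.normal(size=len(g))
    y = x + rng.normal(size=len(g))  # no group effect in truth
    X = pd.DataFrame({"Intercept": np.ones(len(g)), "x": x})
    fit = fit_mixed_model(y, X, g)
    assert fit.sigma2_intercept < 0.1 * fit.sigma2_residual


def test_mixed_all_singleton_groups_warns():
    rng = np.random.default_rng(3)
    g = np.arange(30)
    X = pd.DataFrame({"Intercept": np.ones(30), "x": rng.normal(size=30)})
    y = rng.normal(size=30)
    with pytest.warns(UserWarning, match="replicate"):
        fit = fit_mixed_model(y, X, g)
    assert fit.singular


def test_r2_mixed_planted_variance_shares():
    # fixed-effects variance 1, intercept variance 1, residual 2 -> (0.25, 0.5)
    fitted = np.tile([1.0, -1.0], 50)  # population variance exactly 1
    fit = MixedFit(
        params=pd.Series({"x": 1.0}),
        sigma2_intercept=1.0,
        sigma2_residual=2.0,
        llf=0.0,
        n=100,
        n_groups=10,
        fitted_fixed=fitted,
        reml=True,
        singular=False,
    )
    assert r2_mixed(fit) == (pytest.approx(0.25), pytest.approx(0.5))


def test_r2_mixed_edge_cases():
    y, X, g = _grouped_data(seed=4, sigma_u=0.0)
    fit = fit_mixed_model(y, X, g)
    marg, cond = r2_mixed(fit)
    assert marg <= cond + 1e-12
    assert cond - marg < 0.05  # no group variance in truth
    # intercept-only fixed part: marginal 0
    X0 = X[["Intercept"]]
    fit0 = fit_mixed_model(y, X0, g)
    marg0, cond0 = r2_mixed(fit0)
    assert marg0 == pytest.approx(0.0, abs=1e-10)


def test_mixed_subsets_forced_importance():
    y, X, g = _grouped_data(seed=5)
    Xd = X[["x"]].copy()
    Xd["z"] = np.random.default_rng(6).normal(size=len(y))
    res = all_subsets_importance(
        y,
        Xd,
        [Term("z", ("z",))],
        forced=[Term("x", ("x",))],
        groups=g,
    )
    assert res.importance["x"] == 1.0
    assert res.importance["z"] < 0.8  # pure noise rarely strongly supported
    assert 0.0 <= res.importance["z"] <= 1.0
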