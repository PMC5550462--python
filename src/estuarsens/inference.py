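"""Statistical layer: correlations, linear and mixed trait-environment
models, LMG hierarchical partitioning and all-subsets Akaike-weight
importance.

Each trait-category proportion is modelled as a separate Gaussian response
against the biogeographical/environmental predictors, in two variants (with
and without the biogeography factors), always forcing sampling effort into
the model. Predictor importance is assessed two ways:

* **LMG** (linear models only): a predictor group's share of R² averaged
  over all orders in which groups can enter the model — computed over the
  2^g subsets with combinatorial weights rather than the g! orderings;
* **Akaike-weight importance** ``I``: the summed Akaike weights (AICc by
  default) of all candidate subsets containing the predictor, for both the
  linear and the mixed (random estuary intercept) formulation.

Unordered factors (continent, realm) enter as grouped dummy blocks: one LMG
group and one subset-inclusion unit. Ordered factors (tidal regime, estuary
type, salinity type) enter as their integer codes.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mixed import MixedFit, RandomInterceptML, fit_mixed_model, r2_mixed
from .traits import RESPONSE_COLUMNS

logger = logging.getLogger(__name__)

ORDERED_FACTOR_CODES = {
    "tidal_regime": {"microtidal": 1, "mesotidal": 2, "macrotidal": 3},
    "estuary_type": {"temporarily open": 1, "open": 2},
    "salinity_type": {"regular": 1, "regular-hyperhaline": 2, "hyperhaline": 3},
}


# ---------------------------------------------------------------------------
# table assembly


def transform_table(
    table: pd.DataFrame,
    log_columns=(),
    ordered_columns=ORDERED_FACTOR_CODES,
    required=(),
) -> tuple[pd.DataFrame, int]:
    """Apply the analysis transforms; returns (table, n_rows_dropped).

    ``log_columns`` are log(x+1)-transformed in place; ``ordered_columns``
    maps label columns to their integer codes (columns that are already
    numeric pass through). Rows with missing values in ``required`` columns
    are dropped and counted.
    """
    out = table.copy()
    for col in log_columns:
        if col not in out.columns:
            raise KeyError(f"unknown column {col!r}")
        out[col] = np.log1p(out[col].astype(float))
    for col, mapping in ordered_columns.items():
        if col not in out.columns:
            continue
        if out[col].dtype == object:
            unknown = set(out[col].dropna()) - set(mapping)
            if unknown:
                raise ValueError(f"unknown {col} labels: {sorted(unknown)}")
            out[col] = out[col].map(mapping)
        out[col] = out[col].astype(float)
    required = [c for c in required if c in out.columns]
    if required:
        keep = out[required].notna().all(axis=1)
        dropped = int((~keep).sum())
        out = out.loc[keep].reset_index(drop=True)
    else:
        dropped = 0
    return out, dropped


# ---------------------------------------------------------------------------
# Pearson correlation matrices


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    ns: pd.DataFrame  # True where not significant at alpha
    alpha: float
    n: pd.DataFrame

    def formatted(self, digits: int = 2) -> pd.DataFrame:
        """Correlations with non-significant cells replaced by 'ns'."""
        out = self.r.round(digits).astype(object)
        out[self.ns] = "ns"
        return out


def pearson_matrix(
    table: pd.DataFrame, rows=None, cols=None, alpha: float = 0.05
) -> CorrelationMatrix:
    """Pairwise Pearson r with two-sided p-values on pairwise-complete rows.

    ``rows``/``cols`` select the (possibly rectangular) block of variable
    pairs; by default the full square matrix over all numeric columns.
    Zero-variance pairs yield NaN cells with a logged warning.
    """
    if rows is None:
        rows = [c for c in table.columns if table[c].dtype.kind in "fi"]
    cols = cols if cols is not None else rows
    r = pd.DataFrame(index=rows, columns=cols, dtype=float)
    p = pd.DataFrame(index=rows, columns=cols, dtype=float)
    n = pd.DataFrame(index=rows, columns=cols, dtype=float)
    for a in rows:
        for b in cols:
            x = table[a].astype(float)
            y = table[b].astype(float)
            ok = x.notna() & y.notna()
            m = int(ok.sum())
            n.loc[a, b] = m
            if m < 3:
                raise ValueError(f"fewer than 3 complete pairs for ({a}, {b})")
            if a == b:
                r.loc[a, b], p.loc[a, b] = 1.0, 0.0
                continue
            xv, yv = x[ok], y[ok]
            if xv.std() == 0 or yv.std() == 0:
                logger.warning("zero-variance column in pair (%s, %s)", a, b)
                r.loc[a, b], p.loc[a, b] = np.nan, np.nan
                continue
            res = sps.pearsonr(xv, yv)
            r.loc[a, b], p.loc[a, b] = res.statistic, res.pvalue
    ns = p.isna() | (p >= alpha)
    return CorrelationMatrix(r=r, p=p, ns=ns, alpha=alpha, n=n)


# ---------------------------------------------------------------------------
# design construction


@dataclass(frozen=True)
class Term:
    """One model term: a named group of design columns (1 for continuous
    predictors and ordered factors, k-1 dummies for a k-level factor)."""

    name: str
    columns: tuple[str, ...]


def build_design(
    data: pd.DataFrame, continuous=(), factors=()
) -> tuple[pd.DataFrame, list[Term]]:
    """Design frame (no intercept) + term list with factors dummy-expanded."""
    pieces = []
    terms: list[Term] = []
    for col in continuous:
        pieces.append(data[col].astype(float).rename(col))
        terms.append(Term(col, (col,)))
    for col in factors:
        dummies = pd.get_dummies(
            data[col], prefix=col, drop_first=True, dtype=float
        )
        pieces.append(dummies)
        terms.append(Term(col, tuple(dummies.columns)))
    X = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=data.index)
    return X, terms


def drop_aliased(
    X: pd.DataFrame, tol: float = 1e-8, with_intercept: bool = True
) -> tuple[pd.DataFrame, list[str]]:
    """Drop columns (nearly) linearly dependent on earlier ones.

    Greedy Gram-Schmidt scan: a column whose residual against the basis of
    already-kept columns (seeded with the intercept) falls below ``tol``
    times its own norm is aliased and dropped.
    """
    n = len(X)
    basis: list[np.ndarray] = []
    if with_intercept:
        basis.append(np.full(n, 1.0 / math.sqrt(n)))
    keep: list[str] = []
    dropped: list[str] = []
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        norm0 = np.linalg.norm(v)
        if norm0 == 0:
            dropped.append(col)
            continue
        r = v.copy()
        for q in basis:
            r -= (q @ r) * q
        # re-orthogonalize once for numerical safety
        for q in basis:
            r -= (q @ r) * q
        if np.linalg.norm(r) <= tol * norm0:
            dropped.append(col)
        else:
            keep.append(col)
            basis.append(r / np.linalg.norm(r))
    if dropped:
        logger.warning("dropped aliased design columns: %s", dropped)
    return X[keep], dropped


# ---------------------------------------------------------------------------
# ordinary least squares


@dataclass
class OLSFit:
    params: pd.Series
    r2: float
    rss: float
    tss: float
    llf: float
    aic: float
    aicc: float
    n: int
    k: int  # parameters counted by the information criteria (coefs + sigma)
    fitted: np.ndarray


def fit_linear_model(
    y, X: pd.DataFrame, add_intercept: bool = True, dealias: bool = True
) -> OLSFit:
    """Least-squares fit with Gaussian-likelihood AIC/AICc.

    ``X`` is a design frame without intercept unless ``add_intercept`` is
    False. Aliased columns are dropped (with a warning) unless ``dealias``
    is off; a design that is rank-deficient even after dropping raises.
    """
    y = np.asarray(y, dtype=float)
    if add_intercept:
        X = X.copy()
        X.insert(0, "Intercept", 1.0)
    if dealias:
        X, _ = drop_aliased(X, with_intercept=False)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} too small for {p} coefficients")
    M = X.to_numpy(dtype=float)
    beta, _, rank, _ = np.linalg.lstsq(M, y, rcond=None)
    if rank < p:
        raise ValueError("design rank-deficient after alias dropping")
    fitted = M @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    sigma2 = max(rss / n, 1e-300)
    llf = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    k = p + 1
    aic = -2 * llf + 2 * k
    aicc = aic + (2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else math.inf)
    return OLSFit(
        params=pd.Series(beta, index=list(X.columns)),
        r2=r2,
        rss=rss,
        tss=tss,
        llf=llf,
        aic=aic,
        aicc=aicc,
        n=n,
        k=k,
        fitted=fitted,
    )


# ---------------------------------------------------------------------------
# LMG hierarchical partitioning


def _subset_r2_cache(y, X: pd.DataFrame, groups: list[Term]):
    y = np.asarray(y, dtype=float)
    n = len(y)
    ones = np.ones((n, 1))
    tss = float(((y - y.mean()) ** 2).sum())
    cache: dict[frozenset, float] = {}
    for r in range(len(groups) + 1):
        for combo in itertools.combinations(range(len(groups)), r):
            cols = [c for i in combo for c in groups[i].columns]
            M = np.hstack([ones, X[cols].to_numpy(dtype=float)]) if cols else ones
            beta, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
            rss = float(((y - M @ beta) ** 2).sum())
            cache[frozenset(combo)] = 1.0 - rss / tss if tss > 0 else 0.0
    return cache


def lmg_importance(y, X: pd.DataFrame, groups: list[Term]) -> pd.Series:
    """LMG share of R² per predictor group.

    Share of group g = average over all entry orders of the R² increase when
    g enters, computed over the 2^g subsets with the exact combinatorial
    weights k!(g-1-k)!/g!. Shares are non-negative on full-rank designs and
    sum to the full-model R².
    """
    g = len(groups)
    if g > 15:
        raise ValueError(f"{g} groups would need 2^{g} subset fits; cap is 15")
    cache = _subset_r2_cache(y, X, groups)
    fact = math.factorial
    shares = {}
    others = list(range(g))
    for gi in range(g):
        rest = [i for i in others if i != gi]
        total = 0.0
        for r in range(len(rest) + 1):
            w = fact(r) * fact(g - 1 - r) / fact(g)
            for combo in itertools.combinations(rest, r):
                s = frozenset(combo)
                total += w * (cache[s | {gi}] - cache[s])
        shares[groups[gi].name] = total
    return pd.Series(shares)


# ---------------------------------------------------------------------------
# all-subsets multimodel inference


@dataclass
class SubsetInferenceResult:
    importance: pd.Series  # per term, in [0, 1]; forced terms = 1
    coef_avg: pd.Series  # conditional model-averaged coefficients per column
    weights: np.ndarray
    subsets: list[tuple[str, ...]]
    criterion: str
    best_index: int
    r2_full: float


def all_subsets_importance(
    y,
    X: pd.DataFrame,
    candidates: list[Term],
    forced: list[Term] = (),
    criterion: str = "aicc",
    groups=None,
) -> SubsetInferenceResult:
    """Akaike-weight importance over all candidate-term subsets.

    Every model contains the intercept and all ``forced`` terms. With
    ``groups`` given, models are random-intercept mixed models compared on
    ML likelihoods; otherwise ordinary linear models. ``I(term)`` is the sum
    of Akaike weights of models containing the term; model-averaged
    coefficients are conditional (averaged over the models containing the
    term only). Subsets whose fit fails are dropped with a warning and the
    weights renormalized.
    """
    if criterion not in ("aicc", "aic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    k = len(candidates)
    if k > 15:
        raise ValueError(f"{k} candidates would need 2^{k} fits; cap is 15")
    forced = list(forced)
    forced_cols = [c for t in forced for c in t.columns]
    y = np.asarray(y, dtype=float)

    mixed_engine = None
    if groups is not None:
        Xall = X.copy()
        Xall.insert(0, "Intercept", 1.0)
        mixed_engine = RandomInterceptML(y, Xall, groups)

    crits: list[float] = []
    subsets: list[tuple[str, ...]] = []
    param_list: list[pd.Series] = []
    for r in range(k + 1):
        for combo in itertools.combinations(range(k), r):
            names = tuple(candidates[i].name for i in combo)
            cols = forced_cols + [c for i in combo for c in candidates[i].columns]
            try:
                if mixed_engine is None:
                    fit = fit_linear_model(y, X[cols], dealias=False)
                    crit = fit.aicc if criterion == "aicc" else fit.aic
                    params = fit.params
                else:
                    mfit = mixed_engine.fit_subset(["Intercept"] + cols)
                    p = len(mfit.params) + 2  # fixed coefs + two variances
                    n = mixed_engine.n
                    crit = -2 * mfit.llf + 2 * p
                    if criterion == "aicc":
                        crit += 2 * p * (p + 1) / (n - p - 1) if n - p - 1 > 0 else math.inf
                    params = mfit.params
            except (np.linalg.LinAlgError, ValueError) as exc:
                logger.warning("subset %s dropped: %s", names, exc)
                continue
            crits.append(crit)
            subsets.append(names)
            param_list.append(params)
    if not crits:
        raise RuntimeError("every candidate subset failed to fit")
    crits_arr = np.asarray(crits)
    delta = crits_arr - crits_arr.min()
    w = np.exp(-0.5 * delta)
    w /= w.sum()

    importance = {t.name: 1.0 for t in forced}
    for t in candidates:
        importance[t.name] = float(
            sum(wi for wi, names in zip(w, subsets) if t.name in names)
        )
    coef_num: dict[str, float] = {}
    coef_den: dict[str, float] = {}
    for wi, params in zip(w, param_list):
        for col, val in params.items():
            coef_num[col] = coef_num.get(col, 0.0) + wi * val
            coef_den[col] = coef_den.get(col, 0.0) + wi
    coef_avg = pd.Series({c: coef_num[c] / coef_den[c] for c in coef_num})

    if mixed_engine is None:
        full = fit_linear_model(y, X[forced_cols + [c for t in candidates for c in t.columns]])
        r2_full = full.r2
    else:
        mfull = mixed_engine.fit_subset()
        r2_full = r2_mixed(mfull)[0]
    return SubsetInferenceResult(
        importance=pd.Series(importance),
        coef_avg=coef_avg,
        weights=w,
        subsets=subsets,
        criterion=criterion,
        best_index=int(np.argmin(crits_arr)),
        r2_full=r2_full,
    )


# ---------------------------------------------------------------------------
# trait-environment modelling (the Table-2-shaped analysis)

ENV_CONTINUOUS = (
    "sst",
    "ter_npp",
    "mar_chl",
    "shelf_width_km",
    "estuary_area_km2",
    "tidal_regime",
    "estuary_type",
    "salinity_type",
)
BIOGEO_FACTORS = ("continent", "realm")
FORCED_CONTINUOUS = ("log_effort",)
#: continuous predictors log(x+1)-transformed before modelling (strictly
#: positive scales; temperature and the 1..k ordered codes stay raw)
LOG_TRANSFORMED = ("ter_npp", "mar_chl", "shelf_width_km", "estuary_area_km2")


@dataclass
class ModelTable:
    """Long-format model results plus per-model summaries."""

    table: pd.DataFrame  # response, variant, predictor, C, lmg_pct, I_lm, I_mm
    summary: pd.DataFrame  # response, variant, r2_lm, r2_marginal, r2_conditional, n

    def important(self, threshold: float = 0.5) -> pd.DataFrame:
        """Reporting view: predictors with linear-model importance above the
        threshold (the headline reporting filter)."""
        t = self.table
        return t[t["I_lm"] > threshold].reset_index(drop=True)


def build_analysis_table(
    profiles: pd.DataFrame, estuaries: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Join profiles with estuary features and effort; apply transforms."""
    df = profiles.merge(estuaries, on="estuary_id", how="left")
    df = df.merge(samples[["sample_id", "sampled_area_m2"]], on="sample_id", how="left")
    df["log_effort"] = np.log1p(df["sampled_area_m2"])
    df, dropped = transform_table(
        df,
        log_columns=[c for c in LOG_TRANSFORMED if c in df.columns],
        required=list(RESPONSE_COLUMNS)
        + [c for c in ENV_CONTINUOUS if c in df.columns]
        + ["log_effort"],
    )
    if dropped:
        logger.info("dropped %d incomplete rows from the analysis table", dropped)
    return df


def trait_environment_models(
    analysis: pd.DataFrame,
    responses=RESPONSE_COLUMNS,
    variants=("with_biogeo", "without_biogeo"),
    criterion: str = "aicc",
    group_col: str = "estuary_id",
) -> ModelTable:
    """Fit the full model battery: per response x variant, a linear model
    (full-fit coefficients, LMG shares, subset importance) and a mixed model
    (subset importance, REML variance components, marginal/conditional R²).
    """
    rows = []
    summaries = []
    for variant in variants:
        factors = BIOGEO_FACTORS if variant == "with_biogeo" else ()
        X, terms = build_design(
            analysis, continuous=FORCED_CONTINUOUS + ENV_CONTINUOUS, factors=factors
        )
        X, dropped_cols = drop_aliased(X)
        if dropped_cols:
            terms = [
                Term(t.name, tuple(c for c in t.columns if c in X.columns))
                for t in terms
            ]
            terms = [t for t in terms if t.columns]
        forced = [t for t in terms if t.name in FORCED_CONTINUOUS]
        candidates = [t for t in terms if t.name not in FORCED_CONTINUOUS]
        groups = analysis[group_col]
        for response in responses:
            y = analysis[response].to_numpy(dtype=float)
            lm_full = fit_linear_model(y, X)
            lmg = lmg_importance(y, X, terms)
            lm_sub = all_subsets_importance(y, X, candidates, forced, criterion)
            mm_sub = all_subsets_importance(
                y, X, candidates, forced, criterion, groups=groups
            )
            Xi = X.copy()
            Xi.insert(0, "Intercept", 1.0)
            mm_reml = fit_mixed_model(y, Xi, groups, reml=True)
            r2_marg, r2_cond = r2_mixed(mm_reml)
            for t in terms:
                coef = (
                    float(lm_full.params[t.columns[0]])
                    if len(t.columns) == 1
                    else float("nan")
                )
                rows.append(
                    {
                        "response": response,
                        "variant": variant,
                        "predictor": t.name,
                        "C": coef,
                        "lmg_share": float(lmg[t.name]),
                        "lmg_pct": 100.0 * float(lmg[t.name]) / lm_full.r2
                        if lm_full.r2 > 0
                        else float("nan"),
                        "I_lm": float(lm_sub.importance[t.name]),
                        "I_mm": float(mm_sub.importance[t.name]),
                    }
                )
            summaries.append(
                {
                    "response": response,
                    "variant": variant,
                    "r2_lm": lm_full.r2,
                    "r2_marginal": r2_marg,
                    "r2_conditional": r2_cond,
                    "sigma2_intercept": mm_reml.sigma2_intercept,
                    "sigma2_residual": mm_reml.sigma2_residual,
                    "n": lm_full.n,
                }
            )
    return ModelTable(table=pd.DataFrame(rows), summary=pd.DataFrame(summaries))


def trait_pressure_correlations(
    profiles: pd.DataFrame,
    exposure: pd.DataFrame,
    protection: pd.DataFrame,
    alpha: float = 0.05,
) -> CorrelationMatrix:
    """Trait-category proportions vs normalized pressure and protection
    coverage: the rectangular correlation block of the headline overlap
    question (do sensitive assemblages sit in pressured, unprotected
    places?)."""
    from .protection import PROTECTION_PCT_COLUMNS

    df = profiles.merge(exposure, on="sample_id", how="left", suffixes=("", "_exp"))
    df = df.merge(protection, on="estuary_id", how="left", suffixes=("", "_prot"))
    pressure_cols = [c for c in df.columns if c.endswith("_norm")]
    pa_cols = [c for c in PROTECTION_PCT_COLUMNS if c in df.columns]
    return pearson_matrix(
        df, rows=list(RESPONSE_COLUMNS), cols=pressure_cols + pa_cols, alpha=alpha
    )
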