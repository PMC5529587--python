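"""Iterative AICc/RVI model selection with full model averaging.

With 15-20 explanatory variables and fewer than 300 observations, fitting
all 2^20 candidate models is impractical and a single full model would
overfit.  The procedure here rotates variables through pools of at most 10:
all subsets of the current pool are fitted, Akaike weights over the AICc
values give each variable a relative variable importance (RVI = summed
weight of the models containing it), variables with RVI > 0.5 are kept and
the pool is refilled with the next unused variables.  Once every variable
has entered a pool, a final all-subsets fit over the kept variables yields
full model-averaged estimates with adjusted (unconditional) standard
errors.  Variables with RVI > 0.7 are flagged as relevant.

Binary responses default to clutch-level aggregation (average survival,
sex ratio) with identity-link fitting, the route taken when per-individual
logistic mixed models fail to converge.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats


# ---------------------------------------------------------------------------
# information criterion, weights, RVI

def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike Information Criterion with small-sample correction."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class CandidateModel:
    variables: tuple[str, ...]        # predictor subset (intercept implicit)
    n: int
    k: int
    loglik: float
    aicc: float
    coefs: dict[str, float]           # includes "(Intercept)"
    variances: dict[str, float]
    converged: bool = True
    weight: float = float("nan")


def akaike_weights(aiccs: np.ndarray) -> np.ndarray:
    delta = aiccs - np.min(aiccs)
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def weights_and_rvi(models: list[CandidateModel]) -> tuple[list[CandidateModel], pd.Series]:
    """Assign Akaike weights and compute per-variable RVI.

    RVI(v) = sum of weights of models containing v; the probability that v
    belongs in the best model given the data and candidate set.  Models
    with non-finite AICc (non-convergence) are excluded from the weights.
    """
    ok = [m for m in models if np.isfinite(m.aicc) and m.converged]
    if not ok:
        raise ValueError("no finite candidate models")
    w = akaike_weights(np.array([m.aicc for m in ok]))
    for m, wi in zip(ok, w):
        m.weight = float(wi)
    for m in models:
        if m not in ok:
            m.weight = 0.0
    variables = sorted({v for m in ok for v in m.variables})
    rvi = pd.Series(
        {v: sum(m.weight for m in ok if v in m.variables) for v in variables},
        dtype=float).sort_values(ascending=False)
    return models, rvi


# ---------------------------------------------------------------------------
# fitting backends (contract: (y, X, groups) -> loglik, k, coefs, variances)

@dataclass
class FitResult:
    loglik: float
    k: int
    coefs: dict[str, float]
    variances: dict[str, float]
    converged: bool = True


def fit_gaussian_ls(y: np.ndarray, X: np.ndarray, names: list[str],
                    groups: pd.DataFrame | None = None,
                    weights: np.ndarray | None = None) -> FitResult:
    """Gaussian maximum-likelihood (weighted) least squares, fixed effects.

    With ``weights`` w_i the model is y_i ~ N(x_i'b, sigma^2 / w_i) — the
    natural variance structure for clutch means of w_i chicks.  k counts
    the coefficients plus the residual variance.
    """
    n, p = X.shape
    if weights is None:
        Xw, yw, logw = X, y, 0.0
    else:
        sw = np.sqrt(weights)
        Xw, yw = X * sw[:, None], y * sw
        logw = float(np.sum(np.log(weights)))
    gram = Xw.T @ Xw
    try:
        beta = sla.solve(gram, Xw.T @ yw, assume_a="pos")
        cov_unscaled = sla.inv(gram)
    except sla.LinAlgError:
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        cov_unscaled = np.linalg.pinv(gram)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    if sigma2_ml <= 0:
        sigma2_ml = np.finfo(float).tiny
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2_ml) + 1.0) + 0.5 * logw
    dof = max(n - p, 1)
    var = np.diag(cov_unscaled) * rss / dof
    return FitResult(loglik=loglik, k=p + 1,
                     coefs=dict(zip(names, beta)),
                     variances=dict(zip(names, var)))


def fit_logistic(y: np.ndarray, X: np.ndarray, names: list[str],
                 groups: pd.DataFrame | None = None,
                 weights: np.ndarray | None = None) -> FitResult:
    """Per-individual binomial GLM with logit link (statsmodels)."""
    import statsmodels.api as sm

    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        converged = bool(res.converged)
    except Exception:
        return FitResult(-np.inf, X.shape[1], {}, {}, converged=False)
    return FitResult(loglik=float(res.llf), k=X.shape[1],
                     coefs=dict(zip(names, res.params)),
                     variances=dict(zip(names, np.diag(res.cov_params()))),
                     converged=converged)


def fit_mixed_gaussian(y: np.ndarray, X: np.ndarray, names: list[str],
                       groups: pd.DataFrame | None = None,
                       weights: np.ndarray | None = None) -> FitResult:
    """Gaussian mixed model with nested random intercepts via MixedLM (ML).

    ``groups`` columns are used outermost-first (e.g. aviary, female,
    clutch); the outermost defines the groups, inner levels enter as
    variance components.  k counts fixed effects, every random-effect
    variance, and the residual variance.
    """
    import statsmodels.api as sm

    if groups is None or groups.shape[1] == 0:
        return fit_gaussian_ls(y, X, names)
    data = pd.DataFrame(X[:, 1:], columns=[f"x{i}" for i in range(X.shape[1] - 1)])
    data["y"] = y
    data["_outer"] = groups.iloc[:, 0].astype(str).to_numpy()
    vc_formula = {}
    for j, col in enumerate(groups.columns[1:]):
        data[f"_g{j}"] = groups[col].astype(str).to_numpy()
        vc_formula[f"g{j}"] = f"0 + C(_g{j})"
    fixed = "y ~ 1" + "".join(f" + x{i}" for i in range(X.shape[1] - 1))
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM.from_formula(
                fixed, data, groups="_outer",
                vc_formula=vc_formula or None, re_formula="1")
            res = md.fit(reml=False, method="lbfgs", maxiter=200, disp=False)
        # random-intercept variance + one variance per component + residual
        n_var = 1 + len(vc_formula) + 1
        converged = bool(res.converged)
    except Exception:
        return FitResult(-np.inf, X.shape[1], {}, {}, converged=False)
    params = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[: len(params), : len(params)]
    return FitResult(loglik=float(res.llf), k=X.shape[1] + n_var,
                     coefs=dict(zip(names, params)),
                     variances=dict(zip(names, np.diag(cov))),
                     converged=converged)


BACKENDS = {
    "gaussian_ls": fit_gaussian_ls,
    "logistic": fit_logistic,
    "mixed_gaussian": fit_mixed_gaussian,
}


# ---------------------------------------------------------------------------
# all-subsets enumeration

def all_subsets_fit(table: pd.DataFrame, response: str, pool: list[str],
                    backend: str = "gaussian_ls",
                    group_cols: list[str] | None = None,
                    weight_col: str | None = None,
                    max_pool: int = 10) -> list[CandidateModel]:
    """Fit every subset of ``pool`` (including intercept-only).

    All models are fitted on the same rows (complete cases over response
    plus the whole pool), so AICc values are comparable.  Models for which
    AICc is undefined (n <= k + 1) or that fail to converge are retained in
    the list but excluded from the weights.
    """
    if len(pool) > max_pool:
        raise ValueError(f"pool of {len(pool)} exceeds the maximum of {max_pool}")
    fit = BACKENDS[backend]
    cols = [response] + pool + (group_cols or [])
    data = table.dropna(subset=[response] + pool)
    if data.empty:
        raise ValueError("no complete-case rows")
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    Xfull = np.column_stack([np.ones(n)] + [data[v].to_numpy(dtype=float)
                                            for v in pool])
    groups = data[group_cols] if group_cols else None
    weights = data[weight_col].to_numpy(dtype=float) if weight_col else None
    models: list[CandidateModel] = []
    for r in range(len(pool) + 1):
        for subset in itertools.combinations(range(len(pool)), r):
            idx = [0] + [j + 1 for j in subset]
            names = ["(Intercept)"] + [pool[j] for j in subset]
            res = fit(y, Xfull[:, idx], names, groups, weights)
            try:
                ic = aicc(res.loglik, res.k, n) if res.converged else np.inf
            except ValueError:
                ic = np.inf
            models.append(CandidateModel(
                variables=tuple(pool[j] for j in subset), n=n, k=res.k,
                loglik=res.loglik, aicc=ic, coefs=res.coefs,
                variances=res.variances, converged=res.converged))
    return models


# ---------------------------------------------------------------------------
# model averaging

@dataclass
class AveragedCoefficient:
    variable: str
    estimate: float
    adjusted_se: float
    z: float
    p: float
    rvi: float


def model_average(models: list[CandidateModel],
                  rvi: pd.Series | None = None) -> pd.DataFrame:
    """Full model averaging with adjusted (unconditional) standard errors.

    estimate(v) = sum_i w_i * beta_iv with beta_iv = 0 where v is absent;
    adjusted SE = sqrt(sum_i w_i * (var_iv + (beta_iv - estimate)^2))
    (the revised unconditional variance estimator); two-sided normal p.
    """
    ok = [m for m in models if m.weight > 0 and np.isfinite(m.aicc)]
    if not ok:
        raise ValueError("no weighted models to average")
    total_w = sum(m.weight for m in ok)
    variables = ["(Intercept)"] + sorted({v for m in ok for v in m.variables})
    rows = []
    for v in variables:
        betas = np.array([m.coefs.get(v, 0.0) for m in ok])
        varis = np.array([m.variances.get(v, 0.0) for m in ok])
        w = np.array([m.weight for m in ok]) / total_w
        est = float(w @ betas)
        se = float(np.sqrt(w @ (varis + (betas - est) ** 2)))
        z = est / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append(AveragedCoefficient(
            variable=v, estimate=est, adjusted_se=se, z=z, p=p,
            rvi=(float(rvi[v]) if rvi is not None and v in rvi.index else np.nan)))
    return pd.DataFrame([vars(r) for r in rows])


# ---------------------------------------------------------------------------
# the iterative rotation procedure

@dataclass
class SelectionResult:
    response: str
    rounds: list[dict] = field(default_factory=list)
    final_pool: list[str] = field(default_factory=list)
    final_rvi: pd.Series | None = None
    table: pd.DataFrame | None = None     # averaged coefficient table
    kept: list[str] = field(default_factory=list)        # RVI > keep threshold
    relevant: list[str] = field(default_factory=list)    # RVI > relevant threshold


def iterative_rvi_selection(table: pd.DataFrame, response: str,
                            variables: list[str],
                            backend: str = "gaussian_ls",
                            group_cols: list[str] | None = None,
                            weight_col: str | None = None,
                            pool_size: int = 10,
                            keep_threshold: float = 0.5,
                            relevant_threshold: float = 0.7) -> SelectionResult:
    """Rotate variables through all-subsets pools, keep RVI > 0.5, refit.

    Round 1 fits all subsets of the first ``pool_size`` variables; kept
    variables stay in the pool, which is refilled with the next unused
    variables; this repeats until every variable has entered a pool (never
    more than three rounds for 20 variables).  A final all-subsets fit over
    the union of kept variables is model-averaged for interpretation.
    """
    result = SelectionResult(response=response)
    remaining = list(variables)
    kept: list[str] = []
    while remaining:
        take = pool_size - len(kept)
        if take <= 0:
            # every slot is occupied by kept variables; no further variable
            # can enter, so the rotation terminates with the current pool
            break
        entering, remaining = remaining[:take], remaining[take:]
        pool = kept + entering
        models = all_subsets_fit(table, response, pool, backend=backend,
                                 group_cols=group_cols, weight_col=weight_col,
                                 max_pool=pool_size)
        models, rvi = weights_and_rvi(models)
        kept = [v for v in pool if rvi.get(v, 0.0) > keep_threshold]
        result.rounds.append({"pool": pool, "rvi": rvi, "kept": list(kept)})
        if not kept and not remaining:
            break
    final_pool = kept if kept else []
    models = all_subsets_fit(table, response, final_pool, backend=backend,
                             group_cols=group_cols, weight_col=weight_col,
                             max_pool=pool_size)
    models, final_rvi = weights_and_rvi(models)
    result.final_pool = final_pool
    result.final_rvi = final_rvi
    result.table = model_average(models, final_rvi)
    result.kept = [v for v in final_pool if final_rvi.get(v, 0.0) > keep_threshold]
    result.relevant = [v for v in final_pool
                       if final_rvi.get(v, 0.0) > relevant_threshold]
    return result


# ---------------------------------------------------------------------------
# clutch aggregation and reporting

def aggregate_by_clutch(table: pd.DataFrame, clutch_col: str = "clutch_id",
                        keep_cols: tuple[str, ...] = ("aviary", "mother")) -> pd.DataFrame:
    """Collapse an individual-level table to clutch means.

    Every numeric variable is replaced by its arithmetic clutch mean, so a
    binary survival column becomes the clutch's average survival and a 0/1
    sex code becomes the clutch sex ratio.  Grouping columns that are
    constant within a clutch (aviary, mother) are carried through; the
    random-effect nesting available afterwards is female within aviary.
    """
    if clutch_col not in table.columns:
        raise ValueError(f"missing clutch column {clutch_col!r}")
    rows = []
    for clutch, sub in table.groupby(clutch_col):
        if sub.empty:
            continue
        row: dict = {clutch_col: clutch, "n_in_clutch": len(sub)}
        for col in keep_cols:
            if col in sub.columns:
                row[col] = sub[col].iloc[0]
        for col in sub.columns:
            if col in row or col == clutch_col:
                continue
            if pd.api.types.is_numeric_dtype(sub[col]):
                row[col] = sub[col].mean()
        rows.append(row)
    return pd.DataFrame(rows)


def significance_marker(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


def report_table(result: SelectionResult,
                 keep_threshold: float = 0.5,
                 relevant_threshold: float = 0.7) -> pd.DataFrame:
    """Result table in the shape of the published survival/growth tables.

    Columns: variable, estimate, adjusted_se, p, marker, rvi, relevant.
    Only the intercept and variables with RVI above the keep threshold are
    shown; RVI above the relevant threshold is flagged.
    """
    tab = result.table.copy()
    rvi = result.final_rvi if result.final_rvi is not None else pd.Series(dtype=float)
    keep = tab["variable"].map(
        lambda v: v == "(Intercept)" or rvi.get(v, 0.0) > keep_threshold)
    tab = tab[keep].copy()
    tab["marker"] = tab["p"].map(significance_marker)
    tab["relevant"] = tab["variable"].map(
        lambda v: v != "(Intercept)" and rvi.get(v, 0.0) > relevant_threshold)
    order = ["variable", "estimate", "adjusted_se", "p", "marker", "rvi", "relevant"]
    return tab[order].reset_index(drop=True)
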