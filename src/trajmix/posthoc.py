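"""Stage-3 covariate analysis of latent trajectory classes.

Class membership is fixed by modal posterior assignment *before* any
covariate enters a model (the classical 3-step approach), so predictors can
never reshape the latent classes.  Baseline covariates are screened
univariably (ANOVA / Kruskal-Wallis for continuous, chi-square or an exact
test for categorical) at p < 0.10, then entered into a multinomial logistic
regression with backward pruning of covariates whose every class contrast
has p >= 0.10.  Selected covariates can be scaled per sample SD so odds
ratios read "per 1 SD-unit increase".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

SCREEN_ALPHA = 0.10
PRUNE_ALPHA = 0.10
SEPARATION_COEF = 10.0


class PosthocError(ValueError):
    pass


def modal_assign(posterior: np.ndarray) -> np.ndarray:
    """Hard class labels (1-based) from a posterior matrix.

    Rows must sum to 1 within 1e-6; exact ties break toward the lower class
    index and are logged.
    """
    P = np.asarray(posterior, dtype=float)
    if P.ndim != 2:
        raise PosthocError("posterior must be 2-D")
    sums = P.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = np.where(np.abs(sums - 1.0) > 1e-6)[0]
        raise PosthocError(
            f"posterior rows do not sum to 1 (first offender: row {bad[0]}, "
            f"sum {sums[bad[0]]!r})"
        )
    labels = P.argmax(axis=1)
    ties = (P == P.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        log.info("modal_assign: %d tied posterior row(s); ties broken "
                 "toward the lower class index", int(ties.sum()))
    return labels + 1


# ---------------------------------------------------------------------------
# univariable screening


def _expected_counts(table: np.ndarray) -> np.ndarray:
    rs = table.sum(axis=1, keepdims=True)
    cs = table.sum(axis=0, keepdims=True)
    return rs * cs / table.sum()


def _permutation_exact(x, y, n_sim: int = 2000, seed: int = 0) -> float:
    """Monte-Carlo exact test of independence for an r x c table (used when
    expected cells are sparse and the table exceeds 2 x 2)."""
    rng = np.random.default_rng(seed)
    obs_tab = pd.crosstab(x, y).to_numpy()
    exp = _expected_counts(obs_tab)
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_stat = np.nansum((obs_tab - exp) ** 2 / exp)
    y_arr = np.asarray(y)
    exceed = 0
    for _ in range(n_sim):
        perm = rng.permutation(y_arr)
        tab = pd.crosstab(x, perm).to_numpy()
        exp_p = _expected_counts(tab)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.nansum((tab - exp_p) ** 2 / exp_p)
        if s >= obs_stat - 1e-12:
            exceed += 1
    return (exceed + 1.0) / (n_sim + 1.0)


def univariable_screen(
    cov: pd.DataFrame,
    labels,
    tests: dict = None,
    alpha: float = SCREEN_ALPHA,
    seed: int = 0,
) -> pd.DataFrame:
    """Omnibus class-difference test per covariate.

    Continuous covariates default to one-way ANOVA (override per variable
    with ``tests={'name': 'kruskal'}`` for skewed counts); categorical ones
    to the chi-square test, falling back to an exact test (Fisher for 2x2,
    Monte-Carlo permutation otherwise) when any expected cell count is
    below 5.  Constant covariates are excluded with a note.  Returns one row
    per covariate with the statistic, p, and a ``selected`` flag (p < 0.10).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise PosthocError("need at least two classes present")
    tests = tests or {}
    rows = []
    for name in cov.columns:
        s = cov[name]
        row = {"variable": name, "test": None, "statistic": np.nan,
               "p": np.nan, "selected": False, "note": ""}
        if s.nunique(dropna=True) <= 1:
            row["note"] = "constant covariate; excluded"
            rows.append(row)
            continue
        numeric = pd.api.types.is_numeric_dtype(s) and not (
            pd.api.types.is_bool_dtype(s)
        )
        choice = tests.get(name)
        if numeric and choice != "categorical":
            groups = [s[labels == c].dropna().to_numpy(dtype=float)
                      for c in classes]
            groups = [g for g in groups if len(g) > 0]
            if choice == "kruskal":
                stat, p = stats.kruskal(*groups)
                row["test"] = "kruskal-wallis"
            else:
                stat, p = stats.f_oneway(*groups)
                row["test"] = "anova"
            row["statistic"], row["p"] = float(stat), float(p)
        else:
            tab = pd.crosstab(s, pd.Series(labels, index=s.index))
            arr = tab.to_numpy()
            exp = _expected_counts(arr)
            if (exp < 5).any():
                if arr.shape == (2, 2):
                    _, p = stats.fisher_exact(arr)
                    row["test"] = "fisher"
                    row["statistic"] = np.nan
                else:
                    p = _permutation_exact(s.to_numpy(), labels, seed=seed)
                    row["test"] = "permutation-exact"
                    row["statistic"] = np.nan
                row["p"] = float(p)
            else:
                stat, p, _, _ = stats.chi2_contingency(arr)
                row["test"] = "chi-square"
                row["statistic"], row["p"] = float(stat), float(p)
        row["selected"] = bool(row["p"] < alpha)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multinomial regression


@dataclass
class MultinomialResult:
    """Odds-ratio table from the pruned multinomial logit.

    ``table`` columns: predictor, class, OR, ci_low, ci_high, p.  Estimates
    are relative to ``reference`` (class 1 by default); predictors in
    ``scaled_per_sd`` were divided by their sample SD before fitting, so
    their ORs are per 1-SD-unit increase.
    """

    table: pd.DataFrame
    reference: int
    scaled_per_sd: dict
    dropped: list = field(default_factory=list)
    model: object = None

    def odds_ratio(self, predictor: str, klass: int) -> float:
        sel = self.table[(self.table["predictor"] == predictor)
                         & (self.table["class"] == klass)]
        if sel.empty:
            raise KeyError(f"{predictor!r} vs class {klass}")
        return float(sel["OR"].iloc[0])


def _fit_mnlogit(X: pd.DataFrame, y_codes: np.ndarray):
    import statsmodels.api as sm

    Xc = sm.add_constant(X, has_constant="add")
    model = sm.MNLogit(y_codes, Xc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="newton", maxiter=200, disp=False, tol=1e-10)
    return res, Xc


def multinomial_fit(
    cov: pd.DataFrame,
    labels,
    reference: int = 1,
    scale_per_sd=(),
    prune_alpha: float = PRUNE_ALPHA,
    prune: bool = True,
) -> MultinomialResult:
    """ML multinomial logit of class membership on baseline covariates.

    Covariates listed in ``scale_per_sd`` are divided by their sample SD.
    With ``prune=True``, covariates whose every class contrast has
    p >= ``prune_alpha`` are removed one per pass (largest minimum p first)
    and the model is re-estimated.  Raises on singular designs; warns when
    coefficients suggest separation.
    """
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    if reference not in classes:
        raise PosthocError(f"reference class {reference} not present")
    order = [reference] + [c for c in classes if c != reference]
    code = {c: i for i, c in enumerate(order)}
    y = np.array([code[c] for c in labels])

    X = cov.copy().astype(float)
    sds = {}
    for name in scale_per_sd:
        if name not in X.columns:
            raise PosthocError(f"scale_per_sd names unknown column {name!r}")
        sd = float(X[name].std(ddof=1))
        if sd == 0:
            raise PosthocError(f"covariate {name!r} is constant")
        X[name] = X[name] / sd
        sds[name] = sd

    dropped = []
    while True:
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < (
            X.shape[1] + 1
        ):
            raise PosthocError("singular design matrix")
        res, Xc = _fit_mnlogit(X, y)
        params = np.asarray(res.params)          # (p, K-1)
        pvals = np.asarray(res.pvalues)
        if np.abs(params).max() > SEPARATION_COEF:
            warnings.warn(
                "very large multinomial coefficients suggest (quasi-)"
                "separation; consider collapsing sparse covariates or "
                "penalised estimation"
            )
        if not prune or X.shape[1] <= 1:
            break
        names = list(Xc.columns)
        min_p = {}
        for j, name in enumerate(names):
            if name == "const":
                continue
            min_p[name] = float(np.min(pvals[j]))
        removable = {k: v for k, v in min_p.items() if v >= prune_alpha}
        if not removable:
            break
        worst = max(removable, key=removable.get)
        dropped.append(worst)
        X = X.drop(columns=[worst])

    conf = res.conf_int()   # DataFrame or array (K-1, p, 2)
    ci = np.asarray(conf).reshape(len(order) - 1, -1, 2)
    names = list(Xc.columns)
    rows = []
    for kidx, klass in enumerate(order[1:]):
        for j, name in enumerate(names):
            if name == "const":
                continue
            coef = params[j, kidx]
            rows.append(
                {
                    "predictor": name,
                    "class": klass,
                    "OR": float(np.exp(coef)),
                    "ci_low": float(np.exp(ci[kidx, j, 0])),
                    "ci_high": float(np.exp(ci[kidx, j, 1])),
                    "p": float(pvals[j, kidx]),
                }
            )
    return MultinomialResult(
        table=pd.DataFrame(rows),
        reference=reference,
        scaled_per_sd=sds,
        dropped=dropped,
        model=res,
    )


# ---------------------------------------------------------------------------
# missingness correlates


def missingness_correlates(panel, cov: pd.DataFrame,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Spearman correlation of per-participant missing-visit counts with
    each numeric covariate; flags p < ``alpha`` as auxiliary-variable
    candidates.  Zero-variance missing counts yield NA rows."""
    miss = (~panel.mask).sum(axis=1).astype(float)
    if len(miss) != len(cov):
        raise PosthocError("panel and covariate table must align")
    rows = []
    degenerate = np.std(miss) == 0
    for name in cov.columns:
        s = cov[name]
        if not pd.api.types.is_numeric_dtype(s):
            continue
        if degenerate or s.std(ddof=0) == 0:
            rows.append({"variable": name, "rho": np.nan, "p": np.nan,
                         "auxiliary_candidate": False})
            continue
        rho, p = stats.spearmanr(miss, s.to_numpy(dtype=float))
        rows.append({"variable": name, "rho": float(rho), "p": float(p),
                     "auxiliary_candidate": bool(p < alpha)})
    return pd.DataFrame(rows)
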