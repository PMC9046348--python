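"""Growth mixture model (GMM) engine.

A K-class mixture of latent growth curves for a wide visit panel
``y_i`` (J visits, missing entries allowed):

    y_i | class k  ~  N( X alpha_k ,  Z Psi Z' + Theta )

where X holds the polynomial (or latent-basis) mean loadings, Z the
random-effect loadings (by default intercept and linear slope; variance
components shared across classes), Psi the growth-factor covariance and
Theta the residual variance (scalar by default, optionally visit-specific).
Estimation is EM treating both class membership and the random effects as
latent, which gives closed-form conditional M-steps for every parameter
block and a monotone observed-data log-likelihood.  Missing visits are
handled by full-information maximum likelihood: each participant
contributes the marginal normal density of their observed sub-vector.

Class enumeration is supported through AIC/BIC/ssBIC, classification
entropy, the Lo-Mendell-Rubin adjusted likelihood-ratio test, a
parametric-bootstrap LRT cross-check, and class-size adequacy flags.
Auxiliary missingness correlates can be appended as saturated correlates of
the growth factors so that dropout information enters the likelihood
without touching the growth model itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.vq import kmeans2
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.special import logsumexp

_LOG2PI = np.log(2.0 * np.pi)

_BASIS_ORDER = {"intercept-only": 1, "linear": 2, "quadratic": 3, "cubic": 4}
_RANEF_INDEX = {"intercept": 0, "linear": 1, "slope": 1, "quadratic": 2,
                "cubic": 3}


class GMMError(ValueError):
    pass


class DegenerateFitError(RuntimeError):
    """All EM starts collapsed (e.g. an empty class)."""


# ---------------------------------------------------------------------------
# panel


@dataclass
class VisitPanel:
    """Wide per-participant matrix of trajectory indicators.

    ``y`` is (n, J) with NaN marking missing visits; ``times`` are the visit
    time codes (default 0..J-1 in visit units).
    """

    y: np.ndarray
    times: np.ndarray = None
    ids: np.ndarray = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 2:
            raise GMMError("panel y must be 2-D (participants x visits)")
        if self.times is None:
            self.times = np.arange(self.y.shape[1], dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape[0] != self.y.shape[1]:
            raise GMMError("times must have one entry per visit column")
        if self.ids is None:
            self.ids = np.arange(1, self.y.shape[0] + 1)
        self.ids = np.asarray(self.ids)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def J(self) -> int:
        return self.y.shape[1]

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.y)

    def drop_empty(self) -> "VisitPanel":
        """Exclude participants with zero observed visits (with a warning)."""
        keep = self.mask.any(axis=1)
        if keep.all():
            return self
        warnings.warn(
            f"excluding {int((~keep).sum())} participant(s) with no observed "
            "visits"
        )
        return VisitPanel(self.y[keep], self.times, self.ids[keep])

    @classmethod
    def from_long(cls, df: pd.DataFrame, id_col="id", visit_col="visit",
                  value_col="t_global", observed_col=None) -> "VisitPanel":
        d = df
        if observed_col is not None:
            d = df.copy()
            d.loc[~d[observed_col].astype(bool), value_col] = np.nan
        wide = d.pivot(index=id_col, columns=visit_col, values=value_col)
        wide = wide.sort_index()
        visits = np.asarray(sorted(wide.columns), dtype=float)
        return cls(wide[sorted(wide.columns)].to_numpy(dtype=float),
                   times=visits, ids=wide.index.to_numpy())

    def to_wide_csv(self, path) -> None:
        cols = {f"T{j + 1}": self.y[:, j] for j in range(self.J)}
        pd.DataFrame({"id": self.ids, **cols}).to_csv(path, index=False)

    @classmethod
    def from_wide_csv(cls, path) -> "VisitPanel":
        df = pd.read_csv(path)
        tcols = [c for c in df.columns if c.startswith("T")]
        y = df[tcols].to_numpy(dtype=float)
        ids = df["id"].to_numpy() if "id" in df.columns else None
        return cls(y, ids=ids)


# ---------------------------------------------------------------------------
# model specification


@dataclass
class GrowthSpec:
    """Growth-curve basis and variance structure.

    ``basis``: 'intercept-only' | 'linear' | 'quadratic' | 'cubic' |
    'latent-basis'.  ``random_effects`` names the basis columns that carry
    random effects (shared covariance across classes; the quadratic factor
    carries no random effect by default).  ``loadings`` holds the estimated
    free-loading column for a latent-basis model.
    """

    basis: str = "quadratic"
    random_effects: tuple = ("intercept", "linear")
    visit_specific_residuals: bool = False
    loadings: np.ndarray = None

    def mean_matrix(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        if self.basis == "latent-basis":
            if self.loadings is None:
                raise GMMError("latent-basis spec requires fitted loadings")
            lam = np.asarray(self.loadings, dtype=float)
            if lam.shape[0] != t.shape[0]:
                raise GMMError("loadings length must match times")
            return np.column_stack([np.ones_like(t), lam])
        if self.basis not in _BASIS_ORDER:
            raise GMMError(f"unknown basis: {self.basis!r}")
        order = _BASIS_ORDER[self.basis]
        return np.column_stack([t ** p for p in range(order)])

    def ranef_matrix(self, times) -> np.ndarray:
        X = self.mean_matrix(times)
        idx = []
        for name in self.random_effects:
            if name not in _RANEF_INDEX:
                raise GMMError(f"unknown random effect: {name!r}")
            j = _RANEF_INDEX[name]
            if j >= X.shape[1]:
                raise GMMError(
                    f"random effect {name!r} exceeds the {self.basis} basis"
                )
            idx.append(j)
        return X[:, idx]

    @property
    def n_growth_factors(self) -> int:
        if self.basis == "latent-basis":
            return 2
        return _BASIS_ORDER[self.basis]


@dataclass
class GrowthMixtureFit:
    """A fitted growth mixture model (classes ordered by descending
    intercept, so class 1 is the highest-performing)."""

    K: int
    pi: np.ndarray
    alpha: np.ndarray          # (K, q) growth-factor means
    Psi: np.ndarray            # (r, r) shared growth-factor covariance
    theta: np.ndarray          # residual variance(s): scalar array or (J,)
    posterior: np.ndarray      # (n, K)
    loglik: float
    n_params: int
    spec: GrowthSpec
    times: np.ndarray
    converged: bool = True
    n_iter: int = 0
    n_starts: int = 1
    start_logliks: np.ndarray = None
    best_replicated: bool = True
    history: list = field(default_factory=list)
    warnings_: list = field(default_factory=list)
    aux: dict = None           # {'mu': (m,), 'Gamma': (m, r), 's': (m,)}

    @property
    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.posterior.argmax(axis=1),
                           minlength=self.K)

    def residual_sd(self) -> float:
        return float(np.sqrt(np.mean(self.theta)))

    def to_json(self, path) -> None:
        import json

        payload = {
            "K": self.K,
            "pi": self.pi.tolist(),
            "alpha": self.alpha.tolist(),
            "Psi": self.Psi.tolist(),
            "theta": np.asarray(self.theta).tolist(),
            "posterior": self.posterior.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "times": np.asarray(self.times).tolist(),
            "spec": {
                "basis": self.spec.basis,
                "random_effects": list(self.spec.random_effects),
                "visit_specific_residuals":
                    self.spec.visit_specific_residuals,
                "loadings": (None if self.spec.loadings is None
                             else np.asarray(self.spec.loadings).tolist()),
            },
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_starts": self.n_starts,
            "best_replicated": self.best_replicated,
            "start_logliks": (None if self.start_logliks is None
                              else np.asarray(self.start_logliks).tolist()),
            "warnings": list(self.warnings_),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GrowthMixtureFit":
        import json

        with open(path) as fh:
            d = json.load(fh)
        spec_d = d["spec"]
        spec = GrowthSpec(
            basis=spec_d["basis"],
            random_effects=tuple(spec_d["random_effects"]),
            visit_specific_residuals=spec_d["visit_specific_residuals"],
            loadings=(None if spec_d["loadings"] is None
                      else np.asarray(spec_d["loadings"])),
        )
        return cls(
            K=d["K"], pi=np.asarray(d["pi"]), alpha=np.asarray(d["alpha"]),
            Psi=np.asarray(d["Psi"]), theta=np.asarray(d["theta"]),
            posterior=np.asarray(d["posterior"]), loglik=d["loglik"],
            n_params=d["n_params"], spec=spec,
            times=np.asarray(d["times"]), converged=d["converged"],
            n_iter=d["n_iter"], n_starts=d["n_starts"],
            best_replicated=d["best_replicated"],
            start_logliks=(None if d["start_logliks"] is None
                           else np.asarray(d["start_logliks"])),
            warnings_=d["warnings"],
        )


# ---------------------------------------------------------------------------
# pattern bookkeeping


class _Patterns:
    def __init__(self, panel: VisitPanel, X, Z, aux=None):
        mask = panel.mask
        uniq, inverse = np.unique(mask, axis=0, return_inverse=True)
        self.groups = []
        for p in range(uniq.shape[0]):
            rows = np.where(inverse == p)[0]
            idx = np.where(uniq[p])[0]
            self.groups.append(
                {
                    "rows": rows,
                    "idx": idx,
                    "X": X[idx],
                    "Z": Z[idx],
                    "Y": panel.y[np.ix_(rows, idx)],
                    "A": None if aux is None else aux[rows],
                }
            )
        self.n = panel.n
        self.total_obs = int(mask.sum())
        self.obs_per_visit = mask.sum(axis=0)


def _class_gaussians(g, alpha, Psi, theta_vec, aux_params):
    """Per-pattern Cholesky pieces shared by the E-step and loglik."""
    Z = g["Z"]
    noise = theta_vec[g["idx"]]
    if aux_params is not None:
        Gamma = aux_params["Gamma"]
        Zf = np.vstack([Z, Gamma])
        noise = np.concatenate([noise, aux_params["s"]])
    else:
        Zf = Z
    V = Zf @ Psi @ Zf.T + np.diag(noise)
    try:
        L = cholesky(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise GMMError(f"non-positive-definite marginal covariance: {exc}")
    return Zf, L


def _estep(groups, pi, alpha, Psi, theta_vec, aux_params, n, K,
           want_moments=True):
    loga = np.empty((n, K))
    moments = []  # per group: list over k of (M, C)
    logpi = np.log(np.maximum(pi, 1e-300))
    for g in groups:
        Zf, L = None, None
        per_k = []
        for k in range(K):
            if Zf is None:
                Zf, L = _class_gaussians(g, alpha, Psi, theta_vec, aux_params)
            mean = g["X"] @ alpha[k]
            if aux_params is not None:
                mean = np.concatenate([mean, aux_params["nu"][k]])
                Yf = np.hstack([g["Y"], g["A"]])
            else:
                Yf = g["Y"]
            R = Yf - mean
            half = solve_triangular(L, R.T, lower=True)
            quad = np.einsum("ji,ji->i", half, half)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            Jf = Yf.shape[1]
            loga[g["rows"], k] = (
                logpi[k] - 0.5 * (Jf * _LOG2PI + logdet + quad)
            )
            if want_moments:
                W = cho_solve((L, True), Zf @ Psi)        # (Jf, r)
                M = R @ W                                   # (n_p, r)
                C = Psi - (Zf @ Psi).T @ W                  # (r, r)
                per_k.append((M, C))
        moments.append(per_k)
    ll_i = logsumexp(loga, axis=1)
    resp = np.exp(loga - ll_i[:, None])
    return float(ll_i.sum()), resp, moments


def _mstep(groups, resp, moments, alpha_shape, Psi_dim, theta_vec,
           visit_specific, J, obs_per_visit, aux, aux_params):
    n, K = resp.shape
    q = alpha_shape[1]
    pi = resp.sum(axis=0) / n
    if pi.min() < 1.0 / (10.0 * n):
        raise _DegenerateStart(f"mixing proportion collapsed: {pi}")
    # growth-factor means
    alpha_new = np.empty(alpha_shape)
    for k in range(K):
        A = np.zeros((q, q))
        b = np.zeros(q)
        for g, per_k in zip(groups, moments):
            w = resp[g["rows"], k]
            M, _ = per_k[k]
            A += w.sum() * g["X"].T @ g["X"]
            b += g["X"].T @ (w[:, None] * (g["Y"] - M @ g["Z"].T)).sum(axis=0)
        alpha_new[k] = np.linalg.solve(A, b)
    # shared growth-factor covariance
    S = np.zeros((Psi_dim, Psi_dim))
    for g, per_k in zip(groups, moments):
        for k in range(K):
            w = resp[g["rows"], k]
            M, C = per_k[k]
            S += (w[:, None] * M).T @ M + w.sum() * C
    Psi_new = S / n
    Psi_new = 0.5 * (Psi_new + Psi_new.T)
    # residual variance(s)
    if visit_specific:
        num = np.zeros(J)
        for g, per_k in zip(groups, moments):
            for k in range(K):
                w = resp[g["rows"], k]
                M, C = per_k[k]
                res = g["Y"] - g["X"] @ alpha_new[k] - M @ g["Z"].T
                trZ = np.einsum("jr,rs,js->j", g["Z"], C, g["Z"])
                num[g["idx"]] += (w[:, None] * res ** 2).sum(axis=0) + \
                    w.sum() * trZ
        theta_new = num / np.maximum(obs_per_visit, 1)
    else:
        num = 0.0
        for g, per_k in zip(groups, moments):
            for k in range(K):
                w = resp[g["rows"], k]
                M, C = per_k[k]
                res = g["Y"] - g["X"] @ alpha_new[k] - M @ g["Z"].T
                trZ = np.einsum("jr,rs,js->", g["Z"], C, g["Z"])
                num += float((w[:, None] * res ** 2).sum()) + w.sum() * trZ
        total_obs = obs_per_visit.sum()
        theta_new = np.full(J, max(num / total_obs, 1e-10))
    # saturated auxiliary correlates: a_i | class k ~ N(nu_k + Gamma b_i, S)
    # with nu_k == nu for the class-invariant parameterization
    aux_new = None
    if aux is not None:
        m = aux.shape[1]
        r = Psi_dim
        invariant = aux_params.get("invariant", True)
        Msum_k = np.zeros((K, r))       # sum_i R_ik E[b_i | k]
        ASum_k = np.zeros((K, m))       # sum_i R_ik a_i
        MA = np.zeros((r, m))           # sum_ik R_ik E[b_i | k] a_i'
        Ssum = np.zeros((r, r))         # sum_ik R_ik E[b b' | k]
        for g, per_k in zip(groups, moments):
            A_g = aux[g["rows"]]
            for k in range(K):
                w = resp[g["rows"], k]
                M, C = per_k[k]
                Mw = w[:, None] * M
                Msum_k[k] += Mw.sum(axis=0)
                ASum_k[k] += (w[:, None] * A_g).sum(axis=0)
                MA += Mw.T @ A_g
                Ssum += Mw.T @ M + w.sum() * C
        if invariant:
            Msum = Msum_k.sum(axis=0)
            D = np.zeros((1 + r, 1 + r))
            D[0, 0] = n
            D[0, 1:] = Msum
            D[1:, 0] = Msum
            D[1:, 1:] = Ssum
            rhs = np.vstack([ASum_k.sum(axis=0)[None, :], MA])
            B = np.linalg.solve(D, rhs)
            nu = np.tile(B[0], (K, 1))
            Gamma = B[1:].T
        else:
            wk = resp.sum(axis=0)
            D = np.zeros((K + r, K + r))
            D[:K, :K] = np.diag(wk)
            D[:K, K:] = Msum_k
            D[K:, :K] = Msum_k.T
            D[K:, K:] = Ssum
            rhs = np.vstack([ASum_k, MA])   # (K + r, m)
            B = np.linalg.solve(D, rhs)
            nu = B[:K]                      # (K, m)
            Gamma = B[K:].T                 # (m, r)
        # residual variances: E[(a_j - nu_kj - gamma_j' b)^2] averaged
        s = np.zeros(m)
        for g, per_k in zip(groups, moments):
            A_g = aux[g["rows"]]
            for k in range(K):
                w = resp[g["rows"], k]
                M, C = per_k[k]
                res = A_g - nu[k][None, :] - M @ Gamma.T
                s += (w[:, None] * res ** 2).sum(axis=0)
                s += w.sum() * np.einsum("jr,rs,js->j", Gamma, C, Gamma)
        s = np.maximum(s / n, 1e-8)
        aux_new = {"nu": nu, "Gamma": Gamma, "s": s,
                   "invariant": invariant}
    return pi, alpha_new, Psi_new, theta_new, aux_new


class _DegenerateStart(RuntimeError):
    pass


def _ensure_pd(Psi, warnings_):
    vals = np.linalg.eigvalsh(Psi)
    if vals.min() < 1e-10 * max(vals.max(), 1.0):
        ridge = 1e-8 * max(np.trace(Psi) / Psi.shape[0], 1.0)
        Psi = Psi + ridge * np.eye(Psi.shape[0])
        warnings_.append("near-singular growth-factor covariance; "
                         f"ridge {ridge:.2e} applied")
    return Psi


def _run_em(groups, n, K, init, visit_specific, J, obs_per_visit,
            aux, max_iter, tol, warnings_):
    pi, alpha, Psi, theta_vec, aux_params = init
    history = []
    ll_prev = -np.inf
    for it in range(max_iter):
        ll, resp, moments = _estep(groups, pi, alpha, Psi, theta_vec,
                                   aux_params, n, K)
        history.append(ll)
        if abs(ll - ll_prev) < tol:
            return (pi, alpha, Psi, theta_vec, aux_params, ll, resp,
                    history, True, it + 1)
        ll_prev = ll
        pi, alpha, Psi, theta_vec, aux_params = _mstep(
            groups, resp, moments, alpha.shape, Psi.shape[0], theta_vec,
            visit_specific, J, obs_per_visit, aux, aux_params
        )
        Psi = _ensure_pd(Psi, warnings_)
    ll, resp, _ = _estep(groups, pi, alpha, Psi, theta_vec, aux_params,
                         n, K, want_moments=False)
    history.append(ll)
    return (pi, alpha, Psi, theta_vec, aux_params, ll, resp, history,
            False, max_iter)


def _ols_growth_coefs(panel: VisitPanel, X):
    coefs = np.zeros((panel.n, X.shape[1]))
    resid_var = []
    for i in range(panel.n):
        obs = panel.mask[i]
        Xi, yi = X[obs], panel.y[i, obs]
        beta, _, _, _ = np.linalg.lstsq(Xi, yi, rcond=None)
        coefs[i] = beta
        if obs.sum() > X.shape[1]:
            r = yi - Xi @ beta
            resid_var.append(r @ r / (obs.sum() - X.shape[1]))
    rv = float(np.mean(resid_var)) if resid_var else float(np.nanvar(panel.y))
    return coefs, max(rv, 1e-3)


def _initial_params(panel, X, Z, K, rng, perturb, aux, mode="kmeans",
                    aux_invariant=True):
    coefs, rv = _ols_growth_coefs(panel, X)
    # short follow-ups give wild OLS coefficients; winsorize before k-means
    lo, hi = np.percentile(coefs, [2, 98], axis=0)
    coefs = np.clip(coefs, lo, hi)
    if K == 1:
        labels = np.zeros(panel.n, dtype=int)
    elif mode == "random":
        labels = rng.integers(0, K, size=panel.n)
    else:
        seed = int(rng.integers(2 ** 31 - 1))
        _, labels = kmeans2(coefs, K, minit="++", seed=seed)
        if len(np.unique(labels)) < K:
            labels = rng.integers(0, K, size=panel.n)
    alpha0 = np.empty((K, X.shape[1]))
    col_sd = coefs.std(axis=0) + 1e-3
    for k in range(K):
        sel = labels == k
        alpha0[k] = coefs[sel].mean(axis=0) if sel.any() else coefs.mean(axis=0)
        alpha0[k] += perturb * col_sd * rng.standard_normal(X.shape[1])
    pi0 = np.bincount(labels, minlength=K) / panel.n
    pi0 = np.clip(pi0, 0.05, None)
    pi0 /= pi0.sum()
    # OLS-coef covariance over the leading (random-effect) columns
    sub = coefs[:, : Z.shape[1]]
    Psi0 = np.cov(sub.T) * 0.5 if sub.shape[1] > 1 else np.atleast_2d(
        np.var(sub) * 0.5
    )
    Psi0 = np.atleast_2d(Psi0) + 1e-2 * np.eye(Z.shape[1])
    theta0 = np.full(X.shape[0], rv)
    aux_params0 = None
    if aux is not None:
        aux_params0 = {
            "nu": np.tile(aux.mean(axis=0), (K, 1)),
            "Gamma": np.zeros((aux.shape[1], Z.shape[1])),
            "s": np.maximum(aux.var(axis=0), 1e-6),
            "invariant": aux_invariant,
        }
    return pi0, alpha0, Psi0, theta0, aux_params0


def _count_params(K, q, r, J, visit_specific, n_aux, aux_invariant=True):
    p = K * q + (K - 1) + r * (r + 1) // 2
    p += J if visit_specific else 1
    if n_aux:
        n_means = 1 if aux_invariant else K
        p += n_aux * (n_means + r + 1)  # means, loadings, residual var
    return p


def _canonical_order(pi, alpha, posterior, aux_params=None):
    order = np.argsort(-alpha[:, 0])
    if aux_params is not None:
        aux_params = dict(aux_params, nu=aux_params["nu"][order])
    return pi[order], alpha[order], posterior[:, order], aux_params


def em_fit(
    panel: VisitPanel,
    spec: GrowthSpec = None,
    K: int = 1,
    n_starts: int = 50,
    seed: int = None,
    max_iter: int = 2000,
    tol: float = 1e-6,
    aux: np.ndarray = None,
    aux_means: str = "invariant",
    short_iters: int = 80,
) -> GrowthMixtureFit:
    """Fit a K-class growth mixture by multi-start EM.

    A k-means initialisation on per-person OLS growth coefficients seeds the
    first start; the remaining starts alternate random partitions and
    perturbed k-means.  All starts run a short EM burn-in, the best few
    continue to full convergence, and the top log-likelihood must be
    replicated by a second start or a warning is recorded on the fit.
    Classes are reported in descending-intercept order.

    ``aux`` appends fully observed auxiliary missingness correlates as
    saturated correlates of the growth random effects; with
    ``aux_means='invariant'`` (default) their means are class-invariant so
    the auxiliary block cannot define classes, ``'by_class'`` frees them.
    """
    if aux_means not in ("invariant", "by_class"):
        raise GMMError("aux_means must be 'invariant' or 'by_class'")
    aux_invariant = aux_means == "invariant"
    if K < 1:
        raise GMMError("K must be >= 1")
    if n_starts < 1:
        raise GMMError("n_starts must be >= 1")
    spec = spec or GrowthSpec()
    panel = panel.drop_empty()
    X = spec.mean_matrix(panel.times)
    Z = spec.ranef_matrix(panel.times)
    if aux is not None:
        aux = np.asarray(aux, dtype=float)
        if aux.ndim == 1:
            aux = aux[:, None]
        if aux.shape[0] != panel.n:
            raise GMMError("aux rows must align with the panel")
        if np.isnan(aux).any():
            raise GMMError("auxiliary variables must be fully observed")
    pats = _Patterns(panel, X, Z, aux)
    rng = np.random.default_rng(seed)
    warnings_: list = []

    stage1 = []
    for s in range(n_starts):
        init = _initial_params(panel, X, Z, K, rng,
                               perturb=0.0 if s == 0 else 0.6, aux=aux,
                               mode="kmeans" if s % 2 == 0 else "random",
                               aux_invariant=aux_invariant)
        try:
            out = _run_em(pats.groups, panel.n, K, init,
                          spec.visit_specific_residuals, panel.J,
                          pats.obs_per_visit, aux,
                          max_iter=min(short_iters, max_iter), tol=tol,
                          warnings_=warnings_)
        except _DegenerateStart:
            continue
        stage1.append(out)
    if not stage1:
        raise DegenerateFitError(
            f"all {n_starts} EM starts degenerated (K={K}); the panel may "
            "not support this many classes"
        )
    stage1.sort(key=lambda o: -o[5])
    n_final = max(2, min(5, len(stage1)))
    finals = []
    for out in stage1[:n_final]:
        if out[8]:  # already converged during burn-in
            finals.append(out)
            continue
        init = (out[0], out[1], out[2], out[3], out[4])
        try:
            cont = _run_em(pats.groups, panel.n, K, init,
                           spec.visit_specific_residuals, panel.J,
                           pats.obs_per_visit, aux, max_iter=max_iter,
                           tol=tol, warnings_=warnings_)
        except _DegenerateStart:
            continue
        cont = cont[:7] + (out[7] + cont[7],) + cont[8:]
        finals.append(cont)
    if not finals:
        raise DegenerateFitError("all refined EM starts degenerated")
    final_lls = np.array([o[5] for o in finals])
    best = finals[int(np.argmax(final_lls))]
    replicated = bool((final_lls > final_lls.max() - 1e-3).sum() >= 2)
    if not replicated:
        warnings_.append(
            "best log-likelihood was not replicated by a second start; "
            "the solution may be a local maximum"
        )
    pi, alpha, Psi, theta_vec, aux_params, ll, resp, history, conv, its = best
    pi, alpha, resp, aux_params = _canonical_order(pi, alpha, resp,
                                                   aux_params)
    theta = theta_vec if spec.visit_specific_residuals else theta_vec[:1]
    return GrowthMixtureFit(
        K=K,
        pi=pi,
        alpha=alpha,
        Psi=Psi,
        theta=theta,
        posterior=resp,
        loglik=ll,
        n_params=_count_params(K, X.shape[1], Z.shape[1], panel.J,
                               spec.visit_specific_residuals,
                               0 if aux is None else aux.shape[1],
                               aux_invariant),
        spec=spec,
        times=panel.times,
        converged=conv,
        n_iter=its,
        n_starts=n_starts,
        start_logliks=np.array(sorted((o[5] for o in stage1), reverse=True)),
        best_replicated=replicated,
        history=history,
        warnings_=warnings_,
        aux=aux_params,
    )


def loglik(panel: VisitPanel, fit: GrowthMixtureFit) -> float:
    """Observed-data FIML log-likelihood of ``panel`` under ``fit``.

    Each participant contributes log sum_k pi_k phi(y_obs; mu_k,obs,
    Sigma_obs) with the observed rows/columns selected from mu_k = X alpha_k
    and Sigma = Z Psi Z' + Theta.  (Auxiliary-correlate parameters, if any,
    are ignored: this is the growth model's own likelihood.)
    """
    panel = panel.drop_empty()
    X = fit.spec.mean_matrix(panel.times)
    Z = fit.spec.ranef_matrix(panel.times)
    if X.shape[1] != fit.alpha.shape[1]:
        raise GMMError("fit dimensions do not match the panel basis")
    theta_vec = (np.asarray(fit.theta, dtype=float)
                 if fit.spec.visit_specific_residuals
                 else np.full(panel.J, float(np.asarray(fit.theta).ravel()[0])))
    pats = _Patterns(panel, X, Z, None)
    ll, _, _ = _estep(pats.groups, fit.pi, fit.alpha, fit.Psi, theta_vec,
                      None, panel.n, fit.K, want_moments=False)
    return ll


# ---------------------------------------------------------------------------
# fit indices, enumeration, tests


def entropy(posterior: np.ndarray) -> float:
    """Normalized classification entropy: 1 = crisp, 0 = uninformative.

    Undefined (NaN) for a single class.
    """
    n, K = posterior.shape
    if K == 1:
        return float("nan")
    p = np.clip(posterior, 1e-300, 1.0)
    h = float(-(posterior * np.log(p)).sum())
    return 1.0 - h / (n * np.log(K))


def fit_indices(fit: GrowthMixtureFit, n: int) -> dict:
    """AIC, BIC, sample-size-adjusted BIC and entropy for a converged fit."""
    ll, p = fit.loglik, fit.n_params
    return {
        "loglik": ll,
        "n_params": p,
        "aic": -2.0 * ll + 2.0 * p,
        "bic": -2.0 * ll + p * np.log(n),
        "ssbic": -2.0 * ll + p * np.log((n + 2.0) / 24.0),
        "entropy": entropy(fit.posterior),
    }


@dataclass
class LMRResult:
    statistic: float
    statistic_adjusted: float
    df: int
    p_value: float             # adjusted LMR p (reported by default)
    p_unadjusted: float


def lmr_test(fit_K: GrowthMixtureFit, fit_Kminus1: GrowthMixtureFit,
             n: int) -> LMRResult:
    """Lo-Mendell-Rubin adjusted likelihood-ratio test of K vs K-1 classes.

    The LR statistic 2(l_K - l_{K-1}) is shrunk by the factor
    1 + 1/(q ln n) (q = extra parameters) and referred to a chi-square with
    q degrees of freedom, following the LMR approximation; a worse-fitting
    larger model yields p = 1 with a warning.
    """
    if fit_K.K != fit_Kminus1.K + 1:
        raise GMMError("fits must differ by exactly one class")
    q = fit_K.n_params - fit_Kminus1.n_params
    lr = 2.0 * (fit_K.loglik - fit_Kminus1.loglik)
    if lr < 0:
        warnings.warn(
            "larger model has lower log-likelihood (likely a local maximum); "
            "LMR p set to 1"
        )
        return LMRResult(lr, lr, q, 1.0, 1.0)
    c = 1.0 + 1.0 / (q * np.log(n))
    adj = lr / c
    return LMRResult(
        statistic=lr,
        statistic_adjusted=adj,
        df=q,
        p_value=float(stats.chi2.sf(adj, q)),
        p_unadjusted=float(stats.chi2.sf(lr, q)),
    )


def simulate_from_fit(fit: GrowthMixtureFit, mask: np.ndarray,
                      rng) -> np.ndarray:
    """Draw a panel from a fitted model, preserving a missingness mask."""
    n, J = mask.shape
    X = fit.spec.mean_matrix(fit.times)
    Z = fit.spec.ranef_matrix(fit.times)
    theta_vec = (np.asarray(fit.theta, dtype=float)
                 if fit.spec.visit_specific_residuals
                 else np.full(J, float(np.asarray(fit.theta).ravel()[0])))
    classes = rng.choice(fit.K, size=n, p=fit.pi / fit.pi.sum())
    b = rng.multivariate_normal(np.zeros(fit.Psi.shape[0]), fit.Psi, size=n)
    y = (X @ fit.alpha[classes].T).T + b @ Z.T
    y = y + rng.standard_normal((n, J)) * np.sqrt(theta_vec)
    y[~mask] = np.nan
    return y


def bootstrap_lrt(panel: VisitPanel, spec: GrowthSpec, K: int,
                  n_boot: int = 50, n_starts: int = 8,
                  seed: int = None) -> dict:
    """Parametric-bootstrap LRT of K vs K-1 classes (LMR cross-check).

    Simulates from the fitted (K-1)-class model under the observed
    missingness pattern and compares the real LR statistic with the
    bootstrap distribution.
    """
    rng = np.random.default_rng(seed)
    panel = panel.drop_empty()
    fit0 = em_fit(panel, spec, K - 1, n_starts=n_starts,
                  seed=int(rng.integers(2 ** 31 - 1)))
    fit1 = em_fit(panel, spec, K, n_starts=n_starts,
                  seed=int(rng.integers(2 ** 31 - 1)))
    lr_obs = 2.0 * (fit1.loglik - fit0.loglik)
    exceed = 0
    lrs = []
    for _ in range(n_boot):
        y = simulate_from_fit(fit0, panel.mask, rng)
        bp = VisitPanel(y, panel.times)
        try:
            b0 = em_fit(bp, spec, K - 1, n_starts=max(2, n_starts // 2),
                        seed=int(rng.integers(2 ** 31 - 1)))
            b1 = em_fit(bp, spec, K, n_starts=max(2, n_starts // 2),
                        seed=int(rng.integers(2 ** 31 - 1)))
        except DegenerateFitError:
            continue
        lr_b = 2.0 * (b1.loglik - b0.loglik)
        lrs.append(lr_b)
        if lr_b >= lr_obs:
            exceed += 1
    n_eff = len(lrs)
    p = (exceed + 1.0) / (n_eff + 1.0) if n_eff else float("nan")
    return {"lr": lr_obs, "p_value": p, "bootstrap_lrs": lrs,
            "n_boot_effective": n_eff}


MIN_CLASS_COUNT = 25
MIN_CLASS_SHARE = 0.05


@dataclass
class ClassSolutionTable:
    """Per-K fit summary (log-likelihood, information criteria, entropy,
    LMR p, modal class sizes and adequacy flags)."""

    table: pd.DataFrame
    fits: dict
    lmr: dict

    def best_K(self, alpha: float = 0.05) -> int:
        """Smallest K whose (K+1)-class alternative fails the LMR test at
        ``alpha`` and whose classes are all adequate; falls back to the
        smallest adequate ssBIC minimiser."""
        ok = self.table[self.table["converged"]]
        for _, row in ok.iterrows():
            K = int(row["K"])
            nxt = self.lmr.get(K + 1)
            lmr_ok = nxt is None or nxt.p_value >= alpha
            if lmr_ok and row["adequate"]:
                return K
        adequate = ok[ok["adequate"]]
        pool = adequate if len(adequate) else ok
        return int(pool.loc[pool["ssbic"].idxmin(), "K"])


def enumerate_classes(
    panel: VisitPanel,
    spec: GrowthSpec = None,
    Kmax: int = 4,
    n_starts: int = 50,
    seed: int = None,
    aux: np.ndarray = None,
) -> ClassSolutionTable:
    """Fit 1..Kmax class models and tabulate enumeration diagnostics."""
    if Kmax < 1:
        raise GMMError("Kmax must be >= 1")
    spec = spec or GrowthSpec()
    panel = panel.drop_empty()
    rng = np.random.default_rng(seed)
    rows, fits, lmrs = [], {}, {}
    for K in range(1, Kmax + 1):
        row = {"K": K, "converged": False, "adequate": False}
        try:
            fit = em_fit(panel, spec, K, n_starts=n_starts,
                         seed=int(rng.integers(2 ** 31 - 1)), aux=aux)
        except DegenerateFitError as exc:
            row["note"] = str(exc)
            rows.append(row)
            continue
        fits[K] = fit
        idx = fit_indices(fit, panel.n)
        sizes = fit.class_sizes
        pcts = 100.0 * sizes / panel.n
        row.update(idx)
        row["converged"] = fit.converged
        row["class_sizes"] = sizes.tolist()
        row["class_pcts"] = np.round(pcts, 1).tolist()
        row["adequate"] = bool(
            sizes.min() >= MIN_CLASS_COUNT
            and (sizes / panel.n).min() >= MIN_CLASS_SHARE
        )
        row["best_replicated"] = fit.best_replicated
        if K - 1 in fits:
            res = lmr_test(fit, fits[K - 1], panel.n)
            lmrs[K] = res
            row["lmr_p"] = res.p_value
        else:
            row["lmr_p"] = float("nan")
        rows.append(row)
    table = pd.DataFrame(rows)
    return ClassSolutionTable(table=table, fits=fits, lmr=lmrs)


# ---------------------------------------------------------------------------
# base-model selection


def _neg_loglik_latent_basis(params, panel, pats_mask):
    J = panel.J
    alpha = params[:2]
    lam = np.concatenate([[0.0], params[2:2 + J - 2], [1.0]])
    l11, l21, l22 = params[2 + J - 2: 2 + J + 1]
    Lpsi = np.array([[np.exp(l11), 0.0], [l21, np.exp(l22)]])
    Psi = Lpsi @ Lpsi.T
    s2 = np.exp(params[-1])
    X = np.column_stack([np.ones(J), lam])
    mu = X @ alpha
    V = X @ Psi @ X.T + s2 * np.eye(J)
    ll = 0.0
    for i in range(panel.n):
        obs = pats_mask[i]
        Vi = V[np.ix_(obs, obs)]
        try:
            L = cholesky(Vi, lower=True)
        except np.linalg.LinAlgError:
            return 1e12
        r = panel.y[i, obs] - mu[obs]
        half = solve_triangular(L, r, lower=True)
        ll += -0.5 * (obs.sum() * _LOG2PI
                      + 2.0 * np.log(np.diag(L)).sum() + half @ half)
    return -ll


def _fit_latent_basis_k1(panel: VisitPanel):
    from scipy.optimize import minimize

    J = panel.J
    mask = panel.mask
    ramp = (panel.times - panel.times[0]) / (panel.times[-1] - panel.times[0])
    X0 = np.column_stack([np.ones(J), ramp])
    coefs, rv = _ols_growth_coefs(panel, X0)
    x0 = np.concatenate([
        coefs.mean(axis=0),
        ramp[1:-1],
        [0.5 * np.log(max(np.var(coefs[:, 0]), 1e-2)), 0.0,
         0.5 * np.log(max(np.var(coefs[:, 1]), 1e-2))],
        [np.log(rv)],
    ])
    res = minimize(_neg_loglik_latent_basis, x0, args=(panel, mask),
                   method="L-BFGS-B",
                   options={"maxiter": 500})
    lam = np.concatenate([[0.0], res.x[2:2 + J - 2], [1.0]])
    spec = GrowthSpec(basis="latent-basis", random_effects=("intercept",
                                                            "slope"),
                      loadings=lam)
    n_params = 2 + (J - 2) + 3 + 1
    return {
        "spec": spec,
        "loglik": -float(res.fun),
        "n_params": n_params,
        "converged": bool(res.success),
    }


DEFAULT_BASE_CANDIDATES = ("intercept-only", "linear", "quadratic", "cubic",
                           "latent-basis")


def select_base_model(panel: VisitPanel,
                      candidates=DEFAULT_BASE_CANDIDATES,
                      criterion: str = "aic"):
    """Rank candidate single-class growth curves by AIC/ssBIC.

    Returns ``(best_spec, comparison_table)``.  Random effects are carried
    on the intercept and (where the basis has one) the linear slope.
    """
    panel = panel.drop_empty()
    rows = []
    specs = {}
    for name in candidates:
        if name == "latent-basis":
            if panel.J < 3:
                continue
            out = _fit_latent_basis_k1(panel)
            spec, ll, p = out["spec"], out["loglik"], out["n_params"]
            conv = out["converged"]
            ent = float("nan")
        else:
            re = ("intercept",) if name == "intercept-only" else (
                "intercept", "linear")
            spec = GrowthSpec(basis=name, random_effects=re)
            fit = em_fit(panel, spec, K=1, n_starts=1, seed=0)
            ll, p, conv = fit.loglik, fit.n_params, fit.converged
        n = panel.n
        rows.append({
            "basis": name,
            "loglik": ll,
            "n_params": p,
            "aic": -2 * ll + 2 * p,
            "bic": -2 * ll + p * np.log(n),
            "ssbic": -2 * ll + p * np.log((n + 2) / 24.0),
            "converged": conv,
        })
        specs[name] = spec
    table = pd.DataFrame(rows).sort_values(criterion).reset_index(drop=True)
    best = specs[table.loc[0, "basis"]]
    return best, table


# ---------------------------------------------------------------------------
# missing-data diagnostics and secondary fits


def covariance_coverage(panel: VisitPanel, threshold: float = 0.10):
    """Pairwise indicator coverage: fraction of participants observed at
    both visits of each pair.  Warns when the minimum falls below the
    conventional 0.10 convergence threshold."""
    if panel.J < 2:
        raise GMMError("coverage needs at least two visits")
    m = panel.mask.astype(float)
    cov = (m.T @ m) / panel.n
    mn = float(cov.min())
    if mn < threshold:
        warnings.warn(
            f"minimum covariance coverage {mn:.3f} is below the "
            f"{threshold:.2f} threshold; the model may not converge"
        )
    return cov, mn


def drop_baseline_refit(panel: VisitPanel, spec: GrowthSpec, K: int,
                        n_starts: int = 50, seed: int = None,
                        primary_fit: GrowthMixtureFit = None):
    """Refit the mixture on follow-up visits only (baseline indicator
    removed, original time codes preserved) and cross-tabulate modal class
    membership against the primary fit.

    Returns ``(secondary_fit, shift_table)`` where the shift table rows are
    primary classes and columns secondary classes.
    """
    if panel.J - 1 < 4:
        raise GMMError("need at least 4 follow-up visits after dropping "
                       "baseline")
    spec = spec or GrowthSpec()
    if primary_fit is None:
        primary_fit = em_fit(panel, spec, K, n_starts=n_starts, seed=seed)
    sub = VisitPanel(panel.y[:, 1:], panel.times[1:], panel.ids)
    keep = sub.mask.any(axis=1)
    fit2 = em_fit(VisitPanel(sub.y[keep], sub.times, sub.ids[keep]),
                  spec, K, n_starts=n_starts, seed=seed)
    primary_modal = primary_fit.posterior.argmax(axis=1)[keep]
    secondary_modal = fit2.posterior.argmax(axis=1)
    shift = pd.crosstab(
        pd.Series(primary_modal + 1, name="primary_class"),
        pd.Series(secondary_modal + 1, name="secondary_class"),
    ).reindex(index=range(1, K + 1), columns=range(1, K + 1), fill_value=0)
    return fit2, shift


# ---------------------------------------------------------------------------
# standard errors


def _pack_params(fit: GrowthMixtureFit):
    K, q = fit.alpha.shape
    r = fit.Psi.shape[0]
    L = cholesky(fit.Psi, lower=True)
    chol_parts = []
    for i in range(r):
        for j in range(i + 1):
            chol_parts.append(np.log(L[i, j]) if i == j else L[i, j])
    parts = [
        np.log(fit.pi[1:] / fit.pi[0]),
        fit.alpha.ravel(),
        np.array(chol_parts),
        np.log(np.asarray(fit.theta, dtype=float).ravel()),
    ]
    return np.concatenate(parts)


def _unpack_params(vec, K, q, r, n_theta):
    i = 0
    logits = vec[i:i + K - 1]; i += K - 1
    pi = np.concatenate([[1.0], np.exp(logits)])
    pi = pi / pi.sum()
    alpha = vec[i:i + K * q].reshape(K, q); i += K * q
    L = np.zeros((r, r))
    for a in range(r):
        for b in range(a + 1):
            v = vec[i]; i += 1
            L[a, b] = np.exp(v) if a == b else v
    Psi = L @ L.T
    theta = np.exp(vec[i:i + n_theta])
    return pi, alpha, Psi, theta


def growth_standard_errors(panel: VisitPanel, fit: GrowthMixtureFit) -> np.ndarray:
    """Plain-ML standard errors of the growth-factor means.

    Numerically differentiates the observed-data log-likelihood to form the
    observed information matrix and returns the (K, q) SE block for alpha.
    """
    panel = panel.drop_empty()
    X = fit.spec.mean_matrix(panel.times)
    Z = fit.spec.ranef_matrix(panel.times)
    pats = _Patterns(panel, X, Z, None)
    K, q = fit.alpha.shape
    r = fit.Psi.shape[0]
    n_theta = len(np.asarray(fit.theta).ravel())

    def ll_at(vec):
        pi, alpha, Psi, theta = _unpack_params(vec, K, q, r, n_theta)
        theta_vec = (theta if fit.spec.visit_specific_residuals
                     else np.full(panel.J, theta[0]))
        ll, _, _ = _estep(pats.groups, pi, alpha, Psi, theta_vec, None,
                          panel.n, K, want_moments=False)
        return ll

    x0 = _pack_params(fit)
    p = len(x0)
    h = 1e-4 * np.maximum(np.abs(x0), 1.0)
    H = np.empty((p, p))
    for a in range(p):
        for b in range(a, p):
            ea = np.zeros(p); ea[a] = h[a]
            eb = np.zeros(p); eb[b] = h[b]
            f = (
                ll_at(x0 + ea + eb) - ll_at(x0 + ea - eb)
                - ll_at(x0 - ea + eb) + ll_at(x0 - ea - eb)
            ) / (4 * h[a] * h[b])
            H[a, b] = H[b, a] = f
    info = -H
    cov = np.linalg.pinv(info)
    var = np.clip(np.diag(cov), 0.0, None)
    start = K - 1
    return np.sqrt(var[start:start + K * q]).reshape(K, q)
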