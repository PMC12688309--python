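"""Maximum-likelihood fitting of the three structural equation families.

The path model needs three regression families:

* binary logistic (mediator M1 and non-clustered outcome fits),
* three-category multinomial logistic with a declared reference level
  (mediator M2: physical activity low/moderate/high), and
* random-intercept logistic with a cluster (province) Normal(0, σ²)
  intercept, integrated out by adaptive Gauss–Hermite quadrature
  (the outcome equation of the multilevel model).

Fixed-effect models use Newton–Raphson (Fisher scoring) with
step-halving, relative log-likelihood tolerance 1e-10 and at most 100
iterations; warm starts are supported so bootstrap refits converge in a
couple of steps. Wald 95% intervals use ±1.959964·SE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .exceptions import (
    InvalidArgumentError,
    RankDeficiencyError,
    SeparationError,
    VarianceUnidentifiedError,
)
from .schema import CATEGORY_LEVELS, DEFAULT_REFERENCES

__all__ = [
    "ModelSpec",
    "FitResult",
    "build_design",
    "fit_logistic",
    "fit_multinomial",
    "fit_logistic_ri",
    "information_criteria",
]

Z_975 = 1.959964
_REL_TOL = 1e-10
_MAX_ITER = 100
_INTERCEPT = "intercept"


@dataclass
class ModelSpec:
    """Declarative description of one structural equation."""

    response: str
    family: str = "binary"  # or "multinomial3"
    predictors: list[str] = field(default_factory=list)
    references: dict[str, str] = field(default_factory=dict)
    cluster: str | None = None
    quadrature_points: int = 7

    def reference_for(self, column: str) -> str:
        return self.references.get(column, DEFAULT_REFERENCES.get(column, ""))

    def validate(self) -> None:
        if self.family not in ("binary", "multinomial3"):
            raise InvalidArgumentError(f"unknown family {self.family!r}")
        if self.cluster is not None and self.quadrature_points < 1:
            raise InvalidArgumentError(
                "quadrature_points must be >= 1 when a cluster is set"
            )


@dataclass
class FitResult:
    """One fitted equation: estimates, uncertainty, fit statistics."""

    coefficients: pd.Series
    standard_errors: pd.Series
    vcov: pd.DataFrame
    loglik: float
    n_obs: int
    n_params: int
    aic: float
    bic: float
    converged: bool
    n_iter: int
    variance_component: float | None = None  # sigma^2 when a cluster is set
    variance_component_se: float | None = None

    def conf_int(self) -> pd.DataFrame:
        """Wald 95% confidence intervals (estimate ± 1.959964·SE)."""
        lo = self.coefficients - Z_975 * self.standard_errors
        hi = self.coefficients + Z_975 * self.standard_errors
        return pd.DataFrame({"low": lo, "high": hi})

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "estimate": self.coefficients,
                "se": self.standard_errors,
                "ci_low": ci["low"],
                "ci_high": ci["high"],
            }
        )


def information_criteria(loglik: float, n_params: int, n_obs: int) -> tuple[float, float]:
    """AIC = 2k − 2L and BIC = k·ln(n) − 2L."""
    if n_obs < 1:
        raise InvalidArgumentError("n_obs must be >= 1")
    aic = 2.0 * n_params - 2.0 * loglik
    bic = n_params * float(np.log(n_obs)) - 2.0 * loglik
    return aic, bic


def build_design(
    data: pd.DataFrame, predictors: list[str], references: dict[str, str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept; categoricals coded as treatment
    contrasts against the declared (or schema-default) reference level."""
    references = references or {}
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = [_INTERCEPT]
    for col in predictors:
        if col not in data.columns:
            raise InvalidArgumentError(f"predictor column missing: {col!r}")
        values = data[col]
        if col in CATEGORY_LEVELS:
            ref = references.get(col, DEFAULT_REFERENCES[col])
            levels = CATEGORY_LEVELS[col]
            if ref not in levels:
                raise InvalidArgumentError(f"unknown reference {ref!r} for {col!r}")
            observed = set(values.dropna().unique())
            unknown = observed - set(levels)
            if unknown:
                raise InvalidArgumentError(f"unknown category in {col!r}: {unknown}")
            for level in levels:
                if level == ref:
                    continue
                cols.append((values == level).to_numpy(dtype=float))
                names.append(f"{col}[{level}]")
        else:
            arr = pd.to_numeric(values, errors="raise").to_numpy(dtype=float)
            if not np.all(np.isfinite(arr)):
                raise InvalidArgumentError(f"non-finite values in predictor {col!r}")
            cols.append(arr)
            names.append(col)
    X = np.column_stack(cols)
    return X, names


def _binary_response(data: pd.DataFrame, column: str) -> np.ndarray:
    values = data[column]
    if values.isna().any():
        raise InvalidArgumentError(f"missing values in response {column!r}")
    if values.dtype == object or isinstance(values.dtype, pd.CategoricalDtype):
        mapped = values.map({"yes": 1.0, "no": 0.0})
        if mapped.isna().any():
            raise InvalidArgumentError(
                f"response {column!r} must be yes/no or 0/1"
            )
        return mapped.to_numpy(dtype=float)
    arr = values.to_numpy(dtype=float)
    if not np.isin(arr, (0.0, 1.0)).all():
        raise InvalidArgumentError(f"response {column!r} must be binary")
    return arr


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {X.shape[1]} columns ({names})"
        )


def _logistic_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # sum y*eta - log(1 + exp(eta)), numerically stable
    return float(np.dot(y, eta) - np.logaddexp(0.0, eta).sum())


def _newton_logistic(
    X: np.ndarray, y: np.ndarray, start: np.ndarray | None, names: list[str]
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Newton–Raphson IRLS; returns (beta, vcov, loglik, n_iter)."""
    n, p = X.shape
    if y.min() == y.max():
        raise SeparationError(
            "response is constant; no maximum-likelihood estimate exists"
        )
    beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    eta = X @ beta
    ll = _logistic_loglik(eta, y)
    n_iter = 0
    for n_iter in range(1, _MAX_ITER + 1):
        mu = special.expit(eta)
        grad = X.T @ (y - mu)
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise RankDeficiencyError(f"singular Hessian: {exc}") from exc
        # step-halving line search on the log-likelihood
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            eta_c = X @ cand
            ll_c = _logistic_loglik(eta_c, y)
            if ll_c >= ll - 1e-14:
                break
            scale *= 0.5
        beta, eta, ll_new = cand, eta_c, ll_c
        if np.max(np.abs(beta)) > 40.0:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"coefficient for {worst!r} diverging: likely perfect separation",
                term=worst,
            )
        if abs(ll_new - ll) <= _REL_TOL * (abs(ll) + 1e-12) and np.max(np.abs(grad)) < 1e-6:
            ll = ll_new
            break
        ll = ll_new
    mu = special.expit(eta)
    w = mu * (1.0 - mu)
    H = X.T @ (X * w[:, None])
    vcov = np.linalg.inv(H)
    return beta, vcov, ll, n_iter


def fit_logistic(
    data: pd.DataFrame, spec: ModelSpec, start: np.ndarray | None = None
) -> FitResult:
    """Binary logistic regression by Newton–Raphson.

    At the reported optimum the score has max-norm below 1e-6. Rows must
    be complete for all used columns (the caller filters beforehand).
    """
    spec.validate()
    X, names = build_design(data, spec.predictors, spec.references)
    y = _binary_response(data, spec.response)
    _check_rank(X, names)
    beta, vcov, ll, n_iter = _newton_logistic(X, y, start, names)
    return _pack_result(beta, vcov, ll, names, len(y), n_iter)


def _pack_result(
    beta, vcov, ll, names, n_obs, n_iter, extra_params: int = 0,
    sigma2: float | None = None, sigma2_se: float | None = None,
    converged: bool = True,
) -> FitResult:
    k = len(names) + extra_params
    aic, bic = information_criteria(ll, k, n_obs)
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    return FitResult(
        coefficients=pd.Series(beta, index=names),
        standard_errors=pd.Series(se, index=names),
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        loglik=ll,
        n_obs=n_obs,
        n_params=k,
        aic=aic,
        bic=bic,
        converged=converged,
        n_iter=n_iter,
        variance_component=sigma2,
        variance_component_se=sigma2_se,
    )


# ---------------------------------------------------------------------------
# Multinomial logit
# ---------------------------------------------------------------------------

def fit_multinomial(
    data: pd.DataFrame,
    spec: ModelSpec,
    reference: str | None = None,
    start: np.ndarray | None = None,
) -> FitResult:
    """Multinomial logistic regression (baseline-category logit).

    One coefficient block per non-reference category, named
    ``"<category>:<term>"``. The log-likelihood is the categorical
    likelihood of the chosen categories.
    """
    spec.validate()
    response = data[spec.response]
    if response.isna().any():
        raise InvalidArgumentError(f"missing values in response {spec.response!r}")
    levels = CATEGORY_LEVELS.get(spec.response)
    observed = list(pd.unique(response))
    if levels is None:
        levels = sorted(observed)
    ref = reference if reference is not None else spec.reference_for(spec.response)
    if ref not in levels:
        raise InvalidArgumentError(f"unknown reference category {ref!r}")
    present = [lv for lv in levels if lv in set(observed)]
    missing_levels = [lv for lv in levels if lv not in set(observed)]
    if missing_levels:
        raise InvalidArgumentError(
            f"categories absent from data: {missing_levels}"
        )
    if ref not in present:
        raise InvalidArgumentError(f"reference category {ref!r} absent from data")
    alts = [lv for lv in levels if lv != ref]  # non-reference, canonical order

    X, names = build_design(data, spec.predictors, spec.references)
    _check_rank(X, names)
    n, p = X.shape
    K = len(alts)
    Y = np.column_stack([(response == lv).to_numpy(dtype=float) for lv in alts])

    theta, vcov, ll, n_iter = _newton_multinomial(X, Y, start, names, alts)
    term_names = [f"{alt}:{name}" for alt in alts for name in names]
    return _pack_result(theta, vcov, ll, term_names, n, n_iter)


def _newton_multinomial(
    X: np.ndarray,
    Y: np.ndarray,
    start: np.ndarray | None,
    names: list[str],
    alts: list[str],
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Newton–Raphson for the baseline-category logit on raw arrays.

    ``Y`` holds one indicator column per non-reference category ``alts``.
    """
    n, p = X.shape
    K = Y.shape[1]
    theta = np.zeros(K * p) if start is None else np.asarray(start, dtype=float).copy()

    def unpack(t):
        return t.reshape(K, p)

    def lse_rows(eta: np.ndarray) -> np.ndarray:
        # log(1 + sum_k exp(eta_k)) row-wise, via chained logaddexp
        out = np.logaddexp(0.0, eta[:, 0])
        for k in range(1, eta.shape[1]):
            out = np.logaddexp(out, eta[:, k])
        return out

    def loglik(t) -> float:
        eta = X @ unpack(t).T  # n x K
        return float((Y * eta).sum() - lse_rows(eta).sum())

    ll = loglik(theta)
    n_iter = 0
    for n_iter in range(1, _MAX_ITER + 1):
        eta = X @ unpack(theta).T
        P = np.exp(eta - lse_rows(eta)[:, None])  # n x K, non-reference probs
        grad = np.concatenate([X.T @ (Y[:, k] - P[:, k]) for k in range(K)])
        H = np.empty((K * p, K * p))
        for j in range(K):
            for k in range(K):
                w = P[:, j] * ((1.0 if j == k else 0.0) - P[:, k])
                H[j * p:(j + 1) * p, k * p:(k + 1) * p] = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise RankDeficiencyError(f"singular Hessian: {exc}") from exc
        scale = 1.0
        for _ in range(40):
            cand = theta + scale * step
            ll_c = loglik(cand)
            if ll_c >= ll - 1e-14:
                break
            scale *= 0.5
        theta = cand
        if np.max(np.abs(theta)) > 40.0:
            idx = int(np.argmax(np.abs(theta)))
            term = f"{alts[idx // p]}:{names[idx % p]}"
            raise SeparationError(
                f"coefficient for {term!r} diverging: likely perfect separation",
                term=term,
            )
        if abs(ll_c - ll) <= _REL_TOL * (abs(ll) + 1e-12) and np.max(np.abs(grad)) < 1e-6:
            ll = ll_c
            break
        ll = ll_c
    vcov = np.linalg.inv(H)
    return theta, vcov, ll, n_iter


# ---------------------------------------------------------------------------
# Random-intercept logistic via adaptive Gauss–Hermite quadrature
# ---------------------------------------------------------------------------

def _cluster_index(data: pd.DataFrame, column: str) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(data[column], sort=True)
    if (codes < 0).any():
        raise InvalidArgumentError(f"missing values in cluster column {column!r}")
    return codes.astype(np.intp), len(uniques)


class _RILoglik:
    """Marginal log-likelihood of the random-intercept logistic model.

    For each cluster the integral over the Normal(0, σ²) intercept is
    approximated by adaptive Gauss–Hermite quadrature: nodes are
    recentred at the cluster's posterior mode and rescaled by the local
    curvature, then the standard Hermite rule is applied.
    """

    def __init__(self, X, y, groups, n_groups, n_points):
        self.X, self.y, self.g, self.G = X, y, groups, n_groups
        self.z, self.w = np.polynomial.hermite.hermgauss(n_points)
        self.logw = np.log(self.w)

    def plain(self, beta) -> float:
        return _logistic_loglik(self.X @ beta, self.y)

    def plain_grad(self, beta) -> np.ndarray:
        mu = special.expit(self.X @ beta)
        return self.X.T @ (self.y - mu)

    def __call__(self, params) -> float:
        return self.value_and_grad(params)[0]

    def value_and_grad(self, params) -> tuple[float, np.ndarray]:
        """Marginal log-likelihood and its gradient over (β, σ).

        The gradient uses the Fisher identity — the posterior expectation
        of the complete-data score — evaluated on the same adaptive
        quadrature nodes as the value.
        """
        beta, sigma = params[:-1], params[-1]
        if sigma < 1e-8:
            val = self.plain(beta)
            mu = special.expit(self.X @ beta)
            grad = np.append(self.X.T @ (self.y - mu), 0.0)
            return val, grad
        s2 = sigma * sigma
        eta0 = self.X @ beta
        # posterior mode per cluster: Newton from 0 with clipped steps, so
        # the value is a deterministic, smooth function of the parameters
        u = np.zeros(self.G)
        for _ in range(200):
            eta = eta0 + u[self.g]
            mu = special.expit(eta)
            g1 = np.bincount(self.g, weights=self.y - mu, minlength=self.G) - u / s2
            g2 = -np.bincount(self.g, weights=mu * (1 - mu), minlength=self.G) - 1.0 / s2
            step = np.clip(g1 / g2, -1.0, 1.0)
            u = u - step
            if np.max(np.abs(step)) < 1e-12:
                break
        eta = eta0 + u[self.g]
        mu = special.expit(eta)
        h = np.bincount(self.g, weights=mu * (1 - mu), minlength=self.G) + 1.0 / s2
        tau = 1.0 / np.sqrt(h)

        # nodes: u_jk = u_j + sqrt(2) tau_j z_k
        nodes = u[:, None] + np.sqrt(2.0) * tau[:, None] * self.z[None, :]  # G x K
        K = len(self.z)
        log_f = np.empty((self.G, K))
        for k in range(K):
            eta_k = eta0 + nodes[self.g, k]
            row_ll = self.y * eta_k - np.logaddexp(0.0, eta_k)
            log_f[:, k] = np.bincount(self.g, weights=row_ll, minlength=self.G)
        log_phi = -0.5 * np.log(2.0 * np.pi * s2) - nodes**2 / (2.0 * s2)
        log_terms = (
            self.logw[None, :]
            + self.z[None, :] ** 2
            + 0.5 * np.log(2.0) + np.log(tau)[:, None]
            + log_f + log_phi
        )
        per_cluster = special.logsumexp(log_terms, axis=1)
        value = float(per_cluster.sum())

        # posterior node weights p_jk, then the expected score
        post = np.exp(log_terms - per_cluster[:, None])  # G x K
        grad_beta = np.zeros(len(beta))
        for k in range(K):
            eta_k = eta0 + nodes[self.g, k]
            resid = self.y - special.expit(eta_k)
            grad_beta += self.X.T @ (resid * post[self.g, k])
        grad_sigma = float(
            (post * (nodes**2 / (sigma * s2) - 1.0 / sigma)).sum()
        )
        return value, np.append(grad_beta, grad_sigma)


def _ri_ml_arrays(ll_fn: _RILoglik, beta0: np.ndarray, sigma0: float = 0.15):
    """Maximize the marginal likelihood over (β, σ); σ bounded at zero."""
    p = len(beta0)

    def nll(params):
        v, g = ll_fn.value_and_grad(params)
        return -v, -g

    x0 = np.append(beta0, sigma0)
    bounds = [(None, None)] * p + [(0.0, 50.0)]
    return optimize.minimize(
        nll, x0, method="L-BFGS-B", jac=True, bounds=bounds,
        options={"maxiter": 1000, "ftol": 1e-13, "gtol": 1e-8},
    )


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian (objective is smooth and cheap)."""
    p = len(x)
    H = np.empty((p, p))
    h = eps * np.maximum(1.0, np.abs(x))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def fit_logistic_ri(
    data: pd.DataFrame,
    spec: ModelSpec,
    quadrature_points: int | None = None,
    start: np.ndarray | None = None,
    fix_sigma2: float | None = None,
) -> FitResult:
    """Random-intercept logistic regression by maximum likelihood.

    The cluster intercept is integrated out with adaptive Gauss–Hermite
    quadrature (default 7 points). Reports σ² and its standard error
    (delta method from the σ parameterization). ``fix_sigma2`` pins the
    variance (``fix_sigma2=0`` reduces to plain logistic, a nested-model
    identity used in tests).
    """
    spec.validate()
    if spec.cluster is None:
        raise InvalidArgumentError("spec.cluster must be set for fit_logistic_ri")
    nq = quadrature_points if quadrature_points is not None else spec.quadrature_points
    if nq < 1:
        raise InvalidArgumentError("quadrature_points must be >= 1")
    X, names = build_design(data, spec.predictors, spec.references)
    y = _binary_response(data, spec.response)
    _check_rank(X, names)
    groups, G = _cluster_index(data, spec.cluster)
    if G < 2 and fix_sigma2 is None:
        raise VarianceUnidentifiedError(
            "at least 2 clusters are required to estimate the variance component"
        )
    n, p = X.shape
    ll_fn = _RILoglik(X, y, groups, G, nq)

    # warm start from the plain logistic fit
    if start is not None:
        beta0 = np.asarray(start[:p], dtype=float)
        sigma0 = float(start[p]) if len(start) > p else 0.15
    else:
        beta0, _, _, _ = _newton_logistic(X, y, None, names)
        sigma0 = 0.15

    if fix_sigma2 is not None:
        if fix_sigma2 < 0:
            raise InvalidArgumentError("fix_sigma2 must be >= 0")
        sig = float(np.sqrt(fix_sigma2))

        def nll_b(beta):
            return -ll_fn(np.append(beta, sig))

        def nll_b_grad(beta):
            v, g = ll_fn.value_and_grad(np.append(beta, sig))
            return -v, -g[:-1]

        res = optimize.minimize(
            nll_b_grad, beta0, method="L-BFGS-B", jac=True,
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-8},
        )
        beta = res.x
        ll = -res.fun
        H = _numeric_hessian(nll_b, beta)
        vcov = np.linalg.inv(H)
        return _pack_result(
            beta, vcov, ll, names, n, int(res.nit), extra_params=0,
            sigma2=fix_sigma2, sigma2_se=None, converged=bool(res.success),
        )

    res = _ri_ml_arrays(ll_fn, beta0, sigma0)
    params = res.x
    beta, sigma = params[:p], params[p]
    ll = -res.fun

    at_boundary = sigma < 1e-6
    if at_boundary:
        # variance at the boundary: report sigma^2 = 0, fixed-effect vcov
        def nll_b(b):
            return -ll_fn.plain(b)

        H = _numeric_hessian(nll_b, beta)
        vcov = np.linalg.inv(H)
        sigma2, sigma2_se = 0.0, float("nan")
    else:
        H = _numeric_hessian(lambda x: -ll_fn(x), params)
        vcov_full = np.linalg.inv(H)
        vcov = vcov_full[:p, :p]
        sigma2 = float(sigma**2)
        var_sigma = float(vcov_full[p, p])
        sigma2_se = float(2.0 * sigma * np.sqrt(max(var_sigma, 0.0)))
    return _pack_result(
        beta, vcov, ll, names, n, int(res.nit), extra_params=1,
        sigma2=sigma2, sigma2_se=sigma2_se, converged=bool(res.success),
    )
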