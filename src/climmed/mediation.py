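"""Parallel multiple-mediation model: assembly, decomposition, bootstrap.

The path model has one exposure X (province mean 2 m air temperature),
two parallel mediators — fruit/vegetable adequacy M1 (binary) and
physical-activity level M2 (low/moderate/high, giving two pathways M21
and M22 versus the low reference) — and a binary outcome Y (overweight
or obesity) with a province random intercept:

* M1 equation (logit):        a1 · X  (+ covariates)
* M2 equation (mlogit vs low): a21, a22 · X  (+ covariates)
* Y equation (logit, province random intercept):
  c · X + b1 · M1 + b21 · M2=moderate + b22 · M2=high + covariates

Specific indirect effects are products of log-odds coefficients
(a1·b1, a21·b21, a22·b22); per-path total effects add the direct effect
c; mediator importance is compared by the raw difference between two
indirect effects, with a percentile bootstrap CI obtained by resampling
rows with replacement and refitting all three equations per replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimation as est
from .estimation import FitResult, ModelSpec, build_design
from .exceptions import (
    BootstrapError,
    EstimationError,
    InvalidArgumentError,
)

__all__ = [
    "PathCoefficients",
    "EffectDecomposition",
    "BootstrapResult",
    "assemble_path_model",
    "decompose_effects",
    "raw_difference",
    "bootstrap_effects",
    "zero_excluded",
    "ESTIMANDS",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("sex", "age", "education")

#: mediation pathway labels: M1 fruit/vegetable adequacy, M21 moderate
#: physical activity, M22 high physical activity
PATHS = ("M1", "M21", "M22")

ESTIMANDS = (
    "direct",
    "indirect_M1",
    "indirect_M21",
    "indirect_M22",
    "total_M1",
    "total_M21",
    "total_M22",
    "rawdiff_M1_M21",
    "rawdiff_M1_M22",
)


@dataclass
class PathCoefficients:
    """Structural coefficients of the fitted path model (log-odds scale)."""

    a1: float  # X -> M1
    a21: float  # X -> M2 moderate
    a22: float  # X -> M2 high
    b1: float  # M1 -> Y
    b21: float  # M2 moderate -> Y
    b22: float  # M2 high -> Y
    c: float  # X -> Y direct
    sigma2: float  # province random-intercept variance
    covariates: dict[str, dict[str, float]] = field(default_factory=dict)
    fits: dict[str, FitResult] | None = None

    def validate(self) -> None:
        for name in ("a1", "a21", "a22", "b1", "b21", "b22", "c"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidArgumentError(f"{name} must be finite")
        if self.sigma2 < 0:
            raise InvalidArgumentError("sigma2 must be >= 0")


@dataclass
class EffectDecomposition:
    """Direct, path-specific indirect, per-path total effects, and raw
    differences between indirect effects; all exact coefficient algebra."""

    direct: float
    indirect: dict[str, float]
    total: dict[str, float]
    raw_diff: dict[tuple[str, str], float]

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        rows = [("direct", self.direct)]
        rows += [(f"indirect_{p}", v) for p, v in self.indirect.items()]
        rows += [(f"total_{p}", v) for p, v in self.total.items()]
        rows += [(f"rawdiff_{p}_{q}", v) for (p, q), v in self.raw_diff.items()]
        out = pd.DataFrame(rows, columns=["estimand", "value"])
        if decimals is not None:
            out["value"] = out["value"].round(decimals)
        return out


@dataclass
class BootstrapResult:
    """Percentile-bootstrap summary for one estimand.

    CI endpoints are order statistics of the replicate vector (2.5th
    percentile by the "lower", 97.5th by the "higher" empirical rule).
    """

    estimand: str
    point_estimate: float
    replicates: np.ndarray
    ci_low: float
    ci_high: float
    boot_se: float
    n_reps: int
    resample_size: int
    seed: int
    n_failed_replicates: int


def decompose_effects(path: PathCoefficients) -> EffectDecomposition:
    """Exact product/sum decomposition of the path coefficients."""
    path.validate()
    indirect = {
        "M1": path.a1 * path.b1,
        "M21": path.a21 * path.b21,
        "M22": path.a22 * path.b22,
    }
    total = {p: path.c + indirect[p] for p in PATHS}
    raw_diff = {
        ("M1", "M21"): indirect["M1"] - indirect["M21"],
        ("M1", "M22"): indirect["M1"] - indirect["M22"],
    }
    return EffectDecomposition(
        direct=path.c, indirect=indirect, total=total, raw_diff=raw_diff
    )


def raw_difference(
    decomp: EffectDecomposition, path_a: str, path_b: str, mode: str = "signed"
) -> float:
    """Contrast of two specific indirect effects, indirect[a] − indirect[b]."""
    if mode not in ("signed", "absolute"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    for p in (path_a, path_b):
        if p not in decomp.indirect:
            raise InvalidArgumentError(f"unknown path label {p!r}")
    diff = decomp.indirect[path_a] - decomp.indirect[path_b]
    return abs(diff) if mode == "absolute" else diff


def zero_excluded(result: BootstrapResult) -> bool:
    """True iff the (closed) CI excludes zero: 0 < low or 0 > high."""
    return result.ci_low > 0.0 or result.ci_high < 0.0


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

def filter_analysis_set(data: pd.DataFrame) -> pd.DataFrame:
    """Listwise deletion of rows with missing fruit/vegetable status."""
    return data.dropna(subset=["fv_adequate"]).reset_index(drop=True)


class _PathDesign:
    """Design matrices for the three equations, built once and row-indexed
    per bootstrap replicate (avoids per-replicate categorical encoding)."""

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        covariates: tuple[str, ...],
        covariates_in_mediators: bool,
    ):
        if outcome not in ("overweight", "obesity"):
            raise InvalidArgumentError(f"outcome must be overweight|obesity, got {outcome!r}")
        df = filter_analysis_set(data)
        if df.empty:
            raise InvalidArgumentError("no complete rows after mediator filtering")
        self.df = df
        med_predictors = ["mean_temp_c"] + (list(covariates) if covariates_in_mediators else [])
        self.Xm, self.m_names = build_design(df, med_predictors)
        self.Xy, self.y_names = build_design(
            df, ["mean_temp_c", "fv_adequate", "pa_level"] + list(covariates)
        )
        self.y_m1 = (df["fv_adequate"] == "yes").to_numpy(dtype=float)
        self.Y_m2 = np.column_stack(
            [
                (df["pa_level"] == "moderate").to_numpy(dtype=float),
                (df["pa_level"] == "high").to_numpy(dtype=float),
            ]
        )
        self.y_out = (df[outcome] == "yes").to_numpy(dtype=float)
        codes, uniques = pd.factorize(df["province_id"], sort=True)
        self.groups = codes.astype(np.intp)
        self.n_groups = len(uniques)
        self.n = len(df)

    def fit(
        self, idx: np.ndarray | None, quadrature_points: int, starts=None
    ) -> tuple[float, float, float, float, float, float, float, float, tuple]:
        """Fit all three equations on rows ``idx`` (None = all rows).

        Returns the seven path coefficients, sigma2, and the raw parameter
        vectors (reusable as warm starts). ``quadrature_points=0`` fits the
        outcome equation without the random intercept (plain logistic).
        """
        if idx is None:
            Xm, Xy = self.Xm, self.Xy
            y1, Y2, yo, g = self.y_m1, self.Y_m2, self.y_out, self.groups
        else:
            Xm, Xy = self.Xm[idx], self.Xy[idx]
            y1, Y2, yo, g = (
                self.y_m1[idx], self.Y_m2[idx], self.y_out[idx], self.groups[idx],
            )
        s1, s2, s3 = starts if starts is not None else (None, None, None)
        beta1, _, _, _ = est._newton_logistic(Xm, y1, s1, self.m_names)
        theta2, _, _, _ = est._newton_multinomial(
            Xm, Y2, s2, self.m_names, ["moderate", "high"]
        )
        p = Xm.shape[1]
        i_temp_m = self.m_names.index("mean_temp_c")
        a1 = float(beta1[i_temp_m])
        a21 = float(theta2[i_temp_m])
        a22 = float(theta2[p + i_temp_m])

        if quadrature_points >= 1:
            ll_fn = est._RILoglik(Xy, yo, g, self.n_groups, quadrature_points)
            if s3 is not None:
                beta0, sigma0 = s3[:-1], max(float(s3[-1]), 1e-3)
            else:
                beta0, _, _, _ = est._newton_logistic(Xy, yo, None, self.y_names)
                sigma0 = 0.15
            res = est._ri_ml_arrays(ll_fn, beta0, sigma0)
            if not res.success:
                raise EstimationError(f"outcome equation did not converge: {res.message}")
            betay, sigma = res.x[:-1], float(res.x[-1])
            sigma2 = sigma * sigma
            y_params = res.x
        else:
            betay, _, _, _ = est._newton_logistic(Xy, yo, s3, self.y_names)
            sigma2 = 0.0
            y_params = betay
        c = float(betay[self.y_names.index("mean_temp_c")])
        b1 = float(betay[self.y_names.index("fv_adequate[yes]")])
        b21 = float(betay[self.y_names.index("pa_level[moderate]")])
        b22 = float(betay[self.y_names.index("pa_level[high]")])
        return a1, a21, a22, b1, b21, b22, c, sigma2, (beta1, theta2, y_params)


def assemble_path_model(
    data: pd.DataFrame,
    outcome: str = "overweight",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    quadrature_points: int = 7,
    covariates_in_mediators: bool = True,
) -> PathCoefficients:
    """Fit the three structural equations and extract the path coefficients.

    Rows with missing fruit/vegetable status are dropped first. The
    outcome equation carries the province random intercept; mediator
    equations include the covariates by default (switchable).
    """
    df = filter_analysis_set(data)
    med_predictors = ["mean_temp_c"] + (list(covariates) if covariates_in_mediators else [])
    spec_m1 = ModelSpec("fv_adequate", "binary", med_predictors)
    spec_m2 = ModelSpec("pa_level", "multinomial3", med_predictors)
    spec_y = ModelSpec(
        "overweight" if outcome == "overweight" else "obesity",
        "binary",
        ["mean_temp_c", "fv_adequate", "pa_level"] + list(covariates),
        cluster="province_id",
        quadrature_points=quadrature_points,
    )
    fits: dict[str, FitResult] = {}
    try:
        fits["m1"] = est.fit_logistic(df, spec_m1)
    except EstimationError as exc:
        raise EstimationError(f"mediator equation M1 failed: {exc}") from exc
    try:
        fits["m2"] = est.fit_multinomial(df, spec_m2, reference="low")
    except EstimationError as exc:
        raise EstimationError(f"mediator equation M2 failed: {exc}") from exc
    try:
        fits["outcome"] = est.fit_logistic_ri(df, spec_y)
    except EstimationError as exc:
        raise EstimationError(f"outcome equation failed: {exc}") from exc

    co = fits["outcome"].coefficients
    cm1 = fits["m1"].coefficients
    cm2 = fits["m2"].coefficients
    path = PathCoefficients(
        a1=float(cm1["mean_temp_c"]),
        a21=float(cm2["moderate:mean_temp_c"]),
        a22=float(cm2["high:mean_temp_c"]),
        b1=float(co["fv_adequate[yes]"]),
        b21=float(co["pa_level[moderate]"]),
        b22=float(co["pa_level[high]"]),
        c=float(co["mean_temp_c"]),
        sigma2=float(fits["outcome"].variance_component or 0.0),
        covariates={
            "m1": {k: float(v) for k, v in cm1.items() if k != "mean_temp_c"},
            "m2": {k: float(v) for k, v in cm2.items()
                   if not k.endswith(":mean_temp_c")},
            "outcome": {
                k: float(v) for k, v in co.items()
                if k not in ("mean_temp_c", "fv_adequate[yes]",
                             "pa_level[moderate]", "pa_level[high]")
            },
        },
        fits=fits,
    )
    return path


# ---------------------------------------------------------------------------
# Percentile bootstrap
# ---------------------------------------------------------------------------

def _estimand_values(coefs: tuple) -> dict[str, float]:
    a1, a21, a22, b1, b21, b22, c = coefs
    ind = {"M1": a1 * b1, "M21": a21 * b21, "M22": a22 * b22}
    return {
        "direct": c,
        "indirect_M1": ind["M1"],
        "indirect_M21": ind["M21"],
        "indirect_M22": ind["M22"],
        "total_M1": c + ind["M1"],
        "total_M21": c + ind["M21"],
        "total_M22": c + ind["M22"],
        "rawdiff_M1_M21": ind["M1"] - ind["M21"],
        "rawdiff_M1_M22": ind["M1"] - ind["M22"],
    }


def bootstrap_effects(
    data: pd.DataFrame,
    outcome: str = "overweight",
    estimands: list[str] | None = None,
    n_reps: int = 5000,
    resample_size: int | None = 10000,
    seed: int = 0,
    quadrature_points: int = 7,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    covariates_in_mediators: bool = True,
    strict: bool = False,
) -> dict[str, BootstrapResult]:
    """Percentile bootstrap of direct, indirect, total and raw-difference
    effects: each replicate resamples ``resample_size`` rows with
    replacement from the analysis set and refits all three equations.

    ``quadrature_points=0`` drops the random intercept from replicate
    outcome fits (documented speed option for large simulation studies).
    Replicates whose fits fail are dropped and counted; in ``strict``
    mode more than 1% failures raises :class:`BootstrapError`.
    """
    if n_reps < 2:
        raise InvalidArgumentError("n_reps must be >= 2")
    estimands = list(ESTIMANDS) if estimands is None else list(estimands)
    unknown = set(estimands) - set(ESTIMANDS)
    if unknown:
        raise InvalidArgumentError(f"unknown estimands: {sorted(unknown)}")

    design = _PathDesign(data, outcome, tuple(covariates), covariates_in_mediators)
    if resample_size is None:
        resample_size = design.n  # classical n-out-of-n bootstrap
    if resample_size > design.n:
        raise InvalidArgumentError(
            f"resample_size {resample_size} exceeds {design.n} available rows"
        )
    full = design.fit(None, quadrature_points)
    point = _estimand_values(full[:7])
    starts = full[8]

    rng = np.random.default_rng(seed)
    draws = {k: [] for k in estimands}
    n_failed = 0
    for _ in range(n_reps):
        idx = rng.integers(0, design.n, resample_size)
        try:
            rep = design.fit(idx, quadrature_points, starts=starts)
        except (EstimationError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        values = _estimand_values(rep[:7])
        for k in estimands:
            draws[k].append(values[k])

    if n_failed > 0.01 * n_reps:
        msg = f"{n_failed}/{n_reps} bootstrap replicates failed"
        if strict:
            raise BootstrapError(msg)
        import warnings

        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    out: dict[str, BootstrapResult] = {}
    for k in estimands:
        reps = np.asarray(draws[k])
        lo = float(np.quantile(reps, 0.025, method="lower"))
        hi = float(np.quantile(reps, 0.975, method="higher"))
        out[k] = BootstrapResult(
            estimand=k,
            point_estimate=point[k],
            replicates=reps,
            ci_low=lo,
            ci_high=hi,
            boot_se=float(np.std(reps, ddof=1)),
            n_reps=n_reps,
            resample_size=resample_size,
            seed=seed,
            n_failed_replicates=n_failed,
        )
    return out


def replicates_frame(results: dict[str, BootstrapResult]) -> pd.DataFrame:
    """Replicate draws, one column per estimand (histogram export)."""
    return pd.DataFrame({k: r.replicates for k, r in results.items()})


def effects_frame(results: dict[str, BootstrapResult]) -> pd.DataFrame:
    """Effects table: estimand, point value, bootstrap SE, percentile CI."""
    rows = [
        {
            "estimand": k,
            "value": r.point_estimate,
            "boot_se": r.boot_se,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "zero_excluded": zero_excluded(r),
        }
        for k, r in results.items()
    ]
    return pd.DataFrame(rows)
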