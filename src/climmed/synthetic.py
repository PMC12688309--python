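"""Synthetic cohort generator for the temperature–overweight mediation study.

Emulates the structure of the 2018 Argentine National Risk Factors Survey
(ENFR) anthropometric subsample: 24 provinces whose annual mean 2 m air
temperature spans roughly 4.6–23 °C, individual covariates (sex, age,
education), two mediators — fruit/vegetable adequacy (≥ 5 servings/day,
binary, M1) and IPAQ physical-activity level (low/moderate/high, M2) —
and binary nutritional-status outcomes (overweight BMI ≥ 25, obesity
BMI ≥ 30). Mediators and outcomes are drawn from logistic / multinomial
structural equations; a province-level Normal(0, σ²) random intercept
enters the outcome equations (σ² = 0.026 by default), capturing
unobserved provincial context.

Structural slopes default to the fitted path coefficients of the
parallel multiple-mediation model this package reproduces (e.g. the
temperature effect on high physical activity a22 = −0.059 log-odds/°C).
Intercepts are not part of that model's published output; they are
root-found so that the implied marginal prevalences match the published
sample margins (overweight 67.9 %, activity split 47/36/18 %,
fruit/vegetable adequacy ≈ 6 %) — see :func:`calibrate_intercepts` and
:func:`default_config`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .exceptions import CalibrationError, InvalidArgumentError
from .schema import CATEGORY_LEVELS, COVARIATE_KEYS

__all__ = [
    "GeneratorConfig",
    "make_province_table",
    "simulate_cohort",
    "marginal_prevalence",
    "calibrate_intercepts",
    "default_config",
    "DEFAULT_PREVALENCE_TARGETS",
]

_EDU_LEVELS = CATEGORY_LEVELS["education"]
_PA_LEVELS = CATEGORY_LEVELS["pa_level"]

#: Published sample margins used to calibrate the default intercepts:
#: physical activity low/moderate/high 47/36/18 %, overweight 67.9 %,
#: fruit/vegetable adequacy ~6 %, measured obesity prevalence 32.4 %.
DEFAULT_PREVALENCE_TARGETS = {
    "m1": 0.06,
    "pa_moderate": 0.36,
    "pa_high": 0.18,
    "overweight": 0.679,
    "obesity": 0.324,
}

# Survey margins (n = 16,410): female 9,450; education counts by level
# university 2,845 / incomplete primary 1,647 / incomplete secondary
# 5,906 / complete secondary 6,012; 455 missing fruit/vegetable answers.
_N_SURVEY = 16410.0
_DEFAULT_EDU_PROBS = (2845 / _N_SURVEY, 1647 / _N_SURVEY, 5906 / _N_SURVEY, 6012 / _N_SURVEY)

# Outcome-equation covariate effects (log-odds): female, age per year,
# education vs university.
_DEFAULT_Y_COVARIATES = {
    "sex[female]": -0.365,
    "age": 0.029,
    "education[incomplete_primary]": 0.269,
    "education[incomplete_secondary]": 0.317,
    "education[complete_secondary]": 0.208,
}


def _zero_covariates() -> dict[str, float]:
    return {k: 0.0 for k in COVARIATE_KEYS}


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort generator.

    All structural coefficients are on the log-odds scale. Multinomial
    physical-activity coefficients are contrasts versus the low level.
    """

    n_individuals: int = 16410
    n_provinces: int = 24
    temp_min: float = 4.6
    temp_max: float = 23.0
    temp_mode: str = "equispaced"  # or "uniform_random"
    sex_female_prob: float = 9450 / _N_SURVEY
    age_mean: float = 46.1
    age_sd: float = 17.9
    age_min: float = 18.0
    age_max: float = 95.0
    #: probabilities per education level in schema order
    #: (university, incomplete_primary, incomplete_secondary, complete_secondary)
    education_probs: tuple[float, float, float, float] = _DEFAULT_EDU_PROBS

    # M1: fruit/vegetable adequacy (binary logit)
    m1_intercept: float = 0.0
    m1_temp: float = 0.020  # a1
    m1_covariate_effects: dict[str, float] = field(default_factory=_zero_covariates)

    # M2: physical-activity level (multinomial logit vs low)
    m2_intercept_moderate: float = 0.0
    m2_intercept_high: float = 0.0
    m2_temp_moderate: float = -0.015  # a21
    m2_temp_high: float = -0.059  # a22
    m2_covariate_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"moderate": _zero_covariates(), "high": _zero_covariates()}
    )

    # Y: overweight (binary logit, province random intercept)
    y_intercept: float = 0.0
    y_temp: float = -0.019  # c
    y_m1: float = 0.025  # b1
    y_m2_moderate: float = -0.168  # b21
    y_m2_high: float = -0.362  # b22
    y_covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_Y_COVARIATES)
    )

    # Secondary outcome: obesity (same structure, own coefficients)
    obesity_intercept: float = 0.0
    obesity_temp: float = -0.021
    obesity_m1: float = 0.018
    obesity_m2_moderate: float = -0.234
    obesity_m2_high: float = -0.413
    obesity_covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_Y_COVARIATES)
    )

    province_variance: float = 0.026  # sigma^2 of the random intercept
    ri_in_mediators: bool = False  # sensitivity switch, default off
    missing_m1_prob: float = 455 / _N_SURVEY
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise InvalidArgumentError("n_individuals must be >= 1")
        if self.n_provinces < 1:
            raise InvalidArgumentError("n_provinces must be >= 1")
        if self.temp_mode not in ("equispaced", "uniform_random"):
            raise InvalidArgumentError(f"temp_mode unknown: {self.temp_mode!r}")
        if not (self.temp_min <= self.temp_max):
            raise InvalidArgumentError("temp_min must be <= temp_max")
        if not (self.age_min < self.age_max):
            raise InvalidArgumentError("age_min must be < age_max")
        if self.age_sd <= 0:
            raise InvalidArgumentError("age_sd must be > 0")
        for name in ("sex_female_prob", "missing_m1_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise InvalidArgumentError(f"{name} must be in [0, 1]")
        probs = np.asarray(self.education_probs, dtype=float)
        if probs.shape != (4,) or np.any(probs < 0):
            raise InvalidArgumentError("education_probs must be 4 non-negative values")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise InvalidArgumentError("education_probs must sum to 1 (tolerance 1e-12)")
        if self.province_variance < 0:
            raise InvalidArgumentError("province_variance must be >= 0")
        for name in (
            "m1_intercept", "m1_temp", "m2_intercept_moderate", "m2_intercept_high",
            "m2_temp_moderate", "m2_temp_high", "y_intercept", "y_temp", "y_m1",
            "y_m2_moderate", "y_m2_high", "obesity_intercept", "obesity_temp",
            "obesity_m1", "obesity_m2_moderate", "obesity_m2_high",
        ):
            if not math.isfinite(getattr(self, name)):
                raise InvalidArgumentError(f"{name} must be finite")


def make_province_table(
    n_provinces: int,
    temp_min: float,
    temp_max: float,
    mode: str = "equispaced",
    seed: int = 0,
) -> pd.DataFrame:
    """Build the province-level exposure table.

    ``equispaced`` yields a deterministic even grid including both
    endpoints (a single province sits at the midpoint of the range);
    ``uniform_random`` draws temperatures i.i.d. uniform on the range.
    """
    if n_provinces < 1:
        raise InvalidArgumentError("n_provinces must be >= 1")
    if not (temp_min <= temp_max):
        raise InvalidArgumentError("temp_min must be <= temp_max")
    if mode == "equispaced":
        if n_provinces == 1:
            temps = np.array([(temp_min + temp_max) / 2.0])
        else:
            temps = np.linspace(temp_min, temp_max, n_provinces)
    elif mode == "uniform_random":
        rng = np.random.default_rng(seed)
        temps = rng.uniform(temp_min, temp_max, n_provinces)
    else:
        raise InvalidArgumentError(f"mode unknown: {mode!r}")
    return pd.DataFrame(
        {"province_id": np.arange(1, n_provinces + 1), "mean_temp_c": temps}
    )


# Named sub-streams in fixed order: adding a stage never perturbs the
# draws of earlier stages for the same top-level seed.
_STREAMS = (
    "province_temps", "province_assign", "sex", "age", "education",
    "province_intercepts", "m1", "m2", "overweight", "obesity", "missing",
)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


def _province_table_for(config: GeneratorConfig) -> pd.DataFrame:
    """Province table implied by a config (deterministic given config).

    Uses the same sub-stream as :func:`simulate_cohort`, so the oracle in
    :func:`marginal_prevalence` sees exactly the provinces the cohort gets.
    """
    if config.temp_mode == "uniform_random":
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
        temps = rng.uniform(config.temp_min, config.temp_max, config.n_provinces)
        return pd.DataFrame(
            {"province_id": np.arange(1, config.n_provinces + 1), "mean_temp_c": temps}
        )
    return make_province_table(
        config.n_provinces, config.temp_min, config.temp_max, "equispaced"
    )


def _covariate_design(
    female: np.ndarray, age: np.ndarray, edu_idx: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-row values of the canonical covariate terms."""
    return {
        "sex[female]": female.astype(float),
        "age": age,
        "education[incomplete_primary]": (edu_idx == 1).astype(float),
        "education[incomplete_secondary]": (edu_idx == 2).astype(float),
        "education[complete_secondary]": (edu_idx == 3).astype(float),
    }


def _lp(intercept: float, temp_coef: float, temp: np.ndarray,
        covariate_effects: dict[str, float], design: dict[str, np.ndarray]) -> np.ndarray:
    lp = intercept + temp_coef * temp
    for key, value in covariate_effects.items():
        if key not in design:
            raise InvalidArgumentError(f"unknown covariate-effect key: {key!r}")
        if value != 0.0:
            lp = lp + value * design[key]
    return lp


def simulate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a full synthetic cohort; bit-reproducible given ``config.seed``.

    Returns ``(province_table, cohort_table)``. The outcome equations share
    one province random-intercept draw; mediator equations include it only
    when ``ri_in_mediators`` is set.
    """
    config.validate()
    n = config.n_individuals
    rngs = _rngs(config.seed)

    if config.temp_mode == "uniform_random":
        temps_p = rngs["province_temps"].uniform(
            config.temp_min, config.temp_max, config.n_provinces
        )
        provinces = pd.DataFrame(
            {"province_id": np.arange(1, config.n_provinces + 1), "mean_temp_c": temps_p}
        )
    else:
        provinces = make_province_table(
            config.n_provinces, config.temp_min, config.temp_max, "equispaced"
        )
    temps_p = provinces["mean_temp_c"].to_numpy()

    g = rngs["province_assign"].integers(0, config.n_provinces, n)
    temp = temps_p[g]
    female = rngs["sex"].random(n) < config.sex_female_prob
    a, b = (
        (config.age_min - config.age_mean) / config.age_sd,
        (config.age_max - config.age_mean) / config.age_sd,
    )
    age = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n,
        random_state=rngs["age"],
    )
    edu_idx = rngs["education"].choice(
        4, size=n, p=np.asarray(config.education_probs, dtype=float)
    )
    design = _covariate_design(female, age, edu_idx)

    sigma = math.sqrt(config.province_variance)
    u = rngs["province_intercepts"].normal(0.0, sigma, config.n_provinces)
    u_row = u[g]
    u_med = u_row if config.ri_in_mediators else 0.0

    # M1: fruit/vegetable adequacy
    lp1 = _lp(config.m1_intercept, config.m1_temp, temp, config.m1_covariate_effects, design)
    m1 = rngs["m1"].random(n) < special.expit(lp1 + u_med)

    # M2: physical activity, multinomial logit vs low
    lp_mod = _lp(config.m2_intercept_moderate, config.m2_temp_moderate, temp,
                 config.m2_covariate_effects["moderate"], design) + u_med
    lp_high = _lp(config.m2_intercept_high, config.m2_temp_high, temp,
                  config.m2_covariate_effects["high"], design) + u_med
    eta = np.column_stack([np.zeros(n), lp_mod, lp_high])
    probs = special.softmax(eta, axis=1)
    cum = np.cumsum(probs, axis=1)
    draw = rngs["m2"].random(n)
    m2_idx = (draw[:, None] > cum).sum(axis=1)  # 0 low, 1 moderate, 2 high

    def outcome(prefix: str, rng: np.random.Generator) -> np.ndarray:
        lp = _lp(
            getattr(config, f"{prefix}_intercept"),
            getattr(config, f"{prefix}_temp"),
            temp,
            getattr(config, f"{prefix}_covariate_effects"),
            design,
        )
        lp = (
            lp
            + getattr(config, f"{prefix}_m1") * m1
            + getattr(config, f"{prefix}_m2_moderate") * (m2_idx == 1)
            + getattr(config, f"{prefix}_m2_high") * (m2_idx == 2)
            + u_row
        )
        return rng.random(n) < special.expit(lp)

    # "y_*" fields parameterize the overweight equation.
    y = outcome("y", rngs["overweight"])
    ob = outcome("obesity", rngs["obesity"])

    fv = pd.array(np.where(m1, "yes", "no"), dtype="object")
    miss = rngs["missing"].random(n) < config.missing_m1_prob
    fv[miss] = np.nan

    cohort = pd.DataFrame(
        {
            "province_id": provinces["province_id"].to_numpy()[g],
            "mean_temp_c": temp,
            "sex": np.where(female, "female", "male"),
            "age": age,
            "education": np.asarray(_EDU_LEVELS, dtype=object)[edu_idx],
            "fv_adequate": fv,
            "pa_level": np.asarray(_PA_LEVELS, dtype=object)[m2_idx],
            "overweight": np.where(y, "yes", "no"),
            "obesity": np.where(ob, "yes", "no"),
        }
    )
    return provinces, cohort


# ---------------------------------------------------------------------------
# Deterministic marginal-prevalence oracle and intercept calibration
# ---------------------------------------------------------------------------

_TARGETS = ("m1", "pa_moderate", "pa_high", "overweight", "obesity")
_N_AGE_NODES = 41
_N_GH_NODES = 31


class _MarginalGrid:
    """Covariate integration grid: provinces × sex × education × age nodes.

    Age is integrated by Gauss–Legendre quadrature against the truncated
    normal density; the discrete covariates and provinces are enumerated
    exactly. No sampling anywhere.
    """

    def __init__(self, config: GeneratorConfig):
        temps_p = _province_table_for(config)["mean_temp_c"].to_numpy()
        nodes, glw = np.polynomial.legendre.leggauss(_N_AGE_NODES)
        half = (config.age_max - config.age_min) / 2.0
        mid = (config.age_max + config.age_min) / 2.0
        ages = mid + half * nodes
        a, b = (
            (config.age_min - config.age_mean) / config.age_sd,
            (config.age_max - config.age_mean) / config.age_sd,
        )
        dens = stats.truncnorm.pdf(ages, a, b, loc=config.age_mean, scale=config.age_sd)
        age_w = glw * half * dens
        age_w = age_w / age_w.sum()

        sex_w = np.array([1.0 - config.sex_female_prob, config.sex_female_prob])
        edu_w = np.asarray(config.education_probs, dtype=float)
        prov_w = np.full(len(temps_p), 1.0 / len(temps_p))

        # flatten the product grid
        P, S, E, A = len(temps_p), 2, 4, _N_AGE_NODES
        pi, si, ei, ai = np.meshgrid(
            np.arange(P), np.arange(S), np.arange(E), np.arange(A), indexing="ij"
        )
        pi, si, ei, ai = (x.ravel() for x in (pi, si, ei, ai))
        self.temp = temps_p[pi]
        self.weight = prov_w[pi] * sex_w[si] * edu_w[ei] * age_w[ai]
        self.design = _covariate_design(si.astype(float), ages[ai], ei)


def _mediator_probs(config: GeneratorConfig, grid: _MarginalGrid):
    lp1 = _lp(config.m1_intercept, config.m1_temp, grid.temp,
              config.m1_covariate_effects, grid.design)
    lp_mod = _lp(config.m2_intercept_moderate, config.m2_temp_moderate, grid.temp,
                 config.m2_covariate_effects["moderate"], grid.design)
    lp_high = _lp(config.m2_intercept_high, config.m2_temp_high, grid.temp,
                  config.m2_covariate_effects["high"], grid.design)
    if config.ri_in_mediators and config.province_variance > 0:
        z, w = np.polynomial.hermite_e.hermegauss(_N_GH_NODES)
        w = w / w.sum()
        sd = math.sqrt(config.province_variance)
        p1 = special.expit(lp1[:, None] + sd * z[None, :]) @ w
        eta = np.stack(
            [np.zeros_like(lp_mod)[:, None] + 0.0 * z,
             lp_mod[:, None] + sd * z[None, :],
             lp_high[:, None] + sd * z[None, :]], axis=1
        )
        pm = special.softmax(eta, axis=1) @ w
        return p1, pm[:, 1], pm[:, 2]
    p1 = special.expit(lp1)
    eta = np.column_stack([np.zeros_like(lp_mod), lp_mod, lp_high])
    pm = special.softmax(eta, axis=1)
    return p1, pm[:, 1], pm[:, 2]


def _outcome_prevalence(config: GeneratorConfig, grid: _MarginalGrid, prefix: str) -> float:
    p1, p_mod, p_high = _mediator_probs(config, grid)
    p_low = 1.0 - p_mod - p_high
    lp0 = _lp(
        getattr(config, f"{prefix}_intercept"),
        getattr(config, f"{prefix}_temp"),
        grid.temp,
        getattr(config, f"{prefix}_covariate_effects"),
        grid.design,
    )
    b1 = getattr(config, f"{prefix}_m1")
    b_mod = getattr(config, f"{prefix}_m2_moderate")
    b_high = getattr(config, f"{prefix}_m2_high")

    # enumerate the 6 mediator combinations
    offsets = np.array([0.0, b_mod, b_high, b1, b1 + b_mod, b1 + b_high])
    mix = np.column_stack(
        [(1 - p1) * p_low, (1 - p1) * p_mod, (1 - p1) * p_high,
         p1 * p_low, p1 * p_mod, p1 * p_high]
    )
    eta = lp0[:, None] + offsets[None, :]
    if config.province_variance > 0:
        z, w = np.polynomial.hermite_e.hermegauss(_N_GH_NODES)
        w = w / w.sum()
        sd = math.sqrt(config.province_variance)
        p_y = np.tensordot(special.expit(eta[:, :, None] + sd * z[None, None, :]), w, axes=(2, 0))
    else:
        p_y = special.expit(eta)
    return float(grid.weight @ (mix * p_y).sum(axis=1))


def marginal_prevalence(config: GeneratorConfig, target: str) -> float:
    """Population prevalence implied by the config, by exact enumeration
    and quadrature over covariates, mediators and the random intercept."""
    config.validate()
    if target not in _TARGETS:
        raise InvalidArgumentError(
            f"unknown target {target!r}; expected one of {_TARGETS}"
        )
    grid = _MarginalGrid(config)
    if target in ("m1", "pa_moderate", "pa_high"):
        p1, p_mod, p_high = _mediator_probs(config, grid)
        vec = {"m1": p1, "pa_moderate": p_mod, "pa_high": p_high}[target]
        return float(grid.weight @ vec)
    prefix = "y" if target == "overweight" else "obesity"
    return float(_outcome_prevalence(config, grid, prefix))


def calibrate_intercepts(
    config: GeneratorConfig, targets: dict[str, float]
) -> GeneratorConfig:
    """Root-find intercepts so marginal prevalences match ``targets``.

    Mediator intercepts are solved first (the outcome margins depend on
    them), then each outcome intercept by bisection. Idempotent: feeding
    a calibrated config back returns intercepts unchanged to within the
    1e-6 prevalence tolerance.
    """
    config.validate()
    for key, t in targets.items():
        if key not in _TARGETS:
            raise InvalidArgumentError(f"unknown target {key!r}")
        if not (0.0 < t < 1.0):
            raise InvalidArgumentError(f"target {key!r} must be in (0, 1)")
    if ("pa_moderate" in targets) != ("pa_high" in targets):
        raise InvalidArgumentError(
            "physical-activity targets must be given as a pair (pa_moderate, pa_high)"
        )
    cfg = dataclasses.replace(config)
    grid = _MarginalGrid(cfg)

    if "m1" in targets:
        def f1(b0: float) -> float:
            c = replace(cfg, m1_intercept=b0)
            p1, _, _ = _mediator_probs(c, grid)
            return float(grid.weight @ p1) - targets["m1"]

        cfg = replace(cfg, m1_intercept=_brent(f1, "m1"))

    if "pa_moderate" in targets:
        t = np.array([targets["pa_moderate"], targets["pa_high"]])

        def f2(x: np.ndarray) -> np.ndarray:
            c = replace(cfg, m2_intercept_moderate=x[0], m2_intercept_high=x[1])
            _, p_mod, p_high = _mediator_probs(c, grid)
            return np.array(
                [float(grid.weight @ p_mod), float(grid.weight @ p_high)]
            ) - t

        x0 = special.logit(t)  # decent start for near-flat slope structure
        sol = optimize.root(f2, x0, method="hybr", tol=1e-12)
        if not sol.success or np.max(np.abs(sol.fun)) > 1e-8:
            raise CalibrationError(
                f"physical-activity calibration failed: {sol.message}"
            )
        cfg = replace(
            cfg, m2_intercept_moderate=float(sol.x[0]), m2_intercept_high=float(sol.x[1])
        )

    for key, prefix in (("overweight", "y"), ("obesity", "obesity")):
        if key not in targets:
            continue

        def fy(b0: float, _prefix=prefix, _t=targets[key]) -> float:
            c = replace(cfg, **{f"{_prefix}_intercept": b0})
            return _outcome_prevalence(c, grid, _prefix) - _t

        cfg = replace(cfg, **{f"{prefix}_intercept": _brent(fy, key)})
    return cfg


def _brent(f, label: str, lo: float = -40.0, hi: float = 40.0) -> float:
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise CalibrationError(f"cannot bracket a root for target {label!r}")
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


_DEFAULT_CACHE: dict[str, GeneratorConfig] = {}


def default_config(
    *,
    n_individuals: int = 16410,
    seed: int = 0,
    calibrate: bool = True,
    targets: dict[str, float] | None = None,
    **overrides,
) -> GeneratorConfig:
    """The documented default generator: published path coefficients with
    intercepts calibrated to the published sample margins.

    Calibration is deterministic; results are cached per structural
    configuration (``n_individuals``, ``seed`` and the missingness rate do
    not affect the marginal prevalences under the default equispaced
    temperature grid).
    """
    cfg = GeneratorConfig(n_individuals=n_individuals, seed=seed, **overrides)
    if not calibrate:
        return cfg
    targets = dict(DEFAULT_PREVALENCE_TARGETS if targets is None else targets)
    probe = dataclasses.replace(cfg, n_individuals=1, missing_m1_prob=0.0)
    if cfg.temp_mode == "equispaced":
        probe = dataclasses.replace(probe, seed=0)
    key = repr(probe) + repr(sorted(targets.items()))
    if key not in _DEFAULT_CACHE:
        _DEFAULT_CACHE[key] = calibrate_intercepts(probe, targets)
    cal = _DEFAULT_CACHE[key]
    return dataclasses.replace(
        cfg,
        m1_intercept=cal.m1_intercept,
        m2_intercept_moderate=cal.m2_intercept_moderate,
        m2_intercept_high=cal.m2_intercept_high,
        y_intercept=cal.y_intercept,
        obesity_intercept=cal.obesity_intercept,
    )
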