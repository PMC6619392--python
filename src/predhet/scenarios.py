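"""Scenario grid and Monte Carlo derivation -> validation experiments.

Each scenario draws a derivation sample and a validation sample (default
n = 2000 each) from the same population, applies possibly different
measurement models in the two settings, fits a logistic model on the
derivation measurements, transports it unchanged to the validation
measurements, and records discrimination, calibration and accuracy.

The full default grid comprises 432 scenarios: a full factorial over the
validation measurement factors psi_V in {0, 0.25}, theta_V in {0.5, 1, 2}
and noise SDs sigma_eps(V), sigma_eps(D) in {0.5, 1, 2} (54 cells) for the
single-predictor family; the same factorial for the two-predictor family
with both predictors measured heterogeneously and with only one predictor
measured heterogeneously, each crossed with predictor correlation
rho in {0, 0.5, 0.9} (162 cells each); and 54 differential-error scenarios
for the single-predictor family.

Noise factor values are standard deviations sigma_eps; they are squared
into the variances stored on :class:`~predhet.measurement.MeasurementSpec`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .dgm import (
    OutcomeModel,
    generate_exact_predictors,
    generate_outcomes,
    single_predictor_model,
    two_predictor_model,
)
from .measurement import MeasurementSpec, apply_measurement
from .modeling import fit_logistic, linear_predictor
from .performance import (
    brier_decomposition,
    calibration_in_the_large,
    concordance,
    recalibrate,
)  # noqa: F401  (recalibrate re-exported for interactive use)
from scipy.special import expit

__all__ = [
    "ScenarioSpec",
    "ScenarioSummary",
    "GridFactors",
    "DEFAULT_FACTORS",
    "DIFFERENTIAL_PRESETS",
    "build_grid",
    "homogeneous_scenario",
    "differential_preset",
    "run_replication",
    "run_scenario",
    "run_large_sample",
    "LARGE_SAMPLE_SETTINGS",
]


# ---------------------------------------------------------------------------
# scenario specification


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation grid."""

    scenario_id: str
    model: OutcomeModel
    derivation_specs: tuple[MeasurementSpec, ...]
    validation_specs: tuple[MeasurementSpec, ...]
    heterogeneous_mask: tuple[bool, ...]
    n_derivation: int = 2000
    n_validation: int = 2000
    n_replications: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.model.n_predictors
        if not (len(self.derivation_specs) == len(self.validation_specs) == p):
            raise ValueError("need one measurement spec per predictor and setting")
        if len(self.heterogeneous_mask) != p:
            raise ValueError("heterogeneous_mask must have one flag per predictor")
        for j, het in enumerate(self.heterogeneous_mask):
            if not het and self.validation_specs[j] != self.derivation_specs[j]:
                raise ValueError(
                    f"predictor {j} is marked consistent but has differing "
                    "derivation and validation specs"
                )


@dataclass
class ScenarioSummary:
    """Aggregated Monte Carlo performance for one scenario.

    The c-statistic, CITL and Brier score are summarised by their mean over
    replications, the calibration slope by its median; all carry
    across-replication SDs.
    """

    scenario_id: str
    params: dict = field(default_factory=dict)
    n_replications: int = 0
    n_excluded: int = 0
    c_derivation_mean: float = math.nan
    c_derivation_sd: float = math.nan
    c_validation_mean: float = math.nan
    c_validation_sd: float = math.nan
    slope_median: float = math.nan
    slope_sd: float = math.nan
    citl_mean: float = math.nan
    citl_sd: float = math.nan
    brier_derivation_mean: float = math.nan
    brier_derivation_sd: float = math.nan
    brier_validation_mean: float = math.nan
    brier_validation_sd: float = math.nan

    def to_row(self) -> dict:
        row = {"scenario_id": self.scenario_id, **self.params}
        for k, v in self.__dict__.items():
            if k not in ("scenario_id", "params"):
                row[k] = v
        return row


# ---------------------------------------------------------------------------
# grid construction


@dataclass(frozen=True)
class GridFactors:
    """Factor levels of the full-factorial grid (noise levels are SDs)."""

    psi_v: tuple[float, ...] = (0.0, 0.25)
    theta_v: tuple[float, ...] = (0.5, 1.0, 2.0)
    sigma_eps_v: tuple[float, ...] = (0.5, 1.0, 2.0)
    sigma_eps_d: tuple[float, ...] = (0.5, 1.0, 2.0)
    rho: tuple[float, ...] = (0.0, 0.5, 0.9)
    # case-specific noise SDs crossed in the differential family
    sigma_eps1_d: tuple[float, ...] = (0.5, 1.0, 2.0)
    sigma_eps1_v: tuple[float, ...] = (0.5, 1.0, 2.0)
    sigma_eps0: float = 1.0


DEFAULT_FACTORS = GridFactors()
FAMILIES = ("single", "two_both", "two_one", "differential")


def _dedup(values: Iterable[float]) -> tuple[float, ...]:
    out: list[float] = []
    for v in values:
        if v not in out:
            out.append(v)
    if len(out) != len(tuple(values)):
        warnings.warn("duplicate factor values removed", stacklevel=3)
    return tuple(out)


def build_grid(
    factors: GridFactors = DEFAULT_FACTORS,
    families: Sequence[str] = FAMILIES,
    n_derivation: int = 2000,
    n_validation: int = 2000,
    n_replications: int = 10_000,
    seed: int = 1,
) -> list[ScenarioSpec]:
    """Enumerate the scenario grid.

    Scenario seeds are spawned deterministically from ``seed`` so each
    scenario (and each replication within it) is reproducible in isolation.
    """
    for fam in families:
        if fam not in FAMILIES:
            raise ValueError(f"unknown scenario family: {fam!r}")
    psi_v = _dedup(factors.psi_v)
    theta_v = _dedup(factors.theta_v)
    sd_v = _dedup(factors.sigma_eps_v)
    sd_d = _dedup(factors.sigma_eps_d)
    rhos = _dedup(factors.rho)

    specs: list[ScenarioSpec] = []

    def nd(psi: float, theta: float, sd: float) -> MeasurementSpec:
        return MeasurementSpec.from_sd(psi, theta, sd)

    if "single" in families:
        model = single_predictor_model()
        for p_ in psi_v:
            for t_ in theta_v:
                for sv in sd_v:
                    for sd_ in sd_d:
                        specs.append(
                            ScenarioSpec(
                                scenario_id=f"single_psi{p_}_theta{t_}_sV{sv}_sD{sd_}",
                                model=model,
                                derivation_specs=(nd(0.0, 1.0, sd_),),
                                validation_specs=(nd(p_, t_, sv),),
                                heterogeneous_mask=(True,),
                            )
                        )

    for fam, mask in (("two_both", (True, True)), ("two_one", (True, False))):
        if fam not in families:
            continue
        for rho in rhos:
            model = two_predictor_model(rho)
            for p_ in psi_v:
                for t_ in theta_v:
                    for sv in sd_v:
                        for sd_ in sd_d:
                            der = (nd(0.0, 1.0, sd_), nd(0.0, 1.0, sd_))
                            val = tuple(
                                nd(p_, t_, sv) if het else der[j]
                                for j, het in enumerate(mask)
                            )
                            specs.append(
                                ScenarioSpec(
                                    scenario_id=(
                                        f"{fam}_rho{rho}_psi{p_}_theta{t_}_sV{sv}_sD{sd_}"
                                    ),
                                    model=model,
                                    derivation_specs=der,
                                    validation_specs=val,
                                    heterogeneous_mask=mask,
                                )
                            )

    if "differential" in families:
        model = single_predictor_model()
        s0 = factors.sigma_eps0
        for p_ in psi_v:
            for t_ in theta_v:
                for s1d in _dedup(factors.sigma_eps1_d):
                    for s1v in _dedup(factors.sigma_eps1_v):
                        der = MeasurementSpec(
                            0.0, 0.0, 1.0, 1.0, s0**2, s1d**2
                        )
                        val = MeasurementSpec(
                            p_, p_, t_, t_, s0**2, s1v**2
                        )
                        specs.append(
                            ScenarioSpec(
                                scenario_id=(
                                    f"diff_psi{p_}_theta{t_}_s1V{s1v}_s1D{s1d}"
                                ),
                                model=model,
                                derivation_specs=(der,),
                                validation_specs=(val,),
                                heterogeneous_mask=(True,),
                            )
                        )

    root = np.random.SeedSequence(seed)
    out = []
    for spec, child in zip(specs, root.spawn(len(specs))):
        out.append(
            replace(
                spec,
                n_derivation=n_derivation,
                n_validation=n_validation,
                n_replications=n_replications,
                seed=int(child.generate_state(1, dtype=np.uint32)[0] % (2**31)),
            )
        )
    return out


def homogeneous_scenario(
    sigma_eps: float = 1.0,
    n: int = 2000,
    n_replications: int = 10_000,
    seed: int = 1,
    psi_v: float = 0.0,
    theta_v: float = 1.0,
    sigma_eps_v: float | None = None,
) -> ScenarioSpec:
    """Single-predictor scenario with random error SD ``sigma_eps`` at
    derivation and (by default) the identical measurement at validation."""
    sv = sigma_eps if sigma_eps_v is None else sigma_eps_v
    der = MeasurementSpec.from_sd(0.0, 1.0, sigma_eps)
    val = MeasurementSpec.from_sd(psi_v, theta_v, sv)
    return ScenarioSpec(
        scenario_id=f"single_psi{psi_v}_theta{theta_v}_sV{sv}_sD{sigma_eps}",
        model=single_predictor_model(),
        derivation_specs=(der,),
        validation_specs=(val,),
        heterogeneous_mask=(True,),
        n_derivation=n,
        n_validation=n,
        n_replications=n_replications,
        seed=seed,
    )


# The four headline differential scenarios: case-specific noise SD
# sigma_eps1 in {0.5, 2.0} at one setting, everything else at the default
# nondifferential SD 1.0.
DIFFERENTIAL_PRESETS = {
    "derivation_cases_precise": ("derivation", 0.5),
    "derivation_cases_noisy": ("derivation", 2.0),
    "validation_cases_precise": ("validation", 0.5),
    "validation_cases_noisy": ("validation", 2.0),
}


def differential_preset(
    name: str, n: int = 2000, n_replications: int = 10_000, seed: int = 1
) -> ScenarioSpec:
    """Named differential-error preset (see :data:`DIFFERENTIAL_PRESETS`)."""
    if name not in DIFFERENTIAL_PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(DIFFERENTIAL_PRESETS)}"
        )
    where, s1 = DIFFERENTIAL_PRESETS[name]
    nd = MeasurementSpec.from_sd(0.0, 1.0, 1.0)
    diff = MeasurementSpec(0.0, 0.0, 1.0, 1.0, 1.0, s1**2)
    der, val = (diff, nd) if where == "derivation" else (nd, diff)
    return ScenarioSpec(
        scenario_id=f"diffpreset_{name}",
        model=single_predictor_model(),
        derivation_specs=(der,),
        validation_specs=(val,),
        heterogeneous_mask=(True,),
        n_derivation=n,
        n_validation=n,
        n_replications=n_replications,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Monte Carlo execution


def run_replication(spec: ScenarioSpec, rng: np.random.Generator) -> dict | None:
    """One derivation -> validation experiment.

    Returns a flat metrics record, or ``None`` when any required fit failed
    to converge (the replication is then excluded and counted upstream).
    """
    model = spec.model
    # derivation sample
    X_d = generate_exact_predictors(spec.n_derivation, model, rng)
    y_d = generate_outcomes(X_d, model, rng)
    W_d = apply_measurement(X_d, y_d, spec.derivation_specs, rng)
    fit_d = fit_logistic(y_d, W_d)
    if not fit_d.converged:
        return None
    lp_d = linear_predictor(fit_d, W_d)
    p_d = expit(lp_d)
    parts_d = brier_decomposition(y_d, p_d)

    # validation sample from the identical population
    X_v = generate_exact_predictors(spec.n_validation, model, rng)
    y_v = generate_outcomes(X_v, model, rng)
    W_v = apply_measurement(X_v, y_v, spec.validation_specs, rng)
    lp_t = linear_predictor(fit_d, W_v)  # transported linear predictor
    p_t = expit(lp_t)

    recal_fit = fit_logistic(y_v, lp_t)
    if not recal_fit.converged:
        return None
    parts_v = brier_decomposition(y_v, p_t)
    return {
        "c_derivation": concordance(y_d, lp_d),
        "brier_derivation": parts_d.total,
        "c_validation": concordance(y_v, lp_t),
        "slope": float(recal_fit.coef_hat[0]),
        "recal_intercept": recal_fit.intercept_hat,
        "citl": calibration_in_the_large(y_v, lp_t),
        "brier_validation": parts_v.total,
        "brier_validation_calibration": parts_v.calibration_term,
        "brier_validation_refinement": parts_v.refinement_term,
    }


def _spec_params(spec: ScenarioSpec) -> dict:
    d0, v0 = spec.derivation_specs[0], spec.validation_specs[0]
    return {
        "family": spec.scenario_id.split("_")[0],
        "n_predictors": spec.model.n_predictors,
        "rho": spec.model.predictor_correlation,
        "psi_v": v0.psi0,
        "theta_v": v0.theta0,
        "err_var_d0": d0.err_var0,
        "err_var_d1": d0.err_var1,
        "err_var_v0": v0.err_var0,
        "err_var_v1": v0.err_var1,
        "n_derivation": spec.n_derivation,
        "n_validation": spec.n_validation,
        "seed": spec.seed,
    }


def run_scenario(
    spec: ScenarioSpec,
    n_replications: int | None = None,
    return_replications: bool = False,
):
    """Run all replications of a scenario and aggregate.

    Per-replication random streams are spawned deterministically from
    ``spec.seed``, so summaries are bit-for-bit reproducible and invariant
    to execution order.
    """
    reps = spec.n_replications if n_replications is None else n_replications
    if reps < 2:
        raise ValueError("need at least 2 replications")
    children = np.random.SeedSequence(spec.seed).spawn(reps)
    records: list[dict] = []
    excluded = 0
    for child in children:
        rec = run_replication(spec, np.random.default_rng(child))
        if rec is None:
            excluded += 1
        else:
            records.append(rec)
    if not records:
        raise RuntimeError(f"all replications excluded in {spec.scenario_id}")

    arr = {k: np.array([r[k] for r in records]) for k in records[0]}
    summary = ScenarioSummary(
        scenario_id=spec.scenario_id,
        params=_spec_params(spec),
        n_replications=reps,
        n_excluded=excluded,
        c_derivation_mean=float(arr["c_derivation"].mean()),
        c_derivation_sd=float(arr["c_derivation"].std(ddof=1)),
        c_validation_mean=float(arr["c_validation"].mean()),
        c_validation_sd=float(arr["c_validation"].std(ddof=1)),
        slope_median=float(np.median(arr["slope"])),
        slope_sd=float(arr["slope"].std(ddof=1)),
        citl_mean=float(arr["citl"].mean()),
        citl_sd=float(arr["citl"].std(ddof=1)),
        brier_derivation_mean=float(arr["brier_derivation"].mean()),
        brier_derivation_sd=float(arr["brier_derivation"].std(ddof=1)),
        brier_validation_mean=float(arr["brier_validation"].mean()),
        brier_validation_sd=float(arr["brier_validation"].std(ddof=1)),
    )
    if return_replications:
        return summary, records
    return summary


# ---------------------------------------------------------------------------
# large-sample transport settings


LARGE_SAMPLE_SETTINGS = ("exact_to_pragmatic", "re_estimated", "pragmatic_to_exact")


def run_large_sample(
    setting: str,
    err_var_grid: Sequence[float] = (0.25, 0.5, 1.0, 2.0, 4.0),
    N: int = 1_000_000,
    model: OutcomeModel | None = None,
    seed: int = 1,
) -> list[dict]:
    """Large-sample contrast of within-sample error vs cross-setting
    heterogeneity, for increasing random-error variance.

    Settings: ``exact_to_pragmatic`` derives on X and validates the
    transported model on W; ``re_estimated`` refits on W and evaluates
    in-sample (always slope 1, zero calibration term); ``pragmatic_to_exact``
    derives on W and validates on X.
    """
    if setting not in LARGE_SAMPLE_SETTINGS:
        raise ValueError(
            f"unknown setting {setting!r}; choose from {LARGE_SAMPLE_SETTINGS}"
        )
    model = model or single_predictor_model()
    rng = np.random.default_rng(seed)
    X = generate_exact_predictors(N, model, rng)
    y = generate_outcomes(X, model, rng)
    out = []
    for err_var in err_var_grid:
        spec = MeasurementSpec.nondifferential(err_var=float(err_var))
        W = apply_measurement(X, y, [spec] * model.n_predictors, rng)
        if setting == "exact_to_pragmatic":
            fit, M_val = fit_logistic(y, X), W
        elif setting == "pragmatic_to_exact":
            fit, M_val = fit_logistic(y, W), X
        else:  # re_estimated: fit and evaluate on the same measurement
            fit, M_val = fit_logistic(y, W), W
        lp = linear_predictor(fit, M_val)
        p = expit(lp)
        recal = recalibrate(y, lp)
        parts = brier_decomposition(y, p)
        out.append(
            {
                "setting": setting,
                "err_var": float(err_var),
                "slope": recal.slope,
                "citl": calibration_in_the_large(y, lp),
                "c": concordance(y, lp),
                "brier": parts.total,
                "brier_calibration": parts.calibration_term,
                "brier_refinement": parts.refinement_term,
            }
        )
    return out
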