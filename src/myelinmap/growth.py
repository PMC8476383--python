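"""Saturating-exponential myelination growth model.

A region's longitudinal relaxation rate rises with myelin content and is
well described over early childhood by

    R1(t) = R1_inf + A * exp(-t / tau)

with age t in months, asymptote ``R1_inf`` (the mature value), negative
amplitude ``A`` (so R1 at birth is ``R1_inf + A``) and myelination time
constant ``tau`` — the e-folding time of the approach to maturity.  Fast
regions (corpus callosum, tau ~ 13 months) saturate well before slow ones
(deep grey matter, tau ~ 20 months).

Fitting is weighted nonlinear least squares with per-observation sigma
taken from the subject's ROI standard deviation; the parameter covariance
comes from the weighted Jacobian at the optimum, and tau's quoted
uncertainty is the square root of its diagonal entry.  Fitted curves act
as a normative reference: an individual observation is scored as a
z-deviation from the predicted value, combining measurement and model
uncertainty.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import regions as _regions

__all__ = [
    "GrowthParams",
    "RegionObservation",
    "NormativeReference",
    "FitError",
    "predict_r1",
    "params_from_anchors",
    "fit_growth",
    "fit_growth_arrays",
    "reference_table",
    "deviation_z",
    "compare_strata",
    "reference_growth_params",
    "correct_age",
    "read_observations",
    "write_observations",
]

#: Average weeks per month; converts prematurity (weeks short of 40) to months.
WEEKS_PER_MONTH = 365.25 / 12.0 / 7.0

TAU_BOUNDS = (0.1, 1000.0)


class FitError(RuntimeError):
    """Raised when the growth fit fails to converge or pins tau at a bound."""


@dataclass
class GrowthParams:
    """Fitted parameters of one region's growth curve.

    ``covariance`` is the 3x3 parameter covariance in the order
    (r1_inf, amplitude, tau); ``None`` when the parameters were derived
    analytically rather than fitted.
    """

    r1_inf: float
    amplitude: float
    tau: float
    covariance: np.ndarray | None = None
    tau_uncertainty: float | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.covariance is not None:
            self.covariance = np.asarray(self.covariance, dtype=float)
            if self.covariance.shape != (3, 3):
                raise ValueError("covariance must be 3x3")

    @property
    def r1_birth(self) -> float:
        return self.r1_inf + self.amplitude

    def to_dict(self) -> dict:
        out = {
            "r1_inf": self.r1_inf,
            "amplitude": self.amplitude,
            "tau": self.tau,
            "tau_uncertainty": self.tau_uncertainty,
        }
        if self.covariance is not None:
            out["covariance"] = self.covariance.tolist()
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "GrowthParams":
        return cls(
            r1_inf=float(data["r1_inf"]),
            amplitude=float(data["amplitude"]),
            tau=float(data["tau"]),
            covariance=np.asarray(data["covariance"], dtype=float)
            if data.get("covariance") is not None
            else None,
            tau_uncertainty=data.get("tau_uncertainty"),
        )


@dataclass(frozen=True)
class RegionObservation:
    """One subject's ROI measurement: prematurity-corrected age (months)
    and the ROI mean +- SD of R1 (1/s)."""

    subject_id: str
    age: float
    region: str
    side: str = _regions.MIDLINE
    r1_mean: float = float("nan")
    r1_sd: float = 0.0
    group: str = "negative"
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if not self.r1_mean > 0:
            raise ValueError("r1_mean must be positive")
        if self.r1_sd < 0:
            raise ValueError("r1_sd must be non-negative")
        if (self.region, self.side) not in _regions.REGIONS:
            raise KeyError(f"unknown region/side {(self.region, self.side)!r}")

    @property
    def region_key(self) -> str:
        return _regions.region_key(self.region, self.side)


def predict_r1(params: GrowthParams, age) -> float | np.ndarray:
    """Model value R1_inf + A*exp(-age/tau) at age in months."""
    age = np.asarray(age, dtype=float)
    value = params.r1_inf + params.amplitude * np.exp(-age / params.tau)
    return float(value) if value.ndim == 0 else value


def params_from_anchors(
    tau: float, anchor1: tuple[float, float], anchor2: tuple[float, float]
) -> GrowthParams:
    """Solve (R1_inf, A) in closed form from tau and two (age, R1) anchors.

    Used to reconstruct a full growth curve from published reference
    values, e.g. a region's tabulated R1 at birth and at 12 months plus
    its printed tau.
    """
    (t1, r1), (t2, r2) = anchor1, anchor2
    if t1 == t2:
        raise ValueError("anchor ages must be distinct")
    if tau <= 0:
        raise ValueError("tau must be positive")
    e1, e2 = np.exp(-t1 / tau), np.exp(-t2 / tau)
    amplitude = (r2 - r1) / (e2 - e1)
    r1_inf = r1 - amplitude * e1
    return GrowthParams(r1_inf=r1_inf, amplitude=amplitude, tau=tau)


def _model(t, r1_inf, amplitude, tau):
    return r1_inf + amplitude * np.exp(-t / tau)


def _initial_guess(ages: np.ndarray, r1: np.ndarray) -> tuple[float, float, float]:
    r1_inf0 = float(np.max(r1)) + 0.05
    amp0 = float(np.min(r1)) - r1_inf0
    # log-linear regression of |r1 - r1_inf0| against age: slope = -1/tau
    resid = np.abs(r1 - r1_inf0)
    ok = resid > 1e-12
    if np.count_nonzero(ok) >= 2:
        slope = np.polyfit(ages[ok], np.log(resid[ok]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else 20.0
    else:
        tau0 = 20.0
    tau0 = float(np.clip(tau0, TAU_BOUNDS[0] * 1.01, TAU_BOUNDS[1] * 0.99))
    return r1_inf0, amp0, tau0


def fit_growth_arrays(
    ages, r1, sigma=None, bounds_tau: tuple[float, float] = TAU_BOUNDS
) -> GrowthParams:
    """Weighted least-squares fit of the growth model to raw arrays.

    Minimizes sum(((r1_i - model(t_i)) / sigma_i)^2).  ``sigma`` is each
    point's measurement uncertainty; if any sigma is zero (or sigma is
    omitted) the fit falls back to unweighted with a warning, because a
    zero-uncertainty point would carry infinite weight.
    """
    ages = np.asarray(ages, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    if ages.size < 4:
        raise ValueError(f"need at least 4 observations, got {ages.size}")
    if np.ptp(ages) < 12.0:
        raise ValueError("observations must span at least 12 months of age")
    absolute_sigma = True
    if sigma is not None:
        sigma = np.asarray(sigma, dtype=float)
        if np.any(sigma <= 0):
            warnings.warn(
                "non-positive uncertainties supplied; falling back to an "
                "unweighted fit",
                stacklevel=2,
            )
            sigma = None
    if sigma is None:
        absolute_sigma = False

    p0 = _initial_guess(ages, r1)
    lower = [1e-6, -10.0, bounds_tau[0]]
    upper = [10.0, 10.0, bounds_tau[1]]
    p0 = tuple(np.clip(p0, lower, upper))
    try:
        popt, pcov = curve_fit(
            _model,
            ages,
            r1,
            p0=p0,
            sigma=sigma,
            absolute_sigma=absolute_sigma,
            bounds=(lower, upper),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise FitError(f"growth fit did not converge: {exc}") from exc
    r1_inf, amplitude, tau = (float(v) for v in popt)
    if not (bounds_tau[0] * (1 + 1e-6) < tau < bounds_tau[1] * (1 - 1e-6)):
        raise FitError(
            f"tau={tau:.3g} months pinned at a bound {bounds_tau}; "
            "the data do not constrain the time constant"
        )
    tau_unc = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else None
    return GrowthParams(
        r1_inf=r1_inf,
        amplitude=amplitude,
        tau=tau,
        covariance=pcov if np.all(np.isfinite(pcov)) else None,
        tau_uncertainty=tau_unc,
    )


def fit_growth(observations: list[RegionObservation]) -> GrowthParams:
    """Fit one region's growth curve from observations (all same region)."""
    if not observations:
        raise ValueError("no observations")
    keys = {o.region_key for o in observations}
    if len(keys) > 1:
        raise ValueError(f"observations mix regions: {sorted(keys)}")
    ages = np.array([o.age for o in observations])
    r1 = np.array([o.r1_mean for o in observations])
    sd = np.array([o.r1_sd for o in observations])
    sigma = sd if np.all(sd > 0) else None
    if sigma is None and np.any(sd > 0):
        warnings.warn(
            "some observations have zero r1_sd; using an unweighted fit",
            stacklevel=2,
        )
    return fit_growth_arrays(ages, r1, sigma)


def round_half_away(value: float, decimals: int) -> float:
    """Round half away from zero (0.005 -> 0.01, -0.005 -> -0.01)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class NormativeReference:
    """Fitted growth curves per region plus the ages a reference table
    should tabulate."""

    params: dict[str, GrowthParams]
    reference_ages: tuple[float, ...] = (0.0, 12.0, 24.0)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "reference_ages": list(self.reference_ages),
            "params": {k: p.to_dict() for k, p in self.params.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormativeReference":
        payload = json.loads(Path(path).read_text())
        return cls(
            params={k: GrowthParams.from_dict(v) for k, v in payload["params"].items()},
            reference_ages=tuple(payload.get("reference_ages", (0.0, 12.0, 24.0))),
        )


def reference_table(
    reference: NormativeReference,
    ages: list[float] | None = None,
    precision: int = 2,
) -> pd.DataFrame:
    """Region x age table of predicted R1 (1/s), rounded half away from
    zero to ``precision`` decimals."""
    ages = list(reference.reference_ages) if ages is None else list(ages)
    rows = {}
    for key, params in reference.params.items():
        rows[key] = [round_half_away(predict_r1(params, a), precision) for a in ages]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=[f"{a:g}mo" for a in ages])
    table.index.name = "region"
    return table


@dataclass(frozen=True)
class DeviationScore:
    """z-score of one observation against a normative curve."""

    z: float
    predicted_r1: float
    total_sd: float
    flagged: bool
    threshold: float


def _prediction_sd(params: GrowthParams, age: float) -> float:
    """SD of the model prediction, linearized through the covariance."""
    if params.covariance is None:
        return 0.0
    e = np.exp(-age / params.tau)
    grad = np.array([1.0, e, params.amplitude * age * e / params.tau**2])
    var = float(grad @ params.covariance @ grad)
    return float(np.sqrt(max(var, 0.0)))


def deviation_z(
    observation: RegionObservation,
    params: GrowthParams,
    threshold: float = 2.5,
) -> DeviationScore:
    """Score an individual against the normative curve.

    z = (r1_mean - prediction) / sqrt(r1_sd^2 + model_sd^2); observations
    with |z| above ``threshold`` are flagged as deviating from the norm.
    """
    predicted = predict_r1(params, observation.age)
    model_sd = _prediction_sd(params, observation.age)
    total_var = observation.r1_sd**2 + model_sd**2
    if total_var <= 0:
        raise ValueError(
            "undefined deviation score: observation has zero uncertainty and "
            "the reference curve carries no covariance"
        )
    total_sd = float(np.sqrt(total_var))
    z = float((observation.r1_mean - predicted) / total_sd)
    return DeviationScore(
        z=z,
        predicted_r1=float(predicted),
        total_sd=total_sd,
        flagged=abs(z) > threshold,
        threshold=threshold,
    )


@dataclass
class StratumComparison:
    """Sex-stratified fits for one region and whether the tau +-
    uncertainty intervals overlap (None when a stratum is absent or
    carries no uncertainty)."""

    male: GrowthParams | None
    female: GrowthParams | None
    tau_overlap: bool | None


def compare_strata(
    observations: list[RegionObservation],
) -> dict[str, StratumComparison]:
    """Fit each region separately for male and female subjects and report
    whether the tau uncertainty intervals overlap."""
    by_region: dict[str, dict[str, list[RegionObservation]]] = {}
    for obs in observations:
        by_region.setdefault(obs.region_key, {}).setdefault(obs.sex, []).append(obs)
    out: dict[str, StratumComparison] = {}
    for key, strata in sorted(by_region.items()):
        fits: dict[str, GrowthParams | None] = {}
        for sex in ("male", "female"):
            subset = strata.get(sex, [])
            fits[sex] = fit_growth(subset) if subset else None
        male, female = fits["male"], fits["female"]
        overlap: bool | None = None
        if (
            male is not None
            and female is not None
            and male.tau_uncertainty is not None
            and female.tau_uncertainty is not None
        ):
            lo_m, hi_m = male.tau - male.tau_uncertainty, male.tau + male.tau_uncertainty
            lo_f, hi_f = (
                female.tau - female.tau_uncertainty,
                female.tau + female.tau_uncertainty,
            )
            overlap = (lo_m <= hi_f) and (lo_f <= hi_m)
        out[key] = StratumComparison(male=male, female=female, tau_overlap=overlap)
    return out


def reference_growth_params() -> dict[str, GrowthParams]:
    """Growth curves reconstructed from the published anchors, keyed by
    region (right side for bilateral structures)."""
    params = {}
    for key, anchor in _regions.REFERENCE_ANCHORS.items():
        p = params_from_anchors(anchor.tau, (0.0, anchor.r1_birth), (12.0, anchor.r1_12mo))
        p.tau_uncertainty = anchor.tau_uncertainty
        params[key] = p
    return params


def correct_age(chronological_months: float, gestational_weeks: float | None) -> float:
    """Prematurity-corrected age: subtract the weeks short of 40 weeks
    gestation, converted to months.  Term-born (or unknown) ages pass
    through; corrections never go below zero."""
    if gestational_weeks is None or not np.isfinite(gestational_weeks):
        return float(chronological_months)
    corrected = chronological_months - (40.0 - gestational_weeks) / WEEKS_PER_MONTH
    return float(max(corrected, 0.0))


OBSERVATION_COLUMNS = [
    "subject_id",
    "age_months",
    "sex",
    "group",
    "region",
    "side",
    "r1_mean",
    "r1_sd",
]


def read_observations(path: str | Path) -> list[RegionObservation]:
    """Read an observation CSV (schema ``subject_id,age_months,sex,group,
    region,side,r1_mean,r1_sd``).  An optional ``gestational_weeks``
    column triggers prematurity correction of the ages at ingest."""
    frame = pd.read_csv(path)
    missing = set(OBSERVATION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"observation file {path} lacks columns {sorted(missing)}")
    has_ga = "gestational_weeks" in frame.columns
    observations = []
    for row in frame.itertuples(index=False):
        age = correct_age(
            float(row.age_months),
            float(row.gestational_weeks) if has_ga else None,
        )
        observations.append(
            RegionObservation(
                subject_id=str(row.subject_id),
                age=age,
                region=str(row.region),
                side=str(row.side),
                r1_mean=float(row.r1_mean),
                r1_sd=float(row.r1_sd),
                group=str(row.group),
                sex=str(row.sex),
            )
        )
    return observations


def write_observations(observations: list[RegionObservation], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "subject_id": o.subject_id,
                "age_months": o.age,
                "sex": o.sex,
                "group": o.group,
                "region": o.region,
                "side": o.side,
                "r1_mean": o.r1_mean,
                "r1_sd": o.r1_sd,
            }
            for o in observations
        ],
        columns=OBSERVATION_COLUMNS,
    )
    frame.to_csv(path, index=False)
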