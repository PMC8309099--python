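"""Drug-release kinetics: model fitting, scoring and mechanism classification.

Four classical release models are fit by ordinary least squares on each
model's linearized scale (scipy.stats.linregress does the regression):

===================  =============================  =========================
model                linear form                    rate constant
===================  =============================  =========================
zero order           Q = k0*t + c                   k0  [%/min]
first order          log10(100-Q) = c - k1*t/2.303  k1  [1/min, natural-log]
Higuchi              Q = kH*sqrt(t) + c             kH  [%/sqrt(min)]
Korsmeyer-Peppas     log10(Q) = log10(k) + n*log10(t)   k [%/min^n], n
===================  =============================  =========================

Q(t) is cumulative % released. The Higuchi and Korsmeyer-Peppas (power-law)
forms are short-time approximations, valid only over roughly the first 60%
of release, so those fits are restricted to points with Q <= 60%
(:func:`truncate_to_60`).

Each fit is scored by R^2 (squared Pearson correlation on the transformed
scale — the "is the plot linear?" question) and by MPE, the mean absolute
percentage error of the back-transformed predictions on the raw % scale.
The best model has the highest R^2, with near-ties broken by lowest MPE and
then by model parsimony. The Korsmeyer-Peppas exponent n diagnoses the
transport mechanism: Fickian diffusion (n < 0.45), anomalous transport,
case II (swelling/relaxation controlled, n near 1) and super case II
(n > 1). The case II band used here is 0.89 <= n <= 1.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import AnalysisError, InsufficientDataError, ModelSkipped
from .profiles import DissolutionProfile

__all__ = [
    "ReleaseModel",
    "Mechanism",
    "KineticFitResult",
    "ModelSelectionReport",
    "truncate_to_60",
    "fit_zero_order",
    "fit_first_order",
    "fit_higuchi",
    "fit_korsmeyer_peppas",
    "compute_mpe",
    "select_best_model",
    "classify_mechanism",
    "analyze_profile",
]


class ReleaseModel(str, Enum):
    ZERO_ORDER = "zero_order"
    FIRST_ORDER = "first_order"
    HIGUCHI = "higuchi"
    KORSMEYER_PEPPAS = "korsmeyer_peppas"


class Mechanism(str, Enum):
    FICKIAN = "fickian"
    ANOMALOUS = "anomalous"
    CASE_II = "case_II"
    SUPER_CASE_II = "super_case_II"
    NOT_APPLICABLE = "not_applicable"


#: Tie-break order when R^2 (and then MPE) cannot separate models:
#: simpler / more constrained models win.
PARSIMONY_ORDER = (
    ReleaseModel.ZERO_ORDER,
    ReleaseModel.FIRST_ORDER,
    ReleaseModel.HIGUCHI,
    ReleaseModel.KORSMEYER_PEPPAS,
)

R2_TIE_TOL = 1e-6
TRUNCATION_RELEASE = 60.0


@dataclass(frozen=True)
class KineticFitResult:
    """One model's fit to one profile.

    ``r_squared`` is computed on the model's linearized scale;
    ``r_squared_raw`` is the coefficient of determination of the
    back-transformed predictions on the raw % scale (diagnostic only).
    For the first-order model ``rate_constant`` is in natural-log units
    (transformed base-10 slope times ln 10); ``transformed_slope`` retains
    the base-10 regression slope for either convention.
    """

    model: ReleaseModel
    rate_constant: float
    intercept: float
    r_squared: float
    mpe: float
    n_points_used: int
    exponent_n: float | None = None
    truncated_at_60: bool = False
    r_squared_raw: float = float("nan")
    transformed_slope: float = float("nan")

    def to_dict(self) -> dict:
        d = {
            "model": self.model.value,
            "rate_constant": self.rate_constant,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "mpe": self.mpe,
            "n_points_used": self.n_points_used,
            "truncated_at_60": self.truncated_at_60,
        }
        if self.exponent_n is not None:
            d["exponent_n"] = self.exponent_n
        return d


@dataclass(frozen=True)
class ModelSelectionReport:
    """All fits for one profile plus the best-model and mechanism calls."""

    formulation_id: str
    fits: Mapping[ReleaseModel, KineticFitResult]
    best_model: ReleaseModel
    mechanism: Mechanism
    skipped_models: Mapping[ReleaseModel, str] = field(default_factory=dict)


def truncate_to_60(profile: DissolutionProfile) -> DissolutionProfile:
    """Keep only the points with release <= 60% (the power-law validity range).

    The first point exceeding 60% is excluded along with everything after
    it; the input profile is untouched. May return fewer than 3 points, in
    which case downstream fits refuse.
    """
    return profile.subset(profile.release <= TRUNCATION_RELEASE)


def _linregress(x: np.ndarray, y: np.ndarray, model: ReleaseModel):
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ModelSkipped(
            f"{model.value}: degenerate data (zero variance in "
            f"{'predictor' if np.ptp(x) == 0 else 'response'}), R^2 undefined"
        )
    return stats.linregress(x, y)


def _raw_r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0:
        return float("nan")
    return 1.0 - float(np.sum((observed - predicted) ** 2)) / sst


def compute_mpe(
    observed: Sequence[float], predicted: Sequence[float]
) -> float:
    """Mean percentage error: 100 * mean(|Q_obs - Q_pred| / Q_obs).

    Predictions must already be on the raw % release scale. Points with
    non-positive observed release are skipped (with a warning) because the
    relative error is undefined there.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    usable = observed > 0
    if not np.any(usable):
        raise AnalysisError("MPE undefined: no points with observed release > 0")
    if not np.all(usable):
        warnings.warn(
            f"MPE: skipped {int((~usable).sum())} point(s) with zero observed release",
            stacklevel=2,
        )
    return 100.0 * float(
        np.mean(np.abs(observed[usable] - predicted[usable]) / observed[usable])
    )


def fit_zero_order(profile: DissolutionProfile) -> KineticFitResult:
    """Constant-rate release: Q = k0*t + c on the raw scale."""
    t, q = profile.times, profile.release
    if len(t) < 3:
        raise InsufficientDataError(
            f"{profile.formulation_id}: zero-order fit needs >= 3 points, has {len(t)}"
        )
    res = _linregress(t, q, ReleaseModel.ZERO_ORDER)
    pred = res.slope * t + res.intercept
    return KineticFitResult(
        model=ReleaseModel.ZERO_ORDER,
        rate_constant=res.slope,
        intercept=res.intercept,
        r_squared=res.rvalue**2,
        mpe=compute_mpe(q, pred),
        n_points_used=len(t),
        r_squared_raw=_raw_r2(q, pred),
        transformed_slope=res.slope,
    )


def fit_first_order(profile: DissolutionProfile) -> KineticFitResult:
    """Concentration-dependent release: log10(100 - Q) linear in t.

    Points with Q >= 100 are dropped (log of non-positive remaining drug).
    The reported rate constant is k1 = -slope * ln(10), i.e. the natural-log
    convention dQ/dt = k1*(100 - Q).
    """
    usable = profile.release < 100.0
    t, q = profile.times[usable], profile.release[usable]
    if len(t) < 3:
        raise InsufficientDataError(
            f"{profile.formulation_id}: first-order fit needs >= 3 points with "
            f"release < 100%, has {len(t)}"
        )
    y = np.log10(100.0 - q)
    res = _linregress(t, y, ReleaseModel.FIRST_ORDER)
    pred = 100.0 - 10.0 ** (res.slope * t + res.intercept)
    return KineticFitResult(
        model=ReleaseModel.FIRST_ORDER,
        rate_constant=-res.slope * np.log(10.0),
        intercept=res.intercept,
        r_squared=res.rvalue**2,
        mpe=compute_mpe(q, pred),
        n_points_used=len(t),
        r_squared_raw=_raw_r2(q, pred),
        transformed_slope=res.slope,
    )


def fit_higuchi(profile: DissolutionProfile, truncate: bool = True) -> KineticFitResult:
    """Matrix-diffusion release: Q = kH*sqrt(t) + c, on points with Q <= 60%."""
    sub = truncate_to_60(profile) if truncate else profile
    if sub.n_points < 3:
        raise ModelSkipped(
            f"{profile.formulation_id}: higuchi skipped, only {sub.n_points} "
            "point(s) at <= 60% release (fast drug release)"
        )
    x = np.sqrt(sub.times)
    res = _linregress(x, sub.release, ReleaseModel.HIGUCHI)
    pred = res.slope * x + res.intercept
    return KineticFitResult(
        model=ReleaseModel.HIGUCHI,
        rate_constant=res.slope,
        intercept=res.intercept,
        r_squared=res.rvalue**2,
        mpe=compute_mpe(sub.release, pred),
        n_points_used=sub.n_points,
        truncated_at_60=truncate,
        r_squared_raw=_raw_r2(sub.release, pred),
        transformed_slope=res.slope,
    )


def fit_korsmeyer_peppas(
    profile: DissolutionProfile, truncate: bool = True
) -> KineticFitResult:
    """Power-law release: log10(Q) = log10(k) + n*log10(t), Q <= 60% only.

    Points with t = 0 or Q = 0 are excluded before the log-log transform.
    The slope is the diffusional exponent n; k = 10**intercept.
    """
    sub = truncate_to_60(profile) if truncate else profile
    usable = (sub.times > 0) & (sub.release > 0)
    t, q = sub.times[usable], sub.release[usable]
    if len(t) < 3:
        raise ModelSkipped(
            f"{profile.formulation_id}: korsmeyer_peppas skipped, only "
            f"{len(t)} usable point(s) at <= 60% release (fast drug release)"
        )
    x, y = np.log10(t), np.log10(q)
    res = _linregress(x, y, ReleaseModel.KORSMEYER_PEPPAS)
    pred = 10.0 ** (res.slope * x + res.intercept)
    return KineticFitResult(
        model=ReleaseModel.KORSMEYER_PEPPAS,
        rate_constant=10.0**res.intercept,
        intercept=res.intercept,
        r_squared=res.rvalue**2,
        mpe=compute_mpe(q, pred),
        n_points_used=len(t),
        exponent_n=res.slope,
        truncated_at_60=truncate,
        r_squared_raw=_raw_r2(q, pred),
        transformed_slope=res.slope,
    )


_FITTERS = {
    ReleaseModel.ZERO_ORDER: fit_zero_order,
    ReleaseModel.FIRST_ORDER: fit_first_order,
    ReleaseModel.HIGUCHI: fit_higuchi,
    ReleaseModel.KORSMEYER_PEPPAS: fit_korsmeyer_peppas,
}


def select_best_model(fits: Iterable[KineticFitResult]) -> ReleaseModel:
    """Highest R^2; ties within 1e-6 broken by lowest MPE, then parsimony."""
    fits = list(fits)
    if not fits:
        raise AnalysisError("select_best_model: no fits supplied")
    best_r2 = max(f.r_squared for f in fits)
    tied = [f for f in fits if f.r_squared >= best_r2 - R2_TIE_TOL]
    best_mpe = min(f.mpe for f in tied)
    tied = [f for f in tied if f.mpe <= best_mpe + R2_TIE_TOL]
    for model in PARSIMONY_ORDER:
        for f in tied:
            if f.model == model:
                return model
    return tied[0].model  # unreachable for known models


def classify_mechanism(exponent_n: float) -> Mechanism:
    """Transport mechanism from the power-law exponent n.

    n < 0.45 Fickian diffusion; 0.45 <= n < 0.89 anomalous transport;
    0.89 <= n <= 1.0 case II (swelling/relaxation controlled); n > 1.0
    super case II.
    """
    if not np.isfinite(exponent_n):
        raise ValueError("exponent n must be finite")
    if exponent_n < 0.45:
        return Mechanism.FICKIAN
    if exponent_n < 0.89:
        return Mechanism.ANOMALOUS
    if exponent_n <= 1.0:
        return Mechanism.CASE_II
    return Mechanism.SUPER_CASE_II


def analyze_profile(
    profile: DissolutionProfile,
    models: Sequence[ReleaseModel | str] = tuple(PARSIMONY_ORDER),
    min_points_60: int = 4,
) -> ModelSelectionReport:
    """Fit the requested models, pick the best, classify the mechanism.

    Higuchi and Korsmeyer-Peppas are skipped (with reason recorded) for
    fast-releasing profiles: fewer than ``min_points_60`` points at <= 60%
    release. Any model that raises a skip signal or has insufficient data
    is recorded in ``skipped_models`` rather than aborting the report.
    """
    models = [ReleaseModel(m) for m in models]
    n_below_60 = int(np.sum(profile.release <= TRUNCATION_RELEASE))
    fits: dict[ReleaseModel, KineticFitResult] = {}
    skipped: dict[ReleaseModel, str] = {}
    for model in models:
        if (
            model in (ReleaseModel.HIGUCHI, ReleaseModel.KORSMEYER_PEPPAS)
            and n_below_60 < min_points_60
        ):
            skipped[model] = (
                f"fast drug release: {n_below_60} point(s) at <= 60% release "
                f"(minimum {min_points_60})"
            )
            continue
        try:
            fits[model] = _FITTERS[model](profile)
        except (ModelSkipped, InsufficientDataError) as exc:
            skipped[model] = str(exc)
    if not fits:
        raise AnalysisError(
            f"{profile.formulation_id}: every requested model was skipped: {skipped}"
        )
    best = select_best_model(fits.values())
    kp = fits.get(ReleaseModel.KORSMEYER_PEPPAS)
    mechanism = (
        classify_mechanism(kp.exponent_n) if kp is not None else Mechanism.NOT_APPLICABLE
    )
    return ModelSelectionReport(
        formulation_id=profile.formulation_id,
        fits=fits,
        best_model=best,
        mechanism=mechanism,
        skipped_models=skipped,
    )
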