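"""In-silico dissolution experiments and powder QC measurements.

Emulates a two-stage USP paddle protocol for a sustained-release tablet:
sampling every 15 min for the first 2 h in simulated gastric fluid (pH 1.2),
then every 2 h up to 24 h after the medium is shifted to pH 7.4
(:func:`two_stage_schedule`, 19 points). Noise-free curves come from one of
the four release models in :mod:`dissofit.kinetics`; independent additive
Gaussian measurement noise is applied per point and replicate, optionally
followed by a monotone (running-maximum) projection since true cumulative
release is non-decreasing.

Seeding: replicate ``r`` of a simulation with root seed ``s`` draws from the
stream ``(s, r)``, so adding replicates never perturbs earlier ones and every
output is reproducible from the spec alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .kinetics import ReleaseModel
from .profiles import TWO_STAGE_PH, DissolutionProfile

__all__ = [
    "SimulationSpec",
    "two_stage_schedule",
    "model_curve",
    "simulate_profile",
    "simulate_two_stage_profile",
    "simulate_powder_measurements",
]

CHANGEOVER_MIN = 120.0  # gastric -> intestinal medium change


def two_stage_schedule() -> np.ndarray:
    """Sampling times (min) of the two-stage protocol: 15-min intervals to
    2 h, then 2-h intervals to 24 h — 8 + 11 = 19 points."""
    return np.concatenate(
        [np.arange(15.0, 121.0, 15.0), np.arange(240.0, 1441.0, 120.0)]
    )


def model_curve(
    model: ReleaseModel | str, times: np.ndarray, params: Mapping[str, float]
) -> np.ndarray:
    """Noise-free cumulative % release of a model at the given times.

    ``params`` uses ``k`` for every rate constant and additionally ``n``
    for the power-law exponent. The first-order curve is
    ``100*(1 - exp(-k*t))`` (complete release asymptotically).
    """
    model = ReleaseModel(model)
    t = np.asarray(times, dtype=float)
    k = float(params["k"])
    if model is ReleaseModel.ZERO_ORDER:
        return k * t
    if model is ReleaseModel.FIRST_ORDER:
        return 100.0 * (1.0 - np.exp(-k * t))
    if model is ReleaseModel.HIGUCHI:
        return k * np.sqrt(t)
    return k * np.power(t, float(params["n"]))  # Korsmeyer-Peppas


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to reproduce one simulated dissolution experiment."""

    model: ReleaseModel
    params: Mapping[str, float]
    schedule: np.ndarray = field(default_factory=two_stage_schedule)
    noise_sd: float = 1.0
    cap: float = 100.0
    monotone: bool = False
    n_replicates: int = 1
    seed: int = 0
    formulation_id: str = "SIM"

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", ReleaseModel(self.model))
        object.__setattr__(self, "params", dict(self.params))
        sched = np.asarray(self.schedule, dtype=float)
        object.__setattr__(self, "schedule", sched)
        if np.any(np.diff(sched) <= 0):
            raise ValueError("schedule must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0 < self.cap <= 110.0:
            raise ValueError(f"cap must lie in (0, 110], got {self.cap}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if "k" not in self.params:
            raise ValueError("params must contain rate constant 'k'")
        if self.model is ReleaseModel.KORSMEYER_PEPPAS and "n" not in self.params:
            raise ValueError("korsmeyer_peppas params must contain exponent 'n'")


def _stages_for(schedule: np.ndarray) -> tuple[tuple[float, float], ...]:
    if schedule[-1] > CHANGEOVER_MIN:
        return TWO_STAGE_PH
    return ((0.0, TWO_STAGE_PH[0][1]),)


def _noise_and_pack(
    spec: SimulationSpec, clean: np.ndarray
) -> list[DissolutionProfile]:
    clean = np.clip(clean, 0.0, spec.cap)
    profiles = []
    for r in range(spec.n_replicates):
        values = clean.copy()
        if spec.noise_sd > 0:
            rng = np.random.default_rng([spec.seed, r])
            values = values + rng.normal(0.0, spec.noise_sd, size=len(values))
            # keep noised values physical: never negative, never far above cap
            values = np.clip(values, 0.0, spec.cap + 5.0 * spec.noise_sd)
        if spec.monotone:
            values = np.maximum.accumulate(values)
        profiles.append(
            DissolutionProfile(
                formulation_id=spec.formulation_id,
                times=spec.schedule.copy(),
                release=values,
                stages=_stages_for(spec.schedule),
                replicate_id=f"r{r + 1}" if spec.n_replicates > 1 else None,
            )
        )
    return profiles


def simulate_profile(spec: SimulationSpec) -> list[DissolutionProfile]:
    """Simulate ``spec.n_replicates`` dissolution profiles (one per replicate)."""
    clean = model_curve(spec.model, spec.schedule, spec.params)
    return _noise_and_pack(spec, clean)


def _inverse_time(model: ReleaseModel, params: Mapping[str, float], q: float) -> float:
    """Elapsed model time at which the noise-free curve reaches release q."""
    k = float(params["k"])
    if model is ReleaseModel.ZERO_ORDER:
        return q / k
    if model is ReleaseModel.FIRST_ORDER:
        if q >= 100.0:
            raise ValueError("first-order curve never reaches 100% in finite time")
        return -np.log(1.0 - q / 100.0) / k
    if model is ReleaseModel.HIGUCHI:
        return (q / k) ** 2
    return (q / k) ** (1.0 / float(params["n"]))


def simulate_two_stage_profile(
    spec_stage1: SimulationSpec,
    spec_stage2: SimulationSpec,
    changeover: float = CHANGEOVER_MIN,
    continuation: str = "carryover",
) -> list[DissolutionProfile]:
    """Two-stage simulation: stage-1 kinetics to ``changeover``, stage-2 after.

    The curve is continuous at the changeover (the medium change is a buffer
    addition, not a tablet transfer, so no release jump is modelled). Two
    continuation conventions are offered:

    - ``carryover`` (default): stage 2 resumes its own curve at the elapsed
      "effective time" that reproduces the changeover release level, so
      identical stage specs reproduce the single-stage curve exactly.
    - ``additive``: stage-2 release is added on top of the changeover level
      with the stage-2 clock restarted at zero.

    Noise, cap, monotonicity, replicates and seed are taken from
    ``spec_stage1``; the schedule is stage 1's and must contain the
    changeover time.
    """
    sched = spec_stage1.schedule
    if not np.any(np.isclose(sched, changeover)):
        raise ValueError(f"changeover t={changeover} min is not on the schedule")
    if continuation not in ("carryover", "additive"):
        raise ValueError(f"unknown continuation {continuation!r}")
    q1 = model_curve(spec_stage1.model, sched, spec_stage1.params)
    q1 = np.clip(q1, 0.0, spec_stage1.cap)
    q_change = float(q1[np.isclose(sched, changeover)][0])
    after = sched > changeover
    clean = q1.copy()
    k2 = float(spec_stage2.params["k"])
    if continuation == "additive" or k2 == 0.0:
        # zero stage-2 rate: plateau at the changeover level
        clean[after] = q_change + model_curve(
            spec_stage2.model, sched[after] - changeover, spec_stage2.params
        )
    else:
        tau = _inverse_time(spec_stage2.model, spec_stage2.params, q_change)
        clean[after] = model_curve(
            spec_stage2.model, tau + sched[after] - changeover, spec_stage2.params
        )
    return _noise_and_pack(spec_stage1, clean)


def simulate_powder_measurements(
    true_bulk_density: float,
    true_tapped_density: float,
    cone_height: float,
    cone_radius: float,
    noise_cv: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Noised replicate powder measurements for the QC metrics.

    Densities in g/mL, cone dimensions in cm. Multiplicative Gaussian noise
    with coefficient of variation ``noise_cv`` per quantity and replicate;
    noised tapped density is floored at the noised bulk density so Carr's
    index stays defined. ``noise_cv = 0`` returns the exact inputs.
    """
    if not 0 < true_bulk_density <= true_tapped_density:
        raise ValueError(
            "need tapped >= bulk > 0, got "
            f"bulk={true_bulk_density}, tapped={true_tapped_density}"
        )
    if cone_height <= 0 or cone_radius <= 0:
        raise ValueError("cone dimensions must be positive")
    truth = np.array(
        [true_bulk_density, true_tapped_density, cone_height, cone_radius]
    )
    rows = []
    for r in range(n_replicates):
        if noise_cv > 0:
            rng = np.random.default_rng([seed, r])
            values = truth * (1.0 + rng.normal(0.0, noise_cv, size=4))
            values = np.maximum(values, 1e-12)
            values[1] = max(values[1], values[0])  # tapped >= bulk
        else:
            values = truth.copy()
        rows.append(
            {
                "replicate": f"r{r + 1}",
                "bulk_density": values[0],
                "tapped_density": values[1],
                "cone_height": values[2],
                "cone_radius": values[3],
            }
        )
    return pd.DataFrame(rows)
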