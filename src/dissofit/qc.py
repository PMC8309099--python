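"""Powder flow and tablet robustness quality-control metrics.

Flowability is judged by two compendial-style measures: the angle of repose
of a poured powder cone (theta = arctan(height/radius), lower is better) and
Carr's compressibility index CI% = 100*(tapped - bulk)/tapped (lower is
better). Both map onto an ordinal flowability scale from *excellent* to
*very poor*. The bands follow the standard USP <1174>-style tables, except
that the *excellent* band for the angle extends to 30 degrees — matching the
scale the study applied, which labels angles up to ~27 degrees excellent —
rather than the narrower compendial 25-30 "good" split.

Tablet robustness uses the friability rule: a tablet batch fails when any
tablet fractures or the percentage weight loss after standardized tumbling
exceeds 1%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd

__all__ = [
    "Flowability",
    "PowderQCRecord",
    "FriabilityResult",
    "carr_index",
    "angle_of_repose",
    "classify_angle",
    "classify_ci",
    "friability",
    "friability_verdict",
    "flow_rate",
    "qc_report",
]

FRIABILITY_LOSS_LIMIT = 1.0  # % weight loss


class Flowability(str, Enum):
    EXCELLENT = "excellent"
    GOOD = "good"
    FAIR = "fair"
    PASSABLE = "passable"
    POOR = "poor"
    VERY_POOR = "very_poor"


@dataclass(frozen=True)
class PowderQCRecord:
    """Flow metrics of one formulation with their inferred flowability classes."""

    formulation_id: str
    flow_rate: float
    angle_of_repose: float
    carr_index: float
    angle_inference: Flowability
    ci_inference: Flowability


@dataclass(frozen=True)
class FriabilityResult:
    weight_loss: float
    fractured: bool
    passed: bool


def carr_index(bulk_density: float, tapped_density: float) -> float:
    """CI% = 100 * (tapped - bulk) / tapped; needs tapped >= bulk > 0."""
    if bulk_density <= 0:
        raise ValueError(f"bulk density must be > 0, got {bulk_density}")
    if tapped_density < bulk_density:
        raise ValueError(
            f"tapped density ({tapped_density}) below bulk density ({bulk_density})"
        )
    return 100.0 * (tapped_density - bulk_density) / tapped_density


def angle_of_repose(height: float, radius: float) -> float:
    """Base angle (degrees) of a powder cone: arctan(height / radius)."""
    if height <= 0 or radius <= 0:
        raise ValueError("cone height and radius must be positive")
    return math.degrees(math.atan(height / radius))


def classify_angle(angle: float) -> Flowability:
    """Flowability class from the angle of repose (degrees).

    <= 30 excellent, (30, 35] good, (35, 40] fair, (40, 45] passable,
    > 45 poor.
    """
    if not 0 < angle < 90:
        raise ValueError(f"angle of repose must lie in (0, 90), got {angle}")
    if angle <= 30:
        return Flowability.EXCELLENT
    if angle <= 35:
        return Flowability.GOOD
    if angle <= 40:
        return Flowability.FAIR
    if angle <= 45:
        return Flowability.PASSABLE
    return Flowability.POOR


def classify_ci(ci: float) -> Flowability:
    """Flowability class from Carr's index (%).

    <= 10 excellent, (10, 15] good, (15, 20] fair, (20, 25] passable,
    (25, 31] poor, > 31 very poor.
    """
    if not 0 <= ci < 100:
        raise ValueError(f"Carr's index must lie in [0, 100), got {ci}")
    if ci <= 10:
        return Flowability.EXCELLENT
    if ci <= 15:
        return Flowability.GOOD
    if ci <= 20:
        return Flowability.FAIR
    if ci <= 25:
        return Flowability.PASSABLE
    if ci <= 31:
        return Flowability.POOR
    return Flowability.VERY_POOR


def friability_verdict(weight_loss: float, fractured: bool) -> bool:
    """Pass iff no fracture and weight loss <= 1%."""
    return (not fractured) and weight_loss <= FRIABILITY_LOSS_LIMIT


def friability(
    initial_mass: float, final_mass: float, fractured: bool = False
) -> FriabilityResult:
    """Friability outcome from pre/post tumbling masses.

    A final mass above the initial one is physically a weighing artifact:
    the loss is clamped at 0. Fracture fails the batch regardless of loss.
    """
    if initial_mass <= 0 or final_mass <= 0:
        raise ValueError("masses must be positive")
    loss = max(0.0, 100.0 * (initial_mass - final_mass) / initial_mass)
    return FriabilityResult(
        weight_loss=loss,
        fractured=fractured,
        passed=friability_verdict(loss, fractured),
    )


def flow_rate(mass: float, time: float) -> float:
    """Orifice flow rate in g/s."""
    if time <= 0:
        raise ValueError(f"flow time must be > 0, got {time}")
    return mass / time


def qc_report(measurements: pd.DataFrame) -> pd.DataFrame:
    """Flow/robustness report from raw replicate measurements.

    Expects long-format columns ``formulation_id, bulk_density,
    tapped_density, cone_height, cone_radius, flow_mass_g, flow_time_s`` and
    optionally ``friability_initial_mg, friability_final_mg, fractured``.
    Replicates are summarized as mean +/- SD and the flowability classes are
    assigned to the means.
    """
    rows = []
    for fid, group in measurements.groupby("formulation_id", sort=False):
        ci_vals = [
            carr_index(b, t)
            for b, t in zip(group["bulk_density"], group["tapped_density"])
        ]
        angle_vals = [
            angle_of_repose(h, r)
            for h, r in zip(group["cone_height"], group["cone_radius"])
        ]
        rate_vals = [
            flow_rate(m, s) for m, s in zip(group["flow_mass_g"], group["flow_time_s"])
        ]
        ci = float(pd.Series(ci_vals).mean())
        angle = float(pd.Series(angle_vals).mean())
        row = {
            "formulation_id": fid,
            "flow_rate": float(pd.Series(rate_vals).mean()),
            "flow_rate_sd": float(pd.Series(rate_vals).std(ddof=1)),
            "angle_of_repose": angle,
            "angle_sd": float(pd.Series(angle_vals).std(ddof=1)),
            "carr_index": ci,
            "carr_index_sd": float(pd.Series(ci_vals).std(ddof=1)),
            "angle_inference": classify_angle(angle).value,
            "ci_inference": classify_ci(ci).value,
        }
        if {"friability_initial_mg", "friability_final_mg"} <= set(group.columns):
            frac = bool(group.get("fractured", pd.Series([False])).any())
            result = friability(
                float(group["friability_initial_mg"].iloc[0]),
                float(group["friability_final_mg"].iloc[0]),
                fractured=frac,
            )
            row.update(
                friability_loss=result.weight_loss,
                fractured=result.fractured,
                friability_passed=result.passed,
            )
        rows.append(row)
    return pd.DataFrame(rows)
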