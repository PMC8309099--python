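"""Model-independent dissolution profile comparison (f1 / f2).

The difference factor f1 and similarity factor f2 are the FDA-recommended
model-independent statistics for deciding whether two dissolution profiles
are equivalent:

    f1 = 100 * sum|R_t - T_t| / sum R_t
    f2 = 50 * log10( 100 * [1 + (1/n) sum (R_t - T_t)^2]^(-1/2) )

with R_t / T_t the mean % dissolved of the reference and test product at the
n shared sampling times. f2 equals 100 for identical profiles and can be
written as ``100 - 25*log10(1 + msd)`` with ``msd`` the mean squared
difference; f1 is 0 for identical profiles, is asymmetric in (R, T) and has
no upper bound. Equivalence is declared when f1 is within 0-15 and f2 within
50-100.

Point selection follows the regulatory practice of discarding points after
the reference product is essentially dissolved: the ``fda85`` rule keeps
common time points up to and including the first at which the reference
exceeds 85% release.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .exceptions import ComparisonError
from .profiles import DissolutionProfile, mean_profile

__all__ = [
    "ComparisonSet",
    "ComparisonResult",
    "select_points",
    "difference_factor",
    "similarity_factor",
    "equivalence_verdict",
    "compare_profiles",
]

TIME_MATCH_TOL = 1e-9  # minutes; exact-schedule matching, no interpolation


@dataclass(frozen=True)
class ComparisonSet:
    """Reference and test release values aligned on a common time grid."""

    times: np.ndarray
    reference: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times", "reference", "test"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.times) == len(self.reference) == len(self.test)):
            raise ComparisonError("aligned sequences differ in length")
        if len(self.times) < 2:
            raise ComparisonError("a comparison needs at least 2 common time points")

    @property
    def n_points(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class ComparisonResult:
    """f1/f2 outcome for one reference/test pair."""

    f1: float
    f2: float
    n_points_used: int
    equivalent: bool

    def to_dict(self) -> dict:
        return {
            "f1": self.f1,
            "f2": self.f2,
            "n_points_used": self.n_points_used,
            "equivalent": self.equivalent,
        }


def select_points(
    reference: DissolutionProfile,
    test: DissolutionProfile,
    rule: Literal["all", "fda85"] = "fda85",
) -> ComparisonSet:
    """Align two profiles on their shared time points.

    ``all`` keeps every common time point; ``fda85`` additionally drops the
    points after the first at which the *reference* exceeds 85% released
    (that first point itself is kept). Times must match exactly (within
    1e-9 min); profiles sampled on different schedules are not interpolated.
    """
    if rule not in ("all", "fda85"):
        raise ValueError(f"unknown point-selection rule {rule!r}")
    ref_idx, test_idx = [], []
    for i, t in enumerate(reference.times):
        j = np.flatnonzero(np.abs(test.times - t) <= TIME_MATCH_TOL)
        if len(j):
            ref_idx.append(i)
            test_idx.append(int(j[0]))
    if len(ref_idx) < 2:
        raise ComparisonError(
            f"{reference.formulation_id} vs {test.formulation_id}: fewer than "
            f"2 common time points ({len(ref_idx)} found)"
        )
    times = reference.times[ref_idx]
    r = reference.release[ref_idx]
    t = test.release[test_idx]
    if rule == "fda85":
        over = np.flatnonzero(r > 85.0)
        if len(over):
            keep = over[0] + 1  # include the first point above 85%
            times, r, t = times[:keep], r[:keep], t[:keep]
        if len(r) < 2:
            raise ComparisonError(
                f"{reference.formulation_id} vs {test.formulation_id}: fewer "
                "than 2 points remain under the 85% rule"
            )
    return ComparisonSet(times=times, reference=r, test=t)


def difference_factor(cset: ComparisonSet) -> float:
    """f1 = 100 * sum|R-T| / sum R. Asymmetric in (reference, test); >= 0."""
    total = float(np.sum(cset.reference))
    if total <= 0:
        raise ComparisonError(
            "difference factor undefined: reference profile sums to zero "
            "(f1 divides by the cumulative reference release)"
        )
    return 100.0 * float(np.sum(np.abs(cset.reference - cset.test))) / total


def similarity_factor(cset: ComparisonSet) -> float:
    """f2 = 50*log10(100 / sqrt(1 + msd)) = 100 - 25*log10(1 + msd).

    ``msd`` is the mean squared pointwise difference. Not clamped below:
    extremely divergent profiles give f2 < 0, reported as-is.
    """
    msd = float(np.mean((cset.reference - cset.test) ** 2))
    return float(100.0 - 25.0 * np.log10(1.0 + msd))


def equivalence_verdict(f1: float, f2: float) -> bool:
    """Equivalent iff f1 in [0, 15] and f2 in [50, 100]."""
    if not (np.isfinite(f1) and np.isfinite(f2)):
        raise ValueError("f1 and f2 must be finite")
    return bool(0.0 <= f1 <= 15.0 and 50.0 <= f2 <= 100.0)


def compare_profiles(
    reference: DissolutionProfile | Sequence[DissolutionProfile],
    test: DissolutionProfile | Sequence[DissolutionProfile],
    rule: Literal["all", "fda85"] = "fda85",
) -> ComparisonResult:
    """Full comparison of a reference/test pair, averaging replicates first.

    Either argument may be a sequence of replicate profiles; f1/f2 are
    defined on the mean % dissolved per time point.
    """
    if not isinstance(reference, DissolutionProfile):
        reference = mean_profile(list(reference))
    if not isinstance(test, DissolutionProfile):
        test = mean_profile(list(test))
    cset = select_points(reference, test, rule=rule)
    f1 = difference_factor(cset)
    f2 = similarity_factor(cset)
    return ComparisonResult(
        f1=f1, f2=f2, n_points_used=cset.n_points, equivalent=equivalence_verdict(f1, f2)
    )
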