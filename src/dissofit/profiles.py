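"""Dissolution profile data model and CSV I/O.

A :class:`DissolutionProfile` is the object every comparison and kinetic fit
consumes: cumulative percent of the labeled dose released, sampled at strictly
increasing times (minutes), optionally annotated with pH stages for two-stage
(gastric -> intestinal) dissolution protocols.

Release values are allowed up to 110% because cumulative UV assays routinely
overshoot 100% slightly; anything beyond that is treated as a data error.

The CSV dialect is a plain long table with columns
``formulation_id, replicate, time_min, release_pct, pH``. The pH column is
optional; when absent a single-stage profile is assumed. Replicates are kept
as separate profiles on read — averaging is always an explicit call to
:func:`mean_profile`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ProfileValidationError

__all__ = [
    "DissolutionProfile",
    "CalibrationLine",
    "TWO_STAGE_PH",
    "read_profiles",
    "write_profiles",
    "absorbance_to_release",
    "mean_profile",
]

#: Default two-stage protocol: pH 1.2 (simulated gastric fluid) for the first
#: 2 h, then pH 7.4 (simulated intestinal fluid).
TWO_STAGE_PH: tuple[tuple[float, float], ...] = ((0.0, 1.2), (120.0, 7.4))

MAX_RELEASE = 110.0  # analytical overshoot allowance above 100%


@dataclass(frozen=True)
class DissolutionProfile:
    """One dissolution run: cumulative % released vs. time.

    Parameters
    ----------
    formulation_id
        Label of the dosage form the curve belongs to.
    times
        Sampling times in minutes, strictly increasing, first >= 0.
    release
        Cumulative % of labeled dose released, one value per time,
        each within [0, 110].
    stages
        ``(start_time_min, pH)`` pairs marking medium changes, sorted by
        start time with the first stage starting at time 0. Empty means
        a single unannotated stage.
    replicate_id
        Optional replicate label; replicates are never merged implicitly.
    """

    formulation_id: str
    times: np.ndarray
    release: np.ndarray
    stages: tuple[tuple[float, float], ...] = ()
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        release = np.asarray(self.release, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "release", release)
        if times.ndim != 1 or release.ndim != 1:
            raise ProfileValidationError(
                f"{self.formulation_id}: times and release must be 1-D sequences"
            )
        if len(times) != len(release):
            raise ProfileValidationError(
                f"{self.formulation_id}: times ({len(times)}) and release "
                f"({len(release)}) differ in length"
            )
        if len(times) and times[0] < 0:
            raise ProfileValidationError(
                f"{self.formulation_id}: first sampling time is negative"
            )
        if np.any(np.diff(times) <= 0):
            raise ProfileValidationError(
                f"{self.formulation_id}: sampling times are not strictly increasing"
            )
        if len(release) and (release.min() < 0 or release.max() > MAX_RELEASE):
            raise ProfileValidationError(
                f"{self.formulation_id}: release values outside [0, {MAX_RELEASE}]"
            )
        stages = tuple((float(t0), float(ph)) for t0, ph in self.stages)
        object.__setattr__(self, "stages", stages)
        if stages:
            starts = [t0 for t0, _ in stages]
            if starts != sorted(starts):
                raise ProfileValidationError(
                    f"{self.formulation_id}: stages not sorted by start time"
                )
            if starts[0] != 0.0:
                raise ProfileValidationError(
                    f"{self.formulation_id}: first stage must start at time 0"
                )

    @property
    def n_points(self) -> int:
        return len(self.times)

    def ph_at(self, time_min: float) -> float:
        """pH of the medium at ``time_min`` (NaN when stages are unannotated)."""
        if not self.stages:
            return float("nan")
        ph = self.stages[0][1]
        for start, value in self.stages:
            if time_min >= start:
                ph = value
        return ph

    def subset(self, mask: np.ndarray) -> "DissolutionProfile":
        """New profile keeping only the points selected by a boolean mask."""
        return replace(self, times=self.times[mask], release=self.release[mask])

    def to_frame(self) -> pd.DataFrame:
        """Long-format single-profile table in the package CSV dialect."""
        return pd.DataFrame(
            {
                "formulation_id": self.formulation_id,
                "replicate": self.replicate_id if self.replicate_id is not None else "",
                "time_min": self.times,
                "release_pct": self.release,
                "pH": [self.ph_at(t) for t in self.times] if self.stages else np.nan,
            }
        )


@dataclass(frozen=True)
class CalibrationLine:
    """Linear absorbance -> concentration calibration.

    ``concentration (mg/mL) = slope * absorbance + intercept`` for a fixed
    wavelength; slope must be positive.
    """

    slope: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be > 0, got {self.slope}")

    def concentration(self, absorbance: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(absorbance, dtype=float) + self.intercept


DEFAULT_DIALECT: Mapping[str, str] = {
    "formulation_id": "formulation_id",
    "time_min": "time_min",
    "release_pct": "release_pct",
    "replicate": "replicate",
    "ph": "pH",
}


def _stages_from_ph(times: np.ndarray, ph: np.ndarray) -> tuple[tuple[float, float], ...]:
    """Collapse a per-point pH column into (start_time, pH) stage annotations.

    The pH observed at the first sample is assumed to hold from time 0.
    """
    if len(times) == 0 or np.all(np.isnan(ph)):
        return ()
    stages = [(0.0, float(ph[0]))]
    for t, value in zip(times[1:], ph[1:]):
        if not np.isnan(value) and value != stages[-1][1]:
            stages.append((float(t), float(value)))
    return tuple(stages)


def read_profiles(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[DissolutionProfile]:
    """Read dissolution profiles from a long-format CSV.

    One profile is produced per ``(formulation_id, replicate)`` group; rows
    are sorted by time within each group and all profile invariants are
    enforced. ``dialect`` maps the canonical column roles
    (``formulation_id, time_min, release_pct, replicate, ph``) onto the
    actual column names in the file.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    table = pd.read_csv(path)
    for role in ("formulation_id", "time_min", "release_pct"):
        if cols[role] not in table.columns:
            raise FormatError(
                f"{path}: required column {cols[role]!r} (role {role}) is missing"
            )
    has_rep = cols["replicate"] in table.columns
    has_ph = cols["ph"] in table.columns

    profiles: list[DissolutionProfile] = []
    rep_col = table[cols["replicate"]].fillna("").astype(str) if has_rep else ""
    table = table.assign(__rep=rep_col)
    for (fid, rep), group in table.groupby(
        [cols["formulation_id"], "__rep"], sort=False
    ):
        group = group.sort_values(cols["time_min"], kind="stable")
        times = group[cols["time_min"]].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ProfileValidationError(
                f"{path}: non-monotone (duplicated) times in group "
                f"({fid!r}, replicate {rep!r})"
            )
        ph = (
            group[cols["ph"]].to_numpy(dtype=float)
            if has_ph
            else np.full(len(group), np.nan)
        )
        profiles.append(
            DissolutionProfile(
                formulation_id=str(fid),
                times=times,
                release=group[cols["release_pct"]].to_numpy(dtype=float),
                stages=_stages_from_ph(times, ph),
                replicate_id=rep or None,
            )
        )
    return profiles


def write_profiles(
    profiles: Iterable[DissolutionProfile], path: str | Path
) -> Path:
    """Write profiles to CSV in the package dialect (full float precision).

    ``read_profiles(write_profiles(p))`` reproduces times and release values
    exactly (repr round-trip) and is the supported interchange path.
    """
    path = Path(path)
    frames = [p.to_frame() for p in profiles]
    columns = ["formulation_id", "replicate", "time_min", "release_pct", "pH"]
    if frames:
        out = pd.concat(frames, ignore_index=True)[columns]
    else:
        out = pd.DataFrame(columns=columns)
    out.to_csv(path, index=False, float_format="%.17g")
    return path


def absorbance_to_release(
    absorbances: Sequence[float],
    calibration: CalibrationLine,
    dilution_factor: float = 1.0,
    vessel_volume: float = 900.0,
    dose: float = 80.0,
    sample_volume: float = 0.0,
) -> np.ndarray:
    """Convert raw UV absorbance readings into cumulative % release.

    ``release_i = (slope*A_i + intercept) * dilution_factor * vessel_volume
    / dose * 100``. By default no correction is made for the drug removed in
    sampled aliquots; pass ``sample_volume`` (mL withdrawn per sample) to
    apply the standard cumulative correction
    ``C_i' = C_i + (v/V) * sum_{j<i} C_j``.
    """
    if dose <= 0:
        raise ValueError(f"dose must be > 0, got {dose}")
    if vessel_volume <= 0:
        raise ValueError(f"vessel_volume must be > 0, got {vessel_volume}")
    if dilution_factor < 1:
        raise ValueError(f"dilution_factor must be >= 1, got {dilution_factor}")
    conc = calibration.concentration(absorbances) * dilution_factor
    if sample_volume:
        running = np.concatenate([[0.0], np.cumsum(conc)[:-1]])
        conc = conc + (sample_volume / vessel_volume) * running
    return conc * vessel_volume / dose * 100.0


def mean_profile(profiles: Sequence[DissolutionProfile]) -> DissolutionProfile:
    """Pointwise mean of replicate profiles sharing one sampling grid."""
    if not profiles:
        raise ProfileValidationError("mean_profile needs at least one profile")
    first = profiles[0]
    for p in profiles[1:]:
        if len(p.times) != len(first.times) or np.any(p.times != first.times):
            raise ProfileValidationError(
                f"{first.formulation_id}: replicates sampled on different grids"
            )
    release = np.mean([p.release for p in profiles], axis=0)
    return DissolutionProfile(
        formulation_id=first.formulation_id,
        times=first.times.copy(),
        release=release,
        stages=first.stages,
        replicate_id=None,
    )
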