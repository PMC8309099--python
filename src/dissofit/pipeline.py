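"""Study orchestration: one config in, a reproducible report bundle out.

A study config (YAML or JSON) names input profile CSVs and/or simulation
specs, the comparison pairs, the kinetic models to fit, formulation
compositions and raw QC measurements. :func:`run_study` executes every
requested stage and writes:

- ``comparison.csv``   f1 / f2 / points used / equivalence verdict per pair
- ``kinetics.csv``     per-model R^2, MPE, exponent, best model, mechanism
- ``formulations.csv`` derived composition quantities (Lf, %w/w, totals)
- ``qc.csv``           flow metrics, flowability classes, friability verdicts
- ``manifest.json``    package version, root seed, SHA-256 of every input

One root seed drives all randomness; simulation entry ``i`` draws from a
stream derived from ``(seed, i)`` so single stages can be re-run in
isolation. The same config and seed give byte-identical reports. Numbers
are rounded only at serialization (2 decimals for percentages and f-factors,
3 for R^2 and the exponent n).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparison import compare_profiles
from .exceptions import AnalysisError, DissofitError
from .formulation import Formulation, derived_table, infer_vehicle_mass
from .kinetics import ReleaseModel, analyze_profile
from .profiles import DissolutionProfile, mean_profile, read_profiles, write_profiles
from .qc import qc_report
from .simulate import SimulationSpec, simulate_profile, two_stage_schedule

__all__ = ["StudyConfig", "run_study", "load_config"]

MODEL_ALIASES = {
    "zero": ReleaseModel.ZERO_ORDER,
    "first": ReleaseModel.FIRST_ORDER,
    "kp": ReleaseModel.KORSMEYER_PEPPAS,
}


def parse_model(name: str) -> ReleaseModel:
    name = name.strip().lower()
    if name in MODEL_ALIASES:
        return MODEL_ALIASES[name]
    return ReleaseModel(name)


@dataclass
class StudyConfig:
    """Declarative description of one full study run."""

    seed: int = 0
    output_dir: str = "study_out"
    profiles_csv: str | None = None
    simulations: list[dict] = field(default_factory=list)
    comparisons: list[dict] = field(default_factory=list)
    models: list[str] = field(
        default_factory=lambda: [m.value for m in ReleaseModel]
    )
    min_points_60: int = 4
    formulations: list[dict] = field(default_factory=list)
    qc_csv: str | None = None

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "StudyConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise DissofitError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path: str | Path) -> StudyConfig:
    """Read a YAML or JSON study config."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return StudyConfig.from_mapping(data or {})


def _entry_seed(root_seed: int, index: int) -> int:
    """Independent per-entry seed stream, stable under entry addition."""
    return int(np.random.SeedSequence([root_seed, index]).generate_state(1)[0] % 2**31)


def _build_spec(entry: Mapping[str, Any], seed: int) -> SimulationSpec:
    schedule = entry.get("schedule", "two_stage")
    if isinstance(schedule, str):
        if schedule != "two_stage":
            raise DissofitError(f"unknown schedule preset {schedule!r}")
        schedule = two_stage_schedule()
    else:
        schedule = np.asarray(schedule, dtype=float)
    return SimulationSpec(
        model=parse_model(entry["model"]),
        params=entry["params"],
        schedule=schedule,
        noise_sd=float(entry.get("noise_sd", 1.0)),
        cap=float(entry.get("cap", 100.0)),
        monotone=bool(entry.get("monotone", False)),
        n_replicates=int(entry.get("replicates", 1)),
        seed=seed,
        formulation_id=str(entry["id"]),
    )


def _formulation_from_entry(entry: Mapping[str, Any]) -> Formulation:
    entry = dict(entry)
    if "vehicle_mass" not in entry and "total_mass" in entry:
        entry["vehicle_mass"] = infer_vehicle_mass(
            entry.pop("total_mass"),
            entry["api_mass"],
            entry["avicel_mass"],
            entry.get("eudragit_mass", 0.0),
            entry["aerosil_mass"],
            formulation_id=entry.get("formulation_id", "?"),
        )
    return Formulation(**entry)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _kinetic_rows(
    by_id: dict[str, list[DissolutionProfile]],
    models: list[ReleaseModel],
    min_points_60: int,
) -> pd.DataFrame:
    rows = []
    for fid, reps in by_id.items():
        profile = mean_profile(reps) if len(reps) > 1 else reps[0]
        report = analyze_profile(profile, models=models, min_points_60=min_points_60)
        row: dict[str, Any] = {"formulation_id": fid}
        for model in models:
            fit = report.fits.get(model)
            if fit is None:
                row[f"{model.value}_r2"] = np.nan
                row[f"{model.value}_mpe"] = np.nan
                continue
            row[f"{model.value}_r2"] = round(fit.r_squared, 3)
            row[f"{model.value}_mpe"] = round(fit.mpe, 2)
            row[f"{model.value}_k"] = round(fit.rate_constant, 5)
            if fit.exponent_n is not None:
                row[f"{model.value}_n"] = round(fit.exponent_n, 3)
        row["best_model"] = report.best_model.value
        row["mechanism"] = report.mechanism.value
        row["skipped"] = "; ".join(
            f"{m.value}: {reason}" for m, reason in report.skipped_models.items()
        )
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(config: StudyConfig, base_dir: str | Path = ".") -> dict[str, Any]:
    """Run every configured stage; return the report tables and manifest.

    Any stage failure is re-raised as a :class:`DissofitError` naming the
    stage after a failure manifest (plus whatever partial outputs completed)
    has been written.
    """
    base = Path(base_dir)
    outdir = base / config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "dissofit",
        "version": __version__,
        "seed": config.seed,
        "inputs": {},
        "outputs": [],
        "status": "ok",
    }
    results: dict[str, Any] = {"manifest": manifest}
    stage = "setup"
    try:
        # ---- gather profiles (read + simulate) ----
        stage = "profiles"
        profiles: list[DissolutionProfile] = []
        if config.profiles_csv:
            src = base / config.profiles_csv
            profiles.extend(read_profiles(src))
            manifest["inputs"][str(config.profiles_csv)] = _sha256(src)
        for i, entry in enumerate(config.simulations):
            spec = _build_spec(entry, seed=_entry_seed(config.seed, i))
            profiles.extend(simulate_profile(spec))
        by_id: dict[str, list[DissolutionProfile]] = {}
        for p in profiles:
            by_id.setdefault(p.formulation_id, []).append(p)
        if profiles:
            path = outdir / "profiles.csv"
            write_profiles(profiles, path)
            manifest["outputs"].append(path.name)

        # ---- comparisons ----
        if config.comparisons:
            stage = "comparison"
            rows = []
            for pair in config.comparisons:
                for role in ("reference", "test"):
                    if pair[role] not in by_id:
                        raise AnalysisError(
                            f"comparison names unknown formulation id {pair[role]!r}"
                        )
                result = compare_profiles(
                    by_id[pair["reference"]],
                    by_id[pair["test"]],
                    rule=pair.get("rule", "fda85"),
                )
                rows.append(
                    {
                        "reference": pair["reference"],
                        "test": pair["test"],
                        "rule": pair.get("rule", "fda85"),
                        "f1": round(result.f1, 2),
                        "f2": round(result.f2, 2),
                        "n_points_used": result.n_points_used,
                        "equivalent": result.equivalent,
                    }
                )
            results["comparison"] = pd.DataFrame(rows)
            results["comparison"].to_csv(outdir / "comparison.csv", index=False)
            manifest["outputs"].append("comparison.csv")

        # ---- kinetics ----
        if by_id:
            stage = "kinetics"
            models = [parse_model(m) for m in config.models]
            results["kinetics"] = _kinetic_rows(by_id, models, config.min_points_60)
            results["kinetics"].to_csv(outdir / "kinetics.csv", index=False)
            manifest["outputs"].append("kinetics.csv")

        # ---- formulation arithmetic ----
        if config.formulations:
            stage = "formulation"
            forms = [_formulation_from_entry(e) for e in config.formulations]
            results["formulations"] = derived_table(forms)
            results["formulations"].to_csv(outdir / "formulations.csv", index=False)
            manifest["outputs"].append("formulations.csv")

        # ---- powder / tablet QC ----
        if config.qc_csv:
            stage = "qc"
            src = base / config.qc_csv
            manifest["inputs"][str(config.qc_csv)] = _sha256(src)
            table = qc_report(pd.read_csv(src))
            results["qc"] = table.round(2)
            results["qc"].to_csv(outdir / "qc.csv", index=False)
            manifest["outputs"].append("qc.csv")
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if isinstance(exc, DissofitError):
            raise
        raise DissofitError(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
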