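"""Published measurements of the propranolol sustained-release Liqui-Tablet study.

These tables are the study's printed inputs — component masses, powder-flow
measurements, friability outcomes and per-model goodness-of-fit scores for
ten formulations (two physical-mixture controls PMT-1/PMT-2 and eight
Liqui-Tablets F-1..F-8, all containing 80 mg propranolol HCl with a 20:1
carrier-to-coating ratio). They drive the worked examples in ``analysis/``
and serve as fixed reference inputs in the test suite; nothing here is
computed by this package.

Raw dissolution curves were not published for this study, so there is no
profile table; simulated profiles from :mod:`dissofit.simulate` stand in
for them wherever curves are needed.
"""

from __future__ import annotations

import pandas as pd

from .formulation import Formulation, infer_vehicle_mass

__all__ = [
    "COMPOSITIONS",
    "study_formulations",
    "FLOW_MEASUREMENTS",
    "FRIABILITY_RESULTS",
    "RELEASE_MODEL_SCORES",
]

#: Printed composition table: masses in mg, total is the finished tablet;
#: the liquid-vehicle mass is not printed and is inferred from the total.
#: water is mL granulating water per 20 g admixture; force in PSI.
COMPOSITIONS: tuple[dict, ...] = (
    dict(id="PMT-1", vehicle="", api=80.0, avicel=180.0, aerosil=9.0, eudragit=0.0,
         total=269.0, water=22.3, force=1000.0),
    dict(id="PMT-2", vehicle="", api=80.0, avicel=135.0, aerosil=9.0, eudragit=45.0,
         total=269.0, water=14.9, force=1400.0),
    dict(id="F-1", vehicle="Tween 80", api=80.0, avicel=180.0, aerosil=9.0,
         eudragit=0.0, total=309.0, water=12.9, force=1400.0),
    dict(id="F-2", vehicle="Tween 20", api=80.0, avicel=180.0, aerosil=9.0,
         eudragit=0.0, total=309.0, water=12.9, force=1400.0),
    dict(id="F-3", vehicle="Kolliphor EL", api=80.0, avicel=180.0, aerosil=9.0,
         eudragit=0.0, total=309.0, water=12.9, force=1400.0),
    dict(id="F-4", vehicle="Tween 20", api=80.0, avicel=180.0, aerosil=9.0,
         eudragit=0.0, total=329.0, water=12.2, force=1400.0),
    dict(id="F-5", vehicle="Tween 20", api=80.0, avicel=180.0, aerosil=9.0,
         eudragit=0.0, total=349.0, water=11.5, force=1400.0),
    dict(id="F-6", vehicle="Tween 20", api=80.0, avicel=135.0, aerosil=9.0,
         eudragit=45.0, total=329.0, water=9.7, force=1400.0),
    dict(id="F-7", vehicle="Tween 20", api=80.0, avicel=90.0, aerosil=9.0,
         eudragit=90.0, total=329.0, water=4.86, force=1400.0),
    dict(id="F-8", vehicle="Tween 20", api=80.0, avicel=45.0, aerosil=9.0,
         eudragit=135.0, total=329.0, water=3.0, force=1400.0),
)


def study_formulations() -> list[Formulation]:
    """Formulation objects for all ten study compositions.

    The liquid-vehicle mass is reconstructed from the printed tablet total
    by subtracting the named solids.
    """
    out = []
    for row in COMPOSITIONS:
        vehicle_mass = infer_vehicle_mass(
            row["total"], row["api"], row["avicel"], row["eudragit"],
            row["aerosil"], formulation_id=row["id"],
        )
        out.append(
            Formulation(
                formulation_id=row["id"],
                api_mass=row["api"],
                avicel_mass=row["avicel"],
                aerosil_mass=row["aerosil"],
                eudragit_mass=row["eudragit"],
                vehicle_mass=vehicle_mass,
                vehicle_name=row["vehicle"],
                water_volume_per_20g=row["water"],
                compression_force=row["force"],
            )
        )
    return out


#: Powder-flow measurements (triplicate means) with the study's printed
#: flowability inference labels. flow_rate g/s, angle degrees, CI %.
FLOW_MEASUREMENTS = pd.DataFrame(
    [
        ("PMT-1", 6.86, 24.48, 16.17, "excellent", "fair"),
        ("PMT-2", 8.31, 21.77, 14.26, "excellent", "good"),
        ("F-1", 8.50, 20.77, 12.56, "excellent", "good"),
        ("F-2", 8.17, 22.94, 13.53, "excellent", "good"),
        ("F-3", 7.86, 22.79, 12.50, "excellent", "good"),
        ("F-4", 6.50, 26.82, 13.86, "excellent", "good"),
        ("F-5", 6.80, 23.39, 6.47, "excellent", "excellent"),
        ("F-6", 6.44, 24.84, 12.79, "excellent", "good"),
        ("F-7", 7.28, 24.11, 12.26, "excellent", "good"),
        ("F-8", 7.04, 24.51, 11.84, "excellent", "good"),
    ],
    columns=[
        "formulation_id", "flow_rate", "angle_of_repose", "carr_index",
        "angle_label", "ci_label",
    ],
)

#: Friability outcomes: % weight loss (NaN where tablets fractured and the
#: loss was not reported), fracture flag, published pass/fail verdict.
FRIABILITY_RESULTS = pd.DataFrame(
    [
        ("PMT-1", float("nan"), True, False),
        ("PMT-2", float("nan"), True, False),
        ("F-1", 0.00, False, True),
        ("F-2", 0.00, False, True),
        ("F-3", 0.08, False, True),
        ("F-4", 0.00, False, True),
        ("F-5", float("nan"), True, False),
        ("F-6", 0.00, False, True),
        ("F-7", 0.00, False, True),
        ("F-8", 0.00, False, True),
    ],
    columns=["formulation_id", "weight_loss", "fractured", "passed"],
)

#: Per-model R^2 / MPE scores and power-law exponent n as published, with
#: the study's best-fit-model call. NaN marks models not applied because of
#: fast drug release. (The underlying dissolution curves are unpublished, so
#: these scores cannot be recomputed; they are inputs for model *selection*.)
RELEASE_MODEL_SCORES = pd.DataFrame(
    [
        ("PMT-1", 0.923, 15.60, 0.997, 4.49, None, None, None, None, None, "first_order"),
        ("PMT-2", 0.907, 20.98, 0.996, 7.59, None, None, None, None, None, "first_order"),
        ("F-1", 0.982, 7.87, 0.940, 106.86, None, None, None, None, None, "zero_order"),
        ("F-2", 0.967, 57.16, 0.844, 261.29, None, None, None, None, None, "zero_order"),
        ("F-3", 0.958, 16.03, 0.881, 131.89, None, None, None, None, None, "zero_order"),
        ("F-4", 0.968, 12.49, 0.914, 254.73, None, None, None, None, None, "zero_order"),
        ("F-5", 0.969, 11.82, 0.702, 567.20, None, None, None, None, None, "zero_order"),
        ("F-6", 0.998, 4.74, 0.976, 22.65, 0.971, 20.63, 0.994, 5.07, 1.327, "zero_order"),
        ("F-7", 0.838, 43.18, 0.905, 37.43, 0.953, 17.72, 0.923, 19.48, 0.941, "higuchi"),
        ("F-8", 0.823, 50.84, 0.885, 45.09, 0.946, 20.18, 0.914, 21.76, 1.030, "higuchi"),
    ],
    columns=[
        "formulation_id",
        "zero_order_r2", "zero_order_mpe",
        "first_order_r2", "first_order_mpe",
        "higuchi_r2", "higuchi_mpe",
        "korsmeyer_peppas_r2", "korsmeyer_peppas_mpe", "korsmeyer_peppas_n",
        "best_model",
    ],
).astype({c: float for c in [
    "zero_order_r2", "zero_order_mpe", "first_order_r2", "first_order_mpe",
    "higuchi_r2", "higuchi_mpe", "korsmeyer_peppas_r2", "korsmeyer_peppas_mpe",
    "korsmeyer_peppas_n",
]})
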