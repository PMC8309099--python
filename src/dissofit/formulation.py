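"""Liquisolid / Liqui-Mass composition arithmetic.

A Liqui-Tablet dosage form is described by the masses (mg) of its
components: the API, a non-volatile liquid vehicle (Tween 80/20, Kolliphor
EL, ...), the carrier (Avicel PH-102, plus Eudragit RS PO when a matrix
retardant is included) and the coating material (Aerosil 300). Granulating
water is process metadata only — it evaporates during drying and is never
part of the dosage-form mass.

The central derived quantity is the liquid load factor

    Lf = (API mass + vehicle mass) / carrier mass,

the classical liquisolid ratio of liquid medication to carrier. Eudragit
RS PO is counted as part of the carrier here: it enters the wet mass
alongside Avicel and it is the only convention under which the study
compositions' printed Lf values and the 20:1 carrier-to-coating ratio are
internally consistent across all rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .exceptions import FormulationError

__all__ = [
    "Formulation",
    "COMPONENTS",
    "total_mass",
    "liquid_load_factor",
    "vehicle_percent",
    "component_percent",
    "carrier_coating_ratio",
    "infer_vehicle_mass",
    "derived_table",
]

COMPONENTS = ("api", "vehicle", "avicel", "eudragit", "aerosil")


@dataclass(frozen=True)
class Formulation:
    """Component masses (mg) of one dosage form.

    ``vehicle_name`` is empty for physical-mixture controls;
    ``water_volume_per_20g`` (mL granulating water per 20 g admixture) and
    ``compression_force`` (PSI) are process records and never enter any mass
    arithmetic.
    """

    formulation_id: str
    api_mass: float
    avicel_mass: float
    aerosil_mass: float
    eudragit_mass: float = 0.0
    vehicle_mass: float = 0.0
    vehicle_name: str = ""
    water_volume_per_20g: float = float("nan")
    compression_force: float = float("nan")

    def __post_init__(self) -> None:
        if self.api_mass <= 0:
            raise FormulationError(
                f"{self.formulation_id}: API mass must be > 0"
            )
        for name in ("avicel_mass", "aerosil_mass", "eudragit_mass", "vehicle_mass"):
            if getattr(self, name) < 0:
                raise FormulationError(f"{self.formulation_id}: {name} is negative")
        if self.carrier_mass <= 0:
            raise FormulationError(
                f"{self.formulation_id}: carrier mass (Avicel + Eudragit) must be > 0"
            )

    @property
    def carrier_mass(self) -> float:
        """Avicel plus Eudragit (both absorb the liquid medication)."""
        return self.avicel_mass + self.eudragit_mass

    def component_mass(self, component: str) -> float:
        try:
            return {
                "api": self.api_mass,
                "vehicle": self.vehicle_mass,
                "avicel": self.avicel_mass,
                "eudragit": self.eudragit_mass,
                "aerosil": self.aerosil_mass,
            }[component]
        except KeyError:
            raise ValueError(
                f"unknown component {component!r}; expected one of {COMPONENTS}"
            ) from None


def total_mass(f: Formulation) -> float:
    """Dosage-form mass (mg): API + vehicle + Avicel + Eudragit + Aerosil."""
    return f.api_mass + f.vehicle_mass + f.avicel_mass + f.eudragit_mass + f.aerosil_mass


def liquid_load_factor(f: Formulation) -> float:
    """Lf = liquid medication (API + vehicle) over carrier (Avicel + Eudragit)."""
    return (f.api_mass + f.vehicle_mass) / f.carrier_mass


def vehicle_percent(f: Formulation) -> float:
    """Liquid vehicle as % w/w of the dosage form."""
    return 100.0 * f.vehicle_mass / total_mass(f)


def component_percent(f: Formulation, component: str) -> float:
    """Any single component as % w/w of the dosage form."""
    return 100.0 * f.component_mass(component) / total_mass(f)


def carrier_coating_ratio(f: Formulation) -> float:
    """Carrier (Avicel + Eudragit) to coating (Aerosil) mass ratio."""
    if f.aerosil_mass <= 0:
        raise FormulationError(
            f"{f.formulation_id}: carrier:coating ratio undefined without coating"
        )
    return f.carrier_mass / f.aerosil_mass


def infer_vehicle_mass(
    total: float,
    api: float,
    avicel: float,
    eudragit: float,
    aerosil: float,
    formulation_id: str = "?",
) -> float:
    """Vehicle mass as total minus the named solids (inverse bookkeeping).

    Lets a composition table that prints only solids and the tablet total be
    turned into a full :class:`Formulation`.
    """
    vehicle = total - (api + avicel + eudragit + aerosil)
    if vehicle < 0:
        raise FormulationError(
            f"{formulation_id}: named solids exceed the stated total mass "
            f"by {-vehicle:g} mg"
        )
    return vehicle


def derived_table(formulations: Iterable[Formulation]) -> pd.DataFrame:
    """Composition report: one row per formulation with derived quantities.

    Percentages and ratios are rounded to 2 decimals at this reporting
    layer only; use the scalar functions for full precision.
    """
    rows = []
    for f in formulations:
        rows.append(
            {
                "formulation_id": f.formulation_id,
                "vehicle_name": f.vehicle_name or "-",
                "vehicle_pct_ww": round(vehicle_percent(f), 2),
                "liquid_load_factor": (
                    round(liquid_load_factor(f), 2) if f.vehicle_mass > 0 else float("nan")
                ),
                "eudragit_pct_ww": round(component_percent(f, "eudragit"), 2),
                "carrier_coating_ratio": round(carrier_coating_ratio(f), 2),
                "total_mass_mg": round(total_mass(f), 2),
            }
        )
    return pd.DataFrame(rows)
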