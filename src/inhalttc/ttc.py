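"""TTC derivation formulas and the tiered decision-tree assignment.

Three linear maps take a 5th-percentile no-observed-effect concentration
(mg/m3) to the published threshold expressions:

* air-concentration TTC (mg/m3) = P5 x dexp / uf_total
* body-dose NOEL (ug/kg-d)      = P5 x dexp x (vresp / bw) x 1000
* per-person TTC (ug/person-d)  = NOEL x bw / uf_total

The per-person formula is not printed anywhere explicitly; it is fixed by
requiring consistency between the paired mg/m3 and ug/person-d report
columns (equivalently: air TTC x vresp x 1000), and that identity is
enforced by tests to >= 10 significant digits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from inhalttc.constants import DerivationConstants

CramerClass = Literal["I", "II", "III", "none"]

#: Oral TTC thresholds (ug/day) per decision-tree tier.
KROES_GENOTOX_UG_DAY = 0.15
KROES_OP_CARBAMATE_UG_DAY = 18.0
KROES_CRAMER_UG_DAY: dict[str, float] = {"III": 90.0, "II": 540.0, "I": 1800.0}


def _require_nonnegative(value: float, name: str) -> None:
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value!r}")


def ttc_air_concentration(p5_mg_m3: float, constants: DerivationConstants | None = None) -> float:
    """Air-concentration TTC (mg/m3) from a 5th-percentile NOEC (mg/m3)."""
    constants = constants or DerivationConstants()
    _require_nonnegative(p5_mg_m3, "p5_mg_m3")
    return p5_mg_m3 * constants.dexp / constants.uf_total


def body_dose_noel(p5_mg_m3: float, constants: DerivationConstants | None = None) -> float:
    """Equivalent human body dose (ug/kg-d) from a 5th-percentile NOEC (mg/m3)."""
    constants = constants or DerivationConstants()
    _require_nonnegative(p5_mg_m3, "p5_mg_m3")
    return p5_mg_m3 * constants.dexp * (constants.vresp / constants.bw) * 1000.0


def ttc_person_day(noel_ug_kg_d: float, constants: DerivationConstants | None = None) -> float:
    """Per-person daily TTC (ug/person-d) from a body-dose NOEL (ug/kg-d)."""
    constants = constants or DerivationConstants()
    _require_nonnegative(noel_ug_kg_d, "noel_ug_kg_d")
    return noel_ug_kg_d * constants.bw / constants.uf_total


def air_conc_to_person_day(ttc_mg_m3: float, constants: DerivationConstants | None = None) -> float:
    """Convert an air-concentration TTC (mg/m3) to ug/person-d (x vresp x 1000)."""
    constants = constants or DerivationConstants()
    _require_nonnegative(ttc_mg_m3, "ttc_mg_m3")
    return ttc_mg_m3 * constants.vresp * 1000.0


@dataclass(frozen=True)
class TTCResult:
    """One derived TTC row: group label, group size and the three expressions."""

    group: str
    n_chemicals: int
    p5_mg_m3: float
    ttc_mg_m3: float
    noel_ug_kg_d: float
    ttc_ug_person_d: float
    constants: DerivationConstants = field(default_factory=DerivationConstants)
    insufficient_n: bool = False


def derive_ttc(
    group: str,
    n_chemicals: int,
    p5_mg_m3: float,
    constants: DerivationConstants | None = None,
    min_n: int = 20,
) -> TTCResult:
    """Run the full derivation chain from a 5th percentile in mg/m3.

    Groups with fewer than ``min_n`` chemicals are still computed but
    tagged ``insufficient_n`` so reports can flag them.
    """
    constants = constants or DerivationConstants()
    noel = body_dose_noel(p5_mg_m3, constants)
    return TTCResult(
        group=group,
        n_chemicals=n_chemicals,
        p5_mg_m3=p5_mg_m3,
        ttc_mg_m3=ttc_air_concentration(p5_mg_m3, constants),
        noel_ug_kg_d=noel,
        ttc_ug_person_d=ttc_person_day(noel, constants),
        constants=constants,
        insufficient_n=n_chemicals < min_n,
    )


@dataclass(frozen=True)
class KroesFlags:
    """Per-substance flags feeding the tiered decision tree."""

    excluded_class: bool = False
    cohort_of_concern: bool = False
    genotox_alert: bool = False
    organophosphate: bool = False
    carbamate: bool = False
    steroid: bool = False
    cramer_class: CramerClass = "none"


def kroes_assign(flags: KroesFlags) -> tuple[str, float | str]:
    """Tiered decision-tree assignment to an oral TTC threshold.

    Tier order: exclusions (inorganics, polymers, bioaccumulatives, ...)
    and the cohort of concern exclude a substance entirely; a genotoxicity
    alert outside the cohort gets the most conservative 0.15 ug/day;
    organophosphates/carbamates get 18 ug/day; otherwise the Cramer class
    thresholds apply (III: 90, II: 540, I: 1800 ug/day).  Steroids fall
    in the cohort of concern.

    Returns ``(category label, ug/day value)`` or ``(label, "excluded")``
    / ``("not assigned", "not assigned")``.  Total over the flag lattice:
    never raises on any flag combination.
    """
    if flags.excluded_class:
        return ("excluded class", "excluded")
    if flags.cohort_of_concern or flags.steroid:
        return ("cohort of concern", "excluded")
    if flags.genotox_alert:
        return ("genotoxic alert", KROES_GENOTOX_UG_DAY)
    if flags.organophosphate or flags.carbamate:
        return ("OP/carbamate", KROES_OP_CARBAMATE_UG_DAY)
    if flags.cramer_class in KROES_CRAMER_UG_DAY:
        return (f"Cramer {flags.cramer_class}", KROES_CRAMER_UG_DAY[flags.cramer_class])
    return ("not assigned", "not assigned")
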