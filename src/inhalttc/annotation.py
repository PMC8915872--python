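"""Annotation and extraction of relevant inhalation study records.

Raw study rows (free-text study types, mixed units, species name variants)
are turned into filtered, unit-standardized, study-length-annotated
records.  Every stage produces a new table plus an attrition log; nothing
is dropped silently.
"""

from __future__ import annotations

import re
from typing import Mapping

import numpy as np
import pandas as pd

from inhalttc.constants import MOLAR_VOLUME_L_MOL

#: Days per week / per month used when converting reported durations.
#: 30.44 is the mean Gregorian month length; configurable.
DAYS_PER_WEEK = 7.0
DAYS_PER_MONTH = 30.44

#: Duration thresholds (days).  Chronic strictly > 100; subchronic in
#: [35, 100); subacute < 35.  Exactly 100 days is deliberately
#: unclassified by duration alone.
CHRONIC_MIN_DAYS = 100.0
SUBCHRONIC_MIN_DAYS = 35.0

STUDY_LENGTHS = (
    "subacute",
    "subchronic",
    "chronic",
    "reproductive",
    "developmental",
    "multigenerational",
)

#: Case-insensitive substring tokens matched against the free-text
#: study_type column.  Reproductive-family labels come ONLY from here,
#: never from duration.
DEFAULT_STUDY_TYPE_TOKENS: dict[str, tuple[str, ...]] = {
    "multigenerational": ("multigen", "multi-gen", "generation"),
    "developmental": ("develop",),
    "reproductive": ("reproduct",),
    "subchronic": ("subchronic", "sub-chronic"),
    "chronic": ("chronic",),
    "subacute": ("subacute", "sub-acute", "short-term", "short term"),
}

REPEAT_DOSE_TOKENS = ("repeat",)

#: Identity factors by default: the duration-adjusted columns exist but
#: no extrapolation is applied unless factors are configured explicitly.
DEFAULT_DURATION_FACTORS: dict[str, float] = {label: 1.0 for label in STUDY_LENGTHS}
DEFAULT_DURATION_FACTORS["unclassified"] = 1.0

_RODENT_TOKENS = ("rat", "mouse", "mice", "rabbit")
_NOEC_PATTERN = re.compile(r"^NO\(?A?\)?E[LC]$")


class UnrecognizedUnitError(ValueError):
    """Raised for a toxicity-value unit outside the recognized vocabulary."""


class ConfigurationError(ValueError):
    pass


def _canonical_unit(unit: str) -> str:
    u = unit.strip().lower().replace("µ", "u").replace("^", "").replace(" ", "")
    u = u.replace("m**3", "m3")
    return u


def duration_to_days(value: float | None, units: str | None) -> float | None:
    """Convert a reported study duration to days; None when unconvertible."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if value < 0:
        raise ValueError(f"negative study duration: {value!r}")
    if units is None or (isinstance(units, float) and np.isnan(units)):
        return None
    u = str(units).strip().lower().rstrip(".")
    if u in ("day", "days", "d"):
        return float(value)
    if u in ("week", "weeks", "wk", "wks", "w"):
        return float(value) * DAYS_PER_WEEK
    if u in ("month", "months", "mo", "mos", "m"):
        return float(value) * DAYS_PER_MONTH
    return None


def classify_study_length(
    study_type: str | None,
    duration_value: float | None = None,
    duration_units: str | None = None,
    tokens: Mapping[str, tuple[str, ...]] | None = None,
) -> str:
    """Assign a study-length label from study type text and/or duration.

    Token matches on the study_type text dominate; otherwise duration
    decides: > 100 days chronic, [35, 100) subchronic, < 35 subacute.
    Returns "unclassified" when neither decides (including exactly
    100 days, which the two duration rules leave uncovered).
    """
    tokens = tokens or DEFAULT_STUDY_TYPE_TOKENS
    text = (study_type or "").lower()

    for label in ("multigenerational", "developmental", "reproductive", "subchronic"):
        if any(tok in text for tok in tokens.get(label, ())):
            return label
    # "subchronic" contains "chronic": mask it before the chronic check
    masked = text.replace("subchronic", "").replace("sub-chronic", "")
    if any(tok in masked for tok in tokens.get("chronic", ())):
        return "chronic"
    if any(tok in text for tok in tokens.get("subacute", ())):
        return "subacute"

    days = duration_to_days(duration_value, duration_units)
    if days is None:
        return "unclassified"
    if days > CHRONIC_MIN_DAYS:
        return "chronic"
    if SUBCHRONIC_MIN_DAYS <= days < CHRONIC_MIN_DAYS:
        return "subchronic"
    if days < SUBCHRONIC_MIN_DAYS:
        return "subacute"
    return "unclassified"  # exactly 100 days


def standardize_units(
    value: float,
    unit: str,
    mw: float | None = None,
    molar_volume: float = MOLAR_VOLUME_L_MOL,
) -> tuple[float | None, float | None]:
    """Express a toxicity value on both the mg/m3 and ppm tracks.

    mg/m3 track: g/m3 x1000, ug/m3 /1000, mg/L identity, ppm x MW / 24.45
    (only with a known molecular weight).  ppm track: the reverse.  A
    missing MW leaves the inconvertible track as None — never guessed.
    """
    if not np.isfinite(value):
        raise ValueError(f"toxicity value must be finite, got {value!r}")
    u = _canonical_unit(unit)
    to_mg_m3 = {"mg/m3": 1.0, "mg/l": 1.0, "g/m3": 1000.0, "ug/m3": 1e-3}
    if u == "ppm":
        ppm = float(value)
        mg_m3 = ppm * mw / molar_volume if mw is not None else None
        return mg_m3, ppm
    if u in to_mg_m3:
        mg_m3 = float(value) * to_mg_m3[u]
        ppm = mg_m3 * molar_volume / mw if mw is not None else None
        return mg_m3, ppm
    raise UnrecognizedUnitError(f"unrecognized toxicity unit: {unit!r}")


def normalize_species(species: str | None) -> str:
    """Map free-text species to "rodent" (rat/mouse/rabbit incl. partial
    strain names, case-insensitive) or "other"."""
    text = (species or "").lower()
    if any(tok in text for tok in _RODENT_TOKENS):
        return "rodent"
    return "other"


def remove_ambiguous(records: pd.DataFrame, value_col: str = "toxval_numeric") -> tuple[pd.DataFrame, int]:
    """Drop rows whose toxicity value is exactly 0 or -999; return count removed."""
    mask = records[value_col].isin([0, -999])
    n_removed = int(mask.sum())
    return records.loc[~mask].copy(), n_removed


def adjust_for_duration(
    value: float,
    study_length: str,
    factors: Mapping[str, float] | None = None,
) -> float:
    """Multiply a value by the configured study-length adjustment factor.

    The default factor table is all 1.0: the adjusted columns exist but
    the magnitude of any time extrapolation is configuration, not a fact.
    """
    factors = factors if factors is not None else DEFAULT_DURATION_FACTORS
    if study_length not in factors:
        raise ConfigurationError(f"no duration factor configured for {study_length!r}")
    return value * factors[study_length]


def is_noec_type(toxval_type: str | None) -> bool:
    """True for NO(A)EL / NO(A)EC point-of-departure types (LOAEL etc. excluded)."""
    t = (toxval_type or "").strip().upper().replace(" ", "")
    return bool(_NOEC_PATTERN.match(t))


def annotate_studies(
    records: pd.DataFrame,
    substances: pd.DataFrame,
    duration_factors: Mapping[str, float] | None = None,
    study_type_tokens: Mapping[str, tuple[str, ...]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate raw study records with length, species group and unit tracks.

    ``substances`` must carry ``substance_id`` and ``mw`` columns (mw may
    be missing).  Returns ``(annotated, rejects)``; rejects holds rows
    with unrecognized units or invalid durations plus a ``reject_reason``
    column.  The input table is never mutated.
    """
    mw_map = substances.set_index("substance_id")["mw"].to_dict()
    out_rows: list[dict] = []
    reject_rows: list[dict] = []
    for _, row in records.iterrows():
        rec = row.to_dict()
        mw = mw_map.get(rec.get("substance_id"))
        if mw is not None and (pd.isna(mw) or mw <= 0):
            mw = None
        try:
            days = duration_to_days(rec.get("study_duration_value"), rec.get("study_duration_units"))
        except ValueError as exc:
            rec["reject_reason"] = str(exc)
            reject_rows.append(rec)
            continue
        try:
            mg_m3, ppm = standardize_units(float(rec["toxval_numeric"]), str(rec["toxval_units"]), mw)
        except UnrecognizedUnitError as exc:
            rec["reject_reason"] = str(exc)
            reject_rows.append(rec)
            continue
        length = classify_study_length(
            rec.get("study_type"),
            rec.get("study_duration_value"),
            rec.get("study_duration_units"),
            tokens=study_type_tokens,
        )
        rec["study_length"] = length
        rec["duration_days"] = days
        rec["species_group"] = normalize_species(rec.get("species"))
        rec["value_mg_m3"] = mg_m3
        rec["value_ppm"] = ppm
        rec["value_mg_m3_adjusted"] = (
            adjust_for_duration(mg_m3, length, duration_factors) if mg_m3 is not None else None
        )
        rec["value_ppm_adjusted"] = (
            adjust_for_duration(ppm, length, duration_factors) if ppm is not None else None
        )
        out_rows.append(rec)
    annotated = pd.DataFrame(out_rows)
    rejects = pd.DataFrame(reject_rows)
    return annotated, rejects


def filter_relevant(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep rows passing all four relevance criteria; report attrition.

    (a) study length classified (or an unclassified repeat-dose row,
    kept and counted separately); (b) inhalation exposure route;
    (c) NO(A)EL / NO(A)EC toxval type; (d) rodent species.  Criteria are
    evaluated as independent masks, so application order cannot matter.
    """
    length_ok = records["study_length"].isin(STUDY_LENGTHS)
    repeat_unclassified = (~length_ok) & records["study_type"].fillna("").str.lower().str.contains(
        "|".join(REPEAT_DOSE_TOKENS)
    )
    crit_a = length_ok | repeat_unclassified
    crit_b = records["exposure_route"].fillna("").str.lower().str.contains("inhal")
    crit_c = records["toxval_type"].map(is_noec_type)
    crit_d = records["species_group"] == "rodent"
    keep = crit_a & crit_b & crit_c & crit_d

    n = len(records)
    attrition = pd.DataFrame(
        [
            ("input", n),
            ("fail_study_length", int((~crit_a).sum())),
            ("fail_route", int((~crit_b).sum())),
            ("fail_toxval_type", int((~crit_c).sum())),
            ("fail_species", int((~crit_d).sum())),
            ("kept_unclassified_repeat_dose", int((repeat_unclassified & keep).sum())),
            ("kept", int(keep.sum())),
            ("dropped", int((~keep).sum())),
        ],
        columns=["stage", "count"],
    )
    return records.loc[keep].copy(), attrition
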