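"""Synthetic study-record generator with known ground truth.

Emulates the statistical shape of an aggregated toxicity-value extract:
per-substance molecular weight and category label, three mode-of-action
profiler outcomes with a controllable disagreement rate, and multiple
study records per substance with lognormal no-observed-effect
concentrations expressed in mixed units, free-text study types, duration
spelling variants, species name variants, injected ambiguous values
(0 / -999) and injected extreme outliers.

Truth (true category, true MOA, outlier/ambiguous flags, true mg/m3
value, analytic category quantiles) is written to sidecar tables only —
never to the pipeline-facing tables — so downstream stages can be tested
without leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from inhalttc.constants import MOLAR_VOLUME_L_MOL

UNITS = ("ppm", "mg/m3", "mg/L", "g/m3", "ug/m3")
_UNIT_FROM_MG_M3 = {"mg/m3": 1.0, "mg/L": 1.0, "g/m3": 1e-3, "ug/m3": 1e3}

_RODENT_NAMES = (
    "Rat", "rat", "Rats", "Sprague-Dawley rat", "Wistar rat", "Mouse",
    "mice", "B6C3F1 mouse", "Rabbit", "rabbits", "New Zealand rabbit",
)
_NON_RODENT_NAMES = ("dog", "Beagle dog", "monkey", "guinea pig", "cat")

_STUDY_TYPE_TEMPLATES = {
    "chronic": ("chronic", "chronic toxicity", "combined chronic/carcinogenicity"),
    "subchronic": ("subchronic", "subchronic toxicity", "90-day subchronic"),
    "subacute": ("subacute", "repeat dose", "short-term repeat dose"),
    "reproductive": ("reproduction", "reproductive toxicity"),
    "developmental": ("developmental", "developmental toxicity"),
}
# duration ranges in days per study-length class
_DURATION_DAYS = {
    "chronic": (105.0, 730.0),
    "subchronic": (35.0, 99.0),
    "subacute": (5.0, 34.0),
    "reproductive": (14.0, 120.0),
    "developmental": (10.0, 60.0),
}
_TOXVAL_TYPES = ("NOAEC", "NOAEL", "NOEC", "NOEL")
_SOURCES = ("source_A", "source_B", "source_C")

PROFILER_COLS = ("verhaar_toxtree", "verhaar_toolbox", "oasis_moa")


class SyntheticConfigError(ValueError):
    """A configuration field failed validation."""


@dataclass(frozen=True)
class SyntheticConfig:
    n_substances: int = 100
    #: category label -> (log10 mean of NOEC in mg/m3, log10 sd)
    category_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"baseline": (-0.3, 0.5), "reactive": (-1.0, 0.5)}
    )
    #: {"kind": "fixed", "n": k} | {"kind": "uniform", "min": a, "max": b}
    #: | {"kind": "geometric", "mean": m} (truncated at >= 1)
    studies_per_substance: Mapping[str, float | int | str] = field(
        default_factory=lambda: {"kind": "geometric", "mean": 6.0}
    )
    unit_mix: Mapping[str, float] = field(
        default_factory=lambda: {"ppm": 0.35, "mg/m3": 0.35, "mg/L": 0.1, "g/m3": 0.1, "ug/m3": 0.1}
    )
    outlier_rate: float = 0.0
    outlier_multiplier: float = 4.0  # log10 offset applied to injected outliers
    ambiguous_rate: float = 0.0
    profiler_disagreement_rate: float = 0.0
    non_rodent_rate: float = 0.05
    mw_range: tuple[float, float] = (30.0, 400.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_substances < 0:
            raise SyntheticConfigError(f"n_substances must be >= 0, got {self.n_substances}")
        for name in ("outlier_rate", "ambiguous_rate", "profiler_disagreement_rate", "non_rodent_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SyntheticConfigError(f"{name} must be in [0, 1], got {v}")
        for label, (_, sd) in self.category_params.items():
            if sd <= 0:
                raise SyntheticConfigError(f"category_params[{label!r}] sd must be > 0, got {sd}")
        if not self.category_params:
            raise SyntheticConfigError("category_params must be non-empty")
        lo, hi = self.mw_range
        if not 0 < lo <= hi:
            raise SyntheticConfigError(f"mw_range must satisfy 0 < min <= max, got {self.mw_range}")
        units = set(self.unit_mix)
        if not units <= set(UNITS):
            raise SyntheticConfigError(f"unit_mix has unknown unit(s): {sorted(units - set(UNITS))}")
        spec = dict(self.studies_per_substance)
        if spec.get("kind") not in ("fixed", "uniform", "geometric"):
            raise SyntheticConfigError(f"studies_per_substance kind invalid: {spec.get('kind')!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truths of the generating process, for parameter-recovery tests."""

    category_params: dict[str, tuple[float, float]]

    def analytic_percentile(self, category: str, p: float = 5.0) -> float:
        """Quantile of the generating lognormal: 10^(m + z_p * s) on log10 scale."""
        m, s = self.category_params[category]
        return float(10 ** (m + stats.norm.ppf(p / 100.0) * s))


def _draw_n_studies(spec: Mapping, rng: np.random.Generator) -> int:
    kind = spec["kind"]
    if kind == "fixed":
        return int(spec["n"])
    if kind == "uniform":
        return int(rng.integers(int(spec["min"]), int(spec["max"]) + 1))
    # truncated geometric with the requested mean: support {1, 2, ...}
    mean = float(spec["mean"])
    return int(rng.geometric(1.0 / mean)) if mean > 1 else 1


def generate_substances(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the per-substance table (identity, MW, category, profiler outcomes).

    Each of the three profiler outcome columns equals the substance's
    true category with probability 1 - disagreement_rate, else a random
    other category label.
    """
    rng = np.random.default_rng(config.seed)
    labels = sorted(config.category_params)
    rows = []
    for i in range(config.n_substances):
        true_cat = labels[rng.integers(len(labels))]
        mw = float(rng.uniform(*config.mw_range))
        outcomes = {}
        for col in PROFILER_COLS:
            if len(labels) > 1 and rng.random() < config.profiler_disagreement_rate:
                others = [l for l in labels if l != true_cat]
                outcomes[col] = others[rng.integers(len(others))]
            else:
                outcomes[col] = true_cat
        rows.append(
            {
                "substance_id": f"S{i:05d}",
                "name": f"substance-{i:05d}",
                "casrn": f"{100000 + i}-00-{i % 10}",
                "mw": round(mw, 4),
                "category": true_cat,
                **outcomes,
            }
        )
    cols = ["substance_id", "name", "casrn", "mw", "category", *PROFILER_COLS]
    return pd.DataFrame(rows, columns=cols)


def generate_studies(
    substances: pd.DataFrame, config: SyntheticConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate study records plus a sidecar truth table.

    Returns ``(studies, truth)``.  The studies table carries only
    pipeline-facing columns; truth carries record_id, true_mg_m3,
    is_outlier, is_ambiguous and the true category.
    """
    if substances.empty:
        raise ValueError("substances must be non-empty")
    rng = np.random.default_rng(config.seed + 1)
    unit_labels = list(config.unit_mix)
    unit_probs = np.asarray([config.unit_mix[u] for u in unit_labels], dtype=float)
    unit_probs = unit_probs / unit_probs.sum()

    study_rows: list[dict] = []
    truth_rows: list[dict] = []
    rec = 0
    for _, sub in substances.iterrows():
        m, s = config.category_params[sub["category"]]
        k = _draw_n_studies(dict(config.studies_per_substance), rng)
        for _ in range(k):
            true_mg_m3 = float(10 ** rng.normal(m, s))
            is_outlier = bool(rng.random() < config.outlier_rate)
            value_mg_m3 = true_mg_m3 * 10**config.outlier_multiplier if is_outlier else true_mg_m3

            length = ("chronic", "subchronic", "subacute", "reproductive", "developmental")[
                rng.integers(5)
            ]
            templates = _STUDY_TYPE_TEMPLATES[length]
            study_type = templates[rng.integers(len(templates))]
            lo, hi = _DURATION_DAYS[length]
            days = float(rng.uniform(lo, hi))
            unit_choice = ("days", "weeks", "months")[rng.integers(3)]
            if unit_choice == "days":
                dur_val, dur_units = round(days), ("days", "day", "Days")[rng.integers(3)]
            elif unit_choice == "weeks":
                dur_val, dur_units = round(days / 7.0, 1), ("weeks", "week", "wks")[rng.integers(3)]
            else:
                dur_val, dur_units = round(days / 30.44, 1), ("months", "month", "mo")[rng.integers(3)]

            unit = unit_labels[rng.choice(len(unit_labels), p=unit_probs)]
            mw = sub["mw"]
            if unit == "ppm" and (mw is None or pd.isna(mw)):
                unit = "mg/m3"  # never emit an inconvertible ppm row
            if unit == "ppm":
                value = value_mg_m3 * MOLAR_VOLUME_L_MOL / float(mw)
            else:
                value = value_mg_m3 * _UNIT_FROM_MG_M3[unit]

            is_ambiguous = bool(rng.random() < config.ambiguous_rate)
            if is_ambiguous:
                value = 0.0 if rng.random() < 0.5 else -999.0

            if rng.random() < config.non_rodent_rate:
                species = _NON_RODENT_NAMES[rng.integers(len(_NON_RODENT_NAMES))]
            else:
                species = _RODENT_NAMES[rng.integers(len(_RODENT_NAMES))]

            record_id = f"R{rec:07d}"
            rec += 1
            study_rows.append(
                {
                    "record_id": record_id,
                    "substance_id": sub["substance_id"],
                    "name": sub["name"],
                    "study_type": study_type,
                    "study_duration_value": dur_val,
                    "study_duration_units": dur_units,
                    "exposure_route": "inhalation",
                    "toxval_type": _TOXVAL_TYPES[rng.integers(len(_TOXVAL_TYPES))],
                    "toxval_numeric": value,
                    "toxval_units": unit,
                    "species": species,
                    "source": _SOURCES[rng.integers(len(_SOURCES))],
                }
            )
            truth_rows.append(
                {
                    "record_id": record_id,
                    "substance_id": sub["substance_id"],
                    "true_category": sub["category"],
                    "true_mg_m3": true_mg_m3,
                    "is_outlier": is_outlier,
                    "is_ambiguous": is_ambiguous,
                }
            )
    return pd.DataFrame(study_rows), pd.DataFrame(truth_rows)


def generate_dataset(config: SyntheticConfig) -> dict[str, pd.DataFrame | GroundTruth]:
    """Generate substances, studies and truth in one call."""
    substances = generate_substances(config)
    if substances.empty:
        studies = pd.DataFrame()
        truth = pd.DataFrame()
    else:
        studies, truth = generate_studies(substances, config)
    return {
        "substances": substances.drop(columns=["category"]),
        "substances_truth": substances[["substance_id", "category"]].rename(
            columns={"category": "true_category"}
        ),
        "studies": studies,
        "studies_truth": truth,
        "ground_truth": GroundTruth(dict(config.category_params)),
    }


def write_dataset(dataset: Mapping[str, pd.DataFrame | GroundTruth], outdir: str | Path) -> None:
    """Write the pipeline-facing and sidecar tables as UTF-8 TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key in ("substances", "studies", "substances_truth", "studies_truth"):
        df = dataset[key]
        assert isinstance(df, pd.DataFrame)
        df.to_csv(outdir / f"{key}.tsv", sep="\t", index=False)
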