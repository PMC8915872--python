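"""Cross-dataset verification of derived TTC values.

Re-derives class-wise TTC values from external supplementary-style tables
(local NOAEC in mg/m3 plus systemic NOAEL in mg/kg-day, or
local/systemic/general NOEC in ppm), and compares datasets by identifier
overlap, log-scale Pearson correlation and Welch t-tests.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from inhalttc.constants import DerivationConstants
from inhalttc.dist_stats import empirical_percentile
from inhalttc.ttc import TTCResult, derive_ttc

logger = logging.getLogger(__name__)

CARTHEW_COLUMNS = {
    "local": "Local NOAEC (mg/m^3)",
    "systemic": "Systemic NOAEL (mg/kg/day)",
}
ESCHER_COLUMNS = {
    "local": "Local_NOEC_ppm",
    "systemic": "Systemic_NOEC_ppm",
    "general": "General_NOEC_ppm",
}


def carthew_systemic_to_air(
    noael_mg_kg_d: float, constants: DerivationConstants | None = None
) -> float:
    """Convert a systemic NOAEL (mg/kg-day) to an air concentration (mg/m3).

    Default conversion is the exact inverse of the body-dose formula
    solved for concentration: C = dose x bw / (dexp x vresp).
    """
    constants = constants or DerivationConstants()
    if noael_mg_kg_d < 0:
        raise ValueError(f"NOAEL must be >= 0, got {noael_mg_kg_d!r}")
    return noael_mg_kg_d * constants.bw / (constants.dexp * constants.vresp)


def ppm_to_mg_m3(value_ppm: float, mw: float, constants: DerivationConstants | None = None) -> float:
    constants = constants or DerivationConstants()
    return value_ppm * mw / constants.molar_volume


def rederive_ttc(
    rows: pd.DataFrame,
    endpoint_col: str,
    constants: DerivationConstants | None = None,
    class_col: str = "cramer_class",
    units: str = "mg/m3",
    mw_col: str = "mw",
) -> list[TTCResult]:
    """Class-wise 5th percentile and TTC chain from an external dataset.

    Values of exactly 0 are dropped with a note.  ppm-unit datasets are
    converted to mg/m3 per-chemical via molecular weight; rows lacking MW
    are excluded from the mg/m3 derivation (and counted in the log).
    mg/kg-day endpoints are first converted to air concentrations.
    Classes with fewer than 2 usable values are reported with the
    percentile suppressed (omitted from the result list).
    """
    constants = constants or DerivationConstants()
    results: list[TTCResult] = []
    for cls, group in rows.groupby(class_col, sort=True):
        vals = group[endpoint_col].astype(float)
        mask = vals.notna()
        n_zero = int((vals == 0).sum())
        if n_zero:
            logger.info("class %s: dropped %d zero value(s) before percentile", cls, n_zero)
        mask &= vals > 0
        if units == "ppm":
            mw = group[mw_col].astype(float)
            no_mw = int((mask & mw.isna()).sum())
            if no_mw:
                logger.info("class %s: %d row(s) lack MW, excluded from mg/m3 track", cls, no_mw)
            mask &= mw.notna() & (mw > 0)
            values_mg_m3 = (vals[mask] * mw[mask] / constants.molar_volume).to_numpy()
        elif units == "mg/kg/day":
            values_mg_m3 = np.array(
                [carthew_systemic_to_air(v, constants) for v in vals[mask]]
            )
        elif units == "mg/m3":
            values_mg_m3 = vals[mask].to_numpy()
        else:
            raise ValueError(f"unsupported units {units!r}")
        if values_mg_m3.size < 2:
            logger.warning("class %s: only %d usable value(s); percentile suppressed", cls, values_mg_m3.size)
            continue
        p5 = empirical_percentile(values_mg_m3, 5.0, group=str(cls)).value
        results.append(derive_ttc(str(cls), int(values_mg_m3.size), p5, constants))
    return results


def overlap_by_id(
    ids_a: Sequence[str], ids_b: Sequence[str]
) -> tuple[set[str], set[str], set[str]]:
    """Exact-match identifier overlap: (intersection, a_only, b_only).

    Duplicate identifiers within a dataset are deduplicated with a warning.
    """
    list_a, list_b = list(ids_a), list(ids_b)
    set_a, set_b = set(list_a), set(list_b)
    if len(set_a) < len(list_a):
        logger.warning("dataset A: %d duplicate identifier(s) deduplicated", len(list_a) - len(set_a))
    if len(set_b) < len(list_b):
        logger.warning("dataset B: %d duplicate identifier(s) deduplicated", len(list_b) - len(set_b))
    return set_a & set_b, set_a - set_b, set_b - set_a


def log_pearson(x_values: Sequence[float], y_values: Sequence[float]) -> float:
    """Pearson correlation of log10-transformed paired values.

    Pairs with a non-positive member are excluded (and counted in the log).
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    ok = (x > 0) & (y > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("log_pearson: excluded %d pair(s) with non-positive value", n_dropped)
    if ok.sum() < 3:
        raise ValueError("need at least 3 valid pairs")
    r, _ = stats.pearsonr(np.log10(x[ok]), np.log10(y[ok]))
    return float(r)


def welch_t(
    x_values: Sequence[float],
    y_values: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sample t-test on log10 values (Welch by default)."""
    x = np.log10(np.asarray(x_values, dtype=float))
    y = np.log10(np.asarray(y_values, dtype=float))
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need n >= 2")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.isclose(x.mean(), y.mean()):
            return 0.0, 1.0
        raise ValueError("zero variance in both samples: t undefined")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)
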