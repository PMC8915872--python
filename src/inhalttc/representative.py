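"""Collapse per-substance studies to one representative value.

Singletons are retained untouched; otherwise extreme outliers beyond the
Tukey fences (1.5 x IQR) are removed in a single pass and the minimum of
the survivors is returned, independently per unit track.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence
import warnings

import numpy as np
import pandas as pd

QuartileMethod = Literal["linear", "nearest"]


@dataclass(frozen=True)
class RepresentativeValue:
    substance_id: str
    unit_track: str
    value: float
    n_studies: int
    n_outliers_removed: int


def tukey_fences(
    values: Sequence[float],
    quartile_method: QuartileMethod = "linear",
    two_sided: bool = True,
) -> tuple[list[float], list[float]]:
    """Split values into (surviving, removed) by the 1.5 x IQR fences.

    Fencing is on the raw scale.  Singleton inputs are returned as-is.
    Single pass: fences are computed once from the full input, never
    re-derived after removal.  If removal would empty the set the
    original values are returned with a warning.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("values must be non-empty")
    if any(v <= 0 for v in vals):
        raise ValueError("all values must be positive (clean upstream)")
    if len(vals) == 1:
        return vals, []

    arr = np.asarray(vals)
    method = "linear" if quartile_method == "linear" else "closest_observation"
    q1, q3 = np.quantile(arr, [0.25, 0.75], method=method)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    if two_sided:
        keep = (arr >= lo) & (arr <= hi)
    else:
        keep = arr <= hi
    if not keep.any():
        warnings.warn("Tukey fencing would remove every value; retaining all", stacklevel=2)
        return vals, []
    surviving = arr[keep].tolist()
    removed = arr[~keep].tolist()
    return surviving, removed


def select_representative(
    studies: pd.DataFrame,
    value_cols: dict[str, str] | None = None,
    substance_col: str = "substance_id",
    quartile_method: QuartileMethod = "linear",
    two_sided: bool = True,
) -> pd.DataFrame:
    """One representative (minimum surviving) value per substance and unit track.

    ``value_cols`` maps unit-track label -> column name; defaults to the
    annotation module's adjusted tracks.  Rows with a missing value on a
    track do not contribute to that track.
    """
    value_cols = value_cols or {
        "mg_m3": "value_mg_m3_adjusted",
        "ppm": "value_ppm_adjusted",
    }
    rows: list[RepresentativeValue] = []
    for substance_id, group in studies.groupby(substance_col, sort=True):
        for track, col in value_cols.items():
            vals = group[col].dropna().astype(float)
            vals = vals[vals > 0]
            if vals.empty:
                continue
            surviving, removed = tukey_fences(
                vals.tolist(), quartile_method=quartile_method, two_sided=two_sided
            )
            rows.append(
                RepresentativeValue(
                    substance_id=str(substance_id),
                    unit_track=track,
                    value=min(surviving),
                    n_studies=len(vals),
                    n_outliers_removed=len(removed),
                )
            )
    out = pd.DataFrame([r.__dict__ for r in rows])
    if out.empty:
        out = pd.DataFrame(
            columns=["substance_id", "unit_track", "value", "n_studies", "n_outliers_removed"]
        )
    out.attrs["quartile_method"] = quartile_method
    out.attrs["two_sided"] = two_sided
    return out
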