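"""Consensus of aquatic mode-of-action profiler outcomes.

Three rule-based profilers (Verhaar via two tools, plus an acute-MOA
scheme) each emit a raw label per substance.  Raw labels are mapped to a
canonical vocabulary through a config table, then combined: unanimity
wins, else majority, else the most conservative label under a configured
ordering.  Agreement between schemes is quantified with a confusion
matrix and precision/recall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_LABELS = (
    "unclassified",
    "baseline",
    "ester",
    "less_inert",
    "narcotic_amine",
    "phenol_aniline",
    "aldehyde",
    "ab_unsat_alcohol",
    "specifically_acting",
    "reactive",
)

#: Conservativeness ordering, least to most conservative.  "unclassified"
#: sits below baseline for consensus arithmetic; substances whose
#: consensus is unclassified are excluded from TTC groups downstream.
DEFAULT_CONSERVATIVENESS_ORDER: tuple[str, ...] = CANONICAL_LABELS

SCHEMES = ("verhaar_toxtree", "verhaar_toolbox", "oasis_moa")

#: Raw-label -> canonical mapping per scheme.  Matching is by lowercase
#: substring against the keys, checked in order; this tolerates the
#: free-text variants the profilers emit.
DEFAULT_MAPPING: dict[str, dict[str, str]] = {
    "verhaar_toxtree": {
        "class 1": "baseline",
        "class 2": "less_inert",
        "class 3": "reactive",
        "class 4": "specifically_acting",
        "class 5": "unclassified",
    },
    "verhaar_toolbox": {
        "class 1": "baseline",
        "class 2": "less_inert",
        "class 3": "reactive",
        "class 4": "specifically_acting",
        "class 5": "unclassified",
    },
    "oasis_moa": {
        "basesurface": "baseline",
        "base surface": "baseline",
        "baseline": "baseline",
        "narcotic amine": "narcotic_amine",
        "ester": "ester",
        "phenol": "phenol_aniline",
        "aniline": "phenol_aniline",
        "aldehyde": "aldehyde",
        "unsaturated alcohol": "ab_unsat_alcohol",
        "reactive": "reactive",
        "specific": "specifically_acting",
    },
}


@dataclass(frozen=True)
class ConsensusRecord:
    substance_id: str
    labels: tuple[str, ...]
    consensus: str
    rule_used: str  # unanimity | majority | conservative


def map_outcome(
    scheme: str,
    raw_label: str | None,
    mapping: Mapping[str, Mapping[str, str]] | None = None,
) -> str:
    """Map a profiler's raw label to the canonical vocabulary.

    Unknown raw labels (or unknown schemes) map to "unclassified" with a
    logged warning — never a crash.
    """
    mapping = mapping or DEFAULT_MAPPING
    if scheme not in mapping:
        logger.warning("unknown profiler scheme %r", scheme)
        return "unclassified"
    text = (raw_label or "").strip().lower()
    for key, canonical in mapping[scheme].items():
        if key in text:
            return canonical
    logger.warning("unknown raw label %r for scheme %r -> unclassified", raw_label, scheme)
    return "unclassified"


def consensus(
    labels: Sequence[str | None],
    ordering: Sequence[str] | None = None,
    substance_id: str = "",
) -> ConsensusRecord:
    """Combine up to three canonical labels into one consensus label.

    Unanimity of the present labels wins; else a strict majority; else
    the maximum under the conservativeness ordering.  Order of the input
    labels never matters.
    """
    ordering = list(ordering or DEFAULT_CONSERVATIVENESS_ORDER)
    present = sorted(l for l in labels if l)  # sort => permutation invariance
    if not present:
        raise ValueError("at least one label required for a consensus")
    unknown = set(present) - set(ordering)
    if unknown:
        raise ValueError(f"label(s) outside the configured ordering: {sorted(unknown)}")

    counts = pd.Series(present).value_counts()
    if len(counts) == 1:
        result, rule = present[0], "unanimity"
    elif counts.iloc[0] > len(present) / 2:
        result, rule = counts.index[0], "majority"
    else:
        result, rule = max(present, key=ordering.index), "conservative"
    return ConsensusRecord(
        substance_id=substance_id, labels=tuple(present), consensus=result, rule_used=rule
    )


def consensus_table(
    outcomes: pd.DataFrame,
    ordering: Sequence[str] | None = None,
    substance_col: str = "substance_id",
    scheme_cols: Sequence[str] = SCHEMES,
) -> pd.DataFrame:
    """Per-substance consensus over a wide table of canonical labels."""
    rows = []
    for _, row in outcomes.iterrows():
        labels = [row.get(c) for c in scheme_cols]
        labels = [l if isinstance(l, str) and l else None for l in labels]
        rec = consensus(labels, ordering=ordering, substance_id=str(row[substance_col]))
        rows.append(
            {substance_col: rec.substance_id, "consensus": rec.consensus, "rule_used": rec.rule_used}
        )
    return pd.DataFrame(rows)


def confusion_matrix(
    labels_a: pd.Series,
    labels_b: pd.Series,
) -> tuple[pd.DataFrame, int]:
    """Counts of scheme-a labels (rows) vs scheme-b labels (columns).

    Substances present in only one series are excluded; the number
    excluded is returned as a coverage count.  Row sums equal scheme-a
    marginal counts over the paired substances.
    """
    paired = pd.concat({"a": labels_a, "b": labels_b}, axis=1)
    n_unpaired = int(paired.isna().any(axis=1).sum())
    paired = paired.dropna()
    matrix = pd.crosstab(paired["a"], paired["b"])
    matrix.index.name = "scheme_a"
    matrix.columns.name = "scheme_b"
    return matrix, n_unpaired


def precision_recall(
    matrix: pd.DataFrame, target_label: str
) -> tuple[float | None, float | None]:
    """Precision and recall for one label, with columns (scheme b) as truth.

    precision = diagonal / row total (of predictions, scheme a);
    recall = diagonal / column total (of truth, scheme b).  An empty
    row/column makes the corresponding quantity undefined -> None.
    """
    tp = float(matrix.at[target_label, target_label]) if (
        target_label in matrix.index and target_label in matrix.columns
    ) else 0.0
    pred_total = float(matrix.loc[target_label].sum()) if target_label in matrix.index else 0.0
    truth_total = float(matrix[target_label].sum()) if target_label in matrix.columns else 0.0
    precision = tp / pred_total if pred_total > 0 else None
    recall = tp / truth_total if truth_total > 0 else None
    return precision, recall
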