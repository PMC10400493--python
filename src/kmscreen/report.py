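"""Cohort summary tables in the style of an integrated-database overview.

Every cohort gets one row (plus a pooled "entire database" row) with sample
counts, endpoint availability and mean ± SD follow-up, and per-category
percentage breakdowns in the "% (count)" convention.  Percentage denominators
exclude missing values field by field, so rows whose counts do not sum to the
cohort n indicate missing clinical data.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_ingest import CohortBundle, ValidationError

log = logging.getLogger("kmscreen")

_CATEGORY_FIELDS = {
    "histology": ["serous", "endometrioid", "clear cell", "other"],
    "stage": [1.0, 2.0, 3.0, 4.0],
    "grade": [1.0, 2.0, 3.0, 4.0],
    "debulking": ["suboptimal", "optimal"],
}


def percent_breakdown(counts: Mapping[object, int]) -> dict[object, float]:
    """Percentages over non-missing categories, to one decimal place.

    ``{"optimal": 802, "suboptimal": 536}`` -> ``{"optimal": 59.9, "suboptimal": 40.1}``.
    """
    total = sum(counts.values())
    if total == 0:
        return {k: float("nan") for k in counts}
    return {k: round(100.0 * v / total, 1) for k, v in counts.items()}


def _format_pct(counts: Mapping[object, int]) -> dict[object, str]:
    pcts = percent_breakdown(counts)
    return {k: f"{pcts[k]:.1f}% ({counts[k]})" for k in counts}


def _summarize_clinical(clin: pd.DataFrame, n_total_study: int) -> dict:
    n = len(clin)
    row: dict[str, object] = {"n": n, "pct_of_total": round(100.0 * n / n_total_study, 1)}
    for ep in ("os", "pfs"):
        t = clin[f"{ep}_time_months"]
        e = clin[f"{ep}_event"]
        avail = t.notna() & e.notna()
        row[f"{ep}_n"] = int(avail.sum())
        if avail.any():
            row[f"{ep}_followup_months"] = (
                f"{t[avail].mean():.1f} ± {t[avail].std(ddof=1):.1f}"
                if avail.sum() > 1
                else f"{t[avail].mean():.1f}"
            )
        else:
            row[f"{ep}_followup_months"] = ""
    for fld, cats in _CATEGORY_FIELDS.items():
        observed = clin[fld].dropna()
        counts = {c: int((observed == c).sum()) for c in cats}
        n_missing = n - len(observed)
        if n_missing:
            log.info("field %s: %d missing value(s) excluded from denominators", fld, n_missing)
        if len(observed) == 0:
            for c in cats:
                row[f"{fld}_{c}"] = ""
            continue
        formatted = _format_pct(counts)
        for c in cats:
            row[f"{fld}_{c}"] = formatted[c]
    return row


def cohort_summary(bundles: Sequence[CohortBundle]) -> pd.DataFrame:
    """Per-cohort and pooled summary rows, "% (count)" convention."""
    if not bundles:
        raise ValidationError("no cohorts to summarize")
    n_total = sum(b.n_samples for b in bundles)
    rows = {b.cohort_id: _summarize_clinical(b.clinical, n_total) for b in bundles}
    pooled = pd.concat([b.clinical for b in bundles])
    rows["Entire database"] = _summarize_clinical(pooled, n_total)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "cohort"
    return out
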