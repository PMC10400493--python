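"""Second-pass scaling normalization and rule-based array QC flagging.

Arrays arriving from different platforms are put on a common scale by
rescaling every sample so that its mean intensity *over the shared probe
panel* equals 1000; restricting the mean to the shared panel prevents the
larger platform's extra probes from shifting the scale.  QC applies simple
configurable thresholds to the standard array metrics (background, noise,
percent present calls, bioB spike, GAPDH/ACTB 3'/5' ratio).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_ingest import CohortBundle, ValidationError

log = logging.getLogger("kmscreen")

TARGET_MEAN = 1000.0

#: default QC thresholds; the checks follow standard Affymetrix practice and
#: every value can be overridden in the pipeline config.
DEFAULT_QC_THRESHOLDS: dict[str, object] = {
    "percent_present_calls_min": 25.0,
    "gapdh_actb_3to5_ratio_max": 3.0,
    "background_intensity_max": None,
    "noise_max": None,
    "require_bioB_spike": True,
}

_METRIC_FOR_KEY = {
    "percent_present_calls_min": ("percent_present_calls", "min"),
    "gapdh_actb_3to5_ratio_max": ("gapdh_actb_3to5_ratio", "max"),
    "background_intensity_max": ("background_intensity", "max"),
    "noise_max": ("noise", "max"),
    "require_bioB_spike": ("bioB_spike_present", "bool"),
}


@dataclass
class QCReport:
    """Per-sample QC metrics plus a pass/fail/unevaluable status with reasons."""

    metrics: pd.DataFrame
    status: pd.Series  # "pass" | "fail" | "unevaluable"
    reasons: pd.Series  # list of strings per sample

    def failed_samples(self) -> list[str]:
        return list(self.status.index[self.status == "fail"])


def scaling_normalize(
    bundle: CohortBundle, shared_probes: Iterable[str], target: float = TARGET_MEAN
) -> CohortBundle:
    """Rescale every sample so its mean over ``shared_probes`` equals ``target``.

    The per-sample factor ``f = target / mean(shared probes)`` multiplies *all*
    probes of that sample, so the whole array moves onto the common scale.
    The operation is idempotent and acts sample-by-sample.
    """
    shared = list(dict.fromkeys(shared_probes))
    missing = [p for p in shared if p not in bundle.expression.index]
    if missing:
        raise ValidationError(
            f"shared probes missing from cohort {bundle.cohort_id}: {missing[:5]}"
        )
    if not shared:
        raise ValidationError("shared probe set is empty")
    means = bundle.expression.loc[shared].mean(axis=0)
    factors = target / means
    expr = bundle.expression * factors  # broadcast over columns
    return CohortBundle(bundle.cohort_id, bundle.platform, expr, bundle.clinical)


def qc_flag(
    metrics: pd.DataFrame, thresholds: Mapping[str, object] | None = None
) -> QCReport:
    """Flag samples against configured thresholds.

    ``metrics`` is keyed by sample ID with any subset of the columns
    background_intensity, noise, percent_present_calls, bioB_spike_present,
    gapdh_actb_3to5_ratio; missing values are simply not checked.  Samples with
    every metric missing are "unevaluable", not failed.
    """
    config = dict(DEFAULT_QC_THRESHOLDS)
    for key, value in (thresholds or {}).items():
        if key not in _METRIC_FOR_KEY:
            raise ValidationError(f"unknown QC threshold {key!r}")
        config[key] = value

    known_cols = {m for m, _ in _METRIC_FOR_KEY.values()}
    unknown = set(metrics.columns) - known_cols
    if unknown:
        raise ValidationError(f"unknown QC metric column(s): {sorted(unknown)}")

    numeric_cols = [c for c in metrics.columns if c != "bioB_spike_present"]
    for c in numeric_cols:
        vals = pd.to_numeric(metrics[c], errors="raise")
        if np.any(vals.dropna() < 0):
            raise ValidationError(f"QC metric {c!r} has negative values")

    status = {}
    reasons = {}
    for sample, row in metrics.iterrows():
        if row.isna().all():
            status[sample] = "unevaluable"
            reasons[sample] = []
            continue
        fails: list[str] = []
        for key, (metric, kind) in _METRIC_FOR_KEY.items():
            limit = config[key]
            if limit in (None, False) or metric not in metrics.columns:
                continue
            value = row[metric]
            if pd.isna(value):
                continue
            if kind == "min" and value < limit:
                fails.append(f"{metric}={value} below {limit}")
            elif kind == "max" and value > limit:
                fails.append(f"{metric}={value} above {limit}")
            elif kind == "bool" and not bool(value):
                fails.append(f"{metric} absent")
        status[sample] = "fail" if fails else "pass"
        reasons[sample] = fails
        if fails:
            log.warning("QC fail for %s: %s", sample, "; ".join(fails))
    return QCReport(
        metrics=metrics,
        status=pd.Series(status, name="status"),
        reasons=pd.Series(reasons, name="reasons"),
    )
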