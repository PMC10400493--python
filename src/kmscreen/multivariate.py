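"""Multivariate Cox adjustment of a dichotomized gene for clinical covariates.

The gene enters as the binary high/low indicator at the cutoff selected by
the univariate screen; stage and grade enter as ordinal numerics, debulking
as binary (optimal=0, suboptimal=1), and any extra numeric columns attached
to the clinical table (e.g. precomputed immune-cell scores) enter as-is.
Complete-case analysis with the dropped count reported.  Fitting is done by
lifelines' CoxPHFitter (Efron tie handling, Newton-Raphson).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .io_ingest import CohortBundle, ValidationError

log = logging.getLogger("kmscreen")

CLINICAL_COVARIATES = {"stage", "grade", "debulking"}
_DEBULKING_CODE = {"optimal": 0.0, "suboptimal": 1.0}


@dataclass
class MultivariateResult:
    """Per-covariate estimates plus model-level diagnostics."""

    summary: pd.DataFrame  # index covariate; columns coef, hr, hr_lo, hr_hi, p
    n_used: int
    n_events: int
    log_likelihood: float
    converged: bool
    dropped_samples: int
    collinear_pairs: list[tuple[str, str]]

    def p_for(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])

    def hr_for(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def add_cell_scores(bundle: CohortBundle, scores: pd.DataFrame) -> CohortBundle:
    """Attach numeric per-sample covariate columns (e.g. cell-type scores).

    ``scores`` is keyed by sample ID; samples of the bundle absent from the
    table get missing values, extra rows are ignored with a logged count.
    """
    if scores.shape[0] == 0 or scores.shape[1] == 0:
        raise ValidationError("empty score table")
    overlap = bundle.clinical.index.intersection(scores.index)
    if len(overlap) == 0:
        raise ValidationError("no overlapping sample IDs between bundle and score table")
    extra = len(scores.index.difference(bundle.clinical.index))
    if extra:
        log.info("%d score-table sample(s) not in the bundle ignored", extra)
    clin = bundle.clinical.join(scores.apply(pd.to_numeric), how="left")
    return CohortBundle(bundle.cohort_id, bundle.platform, bundle.expression, clin)


def _design_matrix(
    bundle: CohortBundle, gene: str, cutoff: float, covariates: list[str], endpoint: str
) -> tuple[pd.DataFrame, int]:
    if gene not in bundle.expression.index:
        raise ValidationError(f"gene {gene!r} not in expression matrix")
    surv_cols = [f"{endpoint}_time_months", f"{endpoint}_event"]
    df = pd.DataFrame(index=bundle.expression.columns)
    df["time"] = bundle.clinical.loc[df.index, surv_cols[0]]
    df["event"] = bundle.clinical.loc[df.index, surv_cols[1]]
    df["gene_high"] = (bundle.expression.loc[gene] > cutoff).astype(float)
    for cov in covariates:
        if cov == "debulking":
            df[cov] = bundle.clinical.loc[df.index, "debulking"].map(_DEBULKING_CODE)
        elif cov in bundle.clinical.columns:
            df[cov] = pd.to_numeric(bundle.clinical.loc[df.index, cov])
        else:
            raise ValidationError(f"covariate {cov!r} not available")
    n_total = len(df)
    df = df.dropna()
    return df, n_total - len(df)


def _collinear_pairs(x: pd.DataFrame, cond_threshold: float = 1e8) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    cols = [c for c in x.columns if x[c].std() > 0]
    if len(cols) < 2:
        return pairs
    corr = x[cols].corr().abs()
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if corr.loc[a, b] > 1 - 1e-10:
                pairs.append((a, b))
    if not pairs:
        xs = (x[cols] - x[cols].mean()) / x[cols].std()
        if np.linalg.cond(xs.to_numpy()) > cond_threshold:
            pairs.append(("<design>", "<ill-conditioned>"))
    return pairs


def fit_multivariate(
    bundle: CohortBundle,
    gene: str,
    cutoff: float,
    covariates: list[str] | None = None,
    endpoint: str = "os",
    min_samples: int = 30,
) -> MultivariateResult:
    """Cox regression of survival on the dichotomized gene plus covariates.

    Default covariates are stage, grade and debulking; any numeric column
    previously attached with :func:`add_cell_scores` may be named as well.
    """
    covariates = list(covariates) if covariates is not None else ["stage", "grade", "debulking"]
    df, dropped = _design_matrix(bundle, gene, cutoff, covariates, endpoint)
    if len(df) < min_samples:
        raise ValidationError(
            f"only {len(df)} complete cases (< {min_samples}) for the multivariate model"
        )
    if df["event"].sum() == 0:
        raise ValidationError("no events among complete cases")
    if dropped:
        log.info("multivariate fit for %s: %d sample(s) dropped (missing covariates)", gene, dropped)

    design_cols = [c for c in df.columns if c not in ("time", "event")]
    pairs = _collinear_pairs(df[design_cols])
    for a, b in pairs:
        log.warning("collinear covariates: %s ~ %s", a, b)

    cpf = CoxPHFitter()
    converged = True
    try:
        cpf.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        log.warning("multivariate Cox did not converge: %s", exc)
        converged = False
        try:
            cpf.fit(
                df, duration_col="time", event_col="event",
                fit_options={"step_size": 0.1, "max_steps": 200},
            )
        except ConvergenceError:
            # flagged diagnostic result (e.g. a singular design)
            summary = pd.DataFrame(
                np.nan, index=pd.Index(design_cols, name="covariate"),
                columns=["coef", "hr", "hr_lo", "hr_hi", "p"],
            )
            return MultivariateResult(
                summary=summary,
                n_used=int(len(df)),
                n_events=int(df["event"].sum()),
                log_likelihood=float("nan"),
                converged=False,
                dropped_samples=int(dropped),
                collinear_pairs=pairs,
            )

    s = cpf.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "hr_lo": s["exp(coef) lower 95%"],
            "hr_hi": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    summary.index.name = "covariate"
    return MultivariateResult(
        summary=summary,
        n_used=int(len(df)),
        n_events=int(df["event"].sum()),
        log_likelihood=float(cpf.log_likelihood_),
        converged=converged,
        dropped_samples=int(dropped),
        collinear_pairs=pairs,
    )
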