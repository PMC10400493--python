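"""Univariate cutoff-scan survival screen.

For every gene the expression vector is dichotomized at every distinct
observed value lying between the lower and upper quartiles; each split is
tested with the two-group log-rank statistic; the Benjamini–Hochberg FDR is
computed across the gene's cutoff series; the cutoff with the lowest FDR is
selected (ties broken by the highest hazard ratio, then by the smallest
cutoff), and the hazard ratio of the high- vs low-expression group at the
selected cutoff is estimated by a univariate Cox fit with Efron tie handling.
Two study-level filters affect ranking only: a cutoff floor of 200 intensity
units (twice the ~100-unit array background) and a preference for risk-
direction genes (higher expression, worse prognosis).

Group convention throughout: low = {x <= c}, high = {x > c}; the hazard
ratio is high-vs-low.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_ingest import CohortBundle, SurvivalEndpoint, ValidationError

log = logging.getLogger("kmscreen")

#: reported p-values are floored here to keep downstream logs finite
P_FLOOR = 1e-300
#: cutoff floor in intensity units: twice the ~100-unit background
CUTOFF_FLOOR = 200.0


# ---------------------------------------------------------------------------
# candidate cutoffs
# ---------------------------------------------------------------------------


def candidate_cutoffs(values: np.ndarray) -> np.ndarray:
    """Distinct observed values v with q1 <= v < q3 (linear-interpolation quartiles).

    Every returned cutoff splits the samples into two non-empty groups.  A
    constant vector (q1 == q3) yields an empty list and the gene is skipped.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValidationError("need at least 4 observations for a cutoff scan")
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise ValidationError("expression values must be positive and finite")
    q1, q3 = np.quantile(values, [0.25, 0.75])
    distinct = np.unique(values)
    return distinct[(distinct >= q1) & (distinct < q3)]


# ---------------------------------------------------------------------------
# log-rank machinery
# ---------------------------------------------------------------------------


def logrank_two_group(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    """Textbook two-group log-rank test (1 df), computed per risk table.

    Deliberately naive — one hypergeometric term per distinct event time — so
    it can serve as the independent reference for the vectorized scan.
    Returns ``(chi2, p)``.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, bool)
    if event.sum() == 0:
        raise ValidationError("no events")
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        dying = (time == t) & (event == 1)
        d = dying.sum()
        d1 = (dying & group).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(max(stats.chi2.sf(chi2, 1), P_FLOOR))


def _scan_statistics(
    values: np.ndarray, time: np.ndarray, event: np.ndarray, cutoffs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Log-rank chi-square at every cutoff, fully vectorized.

    Samples are sorted by time; at-risk counts for the high group at each
    distinct event time are suffix sums of the (cutoff x sample) indicator
    matrix, and the per-time hypergeometric moments are accumulated with
    segment sums.  Agrees with :func:`logrank_two_group` to ~1e-12.

    Returns ``(chi2, p, n_low, n_high)`` arrays over cutoffs.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    x = values[order]
    n = len(t)

    high = x[None, :] > cutoffs[:, None]  # (C, n)
    n_high = high.sum(axis=1)
    n_low = n - n_high

    # first index of each distinct time block in the sorted order
    _, first_idx = np.unique(t, return_index=True)
    n_risk = n - first_idx  # at risk at each distinct time
    # suffix counts of high-group members, evaluated at block starts
    suffix_high = np.cumsum(high[:, ::-1], axis=1)[:, ::-1]
    n1_risk = suffix_high[:, first_idx]

    d_all = np.add.reduceat(e, first_idx)
    d1_all = np.add.reduceat(high * e[None, :], first_idx, axis=1)

    has_event = d_all > 0
    d = d_all[has_event]
    nr = n_risk[has_event]
    n1r = n1_risk[:, has_event]
    d1 = d1_all[:, has_event]

    frac = n1r / nr
    o_minus_e = (d1 - d * frac).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vterm = d * frac * (1 - frac) * (nr - d) / np.where(nr > 1, nr - 1, 1)
    vterm[:, nr <= 1] = 0.0
    var = vterm.sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(var > 0, o_minus_e**2 / var, 0.0)
    p = np.maximum(stats.chi2.sf(chi2, 1), P_FLOOR)
    p[var <= 0] = 1.0
    return chi2, p, n_low, n_high


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# univariate Cox (binary covariate, Efron ties)
# ---------------------------------------------------------------------------


def _efron_tables(time: np.ndarray, event: np.ndarray, group: np.ndarray) -> dict:
    """Risk-table arrays per distinct event time: d, d1, n0, n1, plus the
    flattened Efron tie fractions l/d (one entry per tied event)."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    g = group[order].astype(np.int64)
    n = len(t)
    _, first_idx = np.unique(t, return_index=True)
    d_all = np.add.reduceat(e, first_idx)
    d1_all = np.add.reduceat(e * g, first_idx)
    n_risk = n - first_idx
    n1_risk = np.cumsum(g[::-1])[::-1][first_idx]
    has = d_all > 0
    d = d_all[has].astype(float)
    d1 = d1_all[has].astype(float)
    n1 = n1_risk[has].astype(float)
    n0 = n_risk[has].astype(float) - n1
    # flattened l/d per tied event, with the owning time index repeated
    rep = np.repeat(np.arange(len(d)), d.astype(int))
    l_frac = (np.concatenate([np.arange(int(k)) for k in d]) / d[rep]) if len(d) else np.array([])
    return {"d": d, "d1": d1, "n0": n0, "n1": n1, "rep": rep, "l_frac": l_frac}


def _efron_derivs(beta: float, tab: dict) -> tuple[float, float, float]:
    """(loglik, gradient, negative curvature) of the Efron partial likelihood
    for a single binary covariate, vectorized over all tied-event terms."""
    r = np.exp(beta)
    d, d1, n0, n1 = tab["d"], tab["d1"], tab["n0"], tab["n1"]
    rep, l_frac = tab["rep"], tab["l_frac"]
    s_r = n0 + n1 * r
    sp_r = n1 * r
    s_d = (d - d1) + d1 * r
    sp_d = d1 * r
    phi = s_r[rep] - l_frac * s_d[rep]
    a = sp_r[rep] - l_frac * sp_d[rep]
    ratio = a / phi
    ll = float((d1 * beta).sum() - np.log(phi).sum())
    grad = float(d1.sum() - ratio.sum())
    info = float((ratio - ratio**2).sum())
    return ll, grad, info


def cox_binary(
    time: np.ndarray,
    event: np.ndarray,
    group: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> dict:
    """Univariate Cox fit for a binary high/low covariate with Efron ties.

    Newton iterations with step-halving; returns hr, 95% CI, Wald p, the score
    test at beta=0 and a convergence flag.  On separation (|beta| drifting
    beyond ~15 log-hazard units) the fit is declared non-converged and the
    caller should fall back to :func:`logrank_hr_estimate`.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, bool)
    if event.sum() == 0:
        raise ValidationError("no events")
    tables = _efron_tables(time, event, group)

    ll0, grad0, info0 = _efron_derivs(0.0, tables)
    score_chi2 = grad0**2 / info0 if info0 > 0 else 0.0

    beta = 0.0
    ll, grad, info = ll0, grad0, info0
    converged = False
    for _ in range(max_iter):
        if info <= 0:
            break
        step = grad / info
        # step-halving keeps the partial likelihood non-decreasing
        for _ in range(30):
            new_beta = beta + step
            new_ll, new_grad, new_info = _efron_derivs(new_beta, tables)
            if new_ll >= ll - 1e-12:
                break
            step /= 2.0
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if abs(beta) > 15:
            break
        if abs(grad) <= tol:
            converged = True
            break

    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    return {
        "beta": float(beta),
        "hr": float(np.exp(beta)),
        "hr_lo": float(np.exp(beta - 1.959963984540054 * se)),
        "hr_hi": float(np.exp(beta + 1.959963984540054 * se)),
        "se": float(se),
        "wald_p": float(max(2 * stats.norm.sf(abs(z)), P_FLOOR)),
        "score_chi2": float(score_chi2),
        "loglik": float(ll),
        "converged": bool(converged),
    }


@njit
def _efron_derivs_row(beta, n0, n1, d1, d):  # pragma: no cover - numba
    """Efron partial-likelihood value/gradient/curvature for one cutoff;
    identical estimating equations to :func:`_efron_derivs`."""
    acc_ll = 0.0
    acc_gr = 0.0
    acc_in = 0.0
    r = np.exp(beta)
    for j in range(n0.shape[0]):
        s_r = n0[j] + n1[j] * r
        sp_r = n1[j] * r
        dd = d[j]
        if dd == 1:
            ratio = sp_r / s_r
            acc_ll += d1[j] * beta - np.log(s_r)
            acc_gr += d1[j] - ratio
            acc_in += ratio - ratio * ratio
        else:
            s_d = (dd - d1[j]) + d1[j] * r
            sp_d = d1[j] * r
            acc_ll += d1[j] * beta
            acc_gr += d1[j]
            for l in range(dd):
                lf = l / dd
                phi = s_r - lf * s_d
                a = sp_r - lf * sp_d
                ratio = a / phi
                acc_ll -= np.log(phi)
                acc_gr -= ratio
                acc_in += ratio - ratio * ratio
    return acc_ll, acc_gr, acc_in


@njit
def _cox_fit_kernel(n0, n1, d1, d, max_iter, tol):  # pragma: no cover - numba
    """Independent Newton fits (with step-halving) for every cutoff row."""
    n_cut = n0.shape[0]
    beta_out = np.zeros(n_cut)
    se_out = np.full(n_cut, np.inf)
    conv_out = np.zeros(n_cut, dtype=np.bool_)
    for i in range(n_cut):
        beta = 0.0
        ll, grad, info = _efron_derivs_row(beta, n0[i], n1[i], d1[i], d)
        for _ in range(max_iter):
            if info <= 0 or abs(beta) > 15:
                break
            if abs(grad) <= tol:
                conv_out[i] = True
                break
            step = grad / info
            new_beta = beta
            new_ll, new_grad, new_info = ll, grad, info
            for _ in range(30):
                new_beta = beta + step
                new_ll, new_grad, new_info = _efron_derivs_row(
                    new_beta, n0[i], n1[i], d1[i], d
                )
                if new_ll >= ll - 1e-12:
                    break
                step /= 2.0
            beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if abs(grad) <= tol and abs(beta) <= 15 and info > 0:
            conv_out[i] = True
        beta_out[i] = beta
        if info > 0:
            se_out[i] = 1.0 / np.sqrt(info)
    return beta_out, se_out, conv_out


def _cox_binary_batch(
    values: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    cutoffs: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> dict:
    """Univariate Efron Cox fits for the high/low split at *every* cutoff,
    Newton-iterated jointly across cutoffs (same estimating equations as
    :func:`cox_binary`, which serves as its scalar reference in the tests).

    Returns arrays beta, se, converged over cutoffs.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order].astype(np.int64)
    x = values[order]
    n = len(t)
    _, first_idx = np.unique(t, return_index=True)
    d_all = np.add.reduceat(e, first_idx)
    has = d_all > 0
    d = d_all[has].astype(float)
    n_risk = (n - first_idx)[has].astype(float)

    high = x[None, :] > cutoffs[:, None]  # (C, n)
    n1 = np.cumsum(high[:, ::-1], axis=1)[:, ::-1][:, first_idx][:, has].astype(float)
    n0 = n_risk[None, :] - n1
    d1 = np.add.reduceat(high * e[None, :], first_idx, axis=1)[:, has].astype(float)

    beta, se, converged = _cox_fit_kernel(
        np.ascontiguousarray(n0),
        np.ascontiguousarray(n1),
        np.ascontiguousarray(d1),
        d.astype(np.int64),
        max_iter,
        tol,
    )
    return {"beta": beta, "se": se, "converged": converged}


def logrank_hr_estimate(time: np.ndarray, event: np.ndarray, group: np.ndarray) -> float:
    """O/E hazard-ratio estimate (high vs low) used when the Cox fit fails."""
    group = np.asarray(group, bool)
    tab = _efron_tables(np.asarray(time, float), np.asarray(event, int), group)
    d, d1, n0, n1 = tab["d"], tab["d1"], tab["n0"], tab["n1"]
    o1 = d1.sum()
    o0 = (d - d1).sum()
    e1 = (d * n1 / (n0 + n1)).sum()
    e0 = (d * n0 / (n0 + n1)).sum()
    eps = 1e-12
    return float(((o1 + eps) / (e1 + eps)) / ((o0 + eps) / (e0 + eps)))


def cox_score_test(time: np.ndarray, event: np.ndarray, group: np.ndarray) -> float:
    """Cox score chi-square at beta=0 for a binary covariate (Efron ties)."""
    return cox_binary(time, event, group, max_iter=0)["score_chi2"]


# ---------------------------------------------------------------------------
# scan containers + selection
# ---------------------------------------------------------------------------


@dataclass
class CutoffScan:
    """Per-cutoff statistics for one gene."""

    gene: str
    cutoffs: np.ndarray
    n_low: np.ndarray
    n_high: np.ndarray
    chi2: np.ndarray
    p: np.ndarray
    fdr: np.ndarray
    q1: float
    q3: float

    def __len__(self) -> int:
        return len(self.cutoffs)


@dataclass
class GeneScanResult:
    """Selected cutoff and the associated statistics for one gene."""

    gene: str
    selected_cutoff: float
    p_at_selected: float
    fdr_at_selected: float
    hr: float
    hr_lo: float
    hr_hi: float
    direction: str  # "risk" (HR > 1) or "protective"
    passes_floor: bool
    n_samples: int
    n_low: int
    n_high: int
    n_cutoffs: int
    cox_converged: bool


@dataclass
class ScreenTable:
    """Ranked per-gene screen results for one endpoint."""

    table: pd.DataFrame
    endpoint: str
    platform_label: str
    alpha: float  # significance threshold on the per-gene best FDR

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def logrank_scan(
    values: np.ndarray, endpoint: SurvivalEndpoint, gene: str = ""
) -> CutoffScan:
    """Scan every candidate cutoff of one gene with the log-rank statistic and
    apply the BH correction across the gene's cutoff series."""
    values = np.asarray(values, dtype=float)
    time, event = endpoint.time, endpoint.event
    if len(values) != len(time):
        raise ValidationError("expression and survival lengths differ")
    if event.sum() == 0:
        raise ValidationError("no events")
    cutoffs = candidate_cutoffs(values)
    if cutoffs.size == 0:
        raise ValidationError(f"gene {gene or '?'}: no candidate cutoffs (constant vector)")
    chi2, p, n_low, n_high = _scan_statistics(values, time, event, cutoffs)
    q1, q3 = np.quantile(values, [0.25, 0.75])
    return CutoffScan(gene, cutoffs, n_low, n_high, chi2, p, bh_adjust(p), float(q1), float(q3))


def select_best(
    scan: CutoffScan,
    values: np.ndarray,
    endpoint: SurvivalEndpoint,
    cutoff_floor: float = CUTOFF_FLOOR,
) -> GeneScanResult:
    """Pick the cutoff with the lowest FDR; break ties by the highest Cox HR,
    then by the smallest cutoff; estimate the HR at the winner."""
    if len(scan) == 0:
        raise ValidationError("empty scan")
    values = np.asarray(values, dtype=float)
    best_fdr = scan.fdr.min()
    tied = np.flatnonzero(scan.fdr == best_fdr)

    batch = _cox_binary_batch(values, endpoint.time, endpoint.event, scan.cutoffs[tied])
    hrs = np.exp(batch["beta"])
    # fall back to the O/E estimate where the fit separated
    for j in np.flatnonzero(~batch["converged"]):
        group = values > scan.cutoffs[tied[j]]
        hrs[j] = logrank_hr_estimate(endpoint.time, endpoint.event, group)
        log.warning(
            "gene %s cutoff %.4g: Cox fit did not converge; using O/E hazard ratio",
            scan.gene,
            scan.cutoffs[tied[j]],
        )
    winners = tied[hrs == hrs.max()]
    idx = int(winners.min())  # smallest cutoff among remaining ties
    j = int(np.flatnonzero(tied == idx)[0])
    zcrit = 1.959963984540054
    if batch["converged"][j]:
        beta, se = batch["beta"][j], batch["se"][j]
        z = beta / se if se > 0 else 0.0
        fit = {
            "hr": float(np.exp(beta)),
            "hr_lo": float(np.exp(beta - zcrit * se)),
            "hr_hi": float(np.exp(beta + zcrit * se)),
            "wald_p": float(max(2 * stats.norm.sf(abs(z)), P_FLOOR)),
            "converged": True,
        }
    else:
        fit = {"hr": float(hrs[j]), "hr_lo": np.nan, "hr_hi": np.nan,
               "wald_p": np.nan, "converged": False}

    cutoff = float(scan.cutoffs[idx])
    return GeneScanResult(
        gene=scan.gene,
        selected_cutoff=cutoff,
        p_at_selected=float(scan.p[idx]),
        fdr_at_selected=float(scan.fdr[idx]),
        hr=fit["hr"],
        hr_lo=fit["hr_lo"],
        hr_hi=fit["hr_hi"],
        direction="risk" if fit["hr"] > 1 else "protective",
        passes_floor=cutoff > cutoff_floor,
        n_samples=len(values),
        n_low=int(scan.n_low[idx]),
        n_high=int(scan.n_high[idx]),
        n_cutoffs=len(scan),
        cox_converged=bool(fit["converged"]),
    )


def scan_gene(
    values: np.ndarray, endpoint: SurvivalEndpoint, gene: str = ""
) -> GeneScanResult:
    """Convenience: full scan + selection for one gene."""
    return select_best(logrank_scan(values, endpoint, gene), values, endpoint)


# ---------------------------------------------------------------------------
# whole-transcriptome screen
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = [
    "endpoint",
    "n",
    "selected_cutoff",
    "p",
    "fdr",
    "hr",
    "hr_lo",
    "hr_hi",
    "direction",
    "passes_floor",
    "significant",
    "n_cutoffs",
    "cox_converged",
    "rank",
]


def screen(
    bundle: CohortBundle,
    endpoint: str = "os",
    alpha: float = 0.01,
    cutoff_floor: float = CUTOFF_FLOOR,
    min_samples: int = 30,
) -> ScreenTable:
    """Run the cutoff scan over every gene row of a (merged) bundle.

    Significance is called at ``fdr < alpha`` on the per-gene best FDR.
    Ranking: floor-passing genes first, risk direction before protective,
    then ascending FDR, descending HR, gene symbol.  Genes skipped for a
    constant expression vector or missing values keep a row with NaN
    statistics so the full gene universe is preserved.
    """
    surv, mask = bundle.endpoint(endpoint)
    if mask.sum() == 0:
        raise ValidationError(f"endpoint {endpoint!r} missing for all samples")
    if mask.sum() < min_samples:
        raise ValidationError(
            f"only {int(mask.sum())} samples with {endpoint} data (< {min_samples})"
        )
    if surv.event.sum() == 0:
        raise ValidationError("no events")

    rows = {}
    for gene, row in bundle.expression.iterrows():
        x = row.to_numpy(dtype=float)[mask]
        record = dict.fromkeys(_RESULT_COLUMNS, np.nan)
        record.update(
            endpoint=endpoint,
            n=int(len(x)),
            direction="",
            passes_floor=False,
            significant=False,
            cox_converged=False,
        )
        ok = np.all(np.isfinite(x))
        if ok:
            try:
                res = scan_gene(x, surv, gene)
            except ValidationError as exc:
                log.info("gene %s skipped: %s", gene, exc)
            else:
                record.update(
                    selected_cutoff=res.selected_cutoff,
                    p=res.p_at_selected,
                    fdr=res.fdr_at_selected,
                    hr=res.hr,
                    hr_lo=res.hr_lo,
                    hr_hi=res.hr_hi,
                    direction=res.direction,
                    passes_floor=bool(res.selected_cutoff > cutoff_floor),
                    significant=bool(res.fdr_at_selected < alpha),
                    n_cutoffs=res.n_cutoffs,
                    cox_converged=res.cox_converged,
                )
        else:
            log.info("gene %s skipped: missing expression values", gene)
        rows[gene] = record

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene"
    # mergesort is stable, so the final alphabetical tie-break comes from a
    # pre-sort on the gene symbol
    order = (
        table.loc[table.index.sort_values()]
        .assign(
            _floor=lambda d: ~d["passes_floor"].astype(bool),
            _risk=lambda d: d["direction"] != "risk",
            _fdr=lambda d: d["fdr"].fillna(np.inf),
            _hr=lambda d: -d["hr"].fillna(-np.inf),
        )
        .sort_values(["_floor", "_risk", "_fdr", "_hr"], kind="mergesort")
    )
    table = table.loc[order.index]
    table["rank"] = np.arange(1, len(table) + 1)
    return ScreenTable(table[_RESULT_COLUMNS], endpoint, bundle.platform, alpha)


# ---------------------------------------------------------------------------
# Kaplan–Meier export
# ---------------------------------------------------------------------------


def km_curve(
    values: np.ndarray,
    cutoff: float,
    endpoint: SurvivalEndpoint,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Product-limit curves for the low (x <= cutoff) and high (x > cutoff)
    groups with Greenwood confidence intervals and at-risk counts.

    Returns a long-format table: group, time, n_risk, n_event, survival,
    ci_lo, ci_hi.  Cross-checked against lifelines' Kaplan–Meier estimate in
    the test suite.
    """
    values = np.asarray(values, dtype=float)
    group = values > cutoff
    if group.all() or not group.any():
        raise ValidationError("cutoff leaves one group empty")
    zcrit = stats.norm.ppf(0.5 + conf_level / 2)
    frames = []
    for name, sel in (("low", ~group), ("high", group)):
        t = endpoint.time[sel]
        e = endpoint.event[sel]
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        uniq, first = np.unique(t, return_index=True)
        n_risk = len(t) - first
        d = np.add.reduceat(e, first)
        with np.errstate(divide="ignore", invalid="ignore"):
            surv = np.cumprod(1.0 - d / n_risk)
            # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d)))
            gw = np.where(n_risk > d, d / (n_risk * (n_risk - d).clip(min=1)), 0.0)
            se = surv * np.sqrt(np.cumsum(gw))
        frames.append(
            pd.DataFrame(
                {
                    "group": name,
                    "time": uniq,
                    "n_risk": n_risk,
                    "n_event": d,
                    "survival": surv,
                    "ci_lo": np.clip(surv - zcrit * se, 0.0, 1.0),
                    "ci_hi": np.clip(surv + zcrit * se, 0.0, 1.0),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
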