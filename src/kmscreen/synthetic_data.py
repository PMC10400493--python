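"""Multi-cohort expression + survival simulator.

Generates datasets with the statistical structure the downstream screen
assumes: positive MAS5-like intensities (shifted log-normal over a background
of ~100 units), two overlapping platform probe sets (a small shared panel
inside a larger one, mirroring the U133A / U133 Plus 2.0 relationship),
right-censored exponential survival for OS and PFS, planted dichotomous
hazard effects at latent expression cutoffs, and partially missing clinical
fields.  Everything is driven by a single seed fanned out into per-cohort,
per-purpose substreams, so identical configurations reproduce bit-identical
studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io_ingest import (
    CLINICAL_COLUMNS,
    CohortBundle,
    ProbeGeneMap,
    ValidationError,
    write_clinical,
    write_expression,
    write_probe_map,
)

Endpoint = Literal["os", "pfs", "both"]

# Table-1-like pooled category frequencies used for the clinical covariates.
HISTOLOGY_PROBS = {"serous": 0.925, "endometrioid": 0.045, "clear cell": 0.02, "other": 0.01}
STAGE_PROBS = {1: 0.06, 2: 0.06, 3: 0.74, 4: 0.14}
GRADE_PROBS = {1: 0.03, 2: 0.25, 3: 0.65, 4: 0.07}
DEBULKING_PROBS = {"optimal": 0.599, "suboptimal": 0.401}


@dataclass(frozen=True)
class PlantedEffect:
    """A dichotomous prognostic effect: hazard jumps by ``hr`` above the cutoff."""

    gene_id: str
    cutoff_quantile: float
    hr: float
    endpoint: Endpoint = "both"


@dataclass
class SimConfig:
    """Study-design parameters for :func:`simulate_study`.

    Defaults describe a modest two-cohort study: exponential baseline survival
    with mean 40 months for OS and 24 months for PFS (matching typical ovarian
    cancer follow-up), ~40% administrative censoring, log-normal intensities
    over a background of 100 units, and 10% missingness in the categorical
    clinical fields.
    """

    n_cohorts: int = 2
    samples_per_cohort: Sequence[int] = (120, 120)
    n_genes_total: int = 200
    n_shared_genes: int = 150
    planted_effects: Sequence[PlantedEffect] = ()
    baseline_hazard_scale: float = 40.0  # months; exponential mean for OS
    pfs_scale_factor: float = 0.6  # PFS baseline mean = factor * OS mean
    censor_rate_target: float = 0.4
    intensity_log_mean: float = 6.0
    intensity_log_sd: float = 1.0
    gene_log_mean_sd: float = 0.3  # between-gene spread of log-mean intensity
    cohort_log_shift_sd: float = 0.1  # cohort-level intensity shift (log scale)
    background_level: float = 100.0
    clinical_missingness: float = 0.1
    effect_model: Literal["dichotomous", "loglinear"] = "dichotomous"
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_cohorts < 1:
            raise ValidationError("n_cohorts must be >= 1")
        if len(self.samples_per_cohort) != self.n_cohorts:
            raise ValidationError("samples_per_cohort length must equal n_cohorts")
        if any(n < 10 for n in self.samples_per_cohort):
            raise ValidationError("samples_per_cohort entries must all be >= 10")
        if not (0 < self.n_shared_genes <= self.n_genes_total):
            raise ValidationError("need 0 < n_shared_genes <= n_genes_total")
        gene_ids = set(gene_names(self.n_genes_total))
        seen = set()
        for eff in self.planted_effects:
            if eff.gene_id not in gene_ids:
                raise ValidationError(
                    f"planted gene {eff.gene_id!r} beyond n_genes_total={self.n_genes_total}"
                )
            if eff.gene_id in seen:
                raise ValidationError(f"planted gene {eff.gene_id!r} listed twice")
            seen.add(eff.gene_id)
            if not (0 < eff.cutoff_quantile < 1):
                raise ValidationError(
                    f"cutoff_quantile for {eff.gene_id} must lie in (0,1)"
                )
            if eff.hr <= 0:
                raise ValidationError(f"HR for {eff.gene_id} must be > 0")
            if eff.endpoint not in ("os", "pfs", "both"):
                raise ValidationError(f"unknown endpoint {eff.endpoint!r}")
        if not (0 <= self.censor_rate_target < 1):
            raise ValidationError("censor_rate_target must lie in [0, 1)")
        if not (0 <= self.clinical_missingness < 1):
            raise ValidationError("clinical_missingness must lie in [0, 1)")
        if self.baseline_hazard_scale <= 0 or self.pfs_scale_factor <= 0:
            raise ValidationError("hazard scales must be positive")
        if self.background_level < 0:
            raise ValidationError("background_level must be >= 0")
        return self


@dataclass
class SimulatedStudy:
    """Simulator output: cohort bundles, the probe map, and the planted truth.

    ``truth`` echoes the planted effects with the realized cutoff on the
    intensity scale (the requested quantile of the pooled simulated values).
    """

    cohorts: list[CohortBundle]
    probe_map: ProbeGeneMap
    truth: pd.DataFrame
    config: SimConfig


def gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def probe_names(n: int) -> list[str]:
    return [f"{200000 + i}_at" for i in range(1, n + 1)]


def _calibrate_censoring(
    t: np.ndarray, u: np.ndarray, target: float
) -> tuple[np.ndarray, np.ndarray]:
    """Administrative censoring C = tau * U with tau bisected so the realized
    censored fraction matches ``target`` on these draws."""
    if target <= 0:
        return t.copy(), np.ones(len(t), dtype=int)
    lo, hi = 1e-9, float(t.max()) / max(u.min(), 1e-12) + 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        frac = float(np.mean(t > mid * u))  # fraction censored
        if frac > target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9 * hi:
            break
    tau = 0.5 * (lo + hi)
    c = tau * u
    event = (t <= c).astype(int)
    time = np.minimum(t, c)
    return time, event


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate a multi-cohort study under the configured design.

    Expression is gene-independent of survival except for the planted effects:
    samples above a planted gene's realized cutoff draw survival times from a
    proportional-hazards model with the hazard multiplied by the planted HR.
    Censoring is administrative and independent of expression.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    gene_ss, *cohort_ss = root.spawn(1 + config.n_cohorts)

    genes = gene_names(config.n_genes_total)
    probes = probe_names(config.n_genes_total)
    probe_map = ProbeGeneMap(pd.Series(genes, index=pd.Index(probes, name="probe_id")))
    gene_rng = np.random.default_rng(gene_ss)
    # per-gene mean intensities shared across cohorts so cutoffs transfer
    gene_log_means = config.intensity_log_mean + config.gene_log_mean_sd * gene_rng.standard_normal(config.n_genes_total)

    effects = list(config.planted_effects)
    eff_idx = {g: i for i, g in enumerate(genes)}

    # -- expression first (survival depends on the planted genes' values) -----
    per_cohort: list[dict] = []
    for k in range(config.n_cohorts):
        n = config.samples_per_cohort[k]
        streams = cohort_ss[k].spawn(4)
        expr_rng = np.random.default_rng(streams[0])
        platform = "GPL570" if k % 2 == 0 else "GPL96"
        n_genes_k = config.n_genes_total if platform == "GPL570" else config.n_shared_genes
        shift = config.cohort_log_shift_sd * expr_rng.standard_normal()
        z = expr_rng.standard_normal((n_genes_k, n))
        logint = gene_log_means[:n_genes_k, None] + shift + config.intensity_log_sd * z
        intensities = config.background_level + np.exp(logint)
        sample_ids = [f"C{k + 1}S{j + 1:04d}" for j in range(n)]
        expr = pd.DataFrame(
            intensities,
            index=pd.Index(probes[:n_genes_k], name="probe_id"),
            columns=sample_ids,
        )
        per_cohort.append(
            {
                "expr": expr,
                "platform": platform,
                "streams": streams,
                "sample_ids": sample_ids,
                "cohort_id": f"SIM{k + 1:02d}",
            }
        )

    # realized cutoffs from pooled values of each planted gene
    truth_rows = []
    realized_cutoff: dict[str, float] = {}
    for eff in effects:
        probe = probes[eff_idx[eff.gene_id]]
        pooled = np.concatenate(
            [
                c["expr"].loc[probe].to_numpy()
                for c in per_cohort
                if probe in c["expr"].index
            ]
        )
        cut = float(np.quantile(pooled, eff.cutoff_quantile))
        realized_cutoff[eff.gene_id] = cut
        truth_rows.append(
            {
                "gene_id": eff.gene_id,
                "endpoint": eff.endpoint,
                "cutoff_quantile": eff.cutoff_quantile,
                "true_hr": eff.hr,
                "realized_cutoff": cut,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "endpoint", "cutoff_quantile", "true_hr", "realized_cutoff"],
    )

    # -- survival + clinical ---------------------------------------------------
    cohorts: list[CohortBundle] = []
    for k, c in enumerate(per_cohort):
        n = len(c["sample_ids"])
        surv_rng = np.random.default_rng(c["streams"][1])
        cens_rng = np.random.default_rng(c["streams"][2])
        clin_rng = np.random.default_rng(c["streams"][3])

        loghaz = {"os": np.zeros(n), "pfs": np.zeros(n)}
        for eff in effects:
            probe = probes[eff_idx[eff.gene_id]]
            if probe not in c["expr"].index:
                continue
            x = c["expr"].loc[probe].to_numpy()
            if config.effect_model == "dichotomous":
                zscore = (x > realized_cutoff[eff.gene_id]).astype(float)
            else:  # log-linear alternative for robustness checks
                lx = np.log(np.maximum(x - config.background_level, 1e-9))
                zscore = (lx - lx.mean()) / max(lx.std(), 1e-12)
            for ep in ("os", "pfs") if eff.endpoint == "both" else (eff.endpoint,):
                loghaz[ep] += np.log(eff.hr) * zscore

        cols = {}
        for ep, scale in (
            ("os", config.baseline_hazard_scale),
            ("pfs", config.baseline_hazard_scale * config.pfs_scale_factor),
        ):
            lam = np.exp(loghaz[ep]) / scale
            t_true = surv_rng.exponential(1.0 / lam)
            u = cens_rng.uniform(size=n)
            time, event = _calibrate_censoring(t_true, u, config.censor_rate_target)
            cols[f"{ep}_time_months"] = time
            cols[f"{ep}_event"] = event

        clin = pd.DataFrame(cols, index=pd.Index(c["sample_ids"], name="sample_id"))
        clin["cohort"] = c["cohort_id"]

        def draw(probs: dict, rng: np.random.Generator) -> np.ndarray:
            cats = list(probs)
            p = np.array([probs[x] for x in cats], dtype=float)
            return rng.choice(np.array(cats, dtype=object), size=n, p=p / p.sum())

        clin["stage"] = draw(STAGE_PROBS, clin_rng).astype(float)
        clin["grade"] = draw(GRADE_PROBS, clin_rng).astype(float)
        clin["debulking"] = draw(DEBULKING_PROBS, clin_rng)
        clin["histology"] = draw(HISTOLOGY_PROBS, clin_rng)
        for fld in ("stage", "grade", "debulking", "histology"):
            miss = clin_rng.uniform(size=n) < config.clinical_missingness
            clin.loc[miss, fld] = np.nan
        clin = clin[CLINICAL_COLUMNS]

        cohorts.append(
            CohortBundle(c["cohort_id"], c["platform"], c["expr"], clin).validate()
        )

    return SimulatedStudy(cohorts, probe_map, truth, config)


def write_study(study: SimulatedStudy, directory: str | Path) -> list[Path]:
    """Write per-cohort expression + clinical TSVs, the probe map and the truth table."""
    if not study.cohorts:
        raise ValidationError("study has no cohorts to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for b in study.cohorts:
        ep = directory / f"{b.cohort_id}_expression.tsv"
        cp = directory / f"{b.cohort_id}_clinical.tsv"
        write_expression(b.expression, ep)
        write_clinical(b.clinical[CLINICAL_COLUMNS], cp)
        written += [ep, cp]
    mp = directory / "probe_map.tsv"
    write_probe_map(study.probe_map, mp)
    tp = directory / "truth.tsv"
    study.truth.to_csv(tp, sep="\t", index=False, float_format="%.17g")
    written += [mp, tp]
    return written
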