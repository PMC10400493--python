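"""Readers, writers and containers for cohort expression/clinical data.

File dialects
-------------
Expression TSV : header row = sample IDs, first column = probe ID, values are
    positive MAS5-like intensities.
Clinical TSV   : columns sample_id, cohort, os_time_months, os_event,
    pfs_time_months, pfs_event, stage, grade, debulking, histology.
    Missing values are empty cells.
Mapping TSV    : columns probe_id, gene_symbol; exactly one (best) probe per gene.
GMT            : Broad dialect, tab separated: name, description, members...
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("kmscreen")

#: clinical columns after the sample_id index
CLINICAL_COLUMNS = [
    "cohort",
    "os_time_months",
    "os_event",
    "pfs_time_months",
    "pfs_event",
    "stage",
    "grade",
    "debulking",
    "histology",
]
NUMERIC_CLINICAL = [
    "os_time_months",
    "os_event",
    "pfs_time_months",
    "pfs_event",
    "stage",
    "grade",
]
DEBULKING_LEVELS = {"optimal", "suboptimal"}
HISTOLOGY_LEVELS = {"serous", "endometrioid", "clear cell", "other"}


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SurvivalEndpoint:
    """Right-censored survival vectors: time in months, event 1 = observed."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValidationError("time and event lengths differ")
        if not np.all(np.isfinite(self.time)) or np.any(self.time < 0):
            raise ValidationError("survival times must be finite and >= 0")
        if not np.all(np.isin(self.event, [0, 1])):
            raise ValidationError("event indicators must be 0 or 1")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class CohortBundle:
    """One cohort: probes x samples intensity matrix plus per-sample clinical table.

    Invariants: expression columns and clinical index hold the same sample IDs,
    all intensities are positive, survival times >= 0, events binary.
    """

    cohort_id: str
    platform: str
    expression: pd.DataFrame
    clinical: pd.DataFrame

    def validate(self) -> "CohortBundle":
        expr_ids = list(self.expression.columns)
        clin_ids = list(self.clinical.index)
        if len(set(expr_ids)) != len(expr_ids):
            raise ValidationError(f"duplicate sample IDs in expression of {self.cohort_id}")
        if set(expr_ids) != set(clin_ids):
            raise ValidationError(
                f"expression/clinical sample IDs differ in {self.cohort_id}"
            )
        vals = self.expression.to_numpy()
        finite = vals[np.isfinite(vals)]
        if np.any(finite <= 0):
            r, c = np.argwhere((vals <= 0) & np.isfinite(vals))[0]
            raise ValidationError(
                f"non-positive intensity at probe {self.expression.index[r]!r}, "
                f"sample {self.expression.columns[c]!r}"
            )
        for prefix in ("os", "pfs"):
            t = self.clinical[f"{prefix}_time_months"]
            e = self.clinical[f"{prefix}_event"]
            if np.any(t.dropna() < 0):
                raise ValidationError(f"negative {prefix} time in {self.cohort_id}")
            bad = e.dropna()[~e.dropna().isin([0, 1])]
            if len(bad):
                raise ValidationError(f"non-binary {prefix} event in {self.cohort_id}")
        return self

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def endpoint(self, which: str) -> tuple[SurvivalEndpoint, np.ndarray]:
        """Return the survival endpoint plus the boolean mask of usable samples.

        ``which`` is "os" or "pfs"; samples missing either time or event are
        excluded by the mask (the endpoint vectors are already masked).
        """
        which = which.lower()
        if which not in ("os", "pfs"):
            raise ValidationError(f"unknown endpoint {which!r}")
        t = self.clinical.loc[self.expression.columns, f"{which}_time_months"]
        e = self.clinical.loc[self.expression.columns, f"{which}_event"]
        mask = t.notna().to_numpy() & e.notna().to_numpy()
        return SurvivalEndpoint(t.to_numpy()[mask], e.to_numpy()[mask]), mask


@dataclass
class ProbeGeneMap:
    """Best-probe mapping: one designated probe per gene symbol."""

    entries: pd.Series  # index probe_id, value gene_symbol

    def __post_init__(self) -> None:
        counts = self.entries.value_counts()
        dupes = counts[counts > 1]
        if len(dupes):
            raise ValidationError(
                f"genes mapped by more than one probe: {sorted(dupes.index)[:5]}"
            )
        if self.entries.index.has_duplicates:
            raise ValidationError("duplicate probe IDs in probe->gene map")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class GeneSetCollection:
    """Named gene sets: name -> (description, member symbols)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if len(members) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples TSV; raises on non-numeric or duplicate IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.columns.has_duplicates:
        raise ValidationError(f"duplicate sample IDs in {path}")
    if df.index.has_duplicates:
        raise ValidationError(f"duplicate probe IDs in {path}")
    probe = df.apply(pd.to_numeric, errors="coerce")
    bad = probe.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric intensity at probe {df.index[r]!r}, sample "
            f"{df.columns[c]!r} in {path}"
        )
    # astype goes through exact float() parsing, so written values round-trip
    out = df.astype(float)
    out.index.name = "probe_id"
    return out


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV keyed by sample_id; empty cells become missing."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValidationError(f"clinical file {path} lacks a sample_id column")
    df = df.replace("", np.nan).set_index("sample_id")
    if df.index.has_duplicates:
        raise ValidationError(f"duplicate sample IDs in {path}")
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    for col in NUMERIC_CLINICAL:
        df[col] = df[col].astype(float)  # exact float() parsing for round-trips
    return df[CLINICAL_COLUMNS]


def read_cohort(
    expression_path: str | Path,
    clinical_path: str | Path,
    cohort_id: str,
    platform: str,
) -> CohortBundle:
    """Load one cohort; samples present in only one file are dropped with a warning."""
    expr = read_expression(expression_path)
    clin = read_clinical(clinical_path)
    shared = [s for s in expr.columns if s in clin.index]
    dropped = (len(expr.columns) - len(shared)) + (len(clin.index) - len(shared))
    if dropped:
        log.warning(
            "%d sample(s) dropped from cohort %s (present in only one file)",
            dropped,
            cohort_id,
        )
    if not shared:
        raise ValidationError(f"no samples shared between files for {cohort_id}")
    clin = clin.loc[shared].copy()
    clin["cohort"] = cohort_id
    return CohortBundle(cohort_id, platform, expr[shared], clin).validate()


def read_probe_map(path: str | Path) -> ProbeGeneMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_symbol"} <= set(df.columns):
        raise ValidationError(f"mapping file {path} needs probe_id and gene_symbol columns")
    return ProbeGeneMap(df.set_index("probe_id")["gene_symbol"].rename(None))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a Broad-dialect GMT file; members are deduplicated in order."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"GMT line {lineno} has fewer than 3 fields")
            name, desc = fields[0], fields[1]
            members = tuple(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise ValidationError(f"GMT line {lineno}: set {name!r} has no members")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# writers (shared with the simulator so round-trips are exact)
# ---------------------------------------------------------------------------


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id", float_format="%.17g")


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id", float_format="%.17g")


def write_probe_map(pmap: ProbeGeneMap, path: str | Path) -> None:
    pmap.entries.rename("gene_symbol").to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# merging and filtering
# ---------------------------------------------------------------------------


def merge_cohorts(
    bundles: Sequence[CohortBundle],
    probe_map: ProbeGeneMap,
    restrict_to_shared: bool = True,
) -> CohortBundle:
    """Merge cohorts into one gene-level bundle.

    Probe rows are collapsed to gene symbols through the best-probe map (unmapped
    probes are dropped). With ``restrict_to_shared`` the merged row space is the
    genes mapped in *every* bundle, mirroring a shared-platform analysis;
    otherwise the union is used with missing values marked NaN.
    """
    if not bundles:
        raise ValidationError("no cohorts to merge")
    gene_mats = []
    for b in bundles:
        mapped = b.expression.loc[b.expression.index.intersection(probe_map.entries.index)]
        mat = mapped.rename(index=probe_map.entries.to_dict())
        if mat.index.has_duplicates:
            raise ValidationError(f"cohort {b.cohort_id}: multiple probes per gene after mapping")
        gene_mats.append(mat)

    gene_sets = [set(m.index) for m in gene_mats]
    if restrict_to_shared:
        genes = sorted(set.intersection(*gene_sets))
    else:
        genes = sorted(set.union(*gene_sets))
    if not genes:
        raise ValidationError("no genes in the merged row space")

    all_ids: list[str] = []
    for b in bundles:
        all_ids.extend(b.expression.columns)
    dupes = pd.Index(all_ids)[pd.Index(all_ids).duplicated()]
    if len(dupes):
        raise ValidationError(f"duplicate sample IDs across cohorts: {sorted(set(dupes))[:10]}")

    expr = pd.concat([m.reindex(genes) for m in gene_mats], axis=1)
    clin = pd.concat([b.clinical for b in bundles], axis=0)[CLINICAL_COLUMNS]
    merged = CohortBundle(
        cohort_id="+".join(b.cohort_id for b in bundles),
        platform="+".join(dict.fromkeys(b.platform for b in bundles)),
        expression=expr,
        clinical=clin,
    )
    expr_vals = merged.expression.to_numpy()
    if np.any(expr_vals[np.isfinite(expr_vals)] <= 0):
        merged.validate()  # reuse the detailed error message
    return merged


def filter_histology(
    bundle: CohortBundle, keep: Iterable[str] = ("serous",)
) -> CohortBundle:
    """Restrict a bundle to the given histologies (missing histology is dropped)."""
    keep = set(keep)
    sel = bundle.clinical["histology"].isin(keep)
    ids = bundle.clinical.index[sel]
    if len(ids) == 0:
        raise ValidationError(f"no samples with histology in {sorted(keep)}")
    log.info(
        "histology filter %s: kept %d / %d samples", sorted(keep), len(ids), bundle.n_samples
    )
    return CohortBundle(
        bundle.cohort_id,
        bundle.platform,
        bundle.expression[ids],
        bundle.clinical.loc[ids],
    )
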