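"""PFS/OS significance concordance: a 2x2 chi-square test of independence.

Each gene of a common universe is classified as significant or not for PFS
and for OS (best-cutoff p-value below alpha, matching the simplified
endpoint-comparison analysis); the four counts are tested for independence
with the Pearson chi-square (1 df, no continuity correction by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_ingest import ValidationError
from .survival_screen import P_FLOOR, ScreenTable


@dataclass
class ConcordanceTable:
    """2x2 counts of PFS/OS significance with the independence test."""

    neither: int
    pfs_only: int
    os_only: int
    both: int
    expected_both: float
    ratio_observed_expected: float
    chi2: float
    p: float

    @property
    def total(self) -> int:
        return self.neither + self.pfs_only + self.os_only + self.both


def concordance_from_counts(
    neither: int, pfs_only: int, os_only: int, both: int, correction: bool = False
) -> ConcordanceTable:
    """Assemble the table and chi-square directly from the four counts."""
    counts = np.array([[neither, os_only], [pfs_only, both]], dtype=float)
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValidationError("chi-square undefined: a row or column margin is zero")
    total = counts.sum()
    expected_both = (pfs_only + both) * (os_only + both) / total
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=correction)
    return ConcordanceTable(
        neither=int(neither),
        pfs_only=int(pfs_only),
        os_only=int(os_only),
        both=int(both),
        expected_both=float(expected_both),
        ratio_observed_expected=float(both / expected_both) if expected_both > 0 else np.nan,
        chi2=float(chi2),
        p=float(max(p, P_FLOOR)),
    )


def build_concordance(
    screen_pfs: ScreenTable,
    screen_os: ScreenTable,
    alpha: float = 0.01,
    use_fdr: bool = False,
    correction: bool = False,
) -> ConcordanceTable:
    """Classify genes by per-endpoint significance and test independence.

    By default a gene counts as significant when its best-cutoff p-value is
    below ``alpha``; set ``use_fdr`` to classify on the per-gene best FDR
    instead.
    """
    genes_pfs = set(screen_pfs.table.index)
    genes_os = set(screen_os.table.index)
    if genes_pfs != genes_os:
        diff = len(genes_pfs.symmetric_difference(genes_os))
        raise ValidationError(f"gene universes differ ({diff} genes not shared)")
    col = "fdr" if use_fdr else "p"
    genes = sorted(genes_pfs)
    sig_pfs = (screen_pfs.table.loc[genes, col] < alpha).fillna(False).to_numpy()
    sig_os = (screen_os.table.loc[genes, col] < alpha).fillna(False).to_numpy()
    return concordance_from_counts(
        neither=int((~sig_pfs & ~sig_os).sum()),
        pfs_only=int((sig_pfs & ~sig_os).sum()),
        os_only=int((~sig_pfs & sig_os).sum()),
        both=int((sig_pfs & sig_os).sum()),
        correction=correction,
    )
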