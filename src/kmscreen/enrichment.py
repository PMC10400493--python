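"""Hypergeometric over-representation analysis of gene lists against gene sets.

For each set, the upper-tail hypergeometric probability P(X >= k) is computed
with population N = |universe|, successes K = |set ∩ universe| and draws
n = |gene list|; BH correction is applied across the tested sets.  The
universe defaults to all screened genes rather than all annotated genes,
matching the measurable universe of the screen.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_ingest import GeneSetCollection, ValidationError
from .survival_screen import bh_adjust

log = logging.getLogger("kmscreen")


def hypergeom_upper_tail(k: int, n_pop: int, n_success: int, n_draw: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N=n_pop, K=n_success, n=n_draw)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, n_pop, n_success, n_draw))


def ora(
    gene_list: list[str],
    universe: list[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Over-representation of ``gene_list`` in each set of ``collection``.

    Returns a table sorted by ascending p with columns set, description, k,
    set_size, list_size, universe_size, p, fdr, overlap.  Sets disjoint from
    the universe are skipped with a log note.
    """
    if len(collection) == 0:
        raise ValidationError("empty gene-set collection")
    uni = set(universe)
    listed = list(dict.fromkeys(gene_list))
    offenders = [g for g in listed if g not in uni]
    if offenders:
        raise ValidationError(f"gene list not a subset of the universe: {offenders[:10]}")
    n_pop = len(uni)
    n_draw = len(listed)
    listed_set = set(listed)

    rows = []
    for name, (desc, members) in collection.sets.items():
        in_universe = uni.intersection(members)
        if not in_universe:
            log.info("gene set %s disjoint from universe; skipped", name)
            continue
        overlap = sorted(listed_set & in_universe)
        k = len(overlap)
        rows.append(
            {
                "set": name,
                "description": desc,
                "k": k,
                "set_size": len(in_universe),
                "list_size": n_draw,
                "universe_size": n_pop,
                "p": hypergeom_upper_tail(k, n_pop, len(in_universe), n_draw),
                "overlap": ",".join(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["set", "description", "k", "set_size", "list_size",
                     "universe_size", "p", "fdr", "overlap"]
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    return out[["set", "description", "k", "set_size", "list_size",
                "universe_size", "p", "fdr", "overlap"]]
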