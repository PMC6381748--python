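"""Hypergeometric over-representation of gene sets.

p = P(X >= k) for drawing n query genes from a universe of N containing K
set members and observing k in the overlap, with Benjamini-Hochberg FDR
across the collection.  The universe defaults to all quantified proteins in
the input rather than the whole genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

__all__ = ["EnrichmentResult", "hypergeom_enrichment", "differential_go_ranking"]


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    universe_size: int
    set_size: int
    query_size: int
    overlap: int
    p_value: float
    fdr: float
    overlap_genes: tuple[str, ...]


def hypergeom_enrichment(query_genes: set[str], collection: GeneSetCollection,
                         universe: set[str]) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric p per set, BH-adjusted, sorted by p.

    Sets are intersected with the universe before testing; the query must be
    a subset of the universe.
    """
    query = {g.upper() for g in query_genes}
    universe = {g.upper() for g in universe}
    if not universe or not query:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    N, n = len(universe), len(query)
    names, ps, rows = [], [], []
    for name, members in collection.sets.items():
        in_universe = set(members) & universe
        K = len(in_universe)
        overlap = sorted(in_universe & query)
        k = len(overlap)
        # P(X >= k); sf(k-1) is the exact upper tail, 1.0 when k = 0
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        names.append(name)
        ps.append(min(p, 1.0))
        rows.append((name, N, K, n, k, tuple(overlap)))
    fdrs = multipletests(ps, method="fdr_bh")[1] if ps else []
    results = [EnrichmentResult(nm, N, K, n, k, p, float(f), ov)
               for (nm, N, K, n, k, ov), p, f in zip(rows, ps, fdrs)]
    return sorted(results, key=lambda r: (r.p_value, r.set_name))


def differential_go_ranking(enrichments_by_group: dict[str, list[EnrichmentResult]],
                            top_n: int | None = 30) -> pd.DataFrame:
    """Rank sets by the spread of their significance across groups.

    For every set, the standard deviation of -log10 p across the groups is
    computed and the collection is sorted in decreasing order of that SD;
    a set untested in a group is treated as p = 1 and flagged.  ``top_n``
    truncates for display (the study shows 30).
    """
    groups = sorted(enrichments_by_group)
    pmap: dict[str, dict[str, float]] = {}
    for g in groups:
        for r in enrichments_by_group[g]:
            pmap.setdefault(r.set_name, {})[g] = r.p_value
    rows = []
    for name, by_group in sorted(pmap.items()):
        ps = [by_group.get(g, 1.0) for g in groups]
        neglog = -np.log10(np.clip(ps, 1e-320, 1.0))
        rows.append({"set_name": name,
                     **{f"neg_log10_p_{g}": v for g, v in zip(groups, neglog)},
                     "sd_neg_log10_p": float(np.std(neglog, ddof=1)),
                     "missing_in": ",".join(g for g in groups
                                            if g not in by_group)})
    df = pd.DataFrame(rows).sort_values(
        ["sd_neg_log10_p", "set_name"], ascending=[False, True]
    ).reset_index(drop=True)
    return df.head(top_n) if top_n is not None else df
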