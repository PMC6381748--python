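"""Per-time-point differential phosphorylation statistics.

For each p-site and time point the paired log2 fold change is the mean of
the per-replicate differences high_i - low_i, and significance comes from a
two-sided paired t-test on those differences.  A feature is called
regulated when p <= alpha AND |log2FC| > lfc_threshold (both gates, per the
printed study thresholds p <= 0.05 and |log2FC| > 0.3, i.e. a 23% change).
No multiple-testing correction is applied to the calls; a Benjamini-
Hochberg column is emitted alongside for users who want it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import PsiteQuantTable, RunConfig

__all__ = [
    "DiffResult",
    "OverlapCounts",
    "paired_diff_test",
    "diff_all_times",
    "lfc_percent_equivalent",
    "overlap_analysis",
    "reconcile_protein_level",
    "volcano_table",
]

#: -log10(p) cap used when p underflows to 0 in volcano exports
VOLCANO_P_CAP = 320.0

#: sentinel p for identical non-zero paired differences (t is unbounded)
DEGENERATE_P = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class DiffResult:
    key: str                    # canonical p-site string (or accession)
    time: int
    log2fc: float
    p_value: float
    n_pairs: int
    regulated: bool
    direction: str              # up / down / none
    degenerate_variance: bool = False


@dataclass(frozen=True)
class OverlapCounts:
    """Set algebra over regulated-key sets at each time point."""

    times: tuple[int, ...]
    singles: dict[int, int]
    pairwise: dict[tuple[int, int], int]
    triple: int
    union: int
    shared_fraction: float      # triple / union, as a percentage
    exclusive: dict[int, int]

    def check_inclusion_exclusion(self) -> bool:
        """Integer identity: |union| = sum singles - sum pairwise + triple
        (three-set case)."""
        if len(self.times) != 3:
            return True
        return self.union == (sum(self.singles.values())
                              - sum(self.pairwise.values()) + self.triple)


def _call(log2fc: float, p: float, alpha: float, thr: float) -> tuple[bool, str]:
    regulated = bool(p <= alpha and abs(log2fc) > thr)
    direction = "none" if not regulated else ("up" if log2fc > 0 else "down")
    return regulated, direction


def paired_diff_test(table: PsiteQuantTable, time: int,
                     alpha: float = 0.05, lfc_threshold: float = 0.3,
                     paired: bool = True) -> list[DiffResult]:
    """Differential test for every row at one time point.

    Rows with fewer than two complete replicate pairs are excluded.  All-zero
    differences yield p = 1 (no change); identical non-zero differences have
    an unbounded t statistic and are reported with the smallest positive
    float as p and flagged ``degenerate_variance``.
    """
    low = table.condition_block("low", time)
    high = table.condition_block("high", time)
    high.columns = low.columns
    results: list[DiffResult] = []
    for key in table.values.index:
        lo = low.loc[key].to_numpy(dtype=float)
        hi = high.loc[key].to_numpy(dtype=float)
        ok = ~(np.isnan(lo) | np.isnan(hi))
        if ok.sum() < 2:
            continue
        lo, hi = lo[ok], hi[ok]
        d = hi - lo
        lfc = float(np.mean(d))
        degenerate = False
        if paired:
            if np.allclose(d, d[0]):
                if np.allclose(d, 0.0):
                    p = 1.0
                else:
                    p, degenerate = DEGENERATE_P, True
            else:
                p = float(stats.ttest_rel(hi, lo).pvalue)
        else:
            if np.allclose(np.concatenate([lo, hi]),
                           np.concatenate([lo, hi])[0]):
                p = 1.0
            else:
                p = float(stats.ttest_ind(hi, lo).pvalue)
        regulated, direction = _call(lfc, p, alpha, lfc_threshold)
        results.append(DiffResult(key, time, lfc, p, int(ok.sum()),
                                  regulated, direction, degenerate))
    return results


def diff_all_times(table: PsiteQuantTable, config: RunConfig | None = None
                   ) -> dict[int, list[DiffResult]]:
    config = config or RunConfig()
    return {t: paired_diff_test(table, t, config.alpha, config.lfc_threshold,
                                paired=config.paired)
            for t in config.times}


def lfc_percent_equivalent(lfc_threshold: float) -> float:
    """Percent change equivalent of a log2 fold-change threshold:
    100 * (2**threshold - 1).  A threshold of 0.3 is a 23% change."""
    if lfc_threshold < 0:
        raise ValueError("lfc_threshold must be non-negative")
    return 100.0 * (2.0 ** lfc_threshold - 1.0)


def regulated_keys(diffs: list[DiffResult]) -> set[str]:
    return {d.key for d in diffs if d.regulated}


def overlap_analysis(regulated_by_time: dict[int, set[str]]) -> OverlapCounts:
    """Exact set algebra over the regulated sets; percentages are relative
    to the union of all regulated keys."""
    times = tuple(sorted(regulated_by_time))
    if len(times) < 2:
        raise ValueError("overlap analysis needs at least two time points")
    sets = {t: set(regulated_by_time[t]) for t in times}
    singles = {t: len(sets[t]) for t in times}
    pairwise = {(a, b): len(sets[a] & sets[b])
                for i, a in enumerate(times) for b in times[i + 1:]}
    inter = set.intersection(*sets.values())
    union = set.union(*sets.values())
    exclusive = {t: len(sets[t] - set.union(*(sets[o] for o in times if o != t)))
                 for t in times}
    shared = 100.0 * len(inter) / len(union) if union else 0.0
    return OverlapCounts(times, singles, pairwise, len(inter), len(union),
                         shared, exclusive)


def reconcile_protein_level(psite_diffs: list[DiffResult],
                            protein_diffs: list[DiffResult],
                            key_to_protein: dict[str, str]) -> dict:
    """How many proteins carrying regulated p-sites are themselves regulated
    at the total-protein level (the "10/76" ratio form).

    Returns per-protein annotations: a site on a protein-regulated parent is
    flagged protein-confounded, since its apparent phospho-change may simply
    track protein abundance.
    """
    psite_prot = {key_to_protein[d.key] for d in psite_diffs if d.regulated}
    prot_reg = {d.key for d in protein_diffs if d.regulated}
    both = psite_prot & prot_reg
    confounded = sorted(d.key for d in psite_diffs
                        if d.regulated and key_to_protein[d.key] in prot_reg)
    denom = len(psite_prot)
    return {
        "psite_regulated_proteins": denom,
        "also_protein_regulated": len(both),
        "fraction_percent": 100.0 * len(both) / denom if denom else 0.0,
        "confounded_sites": confounded,
    }


def volcano_table(diffs: list[DiffResult]) -> pd.DataFrame:
    """Volcano-plot export: log2FC vs -log10 p with the regulation flag.

    p-values of exactly 0 are capped at -log10 p = 320 so the column stays
    finite; rows are sorted by ascending p.  A BH-adjusted column is added.
    """
    if not diffs:
        return pd.DataFrame(columns=["key", "log2fc", "neg_log10_p", "p_value",
                                     "p_bh", "regulated", "direction"])
    df = pd.DataFrame({
        "key": [d.key for d in diffs],
        "log2fc": [d.log2fc for d in diffs],
        "p_value": [d.p_value for d in diffs],
        "regulated": [d.regulated for d in diffs],
        "direction": [d.direction for d in diffs],
    })
    with np.errstate(divide="ignore"):
        df["neg_log10_p"] = np.minimum(-np.log10(df["p_value"]), VOLCANO_P_CAP)
    df["p_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df[["key", "log2fc", "neg_log10_p", "p_value", "p_bh",
               "regulated", "direction"]].sort_values(
        ["p_value", "key"]).reset_index(drop=True)
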