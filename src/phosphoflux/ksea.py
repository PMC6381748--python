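"""Kinase-substrate enrichment analysis (KSEA).

An enzyme's activity change is inferred from the aggregate fold-change
shift of its known substrate p-sites relative to the whole quantified
dataset:

    z = (s_bar - p_bar) * sqrt(m) / delta

with s_bar the mean log2FC of the m substrate-group members, p_bar the mean
log2FC of all quantified p-sites in that replicate/time, and delta their
standard deviation.  Two-sided significance comes from the standard normal;
a permutation p-value over random same-size site subsets is available as an
independent check of the normal approximation.

Sign convention: for kinases a high score denotes activation; for
phosphatases the reading inverts (their substrates lose phosphate when the
enzyme is active), so a low score denotes activation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import KinaseSubstrateDB, PsiteQuantTable
from .trajectories import order_for_heatmap

__all__ = [
    "SubstrateGroup",
    "KseaScore",
    "KseaMatrix",
    "match_substrates",
    "ksea_zscore",
    "ksea_permutation_p",
    "ksea_over_time",
    "classify_activity_trajectories",
]

HIGHLIGHT_THRESHOLD = 2.0   # |z| beyond which a score is highlighted


@dataclass
class SubstrateGroup:
    enzyme_name: str
    enzyme_class: str                     # kinase | phosphatase
    members: list[str]                    # canonical p-site strings
    match_modes: dict[str, str] = field(default_factory=dict)  # key -> db-site|motif

    @property
    def m(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class KseaScore:
    enzyme_name: str
    z: float
    p_value: float
    m: int
    time: int | None = None
    replicate: int | str | None = None
    enzyme_class: str = "kinase"

    @property
    def interpreted_activity(self) -> str:
        if self.z == 0:
            return "unchanged"
        kinase_reading = "activated" if self.z > 0 else "inhibited"
        if self.enzyme_class == "phosphatase":
            return "inhibited" if kinase_reading == "activated" else "activated"
        return kinase_reading


@dataclass
class KseaMatrix:
    """Per-replicate and replicate-averaged enzyme x time score matrices."""

    per_replicate: pd.DataFrame   # rows enzymes, cols (time, replicate)
    mean: pd.DataFrame            # rows enzymes, cols times
    p_values: pd.DataFrame        # per-replicate two-sided normal p
    p_bh: pd.DataFrame            # BH across enzymes within (time, replicate)
    group_sizes: dict[str, int]
    enzyme_classes: dict[str, str]
    row_order: list[str]
    excluded_low_m: list[str]

    def highlighted(self) -> pd.DataFrame:
        return self.mean.abs() > HIGHLIGHT_THRESHOLD

    def top_bottom(self, n: int = 30) -> tuple[list[str], list[str]]:
        """Enzymes with the highest / lowest overall mean score."""
        overall = self.mean.mean(axis=1).sort_values(ascending=False)
        top = list(overall.index[:n])
        bottom = list(overall.index[::-1][:n])
        return top, bottom


def _window_center(window: str) -> int:
    return len(window) // 2


def _motif_hits_center(pattern: str, window: str) -> bool:
    """True when a motif match covers the central (phospho) residue."""
    center = _window_center(window)
    for m in re.finditer(pattern, window):
        if m.start() <= center < m.end():
            return True
    return False


def match_substrates(table: PsiteQuantTable, ksdb: KinaseSubstrateDB,
                     match_on: str = "gene") -> list[SubstrateGroup]:
    """Build substrate groups by (identifier, site) join and motif match.

    ``match_on`` is ``"gene"`` (uppercase gene symbol + residue/position,
    the default since the cited databases are largely human-centric and
    symbols travel across species better than accessions) or ``"accession"``
    for exact accession joins.  A multi-site feature joins any group whose
    site list intersects its sites, once per group.  Motif groups match the
    feature's +/-7-residue peptide window at the phospho-residue.
    """
    if len(ksdb) == 0 and not ksdb.motif_groups:
        raise ValueError("empty kinase-substrate database")
    # index the quantified dataset by (identifier, residue+position)
    site_index: dict[tuple[str, str], set[str]] = {}
    for key, gene in zip(table.values.index, table.meta["gene"]):
        acc, _, sitepart = key.rpartition("_")
        ident = (gene.upper() if match_on == "gene" and gene else acc)
        for tok in sitepart.split("/"):
            site_index.setdefault((ident, tok), set()).add(key)
    groups: dict[str, SubstrateGroup] = {}
    classes = ksdb.enzyme_classes()
    id_col = "substrate_gene" if match_on == "gene" else "substrate_acc"
    for _, rec in ksdb.records.iterrows():
        ident = rec[id_col] or rec["substrate_acc" if match_on == "gene"
                                   else "substrate_gene"]
        hits = site_index.get((ident, rec["site"]), set())
        for key in sorted(hits):
            g = groups.setdefault(rec["enzyme"], SubstrateGroup(
                rec["enzyme"], classes[rec["enzyme"]], []))
            if key not in g.match_modes:
                g.members.append(key)
                g.match_modes[key] = "db-site"
    for name, pattern in ksdb.motif_groups.items():
        for key, pep in zip(table.values.index, table.meta["peptide"]):
            if pep and _motif_hits_center(pattern, pep):
                g = groups.setdefault(name, SubstrateGroup(name, "kinase", []))
                if key not in g.match_modes:
                    g.members.append(key)
                    g.match_modes[key] = "motif"
    return [groups[name] for name in sorted(groups)]


def match_coverage(groups: list[SubstrateGroup], table: PsiteQuantTable) -> dict:
    matched = set().union(*(g.members for g in groups)) if groups else set()
    total = len(table)
    return {"matched_sites": len(matched), "total_sites": total,
            "coverage_fraction": len(matched) / total if total else 0.0,
            "n_enzymes": len(groups)}


def ksea_zscore(group_fcs: np.ndarray, all_fcs: np.ndarray,
                enzyme_name: str = "", enzyme_class: str = "kinase",
                time: int | None = None,
                replicate: int | str | None = None) -> KseaScore:
    """Mean-based KSEA z-score with two-sided normal p."""
    group_fcs = np.asarray(group_fcs, dtype=float)
    all_fcs = np.asarray(all_fcs, dtype=float)
    m = len(group_fcs)
    if m == 0:
        raise ValueError("empty substrate group")
    delta = float(np.std(all_fcs, ddof=1))
    if delta == 0:
        raise ValueError("degenerate background: zero variance in fold changes")
    z = float((group_fcs.mean() - all_fcs.mean()) * np.sqrt(m) / delta)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return KseaScore(enzyme_name, z, p, m, time, replicate, enzyme_class)


def ksea_permutation_p(group_fcs: np.ndarray, all_fcs: np.ndarray,
                       n_perm: int = 10000, seed: int = 1) -> float:
    """Two-sided permutation p for a group's z from random same-size subsets
    of the background.  Uses the add-one estimator (never exactly 0)."""
    group_fcs = np.asarray(group_fcs, dtype=float)
    all_fcs = np.asarray(all_fcs, dtype=float)
    m, n = len(group_fcs), len(all_fcs)
    if n_perm < 1000:
        raise ValueError("n_perm must be at least 1000")
    if m >= n:
        raise ValueError("group must be a strict subset of the background")
    obs = abs(group_fcs.mean() - all_fcs.mean())
    rng = np.random.default_rng(seed)
    hits = 0
    batch = 10000
    done = 0
    mu = all_fcs.mean()
    while done < n_perm:
        b = min(batch, n_perm - done)
        keys = rng.random((b, n))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        means = all_fcs[idx].mean(axis=1)
        hits += int(np.sum(np.abs(means - mu) >= obs - 1e-15))
        done += b
    return (hits + 1) / (n_perm + 1)


def replicate_fold_changes(table: PsiteQuantTable, time: int) -> pd.DataFrame:
    """Per-replicate log2FC (high_i - low_i) for every row at one time."""
    low = table.condition_block("low", time)
    high = table.condition_block("high", time)
    high.columns = low.columns
    return high - low


def ksea_over_time(table: PsiteQuantTable, groups: list[SubstrateGroup],
                   min_m: int = 1, min_m_for_p: int = 2) -> KseaMatrix:
    """Per-replicate z for every (enzyme, time, replicate), replicate means,
    and a complete-linkage row ordering of the mean profiles.

    Enzymes whose matched group is smaller than ``min_m`` are excluded and
    listed; normal p-values are reported only for groups with at least
    ``min_m_for_p`` members (single-substrate scores are too fragile to
    star).
    """
    kept = [g for g in groups if g.m >= min_m]
    excluded = sorted(g.enzyme_name for g in groups if g.m < min_m)
    times = table.times
    cols = []
    zs: dict[str, list[float]] = {g.enzyme_name: [] for g in kept}
    ps: dict[str, list[float]] = {g.enzyme_name: [] for g in kept}
    for t in times:
        fcs = replicate_fold_changes(table, t)
        for rep in fcs.columns:
            col = fcs[rep].dropna()
            cols.append((t, rep))
            for g in kept:
                members = [k for k in g.members if k in col.index]
                if not members:
                    zs[g.enzyme_name].append(np.nan)
                    ps[g.enzyme_name].append(np.nan)
                    continue
                score = ksea_zscore(col.loc[members].to_numpy(), col.to_numpy(),
                                    g.enzyme_name, g.enzyme_class, t, rep)
                zs[g.enzyme_name].append(score.z)
                ps[g.enzyme_name].append(score.p_value
                                         if len(members) >= min_m_for_p else np.nan)
    mi = pd.MultiIndex.from_tuples(cols, names=["time", "replicate"])
    enzymes = [g.enzyme_name for g in kept]
    per_rep = pd.DataFrame([zs[e] for e in enzymes], index=enzymes, columns=mi)
    p_raw = pd.DataFrame([ps[e] for e in enzymes], index=enzymes, columns=mi)
    p_bh = p_raw.copy()
    for c in p_bh.columns:
        mask = p_bh[c].notna()
        if mask.any():
            p_bh.loc[mask, c] = multipletests(p_raw.loc[mask, c],
                                              method="fdr_bh")[1]
    mean = per_rep.T.groupby(level="time").mean().T[list(times)]
    order = (order_for_heatmap(mean.dropna(how="any"))
             if len(mean.dropna(how="any")) > 1 else list(mean.index))
    return KseaMatrix(per_rep, mean, p_raw, p_bh,
                      {g.enzyme_name: g.m for g in kept},
                      {g.enzyme_name: g.enzyme_class for g in kept},
                      order, excluded)


def classify_activity_trajectories(matrix: KseaMatrix) -> pd.DataFrame:
    """Label each enzyme by the direction and timing of its largest score
    change.

    The mean score series is prepended with 0 (no enrichment before
    stimulation); the largest-magnitude change between consecutive points
    gives the direction, and the interval in which it occurs gives the
    timing class (first interval = early, then intermediate, late).  Flat
    profiles are 'unchanged'.  Phosphatases additionally carry the inverted
    activity interpretation.
    """
    times = list(matrix.mean.columns)
    timing_names = {0: "early", 1: "intermediate", 2: "late"}
    rows = []
    for enzyme, series in matrix.mean.iterrows():
        y = np.concatenate([[0.0], series.to_numpy(dtype=float)])
        if np.any(np.isnan(y)):
            rows.append((enzyme, "unscored", "unscored", "unscored"))
            continue
        steps = np.diff(y)
        if np.allclose(steps, 0.0):
            rows.append((enzyme, "unchanged", "unchanged", "unchanged"))
            continue
        imax = int(np.argmax(np.abs(steps)))
        direction = "positive" if steps[imax] > 0 else "negative"
        timing = timing_names.get(imax, "late")
        cls = matrix.enzyme_classes.get(enzyme, "kinase")
        kinase_reading = "activated" if direction == "positive" else "inhibited"
        activity = (kinase_reading if cls == "kinase"
                    else ("inhibited" if kinase_reading == "activated"
                          else "activated"))
        rows.append((enzyme, direction, timing, activity))
    return pd.DataFrame(rows, columns=["enzyme", "direction", "timing",
                                       "interpreted_activity"]
                        ).set_index("enzyme")
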