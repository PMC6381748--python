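"""Kinetic-archetype clustering of phosphorylation trajectories.

The three-step longitudinal-clustering procedure: (1) describe each
trajectory by a catalogue of scalar measures, (2) select the most
informative measures by factor analysis (principal components on the
correlation matrix, Kaiser eigenvalue > 1 retention, varimax rotation,
highest-|loading| measure per retained factor), (3) partition trajectories
by k-medoids under the 1-norm on the selected, standardized measures.

Trajectories are the per-time log2 fold changes prepended with 0 at t = 0:
the glucose-relative change is zero before stimulation, and the fourth
point keeps the second-difference measures non-degenerate.  The mean of the
second differences is computed but excluded from clustering by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import cdist, squareform

from .differential import DiffResult

__all__ = [
    "Trajectory",
    "TrajectoryClusterModel",
    "MEASURE_NAMES",
    "EXCLUDED_MEASURE",
    "build_trajectories",
    "trajectory_measures",
    "measure_matrix",
    "select_informative_measures",
    "cluster_trajectories",
    "gower_dissimilarity",
    "order_for_heatmap",
]

EXCLUDED_MEASURE = "mean_second_diff"

MEASURE_NAMES = (
    "range",
    "mean_over_time",
    "sd",
    "cv",
    "total_change",
    "mean_change_per_time",
    "change_rel_first",
    "change_rel_mean",
    "slope",
    "slope_r2",
    "max_first_diff",
    "sd_first_diff",
    "mean_abs_first_diff",
    "max_abs_first_diff",
    "ratio_mean_abs_first_to_total",
    "mean_second_diff",
    "mean_abs_second_diff",
    "max_abs_second_diff",
    "ratio_second_to_first",
)

ARCHETYPES = ("early-sustained", "early-transient", "intermediate", "late")


@dataclass(frozen=True)
class Trajectory:
    key: str
    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must be the same length")
        if not all(np.isfinite(self.values)):
            raise ValueError(f"non-finite trajectory values for {self.key}")


@dataclass
class TrajectoryClusterModel:
    keys: list[str]
    measures: pd.DataFrame            # standardized, selected measures
    selected_measures: list[str]
    assignments: np.ndarray           # cluster index 1..k per key
    medoid_keys: list[str]
    cost: float
    archetype_labels: dict[int, str] = field(default_factory=dict)
    archetype_signs: dict[int, str] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.medoid_keys)

    def cluster_sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.assignments, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def build_trajectories(diffs_by_time: dict[int, list[DiffResult]],
                       top_n: int | None = None,
                       baseline: bool = True) -> list[Trajectory]:
    """Trajectories for the union of regulated p-sites across time points.

    A candidate missing a fold change at any time point is excluded.  With
    ``top_n`` the list is reduced to the most markedly changed sites, ranked
    by max |log2FC| across times (ties broken by key).
    """
    times = sorted(diffs_by_time)
    fc: dict[str, dict[int, float]] = {}
    regulated: set[str] = set()
    for t, diffs in diffs_by_time.items():
        for d in diffs:
            fc.setdefault(d.key, {})[t] = d.log2fc
            if d.regulated:
                regulated.add(d.key)
    out = []
    for key in sorted(regulated):
        if any(t not in fc[key] for t in times):
            continue
        vals = [fc[key][t] for t in times]
        if baseline:
            out.append(Trajectory(key, (0.0, *map(float, times)),
                                  (0.0, *vals)))
        else:
            out.append(Trajectory(key, tuple(map(float, times)), tuple(vals)))
    if top_n is not None:
        out.sort(key=lambda tr: (-max(abs(v) for v in tr.values), tr.key))
        out = out[:top_n]
        out.sort(key=lambda tr: tr.key)
    return out


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den != 0 else np.nan


def trajectory_measures(traj: Trajectory) -> pd.Series:
    """All descriptive measures for one trajectory.

    Ratios with a zero denominator are flagged as missing (NaN); such
    measures are dropped before factor analysis rather than imputed.
    """
    t = np.asarray(traj.times, dtype=float)
    y = np.asarray(traj.values, dtype=float)
    if len(y) < 3:
        raise ValueError("trajectory measures need at least 3 points")
    d1 = np.diff(y)
    d2 = np.diff(d1)
    mean = float(np.mean(y))
    sd = float(np.std(y, ddof=1))
    total = float(y[-1] - y[0])
    # least-squares slope of y on t and its R^2
    tc = t - t.mean()
    slope = float(np.dot(tc, y - mean) / np.dot(tc, tc))
    ss_tot = float(np.dot(y - mean, y - mean))
    ss_reg = float(slope ** 2 * np.dot(tc, tc))
    r2 = ss_reg / ss_tot if ss_tot > 0 else 0.0
    mean_abs_d1 = float(np.mean(np.abs(d1)))
    vals = {
        "range": float(y.max() - y.min()),
        "mean_over_time": mean,
        "sd": sd,
        "cv": _safe_ratio(sd, abs(mean)),
        "total_change": total,
        "mean_change_per_time": total / float(t[-1] - t[0]),
        "change_rel_first": _safe_ratio(total, abs(float(y[0]))),
        "change_rel_mean": _safe_ratio(total, abs(mean)),
        "slope": slope,
        "slope_r2": r2,
        "max_first_diff": float(d1.max()),
        "sd_first_diff": float(np.std(d1, ddof=1)),
        "mean_abs_first_diff": mean_abs_d1,
        "max_abs_first_diff": float(np.abs(d1).max()),
        "ratio_mean_abs_first_to_total": _safe_ratio(mean_abs_d1, abs(total)),
        "mean_second_diff": float(np.mean(d2)) if len(d2) else np.nan,
        "mean_abs_second_diff": float(np.mean(np.abs(d2))) if len(d2) else np.nan,
        "max_abs_second_diff": float(np.abs(d2).max()) if len(d2) else np.nan,
        "ratio_second_to_first": (_safe_ratio(float(np.mean(np.abs(d2))),
                                              mean_abs_d1)
                                  if len(d2) else np.nan),
    }
    return pd.Series(vals, index=list(MEASURE_NAMES))


def measure_matrix(trajectories: list[Trajectory]) -> pd.DataFrame:
    return pd.DataFrame({tr.key: trajectory_measures(tr)
                         for tr in trajectories}).T


def _varimax(loadings: np.ndarray, tol: float = 1e-8, max_iter: int = 200
             ) -> np.ndarray:
    """Varimax rotation of a loading matrix (Kaiser, unnormalized)."""
    p, k = loadings.shape
    if k < 2:
        return loadings
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        L = loadings @ R
        u, s, vt = np.linalg.svd(
            loadings.T @ (L ** 3 - L @ np.diag(np.sum(L ** 2, axis=0)) / p))
        R = u @ vt
        var_new = float(np.sum(s))
        if var_new - var_old < tol:
            break
        var_old = var_new
    return loadings @ R


def select_informative_measures(measures: pd.DataFrame,
                                exclude: tuple[str, ...] = (EXCLUDED_MEASURE,)
                                ) -> list[str]:
    """Pick one representative measure per retained factor.

    Degenerate measures (any missing value, or zero variance across
    trajectories) are dropped first, as are the excluded measures.  The
    remaining measures are standardized; principal factors of their
    correlation matrix with eigenvalue > 1 are retained and varimax-rotated;
    the measure with the highest absolute loading on each retained factor is
    selected.
    """
    cand = measures.drop(columns=[c for c in exclude if c in measures.columns])
    cand = cand.loc[:, cand.notna().all(axis=0)]
    cand = cand.loc[:, cand.std(axis=0, ddof=1) > 0]
    if cand.shape[1] == 0:
        raise ValueError("no variance to factor: all measures constant or missing")
    if cand.shape[1] == 1:
        return [cand.columns[0]]
    Z = (cand - cand.mean()) / cand.std(ddof=1)
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_factors = max(1, int(np.sum(eigval > 1.0)))
    loadings = eigvec[:, :n_factors] * np.sqrt(np.maximum(eigval[:n_factors], 0))
    loadings = _varimax(loadings)
    selected: list[str] = []
    for j in range(n_factors):
        ranked = np.argsort(-np.abs(loadings[:, j]))
        for idx in ranked:
            name = cand.columns[idx]
            if name not in selected:
                selected.append(name)
                break
    return selected


def _kmedoids_once(D: np.ndarray, k: int, rng: np.random.Generator,
                   max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, float]:
    n = D.shape[0]
    medoids = np.sort(rng.choice(n, size=k, replace=False))
    for _ in range(max_iter):
        assign = np.argmin(D[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for j in range(k):
            members = np.where(assign == j)[0]
            if len(members) == 0:
                continue
            intra = D[np.ix_(members, members)].sum(axis=0)
            new_medoids[j] = members[int(np.argmin(intra))]
        new_medoids = np.sort(new_medoids)
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    assign = np.argmin(D[:, medoids], axis=1)
    cost = float(D[np.arange(n), medoids[assign]].sum())
    return medoids, assign, cost


def cluster_trajectories(selected: pd.DataFrame, k: int, seed: int = 1,
                         restarts: int = 50,
                         trajectories: list[Trajectory] | None = None
                         ) -> TrajectoryClusterModel:
    """k-medoids partition under the Manhattan (1-norm) distance.

    ``selected`` holds the selected measures (rows = trajectories); columns
    are standardized before distance computation.  The best of ``restarts``
    random initializations (lowest total within-cluster cost) is kept;
    results are reproducible for a fixed seed.  When the source trajectories
    are supplied, each cluster is labeled with a kinetic archetype from its
    mean trajectory.
    """
    n = len(selected)
    if k > n:
        raise ValueError(f"k={k} exceeds number of trajectories n={n}")
    sd = selected.std(ddof=1).replace(0.0, 1.0)
    Z = ((selected - selected.mean()) / sd).to_numpy(dtype=float)
    D = cdist(Z, Z, metric="cityblock")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(restarts):
        medoids, assign, cost = _kmedoids_once(D, k, rng)
        if best is None or cost < best[2] - 1e-12:
            best = (medoids, assign, cost)
    medoids, assign, cost = best
    model = TrajectoryClusterModel(
        keys=list(selected.index),
        measures=pd.DataFrame(Z, index=selected.index, columns=selected.columns),
        selected_measures=list(selected.columns),
        assignments=assign + 1,
        medoid_keys=[selected.index[m] for m in medoids],
        cost=cost,
    )
    if trajectories is not None:
        by_key = {tr.key: tr for tr in trajectories}
        for c in range(1, k + 1):
            members = [key for key, a in zip(model.keys, model.assignments)
                       if a == c and key in by_key]
            if not members:
                continue
            mean_traj = np.mean([by_key[m].values for m in members], axis=0)
            label, sign = label_archetype(mean_traj)
            model.archetype_labels[c] = label
            model.archetype_signs[c] = sign
    return model


def label_archetype(values: np.ndarray) -> tuple[str, str]:
    """Kinetic archetype of a (baseline-augmented) mean trajectory.

    'early' when the largest |step| is the first interval, further split
    into transient (final value back within 50% of the peak excursion) vs
    sustained; otherwise 'intermediate'/'late' by the interval of the
    largest |step|.  Sign follows the peak excursion.
    """
    y = np.asarray(values, dtype=float)
    steps = np.diff(y)
    if np.allclose(y, y[0]):
        return "unchanged", "none"
    peak_idx = int(np.argmax(np.abs(y[1:]))) + 1
    sign = "up" if y[peak_idx] > 0 else "down"
    imax = int(np.argmax(np.abs(steps)))
    if imax == 0:
        if abs(y[-1]) < 0.5 * abs(y[peak_idx]):
            return "early-transient", sign
        return "early-sustained", sign
    if imax == len(steps) - 1:
        return "late", sign
    return "intermediate", sign


# --------------------------------------------------------------------------
# heatmap row ordering


def gower_dissimilarity(matrix: pd.DataFrame) -> np.ndarray:
    """Gower dissimilarity for all-quantitative data: per-variable Manhattan
    distance scaled by the variable's range, averaged over variables.
    Zero-range (constant) variables carry no information and are dropped,
    so the ordering is invariant to appending a constant column."""
    X = matrix.to_numpy(dtype=float)
    ranges = X.max(axis=0) - X.min(axis=0)
    keep = ranges > 0
    if not keep.any():
        return np.zeros((len(X), len(X)))
    Xs = X[:, keep] / ranges[keep]
    return cdist(Xs, Xs, metric="cityblock") / keep.sum()


def order_for_heatmap(matrix: pd.DataFrame) -> list:
    """Leaf order of complete-linkage hierarchical clustering under the
    Gower dissimilarity.  Rows are first sorted by id so the result depends
    only on the (id, row) pairs, not their input order."""
    matrix = matrix.sort_index()
    if len(matrix) <= 1:
        return list(matrix.index)
    D = gower_dissimilarity(matrix)
    Z = linkage(squareform(D, checks=False), method="complete")
    return [matrix.index[i] for i in leaves_list(Z)]
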