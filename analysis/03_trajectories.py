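#!/usr/bin/env python
"""Kinetic-archetype clustering of regulated p-site trajectories.

Builds baseline-augmented log2FC trajectories for the union of regulated
p-sites, selects informative descriptive measures by factor analysis,
partitions them with k-medoids (k = 4, 1-norm), and writes the assignments,
archetype labels, and the Gower/complete-linkage heatmap ordering.
"""

import argparse
from pathlib import Path

import pandas as pd

from phosphoflux import differential as diff
from phosphoflux import trajectories as traj
from phosphoflux.io_formats import RunConfig, read_quant_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("results") / "data")
    ap.add_argument("--out-dir", type=Path,
                    default=Path("results") / "trajectories")
    ap.add_argument("--k", type=int, default=4)
    ap.add_argument("--top-n", type=int, default=None)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)
    rc = RunConfig()

    table = read_quant_table(args.data_dir / "psites.tsv", rc)
    diffs = diff.diff_all_times(table, rc)
    trs = traj.build_trajectories(diffs, top_n=args.top_n)
    mm = traj.measure_matrix(trs)
    selected = traj.select_informative_measures(mm)
    model = traj.cluster_trajectories(mm[selected], args.k, seed=args.seed,
                                      trajectories=trs)
    pd.DataFrame({
        "psite": model.keys, "cluster": model.assignments,
        "archetype": [model.archetype_labels.get(a, "")
                      for a in model.assignments],
        "sign": [model.archetype_signs.get(a, "")
                 for a in model.assignments],
    }).to_csv(out / "clusters.tsv", sep="\t", index=False)
    fc = pd.DataFrame({tr.key: tr.values for tr in trs},
                      index=[f"t{int(t)}" for t in trs[0].times]).T
    order = traj.order_for_heatmap(fc)
    (out / "heatmap_order.txt").write_text("\n".join(order) + "\n")

    print(f"{len(trs)} trajectories; selected measures: "
          f"{', '.join(selected)}")
    for c, size in sorted(model.cluster_sizes().items()):
        print(f"cluster {c}: {size:>4} p-sites  "
              f"{model.archetype_labels.get(c, '?')} "
              f"({model.archetype_signs.get(c, '?')})")


if __name__ == "__main__":
    main()
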