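#!/usr/bin/env python
"""Kinase/phosphatase activity inference over the time course (KSEA).

Matches quantified p-sites to the kinase-substrate relationship table,
scores every (enzyme, time, replicate) with the mean-based enrichment z,
averages replicates, classifies temporal activity trajectories, and writes
the top/bottom enzymes by mean score.
"""

import argparse
import json
from pathlib import Path

from phosphoflux import ksea as ks
from phosphoflux.io_formats import RunConfig, read_ksdb, read_quant_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("results") / "data")
    ap.add_argument("--out-dir", type=Path, default=Path("results") / "ksea")
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)
    rc = RunConfig()

    table = read_quant_table(args.data_dir / "psites.tsv", rc)
    db = read_ksdb(args.data_dir / "ksdb.tsv")
    groups = ks.match_substrates(table, db)
    cov = ks.match_coverage(groups, table)
    matrix = ks.ksea_over_time(table, groups, rc.ksea_min_m,
                               rc.ksea_min_m_for_p)
    matrix.mean.loc[matrix.row_order].to_csv(out / "ksea_mean.tsv", sep="\t",
                                             float_format="%.6g")
    flat = matrix.per_replicate.copy()
    flat.columns = [f"{t}_r{r}" for t, r in flat.columns]
    flat.to_csv(out / "ksea_replicates.tsv", sep="\t", float_format="%.6g")
    classes = ks.classify_activity_trajectories(matrix)
    classes.to_csv(out / "ksea_classes.tsv", sep="\t")
    top, bottom = matrix.top_bottom()
    (out / "top_bottom.json").write_text(json.dumps(
        {"top": top, "bottom": bottom}, indent=1))

    print(f"matched {cov['matched_sites']} of {cov['total_sites']} p-sites "
          f"to {cov['n_enzymes']} enzymes "
          f"({100 * cov['coverage_fraction']:.1f}% coverage)")
    n_hl = int(matrix.highlighted().to_numpy().sum())
    print(f"{n_hl} replicate-mean scores beyond |z| = 2")
    print(classes.groupby(["direction", "timing"]).size().to_string())


if __name__ == "__main__":
    main()
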