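#!/usr/bin/env python
"""Gene-set over-representation of regulated proteins per time point.

Hypergeometric upper-tail p against the quantified-protein universe with
Benjamini-Hochberg FDR, plus the cross-time differential ranking (sets
sorted by the SD of -log10 p across the three time-point groups).
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from phosphoflux import differential as diff
from phosphoflux import enrichment as enr
from phosphoflux.io_formats import RunConfig, read_gmt, read_quant_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("results") / "data")
    ap.add_argument("--out-dir", type=Path,
                    default=Path("results") / "enrichment")
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)
    rc = RunConfig()

    table = read_quant_table(args.data_dir / "psites.tsv", rc)
    collection = read_gmt(args.data_dir / "sets.gmt")
    key_gene = dict(zip(table.values.index, table.meta["gene"]))
    universe = {g.upper() for g in key_gene.values() if g}
    diffs = diff.diff_all_times(table, rc)
    per_group = {}
    for t, d in diffs.items():
        query = {key_gene[x.key].upper() for x in d
                 if x.regulated and key_gene[x.key]}
        res = enr.hypergeom_enrichment(query, collection, universe)
        pd.DataFrame([dataclasses.asdict(r) for r in res]).to_csv(
            out / f"enrichment_{t}min.tsv", sep="\t", index=False,
            float_format="%.6g")
        per_group[str(t)] = res
        sig = [r for r in res if r.fdr <= 0.05]
        print(f"{t:>3} min: {len(query)} query genes, "
              f"{len(sig)} sets at FDR <= 0.05 "
              f"(top: {res[0].set_name}, p = {res[0].p_value:.2g})")
    ranking = enr.differential_go_ranking(per_group)
    ranking.to_csv(out / "differential_go.tsv", sep="\t", index=False,
                   float_format="%.6g")
    print(f"most differential set across times: "
          f"{ranking['set_name'].iloc[0]} "
          f"(SD of -log10 p = {ranking['sd_neg_log10_p'].iloc[0]:.2f})")


if __name__ == "__main__":
    main()
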