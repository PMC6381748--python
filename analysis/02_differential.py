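#!/usr/bin/env python
"""Differential phosphorylation over the time course.

Paired t-tests per p-site and time point with the p <= 0.05 and
|log2FC| > 0.3 regulation gates, volcano exports, the cross-time Venn
summary, and the p-site vs protein-level reconciliation.
"""

import argparse
import dataclasses
import json
from pathlib import Path

from phosphoflux import differential as diff
from phosphoflux.io_formats import RunConfig, read_quant_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("results") / "data")
    ap.add_argument("--out-dir", type=Path,
                    default=Path("results") / "differential")
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)
    rc = RunConfig()

    table = read_quant_table(args.data_dir / "psites.tsv", rc)
    diffs = diff.diff_all_times(table, rc)
    for t, d in diffs.items():
        diff.volcano_table(d).to_csv(out / f"diff_{t}min.tsv", sep="\t",
                                     index=False, float_format="%.6g")
    reg = {t: diff.regulated_keys(d) for t, d in diffs.items()}
    o = diff.overlap_analysis(reg)
    payload = dataclasses.asdict(o)
    payload["pairwise"] = {f"{a}&{b}": v for (a, b), v in o.pairwise.items()}
    (out / "overlap.json").write_text(json.dumps(payload, indent=1,
                                                 sort_keys=True))

    ptable = read_quant_table(args.data_dir / "proteins.tsv", rc)
    key_to_protein = dict(zip(table.values.index, table.meta["protein"]))
    recon = {}
    for t, d in diffs.items():
        pdiffs = [dataclasses.replace(x, key=x.key.rpartition("_")[0])
                  for x in diff.paired_diff_test(ptable, t)]
        recon[t] = diff.reconcile_protein_level(d, pdiffs, key_to_protein)
    (out / "reconciliation.json").write_text(json.dumps(
        {str(t): {k: v for k, v in r.items() if k != "confounded_sites"}
         for t, r in recon.items()}, indent=1, sort_keys=True))

    percent = diff.lfc_percent_equivalent(rc.lfc_threshold)
    print(f"log2FC threshold {rc.lfc_threshold} = {percent:.1f}% change")
    for t in sorted(reg):
        r = recon[t]
        print(f"{t:>3} min: {len(reg[t])} regulated p-sites; "
              f"{r['also_protein_regulated']}/{r['psite_regulated_proteins']} "
              f"proteins also regulated at the protein level "
              f"({r['fraction_percent']:.0f}%)")
    print(f"shared across all times: {o.triple} of {o.union} "
          f"({o.shared_fraction:.1f}%)")


if __name__ == "__main__":
    main()
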