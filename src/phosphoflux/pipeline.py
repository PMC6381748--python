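"""Orchestration of the full time-course analysis.

Stages run in order: ingest -> differential (p-site and optional protein
level) -> overlap -> trajectory clustering -> KSEA -> enrichment.  Every
output file is stamped with the configuration hash; re-running an identical
configuration reproduces byte-identical numeric outputs.  A stage failure
halts the run with a stage-named error; outputs already written are kept
next to a FAILED marker.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import differential as diff
from . import enrichment as enr
from . import ksea as ks
from . import trajectories as traj
from .io_formats import RunConfig, read_gmt, read_ksdb, read_quant_table

__all__ = ["PipelineConfig", "ReportBundle", "StageError",
           "run_time_course_analysis"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    quant_table: str
    out_dir: str
    protein_table: str | None = None
    ksdb_paths: list[str] = field(default_factory=list)
    gmt_path: str | None = None
    run: RunConfig = field(default_factory=RunConfig)
    ksea_enabled: bool = True
    enrichment_enabled: bool = True
    cluster_top_n: int | None = None

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir")   # where outputs land does not change the analysis
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ReportBundle:
    config_hash: str
    out_dir: Path
    diffs_by_time: dict
    overlap: diff.OverlapCounts
    cluster_model: traj.TrajectoryClusterModel | None
    ksea_matrix: ks.KseaMatrix | None
    enrichment_by_time: dict | None
    reconciliation: dict | None
    log: list[str]


def _log(lines: list[str], stage: str, msg: str) -> None:
    lines.append(f"{_time.strftime('%Y-%m-%dT%H:%M:%S')}\t{stage}\t{msg}")


def run_time_course_analysis(config: PipelineConfig) -> ReportBundle:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    log: list[str] = []
    rc = config.run

    # pre-flight
    if config.ksea_enabled and not config.ksdb_paths:
        raise StageError("preflight", ValueError(
            "KSEA enabled but no kinase-substrate database configured"))
    if config.enrichment_enabled and not config.gmt_path:
        raise StageError("preflight", ValueError(
            "enrichment enabled but no GMT configured"))

    def run_stage(name, fn):
        try:
            _log(log, name, "start")
            result = fn()
            _log(log, name, "done")
            return result
        except Exception as exc:
            (out / "FAILED").write_text(f"{name}: {exc}\n")
            (out / "run.log").write_text("\n".join(log) + "\n")
            raise StageError(name, exc) from exc

    table = run_stage("ingest", lambda: read_quant_table(config.quant_table, rc))
    _log(log, "ingest", f"rows={len(table)} filter={table.filter_report}")

    def _diff():
        d = diff.diff_all_times(table, rc)
        for t, results in d.items():
            diff.volcano_table(results).to_csv(
                out / f"diff_{t}min.{h}.tsv", sep="\t", index=False,
                float_format="%.10g")
        return d
    diffs_by_time = run_stage("differential", _diff)

    def _overlap():
        o = diff.overlap_analysis(
            {t: diff.regulated_keys(d) for t, d in diffs_by_time.items()})
        payload = dataclasses.asdict(o)
        payload["pairwise"] = {f"{a}&{b}": v for (a, b), v in o.pairwise.items()}
        payload["config_hash"] = h
        (out / f"overlap.{h}.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True))
        return o
    overlap = run_stage("overlap", _overlap)

    reconciliation = None
    if config.protein_table:
        def _recon():
            ptable = read_quant_table(config.protein_table, rc)
            key_to_protein = dict(zip(table.values.index, table.meta["protein"]))
            rec = {}
            for t, d in diffs_by_time.items():
                pd_ = diff.paired_diff_test(ptable, t, rc.alpha,
                                            rc.lfc_threshold, rc.paired)
                pd_ = [dataclasses.replace(x, key=x.key.rpartition("_")[0])
                       for x in pd_]
                rec[t] = diff.reconcile_protein_level(d, pd_, key_to_protein)
            (out / f"reconciliation.{h}.json").write_text(json.dumps(
                {str(t): {k: v for k, v in r.items() if k != "confounded_sites"}
                 for t, r in rec.items()}, indent=1, sort_keys=True))
            return rec
        reconciliation = run_stage("reconcile", _recon)

    def _cluster():
        trajectories = traj.build_trajectories(diffs_by_time,
                                               top_n=config.cluster_top_n)
        if len(trajectories) < rc.clustering_k:
            _log(log, "trajectories", "too few trajectories; skipped")
            return None
        mm = traj.measure_matrix(trajectories)
        selected = traj.select_informative_measures(
            mm, exclude=(rc.excluded_measure,))
        model = traj.cluster_trajectories(mm[selected], rc.clustering_k,
                                          seed=rc.seed,
                                          trajectories=trajectories)
        assign = pd.DataFrame({
            "psite": model.keys, "cluster": model.assignments,
            "archetype": [model.archetype_labels.get(a, "")
                          for a in model.assignments],
            "sign": [model.archetype_signs.get(a, "")
                     for a in model.assignments]})
        assign.to_csv(out / f"clusters.{h}.tsv", sep="\t", index=False)
        return model
    cluster_model = run_stage("trajectories", _cluster)

    ksea_matrix = None
    if config.ksea_enabled:
        def _ksea():
            db = read_ksdb(config.ksdb_paths)
            groups = ks.match_substrates(table, db)
            matrix = ks.ksea_over_time(table, groups, rc.ksea_min_m,
                                       rc.ksea_min_m_for_p)
            matrix.mean.to_csv(out / f"ksea_mean.{h}.tsv", sep="\t",
                               float_format="%.10g")
            flat = matrix.per_replicate.copy()
            flat.columns = [f"{t}_r{r}" for t, r in flat.columns]
            flat.to_csv(out / f"ksea_replicates.{h}.tsv", sep="\t",
                        float_format="%.10g")
            ks.classify_activity_trajectories(matrix).to_csv(
                out / f"ksea_classes.{h}.tsv", sep="\t")
            return matrix
        ksea_matrix = run_stage("ksea", _ksea)

    enrichment_by_time = None
    if config.enrichment_enabled:
        def _enrich():
            gmt = read_gmt(config.gmt_path)
            key_gene = dict(zip(table.values.index, table.meta["gene"]))
            key_prot = dict(zip(table.values.index, table.meta["protein"]))
            universe = {(key_gene[k] or key_prot[k]).upper()
                        for k in table.values.index}
            per_time = {}
            for t, d in diffs_by_time.items():
                query = {(key_gene[x.key] or key_prot[x.key]).upper()
                         for x in d if x.regulated}
                if not query:
                    continue
                res = enr.hypergeom_enrichment(query, gmt, universe)
                pd.DataFrame([dataclasses.asdict(r) for r in res]).to_csv(
                    out / f"enrichment_{t}min.{h}.tsv", sep="\t", index=False,
                    float_format="%.10g")
                per_time[str(t)] = res
            if len(per_time) > 1:
                enr.differential_go_ranking(per_time).to_csv(
                    out / f"differential_go.{h}.tsv", sep="\t", index=False,
                    float_format="%.10g")
            return per_time
        enrichment_by_time = run_stage("enrichment", _enrich)

    _log(log, "pipeline", f"config_hash={h}")
    (out / "run.log").write_text("\n".join(log) + "\n")
    (out / f"config.{h}.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=True))
    return ReportBundle(h, out, diffs_by_time, overlap, cluster_model,
                        ksea_matrix, enrichment_by_time, reconciliation, log)
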