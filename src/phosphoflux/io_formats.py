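"""Readers, writers and canonical identifiers for all external table formats.

Every downstream stage joins on the canonical p-site string form
``ACCESSION_S123`` (or ``ACCESSION_S519/S523`` for multiply-phosphorylated
peptide features quantified as one key).  Quantitative values are stored as
log2 throughout; missing values are NA, never zero.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "PsiteKey",
    "PsiteQuantTable",
    "KinaseSubstrateDB",
    "GeneSetCollection",
    "OCRTrace",
    "RunConfig",
    "read_quant_table",
    "write_quant_table",
    "read_ksdb",
    "write_ksdb",
    "read_gmt",
    "write_gmt",
    "read_ocr_traces",
    "write_ocr_traces",
]

CONDITIONS = ("low", "high")

_SITE_RE = re.compile(r"^([STY])(\d+)$", re.IGNORECASE)


class FormatError(ValueError):
    """A file does not follow its documented column contract."""


@dataclass(frozen=True, order=True)
class PsiteKey:
    """Identity of a quantified phosphorylation feature.

    ``sites`` is an ordered tuple of (residue, position) pairs; a feature
    carrying more than one site (one quantified peptide, several phosphates)
    is a single key, e.g. ``P16086_S519/S523``.
    """

    protein_accession: str
    sites: tuple[tuple[str, int], ...]
    gene_symbol: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("PsiteKey requires at least one site")
        positions = [p for _, p in self.sites]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError(f"site positions must be strictly increasing: {positions}")
        for res, pos in self.sites:
            if res not in "STY":
                raise ValueError(f"residue must be one of S/T/Y, got {res!r}")
            if pos < 1:
                raise ValueError(f"position must be 1-based positive, got {pos}")

    @classmethod
    def parse(cls, text: str, gene_symbol: str | None = None) -> "PsiteKey":
        """Parse ``ACC_S123`` / ``ACC_S519/S523`` (case-insensitive)."""
        acc, _, sitepart = text.strip().rpartition("_")
        if not acc or not sitepart:
            raise FormatError(f"malformed p-site key: {text!r}")
        sites = []
        for tok in sitepart.split("/"):
            m = _SITE_RE.match(tok.strip())
            if m is None:
                raise FormatError(f"malformed site token {tok!r} in {text!r}")
            sites.append((m.group(1).upper(), int(m.group(2))))
        return cls(acc.upper(), tuple(sites), gene_symbol=gene_symbol)

    def __str__(self) -> str:
        return f"{self.protein_accession}_{'/'.join(f'{r}{p}' for r, p in self.sites)}"

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for _, p in self.sites)


@dataclass
class RunConfig:
    """Analysis parameters; the printed study thresholds are the defaults."""

    alpha: float = 0.05
    lfc_threshold: float = 0.3          # log2 units; 0.3 <=> 23% change
    times: tuple[int, ...] = (5, 30, 60)
    replicates: int = 5
    min_replicates_per_condition: int = 2
    min_localization_prob: float = 0.95
    clustering_k: int = 4
    excluded_measure: str = "mean_second_diff"
    ksea_min_m: int = 1
    ksea_min_m_for_p: int = 2
    paired: bool = True
    values_are_log2: bool = True
    median_center: bool = False         # optional per-channel normalization
    seed: int = 1

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.lfc_threshold <= 0:
            raise ValueError("alpha and lfc_threshold must be positive")
        if self.clustering_k < 2:
            raise ValueError("clustering_k must be >= 2")
        self.times = tuple(int(t) for t in self.times)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["times"] = list(self.times)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def sample_columns(times: Sequence[int], replicates: int) -> list[tuple[str, int, int]]:
    """Canonical (condition, time, replicate) column order."""
    return [(c, t, r) for t in times for c in CONDITIONS for r in range(1, replicates + 1)]


def _column_label(cond: str, time: int, rep: int) -> str:
    return f"{cond}_{time}_r{rep}"


_SAMPLE_COL_RE = re.compile(r"^(low|high)_(\d+)_r(\d+)$")

META_COLS = ("psite", "protein", "gene", "loc_prob", "peptide")


@dataclass
class PsiteQuantTable:
    """Log2 quantitative values, p-sites x (condition, time, replicate).

    ``values`` has a (condition, time, replicate) MultiIndex on columns and
    the canonical p-site string on the row index; ``meta`` is row-aligned
    with gene symbol, localization probability and peptide sequence.
    ``filter_report`` records how many rows each ingest filter removed.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    filter_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share a row index")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> tuple[int, ...]:
        return tuple(sorted({t for _, t, _ in self.values.columns}))

    @property
    def replicates(self) -> tuple[int, ...]:
        return tuple(sorted({r for _, _, r in self.values.columns}))

    def keys(self) -> list[PsiteKey]:
        return [
            PsiteKey.parse(ix, gene_symbol=(g if isinstance(g, str) and g else None))
            for ix, g in zip(self.values.index, self.meta["gene"])
        ]

    def condition_block(self, condition: str, time: int) -> pd.DataFrame:
        """Replicate columns for one condition at one time, ordered by replicate."""
        block = self.values.xs((condition, time), axis=1, level=(0, 1))
        return block.reindex(sorted(block.columns), axis=1)

    def equals(self, other: "PsiteQuantTable") -> bool:
        va = self.values.sort_index().sort_index(axis=1)
        vb = other.values.sort_index().sort_index(axis=1)
        return va.equals(vb) and self.meta.sort_index().equals(other.meta.sort_index())


def _to_multiindex(labels: Iterable[str]) -> pd.MultiIndex:
    parsed = []
    for lab in labels:
        m = _SAMPLE_COL_RE.match(lab)
        if m is None:
            raise FormatError(f"malformed sample column {lab!r}; expected <cond>_<time>_r<rep>")
        parsed.append((m.group(1), int(m.group(2)), int(m.group(3))))
    return pd.MultiIndex.from_tuples(parsed, names=["condition", "time", "replicate"])


def apply_presence_filter(table: PsiteQuantTable, min_replicates: int = 2) -> PsiteQuantTable:
    """Drop rows missing from any (condition, time) cell or quantified in
    fewer than ``min_replicates`` replicates per condition at any time
    point, then drop unpaired replicate values pairwise.

    Idempotent: filtering a filtered table removes nothing further.
    """
    vals = table.values.copy()
    times = table.times
    # pairwise NA propagation: replicate r at time t kept only if both
    # conditions carry a value (the paired design needs complete pairs)
    for t in times:
        low = vals.xs(("low", t), axis=1, level=(0, 1), drop_level=False)
        high = vals.xs(("high", t), axis=1, level=(0, 1), drop_level=False)
        reps = sorted({c[2] for c in low.columns} & {c[2] for c in high.columns})
        for r in reps:
            pair_na = vals[("low", t, r)].isna() | vals[("high", t, r)].isna()
            vals.loc[pair_na, ("low", t, r)] = np.nan
            vals.loc[pair_na, ("high", t, r)] = np.nan
    keep = pd.Series(True, index=vals.index)
    for t in times:
        for cond in CONDITIONS:
            block = vals.xs((cond, t), axis=1, level=(0, 1))
            keep &= block.notna().sum(axis=1) >= min_replicates
    dropped = int((~keep).sum())
    report = dict(table.filter_report)
    report["presence_filter_dropped"] = report.get("presence_filter_dropped", 0) + dropped
    return PsiteQuantTable(vals.loc[keep], table.meta.loc[keep].copy(), report)


def read_quant_table(path: str | Path, config: RunConfig | None = None) -> PsiteQuantTable:
    """Read a p-site quantification TSV and apply the ingest filters.

    Filters, in order: localization probability >= config threshold;
    presence in all (condition, time) cells with at least
    ``min_replicates_per_condition`` replicates each; pairwise completeness
    (a replicate value without its partner in the other condition is
    dropped).  Counts of rows removed by each filter are recorded in
    ``filter_report``.
    """
    config = config or RunConfig()
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={"psite": str, "protein": str, "gene": str,
                            "peptide": str})
    missing = [c for c in META_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"quant table missing required columns: {missing}")
    sample_cols = [c for c in df.columns if c not in META_COLS]
    mi = _to_multiindex(sample_cols)
    values = df[sample_cols]
    bad = values.apply(lambda s: pd.to_numeric(s, errors="coerce"))
    nonnum = values.notna() & bad.isna()
    if nonnum.any().any():
        row = df.loc[nonnum.any(axis=1), "psite"].iloc[0]
        raise FormatError(f"non-numeric quantitative value in row {row!r}")
    values = bad.astype(float)
    values.columns = mi
    # normalize keys to canonical uppercase form
    keys = [str(PsiteKey.parse(k)) for k in df["psite"]]
    values.index = pd.Index(keys, name="psite")
    meta = df[["protein", "gene", "loc_prob", "peptide"]].copy()
    meta["gene"] = meta["gene"].fillna("")
    meta["peptide"] = meta["peptide"].fillna("")
    meta.index = values.index
    if not config.values_are_log2:
        with np.errstate(divide="ignore"):
            values = np.log2(values)
    if config.median_center:
        values = values - values.median(axis=0)
    report: dict = {"rows_read": len(values)}
    loc_ok = meta["loc_prob"].astype(float) >= config.min_localization_prob
    report["localization_filter_dropped"] = int((~loc_ok).sum())
    table = PsiteQuantTable(values.loc[loc_ok], meta.loc[loc_ok], report)
    return apply_presence_filter(table, config.min_replicates_per_condition)


def write_quant_table(table: PsiteQuantTable, path: str | Path) -> None:
    flat = table.values.copy()
    flat.columns = [_column_label(c, t, r) for c, t, r in flat.columns]
    out = pd.concat([table.meta, flat], axis=1)
    out.insert(0, "psite", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# --------------------------------------------------------------------------
# kinase-substrate relationship tables

KSDB_COLS = ("enzyme", "class", "substrate_gene", "substrate_acc", "site", "window")


@dataclass
class KinaseSubstrateDB:
    """Deduplicated enzyme -> substrate-site relationship records.

    ``records`` columns follow the documented TSV contract; ``motif_groups``
    optionally maps a motif-group name to a regular expression over the
    +/-7-residue sequence window (phospho-residue at the window center).
    """

    records: pd.DataFrame
    motif_groups: dict[str, str] = field(default_factory=dict)
    skipped: int = 0

    def __post_init__(self) -> None:
        classes = set(self.records["class"].unique()) - {"kinase", "phosphatase"}
        if classes:
            raise FormatError(f"unknown enzyme class values: {sorted(classes)}")

    def __len__(self) -> int:
        return len(self.records)

    def enzyme_classes(self) -> dict[str, str]:
        return dict(zip(self.records["enzyme"], self.records["class"]))

    def substrate_counts(self) -> pd.Series:
        return self.records.groupby("enzyme").size().sort_values(ascending=False)


def read_ksdb(paths: str | Path | Sequence[str | Path],
              motif_groups: Mapping[str, str] | None = None) -> KinaseSubstrateDB:
    """Read and merge one or more kinase-substrate TSVs, deduplicating on
    (enzyme, substrate, site).  Records lacking an enzyme or any substrate
    identifier are skipped and counted."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for p in paths:
        df = pd.read_csv(p, sep="\t", dtype=str)
        missing = [c for c in ("enzyme", "class", "site") if c not in df.columns]
        if missing:
            raise FormatError(f"kinase-substrate table {p} missing columns: {missing}")
        for col in KSDB_COLS:
            if col not in df.columns:
                df[col] = ""
        frames.append(df[list(KSDB_COLS)])
    merged = pd.concat(frames, ignore_index=True).fillna("")
    has_enzyme = merged["enzyme"].str.strip() != ""
    has_substrate = (merged["substrate_gene"].str.strip() != "") | (
        merged["substrate_acc"].str.strip() != "")
    ok = has_enzyme & has_substrate & (merged["site"].str.strip() != "")
    skipped = int((~ok).sum())
    merged = merged.loc[ok].copy()
    for col in ("enzyme", "substrate_gene", "substrate_acc", "site"):
        merged[col] = merged[col].str.strip().str.upper()
    merged["class"] = merged["class"].str.strip().str.lower()
    merged = merged.drop_duplicates(
        subset=["enzyme", "substrate_gene", "substrate_acc", "site"]
    ).reset_index(drop=True)
    return KinaseSubstrateDB(merged, dict(motif_groups or {}), skipped=skipped)


def write_ksdb(db: KinaseSubstrateDB, path: str | Path) -> None:
    db.records.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# gene sets (GMT)


@dataclass
class GeneSetCollection:
    """Named gene sets; symbols are case-normalized to uppercase."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {lineno}: set {parts[0]!r} has no members")
            name, desc, *members = parts
            members = [m.strip().upper() for m in members if m.strip()]
            if not members:
                raise FormatError(f"GMT line {lineno}: set {name!r} has no members")
            if name in sets:
                raise FormatError(f"duplicate gene-set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# --------------------------------------------------------------------------
# respirometry traces


@dataclass
class OCRTrace:
    """One well's oxygen-consumption-rate time series (pmol O2/min)."""

    well: str
    times: np.ndarray            # minutes, strictly increasing
    ocr: np.ndarray
    treatment: str | None = None
    dose: float | None = None
    injection_time: float | None = None   # glucose-stimulus time, minutes

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        if len(self.times) != len(self.ocr):
            raise ValueError("times and ocr must be the same length")
        if np.any(np.diff(self.times) <= 0):
            raise FormatError(f"non-monotone timestamps in well {self.well!r}")


def read_ocr_traces(path: str | Path,
                    layout: pd.DataFrame | str | Path | None = None) -> list[OCRTrace]:
    """Read a long-form OCR CSV (`well`,`time_min`,`ocr`) and annotate from a
    plate layout (`well`,`treatment`,`dose`,`injection_time_min`).  Wells in
    the data but absent from the layout are kept unannotated."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("well", "time_min", "ocr") if c not in df.columns]
    if missing:
        raise FormatError(f"OCR table missing columns: {missing}")
    ann: dict[str, dict] = {}
    if layout is not None:
        lay = pd.read_csv(layout) if isinstance(layout, (str, Path)) else layout
        for _, row in lay.iterrows():
            ann[str(row["well"])] = {
                "treatment": row.get("treatment"),
                "dose": row.get("dose"),
                "injection_time": row.get("injection_time_min"),
            }
    traces = []
    for well, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("time_min")
        a = ann.get(str(well), {})
        dose = a.get("dose")
        traces.append(OCRTrace(
            well=str(well),
            times=grp["time_min"].to_numpy(),
            ocr=grp["ocr"].to_numpy(),
            treatment=a.get("treatment"),
            dose=None if dose is None or pd.isna(dose) else float(dose),
            injection_time=a.get("injection_time"),
        ))
    return traces


def write_ocr_traces(traces: Sequence[OCRTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        for t, v in zip(tr.times, tr.ocr):
            rows.append({"well": tr.well, "time_min": t, "ocr": v})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_ocr_layout(traces: Sequence[OCRTrace], path: str | Path) -> None:
    rows = [{"well": tr.well, "treatment": tr.treatment, "dose": tr.dose,
             "injection_time_min": tr.injection_time} for tr in traces]
    pd.DataFrame(rows).to_csv(path, index=False)
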