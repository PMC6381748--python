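"""Ground-truthed synthetic inputs for every pipeline stage.

The phospho generator emulates the study design: a paired two-condition
(2.5 vs 16.7 mM glucose) comparison at 5/30/60 min with five replicates of
TMT-style log2 intensities, planted kinase/phosphatase-driven effects with
one of four kinetic archetypes, and additive Gaussian noise on the log2
scale.  High-glucose values are the paired low-glucose values plus the
archetype effect at that time plus noise, so the paired difference of a
null site is pure noise and of a planted site is the effect plus noise.

The respirometry generator emulates a Seahorse-style plate: 6-min cycles, a
pre-stimulus basal segment, and a post-injection ramp to a plateau, with
per-treatment multiplicative effects on the glucose response.

Every generator serializes its ground truth alongside the data and is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import KinaseSubstrateDB, OCRTrace, PsiteQuantTable

__all__ = [
    "PhosphoSimConfig",
    "OCRPlateConfig",
    "SyntheticTruth",
    "generate_phospho_dataset",
    "truth_to_ksdb",
    "generate_gene_sets",
    "generate_ocr_plate",
]

ARCHETYPE_PROFILES = {
    # effect multiplier at each of the three sampling times (piecewise
    # constant): transient = effect at the first time only
    "early-sustained": (1.0, 1.0, 1.0),
    "early-transient": (1.0, 0.0, 0.0),
    "intermediate": (0.0, 1.0, 1.0),
    "late": (0.0, 0.0, 1.0),
}

AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class PhosphoSimConfig:
    """Desk-scale mirror of the study: 3000 p-sites on 1500 proteins, five
    replicates, times 5/30/60 min, planted effects of 0.8 log2 with noise
    SD 0.2 log2, ten substrates per planted enzyme."""

    n_sites: int = 3000
    n_proteins: int = 1500
    times: tuple[int, ...] = (5, 30, 60)
    replicates: int = 5
    n_kinases: int = 9
    n_phosphatases: int = 3
    m_per_enzyme: int = 10
    n_regulated: int = 234            # planted (archetype-bearing) sites
    effect_size: float = 0.8          # log2 units
    noise_sd: float = 0.2             # log2 units, additive
    baseline_mean: float = 20.0       # log2 reporter-intensity scale
    baseline_sd: float = 2.0
    protein_coregulated_fraction: float = 0.15
    missing_rate: float = 0.0         # MCAR, applied per value

    def __post_init__(self) -> None:
        n_enzymes = self.n_kinases + self.n_phosphatases
        if n_enzymes * self.m_per_enzyme > self.n_regulated:
            raise ValueError("m_per_enzyme * n_enzymes exceeds n_regulated")
        if self.n_regulated > self.n_sites:
            raise ValueError("n_regulated exceeds n_sites")


@dataclass
class SyntheticTruth:
    """Serialized ground truth for a generated phospho dataset."""

    seed: int
    noise_sd: float
    effect_size: float
    replicates: int
    times: tuple[int, ...]
    null_fraction: float
    site_archetype: dict[str, str]            # key -> archetype
    site_direction: dict[str, str]            # key -> up/down
    enzyme_effects: dict[str, dict]           # enzyme -> class/direction/archetype
    enzyme_members: dict[str, list[str]]      # enzyme -> substrate keys
    protein_regulated: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["times"] = list(self.times)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["times"] = tuple(d["times"])
        return cls(**d)


def _random_window(rng: np.random.Generator, residue: str) -> str:
    flank = rng.choice(list(AA), size=14)
    return "".join(flank[:7]) + residue + "".join(flank[7:])


def generate_phospho_dataset(config: PhosphoSimConfig | None = None,
                             seed: int = 1
                             ) -> tuple[PsiteQuantTable, PsiteQuantTable,
                                        SyntheticTruth]:
    """Paired low/high log2 tables (p-site level and protein level) plus
    the planted ground truth."""
    cfg = config or PhosphoSimConfig()
    rng = np.random.default_rng(seed)

    # identities: sites distributed over proteins round-robin
    proteins = [f"SP{i:05d}" for i in range(1, cfg.n_proteins + 1)]
    genes = [f"GENE{i:05d}" for i in range(1, cfg.n_proteins + 1)]
    residues = rng.choice(list("STY"), size=cfg.n_sites, p=[0.75, 0.2, 0.05])
    keys, key_protein, key_gene, peptides = [], [], [], []
    used_positions: dict[int, set[int]] = {}
    for i in range(cfg.n_sites):
        pi = i % cfg.n_proteins
        pos_set = used_positions.setdefault(pi, set())
        pos = int(rng.integers(1, 2000))
        while pos in pos_set:
            pos = int(rng.integers(1, 2000))
        pos_set.add(pos)
        keys.append(f"{proteins[pi]}_{residues[i]}{pos}")
        key_protein.append(proteins[pi])
        key_gene.append(genes[pi])
        peptides.append(_random_window(rng, residues[i]))

    # planted structure: first n_regulated sites carry archetype effects;
    # the first n_enzymes * m of those belong to planted enzymes
    archetype_names = list(ARCHETYPE_PROFILES)
    enzymes = ([f"KIN{i:02d}" for i in range(1, cfg.n_kinases + 1)]
               + [f"PHOS{i:02d}" for i in range(1, cfg.n_phosphatases + 1)])
    enzyme_effects: dict[str, dict] = {}
    enzyme_members: dict[str, list[str]] = {}
    site_archetype: dict[str, str] = {}
    site_direction: dict[str, str] = {}
    cursor = 0
    for j, enz in enumerate(enzymes):
        arch = archetype_names[j % len(archetype_names)]
        direction = "up" if j % 2 == 0 else "down"
        members = keys[cursor:cursor + cfg.m_per_enzyme]
        cursor += cfg.m_per_enzyme
        enzyme_effects[enz] = {
            "class": "phosphatase" if enz.startswith("PHOS") else "kinase",
            "direction": direction,
            "archetype": arch,
            "magnitude": cfg.effect_size,
        }
        enzyme_members[enz] = members
        for k in members:
            site_archetype[k] = arch
            site_direction[k] = direction
    for i in range(cursor, cfg.n_regulated):
        site_archetype[keys[i]] = archetype_names[i % len(archetype_names)]
        site_direction[keys[i]] = "up" if rng.random() < 0.5 else "down"

    # values: low = baseline + noise, high = low + effect(time) + noise
    ntimes, nrep = len(cfg.times), cfg.replicates
    base = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_sites)
    effect = np.zeros((cfg.n_sites, ntimes))
    for i, k in enumerate(keys):
        if k in site_archetype:
            prof = ARCHETYPE_PROFILES[site_archetype[k]]
            sgn = 1.0 if site_direction[k] == "up" else -1.0
            effect[i] = sgn * cfg.effect_size * np.asarray(prof)
    low = (base[:, None, None]
           + rng.normal(0, cfg.noise_sd, size=(cfg.n_sites, ntimes, nrep)))
    high = (low + effect[:, :, None]
            + rng.normal(0, cfg.noise_sd, size=(cfg.n_sites, ntimes, nrep)))
    cols = pd.MultiIndex.from_tuples(
        [(c, t, r) for ti, t in enumerate(cfg.times)
         for c in ("low", "high") for r in range(1, nrep + 1)],
        names=["condition", "time", "replicate"])
    data = np.empty((cfg.n_sites, len(cols)))
    for ci, (c, t, r) in enumerate(cols):
        ti = cfg.times.index(t)
        src = low if c == "low" else high
        data[:, ci] = src[:, ti, r - 1]
    if cfg.missing_rate > 0:
        mask = rng.random(data.shape) < cfg.missing_rate
        data[mask] = np.nan
    values = pd.DataFrame(data, index=pd.Index(keys, name="psite"), columns=cols)
    meta = pd.DataFrame({
        "protein": key_protein,
        "gene": key_gene,
        "loc_prob": np.round(rng.uniform(0.95, 1.0, size=cfg.n_sites), 4),
        "peptide": peptides,
    }, index=values.index)
    table = PsiteQuantTable(values, meta, {"synthetic_seed": seed})

    # protein-level table: a fraction of the proteins carrying planted
    # sites is co-regulated at the protein level (early-sustained profile)
    reg_proteins = sorted({key_protein[i] for i in range(cfg.n_regulated)})
    n_co = int(round(cfg.protein_coregulated_fraction * len(reg_proteins)))
    co_regulated = (list(rng.choice(reg_proteins, size=n_co, replace=False))
                    if n_co else [])
    prot_effect = np.zeros((cfg.n_proteins, ntimes))
    co_set = set(co_regulated)
    prot_dir: dict[str, str] = {}
    for pi, prot in enumerate(proteins):
        if prot in co_set:
            sgn = 1.0 if rng.random() < 0.5 else -1.0
            prot_dir[prot] = "up" if sgn > 0 else "down"
            prot_effect[pi] = sgn * cfg.effect_size
    pbase = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_proteins)
    plow = (pbase[:, None, None]
            + rng.normal(0, cfg.noise_sd, size=(cfg.n_proteins, ntimes, nrep)))
    phigh = (plow + prot_effect[:, :, None]
             + rng.normal(0, cfg.noise_sd, size=(cfg.n_proteins, ntimes, nrep)))
    pdata = np.empty((cfg.n_proteins, len(cols)))
    for ci, (c, t, r) in enumerate(cols):
        ti = cfg.times.index(t)
        src = plow if c == "low" else phigh
        pdata[:, ci] = src[:, ti, r - 1]
    # protein rows reuse the p-site container with a dummy site token
    pkeys = [f"{p}_S1" for p in proteins]
    pvalues = pd.DataFrame(pdata, index=pd.Index(pkeys, name="psite"),
                           columns=cols)
    pmeta = pd.DataFrame({
        "protein": proteins, "gene": genes,
        "loc_prob": np.ones(cfg.n_proteins), "peptide": "",
    }, index=pvalues.index)
    protein_table = PsiteQuantTable(pvalues, pmeta, {"synthetic_seed": seed})

    truth = SyntheticTruth(
        seed=seed, noise_sd=cfg.noise_sd, effect_size=cfg.effect_size,
        replicates=nrep, times=cfg.times,
        null_fraction=1.0 - cfg.n_regulated / cfg.n_sites,
        site_archetype=site_archetype, site_direction=site_direction,
        enzyme_effects=enzyme_effects, enzyme_members=enzyme_members,
        protein_regulated={p: [prot_dir[p]] for p in sorted(co_set)},
    )
    return table, protein_table, truth


def truth_to_ksdb(truth: SyntheticTruth) -> KinaseSubstrateDB:
    """Kinase-substrate relationship table implied by the planted truth
    (gene-symbol keyed, as the public databases are)."""
    rows = []
    for enz, members in truth.enzyme_members.items():
        cls = truth.enzyme_effects[enz]["class"]
        for key in members:
            acc, _, site = key.rpartition("_")
            gene = "GENE" + acc[2:]
            rows.append({"enzyme": enz, "class": cls, "substrate_gene": gene,
                         "substrate_acc": acc, "site": site, "window": ""})
    return KinaseSubstrateDB(pd.DataFrame(rows))


def generate_gene_sets(table: PsiteQuantTable, truth: SyntheticTruth,
                       n_random_sets: int = 20, set_size: int = 25,
                       seed: int = 1):
    """A gene-set collection over the quantified universe: one set per
    planted enzyme's substrate proteins (truly enriched among regulated
    genes) plus random sets of the given size."""
    from .io_formats import GeneSetCollection
    rng = np.random.default_rng(seed)
    universe = sorted(set(table.meta["gene"]))
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    key_gene = dict(zip(table.values.index, table.meta["gene"]))
    for enz, members in truth.enzyme_members.items():
        genes = sorted({key_gene[k] for k in members if k in key_gene})
        if genes:
            sets[f"SUBSTRATES_{enz}"] = genes
            descriptions[f"SUBSTRATES_{enz}"] = f"substrate proteins of {enz}"
    for i in range(n_random_sets):
        name = f"RANDOM_{i:03d}"
        sets[name] = sorted(rng.choice(universe, size=min(set_size,
                                                          len(universe)),
                                       replace=False))
        descriptions[name] = "random gene set"
    return GeneSetCollection(sets, descriptions)


# --------------------------------------------------------------------------
# respirometry plates


@dataclass
class OCRPlateConfig:
    """Seahorse-style plate: 6-min cycles, five basal cycles (30 min
    pre-incubation), ten post-injection cycles, basal 100 pmol O2/min with a
    50% glucose response rising over one cycle to a plateau."""

    wells_per_group: int = 5
    cycle_min: float = 6.0
    n_basal_cycles: int = 5
    n_response_cycles: int = 10
    basal_level: float = 100.0          # pmol O2/min
    response_amplitude: float = 50.0    # pmol O2/min over basal at plateau
    rise_cycles: int = 1
    noise_sd: float = 3.0               # pmol O2/min
    # treatment -> (relative effect on response amplitude, relative basal shift)
    treatments: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"mock": (0.0, 0.0)})

    def __post_init__(self) -> None:
        if self.basal_level <= 0:
            raise ValueError("basal level must be positive")


def generate_ocr_plate(config: OCRPlateConfig | None = None, seed: int = 1
                       ) -> tuple[list[OCRTrace], dict]:
    """Plate traces plus the serializable ground truth (expected AUC per
    treatment on the noise-free curve)."""
    cfg = config or OCRPlateConfig()
    rng = np.random.default_rng(seed)
    n_cycles = cfg.n_basal_cycles + cfg.n_response_cycles
    times = np.arange(n_cycles) * cfg.cycle_min
    t_inj = cfg.n_basal_cycles * cfg.cycle_min
    traces, truth_auc = [], {}
    well_no = 1
    for treat, (amp_eff, basal_shift) in cfg.treatments.items():
        basal = cfg.basal_level * (1.0 + basal_shift)
        amp = cfg.response_amplitude * (1.0 + amp_eff)
        rise_end = t_inj + cfg.rise_cycles * cfg.cycle_min
        clean = np.where(
            times < t_inj, basal,
            basal + amp * np.clip((times - t_inj)
                                  / (rise_end - t_inj), 0.0, 1.0))
        truth_auc[treat] = float(np.trapezoid(
            np.where(times >= t_inj, clean - basal, 0.0)[times >= t_inj],
            times[times >= t_inj]))
        for _ in range(cfg.wells_per_group):
            noisy = clean + rng.normal(0, cfg.noise_sd, size=n_cycles)
            traces.append(OCRTrace(
                well=f"W{well_no:03d}", times=times.copy(), ocr=noisy,
                treatment=treat, injection_time=t_inj))
            well_no += 1
    truth = {"seed": seed, "injection_time": float(t_inj),
             "noise_sd": cfg.noise_sd, "expected_auc": truth_auc,
             "basal_level": cfg.basal_level}
    return traces, truth
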