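"""Seeded synthetic fixtures with the statistical structure the analysis assumes.

The generator emulates a Station-ALOHA-style water-column design: seven
depths sampled on twelve occasions (one grid cell is dropped so the full
design holds 83 samples), depth-stratified phage populations in five
distribution groups, persistent vs sporadic temporal regimes (sporadic
contigs homed in the mesopelagic, where boom-and-bust dynamics dominate),
a planted lysogeny gradient below the deep chlorophyll maximum, cellular
contaminant contigs carrying ribosomal markers, and conserved-gene
coverage spikes.

Noise model: per-base read depth is Poisson with a rate that is constant
over short (read-scale) blocks; between samples the rate varies
lognormally (mean-one, configurable sigma), giving positive, sample-level
overdispersed abundances. All randomness flows through a single seeded
generator, so equal seeds give byte-identical fixtures. The planted truth
is serialized separately and never read by any pipeline stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .coverage_stats import CoverageTable
from .design import DEFAULT_DEPTHS, depth_bin
from .exceptions import ConfigError

#: Twelve sampling occasions spanning August 2010 - December 2011.
SAMPLE_DATES = (
    "2010-08-15", "2010-09-15", "2010-11-15", "2010-12-15",
    "2011-02-15", "2011-03-15", "2011-05-15", "2011-06-15",
    "2011-08-15", "2011-09-15", "2011-11-15", "2011-12-15",
)

#: Function labels used for planted candidate novel genes.
NOVEL_FUNCTION_LABELS = (
    "myoinositol_1_phosphate_synthase",
    "carbamoyltransferase_c_terminus",
    "dolichyl_phosphate_mannose_mannosyltransferase",
    "toxin_antitoxin_antitoxin",
    "p83_100_antigen",
    "sodium_bile_acid_symporter",
    "superinfection_immunity",
    "glycosyl_transferase_family_25",
    "sulfotransferase_domain",
    "chitosanase",
    "phytanoyl_coa_dioxygenase",
    "methyltransferase_fkbm",
)

_STRUCTURAL_LABELS = (
    "terminase", "portal", "capsid", "tail", "baseplate",
    "spike", "neck", "head", "major capsid protein", "tail fiber",
)

DEFAULT_GROUP_FRACTIONS = (
    ("surface", 0.30),
    ("DCM", 0.15),
    ("two_hundred", 0.15),
    ("mesopelagic", 0.30),
    ("sporadic", 0.10),
)

DEFAULT_COPY_NUMBERS: Mapping[str, tuple[float, ...]] = {
    "capsid": (3.0, 3.0, 4.0, 2.0, 1.0, 0.7, 0.5),
    "dna_polymerase": (3.0, 3.0, 3.0, 1.5, 0.8, 0.6, 0.45),
    "terminase": (1.0, 1.0, 1.5, 0.8, 0.5, 0.4, 0.31),
    "tail_fiber": (0.5, 0.5, 1.0, 0.3, 0.12, 0.07, 0.04),
}

MARKER_GENE_COUNTS = {
    "capsid": 8,
    "dna_polymerase": 6,
    "terminase": 5,
    "tail_fiber": 4,
    "integrase": 5,
    "ci_repressor": 4,
    "excisionase": 4,
}

#: Share of the planted prophage-marker signal carried by each family.
PROPHAGE_SHARES = {"integrase": 0.5, "excisionase": 0.3, "ci_repressor": 0.2}

_PHAGE_TAXA = ("cyanophage", "pelagiphage", "vibriophage", "other_phage")
_CELL_TAXA = ("Prochlorococcus", "SAR11", "SAR324", "Vibrio", "Roseobacter", "other_bacteria")

from .markers import DEFAULT_CONTAMINANT_MARKERS, UNIVERSAL_SINGLE_COPY  # noqa: E402


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of one synthetic fixture.

    Defaults are the study conditions: 7 depths x 12 occasions (83
    samples), 142 length-passing candidate contigs of 20-108 kbp of which
    13 lack structural genes, a short-contig tail carrying one ribosomal
    contaminant, a mesopelagic:surface prophage-to-capsid fold of 5, and
    shallow-skewed phage marker copy numbers.
    """

    seed: int = 0
    depths_m: tuple[int, ...] = DEFAULT_DEPTHS
    n_timepoints: int = 12
    n_contigs: int = 142
    n_short_contigs: int = 8
    n_no_structural: int = 13
    contaminant_count: int = 1
    n_ambiguous_marker_hits: int = 5
    n_amg_genes: int = 12
    classification_split: tuple[int, int, int] = (10, 40, 79)
    group_fractions: tuple[tuple[str, float], ...] = DEFAULT_GROUP_FRACTIONS
    depth_group_assignment: Mapping[str, str] | None = None
    lysogeny_fold: float = 5.0
    base_lysogeny_index: float = 0.2
    integrase_inflation: float = 1.0
    copy_numbers: Mapping[str, tuple[float, ...]] | None = None
    cell_lambda: tuple[float, ...] = (60.0, 55.0, 45.0, 30.0, 15.0, 10.0, 8.0)
    sigma_log: float = 0.35
    sigma_catalog: float = 0.25
    spike_fraction: float = 0.10
    spike_multiplier: float = 8.0
    detection_floor: float = 0.05
    absent_lambda: float = 0.01
    sporadic_boost: float = 5.0
    block_bp: int = 500
    gene_length: int = 900
    contig_len_range: tuple[int, int] = (20_000, 108_000)
    short_len_range: tuple[int, int] = (1_700, 20_000)
    with_coverage: bool = True
    with_catalog: bool = True
    with_sequences: bool = True

    @property
    def n_depths(self) -> int:
        return len(self.depths_m)

    def validate(self) -> None:
        if list(self.depths_m) != sorted(self.depths_m) or len(set(self.depths_m)) != len(self.depths_m):
            raise ConfigError("depths must be strictly increasing")
        for name in ("n_timepoints", "n_contigs", "block_bp", "gene_length"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("n_short_contigs", "n_no_structural", "contaminant_count",
                     "n_ambiguous_marker_hits", "n_amg_genes"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not self.lysogeny_fold > 0:
            raise ConfigError("lysogeny_fold must be positive")
        if not 0 <= self.spike_fraction < 1:
            raise ConfigError("spike_fraction must lie in [0, 1)")
        if self.n_timepoints > len(SAMPLE_DATES):
            raise ConfigError(f"at most {len(SAMPLE_DATES)} timepoints supported")
        if len(self.cell_lambda) != self.n_depths:
            raise ConfigError("cell_lambda must have one value per depth")
        if self.contaminant_count > self.n_short_contigs:
            raise ConfigError("contaminant_count cannot exceed n_short_contigs")
        if self.n_no_structural > self.n_contigs:
            raise ConfigError("n_no_structural cannot exceed n_contigs")
        cn = self.copy_numbers or DEFAULT_COPY_NUMBERS
        for fam, values in cn.items():
            if len(values) != self.n_depths:
                raise ConfigError(f"copy_numbers[{fam!r}] must have one value per depth")
            if any(v <= 0 for v in values):
                raise ConfigError(f"copy_numbers[{fam!r}] must be positive")


@dataclass
class PlantedTruth:
    """Everything the generator planted, for comparison against estimates.

    Serialized separately from the fixture files the pipeline consumes.
    """

    depth_group: dict = field(default_factory=dict)
    temporal_regime: dict = field(default_factory=dict)
    sporadic_active_dates: dict = field(default_factory=dict)
    classification: dict = field(default_factory=dict)
    contaminant_contig_ids: list = field(default_factory=list)
    no_structural_contig_ids: list = field(default_factory=list)
    amg_gene_ids: list = field(default_factory=list)
    prophage_flagged_contigs: list = field(default_factory=list)
    lysogeny: dict = field(default_factory=dict)
    copy_numbers: dict = field(default_factory=dict)
    catalog: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "depth_group": self.depth_group,
            "temporal_regime": self.temporal_regime,
            "sporadic_active_dates": self.sporadic_active_dates,
            "classification": self.classification,
            "contaminant_contig_ids": self.contaminant_contig_ids,
            "no_structural_contig_ids": self.no_structural_contig_ids,
            "amg_gene_ids": self.amg_gene_ids,
            "prophage_flagged_contigs": self.prophage_flagged_contigs,
            "lysogeny": self.lysogeny,
            "copy_numbers": self.copy_numbers,
            "catalog": self.catalog,
        }


@dataclass
class FixtureSet:
    """One complete synthetic input set plus its planted truth."""

    config: SimConfig
    samples: pd.DataFrame
    contigs: pd.DataFrame
    genes: pd.DataFrame
    domain_hits: pd.DataFrame
    ref_hits: pd.DataFrame
    coverage: CoverageTable | None
    catalog: pd.DataFrame | None
    gene_coverage: pd.DataFrame | None
    sequences: dict[str, str] | None
    truth: PlantedTruth

    def validate(self) -> None:
        contig_ids = set(self.contigs["contig_id"])
        if not set(self.genes["contig_id"]).issubset(contig_ids):
            raise ConfigError("gene references a nonexistent contig")
        gene_ids = set(self.genes["gene_id"])
        if self.catalog is not None:
            gene_ids |= set(self.catalog["gene_id"])
        if not set(self.domain_hits["gene_id"]).issubset(gene_ids):
            raise ConfigError("domain hit references a nonexistent gene")
        if self.coverage is not None:
            sample_ids = set(self.samples["sample_id"])
            for cid, sid in self.coverage._runs:
                if cid not in contig_ids or sid not in sample_ids:
                    raise ConfigError(f"coverage cell ({cid}, {sid}) references unknown ids")


def _ln1(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    """Mean-one lognormal draws (so planted expectations stay exact)."""
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def _apportion(weights: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n items over weighted classes."""
    total = sum(weights.values())
    raw = {k: n * w / total for k, w in weights.items()}
    counts = {k: math.floor(v) for k, v in raw.items()}
    leftover = n - sum(counts.values())
    order = sorted(weights, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in order[:leftover]:
        counts[k] += 1
    return counts


def _lysogeny_profile(config: SimConfig) -> dict[int, float]:
    """Planted prophage:capsid index per depth (before integrase inflation)."""
    base, fold = config.base_lysogeny_index, config.lysogeny_fold
    profile = {}
    for d in config.depths_m:
        b = depth_bin(d)
        if b in ("surface", "DCM"):
            profile[d] = base
        elif b == "two_hundred":
            profile[d] = base * (1 + fold) / 2
        else:
            profile[d] = base * fold
    return profile


# ---------------------------------------------------------------------------
# Spiked coverage vectors
# ---------------------------------------------------------------------------


def generate_spiked_coverage(
    length: int,
    base_lambda: float,
    spike_fraction: float,
    spike_multiplier: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Per-base Poisson depth vector with one contiguous conserved-gene spike.

    A block of floor(spike_fraction * length) positions has mean depth
    spike_multiplier * base_lambda; all other positions have mean
    base_lambda. The spike must stay out of the middle quartiles, so
    spike_fraction >= 0.5 is an error.
    """
    if length < 1:
        raise ConfigError("length must be >= 1")
    if spike_fraction < 0 or spike_fraction >= 0.5:
        raise ConfigError("spike_fraction must lie in [0, 0.5) so the spike cannot dominate the middle quartiles")
    if spike_multiplier < 1:
        raise ConfigError("spike_multiplier must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = np.full(length, float(base_lambda))
    k = math.floor(spike_fraction * length)
    if k > 0:
        start = int(rng.integers(0, length - k + 1))
        lam[start : start + k] *= spike_multiplier
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------


def make_samples(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """The depth x time grid with one randomly dropped cell (83 samples at default)."""
    dates = SAMPLE_DATES[: config.n_timepoints]
    rows = [
        {"sample_id": f"S{d:04d}_{date.replace('-', '')[:6]}", "depth_m": d, "date": date}
        for d in config.depths_m
        for date in dates
    ]
    if len(rows) > 1:
        drop = int(rng.integers(len(rows)))
        rows = [r for i, r in enumerate(rows) if i != drop]
    return pd.DataFrame(rows)


def _home_depths(group: str, home_depth: int | None, depths: tuple[int, ...]) -> tuple[int, ...]:
    if group == "sporadic":
        return (home_depth,)
    return tuple(d for d in depths if depth_bin(d) == group)


def generate_fixture(config: SimConfig) -> FixtureSet:
    """Generate one complete fixture. Deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = PlantedTruth()
    samples = make_samples(config, rng)

    # -- contigs and genes --------------------------------------------------
    cand_ids = [f"AV_{i + 1:04d}" for i in range(config.n_contigs)]
    short_ids = [f"SC_{i + 1:04d}" for i in range(config.n_short_contigs)]
    lo, hi = config.contig_len_range
    slo, shi = config.short_len_range
    lengths = dict(zip(cand_ids, rng.integers(lo, hi + 1, size=len(cand_ids)).tolist()))
    lengths.update(zip(short_ids, rng.integers(slo, shi, size=len(short_ids)).tolist()))
    all_ids = cand_ids + short_ids
    contigs = pd.DataFrame(
        {
            "contig_id": all_ids,
            "length": [lengths[c] for c in all_ids],
            "virsorter_category": rng.integers(1, 7, size=len(all_ids)),
        }
    )
    gene_rows = []
    genes_of: dict[str, list[str]] = {}
    for cid in all_ids:
        n_g = max(1, lengths[cid] // (config.gene_length + 100))
        ids = []
        for i in range(n_g):
            start = i * (config.gene_length + 100) + 50
            gid = f"{cid}_g{i + 1:03d}"
            ids.append(gid)
            gene_rows.append(
                {
                    "gene_id": gid,
                    "contig_id": cid,
                    "start": start,
                    "end": start + config.gene_length,
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
        genes_of[cid] = ids
    genes = pd.DataFrame(gene_rows)

    # -- distribution groups ------------------------------------------------
    if config.depth_group_assignment is not None:
        group_of = dict(config.depth_group_assignment)
    else:
        counts = _apportion(dict(config.group_fractions), len(cand_ids))
        shuffled = list(rng.permutation(cand_ids))
        group_of, pos = {}, 0
        for g, _ in config.group_fractions:
            for cid in shuffled[pos : pos + counts[g]]:
                group_of[cid] = g
            pos += counts[g]
    meso = [d for d in config.depths_m if depth_bin(d) == "mesopelagic"]
    home_of: dict[str, int | None] = {}
    active_of: dict[str, list[str]] = {}
    dates = list(SAMPLE_DATES[: config.n_timepoints])
    for cid in cand_ids:
        g = group_of[cid]
        if g == "sporadic":
            home_of[cid] = int(rng.choice(meso or list(config.depths_m)))
            n_active = int(rng.integers(2, 5))
            active_of[cid] = sorted(rng.choice(dates, size=min(n_active, len(dates)), replace=False))
        else:
            home_of[cid] = None
    truth.depth_group = dict(group_of)
    truth.temporal_regime = {c: ("sporadic" if group_of[c] == "sporadic" else "persistent") for c in cand_ids}
    truth.sporadic_active_dates = dict(active_of)

    # -- curation structure: structural hits, contaminants, ambiguous hits --
    no_structural = sorted(rng.choice(cand_ids, size=config.n_no_structural, replace=False).tolist())
    contaminants = sorted(rng.choice(short_ids, size=config.contaminant_count, replace=False).tolist()) if config.contaminant_count else []
    truth.no_structural_contig_ids = no_structural
    truth.contaminant_contig_ids = contaminants

    hit_rows: list[tuple[str, str, float]] = []
    structural_contigs = []
    for cid in all_ids:
        if cid in no_structural or cid in contaminants:
            continue
        structural_contigs.append(cid)
        pool = genes_of[cid]
        n_hits = min(2, len(pool))
        for gid in rng.choice(pool, size=n_hits, replace=False):
            fam = _STRUCTURAL_LABELS[int(rng.integers(len(_STRUCTURAL_LABELS)))]
            hit_rows.append((gid, fam, float(rng.uniform(12, 90))))
    for j, cid in enumerate(no_structural):
        pool = genes_of[cid]
        for gid in rng.choice(pool, size=min(2, len(pool)), replace=False):
            fam = _STRUCTURAL_LABELS[int(rng.integers(len(_STRUCTURAL_LABELS)))]
            hit_rows.append((gid, fam, float(rng.uniform(2, 9.8))))
        if j == 0:  # pin the strict boundary: exactly 10.0 never qualifies
            hit_rows.append((pool[0], "capsid", 10.0))
    ribo = sorted(DEFAULT_CONTAMINANT_MARKERS.ribosomal)
    for cid in contaminants:
        gid = genes_of[cid][int(rng.integers(len(genes_of[cid])))]
        fam = ribo[int(rng.integers(len(ribo)))]
        hit_rows.append((gid, fam, float(rng.uniform(55, 90))))
    if config.n_ambiguous_marker_hits and structural_contigs:
        hosts = rng.choice([c for c in structural_contigs if c in cand_ids], size=config.n_ambiguous_marker_hits)
        for cid in hosts:
            gid = genes_of[cid][int(rng.integers(len(genes_of[cid])))]
            fam = "recA" if rng.random() < 0.6 else "dna_helicase"
            hit_rows.append((gid, fam, float(rng.uniform(55, 80))))

    # -- prophage flags (Fig-4-style, bit > 30 incl. Cro) -------------------
    flag_fams = ("integrase", "cro", "ci_repressor", "excisionase")
    flagged = []
    for cid in cand_ids:
        if cid in no_structural:
            continue
        p = 0.4 if group_of[cid] in ("mesopelagic", "sporadic") else 0.05
        if rng.random() < p:
            gid = genes_of[cid][int(rng.integers(len(genes_of[cid])))]
            fam = flag_fams[int(rng.integers(len(flag_fams)))]
            hit_rows.append((gid, fam, float(rng.uniform(31, 45))))
            flagged.append(cid)
    truth.prophage_flagged_contigs = sorted(flagged)

    # -- candidate novel genes (AMGs) and decoys ----------------------------
    cand_set = set(cand_ids)
    amg_hosts = sorted(c for c in structural_contigs if c in cand_set)
    if config.n_amg_genes > len(amg_hosts):
        raise ConfigError("n_amg_genes exceeds the number of structural-gene contigs")
    chosen_hosts = rng.choice(amg_hosts, size=config.n_amg_genes, replace=False)
    amg_gene_ids = []
    for i, cid in enumerate(chosen_hosts):
        gid = genes_of[cid][int(rng.integers(len(genes_of[cid])))]
        label = NOVEL_FUNCTION_LABELS[i % len(NOVEL_FUNCTION_LABELS)]
        hit_rows.append((gid, label, float(rng.uniform(32, 95))))
        amg_gene_ids.append(gid)
    truth.amg_gene_ids = sorted(set(amg_gene_ids))
    known_decoys = ("psbA", "phoH", "mazG")
    for k in range(min(3, len(amg_hosts))):
        cid = amg_hosts[int(rng.integers(len(amg_hosts)))]
        gid = genes_of[cid][int(rng.integers(len(genes_of[cid])))]
        hit_rows.append((gid, known_decoys[k % 3], float(rng.uniform(35, 90))))
    for k in range(min(3, len(amg_hosts))):
        cid = amg_hosts[int(rng.integers(len(amg_hosts)))]
        gid = genes_of[cid][int(rng.integers(len(genes_of[cid])))]
        hit_rows.append((gid, NOVEL_FUNCTION_LABELS[k], float(rng.uniform(15, 29.5))))
    if amg_hosts:  # boundary: bit exactly 30.0 never qualifies
        cid = amg_hosts[0]
        hit_rows.append((genes_of[cid][-1], NOVEL_FUNCTION_LABELS[-1], 30.0))
    for k in range(min(3, len(no_structural))):
        cid = no_structural[k]
        gid = genes_of[cid][int(rng.integers(len(genes_of[cid])))]
        hit_rows.append((gid, NOVEL_FUNCTION_LABELS[k % len(NOVEL_FUNCTION_LABELS)], float(rng.uniform(32, 60))))

    # -- reference hits for classification ----------------------------------
    curated = [c for c in cand_ids if c not in no_structural]
    ref_rows: list[tuple[str, str, str, float, float]] = []
    split = dict(zip(("refseq", "virome", "novel"), config.classification_split))
    counts = _apportion(split, len(curated))
    shallow = [c for c in curated if group_of[c] in ("surface", "DCM", "two_hundred")]
    deep = [c for c in curated if c not in set(shallow)]
    ordered = list(rng.permutation(shallow)) + list(rng.permutation(deep))
    refseq_set = ordered[: counts["refseq"]]
    virome_set = ordered[counts["refseq"] : counts["refseq"] + counts["virome"]]
    novel_set = ordered[counts["refseq"] + counts["virome"] :]
    db_counts = _apportion({"uvMED": 16, "GOV": 14, "EV": 7, "uvDeep": 3}, len(virome_set))
    db_of = {}
    pos = 0
    for db in ("uvMED", "GOV", "EV", "uvDeep"):
        for cid in virome_set[pos : pos + db_counts[db]]:
            db_of[cid] = db
        pos += db_counts[db]
    decoy_counter = 0

    def _plant_classified(cid: str, ref: str, db: str) -> None:
        nonlocal decoy_counter
        pool = genes_of[cid]
        k = len(pool) // 2 + 1
        hit_genes = set(rng.choice(pool, size=k, replace=False).tolist())
        for gid in pool:
            if gid in hit_genes:
                ref_rows.append((gid, ref, db, float(rng.uniform(62, 74)), float(rng.uniform(80, 200))))
            elif rng.random() < 0.3:
                decoy_counter += 1
                vdb = ("uvMED", "GOV", "EV", "uvDeep")[int(rng.integers(4))]
                ref_rows.append((gid, f"DEC_{decoy_counter:05d}", vdb, float(rng.uniform(20, 55)), float(rng.uniform(20, 55))))

    for i, cid in enumerate(refseq_set):
        ref = f"RS_{i + 1:03d}"
        _plant_classified(cid, ref, "refseq75")
        truth.classification[cid] = {"category": "refseq_phage", "reference": ref}
    for i, cid in enumerate(virome_set):
        db = db_of[cid]
        ref = f"{db}_{i + 1:03d}"
        _plant_classified(cid, ref, db)
        truth.classification[cid] = {"category": f"virome:{db}", "reference": ref}
    even_novels = [c for c in novel_set if len(genes_of[c]) % 2 == 0]
    boundary_novels = set(even_novels[:2])
    for i, cid in enumerate(novel_set):
        pool = genes_of[cid]
        if cid in boundary_novels:
            # exactly half the genes hit at high AAI: 0.5 is not > 0.5
            for gid in rng.choice(pool, size=len(pool) // 2, replace=False):
                ref_rows.append((gid, f"NOVREF_{i + 1:04d}", "GOV", float(rng.uniform(62, 74)), float(rng.uniform(80, 200))))
        elif rng.random() < 0.5:
            # majority hit one reference but below the AAI cutoff
            vdb = ("uvMED", "GOV", "EV", "uvDeep")[int(rng.integers(4))]
            for gid in rng.choice(pool, size=len(pool) // 2 + 1, replace=False):
                ref_rows.append((gid, f"NOVREF_{i + 1:04d}", vdb, float(rng.uniform(30, 55)), float(rng.uniform(60, 120))))
        else:
            # scattered weak hits to many distinct references
            for gid in pool:
                if rng.random() < 0.4:
                    decoy_counter += 1
                    vdb = ("uvMED", "GOV", "EV", "uvDeep")[int(rng.integers(4))]
                    ref_rows.append((gid, f"DEC_{decoy_counter:05d}", vdb, float(rng.uniform(20, 55)), float(rng.uniform(20, 60))))
        truth.classification[cid] = {"category": "novel", "reference": None}

    # -- contig coverage -----------------------------------------------------
    coverage = None
    if config.with_coverage:
        coverage = _make_coverage(config, rng, samples, cand_ids, lengths, group_of, home_of, active_of)

    # -- gene catalog (gene-centric fixture) ---------------------------------
    catalog = gene_cov = None
    if config.with_catalog:
        catalog, gene_cov, cat_hits = _make_catalog(config, rng, samples, truth)
        hit_rows.extend(cat_hits)

    domain_hits = pd.DataFrame(hit_rows, columns=["gene_id", "family", "bit_score"])
    ref_hits = pd.DataFrame(
        ref_rows, columns=["gene_id", "reference_id", "database", "aai_percent", "bit_score"]
    )

    sequences = None
    if config.with_sequences:
        alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
        sequences = {
            cid: alphabet[rng.integers(0, 4, size=lengths[cid])].tobytes().decode("ascii")
            for cid in all_ids
        }

    fixture = FixtureSet(
        config=config,
        samples=samples,
        contigs=contigs,
        genes=genes,
        domain_hits=domain_hits,
        ref_hits=ref_hits,
        coverage=coverage,
        catalog=catalog,
        gene_coverage=gene_cov,
        sequences=sequences,
        truth=truth,
    )
    fixture.validate()
    return fixture


def _make_coverage(config, rng, samples, cand_ids, lengths, group_of, home_of, active_of) -> CoverageTable:
    depth_of = dict(zip(samples["sample_id"], samples["depth_m"]))
    date_of = dict(zip(samples["sample_id"], samples["date"]))
    sample_ids = samples["sample_id"].tolist()
    runs = {}
    for cid in cand_ids:
        L = lengths[cid]
        base = float(10 ** rng.uniform(np.log10(5), np.log10(50)))
        group = group_of[cid]
        homes = set(_home_depths(group, home_of[cid], config.depths_m))
        active = set(active_of.get(cid, []))
        lam = np.empty(len(sample_ids))
        for j, sid in enumerate(sample_ids):
            home = depth_of[sid] in homes
            if group == "sporadic":
                mu = base * config.sporadic_boost if (home and date_of[sid] in active) else config.absent_lambda
            else:
                mu = base if home else config.absent_lambda
            lam[j] = mu
        lam = lam * _ln1(rng, config.sigma_log, len(sample_ids))
        nb = math.ceil(L / config.block_bp)
        block_lengths = np.full(nb, config.block_bp, dtype=np.int64)
        block_lengths[-1] = L - (nb - 1) * config.block_bp
        profile = np.ones(nb)
        k = math.floor(config.spike_fraction * nb)
        if k > 0:
            start = int(rng.integers(0, nb - k + 1))
            profile[start : start + k] = config.spike_multiplier
        depths_mat = rng.poisson(lam[:, None] * profile[None, :])
        for j, sid in enumerate(sample_ids):
            runs[(cid, sid)] = (depths_mat[j].astype(np.int64), block_lengths)
    return CoverageTable(runs, cand_ids, sample_ids)


def _make_catalog(config, rng, samples, truth) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    depths = list(config.depths_m)
    depth_idx = {d: i for i, d in enumerate(depths)}
    cell_lam = np.asarray(config.cell_lambda, dtype=float)
    copy_numbers = dict(config.copy_numbers or DEFAULT_COPY_NUMBERS)
    index_profile = _lysogeny_profile(config)
    capsid_tot = np.array([copy_numbers["capsid"][i] * cell_lam[i] for i in range(len(depths))])
    prophage_tot = np.array([index_profile[d] for d in depths]) * capsid_tot

    fam_tot: dict[str, np.ndarray] = {}
    for fam in ("capsid", "dna_polymerase", "terminase", "tail_fiber"):
        fam_tot[fam] = np.array(copy_numbers[fam]) * cell_lam
    for fam, share in PROPHAGE_SHARES.items():
        fam_tot[fam] = share * prophage_tot
    fam_tot["integrase"] = fam_tot["integrase"] * config.integrase_inflation

    rows, lam_rows, cat_hits = [], [], []
    marker_gene_ids: dict[str, list[str]] = {}

    def _add(gene_id, lam_profile, aai, psb, taxon):
        rows.append({"gene_id": gene_id, "viral_best_aai": aai, "photosystem_bit": psb, "taxon_label": taxon})
        lam_rows.append(np.asarray(lam_profile, dtype=float))

    for fam, n_genes in MARKER_GENE_COUNTS.items():
        ids = []
        for i in range(n_genes):
            gid = f"cat_{fam}_{i + 1:02d}"
            ids.append(gid)
            _add(gid, fam_tot[fam] / n_genes, float(rng.uniform(91, 99.5)), np.nan, None)
            cat_hits.append((gid, fam, float(rng.uniform(60, 120))))
        marker_gene_ids[fam] = ids
    # one gene matching two families: the higher score must win
    cat_hits.append((marker_gene_ids["integrase"][0], "excisionase", 55.0))
    cat_hits = [h if h[0] != marker_gene_ids["integrase"][0] or h[1] != "integrase" else (h[0], h[1], 90.0) for h in cat_hits]

    for i, cog in enumerate(UNIVERSAL_SINGLE_COPY):
        gid = f"cat_sc_{cog}"
        _add(gid, cell_lam, np.nan, np.nan, "bacteria_core")
        cat_hits.append((gid, cog, float(rng.uniform(60, 100))))
        marker_gene_ids[cog] = [gid]

    phage_ids, cell_ids = [], []
    for d in depths:
        profile = np.full(len(depths), 0.3)
        profile[depth_idx[d]] = 30.0
        for i in range(12):
            gid = f"cat_phage_d{d}_{i + 1:02d}"
            phage_ids.append(gid)
            aai = 90.0 if (d == depths[0] and i == 0) else float(rng.uniform(90.5, 99.5))
            # the 90.0 gene pins the strict boundary: exactly 90 is cellular
            _add(gid, profile, aai, np.nan, _PHAGE_TAXA[i % len(_PHAGE_TAXA)])
        for i in range(18):
            gid = f"cat_cell_d{d}_{i + 1:02d}"
            cell_ids.append(gid)
            aai = float(rng.uniform(10, 60)) if rng.random() < 0.3 else np.nan
            _add(gid, profile, aai, np.nan, _CELL_TAXA[i % len(_CELL_TAXA)])
    ps_profile = np.where(np.array([depth_bin(d) for d in depths]) == "mesopelagic", 0.3, 25.0)
    ps_ids = []
    for i in range(6):
        gid = f"cat_psb_{i + 1:02d}"
        ps_ids.append(gid)
        psb = 30.0 if i == 0 else float(rng.uniform(35, 80))
        # photosystem bit exactly 30 stays in the phage set (strict >)
        _add(gid, ps_profile, float(rng.uniform(90.5, 99.0)), psb, "cyanophage")
    decoy_cells = rng.choice(cell_ids, size=4, replace=False)
    fams = list(MARKER_GENE_COUNTS)
    for gid in decoy_cells:
        cat_hits.append((gid, fams[int(rng.integers(len(fams)))], float(rng.uniform(35, 49.5))))

    catalog = pd.DataFrame(rows)
    lam = np.vstack(lam_rows)  # genes x depths
    sample_ids = samples["sample_id"].tolist()
    d_idx = np.array([depth_idx[d] for d in samples["depth_m"]])
    noise = _ln1(rng, config.sigma_catalog, (lam.shape[0], len(sample_ids)))
    cov = lam[:, d_idx] * noise
    gene_cov = pd.DataFrame(cov, index=catalog["gene_id"], columns=sample_ids)

    infl = config.integrase_inflation
    joint_factor = PROPHAGE_SHARES["integrase"] * infl + PROPHAGE_SHARES["excisionase"] + PROPHAGE_SHARES["ci_repressor"]
    per_depth_index = {str(d): index_profile[d] * joint_factor for d in depths}
    truth.lysogeny = {
        "fold": config.lysogeny_fold,
        "base_index": config.base_lysogeny_index,
        "per_depth_index": per_depth_index,
        "per_sample_ratio": {
            sid: per_depth_index[str(d)] for sid, d in zip(samples["sample_id"], samples["depth_m"])
        },
    }
    truth.copy_numbers = {
        fam: {str(d): float(fam_tot[fam][depth_idx[d]] / cell_lam[depth_idx[d]]) for d in depths}
        for fam in fam_tot
    }
    truth.catalog = {
        "phage_gene_ids": phage_ids,
        "cell_gene_ids": cell_ids,
        "photosystem_gene_ids": ps_ids,
        "marker_genes": {fam: ids for fam, ids in marker_gene_ids.items()},
    }
    return catalog, gene_cov, cat_hits


# ---------------------------------------------------------------------------
# Worked-example fixtures (counts printed as inputs)
# ---------------------------------------------------------------------------


def curation_worked_example(seed: int = 0, n_pass_length: int = 142, n_no_structural: int = 13) -> FixtureSet:
    """Fixture for the curation worked example: ``n_pass_length`` contigs all
    >= 20 kbp, of which ``n_no_structural`` lack any structural hit above
    the bit cutoff."""
    config = SimConfig(
        seed=seed,
        n_contigs=n_pass_length,
        n_no_structural=n_no_structural,
        n_short_contigs=0,
        contaminant_count=0,
        with_coverage=False,
        with_catalog=False,
        with_sequences=False,
    )
    return generate_fixture(config)


def amg_worked_example(
    seed: int = 0, n_contigs: int = 917, n_structural: int = 625, n_candidates: int = 37
) -> FixtureSet:
    """Fixture for the colocalization worked example: ``n_contigs`` contigs of
    which ``n_structural`` carry structural hits, with exactly
    ``n_candidates`` qualifying novel-function genes planted (plus decoys)."""
    config = SimConfig(
        seed=seed,
        n_contigs=n_contigs,
        n_no_structural=n_contigs - n_structural,
        n_short_contigs=0,
        contaminant_count=0,
        n_amg_genes=n_candidates,
        with_coverage=False,
        with_catalog=False,
        with_sequences=False,
    )
    return generate_fixture(config)


def partition_worked_example(
    seed: int = 0, n_viral: int = 177_713, n_photosystem: int = 5_328, n_cell: int = 20_000
) -> pd.DataFrame:
    """Gene catalog for the partition worked example: ``n_viral`` genes above
    the viral AAI cutoff, ``n_photosystem`` of them photosystem-flagged, plus
    a cellular remainder (desk-scale stand-in for the full catalog)."""
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:07d}" for i in range(n_viral + n_cell)]
    aai = np.concatenate([rng.uniform(90.5, 99.9, n_viral), rng.uniform(10.0, 90.0, n_cell)])
    psb = np.full(n_viral + n_cell, np.nan)
    ps_idx = rng.choice(n_viral, size=n_photosystem, replace=False)
    psb[ps_idx] = rng.uniform(30.5, 120.0, n_photosystem)
    # sub-threshold photosystem hits on some other viral genes: must stay phage
    rest = np.setdiff1d(np.arange(n_viral), ps_idx)
    sub_idx = rng.choice(rest, size=min(500, rest.size), replace=False)
    psb[sub_idx] = rng.uniform(5.0, 30.0, sub_idx.size)
    return pd.DataFrame({"gene_id": gene_ids, "viral_best_aai": aai, "photosystem_bit": psb})
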