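"""End-to-end orchestration: curate -> classify -> abundance/groups ->
assemblage -> life history -> AMG, with a reproducible run manifest.

Every stage reads the standard fixture-format files from one input
directory and writes its tables to one output directory. The manifest
records package and library versions, a hash of the configuration, and
per-stage row counts and wall times, so identical inputs and
configuration give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as pdio
from .amg_detection import depth_specificity, find_candidates
from .assemblage_clustering import (
    average_linkage,
    bray_curtis_matrix,
    catalog_relative_abundance,
    compare_dendrograms,
    partition_gene_catalog,
)
from .contig_curation import run_cascade
from .coverage_stats import assign_depth_groups, dispersion_by_depth, relative_abundance
from .exceptions import ConfigError
from .homology_classification import category_proportions, classify_contigs
from .life_history import (
    copy_number_per_genome,
    detect_markers,
    flag_prophage_contigs,
    fold_vs_surface,
    lysogeny_index,
)
from .synthetic_data import FixtureSet, SimConfig, generate_fixture
from .thresholds import DEFAULT_THRESHOLDS, Thresholds

logger = logging.getLogger(__name__)

ALL_STAGES = ("curate", "classify", "abundance", "assemblage", "lifehistory", "amg")

_STAGE_INPUTS = {
    "curate": ("contigs", "genes", "domain_hits"),
    "classify": ("ref_hits", "coverage", "samples", "genes"),
    "abundance": ("coverage", "samples"),
    "assemblage": ("catalog", "gene_coverage"),
    "lifehistory": ("domain_hits", "gene_coverage", "samples", "genes"),
    "amg": ("genes", "domain_hits"),
}


@dataclass
class RunConfig:
    """Paths, thresholds, and stage toggles for one pipeline run."""

    input_dir: Path
    out_dir: Path
    thresholds: Thresholds = DEFAULT_THRESHOLDS
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    sporadic_threshold: float | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a run configuration from a YAML file.

        Recognized keys: input_dir, out_dir, stages, seed,
        sporadic_threshold, log_level, and a ``thresholds`` mapping whose
        entries override the defaults.
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {
            "input_dir", "out_dir", "stages", "seed",
            "sporadic_threshold", "log_level", "thresholds",
        }
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("input_dir", "out_dir"):
            if key not in raw:
                raise ConfigError(f"config must set {key!r}")
        thresholds = Thresholds(**raw.get("thresholds", {}))
        return cls(
            input_dir=Path(raw["input_dir"]),
            out_dir=Path(raw["out_dir"]),
            thresholds=thresholds,
            stages=tuple(raw.get("stages", ALL_STAGES)),
            seed=int(raw.get("seed", 0)),
            sporadic_threshold=raw.get("sporadic_threshold"),
            log_level=str(raw.get("log_level", "INFO")),
        )

    def input_path(self, key: str) -> Path:
        return Path(self.input_dir) / pdio.FIXTURE_FILES[key]

    def check_inputs(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        missing = []
        for stage in self.stages:
            for key in _STAGE_INPUTS[stage]:
                path = self.input_path(key)
                if not path.exists():
                    missing.append(path.name)
        if missing:
            raise ConfigError(f"missing input file(s): {sorted(set(missing))}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_dir"] = str(self.input_dir)
        d["out_dir"] = str(self.out_dir)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.check_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    manifest: dict = {
        "package_version": __version__,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
    }
    thresholds = config.thresholds

    state: dict = {}
    try:
        for stage in [s for s in ALL_STAGES if s in config.stages]:
            t0 = time.perf_counter()
            counts = _STAGE_RUNNERS[stage](config, thresholds, out, state)
            manifest["stages"][stage] = {
                "rows": counts,
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }
            logger.info("stage %-12s done in %.2fs", stage, manifest["stages"][stage]["wall_time_s"])
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        _write_manifest(out, manifest)
        raise
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file() and p.name != "manifest.json"
    }
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _stage_curate(config, thresholds, out, state):
    contigs = pdio.read_contigs_fasta(config.input_path("contigs"))
    genes = pdio.read_genes_gff(config.input_path("genes"))
    domain_hits = pdio.read_tsv(config.input_path("domain_hits"))
    retained, report = run_cascade(contigs, genes, domain_hits, thresholds)
    state["retained"] = retained["contig_id"].tolist()
    state["genes"] = genes
    state["domain_hits"] = domain_hits
    report.to_json(out / "curation_report.json")
    (out / "retained_contigs.txt").write_text("\n".join(state["retained"]) + "\n")
    return {"retained_contigs": len(retained)}


def _load_genes(config, state):
    if "genes" not in state:
        state["genes"] = pdio.read_genes_gff(config.input_path("genes"))
    return state["genes"]


def _load_coverage(config, state):
    if "coverage" not in state:
        state["coverage"] = pdio.read_coverage(config.input_path("coverage"))
    return state["coverage"]


def _load_samples(config, state):
    if "samples" not in state:
        state["samples"] = pdio.read_tsv(config.input_path("samples"))
    return state["samples"]


def _retained(config, state, coverage):
    if "retained" in state:
        return [c for c in coverage.contig_ids if c in set(state["retained"])]
    retained_file = Path(config.out_dir) / "retained_contigs.txt"
    if retained_file.exists():
        keep = set(retained_file.read_text().split())
        return [c for c in coverage.contig_ids if c in keep]
    return list(coverage.contig_ids)


def _stage_classify(config, thresholds, out, state):
    genes = _load_genes(config, state)
    ref_hits = pdio.read_tsv(config.input_path("ref_hits"))
    coverage = _load_coverage(config, state)
    samples = _load_samples(config, state)
    retained = _retained(config, state, coverage)
    retained = [c for c in retained if c in set(genes["contig_id"])]
    classifications = classify_contigs(genes, ref_hits, contig_ids=retained, thresholds=thresholds)
    per_sample, summary = category_proportions(
        classifications, coverage.subset(retained), samples, level="bin"
    )
    pdio._write_tsv(classifications.reset_index(), out / "classifications.tsv")
    pdio._write_tsv(summary, out / "proportions.tsv")
    state["classifications"] = classifications
    return {"classified_contigs": len(classifications)}


def _stage_abundance(config, thresholds, out, state):
    coverage = _load_coverage(config, state)
    samples = _load_samples(config, state)
    retained = _retained(config, state, coverage)
    sub = coverage.subset(retained)
    rel = relative_abundance(sub, on_zero_sample="drop")
    disp = dispersion_by_depth(rel, samples[samples["sample_id"].isin(rel.columns)], level="depth")
    groups = assign_depth_groups(sub, samples, sporadic_threshold=config.sporadic_threshold)
    pdio._write_tsv(rel.rename_axis("contig_id").reset_index(), out / "abundance_matrix.tsv")
    pdio._write_tsv(disp.rename_axis("contig_id").reset_index(), out / "dispersion.tsv")
    pdio._write_tsv(groups.rename_axis("contig_id").reset_index(), out / "depth_groups.tsv")
    state["rel_abundance"] = rel
    state["depth_groups"] = groups
    return {"contigs": len(rel), "samples": rel.shape[1]}


def _stage_assemblage(config, thresholds, out, state):
    catalog = pdio.read_tsv(config.input_path("catalog"))
    gene_cov = pdio.read_gene_coverage(config.input_path("gene_coverage"))
    state["gene_coverage"] = gene_cov
    phage_ids, cell_ids = partition_gene_catalog(catalog, thresholds)
    rel = catalog_relative_abundance(gene_cov)
    trees = {}
    for name, ids in (("phage", phage_ids), ("cell", cell_ids)):
        dist = bray_curtis_matrix(rel.loc[rel.index.intersection(ids)])
        pdio._write_tsv(dist.rename_axis("sample_id").reset_index(), out / f"bray_curtis_{name}.tsv")
        trees[name] = average_linkage(dist)
        (out / f"{name}_tree.nwk").write_text(trees[name].to_newick())
    stats = compare_dendrograms(trees["phage"], trees["cell"])
    with open(out / "assemblage_comparison.json", "w", newline="\n") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"phage_genes": len(phage_ids), "cell_genes": len(cell_ids)}


def _stage_lifehistory(config, thresholds, out, state):
    domain_hits = state.get("domain_hits")
    if domain_hits is None:
        domain_hits = pdio.read_tsv(config.input_path("domain_hits"))
    gene_cov = state.get("gene_coverage")
    if gene_cov is None:
        gene_cov = pdio.read_gene_coverage(config.input_path("gene_coverage"))
    samples = _load_samples(config, state)
    genes = _load_genes(config, state)
    assignments = detect_markers(domain_hits)
    indices = lysogeny_index(assignments, gene_cov)
    folds = fold_vs_surface(indices, samples)
    copies = copy_number_per_genome(assignments, gene_cov)
    flags = flag_prophage_contigs(genes, domain_hits, thresholds)
    pdio._write_tsv(indices.reset_index(), out / "lysogeny_profile.tsv")
    pdio._write_tsv(folds.reset_index(), out / "fold_vs_surface.tsv")
    pdio._write_tsv(copies.reset_index(), out / "copy_numbers.tsv")
    pdio._write_tsv(flags.rename_axis("contig_id").reset_index(), out / "prophage_flags.tsv")
    return {"marker_genes": len(assignments), "samples": len(indices)}


def _stage_amg(config, thresholds, out, state):
    genes = _load_genes(config, state)
    domain_hits = state.get("domain_hits")
    if domain_hits is None:
        domain_hits = pdio.read_tsv(config.input_path("domain_hits"))
    candidates = find_candidates(genes, domain_hits, thresholds=thresholds)
    rel = state.get("rel_abundance")
    if rel is not None and len(candidates):
        with_abundance = candidates[candidates["contig_id"].isin(rel.index)]
        if len(with_abundance):
            samples = _load_samples(config, state)
            spec = depth_specificity(with_abundance, rel, samples)
            candidates = candidates.merge(spec[["gene_id", "depth_labels", "specific"]], on="gene_id", how="left")
    pdio._write_tsv(candidates, out / "amg_candidates.tsv")
    return {"candidates": len(candidates)}


_STAGE_RUNNERS = {
    "curate": _stage_curate,
    "classify": _stage_classify,
    "abundance": _stage_abundance,
    "assemblage": _stage_assemblage,
    "lifehistory": _stage_lifehistory,
    "amg": _stage_amg,
}


def make_fixture(config: SimConfig, outdir) -> Path:
    """Generate a fixture and write it (with a README describing the truth)."""
    fixture: FixtureSet = generate_fixture(config)
    outdir = pdio.write_fixture(fixture, outdir)
    truth = fixture.truth
    lines = [
        "Synthetic water-column phage fixture",
        f"seed: {config.seed}",
        f"contigs: {len(fixture.contigs)} ({config.n_contigs} length-passing candidates)",
        f"samples: {len(fixture.samples)} ({config.n_depths} depths x {config.n_timepoints} occasions)",
        f"planted lysogeny fold (mesopelagic vs surface): {config.lysogeny_fold}",
        f"contaminant contigs: {truth.contaminant_contig_ids}",
        f"contigs lacking structural genes: {len(truth.no_structural_contig_ids)}",
        f"planted candidate novel genes: {len(truth.amg_gene_ids)}",
        "",
        "truth.json holds the planted truth; pipeline stages never read it.",
    ]
    (outdir / "README.txt").write_text("\n".join(lines) + "\n")
    return outdir
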