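"""Quality-control cascade turning candidate viral contigs into a high-confidence set.

Three stages, applied in order:

1. **Length filter** — keep contigs of at least ``min_contig_len`` bp
   (inclusive), focusing on near-complete genomes or large fragments.
2. **Structural-gene requirement** — keep contigs carrying at least one
   gene with distant homology (domain bit score strictly > 10) to any of
   eight phage structural-protein families (terminase, portal, capsid,
   tail, base plate, spike, neck, head).
3. **Contamination screen** — remove contigs carrying a ribosomal
   single-copy prokaryotic marker gene above the marker bit cutoff.
   Hits to recA / DNA helicase are tallied but tolerated, since phages
   encode homologous recombination and replication genes.

Every stage is a per-contig predicate, so the cascade is order-insensitive
in its retained set and each stage's output is a subset of its input.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ConfigError, DataError
from .markers import (
    DEFAULT_CONTAMINANT_MARKERS,
    STRUCTURAL_FAMILIES,
    ContaminantMarkerSet,
    normalize_family,
)
from .thresholds import DEFAULT_THRESHOLDS, Thresholds

logger = logging.getLogger(__name__)


@dataclass
class StageResult:
    name: str
    n_in: int
    n_out: int
    removed_ids: list[str]
    reason: str

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_in": self.n_in,
            "n_out": self.n_out,
            "removed_ids": sorted(self.removed_ids),
            "reason": self.reason,
        }


@dataclass
class CurationReport:
    """Per-stage counts plus the marker-gene tally of the contamination screen.

    ``completeness_proxy`` is the fraction of non-ambiguous single-copy
    marker families observed anywhere in the retained set — a simple
    observed-family proxy for cellular genomic completeness, compared
    only against planted truth in this package's fixtures.
    """

    stages: list[StageResult] = field(default_factory=list)
    n_total_genes: int = 0
    n_marker_hit_genes: int = 0
    n_ambiguous_marker_genes: int = 0
    completeness_proxy: float = 0.0

    def to_dict(self) -> dict:
        return {
            "stages": [s.to_dict() for s in self.stages],
            "n_total_genes": self.n_total_genes,
            "n_marker_hit_genes": self.n_marker_hit_genes,
            "n_ambiguous_marker_genes": self.n_ambiguous_marker_genes,
            "completeness_proxy": self.completeness_proxy,
        }

    def to_json(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _check_contigs(contigs: pd.DataFrame) -> pd.DataFrame:
    missing = {"contig_id", "length"} - set(contigs.columns)
    if missing:
        raise DataError(f"contig table missing columns: {sorted(missing)}")
    if (contigs["length"] < 1).any():
        raise DataError("contig lengths must be >= 1")
    if "virsorter_category" in contigs.columns:
        cats = contigs["virsorter_category"].dropna()
        bad = cats[~cats.isin(range(1, 7))]
        if len(bad):
            raise DataError(f"virsorter_category must be in 1..6, got {sorted(bad.unique())}")
    return contigs


def filter_by_length(
    contigs: pd.DataFrame, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> tuple[pd.DataFrame, StageResult]:
    """Retain contigs with length >= min_contig_len (inclusive), order preserved."""
    contigs = _check_contigs(contigs)
    if contigs.empty:
        warnings.warn("length filter received an empty contig set")
    keep = contigs["length"] >= thresholds.min_contig_len
    retained = contigs[keep].reset_index(drop=True)
    stage = StageResult(
        name="length",
        n_in=len(contigs),
        n_out=len(retained),
        removed_ids=contigs.loc[~keep, "contig_id"].tolist(),
        reason=f"length < {thresholds.min_contig_len} bp",
    )
    return retained, stage


def structural_contig_ids(
    genes: pd.DataFrame,
    domain_hits: pd.DataFrame,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    structural_families: frozenset[str] = STRUCTURAL_FAMILIES,
) -> set[str]:
    """Contigs with >= 1 gene hitting a structural family strictly above the bit cutoff."""
    unknown = {f for f in structural_families if normalize_family(f) not in STRUCTURAL_FAMILIES}
    if unknown:
        raise ConfigError(f"unknown structural families requested: {sorted(unknown)}")
    wanted = {normalize_family(f) for f in structural_families}
    fams = domain_hits["family"].map(normalize_family)
    qualifying = domain_hits[fams.isin(wanted) & (domain_hits["bit_score"] > thresholds.structural_bit)]
    gene_to_contig = genes.set_index("gene_id")["contig_id"]
    return set(gene_to_contig.reindex(qualifying["gene_id"]).dropna())


def require_structural_gene(
    contig_id: str,
    genes: pd.DataFrame,
    domain_hits: pd.DataFrame,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Single-contig predicate form of the structural-gene requirement."""
    sub_genes = genes[genes["contig_id"] == contig_id]
    sub_hits = domain_hits[domain_hits["gene_id"].isin(sub_genes["gene_id"])]
    return contig_id in structural_contig_ids(sub_genes, sub_hits, thresholds)


def filter_by_structural_gene(
    contigs: pd.DataFrame,
    genes: pd.DataFrame,
    domain_hits: pd.DataFrame,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[pd.DataFrame, StageResult]:
    ok = structural_contig_ids(genes, domain_hits, thresholds)
    keep = contigs["contig_id"].isin(ok)
    retained = contigs[keep].reset_index(drop=True)
    stage = StageResult(
        name="structural",
        n_in=len(contigs),
        n_out=len(retained),
        removed_ids=contigs.loc[~keep, "contig_id"].tolist(),
        reason=f"no structural-family hit with bit > {thresholds.structural_bit}",
    )
    return retained, stage


def contamination_screen(
    contigs: pd.DataFrame,
    genes: pd.DataFrame,
    domain_hits: pd.DataFrame,
    marker_set: ContaminantMarkerSet = DEFAULT_CONTAMINANT_MARKERS,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[pd.DataFrame, StageResult, dict]:
    """Remove contigs carrying ribosomal-marker hits; tally all marker hits.

    Returns (retained contigs, stage result, tally dict) where the tally
    holds total marker-hit genes, the recA/DNA-helicase (phage-ambiguous)
    subset, the total gene count, and the completeness proxy.
    """
    if not marker_set.families:
        raise ConfigError("empty contamination marker set")
    sub_genes = genes[genes["contig_id"].isin(contigs["contig_id"])]
    hits = domain_hits[domain_hits["gene_id"].isin(sub_genes["gene_id"])].copy()
    hits["family_norm"] = hits["family"].map(normalize_family)
    fam_norm = {normalize_family(f): f for f in marker_set.families}
    marker_hits = hits[hits["family_norm"].isin(fam_norm) & (hits["bit_score"] > thresholds.marker_bit)]

    ambiguous_norm = {normalize_family(f) for f in marker_set.phage_ambiguous}
    ribosomal_norm = {normalize_family(f) for f in marker_set.ribosomal}

    marker_genes = marker_hits["gene_id"].unique()
    ambiguous_genes = marker_hits.loc[marker_hits["family_norm"].isin(ambiguous_norm), "gene_id"].unique()
    observed = {
        fam_norm[f] for f in marker_hits["family_norm"].unique() if f not in ambiguous_norm
    }
    tally = {
        "n_total_genes": len(sub_genes),
        "n_marker_hit_genes": int(len(marker_genes)),
        "n_ambiguous_marker_genes": int(len(ambiguous_genes)),
        "completeness_proxy": len(observed) / len(marker_set.families),
    }

    ribo_genes = marker_hits.loc[marker_hits["family_norm"].isin(ribosomal_norm), "gene_id"]
    gene_to_contig = sub_genes.set_index("gene_id")["contig_id"]
    contaminated = set(gene_to_contig.reindex(ribo_genes).dropna())
    keep = ~contigs["contig_id"].isin(contaminated)
    retained = contigs[keep].reset_index(drop=True)
    stage = StageResult(
        name="contamination",
        n_in=len(contigs),
        n_out=len(retained),
        removed_ids=contigs.loc[~keep, "contig_id"].tolist(),
        reason=f"ribosomal marker hit with bit > {thresholds.marker_bit}",
    )
    return retained, stage, tally


def run_cascade(
    contigs: pd.DataFrame,
    genes: pd.DataFrame,
    domain_hits: pd.DataFrame,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    marker_set: ContaminantMarkerSet = DEFAULT_CONTAMINANT_MARKERS,
) -> tuple[pd.DataFrame, CurationReport]:
    """Length -> structural -> contamination, with a per-stage report."""
    report = CurationReport()
    retained, stage = filter_by_length(contigs, thresholds)
    report.stages.append(stage)
    retained, stage = filter_by_structural_gene(retained, genes, domain_hits, thresholds)
    report.stages.append(stage)
    retained, stage, tally = contamination_screen(retained, genes, domain_hits, marker_set, thresholds)
    report.stages.append(stage)
    report.n_total_genes = tally["n_total_genes"]
    report.n_marker_hit_genes = tally["n_marker_hit_genes"]
    report.n_ambiguous_marker_genes = tally["n_ambiguous_marker_genes"]
    report.completeness_proxy = tally["completeness_proxy"]
    for s in report.stages:
        logger.info("curation stage %-13s %4d -> %4d", s.name, s.n_in, s.n_out)
    return retained, report
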