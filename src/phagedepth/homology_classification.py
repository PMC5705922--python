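"""Classify curated contigs against reference phage genomes by majority-gene AAI.

A contig classifies to a reference genome when strictly more than half of
its genes best-hit that reference and the mean amino-acid identity of
those genes strictly exceeds 60%. The rule is evaluated per reference
*genome* (never pooled across a database): pooling would let chimeric
similarity to many unrelated references masquerade as homology.

Database precedence mirrors the reporting hierarchy: a qualifying
reference in the curated phage genome database (refseq75) beats any
virome reference; among equals, higher gene fraction, then higher mean
AAI, then lexicographic reference id. Contigs with no qualifying
reference are novel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage_stats import CoverageTable
from .design import depth_bin, validate_samples
from .exceptions import DataError
from .thresholds import DEFAULT_THRESHOLDS, Thresholds

REFSEQ_DB = "refseq75"
VIROME_DBS = ("uvMED", "uvDeep", "GOV", "EV")
CATEGORIES = ("refseq_phage",) + tuple(f"virome:{db}" for db in VIROME_DBS) + ("novel",)


@dataclass(frozen=True)
class ClassificationResult:
    contig_id: str
    category: str
    best_reference_id: str | None
    gene_fraction_hit: float
    mean_aai: float


def _category_for(db: str) -> str:
    return "refseq_phage" if db == REFSEQ_DB else f"virome:{db}"


def best_hit_per_gene(ref_hits: pd.DataFrame) -> pd.DataFrame:
    """Reduce a gene x reference hit table to one best hit per gene.

    Maximal bit score wins; ties break by higher AAI, then lexicographic
    reference id. Duplicate rows are ignored. Returns a frame indexed by
    gene_id with columns reference_id, database, aai_percent, bit_score.
    """
    required = {"gene_id", "reference_id", "database", "aai_percent", "bit_score"}
    missing = required - set(ref_hits.columns)
    if missing:
        raise DataError(f"hit table missing columns: {sorted(missing)}")
    if ((ref_hits["aai_percent"] < 0) | (ref_hits["aai_percent"] > 100)).any():
        raise DataError("aai_percent must lie in [0, 100]")
    if not np.isfinite(ref_hits["bit_score"]).all():
        raise DataError("bit scores must be finite")
    hits = ref_hits.drop_duplicates()
    hits = hits.sort_values(
        ["gene_id", "bit_score", "aai_percent", "reference_id"],
        ascending=[True, False, False, True],
        kind="stable",
    )
    return hits.groupby("gene_id", sort=True).first()


def classify_contig(
    contig_id: str,
    gene_ids: list[str],
    best_hits: pd.DataFrame,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> ClassificationResult:
    """Classify one contig given its gene list and the per-gene best hits.

    The denominator of the gene fraction is *all* genes on the contig,
    including genes with no hit.
    """
    n_genes = len(gene_ids)
    if n_genes == 0:
        raise DataError(f"contig {contig_id!r} has no genes; classification undefined")
    sub = best_hits.loc[best_hits.index.intersection(gene_ids)]
    if sub.empty:
        return ClassificationResult(contig_id, "novel", None, float("nan"), float("nan"))
    per_ref = sub.groupby(["reference_id", "database"], sort=True).agg(
        n=("aai_percent", "size"), mean_aai=("aai_percent", "mean")
    )
    per_ref["fraction"] = per_ref["n"] / n_genes
    qualifying = per_ref[
        (per_ref["fraction"] > thresholds.gene_fraction) & (per_ref["mean_aai"] > thresholds.aai_classify)
    ]
    if qualifying.empty:
        return ClassificationResult(contig_id, "novel", None, float("nan"), float("nan"))
    ranked = qualifying.reset_index()
    ranked["db_rank"] = (ranked["database"] != REFSEQ_DB).astype(int)
    ranked = ranked.sort_values(
        ["db_rank", "fraction", "mean_aai", "reference_id"],
        ascending=[True, False, False, True],
        kind="stable",
    )
    top = ranked.iloc[0]
    return ClassificationResult(
        contig_id,
        _category_for(top["database"]),
        str(top["reference_id"]),
        float(top["fraction"]),
        float(top["mean_aai"]),
    )


def classify_contigs(
    genes: pd.DataFrame,
    ref_hits: pd.DataFrame,
    contig_ids: list[str] | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Classify every contig; returns a frame indexed by contig_id."""
    best = best_hit_per_gene(ref_hits) if len(ref_hits) else pd.DataFrame(
        columns=["reference_id", "database", "aai_percent", "bit_score"]
    )
    if contig_ids is None:
        contig_ids = sorted(genes["contig_id"].unique())
    by_contig = genes.groupby("contig_id")["gene_id"].agg(list)
    rows = []
    for cid in contig_ids:
        if cid not in by_contig.index:
            raise DataError(f"contig {cid!r} has no genes; classification undefined")
        res = classify_contig(cid, by_contig[cid], best, thresholds)
        rows.append(
            {
                "contig_id": res.contig_id,
                "category": res.category,
                "best_reference_id": res.best_reference_id,
                "gene_fraction_hit": res.gene_fraction_hit,
                "mean_aai": res.mean_aai,
            }
        )
    return pd.DataFrame(rows).set_index("contig_id")


def category_proportions(
    classifications: pd.DataFrame,
    coverage: CoverageTable,
    samples: pd.DataFrame,
    level: str = "bin",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample category proportions of mapped nucleotides, plus a summary.

    Proportion(category, sample) = nucleotides mapped to contigs of that
    category / nucleotides mapped to all classified contigs in the
    sample; proportions in a sample sum to 1. Samples with zero total
    mapping are excluded with a warning. The summary aggregates samples
    by habitat bin (``level='bin'``) or sampling depth (``'depth'``),
    reporting the mean and standard error (sd / sqrt(n), ddof=1).
    """
    samples = validate_samples(samples)
    nt = coverage.nucleotides_mapped()
    keep = [c for c in nt.index if c in classifications.index]
    nt = nt.loc[keep]
    totals = nt.sum(axis=0)
    zero = totals[totals <= 0].index.tolist()
    if zero:
        warnings.warn(f"excluding {len(zero)} sample(s) with zero mapping: {zero[:5]}")
        nt = nt.drop(columns=zero)
        totals = totals.drop(index=zero)
    cat = classifications.loc[keep, "category"]
    by_cat = nt.groupby(cat.values).sum()
    per_sample = by_cat.div(totals, axis=1).T  # samples x categories
    per_sample.index.name = "sample_id"

    meta = samples.set_index("sample_id")
    if level == "bin":
        grouping = per_sample.index.map(lambda s: depth_bin(meta.loc[s, "depth_m"]))
    elif level == "depth":
        grouping = per_sample.index.map(lambda s: meta.loc[s, "depth_m"])
    else:
        raise DataError(f"unknown level {level!r}")
    rows = []
    for gname, sub in per_sample.groupby(grouping):
        m = sub.mean()
        se = sub.std(ddof=1) / np.sqrt(len(sub))
        for catname in per_sample.columns:
            rows.append(
                {
                    "group": gname,
                    "category": catname,
                    "mean": m[catname],
                    "se": se[catname],
                    "n": len(sub),
                }
            )
    summary = pd.DataFrame(rows)
    return per_sample, summary
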