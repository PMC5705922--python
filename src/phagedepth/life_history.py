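"""Lysogenic vs lytic signal down the water column.

Two deliberately distinct marker rules coexist:

* **Catalog profile** — marker proteins detected in the gene catalog at a
  domain bit score strictly > 50. The lysogeny index of a sample is the
  summed coverage of prophage markers (integrase, CI repressor,
  excisionase) divided by the summed coverage of capsids, i.e. the
  proportion of phage genomes that carry the lambda-style lysogeny
  module. Folding each depth's mean index by the surface mean gives the
  relative change in lysogenic potential with depth.
* **Per-contig flag** — a contig is flagged as prophage-marker-bearing
  when any of its genes scores strictly > 30 against integrase, CI
  repressor, Cro, or excisionase.

Copy numbers per cellular genome normalize marker coverages by the mean
coverage of ten universal single-copy bacterial marker genes, so a value
of 1 means one marker copy per cell.

Integrases are known to give anomalously high signal (integrative
conjugative elements and other non-phage mobile elements carry them), so
per-family indices are reported alongside the joint index.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .design import SURFACE_DEPTHS, validate_samples
from .exceptions import DataError
from .markers import (
    DEFAULT_MARKER_CATALOG,
    PROPHAGE_FLAG_FAMILIES,
    MarkerCatalog,
    normalize_family,
)
from .thresholds import DEFAULT_THRESHOLDS, Thresholds


def detect_markers(
    domain_hits: pd.DataFrame,
    catalog: MarkerCatalog = DEFAULT_MARKER_CATALOG,
) -> pd.Series:
    """Assign catalog genes to marker families from their domain scores.

    A gene joins a family iff its score against that family's model is
    strictly above the catalog's detection bit (50 across the whole
    sequence); a gene matching several families takes the highest-scoring
    one, ties breaking lexicographically by family name. Returns a Series
    gene_id -> family.
    """
    fams = {normalize_family(f): f for f in catalog.families}
    hits = domain_hits.copy()
    hits["family_norm"] = hits["family"].map(normalize_family)
    hits = hits[hits["family_norm"].isin(fams) & (hits["bit_score"] > catalog.detection_bit)]
    hits = hits.sort_values(
        ["gene_id", "bit_score", "family_norm"], ascending=[True, False, True], kind="stable"
    )
    best = hits.groupby("gene_id", sort=True).first()
    return best["family_norm"].map(fams).rename("family")


def _family_coverage(
    assignments: pd.Series, gene_coverage: pd.DataFrame, families: Iterable[str]
) -> pd.DataFrame:
    """Summed coverage per family x sample (families absent -> 0)."""
    families = list(families)
    genes = assignments[assignments.isin(families)]
    sub = gene_coverage.loc[gene_coverage.index.intersection(genes.index)]
    summed = sub.groupby(genes.reindex(sub.index).values).sum()
    return summed.reindex(families, fill_value=0.0)


def lysogeny_index(
    assignments: pd.Series,
    gene_coverage: pd.DataFrame,
    catalog: MarkerCatalog = DEFAULT_MARKER_CATALOG,
) -> pd.DataFrame:
    """Per-sample lysogeny index: summed prophage-marker / summed capsid coverage.

    Returns a frame indexed by sample with the summed prophage and capsid
    coverages, the joint index, and one per-family index per prophage
    family. Samples with zero capsid coverage are undefined (NaN) and
    flagged with a warning.
    """
    fam_cov = _family_coverage(assignments, gene_coverage, catalog.prophage + ("capsid",))
    capsid = fam_cov.loc["capsid"]
    zero = capsid[capsid <= 0].index.tolist()
    if zero:
        warnings.warn(f"zero capsid coverage in sample(s) {zero[:5]}; index undefined there")
    with np.errstate(divide="ignore", invalid="ignore"):
        prophage_sum = fam_cov.loc[list(catalog.prophage)].sum(axis=0)
        out = pd.DataFrame(
            {
                "prophage_coverage": prophage_sum,
                "capsid_coverage": capsid,
                "index": prophage_sum / capsid,
            }
        )
        for fam in catalog.prophage:
            out[f"index_{fam}"] = fam_cov.loc[fam] / capsid
    out.loc[zero, [c for c in out.columns if c.startswith("index")]] = np.nan
    out.index.name = "sample_id"
    return out


def fold_vs_surface(
    indices: pd.DataFrame,
    samples: pd.DataFrame,
    surface_depths: tuple[int, ...] = SURFACE_DEPTHS,
    column: str = "index",
) -> pd.DataFrame:
    """Per-depth mean index and its fold change versus the surface mean.

    The surface mean is the mean index over all samples at the surface
    depths (25 and 75 m by default); the fold at the surface bin itself
    is 1 by construction.
    """
    samples = validate_samples(samples)
    meta = samples.set_index("sample_id")
    valid = indices[column].dropna()
    if valid.empty:
        raise DataError("no valid lysogeny indices")
    depths = meta.loc[valid.index, "depth_m"]
    surface_vals = valid[depths.isin(surface_depths).values]
    if surface_vals.empty:
        raise DataError(f"no valid surface samples at depths {surface_depths}")
    surface_mean = float(surface_vals.mean())
    if surface_mean == 0:
        raise DataError("surface mean index is zero; fold undefined")
    per_depth = valid.groupby(depths.values).mean()
    out = pd.DataFrame({"mean_index": per_depth, "fold_vs_surface": per_depth / surface_mean})
    out.index.name = "depth_m"
    return out.sort_index()


def copy_number_per_genome(
    assignments: pd.Series,
    gene_coverage: pd.DataFrame,
    catalog: MarkerCatalog = DEFAULT_MARKER_CATALOG,
    mean_kind: str = "arithmetic",
) -> pd.DataFrame:
    """Marker copy number per cellular genome, per sample x marker family.

    Each family's summed coverage is divided by the average coverage of
    the ten universal single-copy bacterial marker families (arithmetic
    mean by default; ``mean_kind='geometric'`` available). A marker family
    with no detected genes reports 0. Every single-copy family must have
    positive coverage in every sample; missing ones are listed in the
    error.
    """
    sc_cov = _family_coverage(assignments, gene_coverage, catalog.single_copy)
    bad = {}
    for sid in sc_cov.columns:
        missing = sc_cov.index[sc_cov[sid] <= 0].tolist()
        if missing:
            bad[sid] = missing
    if bad:
        worst = list(bad.items())[:3]
        raise DataError(f"single-copy families with no coverage (sample -> families): {worst}")
    if mean_kind == "arithmetic":
        denom = sc_cov.mean(axis=0)
    elif mean_kind == "geometric":
        denom = np.exp(np.log(sc_cov).mean(axis=0))
    else:
        raise DataError(f"unknown mean_kind {mean_kind!r}")
    marker_fams = catalog.prophage + catalog.phage
    fam_cov = _family_coverage(assignments, gene_coverage, marker_fams)
    out = fam_cov.div(denom, axis=1).T
    out.index.name = "sample_id"
    return out


def flag_prophage_contigs(
    genes: pd.DataFrame,
    domain_hits: pd.DataFrame,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.Series:
    """Per-contig prophage flag: any gene scoring > 30 bits against
    integrase, CI repressor, Cro, or excisionase.

    Returns a boolean Series over every contig present in ``genes``.
    """
    fams = domain_hits["family"].map(normalize_family)
    qualifying = domain_hits[
        fams.isin(PROPHAGE_FLAG_FAMILIES) & (domain_hits["bit_score"] > thresholds.prophage_flag_bit)
    ]
    gene_to_contig = genes.set_index("gene_id")["contig_id"]
    flagged = set(gene_to_contig.reindex(qualifying["gene_id"]).dropna())
    contigs = sorted(genes["contig_id"].unique())
    return pd.Series([c in flagged for c in contigs], index=contigs, name="prophage_flag")
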