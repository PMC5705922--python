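"""Candidate novel phage genes / auxiliary metabolic genes by colocalization.

A gene is a candidate when (a) it carries a functional domain hit with
bit score strictly > 30 whose label is neither in the shipped list of
functions already known from marine viromes nor itself a structural or
marker family, and (b) it sits on a contig that carries at least one
structural-family hit with bit score strictly > 10 — the colocalization
requirement that anchors the call to a phage genome. In-silico AMG calls
are prone to false positives, so candidates are reported with their
structural support, never as verified functions.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Iterable

import pandas as pd

from .design import validate_samples
from .exceptions import DataError
from .markers import (
    DEFAULT_CONTAMINANT_MARKERS,
    DEFAULT_MARKER_CATALOG,
    STRUCTURAL_FAMILIES,
    normalize_family,
)
from .thresholds import DEFAULT_THRESHOLDS, Thresholds

#: Families that can never count as a "novel function": virion structure,
#: life-history markers, and prokaryotic single-copy markers.
_NON_FUNCTIONAL = (
    set(STRUCTURAL_FAMILIES)
    | {normalize_family(f) for f in DEFAULT_MARKER_CATALOG.families}
    | {normalize_family(f) for f in DEFAULT_MARKER_CATALOG.flag_only}
    | {normalize_family(f) for f in DEFAULT_CONTAMINANT_MARKERS.families}
)


def load_known_functions() -> frozenset[str]:
    """The shipped, editable list of function labels already reported in
    marine viromes (normalized)."""
    text = resources.files("phagedepth").joinpath("data/known_amg_functions.txt").read_text()
    labels = {normalize_family(line) for line in text.splitlines() if line.strip() and not line.startswith("#")}
    return frozenset(labels)


def find_candidates(
    genes: pd.DataFrame,
    domain_hits: pd.DataFrame,
    known_functions: Iterable[str] | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """All genes satisfying the novel-function + colocalization criterion.

    Returns one row per candidate gene with its best novel-function hit,
    the best structural-family hit on the same contig, and both scores.
    An empty known-function list means every functional label counts as
    novel (warned).
    """
    if known_functions is None:
        known = load_known_functions()
    else:
        known = {normalize_family(f) for f in known_functions}
        if not known:
            warnings.warn("empty known-function list: all functional labels treated as novel")

    hits = domain_hits.copy()
    hits["family_norm"] = hits["family"].map(normalize_family)
    gene_to_contig = genes.set_index("gene_id")["contig_id"]

    structural = hits[
        hits["family_norm"].isin(STRUCTURAL_FAMILIES)
        & (hits["bit_score"] > thresholds.structural_bit)
    ].copy()
    structural["contig_id"] = gene_to_contig.reindex(structural["gene_id"]).values
    best_structural = (
        structural.sort_values(["contig_id", "bit_score"], ascending=[True, False], kind="stable")
        .groupby("contig_id", sort=True)
        .first()
    )

    functional = hits[
        (hits["bit_score"] > thresholds.amg_bit)
        & ~hits["family_norm"].isin(_NON_FUNCTIONAL)
        & ~hits["family_norm"].isin(known)
    ].copy()
    functional["contig_id"] = gene_to_contig.reindex(functional["gene_id"]).values
    if functional["contig_id"].isna().any():
        raise DataError("functional hit references a gene absent from the gene table")
    functional = functional[functional["contig_id"].isin(best_structural.index)]
    functional = (
        functional.sort_values(["gene_id", "bit_score"], ascending=[True, False], kind="stable")
        .groupby("gene_id", sort=True)
        .first()
        .reset_index()
    )
    out = pd.DataFrame(
        {
            "gene_id": functional["gene_id"],
            "contig_id": functional["contig_id"],
            "function_label": functional["family"],
            "pfam_bit": functional["bit_score"],
            "structural_family": best_structural.loc[functional["contig_id"], "family"].values,
            "structural_bit": best_structural.loc[functional["contig_id"], "bit_score"].values,
        }
    )
    return out.sort_values("gene_id", kind="stable").reset_index(drop=True)


def depth_specificity(
    candidates: pd.DataFrame,
    rel_abundance: pd.DataFrame,
    samples: pd.DataFrame,
    presence_floor: float = 0.001,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Depth labels and a specificity flag for each candidate's host contig.

    A depth qualifies when the host contig's relative abundance exceeds
    ``presence_floor`` in at least ``min_samples`` samples at that depth.
    The candidate is depth-specific when exactly one depth qualifies, or
    exactly two *adjacent* depths do (matching "25 and 75 m"-style
    reporting). A host contig absent everywhere is an error.
    """
    samples = validate_samples(samples)
    meta = samples.set_index("sample_id")
    depths_present = sorted(meta["depth_m"].unique())
    rows = []
    for _, cand in candidates.iterrows():
        cid = cand["contig_id"]
        if cid not in rel_abundance.index:
            raise DataError(f"candidate host contig {cid!r} has no abundance profile")
        ab = rel_abundance.loc[cid]
        labels = []
        for d in depths_present:
            cols = [s for s in ab.index if meta.loc[s, "depth_m"] == d]
            if (ab[cols] > presence_floor).sum() >= min_samples:
                labels.append(int(d))
        if not labels:
            raise DataError(f"candidate host contig {cid!r} absent at every depth")
        if len(labels) == 1:
            specific = True
        elif len(labels) == 2:
            i, j = depths_present.index(labels[0]), depths_present.index(labels[1])
            specific = abs(i - j) == 1
        else:
            specific = False
        rows.append(
            {
                "gene_id": cand["gene_id"],
                "contig_id": cid,
                "depth_labels": ",".join(str(d) for d in labels),
                "specific": specific,
            }
        )
    return pd.DataFrame(rows)


def validate_candidates(
    candidates: pd.DataFrame,
    genes: pd.DataFrame,
    domain_hits: pd.DataFrame,
    known_functions: Iterable[str] | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Independent re-check that every reported candidate satisfies both
    predicates exactly (and no qualifying gene was missed).

    Implemented as a plain double loop over genes and hits, separate from
    the vectorized path in :func:`find_candidates`.
    """
    known = load_known_functions() if known_functions is None else {
        normalize_family(f) for f in known_functions
    }
    structural_contigs = set()
    gene_to_contig = dict(zip(genes["gene_id"], genes["contig_id"]))
    for row in domain_hits.itertuples(index=False):
        if normalize_family(row.family) in STRUCTURAL_FAMILIES and row.bit_score > thresholds.structural_bit:
            if row.gene_id in gene_to_contig:
                structural_contigs.add(gene_to_contig[row.gene_id])
    expected = set()
    for row in domain_hits.itertuples(index=False):
        fam = normalize_family(row.family)
        if (
            row.bit_score > thresholds.amg_bit
            and fam not in _NON_FUNCTIONAL
            and fam not in known
            and gene_to_contig.get(row.gene_id) in structural_contigs
        ):
            expected.add(row.gene_id)
    return sorted(candidates["gene_id"]) == sorted(expected)
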