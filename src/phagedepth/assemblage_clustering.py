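"""Gene-catalog partition and sample clustering by phage vs cellular genes.

The nonredundant gene catalog is split into a phage-specific set (genes
with a viral best hit strictly above 90% amino-acid identity, minus
photosystem genes, whose phage and host copies cannot be told apart) and
a cellular set (everything else). For each set, samples are clustered by
Bray-Curtis distance on relative gene abundances with average-linkage
(UPGMA) agglomeration, and the two dendrograms are compared numerically
(cophenetic correlation and a 7-group co-clustering agreement) — a
quantitative stand-in for the visual tanglegram comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .exceptions import DataError
from .thresholds import DEFAULT_THRESHOLDS, Thresholds


def partition_gene_catalog(
    catalog: pd.DataFrame, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> tuple[pd.Index, pd.Index]:
    """Split the catalog into (phage_genes, cell_genes) — a disjoint cover.

    Phage set: viral best-hit AAI strictly > ``aai_viral_gene`` AND NOT a
    photosystem gene (photosystem bit strictly > ``photosystem_bit``).
    Both comparisons are strict, so a gene at exactly 90% AAI is cellular
    and a viral gene at photosystem bit exactly 30 stays phage.
    """
    missing = {"gene_id", "viral_best_aai", "photosystem_bit"} - set(catalog.columns)
    if missing:
        raise DataError(f"gene catalog missing columns: {sorted(missing)}")
    aai = catalog["viral_best_aai"].fillna(-np.inf)
    psb = catalog["photosystem_bit"].fillna(-np.inf)
    is_phage = (aai > thresholds.aai_viral_gene) & ~(psb > thresholds.photosystem_bit)
    phage = pd.Index(catalog.loc[is_phage, "gene_id"])
    cell = pd.Index(catalog.loc[~is_phage, "gene_id"])
    return phage, cell


def catalog_relative_abundance(gene_coverage: pd.DataFrame) -> pd.DataFrame:
    """Normalize a genes x samples coverage matrix so each sample sums to 1.

    The denominator is the total coverage of *all* genes in the sample,
    so library size cancels before any gene subset is taken.
    """
    totals = gene_coverage.sum(axis=0)
    zero = totals[totals <= 0].index.tolist()
    if zero:
        raise DataError(f"sample(s) with zero total gene coverage: {zero[:5]}")
    return gene_coverage.div(totals, axis=1)


def bray_curtis_matrix(abundance: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Bray-Curtis distance between samples (columns of ``abundance``).

    d(i, j) = sum_g |x_gi - x_gj| / sum_g (x_gi + x_gj), in [0, 1].
    A sample pair whose combined abundance is all zero has no defined
    distance and raises.
    """
    X = abundance.T.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise DataError("Bray-Curtis needs >= 2 samples")
    if (X < 0).any():
        raise DataError("abundances must be nonnegative")
    sums = X.sum(axis=1)
    if (sums[:, None] + sums[None, :] == 0).any() and (sums == 0).sum() >= 2:
        raise DataError("a sample pair has all-zero combined abundance")
    condensed = pdist(X, metric="braycurtis")
    if not np.isfinite(condensed).all():
        raise DataError("non-finite Bray-Curtis distance (all-zero sample pair?)")
    mat = pd.DataFrame(squareform(condensed), index=abundance.columns, columns=abundance.columns)
    return mat


@dataclass
class Dendrogram:
    """A sample merge tree: a SciPy linkage matrix plus its leaf labels."""

    linkage: np.ndarray
    labels: list[str]

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, n_groups: int) -> pd.Series:
        """Flat cluster labels at an n-group cut."""
        flat = fcluster(self.linkage, t=n_groups, criterion="maxclust")
        return pd.Series(flat, index=self.labels)

    def cophenetic_matrix(self) -> pd.DataFrame:
        cd = cophenet(self.linkage)
        return pd.DataFrame(squareform(cd), index=self.labels, columns=self.labels)

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.labels)
        return str(tree)


def average_linkage(distance: pd.DataFrame) -> Dendrogram:
    """UPGMA merge tree over the samples of a distance matrix.

    At each step the pair of clusters with minimal mean inter-cluster
    distance merges; SciPy's deterministic implementation carries the
    computation, so identical inputs always give identical trees.
    """
    D = distance.to_numpy(dtype=float)
    if not np.isfinite(D).all():
        raise DataError("distance matrix contains non-finite values")
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise DataError("distance matrix must be square and symmetric")
    condensed = squareform(D, checks=False)
    Z = linkage(condensed, method="average")
    return Dendrogram(Z, [str(c) for c in distance.columns])


def compare_dendrograms(
    tree_a: Dendrogram, tree_b: Dendrogram, n_groups: int = 7
) -> dict[str, float]:
    """Numeric similarity of two dendrograms over the same samples.

    ``cophenetic_correlation``: Pearson correlation of the two cophenetic
    distance vectors (pairs aligned by sorted label order).
    ``pair_agreement``: fraction of sample pairs co-clustered identically
    when both trees are cut into ``n_groups`` flat groups.
    """
    if set(tree_a.labels) != set(tree_b.labels):
        raise DataError("dendrograms have different leaf sets")
    order = sorted(tree_a.labels)
    ca = tree_a.cophenetic_matrix().loc[order, order].to_numpy()
    cb = tree_b.cophenetic_matrix().loc[order, order].to_numpy()
    iu = np.triu_indices(len(order), k=1)
    r = float(np.corrcoef(ca[iu], cb[iu])[0, 1])

    cut_a = tree_a.cut(n_groups).loc[order].to_numpy()
    cut_b = tree_b.cut(n_groups).loc[order].to_numpy()
    same_a = cut_a[iu[0]] == cut_a[iu[1]]
    same_b = cut_b[iu[0]] == cut_b[iu[1]]
    agreement = float((same_a == same_b).mean())
    return {"cophenetic_correlation": r, "pair_agreement": agreement}


def taxon_group_abundance(
    catalog: pd.DataFrame,
    rel_abundance: pd.DataFrame,
    label_col: str = "taxon_label",
) -> pd.DataFrame:
    """Summed relative abundance of labelled gene groups per sample.

    Generic support for taxon-panel summaries (e.g. known-phage or
    known-bacteria groups at a chosen identity cutoff): which labels go
    into a panel is configuration, not code.
    """
    if label_col not in catalog.columns:
        raise DataError(f"catalog has no column {label_col!r}")
    labelled = catalog.dropna(subset=[label_col]).set_index("gene_id")[label_col]
    sub = rel_abundance.loc[rel_abundance.index.intersection(labelled.index)]
    return sub.groupby(labelled.reindex(sub.index).values).sum()
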