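"""Score and fraction cutoffs used throughout the pipeline.

Every printed cutoff lives here so that a bare run applies the standard
procedure and any deviation is a single, visible configuration change.

Conventions
-----------
All bit-score, identity, and fraction comparisons are *strict* (``>``).
The single exception is the contig length filter, which is inclusive
(``>= min_contig_len``). Boundary tests in the suite pin both behaviours.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .exceptions import ConfigError


@dataclass(frozen=True)
class Thresholds:
    """Cutoffs applied by the curation, classification, and marker stages.

    Attributes
    ----------
    min_contig_len : int
        Minimum contig length in bp retained by the size filter (inclusive).
    structural_bit : float
        Domain bit score a structural-family hit must exceed for a contig
        to count as carrying a phage structural gene.
    amg_bit : float
        Domain bit score a functional hit must exceed to nominate a
        candidate novel gene / auxiliary metabolic gene.
    marker_bit : float
        Domain bit score for marker-gene detection in the gene catalog
        (life-history markers and single-copy prokaryotic markers).
    prophage_flag_bit : float
        Domain bit score for the per-contig prophage flag (integrase,
        CI repressor, Cro, excisionase). Deliberately distinct from
        ``marker_bit``: the catalog profile and the per-contig flag use
        different rules and are never conflated.
    photosystem_bit : float
        Domain bit score above which a viral gene is treated as a
        photosystem gene and excluded from the phage-specific gene set.
    aai_classify : float
        Percent amino-acid identity a contig's majority gene set must
        exceed (on average) against a reference genome to classify.
    aai_viral_gene : float
        Percent amino-acid identity above which a catalog gene counts as
        viral when partitioning the gene catalog.
    gene_fraction : float
        Fraction of a contig's genes that must best-hit one reference
        genome for classification (strictly greater than).
    top_k : int
        Number of most-abundant contigs ranked per depth bin.
    """

    min_contig_len: int = 20_000
    structural_bit: float = 10.0
    amg_bit: float = 30.0
    marker_bit: float = 50.0
    prophage_flag_bit: float = 30.0
    photosystem_bit: float = 30.0
    aai_classify: float = 60.0
    aai_viral_gene: float = 90.0
    gene_fraction: float = 0.5
    top_k: int = 13

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not value > 0:
                raise ConfigError(f"threshold {f.name!r} must be positive, got {value!r}")
        if not 0 < self.gene_fraction < 1:
            raise ConfigError(f"gene_fraction must lie in (0, 1), got {self.gene_fraction}")


DEFAULT_THRESHOLDS = Thresholds()
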