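"""Gene-family vocabularies: structural, life-history, and contamination markers.

Family names arriving in domain-hit tables are free text; they are
normalized case-insensitively through a fixed synonym table before any
rule is applied, so "Major Capsid Protein" and "capsid" behave the same.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ConfigError

#: The eight phage structural-protein families whose presence (at a domain
#: bit score above the structural cutoff) qualifies a contig as carrying a
#: recognizable virion gene.
STRUCTURAL_FAMILIES = frozenset(
    {"terminase", "portal", "capsid", "tail", "base_plate", "spike", "neck", "head"}
)

_SYNONYMS = {
    "baseplate": "base_plate",
    "base_plate_protein": "base_plate",
    "major_capsid_protein": "capsid",
    "capsid_protein": "capsid",
    "major_head_protein": "head",
    "head_protein": "head",
    "tail_fiber": "tail",
    "tail_fibre": "tail",
    "tail_protein": "tail",
    "portal_protein": "portal",
    "neck_protein": "neck",
    "spike_protein": "spike",
    "terminase_large_subunit": "terminase",
    "ci": "ci_repressor",
    "repressor_protein_ci": "ci_repressor",
    "cro_repressor": "cro",
    "dna_polymerase_a": "dna_polymerase",
    "reca": "recA",
    "dna_helicase": "dna_helicase",
}


def normalize_family(name: str) -> str:
    """Map a free-text family label onto its canonical name.

    Lowercases, collapses spaces/dashes to underscores, and applies the
    synonym table. Unknown labels pass through unchanged (lower-cased),
    so the vocabularies above stay open-ended.
    """
    key = str(name).strip().lower().replace("-", "_").replace(" ", "_")
    return _SYNONYMS.get(key, key)


def is_structural(name: str) -> bool:
    """True if the (normalized) family is one of the eight structural families."""
    return normalize_family(name) in STRUCTURAL_FAMILIES


# ---------------------------------------------------------------------------
# Life-history marker catalog
# ---------------------------------------------------------------------------

#: The ten universal single-copy bacterial marker gene families used for
#: per-genome normalization (the mOTU set of universal COGs).
UNIVERSAL_SINGLE_COPY = (
    "COG0012",
    "COG0016",
    "COG0018",
    "COG0172",
    "COG0215",
    "COG0495",
    "COG0525",
    "COG0533",
    "COG0541",
    "COG0552",
)


@dataclass(frozen=True)
class MarkerCatalog:
    """Marker families used for the lysogeny and copy-number profiles.

    ``prophage`` families (integrase, CI repressor, excisionase — the
    lambda-style lysogeny module) are summed in the numerator of the
    lysogeny index; ``capsid`` (always a member of ``phage``) normalizes
    it. ``flag_only`` families (Cro) participate only in the per-contig
    prophage flag, never in the catalog profile.
    """

    prophage: tuple[str, ...] = ("integrase", "ci_repressor", "excisionase")
    phage: tuple[str, ...] = ("dna_polymerase", "terminase", "capsid", "tail_fiber")
    flag_only: tuple[str, ...] = ("cro",)
    single_copy: tuple[str, ...] = UNIVERSAL_SINGLE_COPY
    detection_bit: float = 50.0

    def __post_init__(self) -> None:
        groups = [set(self.prophage), set(self.phage), set(self.flag_only), set(self.single_copy)]
        union = set().union(*groups)
        if sum(len(g) for g in groups) != len(union):
            raise ConfigError("marker catalog family groups must be disjoint")
        if "capsid" not in self.phage:
            raise ConfigError("'capsid' must be in the phage marker set (it is the normalizer)")

    @property
    def families(self) -> tuple[str, ...]:
        return self.prophage + self.phage + self.single_copy


DEFAULT_MARKER_CATALOG = MarkerCatalog()

#: Families whose presence on a contig (bit > prophage_flag_bit) flags it
#: as carrying a prophage marker.
PROPHAGE_FLAG_FAMILIES = frozenset({"integrase", "ci_repressor", "cro", "excisionase"})


# ---------------------------------------------------------------------------
# Single-copy prokaryotic markers for the contamination screen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContaminantMarkerSet:
    """Named single-copy prokaryotic marker families for the cellular screen.

    ``ribosomal`` families are decisive: a contig carrying one above the
    marker bit cutoff is removed as cellular. ``phage_ambiguous`` families
    (recA, DNA helicase) are recombination/replication genes that phages
    also encode; hits are tallied but never trigger removal.
    """

    families: tuple[str, ...]
    ribosomal: frozenset[str]
    phage_ambiguous: frozenset[str]

    def __post_init__(self) -> None:
        if not self.families:
            raise ConfigError("contaminant marker set must not be empty")
        missing = (set(self.ribosomal) | set(self.phage_ambiguous)) - set(self.families)
        if missing:
            raise ConfigError(f"marker subsets reference unknown families: {sorted(missing)}")


_RIBOSOMAL = tuple(
    f"ribosomal_protein_{x}"
    for x in ("L2", "L3", "L4", "L5", "L6", "S3", "S7", "S8", "S11", "S19")
)
_OTHER_SINGLE_COPY = (
    "recA",
    "dna_helicase",
    "gyrA",
    "gyrB",
    "rpoB",
    "rpoC",
    "secY",
    "ffh",
    "infB",
    "tsf",
    "pheS",
    "ileS",
    "valS",
    "alaS",
    "leuS",
)

DEFAULT_CONTAMINANT_MARKERS = ContaminantMarkerSet(
    families=_RIBOSOMAL + _OTHER_SINGLE_COPY,
    ribosomal=frozenset(_RIBOSOMAL),
    phage_ambiguous=frozenset({"recA", "dna_helicase"}),
)
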