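"""Readers and writers for the pipeline's on-disk formats.

All tables are single-header TSV, UTF-8, LF line endings. Coverage is
run-length encoded per-base depth (contig_id, sample_id, run_start,
run_length, depth). Contig sequences travel as FASTA with the VirSorter
category in the description line; gene calls as GFF3 (1-based inclusive
coordinates, strand in column 7).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coverage_stats import CoverageTable
from .exceptions import DataError
from .synthetic_data import FixtureSet

_FLOAT_FMT = "%.6g"


def _write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT, lineterminator="\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- FASTA ------------------------------------------------------------------


def write_contigs_fasta(path, contigs: pd.DataFrame, sequences: dict[str, str] | None) -> None:
    records = []
    for row in contigs.itertuples(index=False):
        seq = (sequences or {}).get(row.contig_id) or "N" * int(row.length)
        desc = f"length={int(row.length)} virsorter_category={int(row.virsorter_category)}"
        records.append(SeqRecord(Seq(seq), id=str(row.contig_id), description=desc))
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")


def read_contigs_fasta(path, with_sequences: bool = False):
    """Contig table (contig_id, length, virsorter_category) from FASTA.

    Length comes from the sequence itself; the VirSorter category is
    parsed from the description (absent -> NaN).
    """
    rows, seqs = [], {}
    for rec in SeqIO.parse(str(path), "fasta"):
        cat = np.nan
        for token in rec.description.split():
            if token.startswith("virsorter_category="):
                cat = int(token.split("=", 1)[1])
        rows.append({"contig_id": rec.id, "length": len(rec.seq), "virsorter_category": cat})
        if with_sequences:
            seqs[rec.id] = str(rec.seq)
    contigs = pd.DataFrame(rows)
    return (contigs, seqs) if with_sequences else contigs


# -- GFF3 -------------------------------------------------------------------


def write_genes_gff(path, genes: pd.DataFrame) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            attrs = f"ID={row.gene_id}"
            fh.write(
                f"{row.contig_id}\tphagedepth\tCDS\t{int(row.start) + 1}\t{int(row.end)}\t.\t{row.strand}\t0\t{attrs}\n"
            )


def read_genes_gff(path) -> pd.DataFrame:
    """Gene table with 0-based half-open internal coordinates."""
    cols = ["contig_id", "source", "type", "start1", "end1", "score", "strand", "frame", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    gene_ids = df["attributes"].str.extract(r"ID=([^;]+)")[0]
    if gene_ids.isna().any():
        raise DataError("GFF record without an ID attribute")
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "contig_id": df["contig_id"],
            "start": df["start1"].astype(int) - 1,
            "end": df["end1"].astype(int),
            "strand": df["strand"],
        }
    )


# -- coverage ----------------------------------------------------------------


def write_coverage(path, coverage: CoverageTable) -> None:
    _write_tsv(coverage.to_long(), path)


def read_coverage(path) -> CoverageTable:
    return CoverageTable.from_long(read_tsv(path))


# -- gene coverage (catalog) -------------------------------------------------


def write_gene_coverage(path, gene_coverage: pd.DataFrame) -> None:
    long = gene_coverage.stack().rename("coverage").reset_index()
    long.columns = ["gene_id", "sample_id", "coverage"]
    _write_tsv(long, path)


def read_gene_coverage(path) -> pd.DataFrame:
    long = read_tsv(path)
    wide = long.pivot(index="gene_id", columns="sample_id", values="coverage")
    wide.index.name = "gene_id"
    wide.columns.name = None
    return wide


# -- fixture sets ------------------------------------------------------------

FIXTURE_FILES = {
    "contigs": "contigs.fasta",
    "genes": "genes.gff",
    "ref_hits": "ref_hits.tsv",
    "domain_hits": "domain_hits.tsv",
    "coverage": "coverage.tsv",
    "samples": "samples.tsv",
    "catalog": "gene_catalog.tsv",
    "gene_coverage": "gene_coverage.tsv",
    "truth": "truth.json",
}


def write_fixture(fixture: FixtureSet, outdir) -> Path:
    """Write all fixture files (and the planted truth, separately) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_contigs_fasta(outdir / FIXTURE_FILES["contigs"], fixture.contigs, fixture.sequences)
    write_genes_gff(outdir / FIXTURE_FILES["genes"], fixture.genes)
    _write_tsv(fixture.ref_hits, outdir / FIXTURE_FILES["ref_hits"])
    _write_tsv(fixture.domain_hits, outdir / FIXTURE_FILES["domain_hits"])
    _write_tsv(fixture.samples, outdir / FIXTURE_FILES["samples"])
    if fixture.coverage is not None:
        write_coverage(outdir / FIXTURE_FILES["coverage"], fixture.coverage)
    if fixture.catalog is not None:
        _write_tsv(fixture.catalog, outdir / FIXTURE_FILES["catalog"])
    if fixture.gene_coverage is not None:
        write_gene_coverage(outdir / FIXTURE_FILES["gene_coverage"], fixture.gene_coverage)
    with open(outdir / FIXTURE_FILES["truth"], "w", newline="\n") as fh:
        json.dump(fixture.truth.to_dict(), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return outdir
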