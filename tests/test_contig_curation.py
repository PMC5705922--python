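"""Quality-control cascade: length filter, structural requirement, contamination."""

import numpy as np
import pandas as pd
import pytest

from phagedepth.contig_curation import (
    contamination_screen,
    filter_by_length,
    require_structural_gene,
    run_cascade,
)
from phagedepth.exceptions import ConfigError
from phagedepth.markers import DEFAULT_CONTAMINANT_MARKERS
from phagedepth.thresholds import Thresholds


def _contigs(lengths):
    return pd.DataFrame(
        {"contig_id": [f"c{i}" for i in range(len(lengths))], "length": lengths}
    )


def _tables(spec):
    """spec: {contig_id: [(family, bit), ...]} with one gene per hit."""
    genes, hits = [], []
    n = 0
    for cid, fam_bits in spec.items():
        for fam, bit in fam_bits:
            gid = f"{cid}_g{n}"
            n += 1
            genes.append({"gene_id": gid, "contig_id": cid, "start": 0, "end": 900, "strand": "+"})
            if fam is not None:
                hits.append({"gene_id": gid, "family": fam, "bit_score": bit})
    return pd.DataFrame(genes), pd.DataFrame(hits)


class TestLengthFilter:
    def test_boundary_is_inclusive(self):
        contigs = _contigs([19_999, 20_000, 108_000])
        retained, stage = filter_by_length(contigs)
        assert retained["length"].tolist() == [20_000, 108_000]
        assert stage.removed_ids == ["c0"]

    def test_all_short_yields_empty_with_count(self):
        retained, stage = filter_by_length(_contigs([5_000, 1_700]))
        assert retained.empty and stage.n_out == 0

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            retained, _ = filter_by_length(_contigs([]))
        assert retained.empty


class TestStructuralRequirement:
    def test_capsid_above_cutoff_keeps(self):
        genes, hits = _tables({"c0": [("capsid", 10.5)]})
        assert require_structural_gene("c0", genes, hits)

    def test_exactly_ten_is_discarded(self):
        genes, hits = _tables({"c0": [("capsid", 10.0)]})
        assert not require_structural_gene("c0", genes, hits)

    def test_synonyms_and_case_are_normalized(self):
        genes, hits = _tables({"c0": [("Major Capsid Protein", 25.0)]})
        assert require_structural_gene("c0", genes, hits)

    def test_non_structural_hit_does_not_count(self):
        genes, hits = _tables({"c0": [("integrase", 200.0)]})
        assert not require_structural_gene("c0", genes, hits)

    def test_unknown_structural_family_request_rejected(self):
        genes, hits = _tables({"c0": [("capsid", 50.0)]})
        from phagedepth.contig_curation import structural_contig_ids

        with pytest.raises(ConfigError):
            structural_contig_ids(genes, hits, structural_families=frozenset({"flagellin"}))


class TestContaminationScreen:
    def test_no_marker_hits_removes_nothing(self):
        genes, hits = _tables({"c0": [("capsid", 60.0)]})
        contigs = _contigs([30_000])
        retained, stage, tally = contamination_screen(contigs, genes, hits)
        assert stage.n_out == 1
        assert tally["completeness_proxy"] == 0.0

    def test_ribosomal_hit_removes_that_contig_only(self):
        genes, hits = _tables(
            {"c0": [("ribosomal_protein_L2", 60.0)], "c1": [("capsid", 60.0)]}
        )
        contigs = _contigs([30_000, 30_000])
        retained, stage, _ = contamination_screen(contigs, genes, hits)
        assert retained["contig_id"].tolist() == ["c1"]

    def test_ambiguous_reca_hits_tallied_not_removed(self):
        genes, hits = _tables({"c0": [("recA", 70.0), ("dna_helicase", 70.0)]})
        contigs = _contigs([30_000])
        retained, _, tally = contamination_screen(contigs, genes, hits)
        assert len(retained) == 1
        assert tally["n_marker_hit_genes"] == 2
        assert tally["n_ambiguous_marker_genes"] == 2

    def test_completeness_proxy_counts_distinct_nonambiguous_families(self):
        genes, hits = _tables({"c0": [("gyrA", 60.0), ("gyrA", 80.0), ("recA", 60.0)]})
        contigs = _contigs([30_000])
        _, _, tally = contamination_screen(contigs, genes, hits)
        assert tally["completeness_proxy"] == pytest.approx(
            1 / len(DEFAULT_CONTAMINANT_MARKERS.families)
        )


def _cascade_oracle(contigs, genes, hits, thresholds):
    """Evaluate the three predicates independently per contig."""
    from phagedepth.markers import STRUCTURAL_FAMILIES, normalize_family

    keep = []
    ribo = {normalize_family(f) for f in DEFAULT_CONTAMINANT_MARKERS.ribosomal}
    for row in contigs.itertuples(index=False):
        if row.length < thresholds.min_contig_len:
            continue
        gids = set(genes.loc[genes["contig_id"] == row.contig_id, "gene_id"])
        sub = hits[hits["gene_id"].isin(gids)]
        fams = sub["family"].map(normalize_family)
        has_structural = bool(
            ((fams.isin(STRUCTURAL_FAMILIES)) & (sub["bit_score"] > thresholds.structural_bit)).any()
        )
        is_contaminated = bool(
            ((fams.isin(ribo)) & (sub["bit_score"] > thresholds.marker_bit)).any()
        )
        if has_structural and not is_contaminated:
            keep.append(row.contig_id)
    return keep


class TestCascade:
    def test_matches_brute_force_oracle_on_random_fixtures(self, rng):
        fams = ["capsid", "tail", "portal", "recA", "ribosomal_protein_S3", "integrase"]
        for _ in range(25):
            n = int(rng.integers(5, 50))
            contigs = _contigs(rng.integers(10_000, 40_000, size=n).tolist())
            genes, hits = [], []
            for cid in contigs["contig_id"]:
                for g in range(int(rng.integers(1, 4))):
                    gid = f"{cid}_g{g}"
                    genes.append({"gene_id": gid, "contig_id": cid, "start": 0, "end": 900, "strand": "+"})
                    if rng.random() < 0.8:
                        hits.append(
                            {
                                "gene_id": gid,
                                "family": fams[int(rng.integers(len(fams)))],
                                "bit_score": float(rng.uniform(0, 80)),
                            }
                        )
            genes, hits = pd.DataFrame(genes), pd.DataFrame(hits)
            retained, _ = run_cascade(contigs, genes, hits)
            assert retained["contig_id"].tolist() == _cascade_oracle(
                contigs, genes, hits, Thresholds()
            )

    def test_order_insensitive(self, small_fixture):
        fix = small_fixture
        retained, _ = run_cascade(fix.contigs, fix.genes, fix.domain_hits)
        shuffled = fix.contigs.sample(frac=1.0, random_state=0)
        retained2, _ = run_cascade(shuffled, fix.genes, fix.domain_hits)
        assert set(retained["contig_id"]) == set(retained2["contig_id"])

    def test_stage_counts_are_monotone_and_consistent(self, default_fixture):
        fix = default_fixture
        _, report = run_cascade(fix.contigs, fix.genes, fix.domain_hits)
        n_outs = [s.n_out for s in report.stages]
        n_ins = [s.n_in for s in report.stages]
        assert all(o <= i for o, i in zip(n_outs, n_ins))
        assert n_ins[1:] == n_outs[:-1]
        for s in report.stages:
            assert s.n_in - s.n_out == len(s.removed_ids)

    def test_permissive_thresholds_are_identity(self):
        genes, hits = _tables({"c0": [("capsid", 5.0)], "c1": [("tail", 2.0)]})
        contigs = _contigs([1_700, 30_000])
        permissive = Thresholds(min_contig_len=1, structural_bit=1e-9)
        retained, _ = run_cascade(contigs, genes, hits, thresholds=permissive)
        assert retained["contig_id"].tolist() == ["c0", "c1"]

    def test_paper_counts_on_default_fixture(self, default_fixture):
        """142 length-passing contigs, 13 lacking structural hits -> 129."""
        fix = default_fixture
        retained, report = run_cascade(fix.contigs, fix.genes, fix.domain_hits)
        assert report.stages[0].n_out == 142
        assert report.stages[1].n_out == 129
        assert len(retained) == 129

    def test_virsorter_category_validated(self):
        contigs = _contigs([30_000])
        contigs["virsorter_category"] = [9]
        from phagedepth.exceptions import DataError

        with pytest.raises(DataError):
            filter_by_length(contigs)
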