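"""Marker detection, lysogeny index, fold-vs-surface, copy numbers, prophage flags."""

import numpy as np
import pandas as pd
import pytest

from phagedepth.exceptions import DataError
from phagedepth.life_history import (
    copy_number_per_genome,
    detect_markers,
    flag_prophage_contigs,
    fold_vs_surface,
    lysogeny_index,
)
from phagedepth.markers import DEFAULT_MARKER_CATALOG
from phagedepth.synthetic_data import SimConfig, generate_fixture


def _hits(rows):
    return pd.DataFrame(rows, columns=["gene_id", "family", "bit_score"])


def _catalog_fixture(seed=0, **kw):
    base = dict(
        n_contigs=4,
        n_short_contigs=0,
        n_no_structural=0,
        contaminant_count=0,
        n_amg_genes=2,
        with_coverage=False,
        with_sequences=False,
    )
    base.update(kw)
    return generate_fixture(SimConfig(seed=seed, **base))


class TestDetectMarkers:
    def test_exactly_fifty_not_assigned(self):
        out = detect_markers(_hits([("g1", "integrase", 50.0)]))
        assert "g1" not in out.index

    def test_highest_scoring_family_wins(self):
        out = detect_markers(_hits([("g1", "integrase", 80), ("g1", "excisionase", 60)]))
        assert out["g1"] == "integrase"

    def test_tie_breaks_lexicographically(self):
        out = detect_markers(_hits([("g1", "integrase", 80), ("g1", "excisionase", 80)]))
        assert out["g1"] == "excisionase"

    def test_planted_capsids_all_detected(self):
        fix = _catalog_fixture()
        catalog_hits = fix.domain_hits[
            fix.domain_hits["gene_id"].isin(fix.catalog["gene_id"])
        ]
        out = detect_markers(catalog_hits)
        planted = set(fix.truth.catalog["marker_genes"]["capsid"])
        assert set(out[out == "capsid"].index) == planted


def _cov(frame):
    return pd.DataFrame(frame)


class TestLysogenyIndex:
    def _assignments(self):
        return pd.Series(
            {"p1": "integrase", "p2": "excisionase", "k1": "capsid", "k2": "capsid"}
        )

    def test_equal_sums_give_one(self):
        cov = _cov({"s1": {"p1": 5.0, "p2": 5.0, "k1": 4.0, "k2": 6.0}})
        out = lysogeny_index(self._assignments(), cov)
        assert out.loc["s1", "index"] == pytest.approx(1.0)

    def test_no_prophage_markers_gives_zero(self):
        asg = pd.Series({"k1": "capsid"})
        cov = _cov({"s1": {"k1": 4.0}})
        assert lysogeny_index(asg, cov).loc["s1", "index"] == 0.0

    def test_uniform_rescaling_invariance(self):
        cov = _cov({"s1": {"p1": 5.0, "p2": 3.0, "k1": 4.0, "k2": 6.0}})
        a = lysogeny_index(self._assignments(), cov).loc["s1", "index"]
        b = lysogeny_index(self._assignments(), 2.0 * cov).loc["s1", "index"]
        assert a == pytest.approx(b)

    def test_zero_capsid_is_nan_with_warning(self):
        asg = pd.Series({"p1": "integrase", "k1": "capsid"})
        cov = _cov({"s1": {"p1": 5.0, "k1": 0.0}})
        with pytest.warns(UserWarning):
            out = lysogeny_index(asg, cov)
        assert np.isnan(out.loc["s1", "index"])


class TestFoldVsSurface:
    def test_identical_indices_fold_one_everywhere(self, default_fixture):
        samples = default_fixture.samples
        idx = pd.DataFrame({"index": 0.4}, index=samples["sample_id"])
        folds = fold_vs_surface(idx, samples)
        np.testing.assert_allclose(folds["fold_vs_surface"], 1.0)

    def test_surface_bin_fold_is_one_by_construction(self):
        fix = _catalog_fixture(seed=3)
        asg = detect_markers(fix.domain_hits)
        idx = lysogeny_index(asg, fix.gene_coverage)
        folds = fold_vs_surface(idx, fix.samples)
        surface = folds.loc[[25, 75], "mean_index"].mean()
        np.testing.assert_allclose(
            folds.loc[[25, 75], "fold_vs_surface"], folds.loc[[25, 75], "mean_index"] / surface
        )

    def test_planted_fold_five_recovered(self):
        """Mesopelagic:surface fold of 5 recovered within +-15% (20-seed median)."""
        ests = []
        for seed in range(20):
            fix = _catalog_fixture(seed=seed, lysogeny_fold=5.0)
            asg = detect_markers(fix.domain_hits)
            idx = lysogeny_index(asg, fix.gene_coverage)
            folds = fold_vs_surface(idx, fix.samples)
            ests.append(folds.loc[[500, 770, 1000], "fold_vs_surface"].mean())
        assert np.median(ests) == pytest.approx(5.0, rel=0.15)

    def test_null_fold_within_band(self):
        """Planted fold 1 -> estimate within [0.85, 1.18] (20-seed median)."""
        ests = []
        for seed in range(20):
            fix = _catalog_fixture(seed=seed, lysogeny_fold=1.0)
            asg = detect_markers(fix.domain_hits)
            idx = lysogeny_index(asg, fix.gene_coverage)
            folds = fold_vs_surface(idx, fix.samples)
            ests.append(folds.loc[[500, 770, 1000], "fold_vs_surface"].mean())
        assert 0.85 <= np.median(ests) <= 1.18

    def test_fold_recovery_is_monotone_across_planted_folds(self):
        medians = []
        for fold in (1.0, 2.0, 5.0, 10.0):
            ests = []
            for seed in range(20):
                fix = _catalog_fixture(seed=seed, lysogeny_fold=fold)
                asg = detect_markers(fix.domain_hits)
                idx = lysogeny_index(asg, fix.gene_coverage)
                folds = fold_vs_surface(idx, fix.samples)
                ests.append(folds.loc[[500, 770, 1000], "fold_vs_surface"].mean())
            medians.append(np.median(ests))
        assert all(a < b for a, b in zip(medians, medians[1:]))

    def test_integrase_inflation_leaves_other_family_indices_planted(self):
        """Extra integrase-only signal inflates the integrase index while the
        excisionase/CI indices keep the planted fold."""
        plain = _catalog_fixture(seed=11, integrase_inflation=1.0)
        inflated = _catalog_fixture(seed=11, integrase_inflation=3.0)
        outs = {}
        for name, fix in (("plain", plain), ("inflated", inflated)):
            asg = detect_markers(fix.domain_hits)
            idx = lysogeny_index(asg, fix.gene_coverage)
            outs[name] = {
                fam: fold_vs_surface(idx, fix.samples, column=f"index_{fam}")
                .loc[[500, 770, 1000], "mean_index"]
                .mean()
                for fam in ("integrase", "excisionase", "ci_repressor")
            }
        assert outs["inflated"]["integrase"] > 2 * outs["plain"]["integrase"]
        for fam in ("excisionase", "ci_repressor"):
            assert outs["inflated"][fam] == pytest.approx(outs["plain"][fam], rel=0.15)

    def test_zero_surface_mean_rejected(self):
        samples = pd.DataFrame(
            {"sample_id": ["a", "b"], "depth_m": [25, 500], "date": ["2010-08-15"] * 2}
        )
        idx = pd.DataFrame({"index": [0.0, 1.0]}, index=["a", "b"])
        with pytest.raises(DataError):
            fold_vs_surface(idx, samples)


class TestCopyNumbers:
    def _single_copy_assignments(self):
        asg = {f"sc{i}": fam for i, fam in enumerate(DEFAULT_MARKER_CATALOG.single_copy)}
        asg["m1"] = "capsid"
        return pd.Series(asg)

    def test_marker_equal_to_single_copy_mean_is_one(self):
        asg = self._single_copy_assignments()
        cov = _cov({"s1": {g: 10.0 for g in asg.index}})
        out = copy_number_per_genome(asg, cov)
        assert out.loc["s1", "capsid"] == pytest.approx(1.0)

    def test_absent_marker_is_zero(self):
        asg = self._single_copy_assignments()
        cov = _cov({"s1": {g: 10.0 for g in asg.index}})
        out = copy_number_per_genome(asg, cov)
        assert out.loc["s1", "integrase"] == 0.0

    def test_missing_single_copy_family_listed_in_error(self):
        asg = self._single_copy_assignments().drop("sc0")
        cov = _cov({"s1": {g: 10.0 for g in asg.index}})
        with pytest.raises(DataError, match="COG0012"):
            copy_number_per_genome(asg, cov)

    def test_rescaling_invariance(self):
        fix = _catalog_fixture(seed=2)
        asg = detect_markers(fix.domain_hits)
        a = copy_number_per_genome(asg, fix.gene_coverage)
        b = copy_number_per_genome(asg, 3.0 * fix.gene_coverage)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_per_depth_copy_numbers_recovered(self):
        """Per-depth planted copy numbers recovered within +-10% (20-seed median)."""
        ests = {}
        truth = None
        for seed in range(20):
            fix = _catalog_fixture(seed=seed)
            asg = detect_markers(fix.domain_hits)
            cn = copy_number_per_genome(asg, fix.gene_coverage)
            meta = fix.samples.set_index("sample_id")
            per_depth = cn.groupby(meta.loc[cn.index, "depth_m"].values).mean()
            truth = fix.truth.copy_numbers
            for fam in ("capsid", "dna_polymerase", "terminase", "tail_fiber"):
                for depth, value in truth[fam].items():
                    ests.setdefault((fam, int(depth)), []).append(per_depth.loc[int(depth), fam])
        for (fam, depth), values in ests.items():
            planted = truth[fam][str(depth)]
            assert np.median(values) == pytest.approx(planted, rel=0.10), (fam, depth)


class TestProphageFlags:
    def _genes(self):
        return pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "contig_id": ["c1", "c2"],
                "start": [0, 0],
                "end": [900, 900],
                "strand": ["+", "+"],
            }
        )

    def test_cro_at_31_flags(self):
        flags = flag_prophage_contigs(self._genes(), _hits([("g1", "cro", 31.0)]))
        assert flags["c1"] and not flags["c2"]

    def test_exactly_thirty_does_not_flag(self):
        flags = flag_prophage_contigs(self._genes(), _hits([("g1", "integrase", 30.0)]))
        assert not flags["c1"]

    def test_lytic_marker_hits_do_not_flag(self):
        flags = flag_prophage_contigs(
            self._genes(), _hits([("g1", "capsid", 300.0), ("g1", "terminase", 200.0)])
        )
        assert not flags["c1"]

    def test_planted_flags_recovered_on_fixture(self, default_fixture):
        fix = default_fixture
        flags = flag_prophage_contigs(fix.genes, fix.domain_hits)
        assert sorted(flags[flags].index) == fix.truth.prophage_flagged_contigs
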