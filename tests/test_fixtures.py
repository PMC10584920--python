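"""Determinism and ground-truth consistency of the synthetic generators."""

import numpy as np
import pandas as pd
import pytest

from py1h import fixtures, motifs
from py1h.fixtures import PlateTruth, ScreenTruth


def small_truth(**kw):
    strains = [("a", "pair", 0.5), ("b", "empty", 0.1)]
    return fixtures.plate_truth_from_strains(strains, seed=kw.pop("seed", 1), **kw)


class TestGenPlate:
    def test_same_seed_identical_images(self):
        img1, t1 = fixtures.gen_plate(small_truth())
        img2, t2 = fixtures.gen_plate(small_truth())
        assert np.array_equal(img1, img2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_differs(self):
        img1, _ = fixtures.gen_plate(small_truth(seed=1))
        img2, _ = fixtures.gen_plate(small_truth(seed=2))
        assert not np.array_equal(img1, img2)

    def test_zero_amplitude_gives_background_only(self):
        strains = [("a", "pair", 0.0)]
        pt = fixtures.plate_truth_from_strains(strains, seed=0, noise_sd=0.0, bg_gradient=0.0)
        img, _ = fixtures.gen_plate(pt)
        assert (img == 0).all()

    def test_true_area_equals_half_coverage_mask(self):
        """Noise-free disk: truth area equals the >= half-coverage pixel count."""
        strains = [("a", "pair", 0.7)]
        pt = fixtures.plate_truth_from_strains(
            strains, radius=5.0, seed=0, noise_sd=0.0, bg_gradient=0.0, amplitude_jitter=0.0
        )
        img, table = fixtures.gen_plate(pt)
        per_colony_area = table[table.present].true_area
        # 4 quadruplicate colonies, all identical disks
        assert per_colony_area.nunique() == 1
        half_cov = (img >= 0.35 - 1e-12).sum()  # pixel value = amplitude * coverage
        assert half_cov == per_colony_area.sum()
        # plateau pixels hold exactly the amplitude
        assert img.max() == pytest.approx(0.7)

    def test_radius_overflow_raises(self):
        pt = small_truth()
        pt.radius[pt.present] = 15.0
        with pytest.raises(ValueError, match="layout_overflow"):
            fixtures.gen_plate(pt, spacing=20)

    def test_invalid_amplitude_rejected(self):
        pt = small_truth()
        with pytest.raises(ValueError):
            PlateTruth(
                layout=pt.layout,
                amplitude=pt.amplitude - 1.0,
                radius=pt.radius,
                present=pt.present,
            )

    def test_layout_covers_1536_positions_in_blocks(self):
        pt = small_truth()
        assert len(pt.layout) == 32 * 48
        # each strain occupies a full 2x2 block
        for strain in ("a", "b"):
            pos = pt.layout[pt.layout.strain == strain]
            assert len(pos) == 4
            assert pos.row.nunique() == 2 and pos.col.nunique() == 2


class TestGenScreen:
    def test_none_event_all_baseline(self):
        truth = ScreenTruth(baits=["b"], pairs=["p"], events={("b", "p"): "none"})
        plates_t, _ = fixtures.gen_screen(truth, seed=0)
        layout = plates_t["b"].layout
        amp = plates_t["b"].amplitude
        for cls in ("pair", "tf1_single", "tf2_single"):
            sel = layout[layout.strain_class == cls]
            vals = amp[sel.row, sel.col]
            assert np.allclose(vals, fixtures.AMP_BASELINE, rtol=0.25)

    def test_tf1_antagonized_amplitudes(self):
        """TF1-antagonized: TF1-single bright, the pair stays at baseline."""
        truth = ScreenTruth(baits=["b"], pairs=["p"], events={("b", "p"): "TF1-antagonized"})
        plates_t, _ = fixtures.gen_screen(truth, seed=0)
        layout = plates_t["b"].layout
        amp = plates_t["b"].amplitude
        tf1 = layout[layout.strain_class == "tf1_single"]
        pair = layout[layout.strain_class == "pair"]
        assert amp[tf1.row, tf1.col].min() > 0.5
        assert amp[pair.row, pair.col].max() < 0.2

    def test_expected_call_table_consistency(self):
        """100 planted events emit 100 expected rows matching the planted types."""
        from conftest import make_screen

        truth = make_screen(seed=3)
        _, expected = fixtures.gen_screen(truth, seed=4)
        assert len(expected) == 100
        for r in expected.itertuples():
            planted = truth.events[(r.bait, r.pair_id)]
            assert fixtures.EXPECTED_CALL[planted] == r.event

    def test_unknown_event_raises(self):
        truth = ScreenTruth(baits=["b"], pairs=["p"], events={("b", "p"): "bogus"})
        with pytest.raises(ValueError, match="unknown event"):
            fixtures.gen_screen(truth, seed=0)

    def test_missing_event_rejected(self):
        with pytest.raises(ValueError, match="missing planted event"):
            ScreenTruth(baits=["b"], pairs=["p", "q"], events={("b", "p"): "none"})

    def test_1ad_design_plants_modality_patterns(self):
        truth = ScreenTruth(
            baits=["b"], pairs=["p"],
            events={("b", "p"): "sequestration_of_TF1"}, design="1AD",
        )
        plates_t, expected = fixtures.gen_screen(truth, seed=0)
        layout = plates_t["b"].layout
        amp = plates_t["b"].amplitude

        def amp_of(cls):
            sel = layout[layout.strain_class == cls]
            return amp[sel.row, sel.col].mean()

        # (+,-,-,-): TF1-AD alone active, everything else baseline
        assert amp_of("tf1_single_o1") > 0.5
        assert amp_of("pair_o1") < 0.2
        assert amp_of("tf1_single_o2") < 0.2
        assert amp_of("pair_o2") < 0.2
        assert expected.event.iloc[0] == "sequestration_of_TF1"


class TestGenMotifSet:
    def test_planted_site_recorded_with_coordinates(self):
        proms, pwms, truth, _ = fixtures.gen_motif_set(
            2, {"p1": 500}, [(0, "p1", 100, "+")], seed=0
        )
        row = truth.iloc[0]
        k = pwms[0].k
        assert (row.start, row.end, row.strand) == (100, 100 + k, "+")
        assert proms["p1"][100 : 100 + k] == pwms[0].consensus

    def test_minus_strand_site_is_revcomp(self):
        proms, pwms, truth, _ = fixtures.gen_motif_set(
            1, {"p1": 500}, [(0, "p1", 50, "-")], seed=1
        )
        comp = str.maketrans("ACGT", "TGCA")
        k = pwms[0].k
        assert proms["p1"][50 : 50 + k] == pwms[0].consensus.translate(comp)[::-1]

    def test_no_planted_sites_empty_truth(self):
        _, _, truth, cobind = fixtures.gen_motif_set(2, {"p1": 300}, [], seed=0)
        assert truth.empty and cobind.empty

    def test_cobinding_distance_arithmetic(self):
        """Two sites 4 nt apart for two TFs are marked as a co-binding pair."""
        _, pwms, _, _ = fixtures.gen_motif_set(2, {"p1": 500}, [], seed=2)
        k0 = pwms[0].k
        # place the second site exactly 4 nt after the end of the first
        proms, pwms, truth, cobind = fixtures.gen_motif_set(
            2, {"p1": 500}, [(0, "p1", 100, "+"), (1, "p1", 100 + k0 + 4, "+")], seed=2
        )
        assert len(cobind) == 1
        assert cobind.gap.iloc[0] == 4

    def test_out_of_bounds_site_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            fixtures.gen_motif_set(1, {"p1": 100}, [(0, "p1", 95, "+")], seed=0)

    def test_generated_pwms_pass_specificity_filter(self):
        _, pwms, _, _ = fixtures.gen_motif_set(5, {"p1": 200}, [], seed=3)
        assert all(motifs.filter_low_specificity(p) for p in pwms)


class TestGenExpression:
    def test_uniform_gene_equal_totals(self):
        mat, labels = fixtures.gen_expression(6, 187, ["uniform"] * 6, seed=0)
        assert (mat.nunique(axis=1) == 1).all()

    def test_exclusive_gene_single_cluster(self):
        mat, labels = fixtures.gen_expression(5, 50, ["exclusive"] * 5, seed=1)
        assert ((mat > 0).sum(axis=1) == 1).all()

    def test_same_seed_reproducible(self):
        m1, _ = fixtures.gen_expression(10, 30, seed=7)
        m2, _ = fixtures.gen_expression(10, 30, seed=7)
        pd.testing.assert_frame_equal(m1, m2)

    def test_size_validation(self):
        with pytest.raises(ValueError):
            fixtures.gen_expression(0, 10)
        with pytest.raises(ValueError):
            fixtures.gen_expression(5, 1)


class TestGenNetwork:
    def test_null_fixture_evidence_independent(self):
        """enrichment=0: evidence rate on edges matches the off-edge rate."""
        edges, evidence, enriched = fixtures.gen_network(200, 18, 0.0, seed=0)
        assert not enriched
        edge_cells = set()
        for r in edges.itertuples():
            edge_cells.add((r.tf1, r.promoter))
            edge_cells.add((r.tf2, r.promoter))
        ev_cells = set(zip(evidence.tf, evidence.promoter))
        tfs = sorted(set(edges.tf1) | set(edges.tf2))
        proms = sorted(edges.promoter.unique())
        on = [c in ev_cells for c in edge_cells]
        off = [
            (t, p) in ev_cells
            for t in tfs
            for p in proms
            if (t, p) not in edge_cells
        ]
        assert abs(np.mean(on) - np.mean(off)) < 0.05

    def test_enriched_fixture_concentrates_evidence(self):
        edges, evidence, enriched = fixtures.gen_network(100, 15, 0.7, seed=1)
        assert enriched
        edge_cells = set()
        for r in edges.itertuples():
            edge_cells.add((r.tf1, r.promoter))
            edge_cells.add((r.tf2, r.promoter))
        ev_cells = set(zip(evidence.tf, evidence.promoter))
        on_rate = np.mean([c in ev_cells for c in edge_cells])
        assert on_rate > 0.6

    def test_edges_unique(self):
        edges, _, _ = fixtures.gen_network(50, 10, 0.3, seed=2)
        assert not edges.duplicated(["pair_id", "promoter"]).any()


class TestGenAlignments:
    def test_confirmed_well_majority_on_target(self):
        sam, truth = fixtures.gen_alignments({"w1": "G1"}, {"w1": True}, seed=0)
        assert truth.confirmed.iloc[0]
        body = [ln for ln in sam.splitlines() if not ln.startswith("@")]
        on = sum(1 for ln in body if ln.split("\t")[2] == "G1")
        assert on / len(body) > 0.8

    def test_same_seed_identical_sam(self):
        sam1, _ = fixtures.gen_alignments({"w1": "G1"}, {"w1": True}, seed=5)
        sam2, _ = fixtures.gen_alignments({"w1": "G1"}, {"w1": True}, seed=5)
        assert sam1 == sam2

    def test_header_covers_all_targets(self):
        sam, _ = fixtures.gen_alignments({"w1": ("G1", "AD2u_empty")}, {"w1": True}, seed=1)
        sq = {ln.split("\t")[1][3:] for ln in sam.splitlines() if ln.startswith("@SQ")}
        assert {"G1", "AD2u_empty"} <= sq
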