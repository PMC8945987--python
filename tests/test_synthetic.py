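"""Ground-truth generators: planted effects, motifs, and images."""

import numpy as np
import pytest

from cmaquant import motifs, silac, synthetic


def records_from_table(table, treatment="PA"):
    cm = silac.DEFAULT_COLUMN_MAP
    return [
        silac.QuantRecord(
            protein_id=row[cm["protein_id"]],
            gene_symbol=row[cm["gene_symbol"]],
            ratio=row[cm["ratio"]],
            p_value=row[cm["p_value"]],
            peptide_count=row[cm["peptide_count"]],
            confidence=row[cm["confidence"]],
            treatment=treatment,
        )
        for _, row in table.iterrows()
    ]


class TestQuantGenerator:
    def test_null_only_table_has_no_large_ratios(self):
        table, truths = synthetic.gen_quant_table(
            100, frac_up=0, frac_down=0, rep_sd=0.1, seed=1
        )
        assert all(t.planted_label == "null" for t in truths)
        log2r = np.log2(table[silac.DEFAULT_COLUMN_MAP["ratio"]])
        assert np.abs(log2r).max() < 0.5

    def test_noise_free_limit_is_exact(self):
        table, truths = synthetic.gen_quant_table(
            10, frac_up=0.5, frac_down=0.5, rep_sd=0.0, seed=4
        )
        ratios = table[silac.DEFAULT_COLUMN_MAP["ratio"]].to_numpy()
        pvals = table[silac.DEFAULT_COLUMN_MAP["p_value"]].to_numpy()
        for t, ratio, p in zip(truths, ratios, pvals):
            assert ratio == pytest.approx(2.0**t.true_log2_effect, abs=1e-9)
            if t.planted_label != "null":
                assert p < 1e-6

    def test_planted_labels_match_effect_invariants(self):
        _, truths = synthetic.gen_quant_table(300, 0.25, 0.25, seed=7)
        for t in truths:
            if t.planted_label == "up":
                assert t.true_log2_effect >= 1
            elif t.planted_label == "down":
                assert t.true_log2_effect <= -1
            else:
                assert t.true_log2_effect == 0

    def test_deterministic_under_fixed_seed(self):
        t1, u1 = synthetic.gen_quant_table(50, seed=9)
        t2, u2 = synthetic.gen_quant_table(50, seed=9)
        assert t1.equals(t2) and u1 == u2
        t3, _ = synthetic.gen_quant_table(50, seed=10)
        assert not t1.equals(t3)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            synthetic.gen_quant_table(10, frac_up=0.8, frac_down=0.5)
        with pytest.raises(ValueError):
            synthetic.gen_quant_table(10, n_replicates=1)

    def test_roundtrip_through_reader(self, tmp_path):
        table, _ = synthetic.gen_quant_table(30, seed=2)
        path = tmp_path / "quant.tsv"
        synthetic.write_quant_table(table, path)
        result = silac.read_quant_table(path, treatment="SA")
        assert len(result.records) == 30
        assert result.n_dropped == 0


class TestMotifGenerator:
    def test_none_class_yields_no_hits(self):
        truths = synthetic.gen_motif_proteins(5, classes=["none"], length=50, seed=0)
        for t in truths:
            assert t.planted_hits == ()
            assert motifs.scan_sequence(t.sequence) == []

    def test_canonical_insertion_is_found_exactly_once(self):
        truths = synthetic.gen_motif_proteins(
            5, classes=["canonical"], length=60, seed=1
        )
        for t in truths:
            hits = motifs.scan_sequence(t.sequence, t.protein_id)
            assert [(h.start, h.motif_class) for h in hits] == list(t.planted_hits)

    def test_confusion_matrix_is_diagonal(self):
        truths = synthetic.gen_motif_proteins(20, seed=3)
        for t in truths:
            observed = tuple(
                (h.start, h.motif_class) for h in motifs.scan_sequence(t.sequence)
            )
            assert observed == t.planted_hits

    def test_background_uses_safe_alphabet_only(self):
        truths = synthetic.gen_motif_proteins(3, classes=["none"], length=40, seed=5)
        for t in truths:
            assert set(t.sequence) <= set(synthetic.SAFE_ALPHABET)

    def test_explicit_protein_ids_assign_classes_round_robin(self):
        ids = [f"P{i}" for i in range(6)]
        truths = synthetic.gen_motif_proteins(
            0, classes=["canonical", "none"], length=30, seed=6, protein_ids=ids
        )
        assert [t.protein_id for t in truths] == ids
        assert [bool(t.planted_hits) for t in truths] == [True, False] * 3

    def test_too_short_sequence_raises(self):
        with pytest.raises(ValueError):
            synthetic.gen_motif_proteins(1, length=4)

    def test_unknown_class_raises(self):
        with pytest.raises(ValueError):
            synthetic.gen_motif_proteins(1, classes=["bogus"])

    def test_fasta_roundtrip(self, tmp_path):
        truths = synthetic.gen_motif_proteins(2, length=30, seed=8)
        path = tmp_path / "seqs.fasta"
        synthetic.write_fasta(truths, path)
        parsed = motifs.read_fasta(path)
        assert parsed == [(t.protein_id, t.sequence) for t in truths]


class TestImageGenerator:
    def test_empty_field(self):
        image, truth = synthetic.gen_cell_image(0, seed=0)
        assert image.data.shape == (2, 512, 512)
        assert truth.nuclei_centers == [] and truth.puncta == []

    def test_truth_bookkeeping(self):
        _, truth = synthetic.gen_cell_image(5, 8, snr=10, seed=2)
        assert len(truth.nuclei_centers) == 5
        assert [len(cell) for cell in truth.puncta] == [8] * 5

    def test_bit_identical_under_fixed_seed(self):
        a, _ = synthetic.gen_cell_image(5, 8, snr=10, seed=2)
        b, _ = synthetic.gen_cell_image(5, 8, snr=10, seed=2)
        assert np.array_equal(a.data, b.data)

    def test_masks_disjoint_and_puncta_inside(self):
        _, truth = synthetic.gen_cell_image(8, 6, snr=10, seed=3)
        total = np.zeros_like(truth.cell_masks[0], dtype=int)
        for mask in truth.cell_masks:
            total += mask
        assert total.max() == 1  # no pixel claimed by two cells
        for mask, spots in zip(truth.cell_masks, truth.puncta):
            for r, c in spots:
                assert mask[int(round(r)), int(round(c))]

    def test_puncta_respect_minimum_separation(self):
        _, truth = synthetic.gen_cell_image(4, 10, spot_sigma=1.5, snr=10, seed=4)
        for spots in truth.puncta:
            pts = np.asarray(spots)
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 4 * 1.5

    def test_per_cell_count_list(self):
        _, truth = synthetic.gen_cell_image(3, [0, 4, 9], snr=10, seed=5)
        assert [len(c) for c in truth.puncta] == [0, 4, 9]

    def test_intensities_clipped_to_unit_range(self):
        image, _ = synthetic.gen_cell_image(5, 8, snr=20, seed=6)
        assert image.data.min() >= 0.0 and image.data.max() <= 1.0

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            synthetic.gen_cell_image(1, snr=0.0)
        with pytest.raises(ValueError):
            synthetic.gen_cell_image(1, size=(40, 40))  # cells cannot fit

    def test_placement_failure_is_reported(self):
        with pytest.raises(RuntimeError, match="placed only"):
            synthetic.gen_cell_image(40, size=(200, 200), seed=0, max_tries=200)

    def test_tiff_roundtrip(self, tmp_path):
        import tifffile

        image, truth = synthetic.gen_cell_image(2, 3, seed=7)
        path = tmp_path / "img.tif"
        synthetic.write_image_tiff(image, path)
        assert np.array_equal(tifffile.imread(path), image.data)
        synthetic.write_image_truth(
            truth, tmp_path / "truth.json", tmp_path / "labels.tif"
        )
        labels = tifffile.imread(tmp_path / "labels.tif")
        assert set(np.unique(labels)) == {0, 1, 2}
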