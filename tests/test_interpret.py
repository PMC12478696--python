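"""Attention interpretability: region geometry, PWMs, rankings, interchange."""

import numpy as np
import pytest

import epiattend as ea
from epiattend.config import ModelConfig
from epiattend.interpret import (
    InterpretError, MotifHit, RegionPairScore, average_heads,
    best_hit_by_query, build_interaction_table, capture_attention,
    extract_region_pwm, pwm_correlation, read_biogrid, read_meme,
    read_tomtom, region_window, top_region_pairs, write_meme, RegionPWM,
)
from epiattend.nn import EPINetwork
from epiattend.records import SequencePairRecord
from epiattend.synthetic import sample_background, plant_motif


def brute_force_receptive_field(r, cfg):
    """Oracle: enumerate the conv windows under pool window r and union
    their base coverage."""
    L_enh = cfg.enh_pooled_len
    if r < L_enh:
        local, seq_len = r, cfg.enh_len
    else:
        local, seq_len = r - L_enh, cfg.prom_len
    covered = set()
    for j in range(local * cfg.pool_stride, local * cfg.pool_stride + cfg.pool_size):
        for b in range(j, j + cfg.conv_kernel):
            covered.add(b)
    return min(covered), min(max(covered) + 1, seq_len)


class TestRegionWindow:
    def test_default_geometry_anchors(self):
        cfg = ModelConfig()
        w0 = region_window(0, cfg)
        assert (w0.role, w0.start, w0.end) == ("enhancer", 0, 59)
        w148 = region_window(148, cfg)
        assert (w148.role, w148.start, w148.end) == ("promoter", 0, 59)
        w245 = region_window(245, cfg)
        assert (w245.role, w245.start, w245.end) == ("promoter", 1940, 1999)

    def test_out_of_range_rejected(self):
        cfg = ModelConfig()
        for r in (-1, 246):
            with pytest.raises(InterpretError):
                region_window(r, cfg)

    def test_matches_receptive_field_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            kernel = int(rng.integers(3, 12))
            pool = int(rng.integers(2, 7))
            enh_len = int(rng.integers(kernel + pool + 20, 400))
            prom_len = int(rng.integers(kernel + pool + 20, 300))
            filters = 8
            cfg = ModelConfig(enh_len=enh_len, prom_len=prom_len,
                              conv_filters=filters, conv_kernel=kernel,
                              pool_size=pool, pool_stride=pool, n_heads=2,
                              ffn_dense1=8, ffn_dense2=filters, attn_hidden=8)
            for r in rng.integers(0, cfg.merged_len, size=6):
                win = region_window(int(r), cfg)
                assert (win.start, win.end) == brute_force_receptive_field(int(r), cfg)


class TestCaptureAndAverage:
    def test_capture_shapes_and_row_sums(self, trained):
        pos = [r for r in trained["test"] if r.label == 1][:4]
        maps = capture_attention(trained["net"], pos)
        cfg = trained["cfg"]
        assert maps.shape == (4, cfg.n_heads, cfg.merged_len, cfg.merged_len)
        np.testing.assert_allclose(maps.sum(axis=-1), 1.0, atol=1e-4)

    def test_negative_record_rejected(self, trained):
        neg = [r for r in trained["test"] if r.label == 0][:1]
        with pytest.raises(InterpretError):
            capture_attention(trained["net"], neg)
        with pytest.raises(InterpretError):
            capture_attention(trained["net"], [])

    def test_average_identity_and_mean_oracle(self):
        rng = np.random.default_rng(1)
        one = rng.dirichlet(np.ones(6), size=6)         # row-stochastic 6x6
        stack = np.stack([one, one])                    # 2 identical heads
        np.testing.assert_allclose(average_heads(stack), one)
        two = rng.dirichlet(np.ones(6), size=(2, 6))
        np.testing.assert_allclose(average_heads(two), (two[0] + two[1]) / 2)
        # mean of probability rows is a probability row
        np.testing.assert_allclose(average_heads(two).sum(axis=1), 1.0)

    def test_empty_rejected(self):
        with pytest.raises(InterpretError):
            average_heads(np.zeros((0, 4, 4)))


class TestTopRegionPairs:
    def test_dominant_cell_ranks_first(self):
        avg = np.full((10, 10), 0.01)
        l_enh = 6
        avg[2, 8] = 0.9
        pairs = top_region_pairs(avg, l_enh, 5)
        assert (pairs[0].enhancer_region, pairs[0].promoter_region) == (2, 8)

    def test_tie_break_row_major(self):
        avg = np.ones((8, 8))
        pairs = top_region_pairs(avg, 5, 5)
        assert [(p.enhancer_region, p.promoter_region) for p in pairs] == [
            (0, 5), (0, 6), (0, 7), (1, 5), (1, 6)]

    def test_matches_exhaustive_sort_oracle(self):
        rng = np.random.default_rng(2)
        avg = rng.random((246, 246))
        got = top_region_pairs(avg, 148, 8)
        # oracle: score every (e, p) candidate and sort
        cand = []
        for e in range(148):
            for p in range(148, 246):
                cand.append((-(avg[e, p] + avg[p, e]) / 2, e, p))
        cand.sort()
        expected = [(e, p) for _, e, p in cand[:8]]
        assert [(g.enhancer_region, g.promoter_region) for g in got] == expected

    def test_k_bounds_and_exhaustive_mode(self):
        avg = np.random.default_rng(3).random((12, 12))
        with pytest.raises(InterpretError):
            top_region_pairs(avg, 6, 3)
        full = top_region_pairs(avg, 6, 36, k_bounds=None)
        assert len(full) == 36
        assert all(full[i].score >= full[i + 1].score for i in range(35))


class TestRegionPWM:
    def _planted_net_and_records(self):
        """Network whose first enhancer filter is hand-set to match the
        consensus exactly; all other filters zeroed."""
        cfg = ea.scaled_test_config(dropout=0.0)
        net = EPINetwork(cfg, seed=0)
        consensus = "TGACGTCA"
        W = np.zeros_like(net.conv_enh.W.value)
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for j, base in enumerate(consensus):
            W[j, idx[base], 0] = 1.0
        net.conv_enh.W.value[...] = W
        net.conv_enh.b.value[...] = 0.0
        rng = np.random.default_rng(5)
        records = []
        for i in range(6):
            # plant inside region r=3's pool window: conv positions 12..15
            pos = 12 + int(rng.integers(0, 4))
            enh = plant_motif(sample_background(300, rng),
                              ea.PlantedMotif("m", consensus), pos, rng)
            records.append(SequencePairRecord(
                f"p{i}", enh, sample_background(200, rng), 1, "syn"))
        return net, records, consensus

    def test_argmax_recovers_planted_window(self):
        net, records, consensus = self._planted_net_and_records()
        pwm = extract_region_pwm(net, records, 3, pseudocount=0.25)
        assert pwm.counts.shape == (4, 8)
        assert pwm.n_sequences == 6
        # every sample's best window is the planted one, so each column is
        # unanimous for the consensus base
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for j, base in enumerate(consensus):
            assert pwm.counts[idx[base], j] == 6
        assert pwm_correlation(pwm.freq, ea.PlantedMotif("m", consensus).expected_pwm()) > 0.95

    def test_single_sequence_zero_pseudocount_gives_basis_columns(self, trained):
        pos = [r for r in trained["test"] if r.label == 1][:1]
        pwm = extract_region_pwm(trained["net"], pos, 0, pseudocount=0.0)
        freq = pwm.freq
        assert np.all(np.isin(freq, [0.0, 1.0]))
        np.testing.assert_allclose(freq.sum(axis=0), 1.0)

    def test_counts_conserve_samples(self, trained):
        pos = [r for r in trained["test"] if r.label == 1][:5]
        pwm = extract_region_pwm(trained["net"], pos, 10)
        np.testing.assert_array_equal(pwm.counts.sum(axis=0), np.full(pwm.width, 5))
        np.testing.assert_allclose(pwm.freq.sum(axis=0), 1.0, atol=1e-12)

    def test_pwm_correlation_shift_invariance(self):
        target = ea.PlantedMotif("m", "TGACGTCA").expected_pwm()
        assert pwm_correlation(target, target) == pytest.approx(1.0)
        shifted = np.hstack([np.full((4, 2), 0.25), target[:, :-2]])
        assert pwm_correlation(shifted, target) > 0.7


class TestMemeFormat:
    def _pwm(self, seed=0, width=40, n=12):
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(n, [0.25] * 4, size=width).T
        return RegionPWM(seed, "enhancer", counts, n)

    def test_single_motif_block(self, tmp_path):
        path = tmp_path / "m.meme"
        write_meme([self._pwm()], path)
        text = path.read_text()
        assert text.count("MOTIF") == 1
        rows = [l for l in text.splitlines()
                if l.strip() and l.lstrip()[0].isdigit()]
        assert len(rows) == 40

    def test_probability_rows_sum_to_one(self, tmp_path):
        path = tmp_path / "m.meme"
        write_meme([self._pwm()], path)
        mats = read_meme(path)
        for mat in mats.values():
            np.testing.assert_allclose(mat.sum(axis=0), 1.0, atol=1e-4)

    def test_round_trip(self, tmp_path):
        pwms = [self._pwm(seed=i) for i in range(3)]
        path = tmp_path / "m.meme"
        write_meme(pwms, path)
        back = read_meme(path)
        assert set(back) == {p.name for p in pwms}
        for p in pwms:
            np.testing.assert_allclose(back[p.name], p.freq, atol=1e-4)

    def test_empty_rejected(self, tmp_path):
        with pytest.raises(InterpretError):
            write_meme([], tmp_path / "m.meme")


TOMTOM_FIXTURE = """\
Query_ID\tTarget_ID\tOptimal_offset\tp-value\tE-value\tq-value\tOverlap\tQuery_consensus\tTarget_consensus\tOrientation
enhancer_region_3\tSP1_HUMAN.H11MO.0.A\t0\t1e-05\t0.05\t0.01\t8\tAAA\tAAA\t+
enhancer_region_3\tKLF6_HUMAN.H11MO.0.A\t0\t1e-05\t0.08\t0.01\t8\tAAA\tAAA\t+
promoter_region_9\tRXRA_HUMAN.H11MO.0.A\t0\t2e-03\t0.01\t0.01\t8\tAAA\tAAA\t+
promoter_region_9\tEGR1_HUMAN.H11MO.0.A\t0\t5e-05\t0.001\t0.002\t8\tAAA\tAAA\t+
# comment line
"""


class TestTomtom:
    def test_threshold_filtering(self, tmp_path):
        path = tmp_path / "tomtom.tsv"
        path.write_text(TOMTOM_FIXTURE)
        hits = read_tomtom(path)
        kept = {(h.query, h.target) for h in hits}
        # row 2 fails E<0.07, row 3 fails p<1e-4
        assert kept == {("enhancer_region_3", "SP1_HUMAN.H11MO.0.A"),
                        ("promoter_region_9", "EGR1_HUMAN.H11MO.0.A")}

    def test_comments_only_file_is_empty(self, tmp_path):
        path = tmp_path / "tomtom.tsv"
        path.write_text("# nothing here\n# really\n")
        assert read_tomtom(path) == []

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "tomtom.tsv"
        path.write_text("Query_ID\tTarget_ID\n a\tb\n")
        with pytest.raises(InterpretError):
            read_tomtom(path)


BIOGRID_FIXTURE = (
    "#BioGRID Interaction ID\tOfficial Symbol Interactor A\t"
    "Official Symbol Interactor B\tExperimental System\tExperimental System Type\n"
    "1\tSP1\tEGR1\tTwo-hybrid\tphysical\n"
    "2\tSP1\tEGR1\tTwo-hybrid\tphysical\n"
    "3\tKLF6\tRXRA\tSynthetic Lethality\tgenetic\n"
    "4\tCTCF\tYY1\tProximity Label-MS\tphysical\n"
    "5\tSOX2\tCTCF\tUnknown-system\tother\n"
)


class TestBiogrid:
    def test_annotations_and_dedup(self, tmp_path):
        path = tmp_path / "biogrid.tab.txt"
        path.write_text(BIOGRID_FIXTURE)
        lut = read_biogrid(path)
        assert len(lut) == 4                      # duplicate row collapsed
        assert lut.evidence("SP1", "EGR1") == {"physical"}
        assert lut.evidence("EGR1", "SP1") == {"physical"}   # order-insensitive
        assert lut.evidence("KLF6", "RXRA") == {"genetic"}
        assert lut.evidence("SOX2", "CTCF") == {"indirect"}  # unknown type
        assert lut.evidence("SP1", "NOSUCH") == {"unvalidated"}

    def test_malformed_rows_skipped(self, tmp_path):
        path = tmp_path / "biogrid.tab.txt"
        path.write_text(BIOGRID_FIXTURE + "6\tONLY_A\n")
        lut = read_biogrid(path)
        assert len(lut) == 4


class TestInteractionTable:
    def _inputs(self, cfg):
        pairs = [RegionPairScore(3, cfg.enh_pooled_len + 9, 0.5),
                 RegionPairScore(4, cfg.enh_pooled_len + 9, 0.3)]
        hits = [MotifHit("enhancer_region_3", "SP1", 1e-5, 0.01),
                MotifHit("promoter_region_%d" % (cfg.enh_pooled_len + 9), "EGR1", 1e-5, 0.02)]
        return pairs, hits

    def test_aggregation_across_cells(self, scaled_cfg):
        pairs, hits = self._inputs(scaled_cfg)
        table, unassigned = build_interaction_table(
            {"cellA": pairs, "cellB": pairs}, {"cellA": hits, "cellB": hits},
            scaled_cfg)
        assert len(table) == 1
        rec = table[0]
        assert (rec.tf_enhancer, rec.tf_promoter) == ("SP1", "EGR1")
        assert rec.cells == {"cellA", "cellB"}
        assert rec.evidence == {"unvalidated"}
        # second pair's enhancer region has no hit -> side list
        assert [(c, p.enhancer_region) for c, p in unassigned] == [
            ("cellA", 4), ("cellB", 4)]

    def test_biogrid_join_annotates_evidence(self, scaled_cfg, tmp_path):
        pairs, hits = self._inputs(scaled_cfg)
        path = tmp_path / "biogrid.tab.txt"
        path.write_text(BIOGRID_FIXTURE)
        table, _ = build_interaction_table(
            {"cellA": pairs}, {"cellA": hits}, scaled_cfg, read_biogrid(path))
        assert table[0].evidence == {"physical"}

    def test_best_hit_selection(self):
        hits = [MotifHit("q", "A", 1e-5, 0.05), MotifHit("q", "B", 1e-6, 0.01)]
        assert best_hit_by_query(hits)["q"].target == "B"
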