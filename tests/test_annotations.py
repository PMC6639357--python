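"""Annotation parsing, FLI-L1 classification, ages, and the exon filter."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from demethyl1 import annotations as ann


def _write_table(path, rows):
    path.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
    return path


class TestParseTeAnnotation:
    def test_field_mapping(self, tmp_path):
        p = _write_table(tmp_path / "te.bed", [("chr1", 100, 7100, "+", "L1HS", "LINE", "L1", 0.8)])
        (frag,) = ann.parse_te_annotation(p)
        assert frag.length == 7000
        assert frag.class_ == "LINE" and frag.subfamily == "L1HS"
        assert frag.divergence_pct == pytest.approx(0.8)

    def test_non_te_classes_dropped_and_counted(self, tmp_path):
        rows = [
            ("chr1", 0, 10, "+", "L1HS", "LINE", "L1", 1.0),
            ("chr1", 20, 30, "+", "Tigger1", "DNA", "TcMar", 9.0),
            ("chr1", 40, 50, "-", "AluY", "SINE", "Alu", 2.0),
        ]
        stats = {}
        frags = ann.parse_te_annotation(_write_table(tmp_path / "te.bed", rows), stats=stats)
        assert len(frags) == 2
        assert stats["excluded_class"] == 1

    def test_row_count_matches_line_count(self, tmp_path):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(10):
            s = int(rng.integers(0, 1000))
            cls = "DNA" if i in (3, 7) else "LINE"
            rows.append((f"chr1", s + i * 2000, s + i * 2000 + 500, "+", "L1HS", cls, "L1", 1.0))
        p = _write_table(tmp_path / "te.bed", rows)
        n_lines = len(p.read_text().splitlines())
        frags = ann.parse_te_annotation(p)
        assert n_lines == 10
        assert len(frags) == n_lines - 2

    def test_malformed_row_names_line(self, tmp_path):
        p = _write_table(tmp_path / "te.bed", [("chr1", "x", 10, "+", "L1HS", "LINE", "L1", 1.0)])
        with pytest.raises(ValueError, match="line 1"):
            ann.parse_te_annotation(p)

    def test_inverted_interval_rejected(self, tmp_path):
        p = _write_table(tmp_path / "te.bed", [("chr1", 100, 100, "+", "L1HS", "LINE", "L1", 1.0)])
        with pytest.raises(ValueError):
            ann.parse_te_annotation(p)


def _frag(eid, start, end, subfam="L1HS", strand="+", chrom="chr1"):
    return ann.TEFragment(eid, chrom, start, end, strand, subfam, "LINE", "L1", 1.0)


class TestClassifyFliL1:
    ALL = ann.IntactnessFlags(True, True, True, True)

    def test_length_and_flag_rules(self):
        frags = [_frag("a", 0, 7000), _frag("b", 0, 5500)]
        flags = {"a": self.ALL, "b": self.ALL}
        out = ann.classify_fli_l1(frags, flags)
        assert [r.fragment.element_id for r in out] == ["a"]

    def test_missing_flags_treated_not_intact(self):
        assert ann.classify_fli_l1([_frag("a", 0, 7000)], {}) == []

    def test_matches_per_element_brute_force(self):
        rng = np.random.default_rng(1)
        frags, flags = [], {}
        for i in range(20):
            length = int(rng.integers(4000, 8000))
            frags.append(_frag(f"e{i}", 0, length))
            flags[f"e{i}"] = ann.IntactnessFlags(*(bool(b) for b in rng.integers(0, 2, 4)))
        expected = {
            f.element_id
            for f in frags
            if f.length > 6000 and flags[f.element_id].all_intact
        }
        got = ann.classify_fli_l1(frags, flags)
        assert {r.fragment.element_id for r in got} == expected

    def test_idempotent_subset(self):
        rng = np.random.default_rng(2)
        frags = [_frag(f"e{i}", 0, int(rng.integers(5000, 8000))) for i in range(10)]
        flags = {f.element_id: self.ALL for f in frags}
        once = ann.classify_fli_l1(frags, flags)
        twice = ann.classify_fli_l1([r.fragment for r in once], flags)
        assert [r.fragment for r in twice] == [r.fragment for r in once]
        assert {r.fragment.element_id for r in once} <= {f.element_id for f in frags}


class TestSubfamilyAges:
    @pytest.mark.parametrize(
        "subfam,expect",
        [("L1HS", True), ("L1PA2", True), ("L1PA3", True), ("L1PA7", False)],
    )
    def test_hominoid_cut(self, subfam, expect):
        (aged,) = ann.assign_subfamily_ages([_frag("a", 0, 100, subfam=subfam)])
        assert aged.hominoid_specific is expect

    def test_unknown_subfamily_flagged(self):
        (aged,) = ann.assign_subfamily_ages([_frag("a", 0, 100, subfam="L1XX")])
        assert aged.age_my is None and aged.hominoid_specific is None

    def test_age_table_invariant(self):
        rec = ann.SubfamilyAge("L1PA3", 12.4)
        assert rec.hominoid_specific is (rec.age_my < ann.HOMINOID_AGE_CUTOFF_MY)


def _tx(gene, exons, strand="+", chrom="chr1"):
    return ann.TranscriptModel(gene, f"{gene}.t", chrom, strand, tuple(exons), True)


class TestFilterNonexonic:
    def test_overlap_removed_adjacency_kept(self):
        frags = [_frag("a", 100, 200), _frag("b", 100, 200)]
        tx_hit = _tx("g1", [(150, 160)])
        tx_adj = _tx("g2", [(200, 300)])
        assert ann.filter_nonexonic([frags[0]], [tx_hit]) == []
        assert ann.filter_nonexonic([frags[1]], [tx_adj]) == [frags[1]]

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_agrees_with_per_base_oracle(self, data):
        genome = 5_000
        n_te = data.draw(st.integers(5, 40))
        n_ex = data.draw(st.integers(1, 20))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        frags = []
        for i in range(n_te):
            s = int(rng.integers(0, genome - 50))
            frags.append(_frag(f"e{i}", s, s + int(rng.integers(1, 50))))
        exons = []
        for _ in range(n_ex):
            s = int(rng.integers(0, genome - 50))
            exons.append((s, s + int(rng.integers(1, 50))))
        txs = [_tx("g", sorted({exons[0]}))] + [_tx(f"g{i}", [e]) for i, e in enumerate(exons[1:])]
        covered = np.zeros(genome, dtype=bool)
        for tx in txs:
            for s, e in tx.exons:
                covered[s:e] = True
        expected = [f for f in frags if not covered[f.start:f.end].any()]
        assert ann.filter_nonexonic(frags, txs) == expected

    def test_monotone_in_exons(self):
        rng = np.random.default_rng(3)
        frags = [_frag(f"e{i}", int(s), int(s) + 40) for i, s in enumerate(rng.integers(0, 5000, 30))]
        exons = [(int(s), int(s) + 30) for s in rng.integers(0, 5000, 10)]
        txs = [_tx(f"g{i}", [e]) for i, e in enumerate(exons)]
        for k in range(len(txs)):
            small = {f.element_id for f in ann.filter_nonexonic(frags, txs[:k])}
            big = {f.element_id for f in ann.filter_nonexonic(frags, txs[:k + 1])}
            assert big <= small


class TestTranscriptModel:
    def test_tss_strand_aware(self):
        plus = _tx("g", [(100, 200), (300, 400)], "+")
        minus = _tx("g", [(100, 200), (300, 400)], "-")
        assert plus.tss == 100
        assert minus.tss == 399

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError):
            _tx("g", [(100, 250), (200, 300)])


class TestOrfScan:
    def test_planted_orfs_detected(self):
        rng = np.random.default_rng(4)

        def orf(n_codons):
            inner = "".join(
                rng.choice(["GCT", "GGT", "TGT", "ACT", "CCT"]) for _ in range(n_codons - 2)
            )
            return "ATG" + inner + "TAA"

        utr5 = "C" * 900
        seq = utr5 + orf(320) + "CCC" + orf(1200) + "C" * 200
        flags = ann.scan_orf_intactness(seq)
        assert flags.all_intact

    def test_random_sequence_not_intact(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=7000))
        assert not ann.scan_orf_intactness(seq).all_intact


class TestParseGtf:
    def test_simulated_models_round_trip(self, transcripts, sim):
        by_id = {t.transcript_id: t for t in transcripts}
        for tx in sim.annotation.transcripts:
            got = by_id[tx.transcript_id]
            assert got.exons == tx.exons
            assert got.strand == tx.strand
            assert got.coding
            assert got.tss == tx.tss
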