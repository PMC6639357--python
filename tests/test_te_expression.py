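"""Locus-level TE counting, normalization, and the NB differential test."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
import pytest

from demethyl1 import annotations as ann
from demethyl1 import te_expression as texp
from demethyl1._stats import bh_adjust, rank_sum_test


def _frag_model(eid, start, end, subfam="L1HS", strand="+", chrom="chr1"):
    return ann.TEFragment(eid, chrom, start, end, strand, subfam, "LINE", "L1", 1.0)


def _read_fragment(qid, blocks1, blocks2, strand="+", unique=True, chrom="chr1"):
    return texp.ReadFragment(qid, chrom, tuple(blocks1), tuple(blocks2), strand, unique, 60)


def _write_sam(path, records):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100000}]}
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for qname, flag, pos, cigar, mpos, nh in records:
            a = pysam.AlignedSegment(header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = cigar
            a.next_reference_id = 0
            a.next_reference_start = mpos
            a.set_tag("NH", nh)
            out.write(a)
    return path


class TestLoadFragments:
    def test_reverse_stranded_protocol_strand(self, tmp_path):
        # mate1 on the minus strand under dUTP -> plus-strand fragment
        sam = _write_sam(
            tmp_path / "a.sam",
            [("q1", 163, 100, "150M", 300, 1), ("q1", 83, 300, "150M", 100, 1)],
        )
        (frag,) = texp.load_fragments(sam, "reverse-stranded")
        assert frag.fragment_strand == "+"
        assert frag.unique

    def test_forward_stranded_flips(self, tmp_path):
        sam = _write_sam(
            tmp_path / "a.sam",
            [("q1", 163, 100, "150M", 300, 1), ("q1", 83, 300, "150M", 100, 1)],
        )
        (frag,) = texp.load_fragments(sam, "forward-stranded")
        assert frag.fragment_strand == "-"

    def test_secondary_records_ignored(self, tmp_path):
        sam = _write_sam(
            tmp_path / "a.sam",
            [
                ("q1", 163, 100, "150M", 300, 1),
                ("q1", 83, 300, "150M", 100, 1),
                ("q2", 163 + 256, 500, "150M", 700, 2),
            ],
        )
        frags = list(texp.load_fragments(sam, "reverse-stranded"))
        assert [f.query_id for f in frags] == ["q1"]

    def test_unknown_protocol_rejected(self, tmp_path):
        sam = _write_sam(tmp_path / "a.sam", [])
        with pytest.raises(ValueError):
            list(texp.load_fragments(sam, "reverse"))

    def test_fragment_count_equals_simulated_templates(self, rna_sams, truth):
        sample = "control_1"
        frags = list(texp.load_fragments(rna_sams[sample], "reverse-stranded"))
        assert len(frags) == truth["library_sizes"][sample]

    def test_multimap_tag_marks_nonunique(self, tmp_path):
        sam = _write_sam(
            tmp_path / "a.sam",
            [("q1", 163, 100, "150M", 300, 2), ("q1", 83, 300, "150M", 100, 2)],
        )
        (frag,) = texp.load_fragments(sam, "reverse-stranded")
        assert not frag.unique


class TestCountTeFragments:
    TES = [_frag_model("a", 1000, 8000), _frag_model("b", 20000, 21000)]

    def test_unique_fragment_counted_once(self):
        frags = [_read_fragment("q", [(2000, 2150)], [(2300, 2450)])]
        counts, total = texp.count_te_fragments(frags, self.TES)
        assert counts["a"] == 1 and counts["b"] == 0 and total == 1

    def test_nonunique_fragment_discarded(self):
        frags = [_read_fragment("q", [(2000, 2150)], [(2300, 2450)], unique=False)]
        counts, total = texp.count_te_fragments(frags, self.TES)
        assert counts.sum() == 0 and total == 1

    def test_largest_overlap_assignment_and_tie_break(self):
        tes = [_frag_model("x", 100, 300), _frag_model("y", 250, 600)]
        frag = _read_fragment("q", [(200, 350)], [(350, 500)])  # 100 bp in x, 250 in y
        counts, _ = texp.count_te_fragments([frag], tes)
        assert counts["y"] == 1
        tie = _read_fragment("t", [(250, 300)], [])  # 50 bp in both
        counts, _ = texp.count_te_fragments([tie], tes)
        assert counts["x"] == 1  # lower-coordinate element wins ties

    def test_discard_mode_drops_ambiguous(self):
        tes = [_frag_model("x", 100, 300), _frag_model("y", 250, 600)]
        frag = _read_fragment("q", [(200, 350)], [])
        counts, _ = texp.count_te_fragments([frag], tes, ambiguous="discard")
        assert counts.sum() == 0

    def test_matrix_equals_planted_truth(self, te_matrix, truth, rna_sams):
        planted = pd.DataFrame(
            {s: truth["rna_unique_counts"][s] for s in rna_sams}
        ).loc[te_matrix.counts.index]
        assert te_matrix.counts.equals(planted.astype(te_matrix.counts.dtypes.iloc[0]))
        assert dict(te_matrix.library_sizes) == truth["library_sizes"]


class TestFilterAndNormalize:
    def test_min_total_examples(self):
        cm = texp.CountMatrix(
            pd.DataFrame({"s1": [2, 3, 0], "s2": [2, 2, 0]}, index=["f4", "f5", "f0"]),
            pd.Series({"s1": 10, "s2": 10}),
        )
        out = texp.filter_min_total(cm)
        assert list(out.counts.index) == ["f5"]

    def test_all_zero_matrix_empties(self):
        cm = texp.CountMatrix(
            pd.DataFrame(np.zeros((4, 2), dtype=int), columns=["a", "b"]),
            pd.Series({"a": 1, "b": 1}),
        )
        assert texp.filter_min_total(cm).counts.empty

    def test_min_total_matches_row_sum_oracle(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 4, size=(50, 4)), columns=list("abcd"))
        cm = texp.CountMatrix(counts, pd.Series(1, index=list("abcd")))
        out = texp.filter_min_total(cm, 5)
        assert set(out.counts.index) == set(counts.index[counts.sum(axis=1) >= 5])

    def test_median_ratio_doubled_column(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        cm = texp.CountMatrix(counts, pd.Series({"s1": 100, "s2": 200}))
        sf, _ = texp.normalize(cm, "median-ratio")
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)

    def test_library_scaling_equal_sizes(self):
        cm = texp.CountMatrix(
            pd.DataFrame({"s1": [1], "s2": [1]}), pd.Series({"s1": 500, "s2": 500})
        )
        sf, _ = texp.normalize(cm, "library-scaling")
        assert (sf == 1.0).all()

    def test_median_ratio_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.negative_binomial(5, 0.1, size=(50, 2)), columns=["a", "b"])
        cm = texp.CountMatrix(counts, pd.Series(1, index=["a", "b"]))
        sf, _ = texp.normalize(cm, "median-ratio")
        # independent re-derivation of the median-of-ratios formula (the
        # median is taken on the log scale, as in DESeq2)
        mat = counts.to_numpy(float)
        keep = (mat > 0).all(axis=1)
        geo = np.exp(np.log(mat[keep]).mean(axis=1))
        expected = [float(np.exp(np.median(np.log(mat[keep, j] / geo)))) for j in range(2)]
        assert sf.to_numpy() == pytest.approx(expected)

    def test_median_ratio_matches_pydeseq2(self):
        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(5, 0.1, size=(6, 50))
        samples = [f"s{i}" for i in range(6)]
        meta = pd.DataFrame({"condition": ["a"] * 3 + ["b"] * 3}, index=samples)
        dds = DeseqDataSet(
            counts=pd.DataFrame(counts, index=samples), metadata=meta,
            design="~condition", quiet=True,
        )
        dds.fit_size_factors()
        cm = texp.CountMatrix(
            pd.DataFrame(counts.T, columns=samples), pd.Series(1, index=samples)
        )
        sf, _ = texp.normalize(cm, "median-ratio")
        assert sf.to_numpy() == pytest.approx(np.asarray(dds.obs["size_factors"], dtype=float))

    def test_no_common_feature_suggests_library_scaling(self):
        cm = texp.CountMatrix(
            pd.DataFrame({"s1": [1, 0], "s2": [0, 1]}), pd.Series({"s1": 1, "s2": 1})
        )
        with pytest.raises(ValueError, match="library-scaling"):
            texp.normalize(cm, "median-ratio")

    def test_filter_normalize_commute_library_scaling(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(rng.integers(0, 6, size=(40, 3)), columns=list("abc"))
        cm = texp.CountMatrix(counts, pd.Series({"a": 100, "b": 150, "c": 120}))
        _, n_then_f = texp.normalize(texp.filter_min_total(cm), "library-scaling")
        _, full = texp.normalize(cm, "library-scaling")
        f_then_n = full.loc[texp.filter_min_total(cm).counts.index]
        pd.testing.assert_frame_equal(n_then_f, f_then_n)


class TestDifferentialTest:
    GROUPS = {f"c{i}": "control" for i in range(3)} | {f"k{i}": "ko" for i in range(3)}

    def _matrix(self, counts):
        samples = list(self.GROUPS)
        return texp.CountMatrix(
            pd.DataFrame(counts, columns=samples),
            pd.Series({s: 10_000 for s in samples}),
        )

    def test_zero_control_large_ko_significant_up(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(20, size=(30, 6))
        counts[0] = [0, 0, 0, 60, 50, 70]
        res = texp.differential_test(
            self._matrix(counts), self.GROUPS, "library-scaling", reference="control"
        )
        assert res.iloc[0]["log2_fold_change"] > 0
        assert res.iloc[0]["p_adj"] < 0.05

    def test_null_type_i_error_calibrated(self):
        rng = np.random.default_rng(7)
        mu, alpha = 30, 0.1
        counts = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu), size=(10_000, 6))
        res = texp.differential_test(
            self._matrix(counts), self.GROUPS, "library-scaling", reference="control"
        )
        rate = float((res["p_value"] < 0.05).mean())
        assert 0.03 <= rate <= 0.07

    def test_planted_fold_change_recovered(self):
        rng = np.random.default_rng(2)
        mu = 20.0
        counts = rng.negative_binomial(20, 1 / (1 + 0.05 * mu), size=(200, 6))
        planted = rng.choice(200, 20, replace=False)
        boosted = rng.negative_binomial(20, 1 / (1 + 0.05 * mu * 16), size=(20, 3))
        counts[planted, 3:] = boosted
        res = texp.differential_test(
            self._matrix(counts), self.GROUPS, "library-scaling", reference="control"
        )
        assert (res.iloc[planted]["direction"] == "up").all()

    def test_all_zero_feature_excluded_from_bh(self):
        counts = np.vstack([np.zeros(6, dtype=int), np.full(6, 20)])
        res = texp.differential_test(
            self._matrix(counts), self.GROUPS, "library-scaling", reference="control"
        )
        assert np.isnan(res.iloc[0]["p_value"]) and np.isnan(res.iloc[0]["p_adj"])
        assert np.isfinite(res.iloc[1]["p_value"])


class TestSmallSampleStats:
    def test_bh_step_up_worked_example(self):
        padj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert padj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_bh_oracle_random_pvalues(self):
        rng = np.random.default_rng(4)
        p = rng.random(25)
        # hand implementation of the step-up rule
        order = np.argsort(p)
        m = len(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        expected = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(expected, 1)
        assert bh_adjust(p) == pytest.approx(out)

    def test_wilcoxon_exact_separated_ranks(self):
        _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_wilcoxon_identical_singletons(self):
        _, p = rank_sum_test([5.0], [5.0])
        assert p == 1.0

    def test_wilcoxon_matches_scipy_asymptotic(self):
        from scipy import stats as sps

        rng = np.random.default_rng(6)
        x, y = rng.normal(size=30), rng.normal(0.5, size=25)
        _, p = rank_sum_test(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(ref)


class TestStrandAndSubfamily:
    def test_sense_only_simulation_has_sense_excess(self, rna_sams, te_fragments, truth):
        intact = {
            eid: ann.IntactnessFlags(*([bool(info["intact"])] * 4))
            for eid, info in truth["element_info"].items()
        }
        fli = ann.classify_fli_l1(te_fragments, intact)
        assert {r.fragment.element_id for r in fli} == set(truth["fli_l1_ids"])
        frags = list(texp.load_fragments(rna_sams["ko_1"], "reverse-stranded"))
        sc = texp.strand_counts(frags, fli)
        pure = sc.drop(index=[e for e in truth["fusion_genes"].values() if e in sc.index])
        # element-sense transcription only: no antisense counts outside
        # the designed promoter elements
        assert (pure["antisense_count"] == 0).all()
        _, p = texp.sense_antisense_test(sc)
        assert p < 0.05

    def test_unstranded_protocol_rejected(self):
        frag = _read_fragment("q", [(0, 10)], [], strand=None)
        with pytest.raises(ValueError):
            texp.strand_counts([frag], [])

    def test_subfamily_summary_matches_group_by_oracle(self, de_results, te_fragments):
        aged = ann.assign_subfamily_ages(te_fragments)
        summ = texp.subfamily_summary(de_results, aged).set_index("subfamily")
        sub_of = {a.fragment.element_id: a.fragment.subfamily for a in aged}
        up = de_results[(de_results["direction"] == "up")]
        for subfam in summ.index:
            expected = sum(1 for e in up.index if sub_of.get(e) == subfam)
            assert summ.loc[subfam, "n_upregulated"] == expected
            assert summ.loc[subfam, "n_upregulated"] <= summ.loc[subfam, "n_total_elements"]

    def test_age_ordering_youngest_first(self, de_results, te_fragments):
        summ = texp.subfamily_summary(de_results, ann.assign_subfamily_ages(te_fragments))
        ages = summ["age_my"].dropna().to_numpy()
        assert (np.diff(ages) >= 0).all()
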