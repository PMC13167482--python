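import numpy as np
import pytest
from scipy.stats import binom

from ctdna_concord.fragmentomics import (
    AMBIGUOUS,
    FRAGMENT_LABELS,
    MUTANT,
    NON_MUTANT,
    NOT_COVERED,
    OTHER_ALLELE,
    AlignmentRecord,
    analyze_locus,
    classify_fragments,
    classify_read,
    fragment_sizes,
    parse_cigar,
    project_locus,
    read_sam,
    size_summary,
    write_split_sam,
)
from ctdna_concord.simulate import (
    VariantSpec,
    simulate_read_pairs,
    write_sam,
)
from ctdna_concord.stats import rank_sum_less, round_half_away

from conftest import make_sim_config


def make_record(pos, cigar, seq=None, qname="r1", flags=99, chrom="chrS",
                mapq=60, tlen=180):
    cig = parse_cigar(cigar)
    if seq is None:
        qlen = sum(n for op, n in cig if op in "MIS=X")
        seq = "A" * qlen
    return AlignmentRecord(qname, flags, chrom, pos, mapq, cig, seq, tlen)


class TestProjectLocus:
    def test_pure_match(self):
        rec = make_record(100, "50M")
        assert project_locus(rec, 120) == (20, "M")

    def test_inside_deletion_not_covered(self):
        rec = make_record(100, "10M5D40M")
        assert project_locus(rec, 112) == (None, None)

    def test_after_insertion_skips_inserted_bases(self):
        rec = make_record(100, "10M5I40M")
        assert project_locus(rec, 115) == (20, "M")

    def test_before_read_start(self):
        rec = make_record(100, "50M")
        assert project_locus(rec, 99) == (None, None)

    def test_past_read_end(self):
        rec = make_record(100, "50M")
        assert project_locus(rec, 150) == (None, None)

    def test_soft_clip_consumes_query_only(self):
        rec = make_record(100, "5S45M")
        assert project_locus(rec, 100) == (5, "M")

    def test_matches_pysam_on_simulated_reads(self, any_variant, tmp_path):
        pysam = pytest.importorskip("pysam")
        cfg = make_sim_config(any_variant, n_fragments=60, seed=31)
        records, _, _ = simulate_read_pairs(cfg)
        path = tmp_path / "reads.sam"
        write_sam(records, any_variant.chrom, cfg.reference_length, path)
        ours = {
            (r.query_name, r.pos): project_locus(r, any_variant.pos)[0]
            for r in read_sam(path)
        }
        with pysam.AlignmentFile(str(path), "r") as sam:
            for aln in sam:
                pairs = dict(
                    (rp + 1, qp)
                    for qp, rp in aln.get_aligned_pairs(matches_only=True)
                )
                expected = pairs.get(any_variant.pos)
                assert ours[(aln.query_name, aln.reference_start + 1)] == expected


class TestClassifyReadSNV:
    variant = VariantSpec("chrS", 150, "C", "T")

    def _read_with_base(self, base):
        seq = "A" * 30 + base + "A" * 29
        return make_record(120, "60M", seq=seq)

    def test_alt_base_is_mutant(self):
        assert classify_read(self._read_with_base("T"), self.variant).label == MUTANT

    def test_ref_base_is_non_mutant(self):
        assert classify_read(self._read_with_base("C"), self.variant).label == NON_MUTANT

    def test_third_base_is_other_allele(self):
        assert classify_read(self._read_with_base("G"), self.variant).label == OTHER_ALLELE

    def test_no_overlap_not_covered(self):
        rec = make_record(100, "50M")  # spans 100-149, locus at 150
        assert classify_read(rec, self.variant).label == NOT_COVERED

    def test_locus_at_read_edge_lacks_anchor(self):
        rec = make_record(150, "50M")  # locus at first base: no left anchor
        assert classify_read(rec, self.variant).label == NOT_COVERED

    def test_wrong_chromosome_not_covered(self):
        rec = make_record(120, "60M", chrom="chrOther")
        assert classify_read(rec, self.variant).label == NOT_COVERED

    def test_min_anchor_respected(self):
        # read 120-179, locus 150: 30 aligned bases left, 29 right
        rec = self._read_with_base("T")
        assert classify_read(rec, self.variant, min_anchor=29).label == MUTANT
        assert classify_read(rec, self.variant, min_anchor=30).label == NOT_COVERED


class TestClassifyReadDeletion:
    # deletion of GTA: anchor C at 150, deleted span 151-153
    variant = VariantSpec("chrS", 150, "CGTA", "C")

    def test_exact_deletion_is_mutant(self):
        rec = make_record(121, "30M3D30M")  # D spans 151-153
        assert classify_read(rec, self.variant).label == MUTANT

    def test_spanning_match_is_non_mutant(self):
        rec = make_record(121, "60M")
        assert classify_read(rec, self.variant).label == NON_MUTANT

    def test_wrong_length_deletion_is_other(self):
        rec = make_record(121, "30M2D30M")  # D spans 151-152 only
        assert classify_read(rec, self.variant).label == OTHER_ALLELE

    def test_shifted_deletion_is_other(self):
        rec = make_record(122, "30M3D30M")  # D spans 152-154
        assert classify_read(rec, self.variant).label == OTHER_ALLELE

    def test_single_base_right_anchor_suffices(self):
        rec = make_record(121, "30M3D1M")  # aligned at 154 right after the D
        assert classify_read(rec, self.variant).label == MUTANT

    def test_no_right_anchor_not_covered(self):
        # read 121-153 ends inside the would-be deleted span: no anchor at 154
        rec = make_record(121, "33M")
        assert classify_read(rec, self.variant).label == NOT_COVERED


class TestClassifyReadInsertion:
    # insertion of ATG after anchor C at 150
    variant = VariantSpec("chrS", 150, "C", "CATG")

    def _mutant_read(self, inserted="ATG"):
        # 30M spans 121-150, then I, then 27M spans 151-177
        seq = "C" * 30 + inserted + "G" * 27
        return make_record(121, f"30M{len(inserted)}I27M", seq=seq)

    def test_exact_insertion_is_mutant(self):
        assert classify_read(self._mutant_read(), self.variant).label == MUTANT

    def test_wrong_sequence_is_other(self):
        assert classify_read(self._mutant_read("AAA"), self.variant).label == OTHER_ALLELE

    def test_wrong_length_is_other(self):
        assert classify_read(self._mutant_read("AT"), self.variant).label == OTHER_ALLELE

    def test_spanning_match_is_non_mutant(self):
        rec = make_record(121, "60M")
        assert classify_read(rec, self.variant).label == NON_MUTANT

    def test_junction_not_spanned_not_covered(self):
        rec = make_record(121, "30M")  # ends exactly at the anchor
        assert classify_read(rec, self.variant).label == NOT_COVERED


class TestClassifyFragments:
    variant = VariantSpec("chrS", 150, "C", "T")

    def _mate(self, base, qname, pos=120, flags=99, mapq=60):
        seq = "A" * (150 - pos) + base + "A" * (60 - (150 - pos) - 1)
        return make_record(pos, "60M", seq=seq, qname=qname, flags=flags, mapq=mapq)

    def test_agreeing_mates(self):
        recs = [self._mate("T", "f1", flags=99), self._mate("T", "f1", pos=130, flags=147)]
        calls = classify_fragments(recs, self.variant)
        assert calls["f1"].label == MUTANT

    def test_conflicting_mates_ambiguous(self):
        recs = [self._mate("T", "f1", flags=99), self._mate("C", "f1", pos=130, flags=147)]
        calls = classify_fragments(recs, self.variant)
        assert calls["f1"].label == AMBIGUOUS

    def test_single_informative_mate_decides(self):
        far = make_record(300, "60M", qname="f1", flags=147)
        recs = [self._mate("T", "f1"), far]
        assert classify_fragments(recs, self.variant)["f1"].label == MUTANT

    def test_low_mapq_mate_ignored(self):
        recs = [self._mate("T", "f1", mapq=5), self._mate("C", "f1", pos=130, flags=147)]
        assert classify_fragments(recs, self.variant)["f1"].label == NON_MUTANT

    def test_duplicate_flag_ignored(self):
        dup = self._mate("T", "f1", flags=99 | 0x400)
        recs = [dup, self._mate("C", "f1", pos=130, flags=147)]
        assert classify_fragments(recs, self.variant)["f1"].label == NON_MUTANT

    def test_secondary_records_skipped(self):
        sec = self._mate("T", "f1", flags=99 | 0x100)
        calls = classify_fragments([sec], self.variant)
        assert calls == {}

    def test_more_than_two_primaries_is_error(self):
        recs = [self._mate("T", "f1"), self._mate("T", "f1"), self._mate("T", "f1")]
        with pytest.raises(ValueError):
            classify_fragments(recs, self.variant)

    def test_mate_order_invariance(self):
        recs = [
            self._mate("T", "f1"), self._mate("T", "f1", pos=130, flags=147),
            self._mate("C", "f2"), self._mate("G", "f2", pos=130, flags=147),
        ]
        forward = classify_fragments(recs, self.variant)
        backward = classify_fragments(list(reversed(recs)), self.variant)
        assert {k: v.label for k, v in forward.items()} == \
            {k: v.label for k, v in backward.items()}

    def test_partition_invariant(self, any_variant, tmp_path):
        cfg = make_sim_config(any_variant, n_fragments=150, background_fraction=0.2)
        records, truth, _ = simulate_read_pairs(cfg)
        path = tmp_path / "r.sam"
        write_sam(records, any_variant.chrom, cfg.reference_length, path)
        calls = classify_fragments(read_sam(path), any_variant)
        counts = {label: 0 for label in FRAGMENT_LABELS}
        for c in calls.values():
            counts[c.label] += 1
        assert sum(counts.values()) == len(calls) == len(truth)


class TestTruthRecovery:
    """Generator truth labels are an independent oracle for the classifier."""

    def test_labels_recovered_for_all_covered_fragments(self, any_variant, tmp_path):
        cfg = make_sim_config(any_variant, n_fragments=400, seed=17,
                              background_fraction=0.1)
        records, truth, _ = simulate_read_pairs(cfg)
        path = tmp_path / "r.sam"
        write_sam(records, any_variant.chrom, cfg.reference_length, path)
        calls = classify_fragments(read_sam(path), any_variant)
        truth_label = dict(zip(truth.fragment, truth.allele))
        covers = dict(zip(truth.fragment, truth.covers_locus))
        for name, call in calls.items():
            if covers[name]:
                assert call.label == truth_label[name], name
            else:
                assert call.label == NOT_COVERED, name

    def test_sizes_recovered_exactly(self, any_variant, tmp_path):
        cfg = make_sim_config(any_variant, n_fragments=200, seed=23)
        records, truth, _ = simulate_read_pairs(cfg)
        path = tmp_path / "r.sam"
        write_sam(records, any_variant.chrom, cfg.reference_length, path)
        recs = read_sam(path)
        calls = classify_fragments(recs, any_variant)
        sizes, excluded = fragment_sizes(calls, recs)
        assert sum(excluded.values()) == 0
        recovered = sorted(sizes[MUTANT] + sizes[NON_MUTANT])
        assert recovered == sorted(truth.tlen_size)

    def test_vaf_recovery_within_binomial_band(self, snv_variant, tmp_path):
        n, p = 1500, 0.25
        cfg = make_sim_config(snv_variant, n_fragments=n, mutant_fraction=p, seed=99)
        records, _, _ = simulate_read_pairs(cfg)
        path = tmp_path / "r.sam"
        write_sam(records, snv_variant.chrom, cfg.reference_length, path)
        recs = read_sam(path)
        calls = classify_fragments(recs, snv_variant)
        k = sum(1 for c in calls.values() if c.label == MUTANT)
        m = sum(1 for c in calls.values() if c.label in (MUTANT, NON_MUTANT))
        lo, hi = binom.ppf([0.0005, 0.9995], m, p)
        assert lo <= k <= hi


class TestFragmentSizes:
    variant = VariantSpec("chrS", 150, "C", "T")

    def _pair(self, qname, tlen):
        seq = "A" * 30 + "T" + "A" * 29
        a = make_record(120, "60M", seq=seq, qname=qname, flags=99, tlen=tlen)
        b = make_record(120 + abs(tlen) - 60, "60M", qname=qname, flags=147, tlen=-tlen)
        return [a, b]

    def test_counted_once_per_pair(self):
        recs = self._pair("f1", 180)
        calls = classify_fragments(recs, self.variant)
        sizes, _ = fragment_sizes(calls, recs)
        assert sizes[MUTANT] == [180]

    def test_tlen_zero_excluded(self):
        recs = self._pair("f1", 0)
        calls = classify_fragments(recs, self.variant)
        sizes, excluded = fragment_sizes(calls, recs)
        assert sizes[MUTANT] == []
        assert excluded["tlen_zero"] == 1

    def test_oversize_excluded(self):
        recs = self._pair("f1", 1500)
        calls = classify_fragments(recs, self.variant)
        sizes, excluded = fragment_sizes(calls, recs, max_size=1000)
        assert excluded["tlen_too_large"] == 1

    def test_inconsistent_tlens_excluded(self):
        a, b = self._pair("f1", 180)
        b = AlignmentRecord(b.query_name, b.flags, b.chrom, b.pos, b.mapq,
                            b.cigar, b.seq, -170)
        calls = classify_fragments([a, b], self.variant)
        sizes, excluded = fragment_sizes(calls, [a, b])
        assert excluded["tlen_inconsistent"] == 1
        assert sizes[MUTANT] == []


class TestSizeSummary:
    def test_printed_mutant_fraction(self):
        sizes = [100] * 1149 + [200] * (2839 - 1149)
        stats = size_summary(sizes)["all"]
        assert stats.n == 2839
        pct = round_half_away(100 * stats.fraction_below_threshold, 1)
        assert pct == 40.5

    def test_printed_non_mutant_fraction(self):
        sizes = [100] * 7942 + [200] * (31681 - 7942)
        stats = size_summary(sizes)["all"]
        pct = round_half_away(100 * stats.fraction_below_threshold, 1)
        assert pct == 25.1

    def test_threshold_is_strict(self):
        stats = size_summary([149, 150, 151])["all"]
        assert stats.fraction_below_threshold == pytest.approx(1 / 3)

    def test_window_boundaries_inclusive(self):
        out = size_summary([220, 221])
        assert out["mono"].n == 1 and out["mono"].median == 220
        assert out["di"].n == 1 and out["di"].median == 221

    def test_window_edges(self):
        out = size_summary([49, 50, 400, 401])
        assert out["mono"].n == 1
        assert out["di"].n == 1
        assert out["all"].n == 4

    def test_empty_input_flagged(self):
        out = size_summary([])
        assert out["all"].n == 0
        assert out["all"].fraction_below_threshold is None

    def test_histogram_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        sizes = rng.integers(60, 400, 500)
        for stats in size_summary(sizes).values():
            assert sum(c for _, c in stats.histogram) == stats.n

    def test_negative_sizes_rejected(self):
        with pytest.raises(ValueError):
            size_summary([-1])


class TestShiftDetection:
    def test_mutant_shorter_shift_detected(self):
        """One-sided test flags the mono-nucleosome shift direction."""
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            mut = np.clip(rng.normal(153, 20, 500), 60, 450)
            non = np.clip(rng.normal(162, 20, 5000), 60, 450)
            p, _ = rank_sum_less(mut, non)
            hits += p < 0.01
        assert hits >= 95

    def test_no_shift_rarely_significant(self):
        rng = np.random.default_rng(7)
        sig = 0
        for _ in range(50):
            a = rng.normal(160, 20, 200)
            b = rng.normal(160, 20, 200)
            p, _ = rank_sum_less(a, b)
            sig += p < 0.01
        assert sig <= 3


class TestOutputsAndReports:
    def test_split_sam_label_consistency(self, snv_variant, tmp_path):
        cfg = make_sim_config(snv_variant, n_fragments=120, seed=3)
        records, _, _ = simulate_read_pairs(cfg)
        path = tmp_path / "r.sam"
        write_sam(records, snv_variant.chrom, cfg.reference_length, path)
        recs = read_sam(path)
        calls = classify_fragments(recs, snv_variant)
        paths = write_split_sam(recs, calls, tmp_path / "split")
        for label, sam_path in paths.items():
            written = read_sam(sam_path)
            assert written, label
            for rec in written:
                assert calls[rec.query_name].label == label

    def test_analyze_locus_report(self, snv_variant, tmp_path):
        cfg = make_sim_config(snv_variant, n_fragments=300, seed=8,
                              mutant_fraction=0.4)
        records, _, _ = simulate_read_pairs(cfg)
        path = tmp_path / "r.sam"
        write_sam(records, snv_variant.chrom, cfg.reference_length, path)
        report = analyze_locus(read_sam(path), snv_variant)
        assert report["fragment_counts"][MUTANT] > 0
        assert report["rank_sum_less"]["p_value"] < 0.5  # mutants drawn shorter
        assert set(report["summaries"]) == {MUTANT, NON_MUTANT}
        import json

        json.dumps(report)  # must be JSON-serializable


class TestAlignmentRecordValidation:
    def test_cigar_seq_length_mismatch(self):
        with pytest.raises(ValueError):
            make_record(100, "10M", seq="ACGT")

    def test_malformed_cigar(self):
        with pytest.raises(ValueError):
            parse_cigar("12Q")

    def test_malformed_sam_line(self):
        with pytest.raises(ValueError):
            AlignmentRecord.from_sam_line("only\tthree\tfields")
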