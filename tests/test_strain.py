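"""aANI-lowFreq: shared-region masking, exclusive-SNV counting, distances,
calibration, replacement calls and the event-association table."""

import io

import numpy as np
import pandas as pd
import pytest

from longmeta.strain import (
    AlleleCounts,
    StrainConfig,
    aani_lowfreq,
    calibrate_between_patient,
    classify_interval,
    count_exclusive_snvs,
    event_association,
    make_interval_calls,
    pair_eligibility,
    read_allele_counts_tsv,
    shared_mask,
    write_allele_counts_tsv,
    IntervalCall,
)

CFG = StrainConfig()


def uniform_counts(sample, length=100, depth=20, base=0, contig="c0"):
    arr = np.zeros((length, 4), dtype=np.int64)
    arr[:, base] = depth
    return AlleleCounts(sample, {contig: arr})


class TestAlleleCounts:
    def test_depth_is_base_sum(self):
        a = uniform_counts("a", depth=20)
        assert (a.depth("c0") == 20).all()

    def test_tsv_round_trip(self):
        arr = np.zeros((50, 4), dtype=np.int64)
        rng = np.random.default_rng(0)
        arr[:, :] = rng.integers(0, 30, size=(50, 4))
        a = AlleleCounts("a", {"c0": arr})
        buf = io.StringIO()
        write_allele_counts_tsv(a, buf)
        buf.seek(0)
        b = read_allele_counts_tsv(buf, "a", {"c0": 50})
        assert (b.counts["c0"] == arr).all()

    def test_unknown_contig_rejected(self):
        tsv = "contig\tpos\tA\tC\tG\tT\nweird\t0\t5\t0\t0\t0\n"
        with pytest.raises(ValueError, match="weird"):
            read_allele_counts_tsv(io.StringIO(tsv), "a", {"c0": 10})


class TestSharedMask:
    def test_everything_covered(self):
        mask = shared_mask(uniform_counts("a"), uniform_counts("b"), CFG)
        assert mask.shared_length == 100
        assert mask.shared_fraction == 1.0

    def test_contig_below_80pct_contributes_nothing(self):
        # 70% of positions at 10x in a: whole contig disqualified.
        arr = np.zeros((100, 4), dtype=np.int64)
        arr[:70, 0] = 10
        arr[70:, 0] = 9
        a = AlleleCounts("a", {"c0": arr})
        mask = shared_mask(a, uniform_counts("b"), CFG)
        assert mask.shared_length == 0

    def test_single_low_position_dropped(self):
        arr = np.zeros((100, 4), dtype=np.int64)
        arr[:, 0] = 20
        arr[5, 0] = 9
        b = AlleleCounts("b", {"c0": arr})
        mask = shared_mask(uniform_counts("a"), b, CFG)
        assert mask.shared_length == 99
        assert not mask.masks["c0"][5]

    def test_contig_qualification_is_per_sample(self):
        # 85% coverage in a and 85% in b, but on disjoint position sets:
        # contig qualifies in both, positions shared only where both >= 10x.
        arr_a = np.zeros((100, 4), dtype=np.int64)
        arr_a[:85, 0] = 10
        arr_b = np.zeros((100, 4), dtype=np.int64)
        arr_b[15:, 0] = 10
        mask = shared_mask(
            AlleleCounts("a", {"c0": arr_a}),
            AlleleCounts("b", {"c0": arr_b}),
            CFG,
        )
        assert mask.shared_length == 70

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            shared_mask(
                uniform_counts("a", length=100),
                uniform_counts("b", length=90),
                CFG,
            )


def pair_with_snv(a_counts, b_counts, length=100):
    """Two samples at 20x, differing as specified at position 0."""
    arr_a = np.zeros((length, 4), dtype=np.int64)
    arr_a[:, 0] = 20
    arr_a[0] = a_counts
    arr_b = np.zeros((length, 4), dtype=np.int64)
    arr_b[:, 0] = 20
    arr_b[0] = b_counts
    return (
        AlleleCounts("a", {"c0": arr_a}),
        AlleleCounts("b", {"c0": arr_b}),
    )


class TestExclusiveSnvs:
    def count(self, a, b):
        return count_exclusive_snvs(a, b, shared_mask(a, b, CFG), CFG)

    def test_majority_in_a_absent_in_b_counted(self):
        # a: C at 12/20 (60%); b: C at 1/20 (5%).
        a, b = pair_with_snv([8, 12, 0, 0], [19, 1, 0, 0])
        assert self.count(a, b) == 1

    def test_insufficient_supporting_reads(self):
        # 60% frequency but only 9 supporting reads: not a majority call.
        a, b = pair_with_snv([6, 9, 0, 0], [15, 0, 0, 0])
        assert self.count(a, b) == 0

    def test_allele_at_10pct_in_b_not_exclusive(self):
        # b carries the allele at exactly 10%: "present", not exclusive.
        a, b = pair_with_snv([8, 12, 0, 0], [18, 2, 0, 0])
        assert self.count(a, b) == 0

    def test_tied_majorities_skipped(self):
        # Two bases at exactly 50% with 10 reads each: ambiguous, skipped.
        a, b = pair_with_snv([10, 10, 0, 0], [20, 0, 0, 0])
        assert self.count(a, b) == 0

    def test_identical_samples_zero(self):
        a = uniform_counts("a")
        assert self.count(a, a) == 0


class TestDistance:
    def test_identical_counts_zero_distance(self):
        a = uniform_counts("a")
        d = aani_lowfreq(a, a, CFG)
        assert d.aani_lowfreq == 0.0

    def test_arithmetic(self):
        # 3 exclusive SNVs over 30,000 shared bp -> 1e-4.
        length = 30_000
        arr_a = np.zeros((length, 4), dtype=np.int64)
        arr_a[:, 0] = 20
        arr_b = arr_a.copy()
        for pos in (10, 20, 30):
            arr_a[pos] = [0, 20, 0, 0]
        a = AlleleCounts("a", {"c0": arr_a})
        b = AlleleCounts("b", {"c0": arr_b})
        d = aani_lowfreq(a, b, CFG)
        assert d.exclusive_snvs == 3
        assert d.shared_length == length
        assert d.aani_lowfreq == pytest.approx(1e-4)

    def test_asymmetry(self):
        # Allele swap present only in a: a->b counts it, b->a does not.
        a, b = pair_with_snv([0, 20, 0, 0], [20, 0, 0, 0])
        assert aani_lowfreq(a, b, CFG).exclusive_snvs == 1
        assert aani_lowfreq(b, a, CFG).exclusive_snvs == 1
        a2, b2 = pair_with_snv([0, 20, 0, 0], [4, 16, 0, 0])
        # b2 still mostly carries a2's allele: nothing exclusive a->b,
        # and b2's 20% minority A allele is no majority either: b->a is 0.
        assert aani_lowfreq(a2, b2, CFG).exclusive_snvs == 0
        assert aani_lowfreq(b2, a2, CFG).exclusive_snvs == 0

    def test_zero_shared_gives_none_not_error(self):
        low = uniform_counts("a", depth=5)
        d = aani_lowfreq(low, low, CFG)
        assert d.shared_length == 0
        assert d.aani_lowfreq is None

    def test_scale_invariance_under_coverage_multiplication(self):
        a, b = pair_with_snv([8, 12, 0, 0], [19, 1, 0, 0])
        d1 = aani_lowfreq(a, b, CFG)
        a3 = AlleleCounts("a", {"c0": a.counts["c0"] * 3})
        b3 = AlleleCounts("b", {"c0": b.counts["c0"] * 3})
        d3 = aani_lowfreq(a3, b3, CFG)
        assert d1.aani_lowfreq == pytest.approx(d3.aani_lowfreq)


class TestEligibilityAndCalibration:
    @pytest.mark.parametrize(
        "fraction,eligible", [(0.49, False), (0.50, True), (1.0, True)]
    )
    def test_shared_core_boundary(self, fraction, eligible):
        from longmeta.strain import StrainDistance

        d = StrainDistance("a", "b", 0, 1000, fraction)
        assert pair_eligibility(d, CFG) is eligible

    def test_min_between_n_boundary(self):
        assert calibrate_between_patient([0.001] * 9, CFG) is None
        assert calibrate_between_patient([0.001] * 10, CFG) is not None

    def test_replacement_threshold_is_order_statistic(self):
        cal = calibrate_between_patient(
            [0.001 * (i + 1) for i in range(20)], CFG
        )
        # 5th percentile (method="lower") of 20 values is the 1st: 0.001.
        assert classify_interval(0.001, cal, CFG) is True
        assert classify_interval(0.0009, cal, CFG) is False
        assert classify_interval(1.0, cal, CFG) is True

    def test_uncalibrated_returns_none(self):
        assert classify_interval(0.5, None, CFG) is None


class TestEventAssociation:
    def make_call(self, repl, spans):
        return IntervalCall(
            patient="p", species="s", sample_a="a", sample_b="b",
            day_a=0, day_b=10, distance=0.01, replacement=repl,
            spans_event=spans, eligible=True,
        )

    def test_published_table(self):
        calls = (
            [self.make_call(True, True)] * 10
            + [self.make_call(True, False)] * 2
            + [self.make_call(False, True)] * 19
            + [self.make_call(False, False)] * 13
        )
        table, p = event_association(calls)
        assert table.tolist() == [[10, 2], [19, 13]]
        assert p == pytest.approx(0.17, abs=0.005)

    def test_degenerate_table(self):
        with pytest.warns(UserWarning):
            _, p = event_association([self.make_call(True, True)] * 5)
        assert p == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            event_association([])


class TestIntervalCalls:
    def test_planted_replacement_flagged(self):
        # Species with 12 between-patient distances ~0.01 and one patient
        # whose consecutive interval jumps into that range.
        from longmeta.strain import StrainDistance

        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(8)] + ["p1a", "p1b"],
                "patient": [f"q{i}" for i in range(8)] + ["P1", "P1"],
                "day": [0] * 8 + [0, 30],
            }
        )
        events = pd.DataFrame(
            {"patient": ["P1"], "day": [15], "event": ["alloHSCT"]}
        )
        between = [
            StrainDistance(f"s{i}", f"s{j}", 100, 10_000, 1.0)
            for i in range(8)
            for j in range(8)
            if i != j
        ][:12]
        within = [StrainDistance("p1a", "p1b", 120, 10_000, 1.0)]
        calls = make_interval_calls(
            {"speciesX": between + within}, meta, events, CFG
        )
        p1 = [c for c in calls if c.patient == "P1"]
        assert len(p1) == 1
        assert p1[0].replacement is True
        assert p1[0].spans_event is True

    def test_low_within_distance_not_replacement(self):
        from longmeta.strain import StrainDistance

        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(8)] + ["p1a", "p1b"],
                "patient": [f"q{i}" for i in range(8)] + ["P1", "P1"],
                "day": [0] * 8 + [0, 30],
            }
        )
        events = pd.DataFrame(columns=["patient", "day", "event"])
        between = [
            StrainDistance(f"s{i}", f"s{j}", 100, 10_000, 1.0)
            for i in range(8)
            for j in range(8)
            if i != j
        ][:12]
        within = [StrainDistance("p1a", "p1b", 1, 10_000, 1.0)]
        calls = make_interval_calls(
            {"speciesX": between + within}, meta, events, CFG
        )
        p1 = [c for c in calls if c.patient == "P1"]
        assert p1[0].replacement is False
        assert p1[0].spans_event is False
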