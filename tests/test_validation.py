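"""The two-step mapping-based validation: 70/70 read rule, >=20% taxon rule,
seeded subsampling, and the brute-force coverage oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longmeta.alignments import AlignmentRecord
from longmeta.synth import SynthConfig, make_mock_community
from longmeta.taxonomy import ReadAssignment
from longmeta.validation import (
    ValidationConfig,
    covered_query_length,
    read_validated,
    subsample_assignments,
    validate_sample,
    validate_taxon,
)

CFG = ValidationConfig(seed=7)


def aln(start, end, identity, length=1000, target="g1"):
    block = end - start
    return AlignmentRecord(
        query_id="r",
        query_length=length,
        query_start=start,
        query_end=end,
        target_id=target,
        matches=int(round(identity * block)),
        block_length=block,
    )


class TestReadValidated:
    def test_boundary_of_both_rules(self):
        # 70% of the read covered at exactly 70% identity: validated.
        assert read_validated(1000, [aln(0, 700, 0.70)], CFG)

    def test_coverage_one_below_boundary(self):
        assert not read_validated(1000, [aln(0, 699, 1.0)], CFG)

    def test_identity_below_boundary_excluded(self):
        assert not read_validated(1000, [aln(0, 1000, 0.689)], CFG)

    def test_union_of_overlapping_alignments(self):
        # [0,400) + [300,750) union to 750 >= 700.
        assert read_validated(
            1000, [aln(0, 400, 0.9), aln(300, 750, 0.8)], CFG
        )

    def test_no_alignments(self):
        assert not read_validated(1000, [], CFG)

    @given(
        spans=st.lists(
            st.tuples(
                st.integers(0, 180), st.integers(1, 60), st.booleans()
            ),
            max_size=8,
        )
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_union_matches_per_base_oracle(self, spans):
        # Oracle: mark covered bases one by one, as a bitmap.
        length = 240
        alns = []
        bitmap = np.zeros(length, dtype=bool)
        for start, width, good in spans:
            end = min(start + width, length)
            if end <= start:
                continue
            identity = 0.9 if good else 0.5
            alns.append(aln(start, end, identity, length=length))
            if good:
                bitmap[start:end] = True
        assert covered_query_length(alns, CFG.min_identity) == bitmap.sum()
        assert read_validated(length, alns, CFG) == (
            bitmap.sum() >= 0.7 * length
        )


class TestSubsampling:
    def reads(self, n):
        return [ReadAssignment(f"r{i}", True, 562, 500) for i in range(n)]

    def test_small_sample_fully_retained(self):
        got = subsample_assignments(self.reads(500), CFG)
        assert len(got) == 500

    def test_large_sample_truncated(self):
        cfg = ValidationConfig(subsample_size=1000, seed=1)
        got = subsample_assignments(self.reads(5000), cfg)
        assert len(got) == 1000
        assert len({a.read_id for a in got}) == 1000

    def test_deterministic_given_seed(self):
        cfg = ValidationConfig(subsample_size=100, seed=9)
        a = subsample_assignments(self.reads(1000), cfg)
        b = subsample_assignments(self.reads(1000), cfg)
        assert a == b


class TestValidateTaxon:
    def _fixture(self, tree, n_pass, n_fail):
        reads = [
            ReadAssignment(f"p{i}", True, 562, 1000) for i in range(n_pass)
        ] + [
            ReadAssignment(f"f{i}", True, 562, 1000) for i in range(n_fail)
        ]
        alns = {f"p{i}": [aln(0, 1000, 0.95)] for i in range(n_pass)}
        return reads, alns

    def test_rate_at_20_percent_boundary_validates(self, ncbi_tree):
        reads, alns = self._fixture(ncbi_tree, 2, 8)
        res = validate_taxon(ncbi_tree, 562, reads, alns, CFG)
        assert res.rate == pytest.approx(0.2)
        assert res.validated

    def test_rate_below_boundary_rejects(self, ncbi_tree):
        reads, alns = self._fixture(ncbi_tree, 1, 9)
        res = validate_taxon(ncbi_tree, 562, reads, alns, CFG)
        assert res.rate == pytest.approx(0.1)
        assert not res.validated

    def test_zero_sampled_reads_flagged(self, ncbi_tree):
        res = validate_taxon(ncbi_tree, 562, [], {}, CFG)
        assert not res.validated
        assert res.rate == 0.0
        assert "no-sampled-reads" in res.flags

    def test_genus_pools_species_reads(self, ncbi_tree):
        # Reads of two Escherichia/Shigella species pool under the genus.
        reads = [
            ReadAssignment("a", True, 562, 1000),
            ReadAssignment("b", True, 621, 1000),
        ]
        alns = {"a": [aln(0, 1000, 0.95)], "b": [aln(0, 1000, 0.95)]}
        res = validate_taxon(ncbi_tree, 561, reads, alns, CFG)
        assert res.n_sampled == 2
        assert res.rate == 1.0


class TestValidateSample:
    def test_synthetic_ground_truth(self):
        # 6 true species plus misassigned reads landing on 2 decoys:
        # decoys carry no alignment evidence and must be rejected.
        cfg = SynthConfig(
            seed=11,
            n_species=6,
            n_decoy_species=2,
            n_reads=3000,
            genome_length=20_000,
            misassignment_rate=0.03,
        )
        fix = make_mock_community(cfg)
        results = validate_sample(
            fix.tree,
            fix.sample.assignments,
            fix.sample.alignments,
            ValidationConfig(seed=11),
            ranks=("species",),
            target_taxids=fix.sample.target_taxids,
        )
        by_taxid = {r.taxid: r for r in results}
        for s in range(6):
            assert by_taxid[1000 + s].validated
        for s in range(6, 8):
            if 1000 + s in by_taxid:
                assert not by_taxid[1000 + s].validated

    def test_all_perfect_alignments_rate_one(self, ncbi_tree):
        reads = [ReadAssignment(f"r{i}", True, 562, 1000) for i in range(10)]
        alns = {f"r{i}": [aln(0, 1000, 1.0)] for i in range(10)}
        results = validate_sample(
            ncbi_tree, reads, alns, CFG, ranks=("species",)
        )
        assert all(r.rate == 1.0 for r in results)

    def test_monotone_in_identity_threshold(self):
        cfg = SynthConfig(
            seed=3, n_species=4, n_decoy_species=0, n_reads=800,
            genome_length=10_000, long_read_error=0.25,
        )
        fix = make_mock_community(cfg)
        rates = {}
        for min_id in (0.9, 0.7, 0.5, 0.01):
            results = validate_sample(
                fix.tree,
                fix.sample.assignments,
                fix.sample.alignments,
                ValidationConfig(min_identity=min_id, seed=3),
                ranks=("species",),
                target_taxids=fix.sample.target_taxids,
            )
            rates[min_id] = {r.taxid: r.rate for r in results}
        # Loosening the identity threshold never lowers any rate.
        for lo, hi in [(0.7, 0.9), (0.5, 0.7), (0.01, 0.5)]:
            for taxid in rates[hi]:
                assert rates[lo][taxid] >= rates[hi][taxid]
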