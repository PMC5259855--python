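"""Whole-read orchestration: strands, pairing, SAM emission."""

import os
import tempfile

import numpy as np
import pysam
import pytest

from seedvote import (
    IndexParams,
    ReadRecord,
    ReferenceSet,
    VoteParams,
    build_index,
    map_pair,
    map_single,
    reverse_complement,
    sam_header,
    to_sam,
)
from seedvote.mapper import _is_proper, cigar_reference_span

from conftest import random_dna


@pytest.fixture(scope="module")
def dup_ref():
    """Reference with an exact 500 bp duplication (positions 1000 and 4000)."""
    r = np.random.default_rng(77)
    seq = random_dna(r, 6000)
    seq = seq[:4000] + seq[1000:1500] + seq[4500:]
    return ReferenceSet([("chr1", seq)])


@pytest.fixture(scope="module")
def dup_index(dup_ref):
    return build_index(dup_ref, IndexParams())


def parse_sam(text: str):
    fd, path = tempfile.mkstemp(suffix=".sam")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        with pysam.AlignmentFile(path, "r") as fh:
            return list(fh)
    finally:
        os.unlink(path)


class TestMapSingle:
    def test_planted_read_maps_at_origin_forward(self, small_ref, small_index):
        read = ReadRecord("r", small_ref.fetch(350, 150))
        res = map_single(read, small_index, VoteParams(), np.random.default_rng(0))
        assert res.mapped and res.ref_name == "chrA"
        assert (res.position, res.strand, res.cigar) == (351, "+", "150M")
        assert res.optimal == 15 and res.mapq == 60

    def test_reverse_complement_maps_same_origin(self, small_ref, small_index):
        fwd = small_ref.fetch(350, 150)
        res = map_single(
            ReadRecord("r", reverse_complement(fwd)),
            small_index, VoteParams(), np.random.default_rng(0),
        )
        assert res.mapped and (res.position, res.strand) == (351, "-")

    def test_second_sequence_coordinates_are_local(self, small_ref, small_index):
        read = ReadRecord("r", small_ref.fetch(3200, 150))  # inside chrB
        res = map_single(read, small_index, VoteParams(), np.random.default_rng(0))
        assert res.ref_name == "chrB" and res.position == 201

    def test_duplicated_region_gets_mapq_zero(self, dup_ref, dup_index):
        read = ReadRecord("r", dup_ref.fetch(1100, 150))
        hits = set()
        for seed in range(20):
            res = map_single(read, dup_index, VoteParams(), np.random.default_rng(seed))
            assert res.mapped and res.tied and res.mapq == 0
            hits.add(res.position)
        assert hits <= {1101, 4101} and len(hits) == 2

    def test_read_shorter_than_seed_unmapped(self, small_index):
        res = map_single(
            ReadRecord("r", "ACGTACGTACGT"), small_index, VoteParams(),
            np.random.default_rng(0),
        )
        assert not res.mapped and res.reason == "read_shorter_than_seed"

    def test_foreign_read_unmapped(self, small_index, rng):
        res = map_single(
            ReadRecord("r", random_dna(np.random.default_rng(31337), 150)),
            small_index, VoteParams(), np.random.default_rng(0),
        )
        assert not res.mapped

    def test_strand_symmetry(self, small_ref, small_index):
        for start in (0, 777, 1500, 2849):
            fwd = small_ref.fetch(start, 150)
            a = map_single(ReadRecord("f", fwd), small_index, VoteParams(),
                           np.random.default_rng(0))
            b = map_single(ReadRecord("r", reverse_complement(fwd)), small_index,
                           VoteParams(), np.random.default_rng(0))
            assert a.position == b.position and a.strand != b.strand


class TestFastPathConsistency:
    def test_vectorized_tally_matches_scalar_collect_votes(self, small_ref, small_index, rng):
        """The mapper's uint64 Horner fast path must reproduce the scalar
        EncodedKmer voting path exactly, mutations and reverse strand included."""
        from seedvote import collect_votes, extract_seeds
        from seedvote.index import encode_sequence
        from seedvote.mapper import _revcomp_codes, _strand_tally

        for start in (0, 123, 1700, 2849):
            read = small_ref.fetch(start, 150)
            read = read[:50] + "N" + read[51:]  # ambiguity handled identically
            for codes, seq in (
                (encode_sequence(read), read),
                (_revcomp_codes(encode_sequence(read)), reverse_complement(read)),
            ):
                fast = _strand_tally(codes, small_index, VoteParams(), 150)
                slow = collect_votes(
                    extract_seeds(seq, 31), small_index, small_ref, VoteParams(), 150
                )
                assert fast == slow


class TestMapPair:
    def test_concordant_pair_proper_flags_and_tlen(self, small_ref, small_index):
        frag = small_ref.fetch(300, 450)
        r1 = ReadRecord("p", frag[:150], mate_index=1)
        r2 = ReadRecord("p", reverse_complement(frag[-150:]), mate_index=2)
        a1, a2 = map_pair(r1, r2, small_index, VoteParams(), np.random.default_rng(0))
        assert a1.mapped and a2.mapped
        assert (a1.position, a2.position) == (301, 601)
        assert a1.strand == "+" and a2.strand == "-"
        assert _is_proper(a1, a2, 1000)
        sam = (
            sam_header(small_ref)
            + to_sam(a1, r1, mate=a2, proper=True) + "\n"
            + to_sam(a2, r2, mate=a1, proper=True) + "\n"
        )
        recs = parse_sam(sam)
        assert recs[0].template_length == 450 and recs[1].template_length == -450
        assert recs[0].is_proper_pair and recs[1].is_read2

    def test_tied_mate_resolved_by_concordance(self, dup_ref, dup_index):
        # mate 1 unique (outside the duplication), mate 2 inside it: the copy
        # concordant with mate 1 must win over the random tie-break
        frag_start = 900
        r1 = ReadRecord("p", dup_ref.fetch(frag_start, 150), mate_index=1)
        r2 = ReadRecord(
            "p", reverse_complement(dup_ref.fetch(1150, 150)), mate_index=2
        )
        for seed in range(10):
            a1, a2 = map_pair(r1, r2, dup_index, VoteParams(),
                              np.random.default_rng(seed))
            assert a1.position == 901
            assert a2.position == 1151  # never the 4150 copy
            assert a2.tied and a2.mapq == 0

    def test_both_unmapped_pair_flags(self, small_index):
        junk1 = random_dna(np.random.default_rng(555), 150)
        junk2 = random_dna(np.random.default_rng(556), 150)
        r1 = ReadRecord("p", junk1, mate_index=1)
        r2 = ReadRecord("p", junk2, mate_index=2)
        a1, a2 = map_pair(r1, r2, small_index, VoteParams(), np.random.default_rng(0))
        line1 = to_sam(a1, r1, mate=a2)
        flag = int(line1.split("\t")[1])
        assert flag & 0x4 and flag & 0x8 and flag & 0x1


class TestToSam:
    def test_unmapped_conventions(self, small_index):
        read = ReadRecord("u", "ACGT" * 40)
        from seedvote.mapper import AlignmentResult

        res = AlignmentResult("u", mapped=False)
        fields = to_sam(res, read).split("\t")
        assert int(fields[1]) & 0x4
        assert fields[2] == "*" and fields[3] == "0" and fields[5] == "*"

    def test_reverse_strand_stores_reverse_complement(self, small_ref, small_index):
        fwd = small_ref.fetch(500, 150)
        read = ReadRecord("r", reverse_complement(fwd), qualities="I" * 150)
        res = map_single(read, small_index, VoteParams(), np.random.default_rng(0))
        fields = to_sam(res, read).split("\t")
        assert int(fields[1]) & 0x10
        assert fields[9] == fwd  # reverse-complemented back to forward strand

    def test_records_parse_and_validate_against_header(self, small_ref, small_index):
        rng = np.random.default_rng(8)
        lines = [sam_header(small_ref, "test")]
        reads = []
        for i in range(20):
            start = int(rng.integers(0, 2850))
            read = ReadRecord(f"r{i}", small_ref.fetch(start, 150))
            res = map_single(read, small_index, VoteParams(), rng)
            lines.append(to_sam(res, read) + "\n")
            reads.append(read)
        recs = parse_sam("".join(lines))
        assert len(recs) == 20  # every read appears exactly once
        assert sorted(r.query_name for r in recs) == sorted(r.name for r in reads)
        for rec in recs:
            assert not rec.is_unmapped
            assert 1 <= rec.reference_start + 1 <= 3000
            span = cigar_reference_span(rec.cigarstring)
            assert rec.reference_start + span <= 3000
            assert rec.get_tag("ZO") >= 2
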