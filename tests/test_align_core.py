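"""Mapper correctness against the exact Smith-Waterman oracle, read
filters, and SAM round-trips."""

import numpy as np
import pytest

from tdnascope.align_core import (
    IndexedReference,
    filter_long_reads,
    filter_short_reads,
    map_read,
    map_read_pair,
    mean_quality,
    read_fastq,
    read_sam,
    smith_waterman_score,
    write_sam,
)
from tdnascope.models import revcomp
from tdnascope.simgen import HostGenomeSpec, build_host_genome


def _qual(mean_q: float, n: int = 150) -> str:
    return chr(int(round(mean_q)) + 33) * n


class TestReadFilters:
    def test_pair_dropped_when_one_mate_low(self):
        lo = ("r1/1", "A" * 150, _qual(19))
        hi = ("r1/2", "A" * 150, _qual(35))
        kept, dropped = filter_short_reads([(lo, hi)], min_q=20)
        assert kept == [] and dropped == 1

    def test_high_quality_pass_through(self):
        pairs = [
            (("a/1", "ACGT", _qual(40, 4)), ("a/2", "ACGT", _qual(40, 4))),
            (("b/1", "ACGT", _qual(40, 4)), ("b/2", "ACGT", _qual(40, 4))),
        ]
        kept, dropped = filter_short_reads(pairs, min_q=20)
        assert kept == pairs and dropped == 0

    def test_survivors_match_recount_oracle(self):
        rng = np.random.default_rng(1)
        pairs = []
        for i in range(200):
            q1, q2 = rng.uniform(10, 40, size=2)
            pairs.append(
                (
                    (f"p{i}/1", "A" * 50, _qual(q1, 50)),
                    (f"p{i}/2", "A" * 50, _qual(q2, 50)),
                )
            )
        kept, dropped = filter_short_reads(pairs, min_q=25)
        expected = [
            p
            for p in pairs
            if mean_quality(p[0][2]) >= 25 and mean_quality(p[1][2]) >= 25
        ]
        assert kept == expected and dropped == len(pairs) - len(expected)

    def test_long_read_length_boundary(self):
        reads = [("a", "A" * 499, "I" * 499), ("b", "A" * 500, "I" * 500)]
        kept, dropped = filter_long_reads(reads, 500)
        assert [r[0] for r in kept] == ["b"] and dropped == 1

    def test_malformed_fastq_reports_record(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\nIIII\n")
        with pytest.raises(ValueError, match="record"):
            read_fastq(path)


@pytest.fixture(scope="module")
def small_ref():
    host = build_host_genome(HostGenomeSpec({"chrA": 20000, "chrB": 8000}, seed=17))
    return host, IndexedReference(dict(host.sequences), k=15)


class TestMapRead:
    def test_exact_substring(self, small_ref):
        host, index = small_ref
        read = host.fetch("chrA", 1001, 1300)
        recs = map_read(index, "r", read)
        assert len(recs) == 1
        r = recs[0]
        assert (r.target, r.target_start, r.target_end, r.strand) == (
            "chrA", 1001, 1300, "+",
        )
        assert r.identity == 1.0 and r.is_primary

    def test_strand_symmetry(self, small_ref):
        host, index = small_ref
        read = host.fetch("chrA", 1001, 1300)
        fwd = map_read(index, "r", read)[0]
        rev = map_read(index, "r", revcomp(read))[0]
        assert (rev.target_start, rev.target_end) == (
            fwd.target_start, fwd.target_end,
        )
        assert {fwd.strand, rev.strand} == {"+", "-"}

    def test_empty_read_rejected(self, small_ref):
        _, index = small_ref
        with pytest.raises(ValueError, match="empty"):
            map_read(index, "r", "")

    def test_split_read_two_targets(self, small_ref):
        host, index = small_ref
        read = host.fetch("chrA", 5001, 5100) + host.fetch("chrB", 3001, 3100)
        recs = map_read(index, "r", read)
        by_target = {r.target: r for r in recs}
        assert set(by_target) == {"chrA", "chrB"}
        # chance microhomology may shift the split point by a base or two
        a, b = by_target["chrA"], by_target["chrB"]
        assert a.query_start == 1 and abs(a.query_end - 100) <= 2
        assert abs(b.query_start - 101) <= 2 and b.query_end == 200

    def test_concordant_and_discordant_pairs(self, small_ref):
        host, index = small_ref
        m1 = host.fetch("chrA", 2001, 2150)
        m2 = revcomp(host.fetch("chrA", 2251, 2400))
        _, _, disc = map_read_pair(index, ("p/1", m1), ("p/2", m2))
        assert not disc
        m2b = revcomp(host.fetch("chrB", 1001, 1150))
        _, _, disc2 = map_read_pair(index, ("q/1", m1), ("q/2", m2b))
        assert disc2

    def test_primary_score_matches_smith_waterman_oracle(self, small_ref):
        """>= 99% of random erroneous reads score exactly the SW optimum."""
        host, index = small_ref
        rng = np.random.default_rng(42)
        bases = "ACGT"
        agree = total = 0
        for _ in range(200):
            length = int(rng.integers(60, 201))
            start = int(rng.integers(1, 5000 - length))
            read = list(host.fetch("chrA", start, start + length - 1))
            for p in rng.choice(length, size=max(1, int(0.02 * length)), replace=False):
                read[p] = bases[(bases.index(read[p]) + int(rng.integers(1, 4))) % 4]
            read = "".join(read)
            if rng.random() < 0.5:
                read = revcomp(read)
            recs = map_read(index, "r", read)
            if not recs:
                continue
            oracle = max(
                smith_waterman_score(read, host.fetch("chrA", 1, 5200)),
                smith_waterman_score(revcomp(read), host.fetch("chrA", 1, 5200)),
            )
            total += 1
            if recs[0].score == oracle:
                agree += 1
        assert total >= 195
        assert agree / total >= 0.99

    def test_deterministic_output_order(self, small_ref):
        host, index = small_ref
        read = host.fetch("chrA", 5001, 5100) + host.fetch("chrB", 3001, 3100)
        a = [(r.target, r.target_start, r.score) for r in map_read(index, "r", read)]
        b = [(r.target, r.target_start, r.score) for r in map_read(index, "r", read)]
        assert a == b


class TestSamRoundTrip:
    def test_round_trip_preserves_fields(self, small_ref, tmp_path):
        host, index = small_ref
        read = host.fetch("chrA", 5001, 5100) + host.fetch("chrB", 3001, 3100)
        recs = map_read(index, "read1", read)
        path = tmp_path / "out.sam"
        write_sam(recs, dict(host.sequences), path, {"read1": read})
        back, seqs = read_sam(path)
        assert len(back) == len(recs)
        orig_sorted = sorted(recs, key=lambda r: r.query_start)
        back_sorted = sorted(back, key=lambda r: r.query_start)
        for o, b in zip(orig_sorted, back_sorted):
            assert (o.query_start, o.query_end) == (b.query_start, b.query_end)
            assert (o.target, o.target_start, o.target_end) == (
                b.target, b.target_start, b.target_end,
            )
            assert o.strand == b.strand and o.ops == b.ops
        assert seqs["read1"] == read

    def test_supplementary_flag(self, small_ref, tmp_path):
        host, index = small_ref
        read = host.fetch("chrA", 5001, 5200) + host.fetch("chrB", 3001, 3100)
        recs = map_read(index, "read1", read)
        path = tmp_path / "out.sam"
        write_sam(recs, dict(host.sequences), path, {"read1": read})
        flags = [
            int(line.split("\t")[1])
            for line in path.read_text().splitlines()
            if not line.startswith("@")
        ]
        assert any(f & 2048 for f in flags)
        assert sum(1 for f in flags if not f & 2048) == 1

    def test_external_mapper_soft_clipped_fixture(self, tmp_path):
        """A hand-built two-line SAM from an external split-read mapper
        parses into one host and one vector record for the same read."""
        sam = (
            "@HD\tVN:1.6\n"
            "@SQ\tSN:chr1\tLN:1000\n"
            "@SQ\tSN:vec\tLN:500\n"
            "r1\t0\tchr1\t101\t60\t80M70S\t*\t0\t0\t" + "A" * 150 + "\t*\tNM:i:2\n"
            "r1\t2048\tvec\t201\t60\t80S70M\t*\t0\t0\t" + "A" * 150 + "\t*\tNM:i:0\n"
        )
        path = tmp_path / "ext.sam"
        path.write_text(sam)
        records, _ = read_sam(path)
        assert len(records) == 2
        host, vec = records
        assert (host.target, host.query_start, host.query_end) == ("chr1", 1, 80)
        assert (vec.target, vec.query_start, vec.query_end) == ("vec", 81, 150)
        assert host.identity == pytest.approx(78 / 80)
        assert not vec.is_primary
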