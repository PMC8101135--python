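"""Generator correctness: determinism, splice arithmetic, read models."""

import numpy as np
import pytest

from tdnascope.models import Genome, IntegrationEvent, SVEvent, revcomp
from tdnascope.simgen import (
    HostGenomeSpec,
    LongReadSimParams,
    ShortReadSimParams,
    apply_background_svs,
    build_host_genome,
    build_transgenic_haplotype,
    insert_sequence,
    pb29_preset,
    simulate_long_reads,
    simulate_short_reads,
    write_fasta,
    write_gff3,
)
from conftest import small_construct


class TestHostGenome:
    def test_seed_determinism(self):
        spec = HostGenomeSpec({"c1": 1000}, seed=7)
        assert build_host_genome(spec).sequences == build_host_genome(spec).sequences

    def test_degenerate_gc(self):
        g = build_host_genome(HostGenomeSpec({"c1": 500}, gc=1.0, seed=1))
        assert set(g["c1"]) <= {"G", "C"}

    def test_length_bookkeeping(self):
        g = build_host_genome(HostGenomeSpec({"a": 150000, "b": 150000}, seed=2))
        assert len(g.names()) == 2 and g.total_length == 300000

    def test_overlapping_genes_rejected(self):
        from tdnascope.models import GeneModel

        genes = [
            GeneModel("g1", "c1", 100, 500, "+"),
            GeneModel("g2", "c1", 400, 900, "+"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            build_host_genome(HostGenomeSpec({"c1": 1000}, seed=1, genes=genes))


def _brute_force_haplotype(host_seq, construct, ev):
    """Independent string-splice oracle for the transgenic haplotype."""
    unit = construct.sequence[ev.lb_trunc : construct.length - ev.rb_trunc]
    for name in sorted(ev.deleted_features):
        f = construct.feature(name)
        seg = construct.sequence[f.start - 1 : f.end]
        unit = unit.replace(seg, "")
    block = "".join(unit if o == "forward" else revcomp(unit) for o in ev.copies)
    ins = ev.filler_left + block + ev.filler_right
    return host_seq[: ev.del_start - 1] + ins + host_seq[ev.del_end :]


class TestTransgenicHaplotype:
    def test_length_additivity_no_deletion(self):
        rng = np.random.default_rng(0)
        construct = small_construct(rng, length=5000)
        host = build_host_genome(HostGenomeSpec({"c1": 10000}, seed=3))
        ev = IntegrationEvent("c1", 6000, 5999, copies=["forward"])
        hap, _ = build_transgenic_haplotype(host, construct, ev)
        assert hap.length("c1") == 15000

    def test_pb29_event_a_insert_length(self, preset):
        ev = preset.events[0]
        L = preset.construct.length
        api = preset.construct.feature("35S-API-Nos")
        expected = L - 26 - 3 - (api.end - api.start + 1) + 24
        assert len(insert_sequence(preset.construct, ev)) == expected
        hap, truth = build_transgenic_haplotype(preset.host, preset.construct, ev)
        assert hap.length(ev.chrom) == preset.host.length(ev.chrom) - 33 + expected
        assert truth["deletion_width"] == 33

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_string_splice_oracle(self, seed):
        rng = np.random.default_rng(seed)
        construct = small_construct(rng)
        host = build_host_genome(HostGenomeSpec({"c1": 20000}, seed=seed))
        ds = int(rng.integers(5000, 9000))
        ev = IntegrationEvent(
            "c1",
            del_start=ds,
            del_end=ds + int(rng.integers(0, 30)) - 1,
            copies=["reverse" if rng.random() < 0.5 else "forward"],
            lb_trunc=int(rng.integers(0, 40)),
            rb_trunc=int(rng.integers(0, 40)),
            filler_left="ACGTAGGTCAAT",
            deleted_features=frozenset({"cassette"}),
        )
        hap, _ = build_transgenic_haplotype(host, construct, ev)
        assert hap["c1"] == _brute_force_haplotype(host["c1"], construct, ev)

    def test_deleted_feature_in_truncated_region_rejected(self):
        rng = np.random.default_rng(5)
        construct = small_construct(rng)
        host = build_host_genome(HostGenomeSpec({"c1": 10000}, seed=5))
        ev = IntegrationEvent(
            "c1", 5000, 5000, lb_trunc=1500,  # LB truncation eats into cassette
            deleted_features=frozenset({"cassette"}),
        )
        with pytest.raises(ValueError, match="truncated border"):
            build_transgenic_haplotype(host, construct, ev)

    def test_length_conservation_property(self):
        """Closed-form haplotype length for 100 random events."""
        rng = np.random.default_rng(99)
        construct = small_construct(rng)
        host = build_host_genome(HostGenomeSpec({"c1": 30000}, seed=99))
        L = construct.length
        cass = construct.feature("cassette")
        for _ in range(100):
            lb, rb = int(rng.integers(0, 100)), int(rng.integers(0, 100))
            width = int(rng.integers(0, 60))
            ds = int(rng.integers(1000, 20000))
            copies = ["forward", "reverse"][: int(rng.integers(1, 3))]
            excised = rng.random() < 0.5
            ev = IntegrationEvent(
                "c1", ds, ds + width - 1, copies=copies, lb_trunc=lb, rb_trunc=rb,
                filler_left="A" * int(rng.integers(0, 30)),
                filler_right="C" * int(rng.integers(0, 30)),
                deleted_features=frozenset({"cassette"}) if excised else frozenset(),
            )
            feat_len = (cass.end - cass.start + 1) if excised else 0
            unit_len = L - lb - rb - feat_len
            expected = (
                host.length("c1") - width + len(copies) * unit_len
                + len(ev.filler_left) + len(ev.filler_right)
            )
            hap, _ = build_transgenic_haplotype(host, construct, ev)
            assert hap.length("c1") == expected


class TestBackgroundSvs:
    def test_empty_is_identity(self):
        host = build_host_genome(HostGenomeSpec({"c1": 5000}, seed=1))
        assert apply_background_svs(host, []).sequences == host.sequences

    def test_deletion_conserves_length(self):
        host = build_host_genome(HostGenomeSpec({"c1": 20000}, seed=1))
        out = apply_background_svs(host, [SVEvent("DEL", "c1", 5000, 9999, 5000)])
        assert out.length("c1") == 15000

    def test_del_plus_inv_matches_string_oracle(self):
        host = build_host_genome(HostGenomeSpec({"c1": 20000}, seed=4))
        s = host["c1"]
        svs = [
            SVEvent("DEL", "c1", 2000, 2999, 1000),
            SVEvent("INV", "c1", 8000, 8999, 1000),
        ]
        out = apply_background_svs(host, svs)
        expected = (
            s[:1999] + s[2999:7999] + revcomp(s[7999:8999]) + s[8999:]
        )
        assert out["c1"] == expected

    def test_overlapping_svs_rejected(self):
        host = build_host_genome(HostGenomeSpec({"c1": 20000}, seed=4))
        svs = [
            SVEvent("DEL", "c1", 2000, 2999, 1000),
            SVEvent("INV", "c1", 2500, 3500, 1001),
        ]
        with pytest.raises(ValueError, match="overlap"):
            apply_background_svs(host, svs)


class TestShortReads:
    def test_coverage_and_pairing(self):
        host = build_host_genome(HostGenomeSpec({"c1": 100000}, seed=6))
        sim = simulate_short_reads(
            [(host, 1.0)], ShortReadSimParams(seed=1, coverage=30.0, sub_rate=0.0)
        )
        assert abs(len(sim.reads) - 20000) <= 2000
        for m1, m2 in sim.pairs()[:50]:
            t1, t2 = sim.truth[m1[0]], sim.truth[m2[0]]
            assert {t1[4], t2[4]} == {"+", "-"}  # FR orientation

    def test_zero_noise_reads_are_substrings(self):
        host = build_host_genome(HostGenomeSpec({"c1": 50000}, seed=6))
        sim = simulate_short_reads(
            [(host, 1.0)], ShortReadSimParams(seed=2, coverage=2.0, sub_rate=0.0)
        )
        for rid, seq, _ in sim.reads[:200]:
            assert seq in host["c1"] or revcomp(seq) in host["c1"]

    def test_observed_mismatch_fraction(self):
        host = build_host_genome(HostGenomeSpec({"c1": 100000}, seed=6))
        sim = simulate_short_reads(
            [(host, 1.0)], ShortReadSimParams(seed=3, coverage=10.0, sub_rate=0.01)
        )
        mism = total = 0
        for rid, seq, _ in sim.reads:
            _, chrom, s, e, strand = sim.truth[rid]
            truth = host.fetch(chrom, s, e)
            if strand == "-":
                truth = revcomp(truth)
            mism += sum(a != b for a, b in zip(seq, truth))
            total += len(seq)
        assert abs(mism / total - 0.01) < 0.002

    def test_fragment_mean_below_read_length_rejected(self):
        with pytest.raises(ValueError):
            ShortReadSimParams(read_length=150, fragment_mean=100.0)


class TestLongReads:
    def test_floor_and_tally(self):
        host = build_host_genome(HostGenomeSpec({"c1": 100000}, seed=8))
        sim = simulate_long_reads(
            [(host, 1.0)],
            LongReadSimParams(
                seed=1, coverage=40.0, median_length=2000.0, sigma_log=0.8,
                min_length=500,
            ),
        )
        assert min(len(s) for _, s, _ in sim.reads) >= 500
        total = sum(len(s) for _, s, _ in sim.reads)
        assert abs(total / 100000 - 40.0) / 40.0 < 0.1

    def test_zero_noise_reads_are_substrings(self):
        host = build_host_genome(HostGenomeSpec({"c1": 60000}, seed=8))
        sim = simulate_long_reads(
            [(host, 1.0)],
            LongReadSimParams(seed=2, coverage=3.0, median_length=2000.0),
        )
        for rid, seq, _ in sim.reads:
            assert seq in host["c1"] or revcomp(seq) in host["c1"]


class TestPb29Preset:
    def test_two_events_orientations(self, preset):
        assert len(preset.events) == 2
        assert [e.copies for e in preset.events] == [["reverse"], ["forward"]]

    def test_truth_deletion_widths(self, preset):
        assert [e.deletion_width for e in preset.events] == [33, 27]

    def test_truncations_and_filler(self, preset):
        a, b = preset.events
        assert (a.lb_trunc, a.rb_trunc) == (26, 3)
        assert (b.lb_trunc, b.rb_trunc) == (35, 34)
        assert len(a.filler_right) == 24 and not a.filler_left
        assert not b.filler_left and not b.filler_right
        assert a.deleted_features == b.deleted_features == {"35S-API-Nos"}

    def test_byte_identical_outputs(self, preset, tmp_path):
        p2 = pb29_preset()
        for tag, p in (("a", preset), ("b", p2)):
            write_fasta(p.host, tmp_path / f"host_{tag}.fasta")
            write_gff3(p.genes, tmp_path / f"genes_{tag}.gff3")
        assert (tmp_path / "host_a.fasta").read_bytes() == (
            tmp_path / "host_b.fasta"
        ).read_bytes()
        assert (tmp_path / "genes_a.gff3").read_bytes() == (
            tmp_path / "genes_b.gff3"
        ).read_bytes()

    def test_triploid_design(self, preset):
        assert preset.design.ploidy == 3 and preset.design.carriers == 1
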