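"""In-silico PCR, zygosity, and gene-context annotation."""

import numpy as np
import pytest

from tdnascope.junction_caller import InsertionCall
from tdnascope.locus_utils import (
    PrimerPair,
    estimate_zygosity,
    find_disrupted_genes,
    find_neighbor_genes,
    insilico_pcr,
    load_gff3_genes,
)
from tdnascope.models import GeneModel, revcomp
from tdnascope.simgen import write_gff3


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _balanced_20mer(rng):
    while True:
        s = _random_seq(rng, 20)
        gc = (s.count("G") + s.count("C")) / 20
        if 0.4 <= gc <= 0.6:
            return s


class TestInsilicoPcr:
    def test_product_size_arithmetic(self):
        rng = np.random.default_rng(1)
        template = _random_seq(rng, 500)
        fwd = template[100:120]
        rev = revcomp(template[300:320])
        pair = PrimerPair(fwd, rev, "1", "locus-spanning")
        products = insilico_pcr({"t": template}, pair)
        assert len(products) == 1
        assert products[0].size == 220 and products[0].start == 101

    def test_junction_pair_silent_on_wildtype(self):
        rng = np.random.default_rng(2)
        host = _random_seq(rng, 2000)
        tdna = _random_seq(rng, 1000)
        pair = PrimerPair(
            host[500:520], revcomp(tdna[100:120]), "3", "left-junction"
        )
        assert insilico_pcr({"wt": host}, pair) == []
        transgenic = host[:1000] + tdna + host[1000:]
        assert len(insilico_pcr({"tg": transgenic}, pair)) == 1

    def test_matches_exhaustive_scan_oracle(self):
        """Product sets equal a naive all-positions scan on random
        templates, including multi-site and swapped-role bindings."""
        rng = np.random.default_rng(3)
        for trial in range(10):
            core = _random_seq(rng, 800)
            template = core + core[:300]  # repeated region -> multiple sites
            f = _balanced_20mer(rng) if trial % 2 else template[50:70]
            r = revcomp(template[200:220])
            pair = PrimerPair(f, r, "x", "locus-spanning")
            got = {
                (p.template_id, p.start, p.size)
                for p in insilico_pcr({"t": template}, pair, max_product=2000)
            }
            expected = set()
            for left, right in ((f, r), (r, f)):
                rc_right = revcomp(right)
                for i in range(len(template) - len(left) + 1):
                    if template[i : i + len(left)] != left:
                        continue
                    for j in range(len(template) - len(rc_right) + 1):
                        if template[j : j + len(rc_right)] != rc_right:
                            continue
                        size = j + len(rc_right) - i
                        if j >= i and len(left) <= size <= 2000:
                            expected.add(("t", i + 1, size))
            assert got == expected

    def test_degenerate_primer_rejected(self):
        with pytest.raises(ValueError):
            PrimerPair("ACGTNACGTACGTACGTACG", "ACGTACGTACGTACGTACGT", "1", "left-junction")

    def test_mismatch_budget_and_exact_3prime(self):
        rng = np.random.default_rng(4)
        template = _random_seq(rng, 400)
        fwd = list(template[100:120])
        fwd[0] = "ACGT"[("ACGT".index(fwd[0]) + 1) % 4]  # one 5' mismatch
        fwd = "".join(fwd)
        rev = revcomp(template[200:220])
        pair = PrimerPair(fwd, rev, "1", "left-junction")
        assert insilico_pcr({"t": template}, pair, max_mismatch=0) == []
        assert len(insilico_pcr({"t": template}, pair, max_mismatch=1)) == 1
        # a 3'-terminal mismatch is never tolerated
        bad3 = list(template[100:120])
        bad3[-1] = "ACGT"[("ACGT".index(bad3[-1]) + 1) % 4]
        pair3 = PrimerPair("".join(bad3), rev, "2", "left-junction")
        assert insilico_pcr({"t": template}, pair3, max_mismatch=2) == []


TABLE1_GENES = [
    GeneModel("LOC112326972", "Chr03", 9261716, 9274439, "+",
              exons=[(9261716, 9274439)]),
    GeneModel("LOC7475699", "Chr03", 9292074, 9294391, "+",
              exons=[(9292074, 9294391)]),
    GeneModel("LOC7478355", "Chr03", 9283876, 9291377, "+",
              exons=[(9283876, 9284500), (9290000, 9291377)]),
    GeneModel("LOC7498060", "Chr10", 10848741, 10853156, "+",
              exons=[(10848741, 10853156)]),
    GeneModel("LOC7498061", "Chr10", 10870346, 10873516, "+",
              exons=[(10870346, 10873516)]),
    GeneModel("LOC7498062", "Chr10", 10880717, 10883716, "+",
              exons=[(10880717, 10883716)]),
]

CALL_CHR03 = InsertionCall("Chr03", 9283905, 9283937, "reverse")
CALL_CHR10 = InsertionCall("Chr10", 10868777, 10868803, "forward")


class TestGeneContext:
    def test_published_neighbor_distances(self):
        n03 = find_neighbor_genes(TABLE1_GENES, CALL_CHR03, window=20000)
        n10 = find_neighbor_genes(TABLE1_GENES, CALL_CHR10, window=20000)
        d = {n.gene_id: n.distance for n in n03 + n10}
        assert d == {
            "LOC112326972": 9466,
            "LOC7475699": 8137,
            "LOC7498060": 15621,
            "LOC7498061": 1543,
            "LOC7498062": 11914,
        }

    def test_relations_match_published_table(self):
        n03 = {n.gene_id: n for n in find_neighbor_genes(TABLE1_GENES, CALL_CHR03)}
        assert n03["LOC112326972"].relation == "upstream"
        assert n03["LOC7475699"].relation == "downstream"
        # the insertion sits upstream of the downstream genes in their own frame
        n10 = {n.gene_id: n for n in find_neighbor_genes(TABLE1_GENES, CALL_CHR10)}
        assert n10["LOC7498061"].insertion_relative == "upstream"

    def test_window_boundary_exclusive(self):
        gene = GeneModel("far", "Chr03", 9283937 + 20001, 9283937 + 25000, "+")
        near = GeneModel("near", "Chr03", 9283937 + 20000, 9283937 + 25000, "+")
        assert find_neighbor_genes([gene], CALL_CHR03, 20000) == []
        assert len(find_neighbor_genes([near], CALL_CHR03, 20000)) == 1

    def test_disrupted_first_exon(self):
        out = find_disrupted_genes(TABLE1_GENES, CALL_CHR03)
        assert len(out) == 1
        gene, feature = out[0]
        assert gene.gene_id == "LOC7478355" and feature == "exon 1"

    def test_no_overlap_no_disruption(self):
        assert find_disrupted_genes(TABLE1_GENES, CALL_CHR10) == []

    def test_intron_insertion_reported(self):
        gene = GeneModel(
            "g3x", "c", 1000, 5000, "+",
            exons=[(1000, 1500), (2500, 3000), (4500, 5000)],
        )
        call = InsertionCall("c", 2000, 2010, "forward")
        ((_, feature),) = find_disrupted_genes([gene], call)
        assert feature == "intron"

    def test_minus_strand_exon_ordinal(self):
        gene = GeneModel(
            "gneg", "c", 1000, 5000, "-",
            exons=[(1000, 1500), (4500, 5000)],
        )
        call = InsertionCall("c", 4600, 4620, "forward")
        ((_, feature),) = find_disrupted_genes([gene], call)
        assert feature == "exon 1"  # transcription starts at the 3' interval

    def test_gff3_round_trip(self, tmp_path):
        path = tmp_path / "genes.gff3"
        write_gff3(TABLE1_GENES, path)
        back = load_gff3_genes(path)
        assert {g.gene_id for g in back} == {g.gene_id for g in TABLE1_GENES}
        by_id = {g.gene_id: g for g in back}
        for g in TABLE1_GENES:
            assert (by_id[g.gene_id].start, by_id[g.gene_id].end) == (g.start, g.end)
            assert by_id[g.gene_id].exons == sorted(g.exons)


class TestZygosity:
    def _records(self, n_ref, n_split, chrom="c", site=5000):
        from tdnascope.models import AlignmentRecord

        recs = {}
        for i in range(n_ref):
            recs[f"ref{i}"] = [
                AlignmentRecord(f"ref{i}", 1, 2000, chrom, site - 1000,
                                site + 999, "+", 1.0, [("=", 2000)])
            ]
        for i in range(n_split):
            recs[f"split{i}"] = [
                AlignmentRecord(f"split{i}", 1, 1000, chrom, site - 1000,
                                site - 1, "+", 1.0, [("=", 1000)]),
                AlignmentRecord(f"split{i}", 7001, 8000, chrom, site,
                                site + 999, "+", 1.0, [("=", 1000)]),
            ]
        return recs

    def test_all_insert_reads(self):
        call = InsertionCall("c", 5000, 4999, "forward")
        frac, verdict = estimate_zygosity(call, self._records(0, 12))
        assert frac == 0.0 and verdict == "homozygous-insertion"

    def test_wildtype_sample(self):
        call = InsertionCall("c", 5000, 4999, "forward")
        frac, verdict = estimate_zygosity(call, self._records(15, 0))
        assert frac == 1.0 and verdict == "homozygous-reference"

    def test_no_spanning_reads_undetermined(self):
        call = InsertionCall("c", 5000, 4999, "forward")
        frac, verdict = estimate_zygosity(call, {})
        assert frac is None and verdict == "undetermined"

    def test_triploid_single_carrier(self):
        call = InsertionCall("c", 5000, 4999, "forward")
        frac, verdict = estimate_zygosity(call, self._records(20, 10))
        assert verdict == "heterozygous" and abs(frac - 2 / 3) < 0.01
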