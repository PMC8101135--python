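"""Synthetic transgenic-genome and read-set generation.

Emulates the study design behind Agrobacterium T-DNA integration
resequencing experiments: a host genome analog, a binary-vector T-DNA
construct, hemizygous single-copy insertions with border truncations,
target-site deletions, optional filler DNA and internally deleted cassette
features, shared background structural variants present in both the
wild-type and transgenic samples, and 150-bp paired-end short reads plus
long (Nanopore-like) reads at 30-40x coverage.

Everything is deterministic for a fixed seed; truth records carry every
planted breakpoint in both host and haplotype coordinates so downstream
callers can be scored exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .models import (
    Feature,
    GeneModel,
    Genome,
    IntegrationEvent,
    SVEvent,
    TDnaConstruct,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: name used for the vector record in combined references
VECTOR_NAME = "TDNA_vector"


# ---------------------------------------------------------------------------
# specs


@dataclass
class HostGenomeSpec:
    """Host genome analog: chromosome sizes, base composition, planted genes."""

    chromosomes: Dict[str, int]
    gc: float = 0.34
    seed: int = 0
    genes: List[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("GC fraction must be in [0,1]")
        for name, length in self.chromosomes.items():
            if length < 1:
                raise ValueError(f"chromosome {name}: length must be >= 1")
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
            if g.start < 1 or g.end > self.chromosomes[g.chrom]:
                raise ValueError(f"gene {g.gene_id}: outside chromosome")


@dataclass
class ShortReadSimParams:
    """Paired-end short-read simulation (substitution-only error model)."""

    read_length: int = 150
    fragment_mean: float = 300.0
    fragment_sd: float = 30.0
    coverage: float = 30.0
    sub_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0.0 <= self.sub_rate <= 0.3:
            raise ValueError("substitution rate must be in [0, 0.3]")
        if self.read_length > self.fragment_mean:
            raise ValueError("fragment mean must be >= read length")


@dataclass
class LongReadSimParams:
    """Single-end long-read simulation (substitutions + indels).

    Lengths are log-normal; reads below ``min_length`` are discarded,
    mirroring the standard pre-mapping length filter for Nanopore data.
    """

    median_length: float = 20000.0
    sigma_log: float = 0.4
    min_length: int = 500
    coverage: float = 40.0
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= r <= 0.3:
                raise ValueError("error rates must be in [0, 0.3]")


@dataclass
class SampleDesign:
    """Ploidy and haplotype composition of the sequenced samples."""

    ploidy: int = 3
    carriers: int = 1
    shared_svs: List[SVEvent] = field(default_factory=list)
    transgenic_only_svs: List[SVEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if not 1 <= self.carriers <= self.ploidy:
            raise ValueError("carrier haplotypes must be in [1, ploidy]")


@dataclass
class SimulatedReads:
    """Reads plus per-read truth: id -> (haplotype, chrom, start, end, strand)."""

    reads: List[Tuple[str, str, str]]
    truth: Dict[str, Tuple[str, str, int, int, str]]
    filtered_short: int = 0

    def pairs(self) -> List[Tuple[Tuple[str, str, str], Tuple[str, str, str]]]:
        if len(self.reads) % 2:
            raise ValueError("odd read count: not a paired set")
        return [
            (self.reads[i], self.reads[i + 1]) for i in range(0, len(self.reads), 2)
        ]


# ---------------------------------------------------------------------------
# genome construction


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = rng.choice(_BASES, size=length, p=p)
    return arr.tobytes().decode()


def build_host_genome(spec: HostGenomeSpec) -> Genome:
    """Generate the host genome analog described by ``spec``.

    Gene annotations are positional only (the underlying sequence is random);
    overlapping planted genes on one chromosome are rejected.
    """
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in spec.genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, genes in by_chrom.items():
        genes = sorted(genes, key=lambda g: g.start)
        for a, b in zip(genes, genes[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping planted genes {a.gene_id}/{b.gene_id} on {chrom}"
                )
    rng = np.random.default_rng(spec.seed)
    seqs = {
        name: _random_sequence(rng, length, spec.gc)
        for name, length in spec.chromosomes.items()
    }
    return Genome(seqs)


def _excised_unit(construct: TDnaConstruct, event: IntegrationEvent) -> str:
    """The forward-orientation inserted unit: truncated ends, features excised."""
    L = construct.length
    lo, hi = event.lb_trunc + 1, L - event.rb_trunc
    if hi < lo:
        raise ValueError("truncations consume the whole construct")
    cut: List[Tuple[int, int]] = []
    for name in sorted(event.deleted_features):
        f = construct.feature(name)
        if f.start < lo or f.end > hi:
            raise ValueError(
                f"deleted feature {name} overlaps a truncated border region"
            )
        cut.append((f.start, f.end))
    cut.sort()
    for a, b in zip(cut, cut[1:]):
        if b[0] <= a[1]:
            raise ValueError("deleted features overlap each other")
    parts, pos = [], lo
    for (s, e) in cut:
        parts.append(construct.sequence[pos - 1 : s - 1])
        pos = e + 1
    parts.append(construct.sequence[pos - 1 : hi])
    return "".join(parts)


def insert_sequence(construct: TDnaConstruct, event: IntegrationEvent) -> str:
    """Full inserted sequence on the host + strand (fillers + all copies)."""
    unit = _excised_unit(construct, event)
    copies = "".join(unit if o == "forward" else revcomp(unit) for o in event.copies)
    return event.filler_left + copies + event.filler_right


def _apply_edits(seq: str, edits: Sequence[Tuple[int, int, str]]) -> str:
    """Splice ``(start, end, replacement)`` edits (1-based inclusive, blunt =
    end == start-1) into ``seq``. Edits must not overlap; applied right to
    left so host coordinates stay valid throughout."""
    edits = sorted(edits, key=lambda e: e[0])
    for a, b in zip(edits, edits[1:]):
        if b[0] <= a[1]:
            raise ValueError(f"overlapping edits at {a[0]}-{a[1]} and {b[0]}-{b[1]}")
    out = seq
    for start, end, repl in reversed(edits):
        if start < 1 or end > len(seq):
            raise ValueError(f"edit {start}-{end} outside sequence")
        out = out[: start - 1] + repl + out[end:]
    return out


def _sv_edit(
    genome: Genome, sv: SVEvent, rng: np.random.Generator
) -> Tuple[int, int, str]:
    if sv.svtype == "DEL":
        return (sv.start, sv.end, "")
    if sv.svtype == "INS":
        return (sv.start, sv.start - 1, _random_sequence(rng, sv.length, 0.34))
    if sv.svtype == "INV":
        return (sv.start, sv.end, revcomp(genome.fetch(sv.chrom, sv.start, sv.end)))
    if sv.svtype == "DUP":
        return (sv.end + 1, sv.end, genome.fetch(sv.chrom, sv.start, sv.end))
    raise NotImplementedError(f"cannot plant SV of type {sv.svtype}")


def apply_background_svs(
    genome: Genome, svs: Sequence[SVEvent], seed: int = 0
) -> Genome:
    """Plant background SVs (DEL/INS/INV/DUP) into a genome copy."""
    rng = np.random.default_rng(seed)
    by_chrom: Dict[str, List[Tuple[int, int, str]]] = {}
    for sv in svs:
        by_chrom.setdefault(sv.chrom, []).append(_sv_edit(genome, sv, rng))
    seqs = dict(genome.sequences)
    for chrom, edits in by_chrom.items():
        seqs[chrom] = _apply_edits(seqs[chrom], edits)
    return Genome(seqs)


def build_transgenic_haplotype(
    genome: Genome, construct: TDnaConstruct, event: IntegrationEvent
) -> Tuple[Genome, Dict]:
    """Apply one integration event; return the haplotype and its truth record.

    haplotype = host[1..del_start-1] + filler_left + unit(s) + filler_right
    + host[del_end+1..]; the truth record stores all breakpoints in host and
    haplotype coordinates plus the host-(+)-oriented insert sequence.
    """
    if event.chrom not in genome:
        raise ValueError(f"unknown chromosome {event.chrom}")
    if event.del_end > genome.length(event.chrom):
        raise ValueError("deleted interval outside chromosome")
    ins = insert_sequence(construct, event)
    seqs = dict(genome.sequences)
    seqs[event.chrom] = _apply_edits(
        seqs[event.chrom], [(event.del_start, event.del_end, ins)]
    )
    truth = {
        "chrom": event.chrom,
        "del_start": event.del_start,
        "del_end": event.del_end,
        "deletion_width": event.deletion_width,
        "orientation": event.orientation,
        "copies": list(event.copies),
        "lb_trunc": event.lb_trunc,
        "rb_trunc": event.rb_trunc,
        "filler_left_len": len(event.filler_left),
        "filler_right_len": len(event.filler_right),
        "insert_seq": ins,
        "hap_insert_start": event.del_start,
        "hap_insert_end": event.del_start + len(ins) - 1,
        "left_flank_host_end": event.del_start - 1,
        "right_flank_host_start": event.del_end + 1,
    }
    return Genome(seqs), truth


def build_sample_genomes(
    host: Genome,
    construct: TDnaConstruct,
    events: Sequence[IntegrationEvent],
    design: SampleDesign,
    seed: int = 0,
) -> Tuple[List[Tuple[Genome, float]], List[Tuple[Genome, float]], List[Dict]]:
    """Build weighted haplotype sets for the wild-type and transgenic samples.

    Background SVs (shared between samples) and integration events are all
    expressed in host coordinates and spliced right-to-left in one pass, so
    planted truth stays in host coordinates. Returns
    ``(wildtype_haplotypes, transgenic_haplotypes, truth_records)`` where each
    haplotype list carries sampling weights encoding the ploidy design.
    """
    rng = np.random.default_rng(seed)
    wt = apply_background_svs(host, design.shared_svs, seed=seed)

    carrier_svs = list(design.shared_svs) + list(design.transgenic_only_svs)
    carrier = apply_background_svs(host, carrier_svs, seed=seed)
    truths = []
    for ev in events:
        for sv in carrier_svs:
            if sv.chrom == ev.chrom and not (
                sv.end < ev.del_start - 1 or sv.start > ev.del_end + 1
            ):
                raise ValueError("background SV overlaps an integration event")
        carrier, truth = build_transgenic_haplotype(carrier, construct, ev)
        truths.append(truth)

    wt_set = [(wt, 1.0)]
    w_carrier = design.carriers / design.ploidy
    tg_set = [(wt, 1.0 - w_carrier), (carrier, w_carrier)]
    return wt_set, tg_set, truths


# ---------------------------------------------------------------------------
# fillers


def generate_filler(
    rng: np.random.Generator,
    length: int,
    background: Iterable[str],
    k: int = 15,
    max_tries: int = 100,
) -> str:
    """A random sequence sharing no k-mer with any background sequence, so a
    planted filler is detectably of unknown origin."""
    forbidden = set()
    for seq in background:
        both = [seq, revcomp(seq)]
        for s in both:
            for i in range(len(s) - k + 1):
                forbidden.add(s[i : i + k])
    for _ in range(max_tries):
        cand = _random_sequence(rng, length, 0.5)
        kmers = {cand[i : i + k] for i in range(max(1, len(cand) - k + 1))}
        if not (kmers & forbidden):
            return cand
    raise RuntimeError("could not generate a background-free filler")


# ---------------------------------------------------------------------------
# read simulation


def _mutate_subs(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n = rng.binomial(len(arr), rate)
    if n == 0:
        return seq
    pos = rng.choice(len(arr), size=n, replace=False)
    shift = rng.integers(1, 4, size=n)
    idx = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}
    for p, s in zip(pos, shift):
        arr[p] = _BASES[(idx.get(arr[p].tobytes(), 0) + s) % 4]
    return arr.tobytes().decode()


def _mutate_indels(
    seq: str, sub: float, ins: float, dele: float, rng: np.random.Generator
) -> str:
    """Apply substitution/insertion/deletion errors (long-read model)."""
    if sub <= 0 and ins <= 0 and dele <= 0:
        return seq
    out = list(seq)
    n = len(out)
    n_sub = rng.binomial(n, sub) if sub > 0 else 0
    n_ins = rng.binomial(n, ins) if ins > 0 else 0
    n_del = rng.binomial(n, dele) if dele > 0 else 0
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    bases = "ACGT"
    if n_sub:
        for p in rng.choice(n, size=n_sub, replace=False):
            out[p] = bases[(idx.get(out[p], 0) + rng.integers(1, 4)) % 4]
    edits = [(int(p), "I") for p in rng.integers(0, n, size=n_ins)]
    edits += [(int(p), "D") for p in rng.integers(0, n, size=n_del)]
    for p, kind in sorted(edits, reverse=True):
        if kind == "I":
            out.insert(p, bases[rng.integers(0, 4)])
        elif out:
            del out[min(p, len(out) - 1)]
    return "".join(out)


def _check_weights(haplotypes: Sequence[Tuple[Genome, float]]) -> None:
    total = sum(w for _, w in haplotypes)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"haplotype weights must sum to 1 (got {total})")


def _qual_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else min(40, int(round(-10 * math.log10(error_rate))))
    return chr(q + 33)


def simulate_short_reads(
    haplotypes: Sequence[Tuple[Genome, float]], params: ShortReadSimParams
) -> SimulatedReads:
    """Paired-end reads from a weighted haplotype set.

    Coverage is relative to the weighted mean haplotype length, i.e. the
    per-locus sample depth summed over haplotypes. Mates are
    reverse-complement-oriented ends of one fragment (FR layout); read ids
    end in ``/1`` and ``/2`` and consecutive reads form a pair.
    """
    _check_weights(haplotypes)
    rng = np.random.default_rng(params.seed)
    rl = params.read_length
    mean_len = sum(w * h.total_length for h, w in haplotypes)
    n_pairs_total = int(round(params.coverage * mean_len / (2 * rl)))
    qual = _qual_char(params.sub_rate) * rl

    reads: List[Tuple[str, str, str]] = []
    truth: Dict[str, Tuple[str, str, int, int, str]] = {}
    serial = 0
    for hap_idx, (hap, w) in enumerate(haplotypes):
        n_pairs = int(round(w * n_pairs_total))
        chroms = hap.names()
        lens = np.array([hap.length(c) for c in chroms], dtype=float)
        chrom_p = lens / lens.sum()
        chrom_pick = rng.choice(len(chroms), size=n_pairs, p=chrom_p)
        frag_lens = np.maximum(
            rl, rng.normal(params.fragment_mean, params.fragment_sd, size=n_pairs)
        ).astype(int)
        flips = rng.random(size=n_pairs) < 0.5
        for ci, fl, flip in zip(chrom_pick, frag_lens, flips):
            chrom = chroms[ci]
            clen = hap.length(chrom)
            fl = min(fl, clen)
            start = int(rng.integers(1, clen - fl + 2))
            frag = hap.sequences[chrom][start - 1 : start - 1 + fl]
            r_fwd = frag[:rl]
            r_rev = revcomp(frag[-rl:])
            serial += 1
            base = f"sim{serial}_h{hap_idx}"
            if not flip:
                m1 = (r_fwd, chrom, start, start + rl - 1, "+")
                m2 = (r_rev, chrom, start + fl - rl, start + fl - 1, "-")
            else:
                m1 = (r_rev, chrom, start + fl - rl, start + fl - 1, "-")
                m2 = (r_fwd, chrom, start, start + rl - 1, "+")
            for mate, (seq, c, s, e, strand) in enumerate((m1, m2), start=1):
                rid = f"{base}/{mate}"
                reads.append((rid, _mutate_subs(seq, params.sub_rate, rng), qual))
                truth[rid] = (f"h{hap_idx}", c, s, e, strand)
    return SimulatedReads(reads, truth)


def simulate_long_reads(
    haplotypes: Sequence[Tuple[Genome, float]], params: LongReadSimParams
) -> SimulatedReads:
    """Single-end long reads with log-normal lengths and sub+indel errors.

    Draws below ``min_length`` are discarded (the post-basecalling length
    filter); discarded draws do not count toward coverage.
    """
    _check_weights(haplotypes)
    rng = np.random.default_rng(params.seed)
    mean_len = sum(w * h.total_length for h, w in haplotypes)
    target_bases = params.coverage * mean_len
    mu = math.log(params.median_length)
    err = params.sub_rate + params.ins_rate + params.del_rate
    qual_char = _qual_char(err)

    weights = np.array([w for _, w in haplotypes])
    reads: List[Tuple[str, str, str]] = []
    truth: Dict[str, Tuple[str, str, int, int, str]] = {}
    emitted_bases = 0
    serial = 0
    filtered = 0
    while emitted_bases < target_bases:
        hap_idx = int(rng.choice(len(weights), p=weights))
        hap, _ = haplotypes[hap_idx]
        length = int(rng.lognormal(mu, params.sigma_log))
        if length < params.min_length:
            filtered += 1
            continue
        chroms = hap.names()
        lens = np.array([hap.length(c) for c in chroms], dtype=float)
        ci = int(rng.choice(len(chroms), p=lens / lens.sum()))
        chrom = chroms[ci]
        clen = hap.length(chrom)
        length = min(length, clen)
        start = int(rng.integers(1, clen - length + 2))
        seq = hap.sequences[chrom][start - 1 : start - 1 + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        serial += 1
        rid = f"lsim{serial}_h{hap_idx}"
        seq = _mutate_indels(
            seq, params.sub_rate, params.ins_rate, params.del_rate, rng
        )
        reads.append((rid, seq, qual_char * len(seq)))
        truth[rid] = (f"h{hap_idx}", chrom, start, start + length - 1, strand)
        emitted_bases += length
    return SimulatedReads(reads, truth, filtered_short=filtered)


# ---------------------------------------------------------------------------
# file output


def write_fasta(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(reads: Sequence[Tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tsimgen\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(sorted(g.exons), start=1):
                fh.write(
                    f"{g.chrom}\tsimgen\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def write_truth_json(truths: Sequence[Dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(truths, fh, indent=2)
        fh.write("\n")


def write_truth_bed(truths: Sequence[Dict], path) -> None:
    """Breakpoints as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for t in truths:
            fh.write(
                f"{t['chrom']}\t{t['del_start'] - 1}\t{max(t['del_end'], t['del_start'] - 1)}"
                f"\ttdna_insertion_{t['orientation']}\n"
            )


# ---------------------------------------------------------------------------
# the pb29 preset


@dataclass
class Pb29Preset:
    host_spec: HostGenomeSpec
    construct: TDnaConstruct
    events: List[IntegrationEvent]
    design: SampleDesign
    genes: List[GeneModel]
    host: Genome


PRESET_SEED = 741  # fixed: the preset's planted truth never varies

#: construct geometry used by the preset (bp)
PRESET_TDNA_LENGTH = 8000


def _no_positive_prefix(read_bases: str, target_bases: str) -> bool:
    """True when extending an alignment along these base pairs can never
    gain score (match +1, mismatch -2): every prefix sum stays <= 0."""
    s = 0
    for a, b in zip(read_bases, target_bases):
        s += 1 if a == b else -2
        if s > 0:
            return False
        if s < -6:  # cannot recover past this under +1/-2
            return True
    return True


def _clean_site(
    host_seq: str, start0: int, width: int, insert: str, window: int = 50
) -> int:
    """First del_start >= start0 whose junctions carry no microhomology.

    A junction is ambiguous when flank alignments can gain score by
    extending into the inserted sequence (chance base matches at the
    junction); the planted breakpoint is then not observable by any
    aligner. The preset avoids such sites so its truth is exactly
    recoverable.
    """
    for ds in range(start0, start0 + 1000):
        de = ds + width - 1
        left_ok = _no_positive_prefix(
            insert[:window], host_seq[ds - 1 : ds - 1 + window]
        )
        right_ok = _no_positive_prefix(
            insert[::-1][:window], host_seq[max(0, de - window) : de][::-1]
        )
        if left_ok and right_ok:
            return ds
    raise RuntimeError("no clean insertion site found")


def _preset_genes(a_start, a_end, b_start, b_end) -> List[GeneModel]:
    # Neighbor genes sit at the boundary-gap distances reported for the real
    # line (9466/8137 bp around the Chr03 site; 15621/1543/11914 bp around
    # the Chr10 site), and one TAF12-analog gene has its first exon across
    # the Chr03 site.
    taf_start = a_start - 29  # first exon runs across the insertion site
    return [
        GeneModel("g03.up1", "Chr03", a_start - 12466, a_start - 9466, "+",
                  exons=[(a_start - 12466, a_start - 9466)]),
        GeneModel("g03.taf12", "Chr03", taf_start, taf_start + 7501, "+",
                  exons=[(taf_start, a_end + 200),
                         (taf_start + 5000, taf_start + 5400),
                         (taf_start + 7000, taf_start + 7501)]),
        GeneModel("g03.down1", "Chr03", a_end + 8137, a_end + 10437, "-",
                  exons=[(a_end + 8137, a_end + 10437)]),
        GeneModel("g10.up1", "Chr10", b_start - 18621, b_start - 15621, "-",
                  exons=[(b_start - 18621, b_start - 15621)]),
        GeneModel("g10.down1", "Chr10", b_end + 1543, b_end + 4543, "+",
                  exons=[(b_end + 1543, b_end + 4543)]),
        GeneModel("g10.down2", "Chr10", b_end + 11914, b_end + 14914, "+",
                  exons=[(b_end + 11914, b_end + 14914)]),
    ]


def pb29_preset() -> Pb29Preset:
    """Deterministic study-design analog of the transgenic line Pb29.

    Two 150-kb chromosome analogs with one hemizygous single-copy insertion
    each near the midpoint: site A (Chr03 analog) reverse orientation,
    33-bp target-site deletion, LB/RB truncations 26/3 bp, a 24-bp unknown
    right-side filler; site B (Chr10 analog) forward orientation, 27-bp
    deletion, truncations 35/34 bp, no filler. The 2-kb "35S-API-Nos"
    cassette is excised from both inserted units. Ploidy 3 with one carrier
    haplotype; three >1-kb background SVs are shared by both samples.
    """
    rng = np.random.default_rng(PRESET_SEED)
    base_spec = HostGenomeSpec(
        chromosomes={"Chr03": 150000, "Chr10": 150000},
        gc=0.34,
        seed=PRESET_SEED,
    )
    host = build_host_genome(base_spec)

    L = PRESET_TDNA_LENGTH
    tdna_seq = _random_sequence(rng, L, 0.45)
    construct = TDnaConstruct(
        sequence=tdna_seq,
        features=[
            Feature("LB", 1, 25),
            Feature("35S-BtCry1Ac-Nos", 1000, 3999),
            Feature("35S-API-Nos", 4500, 6499),
            Feature("RB", L - 24, L),
        ],
    )

    background = list(host.sequences.values()) + [construct.sequence]
    # the site-A filler must not extend the vector alignment by chance either:
    # walking out of the truncated LB end (position 26 leftward, minus strand)
    # into the filler must never gain score
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    while True:
        filler = generate_filler(rng, 24, background, k=15)
        walk_read = "".join(comp[b] for b in filler)
        walk_target = tdna_seq[:26][::-1]
        if _no_positive_prefix(walk_read, walk_target):
            break

    unit_a = revcomp(tdna_seq[26 : L - 3])  # reverse copy, lb 26 / rb 3
    insert_a = unit_a + filler
    unit_b = tdna_seq[35 : L - 34]  # forward copy, lb 35 / rb 34
    a_start = _clean_site(host["Chr03"], 75000, 33, insert_a)
    b_start = _clean_site(host["Chr10"], 75000, 27, unit_b)

    events = [
        IntegrationEvent(
            chrom="Chr03",
            del_start=a_start,
            del_end=a_start + 32,
            copies=["reverse"],
            lb_trunc=26,
            rb_trunc=3,
            filler_right=filler,
            deleted_features=frozenset({"35S-API-Nos"}),
        ),
        IntegrationEvent(
            chrom="Chr10",
            del_start=b_start,
            del_end=b_start + 26,
            copies=["forward"],
            lb_trunc=35,
            rb_trunc=34,
            deleted_features=frozenset({"35S-API-Nos"}),
        ),
    ]
    genes = _preset_genes(a_start, a_start + 32, b_start, b_start + 26)
    host_spec = HostGenomeSpec(
        chromosomes=dict(base_spec.chromosomes),
        gc=0.34,
        seed=PRESET_SEED,
        genes=genes,
    )
    design = SampleDesign(
        ploidy=3,
        carriers=1,
        shared_svs=[
            SVEvent("DEL", "Chr03", 110000, 114999, 5000),
            SVEvent("DUP", "Chr03", 130000, 131999, 2000),
            SVEvent("INV", "Chr10", 115000, 117999, 3000),
        ],
    )
    return Pb29Preset(host_spec, construct, events, design, genes, host)
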