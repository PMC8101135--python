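"""In-silico PCR verification, zygosity estimation, and gene context.

The PCR model is purely combinatorial: a primer binds where it matches the
template exactly (up to a configurable mismatch budget, 3'-terminal base
always exact) and a product is reported for every convergent primer-site
pair within the size limit. This reproduces the band logic used to verify
insertion sites and orientations — junction primer combinations amplify
the transgenic allele only, wrong-orientation combinations are silent, and
a locus-spanning combination amplifies the wild-type allele (hence both
samples for a hemizygous insertion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .junction_caller import InsertionCall
from .models import AlignmentRecord, GeneModel, Genome, TDnaConstruct, revcomp


@dataclass
class PrimerPair:
    forward: str
    reverse: str
    combination_id: str
    intent: str  # left-junction | right-junction | locus-spanning | wrong-orientation-control

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            if not 18 <= len(p) <= 30:
                raise ValueError("primer length must be 18-30 bp")
            if set(p) - set("ACGT"):
                raise ValueError("degenerate bases not supported in primers")


@dataclass
class PcrProduct:
    template_id: str
    start: int  # 1-based position of the product on the template
    size: int
    sequence: str


@dataclass
class NeighborGene:
    gene_id: str
    interval: Tuple[int, int]
    strand: str
    distance: int  # bp between nearest boundaries (boundary difference)
    relation: str  # gene position relative to the insertion: upstream | downstream
    insertion_relative: str  # insertion position relative to the gene's 5'->3'
    overlap: bool = False


# ---------------------------------------------------------------------------
# in-silico PCR


def _binding_sites(template: str, primer: str, max_mismatch: int) -> List[int]:
    """0-based start positions where the primer matches the + strand
    left-to-right; the 3'-terminal base must match exactly."""
    lp = len(primer)
    n = len(template)
    if n < lp:
        return []
    if max_mismatch == 0:
        sites, pos = [], template.find(primer)
        while pos != -1:
            sites.append(pos)
            pos = template.find(primer, pos + 1)
        return sites
    t = np.frombuffer(template.encode(), dtype="S1")
    p = np.frombuffer(primer.encode(), dtype="S1")
    windows = np.lib.stride_tricks.sliding_window_view(t, lp)
    mism = (windows != p).sum(axis=1)
    ok = (mism <= max_mismatch) & (windows[:, -1] == p[-1])
    return list(np.flatnonzero(ok))


def insilico_pcr(
    templates: Dict[str, str],
    pair: PrimerPair,
    max_product: int = 5000,
    max_mismatch: int = 0,
) -> List[PcrProduct]:
    """All products the pair would amplify from each template.

    Either primer may act on either strand: products arise from a
    plus-strand site of one primer followed downstream by a plus-strand
    site of the other primer's reverse complement. Product size includes
    both primers.
    """
    products: List[PcrProduct] = []
    for tid, template in templates.items():
        for left, right in (
            (pair.forward, pair.reverse),
            (pair.reverse, pair.forward),
        ):
            f_sites = _binding_sites(template, left, max_mismatch)
            r_sites = _binding_sites(template, revcomp(right), max_mismatch)
            for f in f_sites:
                for r in r_sites:
                    end = r + len(right)  # exclusive
                    size = end - f
                    if len(left) <= size <= max_product and r >= f:
                        products.append(
                            PcrProduct(tid, f + 1, size, template[f:end])
                        )
    products.sort(key=lambda p: (p.template_id, p.start, p.size))
    return products


# ---------------------------------------------------------------------------
# primer design for the verification scheme


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _occurrences(hay: str, needle: str) -> int:
    count, pos = 0, hay.find(needle)
    while pos != -1:
        count += 1
        pos = hay.find(needle, pos + 1)
    return count


def _pick_primer(
    region: str,
    contexts: Sequence[str],
    length: int = 20,
    from_end: bool = False,
) -> str:
    """A GC-balanced ``length``-mer from ``region`` unique (both strands)
    in every context sequence."""
    positions = range(len(region) - length, -1, -1) if from_end else range(
        len(region) - length + 1
    )
    for i in positions:
        cand = region[i : i + length]
        if not 0.4 <= _gc(cand) <= 0.6:
            continue
        if all(
            _occurrences(ctx, cand) + _occurrences(ctx, revcomp(cand)) <= 1
            for ctx in contexts
        ):
            return cand
    raise ValueError("no unique GC-balanced primer found in window")


def design_verification_primers(
    call: InsertionCall,
    genome: Genome,
    construct: TDnaConstruct,
    insert_consensus: str,
    flank: int = 250,
    tdna_offset: int = 60,
    site_label: str = "",
) -> Tuple[List[PrimerPair], Dict[str, str]]:
    """The five-combination verification scheme for one resolved call.

    Emits a host-left forward primer (HF), a host-right reverse primer
    (HR) and two T-DNA internal primers near the LB and RB ends, then the
    five combinations: the two junction combinations consistent with the
    called orientation, the two wrong-orientation controls, and the
    locus-spanning combination HF+HR. Returns (pairs, templates) where
    templates hold the wild-type and reconstructed transgenic locus
    sequences (± 5 kb around the site).
    """
    if call.left is None or call.right is None:
        raise ValueError("verification design needs a bilateral resolved call")
    chrom_seq = genome[call.chrom]
    lo = max(1, call.left - 5000)
    hi = min(len(chrom_seq), call.right + 5000)
    wt_locus = chrom_seq[lo - 1 : hi]
    tg_locus = (
        chrom_seq[lo - 1 : call.left - 1]
        + insert_consensus
        + chrom_seq[call.right : hi]
    )
    contexts = [wt_locus, tg_locus]

    host_left = chrom_seq[call.left - 1 - flank : call.left - 1]
    host_right = chrom_seq[call.right : call.right + flank]
    L = construct.length
    tdna_lb = construct.sequence[tdna_offset : tdna_offset + 150]
    tdna_rb = construct.sequence[L - tdna_offset - 150 : L - tdna_offset]

    hf = _pick_primer(host_left, contexts)
    hr = revcomp(_pick_primer(host_right, contexts, from_end=True))
    t_lb = _pick_primer(tdna_lb, [construct.sequence])
    t_rb = _pick_primer(tdna_rb, [construct.sequence], from_end=True)

    fwd_set = [
        ("left-junction", hf, revcomp(t_lb)),
        ("right-junction", t_rb, hr),
    ]
    rev_set = [
        ("left-junction", hf, t_rb),
        ("right-junction", revcomp(t_lb), hr),
    ]
    if call.orientation == "reverse":
        correct, wrong = rev_set, fwd_set
    else:
        correct, wrong = fwd_set, rev_set

    pairs = []
    for i, (intent, f, r) in enumerate(correct, start=1):
        pairs.append(PrimerPair(f, r, f"{site_label}{i}", intent))
    for i, (_, f, r) in enumerate(wrong, start=3):
        pairs.append(PrimerPair(f, r, f"{site_label}{i}", "wrong-orientation-control"))
    pairs.append(PrimerPair(hf, hr, f"{site_label}5", "locus-spanning"))
    templates = {"wildtype-locus": wt_locus, "transgenic-locus": tg_locus}
    return pairs, templates


def band_pattern(
    pairs: Sequence[PrimerPair],
    wt_templates: Dict[str, str],
    tg_templates: Dict[str, str],
    max_product: int = 5000,
) -> Dict[str, str]:
    """Classify each combination by which sample shows a band.

    The transgenic sample of a hemizygous line contains both the
    transgenic and the wild-type allele. Returns combination id ->
    {"transgenic-only", "both", "none"}.
    """
    out = {}
    for pair in pairs:
        wt_band = bool(insilico_pcr(wt_templates, pair, max_product))
        tg_band = bool(insilico_pcr(tg_templates, pair, max_product))
        if tg_band and wt_band:
            out[pair.combination_id] = "both"
        elif tg_band:
            out[pair.combination_id] = "transgenic-only"
        else:
            out[pair.combination_id] = "none"
    return out


# ---------------------------------------------------------------------------
# zygosity


def estimate_zygosity(
    call: InsertionCall,
    records_by_read: Dict[str, List[AlignmentRecord]],
    min_flank: int = 200,
) -> Tuple[Optional[float], str]:
    """Reference-allele fraction among long reads spanning the call site.

    A qualified read covers both margins (site ± ``min_flank``) with host
    alignments; it counts as reference-allele when a single contiguous
    host segment covers both margins, and as insertion-allele when its
    coverage is split at the site. Verdict: heterozygous for a fraction in
    [0.1, 0.9], homozygous-insertion below, homozygous-reference above.
    """
    site_lo = (call.left if call.left is not None else call.right) - min_flank
    site_hi = (call.right if call.right is not None else call.left) + min_flank
    ref_reads = insert_reads = 0
    for recs in records_by_read.values():
        hosts = [r for r in recs if r.target == call.chrom]
        if not hosts:
            continue
        span_lo = min(r.target_start for r in hosts)
        span_hi = max(r.target_end for r in hosts)
        if span_lo > site_lo or span_hi < site_hi:
            continue
        if any(r.target_start <= site_lo and r.target_end >= site_hi for r in hosts):
            ref_reads += 1
        else:
            insert_reads += 1
    total = ref_reads + insert_reads
    if total == 0:
        return None, "undetermined"
    frac = ref_reads / total
    if frac < 0.1:
        return frac, "homozygous-insertion"
    if frac > 0.9:
        return frac, "homozygous-reference"
    return frac, "heterozygous"


# ---------------------------------------------------------------------------
# gene context


def load_gff3_genes(path) -> List[GeneModel]:
    """Parse gene + exon features from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = [
            (e.start, e.end) for e in db.children(g, featuretype="exon")
        ]
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand if g.strand in "+-" else "+",
                exons=sorted(exons),
            )
        )
    return genes


def _call_interval(call: InsertionCall) -> Tuple[int, int]:
    left = call.left if call.left is not None else call.right
    right = call.right if call.right is not None else call.left
    return min(left, right), max(left, right)


def find_neighbor_genes(
    genes: Sequence[GeneModel], call: InsertionCall, window: int = 20000
) -> List[NeighborGene]:
    """Genes within ``window`` bp of the insertion interval (not
    overlapping it), sorted by distance.

    Distance is the boundary difference between the insertion interval and
    the nearest gene boundary. ``relation`` gives the gene's position
    relative to the insertion; ``insertion_relative`` gives the
    insertion's position in the gene's own 5'->3' frame.
    """
    ins_lo, ins_hi = _call_interval(call)
    out = []
    for g in genes:
        if g.chrom != call.chrom:
            continue
        if g.end < ins_lo:
            distance = ins_lo - g.end
            relation = "upstream"
            gene_side = "left"
        elif g.start > ins_hi:
            distance = g.start - ins_hi
            relation = "downstream"
            gene_side = "right"
        else:
            continue  # overlapping: reported by find_disrupted_genes
        if distance > window:
            continue
        if (gene_side == "left") == (g.strand == "+"):
            insertion_relative = "downstream"
        else:
            insertion_relative = "upstream"
        out.append(
            NeighborGene(
                gene_id=g.gene_id,
                interval=(g.start, g.end),
                strand=g.strand,
                distance=distance,
                relation=relation,
                insertion_relative=insertion_relative,
            )
        )
    out.sort(key=lambda n: n.distance)
    return out


def find_disrupted_genes(
    genes: Sequence[GeneModel], call: InsertionCall
) -> List[Tuple[GeneModel, str]]:
    """Genes whose body intersects the insertion interval, with the
    disrupted feature: "exon N" (transcription order) or "intron"."""
    ins_lo, ins_hi = _call_interval(call)
    out = []
    for g in genes:
        if g.chrom != call.chrom or g.end < ins_lo or g.start > ins_hi:
            continue
        exons = sorted(g.exons)
        if g.strand == "-":
            ordered = list(reversed(exons))
        else:
            ordered = exons
        feature = "intron"
        for i, (s, e) in enumerate(ordered, start=1):
            if s <= ins_hi and e >= ins_lo:
                feature = f"exon {i}"
                break
        out.append((g, feature))
    return out
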