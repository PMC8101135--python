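"""Structural-variant detection from long-read split alignments and the
wild-type subtraction / size rule for flagging insertion-induced
rearrangements.

SVs shared by the wild-type and transgenic samples reflect divergence from
the reference genome, not transformation damage; after removing same-type
events at matching positions, remaining events longer than 1 kb (and any
translocation) are flagged as putative chromosomal rearrangements — except
at the insertion sites themselves, whose INS signature is the expected
footprint of the T-DNA.
"""

from __future__ import annotations

from statistics import median_low
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .models import AlignmentRecord, SVEvent


def _read_signatures(
    recs: List[AlignmentRecord],
    vector_name: Optional[str],
    min_size: int,
) -> List[SVEvent]:
    """SV signatures from one read's host alignments (query order)."""
    hosts = sorted(
        (r for r in recs if r.target != vector_name),
        key=lambda r: r.query_start,
    )
    sigs: List[SVEvent] = []
    # the read's own orientation: the strand carrying most aligned bases;
    # a segment on the other strand is inverted sequence
    span_by_strand = {"+": 0, "-": 0}
    for r in hosts:
        span_by_strand[r.strand] += r.query_span
    majority = "+" if span_by_strand["+"] >= span_by_strand["-"] else "-"

    # INV: only fully-spanned inversions are counted — the minority-strand
    # segment must be flanked by majority-strand segments of the same
    # chromosome on both sides, which pins both inversion breakpoints;
    # single-boundary reads give half-open intervals that cannot be
    # clustered reproducibly across samples
    for i in range(1, len(hosts) - 1):
        mid, prev, nxt = hosts[i], hosts[i - 1], hosts[i + 1]
        if (
            mid.strand != majority
            and prev.strand == majority == nxt.strand
            and prev.target == mid.target == nxt.target
        ):
            sigs.append(
                SVEvent(
                    "INV", mid.target, mid.target_start, mid.target_end,
                    mid.target_span,
                )
            )
    for a, b in zip(hosts, hosts[1:]):
        if a.target != b.target:
            sigs.append(
                SVEvent(
                    "TRA",
                    a.target,
                    a.target_end if a.strand == "+" else a.target_start,
                    a.target_end if a.strand == "+" else a.target_start,
                    0,
                    chrom2=b.target,
                    pos2=b.target_start if b.strand == "+" else b.target_end,
                )
            )
            continue
        if a.strand != b.strand:
            continue  # inversion boundaries handled above
        # normalize to reference order for minus-strand reads
        lo, hi = (a, b) if a.target_start <= b.target_start else (b, a)
        ref_gap = hi.target_start - lo.target_end - 1
        query_gap = b.query_start - a.query_end - 1
        if ref_gap >= min_size and query_gap < min_size:
            sigs.append(
                SVEvent("DEL", a.target, lo.target_end + 1, hi.target_start - 1, ref_gap)
            )
        elif query_gap >= min_size:
            # novel sequence dominates; any small reference gap alongside is
            # a target-site deletion accompanying the insertion
            sigs.append(
                SVEvent("INS", a.target, lo.target_end, lo.target_end, query_gap)
            )
        elif ref_gap < -min_size:
            # reference overlap: tandem duplication signature
            sigs.append(
                SVEvent(
                    "DUP",
                    a.target,
                    hi.target_start,
                    lo.target_end,
                    lo.target_end - hi.target_start + 1,
                )
            )
    return sigs


def detect_svs(
    records_by_read: Dict[str, List[AlignmentRecord]],
    min_size: int = 50,
    min_support: int = 3,
    vector_name: Optional[str] = None,
    cluster_window: int = 100,
) -> List[SVEvent]:
    """Cluster per-read split-alignment signatures into SV events.

    Signatures of the same type with both breakpoints within
    ``cluster_window`` bp are merged; an event is reported when supported
    by >= ``min_support`` reads. Vector-target alignments are excluded
    (junctions to the vector are insertion evidence, not host SVs).
    """
    if min_size < 1 or min_support < 1:
        raise ValueError("min_size and min_support must be >= 1")
    sigs: List[SVEvent] = []
    for recs in records_by_read.values():
        sigs.extend(_read_signatures(recs, vector_name, min_size))

    events: List[SVEvent] = []
    by_type: Dict[Tuple[str, str, str], List[SVEvent]] = {}
    for s in sigs:
        by_type.setdefault((s.svtype, s.chrom, s.chrom2 or ""), []).append(s)
    for (svtype, chrom, chrom2), group in sorted(by_type.items()):
        # sort on both breakpoints so signatures truncated by read ends
        # (e.g. reads ending inside an inversion) form their own clusters
        # instead of splitting the fully-spanned event
        group.sort(key=lambda s: (s.start, s.end))
        cluster: List[SVEvent] = []
        for s in group:
            if cluster and (
                s.start - cluster[-1].start > cluster_window
                or abs(s.end - cluster[-1].end) > cluster_window
            ):
                events.append(_merge_cluster(cluster))
                cluster = []
            cluster.append(s)
        if cluster:
            events.append(_merge_cluster(cluster))

    events = [e for e in events if e.support >= min_support]
    events.sort(key=lambda e: (e.chrom, e.start, e.svtype))
    return events


def _merge_cluster(cluster: List[SVEvent]) -> SVEvent:
    first = cluster[0]
    return SVEvent(
        first.svtype,
        first.chrom,
        median_low([s.start for s in cluster]),
        median_low([s.end for s in cluster]),
        median_low([s.length for s in cluster]),
        support=len(cluster),
        chrom2=first.chrom2,
        pos2=median_low([s.pos2 for s in cluster]) if first.pos2 is not None else None,
    )


def subtract_shared_svs(
    transgenic: Sequence[SVEvent],
    wildtype: Sequence[SVEvent],
    pos_tol: int = 500,
) -> List[SVEvent]:
    """Remove transgenic events matched by a same-type wild-type event with
    both breakpoints within ``pos_tol``; greedy nearest-match pairing, each
    wild-type event consumed once."""
    if pos_tol < 0:
        raise ValueError("pos_tol must be >= 0")
    consumed: set = set()
    remaining: List[SVEvent] = []
    for tg in transgenic:
        best, best_d = None, None
        for i, wt in enumerate(wildtype):
            if i in consumed or wt.svtype != tg.svtype or wt.chrom != tg.chrom:
                continue
            d = max(abs(wt.start - tg.start), abs(wt.end - tg.end))
            if d <= pos_tol and (best_d is None or d < best_d):
                best, best_d = i, d
        if best is None:
            remaining.append(tg)
        else:
            consumed.add(best)
    return remaining


def flag_rearrangements(
    remaining: Sequence[SVEvent],
    min_len: int = 1000,
    excluded: Sequence[Tuple[str, int, int]] = (),
    margin: int = 1000,
) -> List[SVEvent]:
    """Flag events strictly longer than ``min_len`` as putative
    insertion-induced rearrangements.

    Events whose breakpoints fall within an excluded insertion interval
    +/- ``margin`` are never flagged (the insertion's own INS signature is
    the T-DNA itself). Translocations are flagged regardless of length
    unless excluded.
    """

    def near_insertion(chrom: str, pos: int) -> bool:
        return any(
            c == chrom and s - margin <= pos <= e + margin for c, s, e in excluded
        )

    out = []
    for e in remaining:
        pts = [(e.chrom, e.start), (e.chrom, e.end)]
        if e.svtype == "TRA" and e.chrom2 is not None:
            pts.append((e.chrom2, e.pos2))
        if any(near_insertion(c, p) for c, p in pts):
            continue
        if e.svtype == "TRA" or e.length > min_len:
            out.append(e)
    return out


# ---------------------------------------------------------------------------
# minimal SV-VCF output


def write_sv_vcf(events: Sequence[SVEvent], contigs: Dict[str, int], path) -> None:
    """Minimal VCF 4.2 with SVTYPE/SVLEN/END/SUPPORT in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">\n')
        fh.write('##INFO=<ID=CHR2,Number=1,Type=String,Description="Mate chromosome (TRA)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, e in enumerate(
            sorted(events, key=lambda e: (e.chrom, e.start)), start=1
        ):
            info = f"SVTYPE={e.svtype};SVLEN={e.length};END={e.end};SUPPORT={e.support}"
            if e.svtype == "TRA" and e.chrom2:
                info += f";CHR2={e.chrom2}"
            fh.write(
                f"{e.chrom}\t{e.start}\tsv{i}\tN\t<{e.svtype}>\t.\tPASS\t{info}\n"
            )
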