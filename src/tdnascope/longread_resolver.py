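"""Long-read resolution of insertion sites.

Long reads whose host alignments flank an insertion on both sides localize
the target-site deletion exactly and carry the complete inserted sequence
between their flank alignments. The per-read inserts (normalized to the
host + strand) are combined into a consensus by star alignment against the
medoid insert with per-column majority voting.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median_low
from typing import Dict, List, Optional, Sequence, Tuple

import edlib

from .junction_caller import InsertionCall
from .models import AlignmentRecord, revcomp


@dataclass
class SpanningRead:
    """A long read aligned to host sequence on both sides of an insertion."""

    read_id: str
    chrom: str
    left_flank: Tuple[int, int]  # host interval of the left flank alignment
    right_flank: Tuple[int, int]
    host_gap: Tuple[int, int]  # host bases between the flanks (1-based incl.)
    query_insert: Tuple[int, int]  # read bases between the flanks, as sequenced
    strand: str  # read strand relative to host


@dataclass
class InsertReconstruction:
    call: InsertionCall
    deletion_interval: Tuple[int, int]
    deletion_width: int
    inserts: List[str]
    consensus: str
    n_reads: int


# ---------------------------------------------------------------------------


def find_spanning_reads(
    records_by_read: Dict[str, List[AlignmentRecord]],
    call: InsertionCall,
    min_flank: int = 200,
    locus_tolerance: int = 1000,
) -> List[SpanningRead]:
    """Reads with two host segments flanking the call site.

    Both flank alignments must be on the call chromosome, the same read
    strand, carry >= ``min_flank`` aligned bases, and sit on opposite sides
    of the called site (within ``locus_tolerance``). Reads whose flank hits
    disagree with the call chromosome are ignored here (they are
    translocation evidence, handled by the SV screen).
    """
    site = call.site()
    out: List[SpanningRead] = []
    for read_id, recs in records_by_read.items():
        hosts = sorted(
            (
                r
                for r in recs
                if r.target == call.chrom and r.query_span >= min_flank
            ),
            key=lambda r: r.query_start,
        )
        found = None
        for a, b in zip(hosts, hosts[1:]):
            if a.strand != b.strand:
                continue
            lo, hi = (a, b) if a.target_start <= b.target_start else (b, a)
            if not (
                lo.target_end <= site + locus_tolerance
                and hi.target_start >= site - locus_tolerance
                and lo.target_end < hi.target_start
            ):
                continue
            q_lo = min(a.query_end, b.query_end)
            q_hi = max(a.query_start, b.query_start)
            if q_hi - q_lo - 1 < 0:
                continue
            found = SpanningRead(
                read_id=read_id,
                chrom=call.chrom,
                left_flank=(lo.target_start, lo.target_end),
                right_flank=(hi.target_start, hi.target_end),
                host_gap=(lo.target_end + 1, hi.target_start - 1),
                query_insert=(q_lo + 1, q_hi - 1),
                strand=a.strand,
            )
            break
        if found:
            out.append(found)
    out.sort(key=lambda s: s.read_id)
    return out


def infer_deletion_interval(
    spanning: Sequence[SpanningRead],
) -> Tuple[Tuple[int, int], int]:
    """Aggregate per-read host gaps by coordinate-wise median.

    Ties resolve toward the smaller coordinate (lower median). Width is
    end - start + 1, or 0 for a blunt insertion (end < start).
    """
    if not spanning:
        raise ValueError("no spanning reads")
    start = median_low([s.host_gap[0] for s in spanning])
    end = median_low([s.host_gap[1] for s in spanning])
    width = max(0, end - start + 1)
    return (start, end), width


def extract_insert_sequences(
    spanning: Sequence[SpanningRead], reads: Dict[str, str]
) -> List[str]:
    """Per-read inserted sequence between the flank alignments, oriented to
    the host + strand (reads aligned antisense are reverse-complemented)."""
    out = []
    for s in spanning:
        seq = reads[s.read_id]
        qs, qe = s.query_insert
        ins = seq[qs - 1 : qe]
        out.append(ins if s.strand == "+" else revcomp(ins))
    return out


# ---------------------------------------------------------------------------
# consensus


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def build_insert_consensus(inserts: Sequence[str]) -> str:
    """Star-alignment consensus of the per-read insert sequences.

    The medoid (minimum total edit distance to the others) is the star
    center; every insert is globally aligned to it and each medoid column
    (plus inter-column insertions) is decided by majority vote, ties broken
    A < C < G < T, with deletions voting for an empty column. A single
    insert is returned verbatim.
    """
    if not inserts:
        raise ValueError("no insert sequences")
    if len(inserts) == 1:
        return inserts[0]

    totals = [
        sum(_edit_distance(a, b) for j, b in enumerate(inserts) if j != i)
        for i, a in enumerate(inserts)
    ]
    medoid = inserts[min(range(len(inserts)), key=lambda i: totals[i])]
    if not medoid:
        return ""
    m = len(medoid)

    # votes[col] counts bases aligned to medoid column col ('' = deletion);
    # insertions[col] counts sequence inserted before medoid column col.
    votes: List[Dict[str, int]] = [dict() for _ in range(m)]
    insertions: List[Dict[str, int]] = [dict() for _ in range(m + 1)]
    from .align_core import parse_cigar

    for seq in inserts:
        res = edlib.align(seq, medoid, mode="NW", task="path")
        qpos, tpos = 0, 0
        for op, n in parse_cigar(res["cigar"]):
            if op in "=XM":
                for _ in range(n):
                    b = seq[qpos]
                    votes[tpos][b] = votes[tpos].get(b, 0) + 1
                    qpos += 1
                    tpos += 1
            elif op == "I":
                ins = seq[qpos : qpos + n]
                insertions[tpos][ins] = insertions[tpos].get(ins, 0) + 1
                qpos += n
            elif op == "D":
                for _ in range(n):
                    votes[tpos][""] = votes[tpos].get("", 0) + 1
                    tpos += 1

    n_seq = len(inserts)
    parts: List[str] = []
    for col in range(m + 1):
        ins_votes = insertions[col]
        if ins_votes and sum(ins_votes.values()) * 2 > n_seq:
            top = max(ins_votes.values())
            parts.append(min(k for k, v in ins_votes.items() if v == top))
        if col < m:
            col_votes = votes[col]
            if not col_votes:
                parts.append(medoid[col])
                continue
            top = max(col_votes.values())
            winner = min(k for k, v in col_votes.items() if v == top)
            parts.append(winner)
    return "".join(parts)


def reconstruct_insert(
    records_by_read: Dict[str, List[AlignmentRecord]],
    reads: Dict[str, str],
    call: InsertionCall,
    min_flank: int = 200,
) -> Optional[InsertReconstruction]:
    """Full resolution of one call: spanning reads -> deletion interval ->
    insert consensus. Returns None when no read spans the site."""
    spanning = find_spanning_reads(records_by_read, call, min_flank=min_flank)
    if not spanning:
        return None
    interval, width = infer_deletion_interval(spanning)
    inserts = extract_insert_sequences(spanning, reads)
    consensus = build_insert_consensus(inserts)
    return InsertReconstruction(
        call=call,
        deletion_interval=interval,
        deletion_width=width,
        inserts=inserts,
        consensus=consensus,
        n_reads=len(spanning),
    )
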