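"""Short-read junction-read identification, clustering, and insertion calls.

A junction read carries both T-DNA (vector) and host flanking sequence and
pins one side of an insertion breakpoint to a single host base. Junction
reads are clustered per (chromosome, flank side, vector end); left/right
clusters on the same chromosome are paired into insertion calls with
orientation inferred from the strand geometry of the evidence.

Orientation convention: "forward" means the canonical T-DNA (LB at
position 1, RB at position L) lies on the host + strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median_low
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .models import AlignmentRecord


@dataclass
class JunctionRead:
    """Read-level evidence joining vector sequence to host sequence."""

    read_id: str
    chrom: str
    host_interval: Tuple[int, int]
    host_strand: str
    vector_interval: Tuple[int, int]
    vector_strand: str
    junction: int  # host base adjacent to the T-DNA
    side: str  # which flank the host segment represents: "left" | "right"
    vector_end: str  # "LB-proximal" | "RB-proximal"


@dataclass
class JunctionCluster:
    chrom: str
    breakpoint: int  # median of member junction coordinates
    side: str
    vector_end: str
    reads: List[JunctionRead] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.reads)


@dataclass
class InsertionCall:
    """A called insertion: host interval removed, orientation, support.

    ``left``/``right`` delimit the removed host interval (1-based
    inclusive; blunt when right < left). For a unilateral call the missing
    boundary is None.
    """

    chrom: str
    left: Optional[int]
    right: Optional[int]
    orientation: str
    support_left: int = 0
    support_right: int = 0
    discordant_support: int = 0
    unilateral: bool = False

    @property
    def deletion_width(self) -> int:
        if self.left is None or self.right is None:
            return 0
        return max(0, self.right - self.left + 1)

    def site(self) -> int:
        """A representative host coordinate for the call."""
        if self.left is not None:
            return self.left
        return self.right  # type: ignore[return-value]


# ---------------------------------------------------------------------------


def _vector_end(coord: int, vector_len: int) -> str:
    return "LB-proximal" if coord <= vector_len / 2 else "RB-proximal"


def find_junction_reads(
    records_by_read: Dict[str, List[AlignmentRecord]],
    vector_name: str,
    vector_len: int,
    min_seg: int = 15,
    max_overlap: int = 5,
    max_gap: int = 50,
) -> List[JunctionRead]:
    """Identify reads with both a host and a vector segment.

    Each segment must carry >= ``min_seg`` aligned query bases and the two
    query intervals must be adjacent on the read: overlapping by at most
    ``max_overlap`` bp (microhomology allowance) and separated by at most
    ``max_gap`` bp (room for short filler DNA at the junction). The
    junction coordinate is the host-segment boundary adjacent to the
    vector segment on the read; the flank side follows from which end of
    the host segment faces the vector and the host strand.
    """
    out: List[JunctionRead] = []
    for read_id, recs in records_by_read.items():
        hosts = [
            r for r in recs if r.target != vector_name and r.query_span >= min_seg
        ]
        vectors = [
            r for r in recs if r.target == vector_name and r.query_span >= min_seg
        ]
        if not hosts or not vectors:
            continue
        for h in hosts:
            # vector segment nearest on the read
            v = min(
                vectors,
                key=lambda v: min(
                    abs(v.query_start - h.query_end),
                    abs(h.query_start - v.query_end),
                ),
            )
            overlap = min(h.query_end, v.query_end) - max(
                h.query_start, v.query_start
            ) + 1
            if overlap > max_overlap or -overlap >= max_gap:
                continue
            vector_after = v.query_start >= h.query_end - max_overlap
            if vector_after:
                junction = h.target_end if h.strand == "+" else h.target_start
                side = "left" if h.strand == "+" else "right"
                v_adj = v.target_start if v.strand == "+" else v.target_end
            else:
                junction = h.target_start if h.strand == "+" else h.target_end
                side = "right" if h.strand == "+" else "left"
                v_adj = v.target_end if v.strand == "+" else v.target_start
            out.append(
                JunctionRead(
                    read_id=read_id,
                    chrom=h.target,
                    host_interval=(h.target_start, h.target_end),
                    host_strand=h.strand,
                    vector_interval=(v.target_start, v.target_end),
                    vector_strand=v.strand,
                    junction=junction,
                    side=side,
                    vector_end=_vector_end(v_adj, vector_len),
                )
            )
    return out


def find_discordant_pairs(
    records_by_read: Dict[str, List[AlignmentRecord]], vector_name: str
) -> List[Tuple[str, str, int]]:
    """Mate pairs whose primaries split host/vector with no within-read
    junction; returned as (pair id, host chromosome, host position)."""
    by_pair: Dict[str, Dict[str, AlignmentRecord]] = {}
    for rid, recs in records_by_read.items():
        if "/" not in rid:
            continue
        base, mate = rid.rsplit("/", 1)
        primary = next((r for r in recs if r.is_primary), None)
        if primary is not None:
            by_pair.setdefault(base, {})[mate] = primary
    out = []
    for base, mates in by_pair.items():
        if len(mates) != 2:
            continue
        p1, p2 = mates.get("1"), mates.get("2")
        if p1 is None or p2 is None:
            continue
        targets = {p1.target, p2.target}
        if vector_name in targets and len(targets) == 2:
            host = p1 if p1.target != vector_name else p2
            out.append((base, host.target, host.target_start))
    return out


def cluster_junction_reads(
    junctions: Sequence[JunctionRead], tolerance: int = 10
) -> List[JunctionCluster]:
    """Single-linkage clustering of junction coordinates per
    (chromosome, side, vector end); clusters sorted by chromosome and
    breakpoint."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    groups: Dict[Tuple[str, str, str], List[JunctionRead]] = {}
    for j in junctions:
        groups.setdefault((j.chrom, j.side, j.vector_end), []).append(j)
    clusters: List[JunctionCluster] = []
    for (chrom, side, vend), members in groups.items():
        members.sort(key=lambda j: j.junction)
        bucket = [members[0]]
        for j in members[1:]:
            if j.junction - bucket[-1].junction > tolerance:
                clusters.append(_finish_cluster(chrom, side, vend, bucket))
                bucket = [j]
            else:
                bucket.append(j)
        clusters.append(_finish_cluster(chrom, side, vend, bucket))
    clusters.sort(key=lambda c: (c.chrom, c.breakpoint, c.side))
    return clusters


def _finish_cluster(chrom, side, vend, members) -> JunctionCluster:
    bp = median_low([j.junction for j in members])
    return JunctionCluster(chrom, bp, side, vend, list(members))


# orientation truth table: (side, relative strand, vector end) -> orientation,
# where relative strand is + when host and vector segments share a strand.
_ORIENT = {
    ("left", "+", "LB-proximal"): "forward",
    ("left", "-", "RB-proximal"): "reverse",
    ("right", "+", "RB-proximal"): "forward",
    ("right", "-", "LB-proximal"): "reverse",
}


def _cluster_orientation(cluster: JunctionCluster) -> Optional[str]:
    votes = set()
    for j in cluster.reads:
        rel = "+" if j.host_strand == j.vector_strand else "-"
        votes.add(_ORIENT.get((j.side, rel, j.vector_end)))
    if len(votes) == 1:
        return votes.pop()
    return None


def infer_orientation(
    left: Optional[JunctionCluster] = None, right: Optional[JunctionCluster] = None
) -> str:
    """Insertion orientation from one or both flank clusters.

    With evidence on both sides the votes must agree, otherwise
    "undetermined".
    """
    if left is None and right is None:
        raise ValueError("at least one cluster required")
    votes = {_cluster_orientation(c) for c in (left, right) if c is not None}
    if len(votes) == 1 and None not in votes:
        return votes.pop()
    return "undetermined"


def call_insertions(
    clusters: Sequence[JunctionCluster],
    discordant: Sequence[Tuple[str, str, int]] = (),
    min_support: int = 2,
    max_span: int = 200,
) -> List[InsertionCall]:
    """Pair left/right clusters into insertion calls.

    The removed host interval is [left_junction + 1, right_junction - 1]:
    junction coordinates are the retained host bases adjacent to the
    T-DNA, so the interval between them is what the integration deleted
    (blunt when the junctions are adjacent). Unpaired clusters become
    unilateral calls; calls with total junction support below
    ``min_support`` are dropped.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    by_chrom: Dict[str, Dict[str, List[JunctionCluster]]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chrom, {"left": [], "right": []})[c.side].append(c)

    calls: List[InsertionCall] = []
    for chrom in sorted(by_chrom):
        lefts = sorted(by_chrom[chrom]["left"], key=lambda c: c.breakpoint)
        rights = sorted(by_chrom[chrom]["right"], key=lambda c: c.breakpoint)
        used_r: set = set()
        for lc in lefts:
            best, best_d = None, None
            for ri, rc in enumerate(rights):
                if ri in used_r:
                    continue
                d = rc.breakpoint - lc.breakpoint
                if -max_span <= d <= max_span and (best_d is None or abs(d) < best_d):
                    best, best_d = ri, abs(d)
            if best is not None:
                rc = rights[best]
                used_r.add(best)
                calls.append(
                    InsertionCall(
                        chrom=chrom,
                        left=lc.breakpoint + 1,
                        right=rc.breakpoint - 1,
                        orientation=infer_orientation(lc, rc),
                        support_left=lc.support,
                        support_right=rc.support,
                    )
                )
            else:
                calls.append(
                    InsertionCall(
                        chrom=chrom,
                        left=lc.breakpoint + 1,
                        right=None,
                        orientation=infer_orientation(left=lc),
                        support_left=lc.support,
                        unilateral=True,
                    )
                )
        for ri, rc in enumerate(rights):
            if ri not in used_r:
                calls.append(
                    InsertionCall(
                        chrom=chrom,
                        left=None,
                        right=rc.breakpoint - 1,
                        orientation=infer_orientation(right=rc),
                        support_right=rc.support,
                        unilateral=True,
                    )
                )

    for call in calls:
        for _, chrom, pos in discordant:
            if chrom == call.chrom and abs(pos - call.site()) <= 1000:
                call.discordant_support += 1

    calls = [
        c for c in calls if c.support_left + c.support_right >= min_support
    ]
    calls.sort(key=lambda c: (c.chrom, c.site()))
    return calls
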