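"""Comparison of a reconstructed insert against the vector T-DNA unit.

Measures what the integration did to the transferred DNA: how many bases
are missing from the LB and RB ends (truncations are defined from the
extremes of vector coverage, so losses beyond the 25-bp border repeat are
representable), which cassette features survived, whether untemplated
filler sequence sits between the T-DNA block and the host flanks, and how
many unit copies the insert contains and in what arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .align_core import IndexedReference, map_read
from .models import TDnaConstruct


@dataclass
class VectorSegment:
    """One local alignment of the insert consensus to the canonical T-DNA."""

    query_interval: Tuple[int, int]  # on the consensus, ascending
    vector_interval: Tuple[int, int]  # on the canonical T-DNA, ascending
    strand: str  # consensus relative to canonical T-DNA
    identity: float


@dataclass
class Filler:
    side: str  # "left" | "right" | "internal"
    sequence: str
    length: int
    host_mappable: bool


@dataclass
class FeaturePresence:
    name: str
    coverage: float
    present: bool


@dataclass
class InsertCharacterization:
    lb_trunc: int
    rb_trunc: int
    features: List[FeaturePresence]
    fillers: List[Filler]
    copies: int
    arrangement: str  # single | tandem-direct | tandem-inverted | complex
    tdna_detected: bool = True

    def feature(self, name: str) -> FeaturePresence:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


# ---------------------------------------------------------------------------


def align_insert_to_vector(
    consensus: str,
    construct: TDnaConstruct,
    min_seg: int = 15,
    min_identity: float = 0.8,
    k: int = 13,
) -> List[VectorSegment]:
    """Chained local alignments of the consensus against the canonical
    T-DNA, both strands, sorted by consensus coordinate. An empty list
    means no T-DNA content was detected."""
    if not consensus:
        raise ValueError("empty consensus")
    index = IndexedReference({"vector": construct.sequence}, k=k)
    records = map_read(
        index,
        "consensus",
        consensus,
        min_identity=min_identity,
        min_seg=min_seg,
        stride=1,
    )
    segs = [
        VectorSegment(
            query_interval=(r.query_start, r.query_end),
            vector_interval=(r.target_start, r.target_end),
            strand=r.strand,
            identity=r.identity,
        )
        for r in records
    ]
    segs.sort(key=lambda s: s.query_interval)
    return segs


def measure_border_truncations(
    segments: Sequence[VectorSegment],
    construct: TDnaConstruct,
    orientation: str = "forward",
) -> Tuple[int, int]:
    """(lb_trunc, rb_trunc) from the extremes of vector coverage.

    lb_trunc = smallest covered vector coordinate - 1;
    rb_trunc = L - largest covered vector coordinate. The insertion
    orientation decides which physical end of the insert carries which
    border but not the measured values.
    """
    if not segments:
        raise ValueError("no vector segments")
    lo = min(s.vector_interval[0] for s in segments)
    hi = max(s.vector_interval[1] for s in segments)
    return lo - 1, construct.length - hi


def assess_feature_presence(
    segments: Sequence[VectorSegment],
    construct: TDnaConstruct,
    cov_threshold: float = 0.5,
) -> List[FeaturePresence]:
    """Per-feature fraction of the vector interval covered by any segment;
    a feature is present iff coverage >= ``cov_threshold``."""
    if not 0.0 < cov_threshold <= 1.0:
        raise ValueError("cov_threshold must be in (0, 1]")
    out = []
    for f in construct.features:
        covered = 0
        pieces = sorted(
            (max(f.start, s.vector_interval[0]), min(f.end, s.vector_interval[1]))
            for s in segments
        )
        last = f.start - 1
        for s, e in pieces:
            if e < s:
                continue
            s = max(s, last + 1)
            if e >= s:
                covered += e - s + 1
                last = max(last, e)
        frac = covered / (f.end - f.start + 1)
        out.append(FeaturePresence(f.name, frac, frac >= cov_threshold))
    return out


def detect_filler(
    consensus: str,
    segments: Sequence[VectorSegment],
    host_index: Optional[IndexedReference] = None,
    min_filler: int = 10,
) -> List[Filler]:
    """Maximal consensus subintervals uncovered by any vector segment.

    Subintervals >= ``min_filler`` bp are reported with their side relative
    to the T-DNA block (the consensus is host-(+)-oriented, so its start
    abuts the left host flank). Each filler is re-mapped against the host
    reference when given and flagged host-mappable or unknown.
    """
    if not segments:
        return []
    covered: List[Tuple[int, int]] = sorted(s.query_interval for s in segments)
    merged = [covered[0]]
    for s, e in covered[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    gaps: List[Tuple[int, int, str]] = []
    if merged[0][0] > 1:
        gaps.append((1, merged[0][0] - 1, "left"))
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        gaps.append((e1 + 1, s2 - 1, "internal"))
    if merged[-1][1] < len(consensus):
        gaps.append((merged[-1][1] + 1, len(consensus), "right"))

    out = []
    for s, e, side in gaps:
        if e - s + 1 < min_filler:
            continue
        seq = consensus[s - 1 : e]
        mappable = False
        if host_index is not None:
            hits = map_read(
                host_index,
                "filler",
                seq,
                min_identity=0.9,
                min_seg=min(len(seq), 15),
                stride=1,
            )
            mappable = any(
                h.query_span >= 0.8 * len(seq) and host_index.is_host(h.target)
                for h in hits
            )
        out.append(Filler(side, seq, len(seq), mappable))
    return out


def count_tdna_copies(
    segments: Sequence[VectorSegment], overlap_tolerance: int = 100
) -> Tuple[int, str]:
    """Number of T-DNA unit traversals in the insert and their arrangement.

    Walking the segments in consensus order, a segment continues the
    current traversal when it keeps the strand and its vector coordinates
    progress in the strand-consistent direction (a + traversal ascends the
    vector, a - traversal descends); anything else starts a new copy.
    """
    if not segments:
        return 0, "none"
    segs = sorted(segments, key=lambda s: s.query_interval)
    copies = [segs[0]]
    strands = [segs[0].strand]
    cur = segs[0]
    for s in segs[1:]:
        cont = False
        if s.strand == cur.strand:
            if s.strand == "+":
                cont = s.vector_interval[0] >= cur.vector_interval[1] - overlap_tolerance
            else:
                cont = s.vector_interval[1] <= cur.vector_interval[0] + overlap_tolerance
        if not cont:
            copies.append(s)
            strands.append(s.strand)
        cur = s
    n = len(copies)
    if n == 1:
        return 1, "single"
    if len(set(strands)) == 1:
        return n, "tandem-direct"
    if all(a != b for a, b in zip(strands, strands[1:])):
        return n, "tandem-inverted"
    return n, "complex"


def characterize_insert(
    consensus: str,
    construct: TDnaConstruct,
    host_index: Optional[IndexedReference] = None,
    cov_threshold: float = 0.5,
    min_filler: int = 10,
) -> InsertCharacterization:
    """Full characterization of one reconstructed insert."""
    segments = align_insert_to_vector(consensus, construct)
    if not segments:
        return InsertCharacterization(
            lb_trunc=0,
            rb_trunc=0,
            features=[],
            fillers=[],
            copies=0,
            arrangement="none",
            tdna_detected=False,
        )
    lb, rb = measure_border_truncations(segments, construct)
    features = assess_feature_presence(segments, construct, cov_threshold)
    fillers = detect_filler(consensus, segments, host_index, min_filler)
    copies, arrangement = count_tdna_copies(segments)
    return InsertCharacterization(
        lb_trunc=lb,
        rb_trunc=rb,
        features=features,
        fillers=fillers,
        copies=copies,
        arrangement=arrangement,
    )
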