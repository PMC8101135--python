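"""Read filtering and a lightweight split-read mapper.

The mapper follows the classical seed-chain-extend design at desk scale:
exact k-mer seeds on both strands against a combined host+vector reference,
diagonal clustering into chains, then per-chain extension. Chains whose
seeds sit on a single diagonal are verified gapless (best-scoring diagonal
segment, which is exact for substitution-only reads); drifting chains are
extended with an edit-distance path (edlib) and trimmed to the best-scoring
local sub-path under the affine scheme below.

Scoring: match +1, mismatch -2, gap open -4, gap extend -1; a gap of length
g costs 4 + g (the open penalty is charged once on top of per-base
extension). The same scheme is used by the exact Smith-Waterman oracle
provided for testing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .models import AlignmentRecord, Genome, revcomp

MATCH = 1
MISMATCH = -2
GAP_OPEN = -4
GAP_EXTEND = -1


def gap_cost(length: int) -> int:
    """Affine cost of a gap run: open once, extend per base."""
    return -(4 + length) if length > 0 else 0


# ---------------------------------------------------------------------------
# FASTQ filtering


def read_fastq(path) -> List[Tuple[str, str, str]]:
    """Parse FASTQ into (id, seq, qual) tuples; report the failing record."""
    reads = []
    try:
        with open(path) as fh:
            for rid, seq, qual in FastqGeneralIterator(fh):
                reads.append((rid.split()[0], seq.upper(), qual))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ near record {len(reads) + 1}: {exc}")
    return reads


def mean_quality(qual: str) -> float:
    if not qual:
        return 0.0
    return float(np.frombuffer(qual.encode(), dtype=np.uint8).mean()) - 33.0


def filter_short_reads(pairs, min_q: float = 20.0):
    """Drop a pair when either mate's mean base quality is below ``min_q``.

    Returns ``(kept_pairs, n_dropped_pairs)``.
    """
    if min_q < 0:
        raise ValueError("min_q must be >= 0")
    kept, dropped = [], 0
    for m1, m2 in pairs:
        if mean_quality(m1[2]) < min_q or mean_quality(m2[2]) < min_q:
            dropped += 1
        else:
            kept.append((m1, m2))
    return kept, dropped


def filter_long_reads(reads, min_len: int = 500):
    """Remove reads strictly shorter than ``min_len``; returns (kept, dropped)."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    kept = [r for r in reads if len(r[1]) >= min_len]
    return kept, len(reads) - len(kept)


# ---------------------------------------------------------------------------
# reference index


class IndexedReference:
    """k-mer index over host chromosomes plus one vector record."""

    def __init__(
        self,
        sequences: Dict[str, str],
        vector_name: Optional[str] = None,
        k: int = 15,
        max_kmer_hits: int = 64,
    ):
        if vector_name is not None and vector_name not in sequences:
            raise ValueError(f"vector record {vector_name!r} not in reference")
        self.sequences = dict(sequences)
        self.vector_name = vector_name
        self.k = k
        self.arrays = {
            name: np.frombuffer(seq.encode(), dtype="S1")
            for name, seq in sequences.items()
        }
        index: Dict[str, List[Tuple[str, int]]] = {}
        for name, seq in sequences.items():
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((name, i + 1))
        # drop repeat-saturated seeds
        self.index = {
            km: occ for km, occ in index.items() if len(occ) <= max_kmer_hits
        }

    def is_host(self, name: str) -> bool:
        return name != self.vector_name

    @classmethod
    def from_genome(
        cls, genome: Genome, vector: Optional[str] = None, vector_name: str = None, k: int = 15
    ) -> "IndexedReference":
        from .simgen import VECTOR_NAME

        seqs = dict(genome.sequences)
        name = None
        if vector is not None:
            name = vector_name or VECTOR_NAME
            seqs[name] = vector
        return cls(seqs, vector_name=name, k=k)


# ---------------------------------------------------------------------------
# alignment helpers

_CIG_RE = re.compile(r"(\d+)([=XIDMS])")


def parse_cigar(cig: str) -> List[Tuple[str, int]]:
    return [(op, int(n)) for n, op in _CIG_RE.findall(cig)]


def _runs_from_matches(match: np.ndarray) -> List[Tuple[str, int]]:
    ops: List[Tuple[str, int]] = []
    if match.size == 0:
        return ops
    changes = np.flatnonzero(np.diff(match.astype(np.int8))) + 1
    bounds = np.concatenate(([0], changes, [match.size]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        ops.append(("=" if match[a] else "X", int(b - a)))
    return ops


def _best_local_segment(scores: np.ndarray) -> Tuple[float, int, int]:
    """Max-scoring contiguous segment (Kadane via prefix minima).

    Returns (score, start, end) with end exclusive; score 0 and an empty
    segment if everything is negative. Ties resolve to the shortest segment
    so zero-net flanking noise is never absorbed into an alignment.
    """
    c = np.concatenate(([0.0], np.cumsum(scores)))
    m = np.minimum.accumulate(c)
    gains = c - m
    j = int(np.argmax(gains))
    best = float(gains[j])
    if best <= 0:
        return 0.0, 0, 0
    i = int(np.flatnonzero(c[:j] == m[j])[-1])
    return best, i, j


#: X-drop: an alignment segment is split wherever its running score falls
#: this far below its running maximum (foreign sequence scores about
#: -1.25/bp here, so ~25 bp of non-matching sequence ends a segment)
XDROP = 30.0


def _xdrop_segments(scores: np.ndarray, x: float = XDROP) -> List[Tuple[int, int]]:
    """Maximal-scoring segments with bounded internal drawdown.

    Kadane's best segment may bridge a long run of mismatches (e.g. an
    inverted or foreign block) on the strength of its flanks; real local
    aligners terminate extension instead. Segments whose running score
    drops more than ``x`` below its peak are split at the peak and the
    remainder re-examined.
    """
    out: List[Tuple[int, int]] = []
    stack = [(0, len(scores))]
    while stack:
        lo, hi = stack.pop()
        if hi <= lo:
            continue
        best, i, j = _best_local_segment(scores[lo:hi])
        if j <= i:
            continue
        run = np.cumsum(scores[lo + i : lo + j])
        peak = np.maximum.accumulate(run)
        drop = peak - run
        t = int(np.argmax(drop))
        if drop[t] <= x:
            out.append((lo + i, lo + j))
            continue
        p = int(np.argmax(run[: t + 1]))
        stack.append((lo + i, lo + i + p + 1))
        stack.append((lo + i + t + 1, lo + j))
    out.sort()
    return out


def _score_ops(ops: Sequence[Tuple[str, int]]) -> float:
    s = 0.0
    for op, n in ops:
        if op == "=":
            s += MATCH * n
        elif op == "X":
            s += MISMATCH * n
        else:
            s += gap_cost(n)
    return s


def _trim_ops_local(
    ops: Sequence[Tuple[str, int]],
) -> List[Tuple[List[Tuple[str, int]], int, int, float]]:
    """High-scoring local sub-paths of an alignment path.

    Match/mismatch runs may be split; gap runs are atomic (an optimal local
    path never starts or ends inside a gap). Returns a list of
    (trimmed ops, query offset, target offset, score), one per X-drop
    segment.
    """
    events: List[Tuple[str, int]] = []
    for op, n in ops:
        if op in "=X":
            events.extend((op, 1) for _ in range(n))
        else:
            events.append((op, n))
    scores = np.array(
        [MATCH if op == "=" else MISMATCH if op == "X" else gap_cost(n)
         for op, n in events],
        dtype=float,
    )
    q_consumed = np.cumsum([n if op in "=XI" else 0 for op, n in events])
    t_consumed = np.cumsum([n if op in "=XD" else 0 for op, n in events])
    out = []
    for i, j in _xdrop_segments(scores):
        qoff = int(q_consumed[i - 1]) if i else 0
        toff = int(t_consumed[i - 1]) if i else 0
        trimmed: List[Tuple[str, int]] = []
        for op, n in events[i:j]:
            if trimmed and trimmed[-1][0] == op:
                trimmed[-1] = (op, trimmed[-1][1] + n)
            else:
                trimmed.append((op, n))
        out.append((trimmed, qoff, toff, float(scores[i:j].sum())))
    return out


# ---------------------------------------------------------------------------
# mapping


@dataclass
class _Chain:
    strand: str
    target: str
    qmin: int
    qmax: int
    tmin: int
    tmax: int
    diags: List[int]
    n_seeds: int = 1
    dominant_diag: Optional[int] = None  # set when one diagonal holds >=90%


def _collect_chains(
    index: IndexedReference, oriented: Dict[str, str], stride: int, band: int
) -> List[_Chain]:
    k = index.k
    chains: List[_Chain] = []
    for strand, s in oriented.items():
        hits: Dict[str, List[Tuple[int, int, int]]] = {}
        n = len(s)
        positions = list(range(0, n - k + 1, stride))
        if positions and positions[-1] != n - k:
            positions.append(n - k)
        get = index.index.get
        for q in positions:
            occ = get(s[q : q + k])
            if occ:
                for name, pos in occ:
                    hits.setdefault(name, []).append((pos - (q + 1), q + 1, pos))
        for target, hs in hits.items():
            hs.sort()
            cur = [hs[0]]
            for h in hs[1:]:
                if h[0] - cur[-1][0] > band:
                    chains.append(_make_chain(strand, target, cur, k))
                    cur = [h]
                else:
                    cur.append(h)
            chains.append(_make_chain(strand, target, cur, k))
    return chains


def _make_chain(strand, target, hits, k) -> _Chain:
    qs = [h[1] for h in hits]
    ts = [h[2] for h in hits]
    diag_counts: Dict[int, int] = {}
    for h in hits:
        diag_counts[h[0]] = diag_counts.get(h[0], 0) + 1
    top_diag, top_n = max(diag_counts.items(), key=lambda kv: (kv[1], -kv[0]))
    dominant = top_diag if top_n >= 0.9 * len(hits) else None
    return _Chain(
        strand, target, min(qs), max(qs) + k - 1, min(ts), max(ts) + k - 1,
        sorted(diag_counts), n_seeds=len(hits), dominant_diag=dominant,
    )


def _extend_gapless(
    chain: _Chain, s: str, sarr: np.ndarray, index: IndexedReference
) -> List[Tuple[List[Tuple[str, int]], int, int, int, int, float]]:
    d = chain.dominant_diag if chain.dominant_diag is not None else chain.diags[0]
    tarr = index.arrays[chain.target]
    q0 = max(1, 1 - d)
    q1 = min(len(s), len(tarr) - d)
    if q1 < q0:
        return []
    match = sarr[q0 - 1 : q1] == tarr[q0 + d - 1 : q1 + d]
    scores = np.where(match, float(MATCH), float(MISMATCH))
    out = []
    for i, j in _xdrop_segments(scores):
        ops = _runs_from_matches(match[i:j])
        qs, qe = q0 + i, q0 + j - 1
        out.append((ops, qs, qe, qs + d, qe + d, float(scores[i:j].sum())))
    return out


def _extend_edlib(
    chain: _Chain, s: str, index: IndexedReference, pad: int, band: int
) -> List[Tuple[List[Tuple[str, int]], int, int, int, int, float]]:
    import edlib

    target = index.sequences[chain.target]
    q0 = max(1, chain.qmin - pad)
    q1 = min(len(s), chain.qmax + pad)
    t0 = max(1, chain.tmin - pad - band)
    t1 = min(len(target), chain.tmax + pad + band)
    qseg = s[q0 - 1 : q1]
    twin = target[t0 - 1 : t1]
    res = edlib.align(qseg, twin, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return []
    tstart = res["locations"][0][0]
    ops = parse_cigar(res["cigar"])
    out = []
    for trimmed, qoff, toff, score in _trim_ops_local(ops):
        if not trimmed:
            continue
        qlen = sum(n for op, n in trimmed if op in "=XI")
        tlen = sum(n for op, n in trimmed if op in "=XD")
        qs = q0 + qoff
        ts = t0 + tstart + toff
        out.append((trimmed, qs, qs + qlen - 1, ts, ts + tlen - 1, score))
    return out


def map_read(
    index: IndexedReference,
    read_id: str,
    seq: str,
    *,
    min_identity: float = 0.8,
    min_seg: int = 15,
    band: int = 50,
    pad: int = 50,
    stride: Optional[int] = None,
) -> List[AlignmentRecord]:
    """Map one read; returns primary-first AlignmentRecords.

    All chains passing the identity/length filters are reported after
    resolving query-interval overlaps in favor of higher score; ties are
    broken by (target name, target start) so output order is deterministic.
    """
    if not seq:
        raise ValueError("empty read")
    if len(seq) < index.k:
        return []
    if stride is None:
        stride = 1 if len(seq) < 1000 else 5
    seq = seq.upper()
    oriented = {"+": seq, "-": revcomp(seq)}
    arrays = {st: np.frombuffer(s.encode(), dtype="S1") for st, s in oriented.items()}
    n = len(seq)

    # long reads sample seeds densely: chains with almost no seed support
    # are random k-mer noise and not worth extending
    min_seeds = 1 if n < 1000 else 3

    raw: List[AlignmentRecord] = []
    seen = set()
    for chain in _collect_chains(index, oriented, stride, band):
        if chain.n_seeds < min_seeds:
            continue
        s = oriented[chain.strand]
        if chain.dominant_diag is not None:
            exts = _extend_gapless(chain, s, arrays[chain.strand], index)
        else:
            exts = _extend_edlib(chain, s, index, pad, band)
        for ops, qs, qe, ts, te, score in exts:
            if qe - qs + 1 < min_seg:
                continue
            cols = sum(x for _, x in ops)
            matches = sum(x for op, x in ops if op == "=")
            identity = matches / cols if cols else 0.0
            if identity < min_identity:
                continue
            if chain.strand == "-":
                qs, qe = n - qe + 1, n - qs + 1
            key = (chain.target, chain.strand, qs, qe, ts, te)
            if key in seen:
                continue
            seen.add(key)
            raw.append(
                AlignmentRecord(
                    read_id=read_id,
                    query_start=qs,
                    query_end=qe,
                    target=chain.target,
                    target_start=ts,
                    target_end=te,
                    strand=chain.strand,
                    identity=identity,
                    ops=ops,
                    score=score,
                )
            )

    raw.sort(key=lambda r: (-r.score, r.target, r.target_start, r.strand))
    kept: List[AlignmentRecord] = []
    for rec in raw:
        overlap = 0
        for kr in kept:
            overlap = max(
                overlap,
                min(rec.query_end, kr.query_end)
                - max(rec.query_start, kr.query_start)
                + 1,
            )
        if overlap > 0.5 * rec.query_span:
            continue
        kept.append(rec)
    if kept:
        kept[0].is_primary = True
    return kept


def map_read_pair(
    index: IndexedReference, mate1: Tuple[str, str], mate2: Tuple[str, str], **kw
) -> Tuple[List[AlignmentRecord], List[AlignmentRecord], bool]:
    """Map both mates independently; flag the pair discordant when their
    primary alignments hit different target records (e.g. host vs vector)."""
    r1 = map_read(index, mate1[0], mate1[1], **kw)
    r2 = map_read(index, mate2[0], mate2[1], **kw)
    discordant = bool(r1 and r2 and r1[0].target != r2[0].target)
    return r1, r2, discordant


# ---------------------------------------------------------------------------
# SAM import/export (plain text SAM via pysam)


def write_sam(
    records: Sequence[AlignmentRecord],
    reference: Dict[str, str],
    path,
    read_seqs: Dict[str, str],
) -> None:
    names = list(reference)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(reference[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            if rec.target not in tid:
                raise ValueError(f"unknown reference name {rec.target!r}")
            seq = read_seqs[rec.read_id]
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            flag = 0
            if rec.strand == "-":
                flag |= 16
            if not rec.is_primary:
                flag |= 2048
            a.flag = flag
            a.reference_id = tid[rec.target]
            a.reference_start = rec.target_start - 1
            a.mapping_quality = 60
            a.cigarstring = rec.cigar(len(seq))
            a.query_sequence = seq if rec.strand == "+" else revcomp(seq)
            a.set_tag("AS", int(rec.score))
            nm = sum(n for op, n in rec.ops if op in "XID")
            a.set_tag("NM", nm)
            out.write(a)


def read_sam(path) -> Tuple[List[AlignmentRecord], Dict[str, str]]:
    """Parse a SAM file back into AlignmentRecords (+ read sequences).

    Files from external mappers are accepted: 'M' CIGAR ops are resolved
    into match/mismatch counts via the NM tag when present, otherwise
    treated as matches.
    """
    records: List[AlignmentRecord] = []
    seqs: Dict[str, str] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.cigarstring is None:
                continue
            ops = parse_cigar(a.cigarstring)
            lead = ops[0][1] if ops and ops[0][0] == "S" else 0
            tail = ops[-1][1] if ops and ops[-1][0] == "S" else 0
            core = [(op, n) for op, n in ops if op != "S"]
            read_len = sum(n for op, n in ops if op in "=XIMS")
            strand = "-" if a.is_reverse else "+"
            if strand == "+":
                qs, qe = lead + 1, read_len - tail
            else:
                qs, qe = tail + 1, read_len - lead
            cols = sum(n for _, n in core)
            m_like = sum(n for op, n in core if op in "=M")
            mism = sum(n for op, n in core if op == "X")
            if a.has_tag("NM") and any(op == "M" for op, _ in core):
                nm = a.get_tag("NM")
                gaps = sum(n for op, n in core if op in "ID")
                mism = max(0, nm - gaps)
                m_like -= mism
            identity = m_like / cols if cols else 0.0
            rec = AlignmentRecord(
                read_id=a.query_name,
                query_start=qs,
                query_end=qe,
                target=a.reference_name,
                target_start=a.reference_start + 1,
                target_end=a.reference_end,
                strand=strand,
                identity=identity,
                ops=core,
                score=float(a.get_tag("AS")) if a.has_tag("AS") else 0.0,
                is_primary=not (a.is_secondary or a.is_supplementary),
            )
            records.append(rec)
            if a.query_sequence:
                s = a.query_sequence
                seqs[a.query_name] = s if strand == "+" else revcomp(s)
    return records, seqs


def group_by_read(records: Iterable[AlignmentRecord]) -> Dict[str, List[AlignmentRecord]]:
    grouped: Dict[str, List[AlignmentRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.read_id, []).append(rec)
    return grouped


# ---------------------------------------------------------------------------
# exact oracle


def smith_waterman_score(query: str, target: str) -> float:
    """Exact local alignment score under the mapper's scoring scheme.

    Affine gaps (open -4 charged once plus -1 per base). Row-vectorized DP:
    the horizontal (target-side) gap state is computed with a prefix-maximum
    scan, which is exact because chaining through an existing horizontal gap
    is never better than extending it directly.
    """
    q = np.frombuffer(query.encode(), dtype="S1")
    t = np.frombuffer(target.encode(), dtype="S1")
    n, m = len(q), len(t)
    neg = -1e9
    H = np.zeros(m + 1)
    F = np.full(m + 1, neg)
    jdx = np.arange(m + 1, dtype=float)
    best = 0.0
    for i in range(n):
        sub = np.where(t == q[i], float(MATCH), float(MISMATCH))
        F = np.maximum(F + GAP_EXTEND, H + GAP_OPEN + GAP_EXTEND)
        Hne = np.zeros(m + 1)
        Hne[1:] = np.maximum(H[:-1] + sub, F[1:])
        Hne = np.maximum(Hne, 0.0)
        # E[j] = max_{k<j} Hne[k] - 4 - (j - k)
        run = np.maximum.accumulate(Hne + jdx)
        E = np.full(m + 1, neg)
        E[1:] = run[:-1] - 4.0 - jdx[1:]
        H = np.maximum(Hne, E)
        best = max(best, float(H.max()))
    return best
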