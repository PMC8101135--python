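"""Shared domain types for T-DNA integration analysis.

Coordinate convention: all genomic intervals are 1-based inclusive
(matching how insertion sites are reported in the plant-transformation
literature, e.g. "Chr03:9,283,905-9,283,937"). Conversion to 0-based
half-open happens only at BED export boundaries. A zero-width (blunt)
interval is encoded as ``end == start - 1``: the insertion sits between
``start - 1`` and ``start`` with no host base removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """An in-memory genome: ordered mapping of sequence name -> sequence."""

    sequences: Dict[str, str]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, name: str, start: int, end: int) -> str:
        """Subsequence at 1-based inclusive [start, end]."""
        if start < 1 or end > len(self.sequences[name]):
            raise ValueError(
                f"interval {name}:{start}-{end} outside sequence of length "
                f"{len(self.sequences[name])}"
            )
        return self.sequences[name][start - 1 : end]

    def names(self) -> List[str]:
        return list(self.sequences)


@dataclass
class GeneModel:
    """A planted gene annotation: gene interval plus ordered exons."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")
        prev_end = None
        for (s, e) in sorted(self.exons):
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene body")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e


@dataclass
class Feature:
    """A named feature interval on the canonical T-DNA (1-based inclusive)."""

    name: str
    start: int
    end: int


@dataclass
class TDnaConstruct:
    """The canonical T-DNA unit of the transformation vector.

    Written 5'->3' with the left border (LB) starting at position 1 and the
    right border (RB) ending at position L. Feature names must be unique and
    include "LB" and "RB".
    """

    sequence: str
    features: List[Feature]

    def __post_init__(self) -> None:
        L = len(self.sequence)
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names on construct")
        by_name = {f.name: f for f in self.features}
        for f in self.features:
            if f.start < 1 or f.end > L or f.end < f.start:
                raise ValueError(f"feature {f.name} outside construct [1,{L}]")
        if "LB" not in by_name or by_name["LB"].start != 1:
            raise ValueError("construct must carry an LB feature containing position 1")
        if "RB" not in by_name or by_name["RB"].end != L:
            raise ValueError("construct must carry an RB feature ending at position L")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


@dataclass
class IntegrationEvent:
    """Ground truth for one T-DNA integration.

    ``del_start``/``del_end`` is the host interval removed at the target site
    (blunt insertion: del_end = del_start - 1). ``copies`` is the ordered
    list of per-copy orientations; "forward" places the canonical unit on the
    host + strand, "reverse" its reverse complement. Truncations are plain
    end-deletions measured from the canonical LB/RB ends, so values larger
    than the 25-bp border repeat are representable.
    """

    chrom: str
    del_start: int
    del_end: int
    copies: List[str] = field(default_factory=lambda: ["forward"])
    lb_trunc: int = 0
    rb_trunc: int = 0
    filler_left: str = ""
    filler_right: str = ""
    deleted_features: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.lb_trunc < 0 or self.rb_trunc < 0:
            raise ValueError("truncations must be >= 0")
        if self.del_end < self.del_start - 1:
            raise ValueError("del_end may be at most del_start - 1 (blunt)")
        if not self.copies:
            raise ValueError("at least one T-DNA copy required")
        for o in self.copies:
            if o not in ("forward", "reverse"):
                raise ValueError(f"bad copy orientation {o!r}")
        for s in (self.filler_left, self.filler_right):
            if set(s) - set("ACGT"):
                raise ValueError("filler sequences must be over ACGT")

    @property
    def orientation(self) -> str:
        return self.copies[0]

    @property
    def deletion_width(self) -> int:
        return self.del_end - self.del_start + 1


@dataclass
class SVEvent:
    """One structural variant (split-read scale: DEL/INS/INV/DUP/TRA)."""

    svtype: str
    chrom: str
    start: int
    end: int
    length: int
    support: int = 0
    chrom2: Optional[str] = None
    pos2: Optional[int] = None

    def __post_init__(self) -> None:
        if self.svtype not in ("DEL", "INS", "INV", "DUP", "TRA"):
            raise ValueError(f"bad SV type {self.svtype!r}")


@dataclass
class AlignmentRecord:
    """One local alignment of a read segment to a reference sequence.

    Query coordinates are 1-based inclusive *on the read as sequenced*;
    target coordinates are 1-based inclusive and always ascending. ``ops``
    is a run-length list over {'=','X','I','D'} along the target direction
    ('I' consumes query only, 'D' target only).
    """

    read_id: str
    query_start: int
    query_end: int
    target: str
    target_start: int
    target_end: int
    strand: str
    identity: float
    ops: List[Tuple[str, int]]
    score: float = 0.0
    is_primary: bool = False

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start + 1

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start + 1

    def validate(self) -> None:
        q = sum(n for op, n in self.ops if op in "=XI")
        t = sum(n for op, n in self.ops if op in "=XD")
        if q != self.query_span or t != self.target_span:
            raise ValueError(
                f"{self.read_id}: ops sum (q={q}, t={t}) inconsistent with "
                f"intervals (q={self.query_span}, t={self.target_span})"
            )

    def cigar(self, read_length: int) -> str:
        """SAM CIGAR with soft clips for the unaligned query ends."""
        if self.strand == "+":
            left, right = self.query_start - 1, read_length - self.query_end
        else:
            left, right = read_length - self.query_end, self.query_start - 1
        parts = []
        if left:
            parts.append(f"{left}S")
        parts.extend(f"{n}{op}" for op, n in self.ops)
        if right:
            parts.append(f"{right}S")
        return "".join(parts)


def ops_matches(ops: Sequence[Tuple[str, int]]) -> int:
    return sum(n for op, n in ops if op == "=")


def ops_columns(ops: Sequence[Tuple[str, int]]) -> int:
    return sum(n for _, n in ops)


def to_jsonable(obj):
    """Recursively turn dataclasses/sets into JSON-serializable structures."""
    if hasattr(obj, "__dataclass_fields__"):
        return {k: to_jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, dict):
        return {k: to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    return obj
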