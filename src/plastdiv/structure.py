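"""Quadripartite plastome structure: IR detection and region summaries.

Angiosperm chloroplast genomes are circular molecules with two identical
regions in opposite orientation — the inverted repeats IRa and IRb (IRb is
the reverse complement of IRa) — separating a large and a small single-copy
region (LSC, SSC).  :func:`detect_inverted_repeat` finds the longest pair of
disjoint spans such that one equals the reverse complement of the other, by
seed-and-extend over exact k-mer matches between the sequence and its
reverse complement; circularity is honored by scanning the doubled
sequence.  Detected spans are self-checking: the postcondition verifies the
reverse-complement equality by direct string comparison.

:func:`partition_regions` assigns the two inter-IR arcs to LSC (the longer)
and SSC, and :func:`summarize_plastome` produces a per-genome summary row:
region coordinates and lengths, per-region GC, and a gene census by kind
(annotated occurrences, so IR-duplicated genes count once per copy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment import FeatureTable

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class NoInvertedRepeatError(ValueError):
    """No reverse-complement repeat of the required length was found."""

    def __init__(self, min_length: int, best: "Span | None",
                 best_partner: "Span | None"):
        self.best = best
        self.best_partner = best_partner
        found = (f"; longest candidate: {best} / {best_partner}"
                 if best else "; no candidate at all")
        super().__init__(f"no IR found with length >= {min_length}{found}")


@dataclass(frozen=True, order=True)
class Span:
    """A region on a circular sequence of length ``n``.

    ``start`` is normalized to ``[0, n)``; ``end = start + length`` may
    exceed ``n``, meaning the span wraps past the origin.
    """

    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length

    def extract(self, seq: str) -> str:
        n = len(seq)
        if self.end <= n:
            return seq[self.start:self.end]
        return seq[self.start:] + seq[:self.end - n]

    def overlaps(self, other: "Span", n: int) -> bool:
        """Circular overlap test for spans on a length-``n`` sequence."""
        for a0 in (self.start, self.start - n):
            a1 = a0 + self.length
            b0, b1 = other.start, other.end
            if a0 < b1 and b0 < a1:
                return True
        return False


def _seed_matches(seq: str, k: int) -> dict[str, list[int]]:
    """Index of k-mer -> start positions in the doubled sequence."""
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i:i + k], []).append(i)
    return idx


def detect_inverted_repeat(sequence: str, min_length: int = 10_000,
                           seed_k: int = 24) -> tuple[Span, Span]:
    """Locate the two inverted repeats of a (circular) plastome sequence.

    Returns ``(IRa, IRb)`` — the longest pair of disjoint spans with one
    equal to the reverse complement of the other (exact match), ties broken
    by leftmost start.  IRa is the span with the smaller start.  Raises
    :class:`NoInvertedRepeatError` (carrying the longest candidate found)
    when nothing reaches ``min_length``.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    seq = sequence.upper()
    n = len(seq)
    if n < 2 * min_length:
        raise NoInvertedRepeatError(min_length, None, None)
    k = max(4, min(seed_k, min_length))
    dbl = seq + seq
    rc = revcomp(seq)
    rc_dbl = rc + rc
    rc_index = _seed_matches(rc_dbl, k)

    # Seeds on the same (i - j) diagonal belong to one gapless match; keep
    # only the first seed met per diagonal, then extend it maximally.
    seen_diagonals: set[int] = set()
    candidates: list[tuple[int, int, int]] = []  # (i, j, length) in dbl coords
    max_len = n  # never extend past one full circle
    for i in range(0, len(dbl) - k + 1):
        for j in rc_index.get(dbl[i:i + k], ()):
            d = i - j
            if d in seen_diagonals:
                continue
            seen_diagonals.add(d)
            lo = 0
            while (i - lo - 1 >= 0 and j - lo - 1 >= 0
                   and dbl[i - lo - 1] == rc_dbl[j - lo - 1]):
                lo += 1
            hi = k
            while (i + hi < len(dbl) and j + hi < len(rc_dbl)
                   and hi + lo < max_len
                   and dbl[i + hi] == rc_dbl[j + hi]):
                hi += 1
            candidates.append((i - lo, j - lo, lo + hi))

    best: tuple[Span, Span] | None = None
    best_any: tuple[Span, Span] | None = None
    for i, j, length in candidates:
        span_a = Span(i % n, length)
        # rc_dbl position j maps back to forward-strand circular coordinates:
        # rc[j] == complement(seq[n-1-j]), so the matched forward segment is
        # [n - (j % n) - length, n - (j % n)) on the circle.
        span_b = Span((n - (j % n) - length) % n, length)
        a, b = sorted((span_a, span_b))
        if a.overlaps(b, n) or length > n // 2:
            continue
        key = (length, -a.start)
        if best_any is None or key > (best_any[0].length, -best_any[0].start):
            best_any = (a, b)
        if length >= min_length:
            if best is None or key > (best[0].length, -best[0].start):
                best = (a, b)
    if best is None:
        raise NoInvertedRepeatError(
            min_length, *(best_any if best_any else (None, None)))
    ira, irb = best
    assert ira.extract(seq) == revcomp(irb.extract(seq)), \
        "IR postcondition violated"
    return ira, irb


@dataclass
class PlastomeStructure:
    """Quadripartite summary of one plastome (a Table-1-style row)."""

    total_length: int
    lsc: Span
    ssc: Span
    ira: Span
    irb: Span
    gc_total: float | None = None
    gc_lsc: float | None = None
    gc_ssc: float | None = None
    gc_ir: float | None = None
    gene_census: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = (self.lsc.length + self.ssc.length
                 + self.ira.length + self.irb.length)
        if total != self.total_length:
            raise ValueError(
                f"region lengths sum to {total}, not {self.total_length}")

    def to_json_dict(self) -> dict:
        def span(s: Span) -> dict:
            return {"start": s.start, "end": s.end, "length": s.length}
        return {
            "total_length": self.total_length,
            "LSC": span(self.lsc), "SSC": span(self.ssc),
            "IRa": span(self.ira), "IRb": span(self.irb),
            "gc": {"total": self.gc_total, "LSC": self.gc_lsc,
                   "SSC": self.gc_ssc, "IR": self.gc_ir},
            "gene_census": self.gene_census,
        }


def gc_content(sequence: str) -> float | None:
    """GC percentage over unambiguous bases: (G+C)/(A+C+G+T) x 100.

    N (and gaps) are excluded from the denominator; a region with no
    unambiguous base at all reports None.
    """
    if not sequence:
        raise ValueError("empty region")
    counts = {b: sequence.upper().count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return None
    return (counts["G"] + counts["C"]) / denom * 100.0


def partition_regions(sequence: str, ira: Span, irb: Span
                      ) -> tuple[Span, Span, Span, Span]:
    """Assign the two inter-IR arcs: returns ``(lsc, ira, ssc, irb)``.

    The longer arc is the LSC (on a tie the arc following the first IR is
    named LSC, with a warning).  The returned IR spans are relabelled so the
    order LSC -> IRa -> SSC -> IRb runs forward around the circle from the
    LSC start — the canonical linearization.
    """
    n = len(sequence)
    a, b = sorted((ira, irb))
    if a.overlaps(b, n):
        raise ValueError("IR spans overlap")
    arc1 = Span(a.end % n, (b.start - a.end) % n)        # after a, before b
    arc2 = Span(b.end % n, (a.start - b.end) % n)        # after b, before a
    if arc1.length == arc2.length:
        logger.warning("inter-IR arcs have equal length %d; naming the arc "
                       "after the first repeat LSC", arc1.length)
    if arc1.length >= arc2.length:
        # forward from the LSC start the order is arc1 -> b -> arc2 -> a
        lsc, ssc = arc1, arc2
        ira_out, irb_out = b, a
    else:
        lsc, ssc = arc2, arc1
        ira_out, irb_out = a, b
    return lsc, ira_out, ssc, irb_out


def summarize_plastome(sequence: str, features: FeatureTable | None = None,
                       min_ir_length: int = 10_000) -> PlastomeStructure:
    """Full quadripartite summary of one plastome sequence."""
    seq = sequence.upper()
    ira, irb = detect_inverted_repeat(seq, min_length=min_ir_length)
    lsc, ira, ssc, irb = partition_regions(seq, ira, irb)
    census = features.census() if features is not None else {}
    return PlastomeStructure(
        total_length=len(seq), lsc=lsc, ssc=ssc, ira=ira, irb=irb,
        gc_total=gc_content(seq),
        gc_lsc=gc_content(lsc.extract(seq)),
        gc_ssc=gc_content(ssc.extract(seq)),
        gc_ir=gc_content(ira.extract(seq)),
        gene_census=census,
    )


def base_frequencies(sequence: str) -> dict[str, float]:
    """Percent frequency of each of A, C, G, T over all positions (N counted
    in the denominator is avoided: frequencies are over unambiguous bases)."""
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("no unambiguous bases")
    return {b: c / denom * 100.0 for b, c in counts.items()}
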