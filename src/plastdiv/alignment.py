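"""Aligned-sequence and annotation I/O.

The canonical in-memory object consumed by every analysis stage is
:class:`Alignment`: an ordered set of equal-length gapped sequences over the
alphabet ``{A, C, G, T, N, -}``.  Sequences are normalized on construction —
lowercase is uppercased and any IUPAC ambiguity code is converted to ``N``
(counted and logged), so downstream code only ever sees the six canonical
symbols.  Alignment construction itself (e.g. MAFFT) is out of scope: the
reader consumes pre-built aligned FASTA.

Internally all coordinates are 0-based half-open; user-facing reports are
1-based inclusive, following the GenBank convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical alphabet, as byte values.
_A, _C, _G, _T, _N, GAP = (ord(c) for c in "ACGTN-")
ALPHABET = frozenset(b"ACGTN-")
#: IUPAC ambiguity codes normalized to N on load.
_AMBIGUITY = frozenset(b"RYSWKMBDHVU")

_NORMALIZE = np.arange(256, dtype=np.uint8)
for _b in b"acgtn":
    _NORMALIZE[_b] = ord(chr(_b).upper())
for _b in _AMBIGUITY | frozenset(bytes(_AMBIGUITY).lower()):
    _NORMALIZE[_b] = _N
_NORMALIZE[_T] = _T  # no-op; keeps table explicit


class AlignmentError(ValueError):
    """Raised for malformed alignments (unequal lengths, bad symbols...)."""


def _encode_row(label: str, seq: str) -> tuple[np.ndarray, int]:
    """Encode one sequence to bytes, normalizing case and ambiguity codes.

    Returns the encoded row and the number of ambiguity substitutions made.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    ambiguous = int(np.isin(raw, np.frombuffer(
        bytes(_AMBIGUITY) + bytes(_AMBIGUITY).lower(), dtype=np.uint8)).sum())
    row = _NORMALIZE[raw]
    bad = ~np.isin(row, np.frombuffer(b"ACGTN-", dtype=np.uint8))
    if bad.any():
        sym = chr(raw[np.argmax(bad)])
        raise AlignmentError(
            f"record {label!r}: unsupported symbol {sym!r} "
            "(alphabet is A,C,G,T,N,- plus IUPAC ambiguity codes; "
            "'.' gaps are rejected)")
    return row, ambiguous


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment with row-major byte storage."""

    taxa: tuple[str, ...]
    matrix: np.ndarray  # uint8, shape (n_taxa, length)

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise AlignmentError("matrix shape does not match taxa")
        if self.matrix.shape[1] < 1:
            raise AlignmentError("alignment must have at least one column")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = {t for t in self.taxa if self.taxa.count(t) > 1}
            raise AlignmentError(f"duplicate taxon labels: {sorted(dupes)}")
        if any(not t for t in self.taxa):
            raise AlignmentError("empty taxon label")

    # -- construction ---------------------------------------------------
    @classmethod
    def from_strings(cls, records: Iterable[tuple[str, str]]) -> "Alignment":
        """Build from ``(label, sequence)`` pairs, applying normalization."""
        taxa: list[str] = []
        rows: list[np.ndarray] = []
        n_ambiguous = 0
        length: int | None = None
        for label, seq in records:
            row, amb = _encode_row(label, seq)
            n_ambiguous += amb
            if length is None:
                length = row.size
            elif row.size != length:
                raise AlignmentError(
                    f"not aligned: record {label!r} has length {row.size}, "
                    f"expected {length}")
            taxa.append(label)
            rows.append(row)
        if not rows:
            raise AlignmentError("no records")
        if n_ambiguous:
            logger.info("normalized %d IUPAC ambiguity symbol(s) to N",
                        n_ambiguous)
        return cls(tuple(taxa), np.vstack(rows))

    # -- basic accessors -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return int(self.matrix.shape[1])

    def index(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment") from None

    def row(self, taxon: str) -> str:
        return self.matrix[self.index(taxon)].tobytes().decode("ascii")

    def ungapped(self, taxon: str) -> str:
        r = self.matrix[self.index(taxon)]
        return r[r != GAP].tobytes().decode("ascii")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Alignment {self.n_taxa} taxa x {self.length} columns>"

    # -- coordinate mapping ----------------------------------------------
    def _gapless_columns(self, taxon: str) -> np.ndarray:
        """Alignment columns holding the row's non-gap characters, in order."""
        return np.flatnonzero(self.matrix[self.index(taxon)] != GAP)

    def map_ungapped_to_alignment(self, taxon: str, position: int) -> int:
        """Alignment column holding ``position``-th non-gap character."""
        cols = self._gapless_columns(taxon)
        if not 0 <= position < cols.size:
            raise IndexError(
                f"ungapped position {position} out of range for {taxon!r} "
                f"(ungapped length {cols.size})")
        return int(cols[position])

    def map_alignment_to_ungapped(self, taxon: str, column: int) -> int:
        """Inverse of :meth:`map_ungapped_to_alignment` on non-gap columns."""
        if not 0 <= column < self.length:
            raise IndexError(f"column {column} out of range")
        r = self.matrix[self.index(taxon)]
        if r[column] == GAP:
            raise ValueError(f"column {column} is a gap in {taxon!r}")
        return int(np.count_nonzero(r[:column] != GAP))


def read_alignment(path: str | Path) -> Alignment:
    """Read a multi-record aligned FASTA file.

    Rows keep file order; lowercase and ambiguity codes are normalized.
    Raises :class:`AlignmentError` on unequal record lengths ("not aligned"),
    duplicate labels, or fewer than two records.
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if len(records) < 2:
        raise AlignmentError(f"{path}: need at least 2 records, got {len(records)}")
    return Alignment.from_strings(records)


def write_alignment(alignment: Alignment, path: str | Path, width: int = 70) -> None:
    """Write aligned FASTA (one wrapped record per taxon)."""
    with open(path, "w") as fh:
        for i, taxon in enumerate(alignment.taxa):
            fh.write(f">{taxon}\n")
            seq = alignment.matrix[i].tobytes().decode("ascii")
            for start in range(0, len(seq), width):
                fh.write(seq[start:start + width] + "\n")


# ---------------------------------------------------------------------------
# annotation features
# ---------------------------------------------------------------------------

FEATURE_KINDS = ("coding", "tRNA", "rRNA", "other")
_KEY_TO_KIND = {"CDS": "coding", "tRNA": "tRNA", "rRNA": "rRNA"}
#: GenBank feature keys ignored entirely (containers / bookkeeping).
_SKIP_KEYS = {"source", "gene", "exon", "intron", "misc_feature"}


@dataclass(frozen=True)
class Feature:
    """One annotated locus on the ungapped reference sequence."""

    name: str
    kind: str  # one of FEATURE_KINDS
    intervals: tuple[tuple[int, int], ...]  # 0-based half-open
    strand: str  # '+' or '-'

    @property
    def start(self) -> int:
        return min(s for s, _ in self.intervals)

    @property
    def end(self) -> int:
        return max(e for _, e in self.intervals)


@dataclass
class FeatureTable:
    """Annotated features of one genome, ordered by position."""

    features: list[Feature] = field(default_factory=list)

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def census(self) -> dict[str, int]:
        """Counts of annotated occurrences by kind (IR duplicates count twice)."""
        out = {k: 0 for k in FEATURE_KINDS}
        for f in self.features:
            out[f.kind] += 1
        return out

    def sorted_by_position(self) -> list[Feature]:
        return sorted(self.features, key=lambda f: (f.start, f.end))

    def validate(self, sequence_length: int) -> None:
        for f in self.features:
            for s, e in f.intervals:
                if not (0 <= s < e <= sequence_length):
                    raise ValueError(
                        f"feature {f.name!r}: interval [{s},{e}) outside "
                        f"sequence of length {sequence_length}")


def read_genbank_features(path: str | Path) -> tuple[FeatureTable, str]:
    """Parse a GenBank flatfile into a :class:`FeatureTable` plus its sequence.

    CDS features map to kind ``coding``; tRNA and rRNA keep their key; every
    other annotated feature becomes ``other``.  ``join``/``complement``
    locations are flattened to 0-based half-open interval lists.  Features
    with unparseable locations are skipped with a warning.
    """
    record = SeqIO.read(str(path), "genbank")
    sequence = str(record.seq).upper()
    if not sequence or set(sequence) == {"N"}:
        raise ValueError(f"{path}: flatfile has no usable ORIGIN sequence")
    table = FeatureTable()
    skipped = 0
    for feat in record.features:
        if feat.type in _SKIP_KEYS:
            continue
        kind = _KEY_TO_KIND.get(feat.type, "other")
        name = feat.qualifiers.get("gene", feat.qualifiers.get(
            "product", [feat.type]))[0]
        try:
            intervals = tuple(sorted(
                (int(part.start), int(part.end)) for part in feat.location.parts))
            strand = "-" if feat.location.strand == -1 else "+"
        except (TypeError, AttributeError):
            skipped += 1
            continue
        table.features.append(Feature(name, kind, intervals, strand))
    if skipped:
        logger.warning("%s: skipped %d feature(s) with unparseable locations",
                       path, skipped)
    table.validate(len(sequence))
    return table, sequence


def write_genbank(sequence: str, table: FeatureTable, path: str | Path,
                  name: str = "plastome") -> None:
    """Write a minimal GenBank flatfile (ORIGIN + flattened features).

    The inverse of :func:`read_genbank_features` for synthetic references;
    multi-interval features are emitted as ``join`` locations.
    """
    from Bio.Seq import Seq
    from Bio.SeqFeature import (CompoundLocation, SeqFeature, SimpleLocation)
    from Bio.SeqRecord import SeqRecord

    kind_to_key = {"coding": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                   "other": "misc_RNA"}
    record = SeqRecord(Seq(sequence), id=name, name=name[:16],
                       description="synthetic plastome",
                       annotations={"molecule_type": "DNA",
                                    "topology": "circular"})
    for f in table.sorted_by_position():
        strand = -1 if f.strand == "-" else 1
        parts = [SimpleLocation(s, e, strand) for s, e in f.intervals]
        loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        record.features.append(SeqFeature(
            loc, type=kind_to_key[f.kind], qualifiers={"gene": [f.name]}))
    SeqIO.write([record], str(path), "genbank")


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write features as TSV (1-based inclusive coordinates, GenBank style)."""
    with open(path, "w") as fh:
        fh.write("name\tkind\tstrand\tstart\tend\tintervals\n")
        for f in table.sorted_by_position():
            ivals = ",".join(f"{s + 1}-{e}" for s, e in f.intervals)
            fh.write(f"{f.name}\t{f.kind}\t{f.strand}\t{f.start + 1}\t"
                     f"{f.end}\t{ivals}\n")
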