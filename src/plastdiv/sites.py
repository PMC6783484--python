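"""Per-column site classification and private/shared SNP partitioning.

Every alignment column gets a :class:`SiteRecord` with two independent flags:

``is_indel``
    at least one row carries a gap in the column;
``is_snp``
    at least two distinct nucleotide states among the non-missing rows
    (gaps and N are missing — they never create nor block a SNP call,
    they only shrink the informative taxon set).

A column can be both (a gapped column may still segregate a SNP among the
ungapped taxa), and columns with fewer than two informative rows are
*uninformative* — neither SNP nor monomorphic.

The private/shared partition (:func:`snp_partition`) credits, at each SNP
column, every allele class ``C`` with ``1 <= |C| < n_informative``: all taxa
in ``C`` share one state and every other informative taxon carries a
different one.  A size-1 class is a *private* SNP of that taxon — including
columns where the remaining taxa are polymorphic among themselves, which is
why, with five taxa, the private count of a species can exceed the count of
the complementary four-species class.  Subsets of the full taxon set arising
from monomorphic columns are never credited.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignment import Alignment, GAP, AlignmentError

_Nb = ord("N")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True, slots=True)
class SiteRecord:
    """Classification of one alignment column.

    ``alleles`` maps each observed nucleotide state to the tuple of taxon
    indices carrying it; ``missing`` lists taxa with gap or N.  Together they
    partition the taxon set.
    """

    column: int
    is_indel: bool
    is_snp: bool
    alleles: tuple[tuple[str, tuple[int, ...]], ...]
    missing: tuple[int, ...]

    @property
    def n_informative(self) -> int:
        return sum(len(t) for _, t in self.alleles)

    @property
    def is_uninformative(self) -> bool:
        return self.n_informative < 2

    @property
    def is_monomorphic(self) -> bool:
        return self.n_informative >= 2 and len(self.alleles) == 1


def classify_columns(alignment: Alignment) -> list[SiteRecord]:
    """Classify every column of the alignment (one record per column)."""
    if alignment.n_taxa < 2:
        raise AlignmentError("need at least 2 taxa to classify columns")
    m = alignment.matrix
    informative = (m != GAP) & (m != _Nb)
    indel_cols = (m == GAP).any(axis=0)
    # SNP flag: >= 2 distinct states among informative rows, vectorized as
    # "some informative pair of rows disagrees".
    base_presence = np.stack([((m == b) & informative).any(axis=0)
                              for b in _BASES])
    snp_cols = base_presence.sum(axis=0) >= 2

    records: list[SiteRecord] = []
    for col in range(alignment.length):
        colv = m[:, col]
        inf = informative[:, col]
        alleles: list[tuple[str, tuple[int, ...]]] = []
        for b in _BASES:
            idx = np.flatnonzero((colv == b) & inf)
            if idx.size:
                alleles.append((chr(b), tuple(int(i) for i in idx)))
        missing = tuple(int(i) for i in np.flatnonzero(~inf))
        records.append(SiteRecord(
            column=col,
            is_indel=bool(indel_cols[col]),
            is_snp=bool(snp_cols[col]),
            alleles=tuple(alleles),
            missing=missing,
        ))
    return records


@dataclass
class SubsetCountTable:
    """SNP counts per non-trivial taxon subset (the Venn regions).

    Keys are tuples of taxon labels sorted in alignment order; only subsets
    credited at least once appear.  ``total_snp_columns`` is the number of
    columns flagged as SNPs.
    """

    taxa: tuple[str, ...]
    counts: dict[tuple[str, ...], int]
    total_snp_columns: int

    def count(self, subset: Iterable[str]) -> int:
        return self.counts.get(self._key(subset), 0)

    def private(self, taxon: str) -> int:
        return self.count((taxon,))

    def _key(self, subset: Iterable[str]) -> tuple[str, ...]:
        order = {t: i for i, t in enumerate(self.taxa)}
        members = tuple(sorted(subset, key=order.__getitem__))
        unknown = [t for t in members if t not in order]
        if unknown:
            raise KeyError(f"taxa not in table: {unknown}")
        return members

    def to_json_dict(self) -> dict:
        return {
            "taxa": list(self.taxa),
            "total_snp_columns": self.total_snp_columns,
            "counts": {"|".join(k): v for k, v in sorted(self.counts.items())},
        }


def snp_partition(records: Sequence[SiteRecord],
                  taxa: Sequence[str]) -> SubsetCountTable:
    """Credit taxon subsets with SNPs across all columns (Venn partition).

    At each SNP column every allele class ``C`` with ``1 <= |C| <
    n_informative`` is credited once.  Each (column, subset) pair is credited
    at most once; allele classes are disjoint so this holds by construction.
    """
    taxa = tuple(taxa)
    n = len(taxa)
    for rec in records:
        touched = {i for _, tt in rec.alleles for i in tt} | set(rec.missing)
        if touched and max(touched) >= n:
            raise AlignmentError(
                "records refer to taxon indices outside the given taxa")
        if len(touched) != n:
            raise AlignmentError(
                f"column {rec.column}: records cover {len(touched)} taxa, "
                f"expected {n}")
    counts: dict[tuple[str, ...], int] = {}
    total = 0
    for rec in records:
        if not rec.is_snp:
            continue
        total += 1
        n_inf = rec.n_informative
        for _state, members in rec.alleles:
            if 1 <= len(members) < n_inf:
                key = tuple(taxa[i] for i in sorted(members))
                counts[key] = counts.get(key, 0) + 1
    return SubsetCountTable(taxa=taxa, counts=counts, total_snp_columns=total)


def count_totals(records: Sequence[SiteRecord]) -> dict[str, int]:
    """Column tallies: SNP, indel, uninformative and monomorphic columns."""
    return {
        "snp_columns": sum(r.is_snp for r in records),
        "indel_columns": sum(r.is_indel for r in records),
        "uninformative_columns": sum(r.is_uninformative for r in records),
        "monomorphic_columns": sum(
            r.is_monomorphic and not r.is_snp for r in records),
    }


def write_site_table(records: Sequence[SiteRecord], taxa: Sequence[str],
                     path) -> None:
    """TSV site table: 1-based column, class, allele partition."""
    with open(path, "w") as fh:
        fh.write("column\tis_snp\tis_indel\tclass\talleles\tmissing\n")
        for r in records:
            if r.is_uninformative:
                cls = "uninformative"
            elif r.is_snp:
                cls = "snp"
            else:
                cls = "monomorphic"
            alleles = ";".join(
                f"{state}:" + ",".join(taxa[i] for i in members)
                for state, members in r.alleles)
            missing = ",".join(taxa[i] for i in r.missing)
            fh.write(f"{r.column + 1}\t{int(r.is_snp)}\t{int(r.is_indel)}\t"
                     f"{cls}\t{alleles}\t{missing}\n")
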