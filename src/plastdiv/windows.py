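"""Sliding-window variability profiles, hotspot and deletion screening.

Windows of length ``L`` (default 500 bp) advance by step ``s`` (default
250 bp) over alignment columns; each window counts the distinct columns
flagged as SNPs and as indel positions.  A trailing partial window
(``start + L > length``) is dropped by default, so every emitted window has
exactly ``L`` columns; pass ``include_partial=True`` for a final truncated
window.  Window midpoints (``start + L/2``) are the natural x-coordinate
for plotting.

Hotspots — candidate DNA-barcode loci — are windows selected either by a
minimum SNP count or as the top-k windows; overlapping or adjacent selected
windows merge into regions, and each merged region recounts *distinct* SNP
columns so that columns shared by overlapping windows are not double
counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import Alignment, FeatureTable, GAP
from .sites import SiteRecord


@dataclass
class WindowProfile:
    """Per-window SNP / indel-position counts over an alignment."""

    window_length: int
    step: int
    starts: np.ndarray  # int, window starts (0-based)
    ends: np.ndarray    # half-open ends
    snp_counts: np.ndarray
    indel_counts: np.ndarray
    labels: list[str] | None = None

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    @property
    def indel_density_per_kb(self) -> np.ndarray:
        widths = self.ends - self.starts
        return self.indel_counts / widths * 1000.0

    @property
    def n_windows(self) -> int:
        return int(self.starts.size)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "start": self.starts,
            "end": self.ends,
            "midpoint": self.midpoints,
            "snp_count": self.snp_counts,
            "indel_position_count": self.indel_counts,
            "indel_per_kb": self.indel_density_per_kb,
        })
        if self.labels is not None:
            df["labels"] = self.labels
        return df


@dataclass(frozen=True)
class HotspotRegion:
    """A merged run of selected windows, with distinct-column SNP total."""

    start: int
    end: int
    merged_window_count: int
    snp_total: int
    label: str = ""


def _window_bounds(length: int, window_length: int, step: int,
                   include_partial: bool) -> tuple[np.ndarray, np.ndarray]:
    if window_length < 1:
        raise ValueError("window length must be >= 1")
    if not 1 <= step <= window_length:
        raise ValueError("step must satisfy 1 <= step <= window length")
    if length < window_length:
        raise ValueError(
            f"alignment length {length} shorter than window length "
            f"{window_length}; choose a smaller window")
    starts = np.arange(0, length - window_length + 1, step)
    ends = starts + window_length
    if include_partial and ends[-1] < length:
        starts = np.append(starts, starts[-1] + step)
        ends = np.append(ends, length)
    return starts, ends


def _count_in_windows(columns: np.ndarray, starts: np.ndarray,
                      ends: np.ndarray) -> np.ndarray:
    columns = np.sort(columns)
    return (np.searchsorted(columns, ends, side="left")
            - np.searchsorted(columns, starts, side="left"))


def window_profile(records: Sequence[SiteRecord], window_length: int = 500,
                   step: int = 250, *,
                   include_partial: bool = False) -> WindowProfile:
    """Count SNP and indel-position columns in each sliding window."""
    length = len(records)
    starts, ends = _window_bounds(length, window_length, step, include_partial)
    snp_cols = np.array([r.column for r in records if r.is_snp], dtype=int)
    indel_cols = np.array([r.column for r in records if r.is_indel], dtype=int)
    return WindowProfile(
        window_length=window_length, step=step, starts=starts, ends=ends,
        snp_counts=_count_in_windows(snp_cols, starts, ends),
        indel_counts=_count_in_windows(indel_cols, starts, ends),
    )


def detect_hotspots(profile: WindowProfile, records: Sequence[SiteRecord],
                    mode: str = "min_count", param: float = 1,
                    which: str = "snp") -> list[HotspotRegion]:
    """Select SNP-rich (or indel-rich) windows and merge them into regions.

    ``mode='min_count'`` selects windows with count >= ``param``;
    ``mode='top_k'`` selects the ``param`` highest-count windows, ties broken
    by (count desc, start asc).  Overlapping or adjacent selected windows
    merge; each merged region recounts distinct flagged columns.
    """
    if profile.n_windows == 0:
        raise ValueError("empty window profile")
    if param <= 0:
        raise ValueError("hotspot parameter must be > 0")
    counts = profile.snp_counts if which == "snp" else profile.indel_counts
    if mode == "min_count":
        selected = np.flatnonzero(counts >= param)
    elif mode == "top_k":
        k = int(param)
        order = sorted(range(profile.n_windows),
                       key=lambda i: (-counts[i], profile.starts[i]))
        selected = np.array(sorted(order[:k]), dtype=int)
    else:
        raise ValueError(f"unknown hotspot mode {mode!r}")
    if selected.size == 0:
        return []

    flag = "is_snp" if which == "snp" else "is_indel"
    flagged = np.array([r.column for r in records if getattr(r, flag)],
                       dtype=int)

    regions: list[HotspotRegion] = []
    run_start = int(profile.starts[selected[0]])
    run_end = int(profile.ends[selected[0]])
    run_n = 1
    for i in selected[1:]:
        s, e = int(profile.starts[i]), int(profile.ends[i])
        if s <= run_end:  # overlapping or adjacent
            run_end = max(run_end, e)
            run_n += 1
        else:
            regions.append(_make_region(run_start, run_end, run_n, flagged))
            run_start, run_end, run_n = s, e, 1
    regions.append(_make_region(run_start, run_end, run_n, flagged))
    return regions


def _make_region(start: int, end: int, n_windows: int,
                 flagged: np.ndarray) -> HotspotRegion:
    total = int(_count_in_windows(flagged, np.array([start]),
                                  np.array([end]))[0])
    return HotspotRegion(start=start, end=end, merged_window_count=n_windows,
                         snp_total=total)


def high_deletion_windows(alignment: Alignment, window_length: int = 500,
                          step: int = 250, fraction: float = 0.70
                          ) -> list[tuple[tuple[int, int], tuple[str, ...]]]:
    """Windows where some single taxon has a gap proportion above ``fraction``.

    Returns ``((start, end), offending_taxa)`` pairs; used to flag intervals
    where apparent indel density really reflects wholesale deletion in one
    species.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    starts, ends = _window_bounds(alignment.length, window_length, step, False)
    gaps = (alignment.matrix == GAP)
    cum = np.concatenate([np.zeros((alignment.n_taxa, 1), dtype=int),
                          np.cumsum(gaps, axis=1)], axis=1)
    out = []
    for s, e in zip(starts, ends):
        per_taxon = (cum[:, e] - cum[:, s]) / (e - s)
        hit = np.flatnonzero(per_taxon > fraction)
        if hit.size:
            out.append(((int(s), int(e)),
                        tuple(alignment.taxa[i] for i in hit)))
    return out


def identity_profile(alignment: Alignment, reference_taxon: str,
                     window_length: int = 500, step: int = 250
                     ) -> pd.DataFrame:
    """Windowed percent identity of every taxon against a reference.

    Identity = matching columns / comparable columns, where a column is
    comparable when both reference and taxon are non-missing there or
    exactly one of them is gapped (gap vs base is a mismatch; gap vs gap and
    any N are excluded).  Windows with zero comparable columns report NaN.
    Mirrors mVISTA-style percent-identity panels.
    """
    ref_i = alignment.index(reference_taxon)
    starts, ends = _window_bounds(alignment.length, window_length, step, False)
    m = alignment.matrix
    nb = ord("N")
    ref = m[ref_i]
    data: dict[str, np.ndarray] = {}
    for t_i, taxon in enumerate(alignment.taxa):
        row = m[t_i]
        has_n = (ref == nb) | (row == nb)
        both_gap = (ref == GAP) & (row == GAP)
        comparable = ~(has_n | both_gap)
        match = comparable & (ref == row)
        cum_c = np.concatenate([[0], np.cumsum(comparable)])
        cum_m = np.concatenate([[0], np.cumsum(match)])
        n_c = (cum_c[ends] - cum_c[starts]).astype(float)
        n_m = (cum_m[ends] - cum_m[starts]).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident = np.where(n_c > 0, n_m / n_c * 100.0, np.nan)
        data[taxon] = ident
    df = pd.DataFrame(data)
    df.insert(0, "start", starts)
    df.insert(1, "end", ends)
    df.insert(2, "midpoint", (starts + ends) / 2.0)
    return df


def annotate_windows(profile: WindowProfile, features: FeatureTable,
                     alignment: Alignment, reference_taxon: str
                     ) -> WindowProfile:
    """Label each window with overlapping features and intergenic spacers.

    Features are given on the reference's ungapped coordinates and lifted to
    alignment columns through the reference row's gap structure.  Spacers
    between consecutive (position-sorted, flattened) features are named
    ``geneA-geneB spacer``; a window straddling a gene end receives both the
    gene and the spacer label.
    """
    ref_i = alignment.index(reference_taxon)
    cols = np.flatnonzero(alignment.matrix[ref_i] != GAP)

    def lift(pos: int) -> int:
        # half-open end may equal ungapped length -> one past last column
        if pos >= cols.size:
            return alignment.length
        return int(cols[pos])

    ordered = features.sorted_by_position()
    intervals: list[tuple[int, int, str]] = []
    for f in ordered:
        intervals.append((lift(f.start), lift(f.end - 1) + 1, f.name))
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start > prev.end:
            intervals.append((lift(prev.end - 1) + 1, lift(nxt.start),
                              f"{prev.name}-{nxt.name} spacer"))
    labels: list[str] = []
    for s, e in zip(profile.starts, profile.ends):
        hits = [name for (fs, fe, name) in intervals if fs < e and s < fe]
        labels.append(";".join(dict.fromkeys(hits)))
    return WindowProfile(
        window_length=profile.window_length, step=profile.step,
        starts=profile.starts, ends=profile.ends,
        snp_counts=profile.snp_counts, indel_counts=profile.indel_counts,
        labels=labels)


def write_profile(profile: WindowProfile, path, comment: str = "") -> None:
    """TSV profile with 1-based inclusive coordinates in the header columns."""
    df = profile.to_dataframe()
    df["start"] = df["start"] + 1  # 1-based inclusive for reports
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.3f")


def write_bed(regions, path, name_prefix: str = "region") -> None:
    """BED (0-based half-open) for hotspot / high-deletion regions."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            if isinstance(r, HotspotRegion):
                fh.write(f"aln\t{r.start}\t{r.end}\t{name_prefix}{i + 1}\t"
                         f"{r.snp_total}\t.\n")
            else:
                (s, e), taxa = r
                fh.write(f"aln\t{s}\t{e}\t{','.join(taxa)}\t0\t.\n")
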