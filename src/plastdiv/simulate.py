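"""Synthetic plastome alignments with complete ground truth.

The generator emulates the data this pipeline is built for: a quadripartite
chloroplast genome (LSC + IRa + SSC + IRb, with IRb the exact reverse
complement of IRa), five ingroup taxa plus one outgroup evolved from the
reference on a star tree, region-dependent substitution rates (near-zero in
the inverted repeats), localized mutation hotspots, a scattered indel
process plus planted long single-taxon deletions (the ">70 % of a window
deleted" pattern), and optional per-lineage rate multipliers for relative
rate-test power studies.

Defaults describe a realistic oak-like plastome: region lengths 90,353 /
25,840 / 18,955 / 25,840 bp, base composition A 31.1 / C 18.7 / G 18.0 /
T 32.2 %, per-branch substitution probability 3e-3 per single-copy site
(star-tree divergence of the order of the ~0.005 p-distances typical of
congeneric oaks), IR rate multiplier 0.1, four 750 bp hotspots at 8x the
background rate, and an outgroup branch 4x the ingroup branch length.

Substitutions are Jukes–Cantor-like: a mutated site picks uniformly among
the three alternative bases.  Indels are simulated post-substitution as gap
runs in single taxa at reference columns (deletions only, no insertion
columns), which keeps the truth bookkeeping exact: alignment columns are
reference coordinates.

Everything is driven by one seeded :class:`numpy.random.Generator`; a fixed
seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import Alignment, Feature, FeatureTable, GAP

_BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedHotspot:
    """A localized rate elevation on reference coordinates."""

    start: int
    end: int  # half-open
    multiplier: float


@dataclass(frozen=True)
class PlantedDeletion:
    """A planted long deletion: ``taxon`` loses ``[start, end)``."""

    taxon: str
    start: int
    end: int


@dataclass
class SimulationConfig:
    """Stated world of the generator; every default is a deliberate choice."""

    n_ingroup: int = 5
    outgroup: bool = True
    lsc_length: int = 90_353
    ira_length: int = 25_840
    ssc_length: int = 18_955
    #: per-branch substitution probability per single-copy site
    rate: float = 3e-3
    ir_rate_multiplier: float = 0.1
    #: None -> four default 750 bp hotspots (three in LSC, one in SSC) at 8x
    hotspots: tuple[PlantedHotspot, ...] | None = None
    #: extra branch-length multiplier per taxon label (RRT power studies)
    lineage_rate_multipliers: dict[str, float] = field(default_factory=dict)
    outgroup_rate_multiplier: float = 4.0
    #: per-site probability that a short deletion starts here, per taxon
    indel_rate: float = 5e-4
    #: geometric mean length of short deletions, bp
    indel_mean_length: float = 5.0
    #: None -> one default 600 bp deletion in the first ingroup taxon, mid-LSC
    long_deletions: tuple[PlantedDeletion, ...] | None = None
    base_composition: tuple[float, float, float, float] = (
        0.311, 0.187, 0.180, 0.322)  # A, C, G, T
    seed: int = 0

    # -- derived -------------------------------------------------------
    @property
    def irb_length(self) -> int:
        return self.ira_length

    @property
    def total_length(self) -> int:
        return self.lsc_length + 2 * self.ira_length + self.ssc_length

    @property
    def taxa(self) -> tuple[str, ...]:
        names = tuple(f"taxon{i + 1}" for i in range(self.n_ingroup))
        return names + (("outgroup",) if self.outgroup else ())

    @property
    def ingroup_taxa(self) -> tuple[str, ...]:
        return tuple(f"taxon{i + 1}" for i in range(self.n_ingroup))

    def region_spans(self) -> dict[str, tuple[int, int]]:
        lsc = (0, self.lsc_length)
        ira = (lsc[1], lsc[1] + self.ira_length)
        ssc = (ira[1], ira[1] + self.ssc_length)
        irb = (ssc[1], ssc[1] + self.ira_length)
        return {"LSC": lsc, "IRa": ira, "SSC": ssc, "IRb": irb}

    def validate(self) -> None:
        if self.n_ingroup < 2:
            raise ValueError("need at least 2 ingroup taxa")
        for name in ("lsc_length", "ira_length", "ssc_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.ir_rate_multiplier < 0:
            raise ValueError("multipliers must be >= 0")
        if any(m <= 0 for m in self.lineage_rate_multipliers.values()):
            raise ValueError("lineage multipliers must be > 0")
        if abs(sum(self.base_composition) - 1.0) > 1e-6:
            raise ValueError("base composition must sum to 1")
        n = self.total_length
        for h in self.resolved_hotspots():
            if not 0 <= h.start < h.end <= n:
                raise ValueError(f"hotspot {h} outside sequence")
            if h.multiplier <= 0:
                raise ValueError("hotspot multiplier must be > 0")
        taxa = set(self.taxa)
        for d in self.resolved_long_deletions():
            if d.taxon not in taxa:
                raise ValueError(f"deletion taxon {d.taxon!r} unknown")
            if not 0 <= d.start < d.end <= n:
                raise ValueError(f"deletion {d} outside sequence")

    def resolved_hotspots(self) -> tuple[PlantedHotspot, ...]:
        if self.hotspots is not None:
            return self.hotspots
        # three spacer-like hotspots in the LSC, one at the SSC 3' gene end
        lsc, ssc = self.lsc_length, self.region_spans()["SSC"]
        width = min(750, max(1, lsc // 10))
        anchors = [int(lsc * f) for f in (0.05, 0.30, 0.70)]
        spots = [PlantedHotspot(a, min(a + width, lsc), 8.0) for a in anchors]
        s_anchor = ssc[0] + int((ssc[1] - ssc[0]) * 0.6)
        spots.append(PlantedHotspot(
            s_anchor, min(s_anchor + width, ssc[1]), 8.0))
        return tuple(spots)

    def resolved_long_deletions(self) -> tuple[PlantedDeletion, ...]:
        if self.long_deletions is not None:
            return self.long_deletions
        start = self.lsc_length // 2
        length = min(600, self.lsc_length // 4)
        return (PlantedDeletion(self.ingroup_taxa[0], start, start + length),)

    def branch_multiplier(self, taxon: str) -> float:
        m = self.lineage_rate_multipliers.get(taxon, 1.0)
        if taxon == "outgroup":
            m *= self.outgroup_rate_multiplier
        return m


@dataclass
class TruthTable:
    """Ground truth recorded while simulating, for exact round-trip checks."""

    taxa: tuple[str, ...]
    snp_columns: np.ndarray          # sorted column indices
    indel_columns: np.ndarray
    subset_credits: dict[tuple[str, ...], int]
    hotspots: tuple[PlantedHotspot, ...]
    deletions: dict[str, list[tuple[int, int]]]
    regions: dict[str, tuple[int, int]]
    lineage_rates: dict[str, float]
    substitutions: dict[str, dict[int, str]]

    @property
    def n_snp_columns(self) -> int:
        return int(self.snp_columns.size)


def _random_sequence(rng: np.random.Generator, length: int,
                     composition) -> np.ndarray:
    return _BASE_BYTES[rng.choice(4, size=length, p=list(composition))]


def simulate_reference(config: SimulationConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[str, FeatureTable]:
    """Build the annotated reference plastome for a configuration.

    The sequence is LSC + IRa + SSC + revcomp(IRa); toy features (CDS, tRNA,
    rRNA cycling) are tiled in every region so annotation overlay and gene
    census have something to chew on.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng([config.seed, 0])
    lsc = _random_sequence(rng, config.lsc_length, config.base_composition)
    ira = _random_sequence(rng, config.ira_length, config.base_composition)
    ssc = _random_sequence(rng, config.ssc_length, config.base_composition)
    # Make the planted repeats maximal: a junction base that happens to pair
    # with its counterpart would extend the exact repeat beyond the planted
    # span.  IRa's left flank pairs with IRb's right flank (circularly the
    # first LSC base) and IRa's right flank with IRb's left flank.
    _break_pairing(lsc, -1, lsc, 0)
    _break_pairing(ssc, 0, ssc, -1)
    irb = np.frombuffer(
        _revcomp_bytes(ira.tobytes().decode("ascii")).encode("ascii"),
        dtype=np.uint8)
    seq = np.concatenate([lsc, ira, ssc, irb]).tobytes().decode("ascii")

    kinds = ("coding", "tRNA", "rRNA")
    table = FeatureTable()
    for region, (start, end) in config.region_spans().items():
        span_len = end - start
        pitch = max(600, span_len // max(1, span_len // 1500))
        feat_len = min(300, max(1, pitch // 2))
        i = 0
        pos = start + pitch // 4
        while pos + feat_len <= end:
            kind = kinds[i % 3]
            table.features.append(Feature(
                name=f"{region.lower()}g{i + 1}", kind=kind,
                intervals=((pos, pos + feat_len),),
                strand="+" if i % 2 == 0 else "-"))
            i += 1
            pos += pitch
    return seq, table


_COMPLEMENT_BYTE = dict(zip(b"ACGT", b"TGCA"))


def _break_pairing(arr_a: np.ndarray, i: int, arr_b: np.ndarray,
                   j: int) -> None:
    """Ensure ``arr_a[i] != complement(arr_b[j])`` by cycling ``arr_a[i]``.

    No DNA base is self-complementary, so when both indices address the same
    cell the condition already holds.
    """
    if arr_a[i] == _COMPLEMENT_BYTE[int(arr_b[j])]:
        pos = int(np.flatnonzero(_BASE_BYTES == arr_a[i])[0])
        arr_a[i] = _BASE_BYTES[(pos + 1) % 4]


def _revcomp_bytes(seq: str) -> str:
    from .structure import revcomp
    return revcomp(seq)


def simulate_alignment(reference: str, config: SimulationConfig
                       ) -> tuple[Alignment, TruthTable]:
    """Evolve every taxon from the reference on a star tree.

    Returns the gapped, column-synchronized alignment (columns are reference
    coordinates, since indels are single-taxon deletions) and the filled
    :class:`TruthTable`.
    """
    config.validate()
    n = len(reference)
    if n != config.total_length:
        raise ValueError(
            f"reference length {n} does not match config total "
            f"{config.total_length}")
    # child stream distinct from the reference generator's ([seed, 0])
    rng = np.random.default_rng([config.seed, 1])
    ref = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)

    # per-site rate profile shared by all taxa
    site_rate = np.full(n, config.rate)
    spans = config.region_spans()
    for region in ("IRa", "IRb"):
        s, e = spans[region]
        site_rate[s:e] *= config.ir_rate_multiplier
    for h in config.resolved_hotspots():
        site_rate[h.start:h.end] *= h.multiplier

    base_index = np.zeros(256, dtype=np.int64)
    for i, b in enumerate(_BASE_BYTES):
        base_index[b] = i

    planted = {d.taxon: d for d in config.resolved_long_deletions()}
    rows = []
    substitutions: dict[str, dict[int, str]] = {}
    deletions: dict[str, list[tuple[int, int]]] = {}
    for taxon in config.taxa:
        p = np.clip(site_rate * config.branch_multiplier(taxon), 0.0, 1.0)
        mutated = np.flatnonzero(rng.random(n) < p)
        row = ref.copy()
        subs: dict[int, str] = {}
        if mutated.size:
            shift = rng.integers(1, 4, size=mutated.size)
            new = _BASE_BYTES[(base_index[ref[mutated]] + shift) % 4]
            row[mutated] = new
            subs = {int(c): chr(b) for c, b in zip(mutated, new)}
        dels: list[tuple[int, int]] = []
        if config.indel_rate > 0:
            starts = np.flatnonzero(rng.random(n) < config.indel_rate)
            if starts.size:
                lengths = rng.geometric(1.0 / config.indel_mean_length,
                                        size=starts.size)
                for s, l in zip(starts, lengths):
                    dels.append((int(s), min(int(s + l), n)))
        if taxon in planted:
            d = planted[taxon]
            dels.append((d.start, d.end))
        dels = _merge_intervals(dels)
        for s, e in dels:
            row[s:e] = GAP
        rows.append(row)
        substitutions[taxon] = subs
        deletions[taxon] = dels

    alignment = Alignment(config.taxa, np.vstack(rows))
    truth = _build_truth(ref, config, substitutions, deletions)
    return alignment, truth


def _merge_intervals(intervals: list[tuple[int, int]]
                     ) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _build_truth(ref: np.ndarray, config: SimulationConfig,
                 substitutions: dict[str, dict[int, str]],
                 deletions: dict[str, list[tuple[int, int]]]) -> TruthTable:
    """Derive truth flags from the planted events alone.

    This is a deliberately independent code path from the site classifier:
    per-taxon states come from the substitution/deletion bookkeeping, and
    subset credits from explicit enumeration of all proper taxon subsets.
    """
    n = ref.size
    taxa = config.taxa
    deleted = np.zeros((len(taxa), n), dtype=bool)
    for t_i, taxon in enumerate(taxa):
        for s, e in deletions[taxon]:
            deleted[t_i, s:e] = True
    indel_columns = np.flatnonzero(deleted.any(axis=0))

    # columns possibly polymorphic: some taxon has a substitution there
    candidate = sorted({c for subs in substitutions.values() for c in subs})
    snp_cols: list[int] = []
    credits: dict[tuple[str, ...], int] = {}
    from itertools import combinations
    for col in candidate:
        states = {}
        for t_i, taxon in enumerate(taxa):
            if deleted[t_i, col]:
                continue
            states[taxon] = substitutions[taxon].get(col, chr(ref[col]))
        if len(set(states.values())) < 2:
            continue
        snp_cols.append(col)
        informative = list(states)
        for r in range(1, len(informative)):
            for subset in combinations(informative, r):
                inside = {states[t] for t in subset}
                outside = {states[t] for t in informative
                           if t not in subset}
                if len(inside) == 1 and inside.isdisjoint(outside):
                    key = tuple(t for t in taxa if t in subset)
                    credits[key] = credits.get(key, 0) + 1
    return TruthTable(
        taxa=taxa,
        snp_columns=np.array(snp_cols, dtype=int),
        indel_columns=indel_columns,
        subset_credits=credits,
        hotspots=config.resolved_hotspots(),
        deletions=deletions,
        regions=config.region_spans(),
        lineage_rates={t: config.branch_multiplier(t) for t in taxa},
        substitutions=substitutions,
    )


def simulate(config: SimulationConfig
             ) -> tuple[str, FeatureTable, Alignment, TruthTable]:
    """Reference + annotation + alignment + truth in one seeded call."""
    reference, features = simulate_reference(config)
    alignment, truth = simulate_alignment(reference, config)
    return reference, features, alignment, truth


def simulate_rrt_replicates(n_replicates: int, length: int = 10_000,
                            rate_a: float = 5e-3, rate_b: float = 5e-3,
                            outgroup_rate: float = 2e-2,
                            base_composition=(0.311, 0.187, 0.180, 0.322),
                            seed: int = 0) -> list[Alignment]:
    """Independent (A, B, outgroup) triples for rate-test calibration/power.

    Each replicate draws a fresh reference and evolves the three taxa
    independently with the given per-site substitution probabilities; no
    indels, so every column is informative.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    comp = list(base_composition)
    base_index = np.zeros(256, dtype=np.int64)
    for i, b in enumerate(_BASE_BYTES):
        base_index[b] = i
    out = []
    for _ in range(n_replicates):
        ref = _BASE_BYTES[rng.choice(4, size=length, p=comp)]
        rows = []
        for rate in (rate_a, rate_b, outgroup_rate):
            mutated = np.flatnonzero(rng.random(length) < rate)
            row = ref.copy()
            if mutated.size:
                shift = rng.integers(1, 4, size=mutated.size)
                row[mutated] = _BASE_BYTES[
                    (base_index[ref[mutated]] + shift) % 4]
            rows.append(row)
        out.append(Alignment(("A", "B", "outgroup"), np.vstack(rows)))
    return out
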