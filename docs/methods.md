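# Methods

`plastdiv` quantifies sequence diversity across whole chloroplast genomes
(plastomes) of closely related plant species, given a pre-built multiple
alignment.  This note records the definitions, conventions and deliberate
choices behind each stage; nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Alignment model

An alignment is an ordered set of equal-length rows over `{A,C,G,T,N,-}`.
On load, lowercase is uppercased and every IUPAC ambiguity code becomes `N`
(counted and logged): `N` is already the missing-data symbol of the domain,
and no stage distinguishes "ambiguous" from "unknown".  Only `-` is a gap;
`.` is rejected outright — a single gap dialect with an explicit error
beats a silent misparse.  Internal coordinates are 0-based half-open;
written reports use 1-based inclusive positions (the GenBank convention
users read), except BED output, which is 0-based half-open by definition.

## Site classification

Each column gets two independent flags:

* **indel position** — any row carries `-`;
* **SNP** — at least two distinct nucleotide states among the rows that are
  neither gap nor `N` (the *informative* rows).

A gapped column can still be a SNP among the ungapped taxa: the two flags
feed two separate series in the window profile.  Missing data never creates
nor blocks a SNP call; it only shrinks the informative set.  Columns with
fewer than two informative rows are *uninformative* — neither SNP nor
monomorphic.  This conservative treatment of `N` is a design choice; the
alternative (treating `N` as a fifth state) would manufacture SNPs out of
sequencing gaps.

## Private/shared SNP partition

At every SNP column, each allele class `C` — a maximal set of taxa sharing
one state — is credited once, provided `1 <= |C| < n_informative`.  A
size-1 class is a **private SNP** of that taxon.  Note the asymmetry this
produces with five taxa: a column with states `A | C C | G G` credits the
singleton and both pairs but *not* the four-taxon complement, so a species'
private count can exceed the count of the complementary four-species
subset.  This is the only reading under which a species can simultaneously
lead the private tally while being excluded from the largest shared class,
which is exactly the pattern reported for these data; it remains an
inference about the original scripts' definition and is flagged here
deliberately.  Subsets equal to the full informative set (monomorphic
columns) are never credited, and each (column, subset) pair is credited at
most once — automatic, since allele classes are disjoint.

The partition is verified against a brute-force oracle that enumerates all
non-empty proper subsets of the taxon set per column.

## Window profiles, hotspots, deletion screens

Windows of length `L = 500` bp step by `s = 250` bp (the published analysis
grid).  The trailing partial window is dropped by default so every window
has exactly `L` columns — merged hotspot regions then come out as multiples
of 250 bp, matching how such regions are conventionally reported; a flag
re-enables a final truncated window.  Window midpoint `start + L/2` is the
plotting x-coordinate.

Hotspots: windows are selected by `min_count` (count ≥ threshold) or
`top_k`; ties break by (count desc, start asc).  Overlapping/adjacent
selections merge, and each merged region recounts **distinct** SNP columns
— overlapping windows share columns, so summing per-window counts would
double-count.

High-deletion screen: a window is flagged when any single taxon's gap
fraction exceeds 0.70 (default), the situation where apparent indel density
really reflects wholesale deletion of the region in one lineage.

Percent identity vs a reference taxon (mVISTA-style): per window,
matches / comparable columns, where gap-vs-base is a comparable mismatch,
gap-vs-gap is excluded, and any `N` is excluded.  Zero comparable columns
reports NaN, never 0 — an empty window is not 0 % identical.

## Distances and relative rates

**p-distance** (no model correction) defaults to *complete deletion*:
every column containing `-` or `N` in any row is removed first, giving one
shared denominator for all pairs — this is what makes a single
"positions in final dataset" count meaningful.  Pairwise deletion is
available but not default.

**Tajima's one-degree-of-freedom relative rate test** for ingroup taxa A, B
with outgroup O: over columns where all three are informative,
`mA = #{A differs, B = O}`, `mB = #{B differs, A = O}`; columns where all
three states differ are uninformative.  `chi2 = (mA - mB)^2 / (mA + mB)`
with p from the continuous 1-df chi-square upper tail (no continuity
correction, matching the standard implementation of the 1D test);
`mA + mB = 0` reports chi2 = 0, p = 1 (no information).  Deletion is
applied **per triple**, not globally — the test is run pair by pair against
one outgroup, so discarding columns for taxa not involved would throw away
signal; documented as an assumption.  The slower lineage is reported only
when p < alpha (default 0.01, the significance convention of the published
table).

## Quadripartite structure

`detect_inverted_repeat` finds the longest pair of disjoint spans where one
equals the reverse complement of the other: exact k-mer seeds (k = 24)
between the doubled sequence and its doubled reverse complement, one
maximal gapless extension per diagonal, candidates filtered for circular
disjointness and length ≤ n/2, ties broken by leftmost start.  Extension is
exact-match by default — published per-genome IR lengths are single
numbers, implying exact annotated spans — and the result self-checks by
direct string comparison.  Circularity is handled by scanning the doubled
sequence with reported starts normalized to `[0, n)`.

The two inter-IR arcs become LSC (longer) and SSC (shorter); on a tie the
arc after the first repeat is named LSC with a warning.  Region lengths sum
to the total length by construction.  GC is `(G+C)/(A+C+G+T) x 100` with
`N` excluded from the denominator, reported to 0.1.  The gene census counts
annotated feature *occurrences* by kind (coding/tRNA/rRNA), so a gene
duplicated in the IRs counts once per copy — e.g. 8 rRNA occurrences = 4
genes x 2 IR copies — matching how plastome summary tables are usually
printed.  (One published source we compared against prints two different
overall GC values, 36.7 % in text and 36.9 % in its table, for the same
genome; `plastdiv` always reports the computed value and does not arbitrate.)

## Synthetic data: the stated world

The generator emulates the data the pipeline is designed for, and its
defaults are fixed commitments, not tuning knobs:

* **Region plan** LSC 90,353 / IR 25,840 / SSC 18,955 bp (oak-like;
  total 160,988) with IRb the exact reverse complement of IRa.  Junction
  bases are adjusted so the planted repeat is *maximal* — a flanking base
  that happened to pair with its counterpart would extend the exact repeat
  and shift the detected boundary by construction, not by error.
* **Base composition** A 31.1 / C 18.7 / G 18.0 / T 32.2 %.
* **Substitution** star tree, per-branch substitution probability
  `3e-3`/site in single-copy regions — chosen so five-taxon divergence is
  of the order of the ~0.005 p-distances typical of congeneric oaks —
  with a mutated site drawing uniformly among the three alternatives
  (Jukes–Cantor-like).  IR sites get multiplier 0.1 (IRs are observed to be
  nearly invariant); four default 750 bp hotspots (three LSC, one SSC) get
  multiplier 8, a level at which hotspot windows clearly top the background
  without dominating the genome; lineage multipliers (and a 4x outgroup
  branch) support rate-heterogeneity studies.
* **Indels** are single-taxon deletions: per-site start probability
  `5e-4`, geometric lengths (mean 5 bp), plus one planted 600 bp deletion
  by default (the ">70 % of a window deleted in one species" pattern).
  Because no insertions are simulated, alignment columns are reference
  coordinates and the truth bookkeeping is exact.  This is the main
  departure from real data: real alignments contain insertion columns,
  multi-taxon indels and alignment errors, so a green round-trip test
  establishes correctness of the statistics, not robustness to aligner
  artifacts.
* **Truth** is derived from the planted events through an independent code
  path (explicit subset enumeration, not the production crediting code).
* One seeded generator stream per purpose (`[seed, 0]` reference,
  `[seed, 1]` evolution); a fixed seed gives byte-identical output.

RRT calibration replicates use per-branch rate `5e-3` with outgroup `2e-2`
over 10 kb, giving expected unique-site counts near 100 per pair — large
enough for the chi-square approximation, small enough to be realistic for
congeneric plastomes.

## Known limitations

* No insertion columns in the simulator (above).
* The IR detector assumes one dominant inverted repeat pair; plastomes with
  drastically reduced or lost IRs report "no IR found" with the longest
  candidate rather than guessing.
* Published-number reproduction requires the original GenBank genomes and a
  MAFFT alignment; these cannot be redistributed, so those checks run only
  when the user supplies `data/real/` (see `tests/test_acceptance.py`), and
  alignment-dependent counts are checked within a small tolerance because
  the aligner version used originally is unknown.  The outgroup accession
  for the rate-test table was never published; reproducing it requires the
  user to identify that sequence.
* p-distance and the rate test ignore substitution-model corrections by
  design (they mirror the published analyses); do not extrapolate them to
  deep divergences.
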