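"""Brute-force reference implementations used as independent oracles.

Everything here is written for clarity, not speed: plain Python over string
rows, explicit enumeration of subsets and columns.  The production code
must agree with these on small random inputs.
"""

from itertools import combinations

MISSING = set("N-")


def informative_taxa(column_states: dict[str, str]) -> dict[str, str]:
    return {t: s for t, s in column_states.items() if s not in MISSING}


def brute_classify(rows: dict[str, str]) -> list[dict]:
    """Per-column classification by direct inspection."""
    taxa = list(rows)
    length = len(next(iter(rows.values())))
    out = []
    for col in range(length):
        states = {t: rows[t][col] for t in taxa}
        inf = informative_taxa(states)
        distinct = set(inf.values())
        out.append({
            "column": col,
            "is_indel": "-" in states.values(),
            "is_snp": len(distinct) >= 2,
            "uninformative": len(inf) < 2,
        })
    return out


def brute_subset_credits(rows: dict[str, str]) -> dict[tuple, int]:
    """Enumerate every non-empty proper subset of the taxon set per column.

    A subset S is credited at a SNP column when every member is informative
    and shares one state, every other informative taxon carries a different
    state, and at least one informative taxon lies outside S.
    """
    taxa = list(rows)
    length = len(next(iter(rows.values())))
    credits: dict[tuple, int] = {}
    for col in range(length):
        states = {t: rows[t][col] for t in taxa}
        inf = informative_taxa(states)
        if len(set(inf.values())) < 2:
            continue  # not a SNP column
        for r in range(1, len(taxa)):
            for subset in combinations(taxa, r):
                if any(t not in inf for t in subset):
                    continue
                inside = {inf[t] for t in subset}
                outside = [t for t in inf if t not in subset]
                if not outside:
                    continue
                if len(inside) == 1 and all(
                        inf[t] not in inside for t in outside):
                    credits[subset] = credits.get(subset, 0) + 1
    return credits


def brute_window_counts(flag_columns, starts, ends):
    """Recount flagged columns per window by direct membership tests."""
    cols = set(flag_columns)
    return [sum(1 for c in cols if s <= c < e) for s, e in zip(starts, ends)]


def brute_p_distance(rows: dict[str, str]):
    """Complete-deletion p-distances by per-column scanning."""
    taxa = list(rows)
    length = len(next(iter(rows.values())))
    keep = [col for col in range(length)
            if all(rows[t][col] not in MISSING for t in taxa)]
    dist = {}
    for a, b in combinations(taxa, 2):
        mism = sum(1 for col in keep if rows[a][col] != rows[b][col])
        dist[(a, b)] = mism / len(keep) if keep else None
    return dist, len(keep)


def brute_rrt_counts(rows: dict[str, str], a: str, b: str, og: str):
    """Unique-difference site counts for the relative rate test."""
    m_a = m_b = 0
    for sa, sb, so in zip(rows[a], rows[b], rows[og]):
        if any(s in MISSING for s in (sa, sb, so)):
            continue
        if sa != sb and sb == so:
            m_a += 1
        elif sb != sa and sa == so:
            m_b += 1
    return m_a, m_b


def random_alignment_rows(rng, n_taxa, n_cols, p_gap=0.08, p_n=0.05):
    """Random gapped rows over A,C,G,T,N,- with mild polymorphism."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    rows = {}
    # draw a reference so columns are usually low-diversity, like real data
    ref = rng.choice(list("ACGT"), size=n_cols)
    for t in taxa:
        chars = []
        for col in range(n_cols):
            u = rng.random()
            if u < p_gap:
                chars.append("-")
            elif u < p_gap + p_n:
                chars.append("N")
            elif u < p_gap + p_n + 0.25:
                chars.append(rng.choice(list("ACGT")))
            else:
                chars.append(ref[col])
        rows[t] = "".join(chars)
    return rows
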