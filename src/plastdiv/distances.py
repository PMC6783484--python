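"""p-distances under complete deletion and Tajima's 1D relative rate test.

The p-distance between two rows is the proportion of differing sites over
the compared sites, with no substitution-model correction.  Under *complete
deletion* (the default, and the convention behind a single shared
denominator for all pairs), every column containing a gap or an N in ANY
row is removed before counting; *pairwise deletion* instead drops columns
per pair.

The relative rate test compares two ingroup taxa A and B against an
outgroup O: restricting to columns where all three are non-missing,

    mA = #{A differs, B = O}      mB = #{B differs, A = O}

Under rate constancy E[mA] = E[mB]; the statistic
``chi2 = (mA - mB)^2 / (mA + mB)`` is referred to a chi-square distribution
with one degree of freedom (no continuity correction).  Columns where all
three states differ are uninformative and enter neither count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import Alignment, GAP

_Nb = ord("N")


@dataclass
class PDistanceResult:
    """Symmetric p-distance matrix plus the retained-site count."""

    taxa: tuple[str, ...]
    matrix: np.ndarray            # float, (n, n), diagonal 0
    n_complete: int               # sites retained (complete deletion)
    n_pairwise: np.ndarray | None = None  # per-pair denominators if pairwise

    def distance(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.matrix[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa)


def p_distance(alignment: Alignment,
               deletion: str = "complete") -> PDistanceResult:
    """Pairwise p-distance matrix (``deletion`` = 'complete' or 'pairwise')."""
    if alignment.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    m = alignment.matrix
    missing = (m == GAP) | (m == _Nb)
    n = alignment.n_taxa
    if deletion == "complete":
        keep = ~missing.any(axis=0)
        n_complete = int(keep.sum())
        if n_complete == 0:
            raise ValueError("no complete columns: every column has a gap "
                             "or missing base in some row")
        sub = m[:, keep]
        diff = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = np.count_nonzero(sub[i] != sub[j]) / n_complete
                diff[i, j] = diff[j, i] = d
        return PDistanceResult(alignment.taxa, diff, n_complete)
    elif deletion == "pairwise":
        diff = np.zeros((n, n))
        denom = np.zeros((n, n), dtype=int)
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~(missing[i] | missing[j])
                nn = int(ok.sum())
                if nn == 0:
                    raise ValueError(
                        f"no comparable columns between "
                        f"{alignment.taxa[i]!r} and {alignment.taxa[j]!r}")
                d = np.count_nonzero(m[i, ok] != m[j, ok]) / nn
                diff[i, j] = diff[j, i] = d
                denom[i, j] = denom[j, i] = nn
        return PDistanceResult(alignment.taxa, diff,
                               int(denom[denom > 0].min()), denom)
    raise ValueError(f"unknown deletion mode {deletion!r}")


@dataclass(frozen=True)
class RateTestResult:
    """One Tajima relative-rate comparison of taxa A and B vs an outgroup."""

    taxon_a: str
    taxon_b: str
    outgroup: str
    m_a: int          # sites where A alone differs (B = outgroup)
    m_b: int          # sites where B alone differs (A = outgroup)
    chi2: float
    p: float
    n_sites: int      # columns with all three taxa non-missing

    def slower_taxon(self, alpha: float = 0.01) -> str | None:
        """The slower-evolving taxon when the test is significant, else None."""
        if self.p >= alpha or self.m_a == self.m_b:
            return None
        return self.taxon_a if self.m_a < self.m_b else self.taxon_b


def tajima_rrt(alignment: Alignment, taxon_a: str, taxon_b: str,
               outgroup: str) -> RateTestResult:
    """Tajima's one-degree-of-freedom relative rate test for one pair.

    Deletion is applied per triple: only columns where A, B and the outgroup
    are all non-gap and non-N are used.
    """
    names = (taxon_a, taxon_b, outgroup)
    if len(set(names)) != 3:
        raise ValueError("taxon A, taxon B and outgroup must be distinct")
    rows = [alignment.matrix[alignment.index(t)] for t in names]
    a, b, o = rows
    ok = np.ones(alignment.length, dtype=bool)
    for r in rows:
        ok &= (r != GAP) & (r != _Nb)
    a, b, o = a[ok], b[ok], o[ok]
    m_a = int(np.count_nonzero((a != b) & (b == o)))
    m_b = int(np.count_nonzero((b != a) & (a == o)))
    if m_a + m_b == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (m_a - m_b) ** 2 / (m_a + m_b)
        p = float(stats.chi2.sf(chi2, df=1))
    return RateTestResult(taxon_a, taxon_b, outgroup, m_a, m_b,
                          float(chi2), p, int(ok.sum()))


def rrt_all_pairs(alignment: Alignment, ingroup: Sequence[str],
                  outgroup: str, alpha: float = 0.01
                  ) -> list[RateTestResult]:
    """Relative rate test for every unordered ingroup pair (upper triangle)."""
    ingroup = list(ingroup)
    if len(ingroup) < 2:
        raise ValueError("need at least 2 ingroup taxa")
    if outgroup in ingroup:
        raise ValueError("outgroup cannot be an ingroup taxon")
    out = []
    for i, a in enumerate(ingroup):
        for b in ingroup[i + 1:]:
            out.append(tajima_rrt(alignment, a, b, outgroup))
    return out


def rrt_table(results: Sequence[RateTestResult],
              alpha: float = 0.01) -> pd.DataFrame:
    """Long-format relative-rate table (chi2, p, slower taxon per pair)."""
    rows = []
    for r in results:
        rows.append({
            "taxon_a": r.taxon_a, "taxon_b": r.taxon_b,
            "outgroup": r.outgroup, "m_a": r.m_a, "m_b": r.m_b,
            "n_sites": r.n_sites, "chi2": round(r.chi2, 4),
            "p": r.p, "significant": r.p < alpha,
            "slower": r.slower_taxon(alpha) or "",
        })
    return pd.DataFrame(rows)
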