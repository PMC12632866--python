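"""Four-taxon Patterson's D (ABBA-BABA) over all ingroup trios.

Alleles are haploid (one genome per taxon) and polarized against the
outgroup call: B marks the derived state. For an arrangement (P1, P2, P3, O),
D = (nABBA - nBABA) / (nABBA + nBABA), zero in expectation under incomplete
lineage sorting alone. Significance comes from a weighted delete-one block
jackknife over contiguous SNP blocks. The trio scan arranges each unordered
trio so that the BBAA count is the largest of the three pattern counts and
D >= 0, making P3 the candidate introgressor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .winio import SnpMatrix

__all__ = [
    "SitePatternCounts4",
    "DResult",
    "count_patterns4",
    "patterson_d",
    "jackknife_z",
    "dtrios_scan",
]


@dataclass(frozen=True)
class SitePatternCounts4:
    """ABBA/BABA/BBAA tallies for an ordered (P1, P2, P3, outgroup) quartet."""

    n_abba: int
    n_baba: int
    n_bbaa: int
    n_sites_used: int

    def __post_init__(self):
        if min(self.n_abba, self.n_baba, self.n_bbaa) < 0:
            raise ValueError("pattern counts must be non-negative")
        if self.n_abba + self.n_baba + self.n_bbaa > self.n_sites_used:
            raise ValueError("pattern counts exceed sites used")


@dataclass(frozen=True)
class DResult:
    p1: str
    p2: str
    p3: str
    n_abba: int
    n_baba: int
    n_bbaa: int
    d: float
    z: float
    p: float
    n_blocks: int
    flag: str  # "ok", "no_informative_sites", "degenerate_variance", "too_few_blocks"


def _pattern_codes(
    snps: SnpMatrix, p1: str, p2: str, p3: str, outgroup: str
) -> np.ndarray:
    """Per-site code: 0=ABBA, 1=BABA, 2=BBAA, -1 = usable other, -2 = skipped.

    A site is usable when all four calls are non-missing and exactly two
    alleles segregate among the four taxa.
    """
    names = (p1, p2, p3, outgroup)
    if len(set(names)) != 4:
        raise ValueError(f"taxa must be distinct, got {names}")
    rows = np.stack([snps.row(t) for t in names]).view(np.uint8)
    valid = ~(rows == ord("N")).any(axis=0)
    anc = rows[3]
    derived = rows[:3] != anc  # shape (3, n_sites)
    # bi-allelic over the quartet: every derived call equals the same alternate
    alt = np.max(np.where(derived, rows[:3], 0), axis=0)
    biallelic = np.ones(rows.shape[1], dtype=bool)
    for i in range(3):
        biallelic &= ~derived[i] | (rows[i] == alt)
    usable = valid & biallelic & derived.any(axis=0)

    codes = np.full(rows.shape[1], -2, dtype=np.int8)
    d1, d2, d3 = derived
    abba = usable & ~d1 & d2 & d3
    baba = usable & d1 & ~d2 & d3
    bbaa = usable & d1 & d2 & ~d3
    other = usable & ~(abba | baba | bbaa)
    codes[abba] = 0
    codes[baba] = 1
    codes[bbaa] = 2
    codes[other] = -1
    return codes


def count_patterns4(
    snps: SnpMatrix, p1: str, p2: str, p3: str, outgroup: str
) -> SitePatternCounts4:
    """Tally ABBA (P2,P3 derived), BABA (P1,P3) and BBAA (P1,P2) patterns.

    Sites with any missing call among the four taxa, or more than two
    alleles over the quartet, are skipped.
    """
    codes = _pattern_codes(snps, p1, p2, p3, outgroup)
    return SitePatternCounts4(
        n_abba=int((codes == 0).sum()),
        n_baba=int((codes == 1).sum()),
        n_bbaa=int((codes == 2).sum()),
        n_sites_used=int((codes >= -1).sum()),
    )


def patterson_d(counts: SitePatternCounts4) -> float:
    """D = (nABBA - nBABA) / (nABBA + nBABA); NaN when the denominator is 0
    (the trio is untestable)."""
    denom = counts.n_abba + counts.n_baba
    if denom == 0:
        return math.nan
    return (counts.n_abba - counts.n_baba) / denom


def jackknife_z(
    snps: SnpMatrix,
    p1: str,
    p2: str,
    p3: str,
    outgroup: str,
    n_blocks: int = 20,
) -> tuple[float, float, int, str]:
    """Weighted delete-one block jackknife for D over contiguous SNP blocks.

    Blocks partition the SNP ranks into ``n_blocks`` contiguous,
    (near-)equal-count chunks. Returns (Z, two-sided p, blocks used, flag).
    When every delete-one estimate coincides the variance is degenerate:
    Z is reported infinite with p = 0 and flagged.
    """
    codes = _pattern_codes(snps, p1, p2, p3, outgroup)
    n_sites = len(codes)
    abba_all = int((codes == 0).sum())
    baba_all = int((codes == 1).sum())
    if abba_all + baba_all == 0:
        return math.nan, math.nan, 0, "no_informative_sites"
    d_hat = (abba_all - baba_all) / (abba_all + baba_all)

    edges = np.linspace(0, n_sites, n_blocks + 1).astype(int)
    edges = np.unique(edges)
    g = len(edges) - 1
    if g < 2:
        return math.nan, math.nan, g, "too_few_blocks"

    m = np.diff(edges).astype(float)  # sites per block
    abba_b = np.array(
        [(codes[a:b] == 0).sum() for a, b in zip(edges[:-1], edges[1:])], dtype=float
    )
    baba_b = np.array(
        [(codes[a:b] == 1).sum() for a, b in zip(edges[:-1], edges[1:])], dtype=float
    )
    num_del = (abba_all - abba_b) - (baba_all - baba_b)
    den_del = (abba_all - abba_b) + (baba_all - baba_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_del = np.where(den_del > 0, num_del / den_del, d_hat)

    n = float(n_sites)
    h = n / m
    theta_j = g * d_hat - ((1.0 - m / n) * d_del).sum()
    tau = h * d_hat - (h - 1.0) * d_del
    var = float((np.square(tau - theta_j) / (h - 1.0)).sum() / g)
    if var <= 0:
        z = math.inf if d_hat != 0 else 0.0
        return z, 0.0 if d_hat != 0 else 1.0, g, "degenerate_variance"
    z = d_hat / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p), g, "ok"


def dtrios_scan(
    snps: SnpMatrix,
    outgroup: str,
    taxa: Optional[Sequence[str]] = None,
    n_blocks: int = 20,
) -> pd.DataFrame:
    """Patterson's D for every unordered ingroup trio.

    Each trio is arranged so the BBAA pattern count is the largest of the
    three (the majority pair becomes (P1, P2)) and P1/P2 are swapped if
    needed so that D >= 0; P3 is then the candidate introgressor. Untestable
    trios are listed with their flag. One row per trio.
    """
    if taxa is None:
        taxa = [t for t in snps.taxa if t != outgroup]
    taxa = list(taxa)
    if outgroup in taxa:
        raise ValueError("outgroup cannot be among the ingroup taxa")
    if len(taxa) < 3:
        raise ValueError("need at least 3 ingroup taxa")

    rows = []
    for trio in combinations(taxa, 3):
        x, y, z_ = trio
        # pair counts under polarization: BBAA-style count for each pair
        pair_counts = {}
        for p1, p2, p3 in ((x, y, z_), (x, z_, y), (y, z_, x)):
            c = count_patterns4(snps, p1, p2, p3, outgroup)
            pair_counts[(p1, p2)] = (c, p3)
        (p1, p2), (c, p3) = max(
            pair_counts.items(), key=lambda kv: (kv[1][0].n_bbaa, kv[0])
        )
        d = patterson_d(c)
        if not math.isnan(d) and d < 0:
            p1, p2 = p2, p1
            c = SitePatternCounts4(c.n_baba, c.n_abba, c.n_bbaa, c.n_sites_used)
            d = -d
        z, p, nb, flag = jackknife_z(snps, p1, p2, p3, outgroup, n_blocks=n_blocks)
        rows.append(
            DResult(p1, p2, p3, c.n_abba, c.n_baba, c.n_bbaa, d, z, p, nb, flag)
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df


def best_per_pair(results: pd.DataFrame) -> pd.DataFrame:
    """The most significant trio row per (P2, P3) pair — the bubble-chart
    table of the trio scan."""
    ok = results[results["flag"].isin(["ok", "degenerate_variance"])].copy()
    if ok.empty:
        return ok
    ok = ok.sort_values(["p", "d"], ascending=[True, False])
    return ok.groupby(["p2", "p3"], as_index=False).first()
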