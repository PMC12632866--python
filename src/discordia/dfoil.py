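"""Five-taxon D_FOIL statistics with introgression-direction classification.

The test assumes the symmetric topology (((P1, P2), (P3, P4)), O) with the
(P1, P2) ancestor younger than the (P3, P4) ancestor (a chronology
precondition declared by the caller). Site patterns over (P1, P2, P3, P4)
are polarized against the outgroup; four D-like statistics are computed
from left/right pattern-count sums:

    D_FO: {BABA, BBBA, ABAB, AAAB}  vs  {BAAB, BBAB, ABBA, AABA}
    D_IL: {ABBA, BBBA, BAAB, AAAB}  vs  {ABAB, BBAB, BABA, AABA}
    D_FI: {BABA, BABB, ABAB, ABAA}  vs  {ABBA, ABBB, BAAB, BAAA}
    D_OL: {BAAB, BABB, ABBA, ABAA}  vs  {ABAB, ABBB, BABA, BAAA}

D_FO/D_IL are antisymmetric under P3<->P4 and D_FI/D_OL under P1<->P2, so
all four are zero in expectation under incomplete lineage sorting alone.
The joint sign pattern (signs thresholded by a per-component chi-square
test) identifies the donor and recipient: a recipient in the younger pair
leaves the other young taxon's statistic (D_IL or D_FO) at zero while D_FI
and D_OL deviate jointly; a recipient in the older pair drags its sister
along, moving D_FO and D_IL jointly while exactly one of D_FI/D_OL — the
one naming the donor — deviates. The nominally zero components are exact
only to leading order; with very large site counts their small systematic
deviations can become statistically significant, in which case the vector
falls outside the table and is reported as ``complex``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .winio import SnpMatrix

__all__ = [
    "SitePatternCounts5",
    "DfoilResult",
    "PATTERN_NAMES",
    "count_patterns5",
    "dfoil_stats",
    "dfoil_scan",
    "classify_signs",
]

#: index = binary pattern over (P1, P2, P3, P4); bit 3 = P1 ... bit 0 = P4.
PATTERN_NAMES = tuple(
    "".join("B" if (i >> b) & 1 else "A" for b in (3, 2, 1, 0)) for i in range(16)
)
_PIDX = {name: i for i, name in enumerate(PATTERN_NAMES)}

_COMPONENTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "DFO": (("BABA", "BBBA", "ABAB", "AAAB"), ("BAAB", "BBAB", "ABBA", "AABA")),
    "DIL": (("ABBA", "BBBA", "BAAB", "AAAB"), ("ABAB", "BBAB", "BABA", "AABA")),
    "DFI": (("BABA", "BABB", "ABAB", "ABAA"), ("ABBA", "ABBB", "BAAB", "BAAA")),
    "DOL": (("BAAB", "BABB", "ABBA", "ABAA"), ("ABAB", "ABBB", "BABA", "BAAA")),
}

#: joint sign vector (DFO, DIL, DFI, DOL) -> (donor, recipient) in position
#: labels; None marks an undirected/ancestral or unclassifiable signal.
SIGN_TABLE: dict[tuple[int, int, int, int], tuple[Optional[str], Optional[str], str]] = {
    (0, 0, 0, 0): (None, None, "none"),
    (1, 0, 1, 1): ("P3", "P1", "P3=>P1"),
    (-1, 0, 1, 1): ("P4", "P1", "P4=>P1"),
    (0, 1, -1, -1): ("P3", "P2", "P3=>P2"),
    (0, -1, -1, -1): ("P4", "P2", "P4=>P2"),
    (1, 1, 1, 0): ("P1", "P3", "P1=>P3"),
    (1, 1, -1, 0): ("P2", "P3", "P2=>P3"),
    (-1, -1, 0, 1): ("P1", "P4", "P1=>P4"),
    (-1, -1, 0, -1): ("P2", "P4", "P2=>P4"),
    (1, 1, 0, 0): (None, None, "ancestral(P3)"),
    (-1, -1, 0, 0): (None, None, "ancestral(P4)"),
}


@dataclass(frozen=True)
class SitePatternCounts5:
    """Tallies of the 16 derived/ancestral patterns over (P1..P4), outgroup
    ancestral. The all-ancestral (AAAA) and all-derived (BBBB) patterns are
    carried but unused by the statistics."""

    counts: tuple[int, ...]
    n_sites_used: int

    def __post_init__(self):
        if len(self.counts) != 16:
            raise ValueError("need exactly 16 pattern counts")
        if min(self.counts) < 0:
            raise ValueError("pattern counts must be non-negative")

    def __getitem__(self, name: str) -> int:
        return self.counts[_PIDX[name]]


@dataclass(frozen=True)
class DfoilResult:
    taxa: tuple[str, str, str, str, str]  # (P1, P2, P3, P4, outgroup)
    stats: dict[str, float]  # component -> value (NaN when undefined)
    pvalues: dict[str, float]
    signs: tuple[int, int, int, int]
    donor: Optional[str]  # actual taxon label, None if not determinable
    recipient: Optional[str]
    classification: str
    n_sites_used: int
    flag: str  # "ok" or "untestable"


def count_patterns5(
    snps: SnpMatrix, p1: str, p2: str, p3: str, p4: str, outgroup: str
) -> SitePatternCounts5:
    """Tally the 16 (P1..P4) derived/ancestral patterns.

    Only bi-allelic sites with no missing call among the five taxa are used;
    the outgroup allele defines the ancestral state.
    """
    names = (p1, p2, p3, p4, outgroup)
    if len(set(names)) != 5:
        raise ValueError(f"taxa must be distinct, got {names}")
    rows = np.stack([snps.row(t) for t in names]).view(np.uint8)
    valid = ~(rows == ord("N")).any(axis=0)
    anc = rows[4]
    derived = rows[:4] != anc
    alt = np.max(np.where(derived, rows[:4], 0), axis=0)
    biallelic = np.ones(rows.shape[1], dtype=bool)
    for i in range(4):
        biallelic &= ~derived[i] | (rows[i] == alt)
    usable = valid & biallelic & derived.any(axis=0)

    idx = (
        derived[0].astype(np.int8) * 8
        + derived[1] * 4
        + derived[2] * 2
        + derived[3]
    )
    counts = np.bincount(idx[usable], minlength=16)
    return SitePatternCounts5(tuple(int(c) for c in counts), int(usable.sum()))


def dfoil_stats(
    counts: SitePatternCounts5,
    alpha: float = 0.01,
    taxa: tuple[str, str, str, str, str] = ("P1", "P2", "P3", "P4", "O"),
) -> DfoilResult:
    """Compute the four D_FOIL components and classify the sign pattern.

    Each component is (L - R) / (L + R) over its pattern-count sums; its
    sign is set to 0 unless a chi-square goodness-of-fit test of L vs R
    against equality is significant at ``alpha`` (or when L + R = 0, in
    which case the component is undefined). The joint sign vector is looked
    up in the direction table; vectors outside the table are reported as
    ``complex`` (inconsistent with a single introgression event).
    """
    values: dict[str, float] = {}
    pvalues: dict[str, float] = {}
    signs = []
    testable = False
    for name, (left, right) in _COMPONENTS.items():
        l_sum = sum(counts[p] for p in left)
        r_sum = sum(counts[p] for p in right)
        tot = l_sum + r_sum
        if tot == 0:
            values[name] = math.nan
            pvalues[name] = math.nan
            signs.append(0)
            continue
        testable = True
        d = (l_sum - r_sum) / tot
        chi2, p = stats.chisquare([l_sum, r_sum])
        values[name] = float(d)
        pvalues[name] = float(p)
        if p < alpha and d != 0:
            signs.append(1 if d > 0 else -1)
        else:
            signs.append(0)

    sign_vec = tuple(signs)
    donor_pos, recip_pos, label = SIGN_TABLE.get(
        sign_vec, (None, None, "complex")
    )
    position = dict(zip(("P1", "P2", "P3", "P4", "O"), taxa))
    donor = position[donor_pos] if donor_pos else None
    recipient = position[recip_pos] if recip_pos else None
    if label not in ("none", "complex") and donor is not None:
        label = f"{donor}=>{recipient}"
    elif label.startswith("ancestral"):
        inner = label[label.index("(") + 1 : -1]
        label = f"ancestral({position[inner]})"
    return DfoilResult(
        taxa=taxa,
        stats=values,
        pvalues=pvalues,
        signs=sign_vec,  # type: ignore[arg-type]
        donor=donor,
        recipient=recipient,
        classification=label,
        n_sites_used=counts.n_sites_used,
        flag="ok" if testable else "untestable",
    )


def dfoil_scan(
    snps: SnpMatrix,
    families: Sequence[tuple[str, str, str, str, str]],
    alpha: float = 0.01,
    pair_ages: Optional[dict[frozenset[str], float]] = None,
) -> pd.DataFrame:
    """Run D_FOIL on each declared family (P1, P2, P3, P4, outgroup).

    The symmetric-topology chronology — the (P1, P2) ancestor younger than
    the (P3, P4) ancestor — is the caller's declaration; when ``pair_ages``
    (mapping frozenset({a, b}) to divergence times) is supplied it is
    checked and violating families raise ``ValueError``.
    """
    rows = []
    for fam in families:
        if len(fam) != 5:
            raise ValueError(f"family must have 5 taxa, got {fam}")
        p1, p2, p3, p4, og = fam
        if pair_ages is not None:
            t12 = pair_ages.get(frozenset((p1, p2)))
            t34 = pair_ages.get(frozenset((p3, p4)))
            if t12 is None or t34 is None:
                raise ValueError(f"pair_ages missing entries for family {fam}")
            if not t12 < t34:
                raise ValueError(
                    f"family {fam} violates chronology: ({p1},{p2}) ancestor "
                    f"({t12}) is not younger than ({p3},{p4}) ancestor ({t34})"
                )
        counts = count_patterns5(snps, p1, p2, p3, p4, og)
        res = dfoil_stats(counts, alpha=alpha, taxa=fam)
        rows.append(
            {
                "p1": p1,
                "p2": p2,
                "p3": p3,
                "p4": p4,
                "outgroup": og,
                **{k.lower(): v for k, v in res.stats.items()},
                **{f"p_{k.lower()}": v for k, v in res.pvalues.items()},
                "signs": "".join(
                    {1: "+", 0: "0", -1: "-"}[s] for s in res.signs
                ),
                "donor": res.donor,
                "recipient": res.recipient,
                "classification": res.classification,
                "n_sites_used": res.n_sites_used,
                "flag": res.flag,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "p1", "p2", "p3", "p4", "outgroup",
            "dfo", "dil", "dfi", "dol",
            "p_dfo", "p_dil", "p_dfi", "p_dol",
            "signs", "donor", "recipient", "classification",
            "n_sites_used", "flag",
        ],
    )


def classify_signs(signs: tuple[int, int, int, int]) -> str:
    """Classification label for a joint sign vector (position labels)."""
    return SIGN_TABLE.get(tuple(signs), (None, None, "complex"))[2]
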