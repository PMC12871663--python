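"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — character-by-character scans,
exact rational arithmetic, exhaustive subset enumeration — and shares no
code path with the package internals it checks.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations, product
from math import comb

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _matches(seq_base: str, pattern_code: str) -> bool:
    # an N in the sequence matches nothing
    return seq_base in _IUPAC[pattern_code]


def naive_find_sites(
    seq: str, protospacer: str, pam: str = "NGG", max_mm: int = 0
) -> list[tuple[int, str, int, int]]:
    """Per-position sliding-window scan on both strands.

    Returns (position, strand, mismatches, cut_position) tuples sorted by
    (position, strand), with minus-strand hits mirrored onto the + strand.
    """
    m, p = len(protospacer), len(pam)
    n = len(seq)
    hits: list[tuple[int, str, int, int]] = []

    def scan(s: str):
        found = []
        for i in range(len(s) - m - p + 1):
            ok_pam = all(_matches(s[i + m + j], pam[j]) for j in range(p))
            if not ok_pam:
                continue
            mm = sum(not _matches(s[i + j], protospacer[j]) for j in range(m))
            if mm <= max_mm:
                found.append((i, mm))
        return found

    for i, mm in scan(seq):
        hits.append((i, "+", mm, i + m - 3))
    rc = naive_revcomp(seq)
    for i, mm in scan(rc):
        pos = n - i - m
        hits.append((pos, "-", mm, pos + 3))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def fisher_exact_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher's exact p by full hypergeometric enumeration.

    Exact rational arithmetic; the probability-mass rule (sum over all
    tables with the fixed margins whose probability is <= the observed
    table's).
    """
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = comb(n, col1)
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    probs = {
        x: Fraction(comb(row1, x) * comb(n - row1, col1 - x), denom)
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)


def enumerate_outermost_outcomes(
    unit_intervals: list[tuple[int, int, bool]],
    cut_positions: list[int],
    cleavage_prob: float,
) -> dict[int, float]:
    """Exact copy-total distribution under outermost-join repair.

    ``unit_intervals`` are (start, end, is_repeat) parent units.  Each cut
    is made independently with ``cleavage_prob``; with fewer than two
    distinct cut positions nothing changes; otherwise every repeat unit
    strictly inside the outermost cut pair is lost (units clipped at a cut
    still count — a clipped repeat is truncated, not gone).  Returns
    {copy_total: probability} by enumerating all 2^n cleaved subsets.
    """
    n = len(cut_positions)
    parent_total = sum(1 for *_, rep in unit_intervals if rep)
    dist: dict[int, float] = {}
    for mask in product([0, 1], repeat=n):
        prob = 1.0
        for bit in mask:
            prob *= cleavage_prob if bit else (1.0 - cleavage_prob)
        if prob == 0.0:
            continue
        cuts = sorted({c for c, bit in zip(cut_positions, mask) if bit})
        if len(cuts) < 2:
            total = parent_total
        else:
            dl, dr = cuts[0], cuts[-1]
            lost = sum(
                1 for s, e, rep in unit_intervals if rep and s >= dl and e <= dr
            )
            total = parent_total - lost
        dist[total] = dist.get(total, 0.0) + prob
    return dist


def enumerate_random_pair_outcomes(
    unit_intervals: list[tuple[int, int, bool]],
    cut_positions: list[int],
    cleavage_prob: float,
) -> dict[int, float]:
    """Exact copy-total distribution under random-pair-join repair."""
    n = len(cut_positions)
    parent_total = sum(1 for *_, rep in unit_intervals if rep)
    dist: dict[int, float] = {}

    def add(total: int, prob: float) -> None:
        dist[total] = dist.get(total, 0.0) + prob

    for mask in product([0, 1], repeat=n):
        prob = 1.0
        for bit in mask:
            prob *= cleavage_prob if bit else (1.0 - cleavage_prob)
        if prob == 0.0:
            continue
        cuts = sorted({cut_positions[i] for i, bit in enumerate(mask) if bit})
        if len(cuts) < 2:
            add(parent_total, prob)
            continue
        # one pair of distinct cleaved cut positions, uniform over pairs
        pairs = list(combinations(cuts, 2))
        for dl, dr in pairs:
            lost = sum(1 for s, e, rep in unit_intervals if rep and s >= dl and e <= dr)
            add(parent_total - lost, prob / len(pairs))
    return dist
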