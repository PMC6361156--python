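"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive — plain loops, explicit case
analysis, exact enumeration — and shares no code with the package paths it
checks.
"""

from __future__ import annotations

from math import comb
from typing import Dict, List, Tuple


def hwe_enumeration_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p by full enumeration of heterozygote counts.

    Conditional on allele counts, P(het = h) is proportional to
    ``2^h * n! / (hom1! * h! * hom2!)``; the two-sided p sums the
    probabilities of all outcomes no more likely than the observed one.
    """
    n = n_AA + n_Aa + n_aa
    n_a = n_Aa + 2 * n_aa
    rare = min(n_a, 2 * n - n_a)
    probs: Dict[int, float] = {}
    total = 0.0
    for h in range(rare % 2, rare + 1, 2):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        w = (2 ** h) * comb(n, h) * comb(n - h, hom_r)
        probs[h] = float(w)
        total += w
    for h in probs:
        probs[h] /= total
    obs = probs[n_Aa]
    return min(1.0, sum(p for p in probs.values() if p <= obs * (1 + 1e-12)))


def tdt_trio_counts(
    father: str, mother: str, child: str, minor: str
) -> Tuple[int, int]:
    """(b, c) contribution of one trio at one marker, by case analysis.

    Genotypes are two-character strings like ``"AG"``; ``minor`` is the
    counted allele.  Unresolvable double-het/het-child trios contribute
    one transmission and one non-transmission.
    """
    def dose(g: str) -> int:
        return g.count(minor)

    f, m, c = dose(father), dose(mother), dose(child)
    b = ccount = 0
    if f == 1 and m == 1:
        if c == 2:
            b = 2
        elif c == 0:
            ccount = 2
        else:
            b = ccount = 1
    elif f == 1:
        t = c - m // 2
        if t == 1:
            b = 1
        elif t == 0:
            ccount = 1
        # anything else is a Mendelian inconsistency: contributes nothing
    elif m == 1:
        t = c - f // 2
        if t == 1:
            b = 1
        elif t == 0:
            ccount = 1
    return b, ccount


def scan_scores_naive(sequence: str, matrix_rows: Dict[str, List[float]]) -> List[float]:
    """Window scores by an explicit double loop over starts and positions."""
    width = len(next(iter(matrix_rows.values())))
    out = []
    for start in range(len(sequence) - width + 1):
        s = 0.0
        for k in range(width):
            s += matrix_rows[sequence[start + k]][k]
        out.append(s)
    return out


def coverage_fraction_naive(depth_tracks: List[List[int]], min_depth: int) -> float:
    """Per-base loop version of the coverage fraction."""
    n = 0
    hit = 0
    for track in depth_tracks:
        for d in track:
            n += 1
            if d >= min_depth:
                hit += 1
    return hit / n


def overlap_count_naive(
    intervals: List[Tuple[str, int, int]], region: Tuple[str, int, int]
) -> int:
    """O(n) scan counting intervals overlapping the region by >= 1 bp."""
    chrom, start, end = region
    count = 0
    for c, s, e in intervals:
        if c != chrom:
            continue
        if s <= end and e >= start:
            count += 1
    return count


def binom_two_sided_sign_p(b: int, c: int) -> float:
    """Exact two-sided sign-test p for b transmissions out of b + c."""
    n = b + c
    d = abs(b - c)
    total = 0.0
    for k in range(n + 1):
        if abs(2 * k - n) >= d:
            total += comb(n, k) / 2 ** n
    return min(1.0, total)
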