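"""Independent brute-force reference implementations.

Everything here is written from the definitions by direct enumeration —
pairwise loops, column scans, exhaustive window search — deliberately
avoiding the vectorised code paths in the package, so agreement is a
real two-route check and not a tautology.
"""

from __future__ import annotations

import math
from itertools import combinations

MISSING = {"N", "-"}


def usable_columns(seqs: list[str]) -> list[int]:
    """Complete deletion: columns with no missing character anywhere."""
    L = len(seqs[0])
    return [j for j in range(L) if all(s[j] not in MISSING for s in seqs)]


def pair_diffs(a: str, b: str, cols: list[int]) -> int:
    return sum(a[j] != b[j] for j in cols)


def brute_pi(seqs: list[str]) -> float:
    cols = usable_columns(seqs)
    n = len(seqs)
    if n < 2 or not cols:
        return float("nan")
    total = sum(
        pair_diffs(seqs[i], seqs[j], cols) for i, j in combinations(range(n), 2)
    )
    return total / (math.comb(n, 2) * len(cols))


def brute_segregating_sites(seqs: list[str]) -> int:
    cols = usable_columns(seqs)
    return sum(len({s[j] for s in seqs}) > 1 for j in cols)


def brute_theta_w(seqs: list[str]) -> float:
    cols = usable_columns(seqs)
    n = len(seqs)
    if n < 2 or not cols:
        return float("nan")
    a1 = sum(1 / i for i in range(1, n))
    return brute_segregating_sites(seqs) / (a1 * len(cols))


def brute_tajimas_d(seqs: list[str]) -> float:
    """Direct transcription of the 1989 constants, coded separately."""
    n = len(seqs)
    cols = usable_columns(seqs)
    if n < 4 or not cols:
        return float("nan")
    s = brute_segregating_sites(seqs)
    if s == 0:
        return float("nan")
    pihat = sum(
        pair_diffs(seqs[i], seqs[j], cols) for i, j in combinations(range(n), 2)
    ) / math.comb(n, 2)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pihat - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def brute_dxy(seqs_a: list[str], seqs_b: list[str]) -> float:
    cols = usable_columns(seqs_a + seqs_b)
    if not cols:
        return float("nan")
    total = sum(pair_diffs(a, b, cols) for a in seqs_a for b in seqs_b)
    return total / (len(seqs_a) * len(seqs_b) * len(cols))


def brute_fst(seqs_a: list[str], seqs_b: list[str]) -> float:
    """1 - Hw/Hb with everything on the joint usable column set."""
    cols = usable_columns(seqs_a + seqs_b)
    if not cols:
        return float("nan")

    def pi_on(seqs: list[str]) -> float:
        n = len(seqs)
        total = sum(
            pair_diffs(seqs[i], seqs[j], cols) for i, j in combinations(range(n), 2)
        )
        return total / (math.comb(n, 2) * len(cols))

    hb = brute_dxy(seqs_a, seqs_b)
    if hb == 0 or math.isnan(hb):
        return float("nan")
    return 1 - (pi_on(seqs_a) + pi_on(seqs_b)) / 2 / hb


def brute_call_base(counts: dict[str, int], min_cov: int, het_frac: float) -> str:
    from hzdiv.locus_io import PAIR_TO_IUPAC

    total = sum(counts.values())
    if total < min_cov:
        return "N"
    ranked = sorted("ACGT", key=lambda b: (-counts.get(b, 0), b))
    top, second = ranked[0], ranked[1]
    if counts.get(second, 0) > 0 and counts.get(second, 0) / total >= het_frac:
        return PAIR_TO_IUPAC[frozenset((top, second))]
    return top


def brute_informative_sites(seqs: list[str]) -> list[int]:
    L = len(seqs[0])
    out = []
    for j in range(L):
        col = [s[j] for s in seqs]
        if any(c in MISSING for c in col):
            continue
        if len(set(col)) == 2:
            out.append(j)
    return out


def brute_window_compatible(seqs: list[str], start: int, end: int) -> bool:
    sites = [j for j in brute_informative_sites(seqs) if start <= j < end]
    for i, j in combinations(sites, 2):
        gametes = {(s[i], s[j]) for s in seqs}
        if len(gametes) == 4:
            return False
    return True


def brute_longest_block(seqs: list[str]) -> tuple[int, int]:
    """Exhaustive search over all windows; leftmost of the longest."""
    L = len(seqs[0])
    best = (0, 0)
    for start in range(L):
        for end in range(start + 1, L + 1):
            if end - start <= best[1] - best[0]:
                continue
            if brute_window_compatible(seqs, start, end):
                best = (start, end)
    return best
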