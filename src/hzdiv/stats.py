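"""Per-locus diversity and divergence statistics.

Within-species: nucleotide diversity pi, segregating sites S,
Watterson's theta and Tajima's D.  Between-species: absolute divergence
Dxy (mean per-site difference over all between-group pairs) and relative
differentiation Fst = 1 - Hw/Hb with Hw = (pi_A + pi_B)/2 and Hb = Dxy
(the Hudson-Slatkin-Maddison form); the Lynch-Crease Nst variant is
available as an option.

Site filtering follows the complete-deletion convention of classic
sequence-analysis software by default: any column containing missing
data (N, and gaps when ``treat_gap_as_missing``) in any retained
sequence is dropped before counting.  All counts are accumulated as
integers and divided once, so results agree with brute-force pairwise
enumeration to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from hzdiv.locus_io import LocusAlignment, LocusMetadata


@dataclass(frozen=True)
class SiteFilterPolicy:
    mode: str = "complete_deletion"  # or "pairwise_deletion"
    treat_gap_as_missing: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("complete_deletion", "pairwise_deletion"):
            raise ValueError(f"bad mode {self.mode!r}")

    @property
    def missing_chars(self) -> tuple[str, ...]:
        return ("N", "-") if self.treat_gap_as_missing else ("N",)


DEFAULT_POLICY = SiteFilterPolicy()


@dataclass
class SpeciesStats:
    """Within-species per-locus summaries (per-site scale for pi/theta)."""

    n_sequences: int
    sites_used: int
    s: int
    pi: float
    theta_w: float
    tajimas_d: float  # NaN when undefined (S=0 or n<4)


@dataclass
class LocusStats:
    locus_id: str
    per_species: dict[str, SpeciesStats]
    dxy: float
    fst: float
    sites_used: int  # joint (both-species) usable sites
    linkage: str = "unknown"
    introgression_class: str = "unclassified"


def _matrix(seqs: Sequence[str]) -> np.ndarray:
    if not seqs:
        raise ValueError("no sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences have unequal lengths")
    return np.array([list(s.upper()) for s in seqs], dtype="<U1")


def _missing_mask(mat: np.ndarray, policy: SiteFilterPolicy) -> np.ndarray:
    miss = mat == "N"
    if policy.treat_gap_as_missing:
        miss |= mat == "-"
    return miss


def usable_sites(
    seqs: Sequence[str] | np.ndarray, policy: SiteFilterPolicy = DEFAULT_POLICY
) -> np.ndarray:
    """Indices of columns retained under the policy.

    Complete deletion keeps columns with no missing character in any
    sequence; pairwise deletion keeps every column (missingness is then
    handled pair by pair inside each statistic).
    """
    mat = seqs if isinstance(seqs, np.ndarray) else _matrix(seqs)
    if policy.mode == "pairwise_deletion":
        return np.arange(mat.shape[1])
    return np.flatnonzero(~_missing_mask(mat, policy).any(axis=0))


def _allele_counts(mat: np.ndarray) -> np.ndarray:
    """(5, L) counts of A,C,G,T,- per column (N ignored; the gap row
    only matters when gaps are treated as characters)."""
    return np.stack([(mat == b).sum(axis=0) for b in "ACGT-"])


def _within_diff_pairs(mat: np.ndarray) -> int:
    """Total differing pairs summed over columns (no missing assumed)."""
    counts = _allele_counts(mat)
    n = mat.shape[0]
    same = (counts * (counts - 1) // 2).sum()
    return int(mat.shape[1] * (n * (n - 1) // 2) - same)


def nucleotide_diversity(
    seqs: Sequence[str], policy: SiteFilterPolicy = DEFAULT_POLICY
) -> float:
    """Mean pairwise difference proportion (pi, per usable site)."""
    mat = _matrix(seqs)
    n = mat.shape[0]
    if n < 2:
        return float("nan")
    if policy.mode == "complete_deletion":
        cols = usable_sites(mat, policy)
        if cols.size == 0:
            return float("nan")
        sub = mat[:, cols]
        total = _within_diff_pairs(sub)
        return total / (n * (n - 1) // 2 * cols.size)
    # pairwise deletion: average per-pair proportions
    miss = _missing_mask(mat, policy)
    props = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(miss[i] | miss[j])
            L = int(ok.sum())
            if L == 0:
                continue
            props.append(int((mat[i, ok] != mat[j, ok]).sum()) / L)
    return float(np.mean(props)) if props else float("nan")


def segregating_sites(
    seqs: Sequence[str], policy: SiteFilterPolicy = DEFAULT_POLICY
) -> int:
    """Number of polymorphic usable columns (any number of alleles)."""
    mat = _matrix(seqs)
    if policy.mode == "complete_deletion":
        cols = usable_sites(mat, policy)
        sub = mat[:, cols]
        counts = _allele_counts(sub)
        return int(((counts > 0).sum(axis=0) > 1).sum())
    # pairwise deletion: polymorphic among called characters
    miss = _missing_mask(mat, policy)
    s = 0
    for j in range(mat.shape[1]):
        alleles = set(mat[~miss[:, j], j])
        if len(alleles) > 1:
            s += 1
    return s


def harmonic_a1(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def wattersons_theta(
    seqs: Sequence[str], policy: SiteFilterPolicy = DEFAULT_POLICY
) -> float:
    """Watterson's theta per usable site: S / (a1 * sites_used)."""
    mat = _matrix(seqs)
    n = mat.shape[0]
    if n < 2:
        return float("nan")
    cols = usable_sites(mat, policy)
    if cols.size == 0:
        return float("nan")
    s = segregating_sites(seqs, policy)
    return s / (harmonic_a1(n) * cols.size)


def tajimas_d(seqs: Sequence[str], policy: SiteFilterPolicy = DEFAULT_POLICY) -> float:
    """Tajima's D over usable sites; NaN when n < 4 or S = 0.

    Uses the count form of mean pairwise differences (not per site) with
    the 1989 normalising constants::

        a1 = sum 1/i,  a2 = sum 1/i^2            (i = 1..n-1)
        b1 = (n+1)/(3(n-1)),  b2 = 2(n^2+n+3)/(9n(n-1))
        c1 = b1 - 1/a1,       c2 = b2 - (n+2)/(a1 n) + a2/a1^2
        e1 = c1/a1,           e2 = c2/(a1^2 + a2)
        D  = (pihat - S/a1) / sqrt(e1 S + e2 S (S-1))
    """
    mat = _matrix(seqs)
    n = mat.shape[0]
    if n < 4:
        return float("nan")
    if policy.mode != "complete_deletion":
        cols = np.flatnonzero(~_missing_mask(mat, policy).any(axis=0))
    else:
        cols = usable_sites(mat, policy)
    if cols.size == 0:
        return float("nan")
    sub = mat[:, cols]
    counts = _allele_counts(sub)
    s = int(((counts > 0).sum(axis=0) > 1).sum())
    if s == 0:
        return float("nan")
    pihat = _within_diff_pairs(sub) / (n * (n - 1) // 2)
    a1 = harmonic_a1(n)
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pihat - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def _between_diff_total(matA: np.ndarray, matB: np.ndarray) -> int:
    """Sum over columns of differing between-group pairs (no missing)."""
    cA = _allele_counts(matA)
    cB = _allele_counts(matB)
    same = (cA * cB).sum()
    return int(matA.shape[1] * matA.shape[0] * matB.shape[0] - same)


def dxy(
    seqs_a: Sequence[str],
    seqs_b: Sequence[str],
    policy: SiteFilterPolicy = DEFAULT_POLICY,
) -> float:
    """Absolute divergence: mean per-site difference over A x B pairs."""
    matA, matB = _matrix(seqs_a), _matrix(seqs_b)
    if matA.shape[1] != matB.shape[1]:
        raise ValueError("group alignments have different lengths")
    if policy.mode == "complete_deletion":
        joint = np.vstack([matA, matB])
        cols = usable_sites(joint, policy)
        if cols.size == 0:
            return float("nan")
        total = _between_diff_total(matA[:, cols], matB[:, cols])
        return total / (matA.shape[0] * matB.shape[0] * cols.size)
    missA = _missing_mask(matA, policy)
    missB = _missing_mask(matB, policy)
    props = []
    for i in range(matA.shape[0]):
        for j in range(matB.shape[0]):
            ok = ~(missA[i] | missB[j])
            L = int(ok.sum())
            if L == 0:
                continue
            props.append(int((matA[i, ok] != matB[j, ok]).sum()) / L)
    return float(np.mean(props)) if props else float("nan")


def fst(
    seqs_a: Sequence[str],
    seqs_b: Sequence[str],
    policy: SiteFilterPolicy = DEFAULT_POLICY,
    estimator: str = "hsm",
) -> float:
    """Relative differentiation between two groups.

    ``hsm``: 1 - Hw/Hb with Hw = (pi_A + pi_B)/2, Hb = Dxy, all three
    computed on the joint usable site set so the identity
    Hw = (1 - Fst) * Hb holds exactly.  ``nst``: (pi_T - pi_S)/pi_T with
    pi_S the sample-size-weighted mean within-group diversity and pi_T
    the pooled diversity.  Negative values are reported as-is.  NaN when
    the denominator is zero.
    """
    matA, matB = _matrix(seqs_a), _matrix(seqs_b)
    if matA.shape[0] < 2 or matB.shape[0] < 2:
        return float("nan")
    joint = np.vstack([matA, matB])
    cols = usable_sites(joint, policy)
    if cols.size == 0:
        return float("nan")
    subA, subB = matA[:, cols], matB[:, cols]
    nA, nB, L = matA.shape[0], matB.shape[0], cols.size
    piA = _within_diff_pairs(subA) / (nA * (nA - 1) // 2 * L)
    piB = _within_diff_pairs(subB) / (nB * (nB - 1) // 2 * L)
    if estimator == "hsm":
        hb = _between_diff_total(subA, subB) / (nA * nB * L)
        if hb == 0:
            return float("nan")
        return 1.0 - (piA + piB) / 2.0 / hb
    if estimator == "nst":
        pi_t = _within_diff_pairs(np.vstack([subA, subB])) / (
            (nA + nB) * (nA + nB - 1) // 2 * L
        )
        if pi_t == 0:
            return float("nan")
        pi_s = (nA * piA + nB * piB) / (nA + nB)
        return (pi_t - pi_s) / pi_t
    raise ValueError(f"unknown estimator {estimator!r}")


def compute_locus_stats(
    alignment: LocusAlignment,
    metadata: LocusMetadata | None = None,
    policy: SiteFilterPolicy = DEFAULT_POLICY,
) -> LocusStats:
    """All per-locus statistics, grouping sequences by species label.

    Expects a haplotype alignment (males already collapsed at X loci).
    Species with fewer than 2 sequences get NaN within-species fields;
    between-species fields need exactly 2 species with sequences, else
    NaN.
    """
    groups = alignment.by_species()
    per_species: dict[str, SpeciesStats] = {}
    for sp, seqs in sorted(groups.items()):
        n = len(seqs)
        if n < 2:
            per_species[sp] = SpeciesStats(n, 0, 0, float("nan"), float("nan"), float("nan"))
            continue
        cols = usable_sites(seqs, policy)
        per_species[sp] = SpeciesStats(
            n_sequences=n,
            sites_used=int(cols.size),
            s=segregating_sites(seqs, policy),
            pi=nucleotide_diversity(seqs, policy),
            theta_w=wattersons_theta(seqs, policy),
            tajimas_d=tajimas_d(seqs, policy),
        )
    species = sorted(groups)
    if len(species) == 2:
        a, b = (groups[s] for s in species)
        d = dxy(a, b, policy)
        f = fst(a, b, policy) if min(len(a), len(b)) >= 2 else float("nan")
        joint = usable_sites([s for sp in species for s in groups[sp]], policy)
        sites = int(joint.size)
    else:
        d, f, sites = float("nan"), float("nan"), 0
    return LocusStats(
        locus_id=alignment.locus_id,
        per_species=per_species,
        dxy=d,
        fst=f,
        sites_used=sites,
        linkage=metadata.linkage if metadata else "unknown",
        introgression_class=metadata.introgression_class if metadata else "unclassified",
    )


def stats_to_frame(stats: Iterable[LocusStats]) -> pd.DataFrame:
    """Flatten LocusStats into one row per locus (the contrasts input)."""
    rows = []
    for st in stats:
        row: dict[str, object] = {
            "locus_id": st.locus_id,
            "linkage": st.linkage,
            "class": st.introgression_class,
            "dxy": st.dxy,
            "fst": st.fst,
            "sites_used": st.sites_used,
        }
        for sp, ss in st.per_species.items():
            row[f"n_{sp}"] = ss.n_sequences
            row[f"S_{sp}"] = ss.s
            row[f"pi_{sp}"] = ss.pi
            row[f"theta_w_{sp}"] = ss.theta_w
            row[f"tajimas_d_{sp}"] = ss.tajimas_d
        rows.append(row)
    return pd.DataFrame(rows)


def write_stats_table(stats: Iterable[LocusStats], path: str | Path) -> None:
    stats_to_frame(stats).to_csv(path, sep="\t", index=False)


def read_stats_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
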