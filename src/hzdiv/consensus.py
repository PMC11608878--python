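"""Diploid consensus calling from per-site read pileups.

A site is called only when total coverage reaches ``min_cov`` (default 8,
inclusive); it is called heterozygous when the second most frequent base
carries at least ``het_frac`` (default 25%) of the reads, in which case
the two-base IUPAC code of the top two bases is emitted.  Undercovered
sites become N.  Ties for the modal base break by A < C < G < T so calls
are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from hzdiv.locus_io import BASES, PAIR_TO_IUPAC

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PileupCounts:
    """Per-site A/C/G/T read counts for one individual at one locus."""

    individual: str
    locus_id: str
    counts: np.ndarray  # (L, 4) non-negative ints, columns A,C,G,T

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be an (L, 4) array")
        if (self.counts < 0).any():
            raise ValueError("negative read counts")

    @property
    def length(self) -> int:
        return self.counts.shape[0]


def call_consensus_base(
    site_counts: Mapping[str, int] | np.ndarray,
    min_cov: int = 8,
    het_frac: float = 0.25,
) -> str:
    """Call one site from base counts; returns A/C/G/T, a two-base IUPAC
    heterozygote, or N when coverage is below *min_cov*."""
    if isinstance(site_counts, Mapping):
        counts = np.zeros(4, dtype=np.int64)
        for b, c in site_counts.items():
            counts[_BASE_INDEX[b.upper()]] = c
    else:
        counts = np.asarray(site_counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("negative read counts")
    total = int(counts.sum())
    if total < min_cov:
        return "N"
    order = np.argsort(-counts, kind="stable")  # ties -> A<C<G<T (stable)
    top, second = order[0], order[1]
    if counts[second] / total >= het_frac and counts[second] > 0:
        return PAIR_TO_IUPAC[frozenset((BASES[top], BASES[second]))]
    return BASES[top]


def call_consensus_sequence(
    pileup: PileupCounts, min_cov: int = 8, het_frac: float = 0.25
) -> tuple[str, float]:
    """Site-wise consensus over a pileup; returns (sequence, called_fraction)."""
    counts = pileup.counts
    L = counts.shape[0]
    totals = counts.sum(axis=1)
    # vectorised: sort each row descending with A<C<G<T tie order
    order = np.argsort(-counts, axis=1, kind="stable")
    top = order[:, 0]
    second = order[:, 1]
    top_n = counts[np.arange(L), top]
    second_n = counts[np.arange(L), second]
    with np.errstate(divide="ignore", invalid="ignore"):
        het = (second_n > 0) & (second_n / np.maximum(totals, 1) >= het_frac)
    called = totals >= min_cov
    # lookup table: sorted base-index pair -> two-base IUPAC code
    pair_code = np.empty(16, dtype="<U1")
    for i in range(4):
        for j in range(i + 1, 4):
            pair_code[i * 4 + j] = PAIR_TO_IUPAC[frozenset((BASES[i], BASES[j]))]
    bmin = np.minimum(top, second)
    bmax = np.maximum(top, second)
    base_chars = np.array(list(BASES), dtype="<U1")
    out = np.where(
        ~called, "N", np.where(het, pair_code[bmin * 4 + bmax], base_chars[top])
    )
    seq = "".join(out)
    called_fraction = float(called.mean()) if L else 0.0
    return seq, called_fraction


def flag_low_call_rate(
    called_fractions: Mapping[tuple[str, str], float], floor: float = 0.5
) -> set[tuple[str, str]]:
    """(individual, locus) pairs whose called fraction falls below *floor*.

    Mirrors the study-design practice of dropping undercovered
    individual/locus combinations; the floor is a parameter, not a claim
    about the original criterion.
    """
    return {key for key, frac in called_fractions.items() if frac < floor}


def read_pileup_table(path: str | Path, locus_lengths: Mapping[str, int]) -> list[PileupCounts]:
    """Read a TSV (individual, locus, site, A, C, G, T) into pileups.

    Sites are 0-based; absent sites get zero counts.
    """
    df = pd.read_csv(path, sep="\t")
    pileups: list[PileupCounts] = []
    for (ind, locus), grp in df.groupby(["individual", "locus"], sort=True):
        L = locus_lengths[str(locus)]
        counts = np.zeros((L, 4), dtype=np.int64)
        sites = grp["site"].to_numpy(dtype=int)
        counts[sites] = grp[list(BASES)].to_numpy(dtype=np.int64)
        pileups.append(PileupCounts(str(ind), str(locus), counts))
    return pileups


def write_pileup_table(pileups: Iterable[PileupCounts], path: str | Path) -> None:
    frames = []
    for p in pileups:
        df = pd.DataFrame(p.counts, columns=list(BASES))
        df.insert(0, "site", np.arange(p.length))
        df.insert(0, "locus", p.locus_id)
        df.insert(0, "individual", p.individual)
        frames.append(df[df[list(BASES)].sum(axis=1) > 0])
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
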