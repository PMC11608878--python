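"""Longest four-gamete-compatible block of a phased alignment.

Two biallelic sites at which all four haplotype combinations occur
imply recombination (or recurrent mutation) between them.  To feed a
no-recombination analysis, each locus is trimmed to the longest
contiguous window that contains no such incompatible pair.  Sites with
missing data or more than two alleles carry no four-gamete information
here and are ignored when testing pairs; ties between equally long
windows resolve to the leftmost.  This is window trimming only — no
sequences are dropped to enlarge the retained region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from hzdiv.locus_io import LocusAlignment


@dataclass(frozen=True)
class CompatibleBlock:
    locus_id: str
    start: int  # 0-based half-open
    end: int
    n_segregating_inside: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _informative_sites(mat: np.ndarray) -> np.ndarray:
    """Positions of fully called biallelic columns."""
    n, L = mat.shape
    missing = (mat == "N") | (mat == "-")
    ok = ~missing.any(axis=0)
    sites = []
    for j in np.flatnonzero(ok):
        if len(set(mat[:, j])) == 2:
            sites.append(j)
    return np.array(sites, dtype=int)


def incompatible_pairs(seqs: Sequence[str] | LocusAlignment) -> list[tuple[int, int]]:
    """All site pairs (i < j) exhibiting all four gametes."""
    if isinstance(seqs, LocusAlignment):
        mat = seqs.to_matrix()
    else:
        mat = np.array([list(s.upper()) for s in seqs], dtype="<U1")
    sites = _informative_sites(mat)
    n = mat.shape[0]
    full = (1 << n) - 1
    # bitmask of rows carrying the (lexicographically smaller) allele
    masks = []
    for j in sites:
        col = mat[:, j]
        allele = min(set(col))
        m = 0
        for row in np.flatnonzero(col == allele):
            m |= 1 << int(row)
        masks.append(m)
    pairs = []
    for ai in range(len(sites)):
        a = masks[ai]
        for bi in range(ai + 1, len(sites)):
            b = masks[bi]
            if (a & b) and (a & ~b & full) and (~a & b & full) and (~a & ~b & full):
                pairs.append((int(sites[ai]), int(sites[bi])))
    return pairs


def longest_compatible_block(
    seqs: Sequence[str] | LocusAlignment, locus_id: str | None = None
) -> CompatibleBlock:
    """Longest contiguous window with no incompatible site pair inside.

    Single left-to-right sweep: for each right edge, the leftmost
    admissible start is one past the largest left member of any
    incompatible pair already wholly to the left of the edge.  With no
    segregating sites the whole locus is returned.
    """
    if isinstance(seqs, LocusAlignment):
        mat = seqs.to_matrix()
        lid = seqs.locus_id
    else:
        mat = np.array([list(s.upper()) for s in seqs], dtype="<U1")
        lid = locus_id or ""
    n, L = mat.shape
    sites = _informative_sites(mat)
    pairs = incompatible_pairs([  # reuse matrix path
        "".join(row) for row in mat
    ])
    # pairs keyed by their right member
    by_right: dict[int, list[int]] = {}
    for i, j in pairs:
        by_right.setdefault(j, []).append(i)
    best_len, best_start = 0, 0
    min_start = 0
    for r in range(1, L + 1):
        # a pair (i, j) constrains windows once j < r i.e. j == r-1 enters
        for i in by_right.get(r - 1, ()):
            min_start = max(min_start, i + 1)
        if r - min_start > best_len:
            best_len, best_start = r - min_start, min_start
    inside = int(((sites >= best_start) & (sites < best_start + best_len)).sum())
    return CompatibleBlock(lid, best_start, best_start + best_len, inside)


def trim_to_block(alignment: LocusAlignment, block: CompatibleBlock) -> LocusAlignment:
    """Alignment restricted to the block's site window."""
    return LocusAlignment(
        alignment.locus_id,
        [(lab, seq[block.start : block.end]) for lab, seq in alignment.sequences],
    )
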