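from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from hzdiv.locus_io import LocusAlignment, SampleLabel


def random_haplotypes(
    rng: np.random.Generator,
    n: int,
    length: int,
    missing_rate: float = 0.05,
    gap_rate: float = 0.02,
    n_variable: int | None = None,
) -> list[str]:
    """Random alignment: a shared backbone with variable columns and
    sprinkled missing data."""
    backbone = rng.choice(list("ACGT"), size=length)
    mat = np.tile(backbone, (n, 1))
    if n_variable is None:
        n_variable = max(1, length // 10)
    var_sites = rng.choice(length, size=min(n_variable, length), replace=False)
    for j in var_sites:
        alt = rng.choice([b for b in "ACGT" if b != backbone[j]])
        carriers = rng.random(n) < rng.uniform(0.1, 0.9)
        mat[carriers, j] = alt
    if missing_rate > 0:
        mask = rng.random(mat.shape) < missing_rate
        mat[mask] = "N"
    if gap_rate > 0:
        mask = rng.random(mat.shape) < gap_rate
        mat[mask] = "-"
    return ["".join(row) for row in mat]


def make_alignment(
    seqs: list[str],
    species: list[str] | None = None,
    locus_id: str = "locus1",
) -> LocusAlignment:
    if species is None:
        species = ["sp1"] * len(seqs)
    rows = []
    counts: dict[str, int] = {}
    for sp, seq in zip(species, seqs):
        k = counts.get(sp, 0)
        counts[sp] = k + 1
        rows.append((SampleLabel(f"{sp}_i{k:02d}", sp, "pop1", 1), seq))
    return LocusAlignment(locus_id, rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
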