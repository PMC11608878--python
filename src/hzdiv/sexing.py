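"""Sex inference from X-linked homozygosity, and male X collapsing.

The crickets are X0: males carry a single X, so a male's diploid
consensus at an X-linked locus is homozygous everywhere except for
sequencing error.  An individual screened at enough X loci is called
male when its heterozygous-site count (after an optional pileup-quality
discount) stays at or below a small tolerance, female otherwise.
Confirmed males then have one of their two identical X rows removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from hzdiv.consensus import PileupCounts, call_consensus_base
from hzdiv.locus_io import IUPAC_PAIRS, LocusAlignment, LocusMetadata


@dataclass(frozen=True)
class SexAssignment:
    individual: str
    inferred_sex: str  # male / female / unknown
    het_site_count: int
    loci_screened: int


def _is_het(c: str) -> bool:
    return c in IUPAC_PAIRS


def infer_sex(
    individual: str,
    x_genotypes: Sequence[str],
    min_loci: int = 5,
    max_het_sites: int = 3,
    pileups: Sequence[PileupCounts] | None = None,
    min_cov: int = 8,
    het_frac: float = 0.25,
) -> SexAssignment:
    """Classify one individual from its diploid consensus at X loci.

    Heterozygous sites are counted across all screened loci; a count of
    *max_het_sites* or fewer (default 3, allowing a little sequencing
    error) means male.  Fewer than *min_loci* screened loci means
    unknown.  When *pileups* are supplied (parallel to *x_genotypes*),
    heterozygous sites whose pileup does not itself support a confident
    heterozygote at (min_cov, het_frac) are discounted before counting —
    the mechanical analogue of checking each polymorphism's allele
    quality and frequency by hand.
    """
    if len(x_genotypes) == 0:
        warnings.warn(f"{individual}: no X-linked loci supplied; sex unknown")
        return SexAssignment(individual, "unknown", 0, 0)
    het = 0
    for k, seq in enumerate(x_genotypes):
        for site, c in enumerate(seq):
            if not _is_het(c):
                continue
            if pileups is not None:
                counts = pileups[k].counts[site]
                call = call_consensus_base(counts, min_cov=min_cov, het_frac=het_frac)
                if not _is_het(call):
                    continue  # weakly supported het: discount
            het += 1
    if len(x_genotypes) < min_loci:
        return SexAssignment(individual, "unknown", het, len(x_genotypes))
    sex = "male" if het <= max_het_sites else "female"
    return SexAssignment(individual, sex, het, len(x_genotypes))


def select_screening_loci(
    called_fraction_by_locus: Mapping[str, Mapping[str, float]],
    x_locus_ids: Iterable[str],
    n: int = 5,
) -> list[str]:
    """The *n* X loci with the highest mean called fraction.

    ``called_fraction_by_locus[locus][individual]`` holds per-individual
    called fractions.  The study screened its five highest-coverage X
    loci; mean called fraction is the coverage proxy available here.
    """
    def mean_frac(lid: str) -> float:
        vals = list(called_fraction_by_locus.get(lid, {}).values())
        return sum(vals) / len(vals) if vals else 0.0

    ranked = sorted(x_locus_ids, key=lambda lid: (-mean_frac(lid), lid))
    return ranked[:n]


def collapse_male_x(
    alignment: LocusAlignment,
    sex_assignments: Mapping[str, str],
    metadata: LocusMetadata,
) -> LocusAlignment:
    """Drop copy 2 for every male at an X-linked locus.

    Autosomal (and unknown-linkage) alignments are returned unchanged.
    A male whose two X rows differ at called sites keeps copy 1 with a
    warning; for an X0 male the two rows should be identical reads.
    """
    if metadata.linkage != "X":
        return alignment
    keep: list[int] = []
    by_ind: dict[str, dict[int, str]] = {}
    for i, (lab, seq) in enumerate(alignment.sequences):
        by_ind.setdefault(lab.individual, {})[lab.copy_index] = seq
    for i, (lab, seq) in enumerate(alignment.sequences):
        if sex_assignments.get(lab.individual) == "male":
            if lab.copy_index != 1:
                copies = by_ind[lab.individual]
                if 1 in copies and 2 in copies:
                    diff = sum(
                        a != b
                        for a, b in zip(copies[1], copies[2])
                        if a not in "N-" and b not in "N-"
                    )
                    if diff:
                        warnings.warn(
                            f"locus {alignment.locus_id}: male {lab.individual} has "
                            f"{diff} discordant called sites between X copies; "
                            "keeping copy 1"
                        )
                continue
        keep.append(i)
    return alignment.subset(keep)


def write_sex_table(assignments: Iterable[SexAssignment], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "individual": a.individual,
                "inferred_sex": a.inferred_sex,
                "het_site_count": a.het_site_count,
                "loci_screened": a.loci_screened,
            }
            for a in assignments
        ]
    ).to_csv(path, sep="\t", index=False)


def apply_known_sex_overrides(
    assignments: Sequence[SexAssignment], sample_table: pd.DataFrame
) -> list[SexAssignment]:
    """Known sexes from the sample table override inference."""
    out = []
    for a in assignments:
        known = "unknown"
        if a.individual in sample_table.index:
            known = str(sample_table.loc[a.individual].get("sex", "unknown"))
        if known in ("male", "female"):
            out.append(SexAssignment(a.individual, known, a.het_site_count, a.loci_screened))
        else:
            out.append(a)
    return out
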