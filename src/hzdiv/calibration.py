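"""Outgroup-calibrated divergence times and per-locus mutation rates.

The chain is D = 2*mu*t applied twice.  First the mitochondrial
divergence D between the ingroup and each outgroup, at the standard
arthropod mtDNA rate of 0.0115 substitutions/site/My, dates the
outgroup splits (t = D / 2mu).  Then each nuclear locus's divergence to
the same outgroup, with that split time, yields a per-locus nuclear
rate mu = D_locus / 2t.  When both outgroups are available the two
per-locus rates are averaged; loci without any outgroup get no rate.
Generation time is one year (univoltine crickets overwintering as
diapause eggs), so rates per year and per generation coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from hzdiv.locus_io import BASES, PAIR_TO_IUPAC

#: standard arthropod mtDNA clock, substitutions/site/My (pairwise)
DEFAULT_MT_RATE_PER_MY = 0.0115
#: mtDNA-dated splits from the ingroup, in years
DEFAULT_OUTGROUP_SPLIT_YEARS = {
    "G_bimaculatus": 3.2e6,
    "G_rubens": 2.7e6,
}


@dataclass
class CalibrationResult:
    locus_id: str
    d_outgroup: dict[str, float]       # per-site divergence per outgroup
    t_outgroup: dict[str, float]       # split time per outgroup (years)
    mu_locus: float | None             # subs/site/year, mean over outgroups
    outgroups_used: int
    implausible_zero: bool = False     # D = 0 gives mu = 0


def species_consensus(seqs: Sequence[str]) -> str:
    """Site-wise majority base across sequences.

    N and gaps are ignored at each site; a site with no called base
    becomes N.  A two-way tie is reported as the two-base IUPAC code
    (and later excluded from divergence sites); wider ties become N.
    """
    if not seqs:
        raise ValueError("no sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("unequal sequence lengths")
    out = []
    for col in zip(*(s.upper() for s in seqs)):
        counts = {b: 0 for b in BASES}
        for c in col:
            if c in counts:
                counts[c] += 1
        mx = max(counts.values())
        if mx == 0:
            out.append("N")
            continue
        top = [b for b, c in counts.items() if c == mx]
        if len(top) == 1:
            out.append(top[0])
        elif len(top) == 2:
            out.append(PAIR_TO_IUPAC[frozenset(top)])
        else:
            out.append("N")
    return "".join(out)


def consensus_divergence(cons_a: str, cons_b: str, model: str = "p") -> float:
    """Per-site divergence between two consensus sequences.

    Only sites where both consensuses carry an unambiguous base
    (A/C/G/T) are compared.  ``model='p'`` gives the raw proportion of
    differing sites; ``model='JC'`` applies the Jukes-Cantor correction
    -(3/4) ln(1 - 4p/3).  NaN when no comparable sites exist.
    """
    if len(cons_a) != len(cons_b):
        raise ValueError("consensus lengths differ")
    comparable = 0
    diff = 0
    bases = set(BASES)
    for a, b in zip(cons_a.upper(), cons_b.upper()):
        if a in bases and b in bases:
            comparable += 1
            if a != b:
                diff += 1
    if comparable == 0:
        return float("nan")
    p = diff / comparable
    if model == "p":
        return p
    if model == "JC":
        if p >= 0.75:
            raise ValueError(f"p-distance {p} out of Jukes-Cantor range")
        return -0.75 * math.log1p(-4 * p / 3)
    raise ValueError(f"unknown model {model!r}")


def divergence_time(d: float, mu_per_site_per_my: float = DEFAULT_MT_RATE_PER_MY) -> float:
    """Invert D = 2*mu*t for the split time, in years."""
    if d < 0:
        raise ValueError("divergence must be non-negative")
    if mu_per_site_per_my <= 0:
        raise ValueError("mutation rate must be positive")
    return d / (2 * mu_per_site_per_my) * 1e6


def locus_mutation_rate(d_locus: float, t_years: float) -> float:
    """mu = D / (2t), substitutions/site/year."""
    if t_years <= 0:
        raise ValueError("divergence time must be positive")
    if d_locus < 0:
        raise ValueError("divergence must be non-negative")
    return d_locus / (2 * t_years)


def calibrate_locus(
    locus_id: str,
    ingroup_consensus: str,
    outgroup_seqs: Mapping[str, Sequence[str]],
    split_times_years: Mapping[str, float] = DEFAULT_OUTGROUP_SPLIT_YEARS,
    model: str = "p",
) -> CalibrationResult:
    """Per-locus mutation rate from divergence to each available outgroup."""
    d_out: dict[str, float] = {}
    t_out: dict[str, float] = {}
    mus: list[float] = []
    for og, seqs in outgroup_seqs.items():
        if not seqs:
            continue
        if og not in split_times_years:
            raise ValueError(f"no split time for outgroup {og!r}")
        cons = species_consensus(list(seqs))
        d = consensus_divergence(ingroup_consensus, cons, model=model)
        if math.isnan(d):
            continue
        t = split_times_years[og]
        d_out[og] = d
        t_out[og] = t
        mus.append(locus_mutation_rate(d, t))
    mu = float(np.mean(mus)) if mus else None
    return CalibrationResult(
        locus_id=locus_id,
        d_outgroup=d_out,
        t_outgroup=t_out,
        mu_locus=mu,
        outgroups_used=len(d_out),
        implausible_zero=(mu == 0.0 if mu is not None else False),
    )


def write_calibration_table(results: Iterable[CalibrationResult], path: str | Path) -> None:
    rows = []
    for r in results:
        row: dict[str, object] = {
            "locus_id": r.locus_id,
            "outgroups_used": r.outgroups_used,
            "mu_mean": "" if r.mu_locus is None else r.mu_locus,
        }
        for og in sorted(r.d_outgroup):
            row[f"D_{og}"] = r.d_outgroup[og]
            row[f"mu_{og}"] = locus_mutation_rate(r.d_outgroup[og], r.t_outgroup[og])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
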