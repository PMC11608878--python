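"""Per-locus FASTA alignments, sample labels and metadata tables.

One FASTA file per locus, every record the same length.  Headers follow
the canonical dialect ``individual|species|population|copy`` or are
resolved through a sample table.  Diploid consensus sequences use
two-base IUPAC codes for heterozygous sites; :func:`expand_to_haplotypes`
splits them into a haplotype pair with a seeded random phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# Two-base IUPAC ambiguity codes and their (sorted) base pairs.
IUPAC_PAIRS: dict[str, tuple[str, str]] = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}
PAIR_TO_IUPAC: dict[frozenset[str], str] = {
    frozenset(v): k for k, v in IUPAC_PAIRS.items()
}
# Three-base codes; masked to N because they signal poor base quality.
TRIPLE_CODES = set("DHVB")
BASES = ("A", "C", "G", "T")
HAPLOID_ALPHABET = set("ACGTN-")
IUPAC_ALPHABET = HAPLOID_ALPHABET | set(IUPAC_PAIRS) | TRIPLE_CODES


@dataclass(frozen=True)
class SampleLabel:
    """Identity of one sequence row: who it is and which copy."""

    individual: str
    species: str
    population: str = ""
    copy_index: int = 1
    sex: str = "unknown"  # male / female / unknown

    def __post_init__(self) -> None:
        if self.copy_index not in (1, 2):
            raise ValueError(f"copy_index must be 1 or 2, got {self.copy_index}")
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"bad sex {self.sex!r}")

    def header(self) -> str:
        return f"{self.individual}|{self.species}|{self.population}|{self.copy_index}"


@dataclass
class LocusAlignment:
    """Equal-length sequences for one locus, with per-row labels."""

    locus_id: str
    sequences: list[tuple[SampleLabel, str]]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"locus {self.locus_id}: empty alignment")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(
                f"locus {self.locus_id}: ragged alignment (lengths {sorted(lengths)})"
            )
        seen: set[tuple[str, int]] = set()
        for lab, _ in self.sequences:
            key = (lab.individual, lab.copy_index)
            if key in seen:
                raise ValueError(
                    f"locus {self.locus_id}: duplicate (individual, copy) {key}"
                )
            seen.add(key)

    @property
    def length(self) -> int:
        return len(self.sequences[0][1])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def labels(self) -> list[SampleLabel]:
        return [lab for lab, _ in self.sequences]

    def seqs(self) -> list[str]:
        return [s for _, s in self.sequences]

    def by_species(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for lab, s in self.sequences:
            out.setdefault(lab.species, []).append(s)
        return out

    def subset(self, keep: Iterable[int]) -> "LocusAlignment":
        idx = list(keep)
        return LocusAlignment(self.locus_id, [self.sequences[i] for i in idx])

    def to_matrix(self) -> np.ndarray:
        """(n, L) array of single characters (dtype '<U1')."""
        return np.array([list(s) for _, s in self.sequences], dtype="<U1")


@dataclass(frozen=True)
class LocusMetadata:
    """Linkage and introgression class for one locus."""

    locus_id: str
    linkage: str = "unknown"  # autosomal / X / unknown
    introgression_class: str = "unclassified"
    linkage_group: str = ""
    cm: float = float("nan")

    def __post_init__(self) -> None:
        if self.linkage not in ("autosomal", "X", "unknown"):
            raise ValueError(f"bad linkage {self.linkage!r}")
        if self.introgression_class not in (
            "introgressing", "non_introgressing", "unclassified",
        ):
            raise ValueError(f"bad class {self.introgression_class!r}")


def _validate_alphabet(seq: str, allowed: set[str], context: str) -> None:
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"{context}: non-IUPAC characters {sorted(bad)}")


def mask_low_quality_ambiguity(seq: str) -> str:
    """Mask poor-quality triple-ambiguity codes D, H, V, B to N.

    Two-base codes (heterozygous diploid calls) and A/C/G/T/N/- pass
    through unchanged.  Any character outside the IUPAC alphabet raises.
    """
    seq = seq.upper()
    _validate_alphabet(seq, IUPAC_ALPHABET, "mask_low_quality_ambiguity")
    return seq.translate(str.maketrans("DHVB", "NNNN"))


def expand_to_haplotypes(diploid_seq: str, seed: int) -> tuple[str, str]:
    """Split a diploid consensus into two haplotypes with random phase.

    Every two-base IUPAC site contributes its two bases, one to each
    haplotype; which haplotype gets which base is decided by a seeded
    RNG, so the per-site allele multiset is always conserved and all
    frequency-based statistics are invariant to the seed.  Triple codes
    must have been masked first.
    """
    diploid_seq = diploid_seq.upper()
    bad = set(diploid_seq) & TRIPLE_CODES
    if bad:
        raise ValueError(
            f"triple-ambiguity codes {sorted(bad)} present; mask to N first"
        )
    _validate_alphabet(diploid_seq, HAPLOID_ALPHABET | set(IUPAC_PAIRS),
                       "expand_to_haplotypes")
    rng = np.random.default_rng(seed)
    h1 = list(diploid_seq)
    h2 = list(diploid_seq)
    for i, c in enumerate(diploid_seq):
        pair = IUPAC_PAIRS.get(c)
        if pair is not None:
            a, b = pair
            if rng.integers(2):
                a, b = b, a
            h1[i], h2[i] = a, b
    return "".join(h1), "".join(h2)


def collapse_to_diploid(hap1: str, hap2: str) -> str:
    """Inverse of expansion: merge a haplotype pair into IUPAC consensus."""
    if len(hap1) != len(hap2):
        raise ValueError("haplotype lengths differ")
    out = []
    for a, b in zip(hap1, hap2):
        if a == b:
            out.append(a)
        elif "N" in (a, b) or "-" in (a, b):
            out.append("N")
        else:
            out.append(PAIR_TO_IUPAC[frozenset((a, b))])
    return "".join(out)


def _parse_header(header: str, sample_table: pd.DataFrame | None) -> SampleLabel:
    first = header.split()[0]
    parts = first.split("|")
    if len(parts) == 4:
        ind, species, pop, copy = parts
        sex = "unknown"
        if sample_table is not None and ind in sample_table.index:
            sex = str(sample_table.loc[ind].get("sex", "unknown") or "unknown")
        return SampleLabel(ind, species, pop, int(copy), sex)
    if sample_table is not None:
        # arbitrary header: strip a trailing _1/_2 copy suffix if present
        copy = 1
        ind = first
        if first.endswith(("_1", "_2")):
            ind, copy = first[:-2], int(first[-1])
        if ind in sample_table.index:
            row = sample_table.loc[ind]
            return SampleLabel(
                ind,
                str(row["species"]),
                str(row.get("population", "") or ""),
                copy,
                str(row.get("sex", "unknown") or "unknown"),
            )
    raise ValueError(f"unresolvable FASTA header {header!r}")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns individual, species, population, sex (optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "individual" not in df.columns or "species" not in df.columns:
        raise ValueError("sample table needs 'individual' and 'species' columns")
    if "sex" in df.columns:
        df["sex"] = df["sex"].replace("", "unknown")
    else:
        df["sex"] = "unknown"
    return df.set_index("individual", drop=False)


def read_locus_metadata(path: str | Path) -> dict[str, LocusMetadata]:
    """TSV with columns locus_id, linkage, class, [linkage_group, cM]."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, LocusMetadata] = {}
    for _, row in df.iterrows():
        lid = str(row["locus_id"])
        if lid in out:
            raise ValueError(f"duplicate locus_id {lid} in metadata")
        out[lid] = LocusMetadata(
            lid,
            row.get("linkage", "unknown") or "unknown",
            row.get("class", "unclassified") or "unclassified",
            row.get("linkage_group", ""),
            float(row["cM"]) if row.get("cM", "") else float("nan"),
        )
    return out


def write_locus_metadata(metadata: Iterable[LocusMetadata], path: str | Path) -> None:
    rows = [
        {
            "locus_id": m.locus_id,
            "linkage": m.linkage,
            "class": m.introgression_class,
            "linkage_group": m.linkage_group,
            "cM": "" if np.isnan(m.cm) else m.cm,
        }
        for m in metadata
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_locus_fasta(
    path: str | Path,
    sample_table: pd.DataFrame | None = None,
    locus_id: str | None = None,
) -> LocusAlignment:
    """Read one per-locus FASTA into a validated alignment.

    Raises on ragged records (naming the offender) and on headers that
    resolve neither through the canonical ``ind|species|pop|copy``
    dialect nor through *sample_table*.
    """
    path = Path(path)
    if locus_id is None:
        locus_id = path.stem
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    length = len(records[0].seq)
    sequences: list[tuple[SampleLabel, str]] = []
    for rec in records:
        if len(rec.seq) != length:
            raise ValueError(
                f"{path}: ragged alignment — record {rec.id!r} has length "
                f"{len(rec.seq)}, expected {length}"
            )
        label = _parse_header(rec.description, sample_table)
        sequences.append((label, str(rec.seq).upper()))
    return LocusAlignment(locus_id, sequences)


def write_locus_fasta(
    alignment: LocusAlignment, path: str | Path, line_width: int = 70
) -> None:
    records = [
        SeqRecord(Seq(seq), id=lab.header(), description="")
        for lab, seq in alignment.sequences
    ]
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            s = str(rec.seq)
            for i in range(0, len(s), line_width):
                fh.write(s[i : i + line_width] + "\n")


def expand_alignment(
    alignment: LocusAlignment, seed: int, haploid_individuals: set[str] | None = None
) -> LocusAlignment:
    """Expand every diploid consensus row into two haplotype rows.

    Rows for *haploid_individuals* (e.g. males at an X locus) are kept as
    a single copy; any residual heterozygous site there is masked to N
    with a warning, since a hemizygote has one allele.
    """
    haploid_individuals = haploid_individuals or set()
    rng = np.random.default_rng(seed)
    out: list[tuple[SampleLabel, str]] = []
    for lab, seq in alignment.sequences:
        if lab.individual in haploid_individuals:
            het = sum(c in IUPAC_PAIRS for c in seq)
            if het:
                warnings.warn(
                    f"locus {alignment.locus_id}: hemizygous {lab.individual} "
                    f"has {het} heterozygous sites; masked to N"
                )
                seq = "".join("N" if c in IUPAC_PAIRS else c for c in seq)
            out.append((replace(lab, copy_index=1), seq))
        else:
            child = int(rng.integers(0, 2**31 - 1))
            h1, h2 = expand_to_haplotypes(seq, child)
            out.append((replace(lab, copy_index=1), h1))
            out.append((replace(lab, copy_index=2), h2))
    return LocusAlignment(alignment.locus_id, out)
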