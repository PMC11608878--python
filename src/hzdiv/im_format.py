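"""IM/IMa3-style locus-block text files.

Layout written (and parsed back, for round-trip testing)::

    <title line>
    # comment lines
    2
    <pop0 name> <pop1 name>
    (0,1):2
    <number of loci>
    <locus name> <n0> <n1> <length> I <inheritance scalar> [<mu per year>]
    <10-char sample name><sequence>
    ...

The mutation model token is always ``I`` (infinite sites); the
inheritance scalar is 1.0 for autosomal loci and 0.75 for X-linked
(males are hemizygous, so the X has three-quarters the copy number).
Loci with no outgroup-calibrated rate omit the mutation-rate field.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from hzdiv.locus_io import LocusAlignment, LocusMetadata

INHERITANCE_SCALARS = {"autosomal": 1.0, "X": 0.75}
NAME_WIDTH = 10


@dataclass
class ImLocus:
    name: str
    n_per_pop: tuple[int, int]
    length: int
    model: str
    inheritance: float
    mu_per_year: float | None
    sequences: list[tuple[str, str]]  # (sample name, sequence)


def _scalar_for(metadata: LocusMetadata, default: float | None) -> float:
    try:
        return INHERITANCE_SCALARS[metadata.linkage]
    except KeyError:
        if default is None:
            raise ValueError(
                f"locus {metadata.locus_id}: unknown linkage and no default scalar"
            )
        return default


def write_im_input(
    alignments: Sequence[LocusAlignment],
    metadata: Mapping[str, LocusMetadata],
    species: tuple[str, str],
    path: str | Path,
    mutation_rates: Mapping[str, float] | None = None,
    title: str = "hzdiv IM input",
    default_scalar: float | None = None,
) -> None:
    """Write trimmed per-locus alignments as an IM-format file.

    *alignments* should already be haplotype rows trimmed to their
    non-recombining block, with males collapsed at X loci.  Rows are
    ordered population 0 then population 1 as IM expects.
    """
    mutation_rates = mutation_rates or {}
    lines = [title, "# written by hzdiv", "2", f"{species[0]} {species[1]}",
             "(0,1):2", str(len(alignments))]
    for aln in alignments:
        meta = metadata[aln.locus_id]
        scalar = _scalar_for(meta, default_scalar)
        rows0 = [(lab, s) for lab, s in aln.sequences if lab.species == species[0]]
        rows1 = [(lab, s) for lab, s in aln.sequences if lab.species == species[1]]
        if len(rows0) + len(rows1) != len(aln.sequences):
            raise ValueError(
                f"locus {aln.locus_id}: sequences from species outside {species}"
            )
        mu = mutation_rates.get(aln.locus_id)
        header = (
            f"{aln.locus_id} {len(rows0)} {len(rows1)} {aln.length} I {scalar:g}"
        )
        if mu is not None:
            header += f" {mu:.6g}"
        lines.append(header)
        for lab, seq in rows0 + rows1:
            name = f"{lab.individual}_{lab.copy_index}"[:NAME_WIDTH]
            lines.append(f"{name:<{NAME_WIDTH}}{seq}")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_im_input(path: str | Path) -> dict:
    """Parse a file written by :func:`write_im_input` (round-trip check)."""
    raw = Path(path).read_text().splitlines()
    lines = [ln for ln in raw if not ln.startswith("#")]
    title = lines[0]
    npops = int(lines[1])
    pops = lines[2].split()
    tree = lines[3]
    nloci = int(lines[4])
    loci: list[ImLocus] = []
    k = 5
    for _ in range(nloci):
        fields = lines[k].split()
        name, n0, n1, length, model = (
            fields[0], int(fields[1]), int(fields[2]), int(fields[3]), fields[4]
        )
        inheritance = float(fields[5])
        mu = float(fields[6]) if len(fields) > 6 else None
        k += 1
        seqs = []
        for _ in range(n0 + n1):
            ln = lines[k]
            seqs.append((ln[:NAME_WIDTH].strip(), ln[NAME_WIDTH:].strip()))
            k += 1
        loci.append(ImLocus(name, (n0, n1), length, model, inheritance, mu, seqs))
    return {
        "title": title,
        "n_populations": npops,
        "populations": pops,
        "tree": tree,
        "loci": loci,
    }
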