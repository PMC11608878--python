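"""Two-species structured-coalescent simulator with infinite-sites mutation.

Backwards in time, sampled lineages coalesce within their species' deme
at rate k(k-1)/2 / (2 Ne_eff), migrate between demes at per-lineage
rate m (backwards), and merge into a single ancestral deme at the split
time; waiting times are exponential (continuous time), so closed-form
coalescent expectations hold exactly and can anchor the tests.
Mutations fall on branches as a Poisson process and each takes a fresh
site (infinite sites), mapped uniformly without replacement onto the
finite locus; if a locus draws more mutations than sites, placement
falls back to sampling with replacement and a multi-hit warning.

X linkage is handled at two points: X loci use 3/4 of the nominal
diploid Ne, and sampled males contribute a single lineage (the crickets
are X0).  A sweep is modelled as a local Ne multiplier on the affected
loci — the diversity-reduction signature with one parameter, without an
explicit sweep trajectory.

One master seed drives everything: a ``numpy.random.SeedSequence`` is
spawned once per locus in locus order, so any locus can be regenerated
independently and datasets are byte-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from hzdiv.consensus import PileupCounts
from hzdiv.locus_io import (
    BASES,
    LocusAlignment,
    LocusMetadata,
    SampleLabel,
    collapse_to_diploid,
    write_locus_fasta,
    write_locus_metadata,
)

X_NE_FACTOR = 0.75


@dataclass(frozen=True)
class IndividualSpec:
    individual: str
    species: str
    population: str
    sex: str  # male / female


@dataclass
class SimConfig:
    """Demography and sampling for one locus."""

    ne1: float = 125_000.0
    ne2: float = 125_000.0
    ne_anc: float = 125_000.0
    t_split: float = 800_000.0      # generations
    m12: float = 0.0                # backwards per-lineage per-generation
    m21: float = 0.0
    mu: float = 4.05e-9             # substitutions/site/generation
    length: int = 5000
    linkage: str = "autosomal"      # or "X"
    ne_multiplier: float = 1.0      # local sweep multiplier on daughter demes
    samples: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"speciesA": (6, 6), "speciesB": (6, 6)}
    )  # species -> (n_males, n_females)
    n_populations: int = 4          # label-only split within each species
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.ne1, self.ne2, self.ne_anc) <= 0:
            raise ValueError("effective sizes must be positive")
        if not (0 <= self.m12 < 1 and 0 <= self.m21 < 1):
            raise ValueError("migration probabilities must be in [0, 1)")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.linkage not in ("autosomal", "X"):
            raise ValueError(f"bad linkage {self.linkage!r}")

    def individuals(self) -> list[IndividualSpec]:
        out = []
        for sp in sorted(self.samples):
            n_m, n_f = self.samples[sp]
            sexes = ["male"] * n_m + ["female"] * n_f
            for i, sex in enumerate(sexes):
                pop = f"pop{i % self.n_populations + 1}"
                out.append(IndividualSpec(f"{sp}_i{i:03d}", sp, pop, sex))
        return out


@dataclass
class GenealogySummary:
    tmrca: float
    total_branch_length: float
    n_mutations: int
    n_migrations: int
    multi_hit: bool


def _effective_sizes(cfg: SimConfig) -> tuple[float, float, float]:
    f = X_NE_FACTOR if cfg.linkage == "X" else 1.0
    return (
        cfg.ne1 * f * cfg.ne_multiplier,
        cfg.ne2 * f * cfg.ne_multiplier,
        cfg.ne_anc * f,  # sweep acts post-split; ancestral deme unscaled
    )


def _simulate_tree(
    cfg: SimConfig, rng: np.random.Generator, leaf_demes: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Coalescent tree over the leaves; returns (parent, time, root, n_mig)."""
    n = len(leaf_demes)
    max_nodes = 2 * n - 1
    parent = np.full(max_nodes, -1, dtype=int)
    time = np.zeros(max_nodes)
    active: list[int] = list(range(n))
    deme = {i: d for i, d in enumerate(leaf_demes)}
    next_node = n
    t = 0.0
    ne1, ne2, ne_anc = _effective_sizes(cfg)
    n_mig = 0
    merged = False
    while len(active) > 1:
        if not merged:
            k1 = sum(1 for i in active if deme[i] == 0)
            k2 = len(active) - k1
            rate_c1 = k1 * (k1 - 1) / 2 / (2 * ne1)
            rate_c2 = k2 * (k2 - 1) / 2 / (2 * ne2)
            rate_m12 = k1 * cfg.m12
            rate_m21 = k2 * cfg.m21
            total = rate_c1 + rate_c2 + rate_m12 + rate_m21
            wait = rng.exponential(1 / total) if total > 0 else np.inf
            if t + wait >= cfg.t_split:
                t = cfg.t_split
                merged = True  # demes fuse into the ancestral population
                continue
            t += wait
            u = rng.uniform(0, total)
            if u < rate_c1 or u < rate_c1 + rate_c2:
                which = 0 if u < rate_c1 else 1
                pool = [i for i in active if deme[i] == which]
                a, b = rng.choice(len(pool), size=2, replace=False)
                ca, cb = pool[a], pool[b]
                node = next_node
                next_node += 1
                parent[ca] = parent[cb] = node
                time[node] = t
                deme[node] = which
                active.remove(ca)
                active.remove(cb)
                active.append(node)
            elif u < rate_c1 + rate_c2 + rate_m12:
                pool = [i for i in active if deme[i] == 0]
                deme[pool[int(rng.integers(len(pool)))]] = 1
                n_mig += 1
            else:
                pool = [i for i in active if deme[i] == 1]
                deme[pool[int(rng.integers(len(pool)))]] = 0
                n_mig += 1
        else:
            k = len(active)
            rate = k * (k - 1) / 2 / (2 * ne_anc)
            t += rng.exponential(1 / rate)
            a, b = rng.choice(k, size=2, replace=False)
            ca, cb = active[a], active[b]
            node = next_node
            next_node += 1
            parent[ca] = parent[cb] = node
            time[node] = t
            active.remove(ca)
            active.remove(cb)
            active.append(node)
    root = active[0]
    return parent[:next_node], time[:next_node], root, n_mig


def _leaf_sets(parent: np.ndarray, n_leaves: int) -> list[set[int]]:
    sets: list[set[int]] = [set() for _ in range(parent.size)]
    for leaf in range(n_leaves):
        sets[leaf].add(leaf)
        node = leaf
        while parent[node] != -1:
            node = parent[node]
            sets[node].add(leaf)
    return sets


def simulate_locus(
    cfg: SimConfig,
) -> tuple[LocusAlignment, GenealogySummary]:
    """One locus under the two-deme coalescent; returns haplotypes + truth.

    Haplotype rows are labelled with individual/species/population/copy
    and carry the true sex; at X loci each male contributes one row.
    Fixed seed gives a byte-identical alignment.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    inds = cfg.individuals()
    species = sorted(cfg.samples)
    leaf_labels: list[SampleLabel] = []
    leaf_demes: list[int] = []
    for ind in inds:
        copies = 1 if (cfg.linkage == "X" and ind.sex == "male") else 2
        for c in range(1, copies + 1):
            leaf_labels.append(
                SampleLabel(ind.individual, ind.species, ind.population, c, ind.sex)
            )
            leaf_demes.append(species.index(ind.species))
    parent, time, root, n_mig = _simulate_tree(cfg, rng, leaf_demes)
    n_leaves = len(leaf_labels)
    branch = np.array([
        time[parent[v]] - time[v] if parent[v] != -1 else 0.0
        for v in range(parent.size)
    ])
    total_len = float(branch.sum())
    n_mut = int(rng.poisson(cfg.mu * cfg.length * total_len))
    multi_hit = n_mut > cfg.length
    if multi_hit:
        warnings.warn(
            f"locus seed {cfg.seed}: {n_mut} mutations exceed {cfg.length} sites; "
            "multi-hit placement with replacement"
        )
        sites = rng.integers(0, cfg.length, size=n_mut)
    else:
        sites = rng.choice(cfg.length, size=n_mut, replace=False)
    ancestral = rng.choice(list(BASES), size=cfg.length)
    seqs = np.tile(ancestral, (n_leaves, 1))
    if n_mut:
        probs = branch / total_len
        mut_nodes = rng.choice(parent.size, size=n_mut, p=probs)
        sets = _leaf_sets(parent, n_leaves)
        for site, node in zip(sites, mut_nodes):
            current = ancestral[site]
            derived = rng.choice([b for b in BASES if b != current])
            carriers = list(sets[node])
            seqs[carriers, site] = derived
    alignment = LocusAlignment(
        f"sim{cfg.seed}",
        [(lab, "".join(row)) for lab, row in zip(leaf_labels, seqs)],
    )
    summary = GenealogySummary(
        tmrca=float(time[root]),
        total_branch_length=total_len,
        n_mutations=n_mut,
        n_migrations=n_mig,
        multi_hit=multi_hit,
    )
    return alignment, summary


def simulate_recombinant_locus(
    cfg: SimConfig, breakpoint: int | None = None
) -> tuple[LocusAlignment, GenealogySummary, GenealogySummary]:
    """Concatenate two independent gene trees at *breakpoint*.

    A minimal recombination model for exercising the four-gamete
    trimmer: sites left of the breakpoint evolve on one genealogy,
    sites right of it on another.
    """
    if breakpoint is None:
        breakpoint = cfg.length // 2
    if not 0 < breakpoint < cfg.length:
        raise ValueError("breakpoint must be inside the locus")
    ss = np.random.SeedSequence(cfg.seed)
    s_left, s_right = ss.spawn(2)
    left_cfg = replace(cfg, length=breakpoint, seed=int(s_left.generate_state(1)[0] % 2**31))
    right_cfg = replace(cfg, length=cfg.length - breakpoint,
                        seed=int(s_right.generate_state(1)[0] % 2**31))
    left, sum_l = simulate_locus(left_cfg)
    right, sum_r = simulate_locus(right_cfg)
    merged = LocusAlignment(
        f"sim{cfg.seed}rec",
        [
            (lab, sl + sr)
            for (lab, sl), (_, sr) in zip(left.sequences, right.sequences)
        ],
    )
    return merged, sum_l, sum_r


@dataclass
class ScenarioSpec:
    """A multi-locus study design over (linkage x category) cells.

    ``n_loci`` maps (linkage, category) to a locus count; categories are
    ``background`` (introgressing-like: gene flow) and ``barrier``
    (non-introgressing-like).  ``category_effects`` overrides migration
    and/or applies a local Ne multiplier per category.
    """

    base: SimConfig = field(default_factory=SimConfig)
    n_loci: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("autosomal", "background"): 8,
            ("autosomal", "barrier"): 13,
            ("X", "background"): 5,
            ("X", "barrier"): 22,
        }
    )
    category_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for (linkage, cat), n in self.n_loci.items():
            if linkage not in ("autosomal", "X") or cat not in ("background", "barrier"):
                raise ValueError(f"bad cell {(linkage, cat)}")
            if n < 1:
                raise ValueError("each used cell needs >= 1 locus")


CATEGORY_TO_CLASS = {"background": "introgressing", "barrier": "non_introgressing"}


@dataclass
class SimulatedDataset:
    alignments: list[LocusAlignment]
    metadata: list[LocusMetadata]
    sample_table: pd.DataFrame
    truth: pd.DataFrame  # per-locus truth: category, m, ne_multiplier

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta_dir = outdir / "loci"
        fasta_dir.mkdir(exist_ok=True)
        for aln in self.alignments:
            write_locus_fasta(aln, fasta_dir / f"{aln.locus_id}.fasta")
        meta_path = outdir / "locus_metadata.tsv"
        write_locus_metadata(self.metadata, meta_path)
        sample_path = outdir / "samples.tsv"
        self.sample_table.to_csv(sample_path, sep="\t", index=False)
        truth_path = outdir / "truth.tsv"
        self.truth.to_csv(truth_path, sep="\t", index=False)
        return {
            "fasta_dir": fasta_dir,
            "locus_metadata": meta_path,
            "sample_table": sample_path,
            "truth": truth_path,
        }


def simulate_dataset(spec: ScenarioSpec) -> SimulatedDataset:
    """Simulate every locus of a scenario with per-locus spawned seeds."""
    ss = np.random.SeedSequence(spec.seed)
    cells = sorted(spec.n_loci.items())
    total = sum(n for _, n in cells)
    children = ss.spawn(total)
    alignments: list[LocusAlignment] = []
    metadata: list[LocusMetadata] = []
    truth_rows = []
    k = 0
    for (linkage, category), n in cells:
        eff = spec.category_effects.get(category, {})
        for _ in range(n):
            child_seed = int(children[k].generate_state(1)[0] % 2**31)
            cfg = replace(
                spec.base,
                linkage=linkage,
                m12=eff.get("m12", eff.get("m", spec.base.m12)),
                m21=eff.get("m21", eff.get("m", spec.base.m21)),
                ne_multiplier=eff.get("ne_multiplier", spec.base.ne_multiplier),
                seed=child_seed,
            )
            locus_id = f"L{k:03d}_{linkage}_{category}"
            aln, summary = simulate_locus(cfg)
            aln.locus_id = locus_id
            alignments.append(aln)
            metadata.append(
                LocusMetadata(locus_id, linkage, CATEGORY_TO_CLASS[category])
            )
            truth_rows.append({
                "locus_id": locus_id,
                "linkage": linkage,
                "category": category,
                "m12": cfg.m12,
                "m21": cfg.m21,
                "ne_multiplier": cfg.ne_multiplier,
                "seed": child_seed,
                "tmrca": summary.tmrca,
                "n_mutations": summary.n_mutations,
            })
            k += 1
    inds = spec.base.individuals()
    sample_table = pd.DataFrame(
        [
            {
                "individual": i.individual,
                "species": i.species,
                "population": i.population,
                "sex": i.sex,
            }
            for i in inds
        ]
    )
    return SimulatedDataset(alignments, metadata, sample_table, pd.DataFrame(truth_rows))


def simulate_pileup(
    haplotypes: tuple[str, str],
    mean_coverage: float,
    error_rate: float,
    seed: int,
    individual: str = "",
    locus_id: str = "",
) -> PileupCounts:
    """Per-site read counts from a haplotype pair.

    Reads per site are Poisson(mean_coverage), drawn from the two
    haplotypes with equal probability; each read's base is replaced by a
    uniformly chosen different base with probability *error_rate*.  For
    a hemizygous male X, pass the same haplotype twice.
    """
    h1, h2 = haplotypes
    if len(h1) != len(h2):
        raise ValueError("haplotype lengths differ")
    if mean_coverage < 0 or not (0 <= error_rate < 1):
        raise ValueError("bad coverage or error rate")
    rng = np.random.default_rng(seed)
    L = len(h1)
    counts = np.zeros((L, 4), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate(BASES)}
    depth = rng.poisson(mean_coverage, size=L)
    from_h1 = rng.binomial(depth, 0.5)
    rows = np.arange(L)
    for hap, n_reads in ((h1, from_h1), (h2, depth - from_h1)):
        idx = np.array([base_idx.get(c, -1) for c in hap])
        n_reads = np.where(idx >= 0, n_reads, 0)  # uncalled template: no read
        errors = rng.binomial(n_reads, error_rate) if error_rate > 0 else np.zeros(L, dtype=np.int64)
        np.add.at(counts, (rows, np.abs(idx)), n_reads - errors)
        if errors.any():
            # each error read shows one of the three other bases, uniformly
            spread = rng.multinomial(errors, [1 / 3] * 3)
            for k in range(3):
                other = (np.abs(idx) + 1 + k) % 4
                np.add.at(counts, (rows, other), spread[:, k])
    return PileupCounts(individual, locus_id, counts)


def study_scale_scenario(
    scenario: str = "semi_permeable",
    seed: int = 0,
    base: SimConfig | None = None,
) -> ScenarioSpec:
    """Named study-scale presets.

    Both presets use the full design: 48 loci (21 autosomal, 27
    X-linked) and 96 individuals (48 per species across 4 labelled
    populations, roughly half male).  ``semi_permeable``: background
    loci exchange migrants at 4*Ne*m = 1 while barrier loci are sealed
    (m = 0) — the islands-of-restricted-introgression world, where
    barrier loci rise in both Fst and Dxy.  ``no_flow_sweeps``: no
    gene flow anywhere; barrier-category loci instead carry a local Ne
    multiplier of 0.25 (the footprint of recurrent sweeps) — elevated
    Fst without elevated Dxy.
    """
    if base is None:
        base = SimConfig(
            samples={"G_firmus": (25, 23), "G_pennsylvanicus": (30, 18)},
        )
    n_loci = {
        ("autosomal", "background"): 8,
        ("autosomal", "barrier"): 13,
        ("X", "background"): 5,
        ("X", "barrier"): 22,
    }
    m_background = 1.0 / (4 * base.ne1)  # 4*Ne*m = 1
    if scenario == "semi_permeable":
        effects = {
            "background": {"m": m_background},
            "barrier": {"m": 0.0},
        }
    elif scenario == "no_flow_sweeps":
        effects = {
            "background": {"m": 0.0},
            "barrier": {"m": 0.0, "ne_multiplier": 0.25},
        }
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return ScenarioSpec(base=base, n_loci=n_loci, category_effects=effects, seed=seed)
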