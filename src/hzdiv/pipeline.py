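"""End-to-end orchestration: simulate or load -> call -> sex -> stats ->
contrasts -> calibrate -> trim -> IM input, with a run manifest.

The pipeline consumes either ready haplotype alignments (one FASTA per
locus) or read pileups; with pileups it reconstructs diploid consensus
sequences first, infers sex from X-linked homozygosity, expands
heterozygotes into seeded random-phase haplotypes, and collapses male X
rows before any statistic is computed.  Every stage writes a TSV and is
recorded in a JSON manifest holding the config snapshot, input digests,
seeds, outputs and machine-readable warnings, so a rerun with the same
config and seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import warnings as _warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from hzdiv import consensus as cns
from hzdiv import sexing as sx
from hzdiv.calibration import calibrate_locus, species_consensus, write_calibration_table
from hzdiv.contrasts import compare_categories
from hzdiv.fourgamete import longest_compatible_block, trim_to_block
from hzdiv.im_format import write_im_input
from hzdiv.locus_io import (
    LocusAlignment,
    expand_alignment,
    read_locus_fasta,
    read_locus_metadata,
    read_sample_table,
)
from hzdiv.simulate import ScenarioSpec, study_scale_scenario, simulate_dataset, simulate_pileup
from hzdiv.stats import SiteFilterPolicy, compute_locus_stats, stats_to_frame


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    stage_info: dict[str, Any] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(_jsonable(asdict(self)), indent=2) + "\n")


def _jsonable(obj: Any) -> Any:
    """Coerce manifest contents (dataclasses, tuple keys, paths) to JSON."""
    import dataclasses

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {
            (k if isinstance(k, str) else ":".join(map(str, k)) if isinstance(k, tuple) else str(k)): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    if isinstance(obj, np.generic):
        return obj.item()
    return str(obj)


DEFAULT_PARAMS = {
    "min_cov": 8,
    "het_frac": 0.25,
    "min_loci": 5,
    "max_het_sites": 3,
    "call_floor": 0.5,
    "n_perm": 10_000,
    "policy": "complete_deletion",
    "model": "p",
    "mean_coverage": 30.0,
    "error_rate": 0.002,
}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _diploid_genotypes(
    alignments: list[LocusAlignment],
) -> dict[str, dict[str, tuple[str, str]]]:
    """locus -> individual -> (hap1, hap2); hemizygotes duplicated."""
    out: dict[str, dict[str, tuple[str, str]]] = {}
    for aln in alignments:
        per: dict[str, dict[int, str]] = {}
        for lab, seq in aln.sequences:
            per.setdefault(lab.individual, {})[lab.copy_index] = seq
        out[aln.locus_id] = {
            ind: (copies.get(1, copies.get(2)), copies.get(2, copies.get(1)))
            for ind, copies in per.items()
        }
    return out


def _scenario_from_config(sim_cfg: Any, seed: int) -> ScenarioSpec:
    """Build a scenario from a name, a ScenarioSpec, or a YAML-style dict.

    Dict form: ``{scenario: <name>}`` optionally with ``base`` (SimConfig
    field overrides; ``samples`` maps species -> [n_males, n_females]),
    ``n_loci`` (keys "<linkage>:<category>") and ``category_effects``.
    """
    from dataclasses import replace as _replace

    if isinstance(sim_cfg, str):
        return study_scale_scenario(sim_cfg, seed=seed)
    if isinstance(sim_cfg, ScenarioSpec):
        return sim_cfg
    base_over = dict(sim_cfg.get("base", {}))
    if "samples" in base_over:
        base_over["samples"] = {
            sp: tuple(v) for sp, v in base_over["samples"].items()
        }
    spec = study_scale_scenario(sim_cfg.get("scenario", "semi_permeable"), seed=seed)
    if base_over:
        new_base = _replace(spec.base, **base_over)
        spec = ScenarioSpec(
            base=new_base,
            n_loci=spec.n_loci,
            category_effects=spec.category_effects,
            seed=seed,
        )
        # rescale the background migration rate to the overridden Ne
        if spec.category_effects.get("background", {}).get("m"):
            spec.category_effects["background"]["m"] = 1.0 / (4 * new_base.ne1)
    if "n_loci" in sim_cfg:
        spec.n_loci = {
            tuple(k.split(":")): int(v) for k, v in sim_cfg["n_loci"].items()
        }
    if "category_effects" in sim_cfg:
        spec.category_effects = {
            cat: dict(eff) for cat, eff in sim_cfg["category_effects"].items()
        }
    return spec


def run_pipeline(config: Mapping[str, Any] | str | Path, outdir: str | Path) -> RunManifest:
    """Run the configured stages; returns (and writes) the manifest.

    *config* is a mapping or a path to a YAML file.  Recognised top-level
    keys: ``seed``, ``simulate`` (scenario name or spec dict),
    ``inputs`` (fasta_dir, sample_table, locus_metadata, outgroup_dir),
    ``params`` (stage parameters, see DEFAULT_PARAMS), ``pileups``
    (``simulate: true`` to exercise the caller on simulated reads).
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    config = dict(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    policy = SiteFilterPolicy(mode=params["policy"])
    manifest = RunManifest(config=config, seed=seed)
    ss = np.random.SeedSequence(seed)
    seed_phase, seed_pileup, seed_perm = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)
    )

    caught: list[str] = []
    with _warnings.catch_warnings(record=True) as wlist:
        _warnings.simplefilter("always")

        # ------------------------------------------------ inputs / simulate
        if "simulate" in config:
            spec = _scenario_from_config(config["simulate"], seed)
            dataset = simulate_dataset(spec)
            paths = dataset.write(outdir / "simdata")
            manifest.outputs.update({k: str(v) for k, v in paths.items()})
            alignments = dataset.alignments
            metadata = {m.locus_id: m for m in dataset.metadata}
            sample_table = dataset.sample_table.set_index("individual", drop=False)
            truth = dataset.truth
        else:
            inputs = config.get("inputs", {})
            for key in ("fasta_dir", "sample_table", "locus_metadata"):
                if key not in inputs:
                    raise ValueError(f"config error: inputs.{key} is required")
                if not Path(inputs[key]).exists():
                    raise ValueError(f"config error: inputs.{key} not found: {inputs[key]}")
            sample_table = read_sample_table(inputs["sample_table"])
            metadata = read_locus_metadata(inputs["locus_metadata"])
            alignments = []
            for fa in sorted(Path(inputs["fasta_dir"]).glob("*.fasta")):
                alignments.append(read_locus_fasta(fa, sample_table))
                manifest.input_digests[fa.name] = _digest(fa)
            truth = None
        sexes_known = {
            str(r["individual"]): str(r.get("sex", "unknown"))
            for _, r in sample_table.iterrows()
        }

        # --------------------------------------- genotype calling (optional)
        pileup_cfg = config.get("pileups", {})
        called_fractions: dict[str, dict[str, float]] = {}
        if pileup_cfg.get("simulate"):
            # resequence the simulated haplotypes and re-call genotypes
            genos = _diploid_genotypes(alignments)
            pileup_ss = np.random.SeedSequence(seed_pileup)
            diploid_alignments = []
            children = iter(pileup_ss.spawn(sum(len(v) for v in genos.values())))
            for aln in alignments:
                rows = []
                fracs: dict[str, float] = {}
                for ind, pair in sorted(genos[aln.locus_id].items()):
                    child = int(next(children).generate_state(1)[0] % 2**31)
                    pile = simulate_pileup(
                        pair, params["mean_coverage"], params["error_rate"],
                        child, individual=ind, locus_id=aln.locus_id,
                    )
                    seq, frac = cns.call_consensus_sequence(
                        pile, params["min_cov"], params["het_frac"]
                    )
                    fracs[ind] = frac
                    lab = next(l for l, _ in aln.sequences if l.individual == ind)
                    rows.append((lab.__class__(ind, lab.species, lab.population, 1, lab.sex), seq))
                called_fractions[aln.locus_id] = fracs
                diploid_alignments.append(LocusAlignment(aln.locus_id, rows))
            consensus_alignments = diploid_alignments
        else:
            consensus_alignments = None

        # ------------------------------------------------------------ sexing
        if consensus_alignments is not None:
            x_ids = [lid for lid, m in metadata.items() if m.linkage == "X"]
            screen = sx.select_screening_loci(called_fractions, x_ids, n=params["min_loci"])
            by_locus = {a.locus_id: a for a in consensus_alignments}
            individuals = sorted(sexes_known)
            assignments = []
            for ind in individuals:
                genos_x = []
                for lid in screen:
                    aln = by_locus[lid]
                    for lab, seq in aln.sequences:
                        if lab.individual == ind:
                            genos_x.append(seq)
                assignments.append(
                    sx.infer_sex(ind, genos_x, params["min_loci"], params["max_het_sites"])
                )
            if config.get("use_known_sex"):
                assignments = sx.apply_known_sex_overrides(assignments, sample_table)
            sex_path = outdir / "sex_assignments.tsv"
            sx.write_sex_table(assignments, sex_path)
            manifest.outputs["sex_assignments"] = str(sex_path)
            sexmap = {a.individual: a.inferred_sex for a in assignments}
            if truth is not None:
                correct = sum(
                    sexmap.get(i) == s for i, s in sexes_known.items() if s != "unknown"
                )
                known = sum(1 for s in sexes_known.values() if s != "unknown")
                manifest.stage_info["sex_inference_accuracy"] = correct / known if known else None

            # expand to haplotypes; collapse male X
            haplotype_alignments = []
            phase_ss = np.random.SeedSequence(seed_phase)
            for aln, child in zip(consensus_alignments, phase_ss.spawn(len(consensus_alignments))):
                males = {i for i, s in sexmap.items() if s == "male"}
                is_x = metadata[aln.locus_id].linkage == "X"
                expanded = expand_alignment(
                    aln,
                    int(child.generate_state(1)[0] % 2**31),
                    haploid_individuals=males if is_x else set(),
                )
                haplotype_alignments.append(expanded)
            analysis_alignments = haplotype_alignments
            manifest.stage_info["phase_seed"] = seed_phase
        else:
            # haplotype FASTAs straight in; collapse male X from known sexes
            analysis_alignments = [
                sx.collapse_male_x(aln, sexes_known, metadata[aln.locus_id])
                for aln in alignments
            ]

        # ------------------------------------------------------------- stats
        stats = [
            compute_locus_stats(aln, metadata[aln.locus_id], policy)
            for aln in analysis_alignments
        ]
        stats_df = stats_to_frame(stats)
        stats_path = outdir / "locus_stats.tsv"
        stats_df.to_csv(stats_path, sep="\t", index=False)
        manifest.outputs["locus_stats"] = str(stats_path)

        # --------------------------------------------------------- contrasts
        contrasts = compare_categories(stats_df, n_perm=params["n_perm"], seed=seed_perm)
        contrasts_path = outdir / "category_contrasts.tsv"
        contrasts.to_csv(contrasts_path, sep="\t", index=False)
        manifest.outputs["category_contrasts"] = str(contrasts_path)
        manifest.stage_info["permutation_seed"] = seed_perm

        # ------------------------------------------------------- calibration
        inputs = config.get("inputs", {})
        rates: dict[str, float] = {}
        if inputs.get("outgroup_dir"):
            ogdir = Path(inputs["outgroup_dir"])
            calibs = []
            for aln in analysis_alignments:
                outgroups = {}
                for og_fa in sorted(ogdir.glob(f"{aln.locus_id}.*.fasta")):
                    og_name = og_fa.name.split(".")[1]
                    og_aln = read_locus_fasta(og_fa, None)
                    outgroups[og_name] = og_aln.seqs()
                if not outgroups:
                    continue
                cons = species_consensus(aln.seqs())
                res = calibrate_locus(aln.locus_id, cons, outgroups, model=params["model"])
                calibs.append(res)
                if res.mu_locus:
                    rates[aln.locus_id] = res.mu_locus
            calib_path = outdir / "calibration.tsv"
            write_calibration_table(calibs, calib_path)
            manifest.outputs["calibration"] = str(calib_path)

        # ----------------------------------------------- trimming + IM input
        blocks = []
        trimmed = []
        for aln in analysis_alignments:
            block = longest_compatible_block(aln)
            blocks.append(block)
            trimmed.append(trim_to_block(aln, block))
        blocks_df = pd.DataFrame(
            [
                {
                    "locus_id": b.locus_id,
                    "start": b.start,
                    "end": b.end,
                    "length": b.length,
                    "n_segregating_inside": b.n_segregating_inside,
                }
                for b in blocks
            ]
        )
        blocks_path = outdir / "compatible_blocks.tsv"
        blocks_df.to_csv(blocks_path, sep="\t", index=False)
        manifest.outputs["compatible_blocks"] = str(blocks_path)

        species = sorted({lab.species for a in analysis_alignments for lab in a.labels()})
        if len(species) == 2:
            im_path = outdir / "im_input.txt"
            write_im_input(
                trimmed, metadata, (species[0], species[1]), im_path,
                mutation_rates=rates,
            )
            manifest.outputs["im_input"] = str(im_path)

        caught = [str(w.message) for w in wlist]

    manifest.warnings = caught
    manifest_path = outdir / "manifest.json"
    manifest.write(manifest_path)
    manifest.outputs["manifest"] = str(manifest_path)
    return manifest
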