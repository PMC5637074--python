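"""End-to-end orchestration: simulate -> quantify -> diffexp -> network -> compare.

A run is driven by one JSON config document; defaults are filled in,
validated, and the effective config is written into the run directory next
to a manifest recording parameters and SHA-256 checksums of every output,
so reruns with the same config can be verified byte-for-byte on the
deterministic stages.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path

import pandas as pd

from . import __version__
from . import catalog as cat
from . import coexpression as coexpr
from . import comparative as comp
from . import diffexp as de
from . import quantify as qt
from . import simulate as sim
from .stages import STAGES, stage_of_library

DEFAULT_CONFIG: dict = {
    "seed": sim.DEFAULT_SEED,
    "simulate": {
        "n_genes_per_wave": {"maternal": 12, "A1": 20, "A2": 20, "B": 20, "C": 20},
        "n_background_genes": 65,
        "dispersion": 0.02,
        "lib_size_mean": 1_000_000.0,
        "read_lib_size_mean": 100_000.0,
        "tailmod_rate_by_stage": sim._default_tailmod_rates(),
        "tail_composition": {"A": 0.50, "U": 0.25, "other": 0.25},
        "pirna_fraction_by_stage": sim._default_pirna_fractions(),
    },
    "quantify": {
        "min_len": 16,
        "max_len": 29,
        "five_prime_tolerance": 2,
        "max_tail": 5,
        "count_templated_extensions": False,
    },
    "network": {
        "threshold": 0.9,
        "sub_threshold": 0.925,
        "min_module_size": 3,
    },
    "compare": {"n_drivers": 3},
}


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def validate_config(document: dict | None) -> dict:
    """Fill defaults, type/range-check, and reject unknown keys.

    Normalization is idempotent: ``validate_config(validate_config(x)) ==
    validate_config(x)``.
    """
    document = document or {}
    errors: list[str] = []
    config = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst: dict, src: dict, path: str):
        for key, val in src.items():
            if key not in dst:
                errors.append(f"unknown key {path}{key}")
                continue
            if isinstance(dst[key], dict) and not _is_leaf_map(path + key):
                if not isinstance(val, dict):
                    errors.append(f"{path}{key}: expected a mapping")
                    continue
                merge(dst[key], val, path + key + ".")
            else:
                dst[key] = val

    def _is_leaf_map(path_key: str) -> bool:
        return path_key.split(".")[-1] in (
            "n_genes_per_wave", "tailmod_rate_by_stage",
            "tail_composition", "pirna_fraction_by_stage",
        )

    if not isinstance(document, dict):
        raise ConfigError(["config document must be a JSON object"])
    merge(config, document, "")

    seed = config["seed"]
    if not isinstance(seed, int) or isinstance(seed, bool) or seed < 0:
        errors.append(f"seed must be a non-negative integer, got {seed!r}")
    for key in ("threshold", "sub_threshold"):
        v = config["network"][key]
        if not isinstance(v, (int, float)) or not 0 < v < 1:
            errors.append(f"network.{key} must lie in (0, 1), got {v!r}")
    if config["network"]["min_module_size"] < 1:
        errors.append("network.min_module_size must be >= 1")
    q = config["quantify"]
    if q["min_len"] > q["max_len"]:
        errors.append("quantify.min_len must be <= max_len")
    if not errors:
        try:
            _sim_config(config).validate()
        except ValueError as exc:
            errors.append(str(exc))
    if errors:
        raise ConfigError(errors)
    return config


def _sim_config(config: dict) -> sim.SimConfig:
    s = config["simulate"]
    return sim.SimConfig(
        n_genes_per_wave=dict(s["n_genes_per_wave"]),
        n_background_genes=s["n_background_genes"],
        dispersion=s["dispersion"],
        lib_size_mean=s["lib_size_mean"],
        read_lib_size_mean=s["read_lib_size_mean"],
        tailmod_rate_by_stage=dict(s["tailmod_rate_by_stage"]),
        tail_composition=dict(s["tail_composition"]),
        pirna_fraction_by_stage=dict(s["pirna_fraction_by_stage"]),
        seed=config["seed"],
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict | None, outdir, write_fastq: bool = False) -> dict:
    """Execute all stages in dependency order; returns the manifest.

    On failure the offending stage is named and a ``failed/`` marker with the
    stage name is left in the run directory alongside any partial outputs.
    """
    config = validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config, indent=1, sort_keys=True))

    log_lines: list[str] = []
    outputs: list[Path] = []
    current_stage = "setup"

    def log(msg: str):
        log_lines.append(msg)

    try:
        t0 = time.perf_counter()
        current_stage = "simulate"
        sim_cfg = _sim_config(config)
        genome, catalog, decoys = sim.default_catalog(config["seed"])
        cat.write_gff3(catalog, out / "annotation.gff3")
        cat.write_catalog_json(catalog, out / "catalog.json")
        _write_fasta(genome, out / "genome.fa")
        outputs += [out / "annotation.gff3", out / "catalog.json", out / "genome.fa"]

        waves = sim.assign_units_to_waves(catalog)
        counts, truth = sim.simulate_counts(sim_cfg, gene_ids=waves)
        sim.write_counts_tsv(counts, out / "sim_counts.tsv")
        outputs.append(out / "sim_counts.tsv")
        reads, truth = sim.simulate_reads(
            sim_cfg, catalog, genome, decoy_positions=decoys, truth=truth,
            stage_weights=truth.mean_profiles,
        )
        if write_fastq:
            fq_dir = out / "reads"
            fq_dir.mkdir(exist_ok=True)
            for lib, records in reads.items():
                sim.write_fastq(records, fq_dir / f"{lib}.fastq")
                outputs.append(fq_dir / f"{lib}.fastq")
        log(f"simulate: {len(catalog.genes)} genes, "
            f"{sum(len(r) for r in reads.values())} reads "
            f"({time.perf_counter() - t0:.1f}s)")

        t0 = time.perf_counter()
        current_stage = "quantify"
        qcfg = config["quantify"]
        selected = {
            lib: qt.size_select(recs, qcfg["min_len"], qcfg["max_len"])
            for lib, recs in reads.items()
        }
        assignments = qt.assign_reads(
            selected, catalog, genome,
            five_prime_tolerance=qcfg["five_prime_tolerance"],
            max_tail=qcfg["max_tail"],
        )
        counts_q = qt.assignments_to_counts(assignments, catalog)
        counts_q.to_csv(out / "quant_counts.tsv", sep="\t")
        cpm_q = qt.cpm_normalize(counts_q)
        cpm_q.to_csv(out / "quant_cpm.tsv", sep="\t", float_format="%.4f")
        tails = qt.tailmod_profile(assignments, qcfg["count_templated_extensions"])
        qt.write_tail_profile_tsv(tails, out / "tail_profile.tsv")
        dist = qt.length_distribution(reads, qcfg["min_len"], qcfg["max_len"])
        qt.write_length_histogram_tsv(dist, out / "length_histogram.tsv")
        outputs += [out / "quant_counts.tsv", out / "quant_cpm.tsv",
                    out / "tail_profile.tsv", out / "length_histogram.tsv"]
        log(f"quantify: {time.perf_counter() - t0:.1f}s")

        t0 = time.perf_counter()
        current_stage = "diffexp"
        results = de.all_adjacent_transitions(counts)
        de_dir = out / "diffexp"
        de_dir.mkdir(exist_ok=True)
        for (a, b), res in results.items():
            p = de_dir / f"{a}_vs_{b}.tsv"
            res.to_csv(p, sep="\t", float_format="%.6g")
            outputs.append(p)
        summary = de.transition_summary(results)
        summary.to_csv(out / "transition_summary.tsv", sep="\t")
        outputs.append(out / "transition_summary.tsv")
        log(f"diffexp: {time.perf_counter() - t0:.1f}s")

        t0 = time.perf_counter()
        current_stage = "network"
        ncfg = config["network"]
        cpm = qt.cpm_normalize(counts)
        profiles = coexpr.stage_means(cpm)
        rho = coexpr.spearman_matrix(profiles)
        network = coexpr.build_network(rho, ncfg["threshold"])
        modules = coexpr.find_modules(network, ncfg["min_module_size"])
        for m in modules:
            m.metagene = coexpr.metagene(profiles.loc[list(m.members)])
        submodules = []
        if modules:
            submodules = coexpr.split_largest(
                network, rho, ncfg["sub_threshold"], ncfg["min_module_size"]
            )
            for m in submodules:
                m.metagene = coexpr.metagene(profiles.loc[list(m.members)])
        coexpr.write_edge_list(network, out / "edges.tsv")
        coexpr.write_modules_tsv(modules + submodules, out / "modules.tsv")
        coexpr.write_metagenes_tsv(modules + submodules, out / "metagenes.tsv")
        coexpr.write_graphml(network, out / "network.graphml")
        outputs += [out / "edges.tsv", out / "modules.tsv",
                    out / "metagenes.tsv", out / "network.graphml"]
        log(f"network: {len(modules)} modules, {len(submodules)} submodules "
            f"({time.perf_counter() - t0:.1f}s)")

        t0 = time.perf_counter()
        current_stage = "compare"
        panel, species = sim.make_species_panel(config["seed"])
        shared = comp.shared_family_table(panel, species)
        rel = comp.relative_abundance(shared)
        shared.to_csv(out / "shared_families.tsv", sep="\t", float_format="%.4f")
        hc = comp.hcluster_libraries(rel)
        (out / "dendrogram.nwk").write_text(hc.to_newick() + "\n")
        pca = comp.pca_drivers(rel, config["compare"]["n_drivers"])
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.6f")
        pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t", float_format="%.6f")
        outputs += [out / "shared_families.tsv", out / "dendrogram.nwk",
                    out / "pca_scores.tsv", out / "pca_loadings.tsv"]
        log(f"compare: drivers {pca.drivers} ({time.perf_counter() - t0:.1f}s)")

    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        (failed / "stage.txt").write_text(current_stage + "\n")
        (out / "run.log").write_text("\n".join(log_lines) + f"\nFAILED: {current_stage}\n")
        raise PipelineError(current_stage, exc) from exc

    manifest = {
        "version": __version__,
        "config": config,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(outputs)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return manifest


def _write_fasta(genome: dict[str, str], path: Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
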