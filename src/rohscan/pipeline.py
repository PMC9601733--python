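"""End-to-end pipeline: simulate/read -> QC -> ROH -> inbreeding -> islands
-> annotation, driven by a YAML config, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict

import yaml

from . import __version__
from .annotate import genes_in_islands, read_gene_models
from .inbreeding import (
    coefficient_stats,
    compute_inbreeding,
    compute_laut,
    correlation_matrix,
    length_class_summary,
)
from .io import (
    QCParams,
    qc_filter,
    read_vcf_genotypes,
    write_class_summary,
    write_correlation_matrix,
    write_inbreeding_table,
    write_island_table,
    write_roh_table,
)
from .islands import find_islands
from .roh import CallerParams, detect_roh
from .sim import SimulationConfig, simulate_dataset, write_outputs

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "vcf",
    "gff",
    "out_dir",
    "seed",
    "simulate",
    "qc",
    "caller",
    "laut",
    "island_top_fraction",
    "island_gap_kb",
}


class PipelineConfigError(ValueError):
    pass


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
    if "vcf" not in cfg and "simulate" not in cfg:
        raise PipelineConfigError("config needs either 'vcf' or a 'simulate' block")
    if "vcf" in cfg and not os.path.exists(cfg["vcf"]):
        raise PipelineConfigError(f"VCF not found: {cfg['vcf']}")
    if "gff" in cfg and not os.path.exists(cfg["gff"]):
        raise PipelineConfigError(f"GFF not found: {cfg['gff']}")
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict | str, out_dir: str | None = None) -> str:
    """Execute every stage the config enables; returns the output directory.

    Reruns with the same config and inputs produce identical tables.
    """
    if isinstance(config, str):
        cfg = load_config(config)
    else:
        cfg = dict(config)
        unknown = set(cfg) - _KNOWN_KEYS
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
    out_dir = out_dir or cfg.get("out_dir") or "rohscan_out"
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {"rohscan_version": __version__, "config": _jsonable(cfg)}

    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"])
        sim_kwargs.setdefault("seed", cfg.get("seed", 0))
        sim_kwargs["tract_spec"] = [tuple(t) for t in sim_kwargs.get("tract_spec", [])]
        sim_config = SimulationConfig(**sim_kwargs)
        snp_map, geno, truths = simulate_dataset(sim_config)
        write_outputs(geno, snp_map, truths, sim_config, os.path.join(out_dir, "sim"))
        vcf_path = os.path.join(out_dir, "sim.vcf")
    else:
        vcf_path = cfg["vcf"]
        snp_map, geno = read_vcf_genotypes(vcf_path)
    manifest["input_vcf_sha256"] = _sha256(vcf_path)

    qc_params = QCParams(**cfg.get("qc", {}))
    snp_map, geno, qc_report = qc_filter(snp_map, geno, qc_params)
    manifest["qc"] = asdict(qc_report)

    caller = CallerParams(**cfg.get("caller", {}))
    segments = detect_roh(snp_map, geno, caller)
    write_roh_table(segments, os.path.join(out_dir, "roh_segments.tsv"))
    manifest["n_segments"] = len(segments)

    genome = compute_laut(snp_map, override=cfg.get("laut"))
    manifest["l_aut"] = genome.l_aut
    records = compute_inbreeding(segments, geno, genome)
    write_inbreeding_table(records, os.path.join(out_dir, "inbreeding.tsv"))
    write_inbreeding_table(
        coefficient_stats(records), os.path.join(out_dir, "inbreeding_summary.tsv")
    )
    write_correlation_matrix(
        correlation_matrix(records), os.path.join(out_dir, "correlations.tsv")
    )
    write_class_summary(
        length_class_summary(segments), os.path.join(out_dir, "length_classes.tsv")
    )

    track, candidates, islands = find_islands(
        segments,
        snp_map,
        geno.n_individuals,
        top_fraction=cfg.get("island_top_fraction", 0.005),
        island_gap_kb=cfg.get("island_gap_kb"),
    )
    track.to_csv(os.path.join(out_dir, "roh_frequency.tsv"), sep="\t", index=False)
    if "gff" in cfg:
        genes = read_gene_models(cfg["gff"])
        islands = genes_in_islands(islands, genes)
        manifest["n_genes_loaded"] = len(genes)
    write_island_table(islands, os.path.join(out_dir, "islands.tsv"))
    manifest["n_islands"] = len(islands)
    manifest["n_candidate_snps"] = int(len(candidates))

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", out_dir)
    return out_dir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
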