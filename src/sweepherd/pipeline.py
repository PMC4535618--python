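"""End-to-end orchestration of the cohort analysis under one config.

Stages (each also exposed as its own function / CLI subcommand):

    simulate   write a synthetic cohort from a genome/breed/sweep spec
    annotate   functional categories + SIFT classes + novelty flags
    qc         Ti/Tv per breed and novel fraction
    scan       pooled-heterozygosity ZHp sweep scan per breed
    structure  similarity matrix + K2P neighbour-joining tree
    concord    chip-vs-sequencing concordance
    all        everything above, plus a machine-readable JSON summary

Configuration lives in a single YAML file with two blocks (``paths`` and
``params``) plus an optional ``simulate`` block; CLI options override the
file, which overrides the defaults.  Every output table carries a header
line naming the parameters used, and reruns on identical inputs are
byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import population_structure as popstruct
from . import sweep_scan
from . import synthetic_data as synth
from . import variant_annotation as annot

__all__ = [
    "ConfigError",
    "DataError",
    "PipelineConfig",
    "run_simulate",
    "run_annotate",
    "run_qc",
    "run_scan",
    "run_structure",
    "run_concord",
    "run_all",
]

logger = logging.getLogger("sweepherd")


class ConfigError(Exception):
    """Bad or missing configuration (CLI exit code 2)."""


class DataError(Exception):
    """A stage failed on the input data (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    # input paths
    vcf: str | None = None
    breed_map: str | None = None
    genome_table: str | None = None
    reference_fasta: str | None = None
    gene_models: str | None = None
    known_sites: str | None = None
    sift_table: str | None = None
    chip_table: str | None = None
    outdir: str = "sweepherd_out"
    # analysis parameters
    window_size: int = 150_000
    step: int = 75_000
    maf: float = 0.05
    min_snps: int = 10
    zhp_threshold: float = -2.0
    sift_threshold: float = 0.05
    absent_as_homref: bool = True
    # simulate block
    seed: int = 1
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window_size <= 0 or self.step <= 0 or self.min_snps < 0:
            raise ConfigError("window_size, step must be positive; min_snps >= 0")
        if not 0 < self.maf <= 0.5:
            raise ConfigError("maf must be in (0, 0.5]")
        if not 0 <= self.sift_threshold <= 1:
            raise ConfigError("sift_threshold must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as e:
            raise ConfigError(f"cannot read config {path}: {e}") from e
        flat: dict = {}
        flat.update(raw.get("paths", {}))
        flat.update(raw.get("params", {}))
        if "simulate" in raw:
            flat["simulate"] = raw["simulate"]
        if "seed" in raw:
            flat["seed"] = raw["seed"]
        flat.update({k: v for k, v in overrides.items() if v is not None})
        known = set(cls.__dataclass_fields__)
        unknown = set(flat) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**flat)
        except TypeError as e:
            raise ConfigError(str(e)) from e

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ConfigError(f"missing required paths: {missing}")

    def params_header(self) -> str:
        return (
            f"window_size={self.window_size} step={self.step} maf={self.maf} "
            f"min_snps={self.min_snps} zhp_threshold={self.zhp_threshold} "
            f"sift_threshold={self.sift_threshold}"
        )


def _setup_run_logging(outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(outdir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("sweepherd")
    root.addHandler(handler)
    root.setLevel(logging.INFO)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _simulate_spec(cfg: PipelineConfig):
    sim = cfg.simulate or {}
    chroms = sim.get("chromosomes", [["chr1", 4_000_000]])
    genome = synth.GenomeSpec(
        chromosomes=tuple((str(c), int(l)) for c, l in chroms),
        snp_density=float(sim.get("snp_density", 1 / 500)),
    )
    if "breeds" in sim:
        breeds = [synth.BreedModel(**b) for b in sim["breeds"]]
    else:
        breeds = synth.default_breeds()
    sweeps = [
        synth.SweepSpec(
            chromosome=s["chromosome"],
            start=int(s["start"]),
            end=int(s["end"]),
            breeds=tuple(s["breeds"]),
            residual_maf=float(s.get("residual_maf", 0.01)),
        )
        for s in sim.get("sweeps", [])
    ]
    chip = synth.ChipSpec(**sim["chip"]) if "chip" in sim else None
    extras = {
        k: sim[k]
        for k in ("known_fraction", "sift_coverage", "ti_fraction")
        if k in sim
    }
    return genome, breeds, sweeps, chip, extras


def run_simulate(cfg: PipelineConfig, force: bool = False) -> synth.CohortFiles:
    """Write a synthetic cohort into cfg.outdir (refusing to clobber an
    existing manifest unless forced)."""
    manifest = os.path.join(cfg.outdir, "truth", "manifest.json")
    if os.path.exists(manifest) and not force:
        raise ConfigError(f"{cfg.outdir} already holds a cohort (use --force)")
    genome, breeds, sweeps, chip, extras = _simulate_spec(cfg)
    logger.info("simulating cohort: seed=%d, %d chromosomes, %d breeds, %d sweeps",
                cfg.seed, len(genome.chromosomes), len(breeds), len(sweeps))
    return synth.write_cohort(
        cfg.outdir, genome, breeds, sweeps=sweeps, chip=chip, seed=cfg.seed, **extras
    )


def _load_common(cfg: PipelineConfig):
    cfg.require("vcf", "breed_map")
    breed_map = sweep_scan.read_breed_map(cfg.breed_map)
    return breed_map


def run_annotate(cfg: PipelineConfig) -> pd.DataFrame:
    """Classify every SNP; attach SIFT classes and novelty flags; write the
    annotated table, an annotated VCF and a category summary table."""
    cfg.require("vcf", "breed_map", "gene_models", "reference_fasta")
    os.makedirs(cfg.outdir, exist_ok=True)
    from pyfaidx import Fasta

    breed_map = _load_common(cfg)
    gene_models = annot.load_gene_models(cfg.gene_models)
    reference = Fasta(cfg.reference_fasta)
    samples, dosage, _haps, sites = popstruct.load_genotypes(cfg.vcf)
    try:
        annotated = annot.annotate_variants(sites, gene_models, reference)
    except ValueError as e:
        raise DataError(f"annotate: {e}") from e

    if cfg.known_sites:
        known = pd.read_csv(cfg.known_sites, sep="\t")
        annotated, frac = annot.novelty(
            annotated, zip(known["chrom"].astype(str), known["pos"].astype(int))
        )
        logger.info("novel fraction: %.4f", frac)
    if cfg.sift_table:
        sift = pd.read_csv(cfg.sift_table, sep="\t")
        ns = annotated["category"] == "non_synonymous_coding"
        classified = annot.sift_classify(
            annotated.loc[ns], sift, threshold=cfg.sift_threshold
        )
        annotated.loc[ns, "sift_class"] = classified["sift_class"].to_numpy()
        annotated.loc[ns, "sift_score"] = classified["sift_score"].to_numpy()
    else:
        annotated.loc[
            annotated["category"] == "non_synonymous_coding", "sift_class"
        ] = "unscored"

    sample_breeds = [
        breed_map.set_index("sample")["breed"].to_dict().get(s) for s in samples
    ]
    breed_order = list(dict.fromkeys(breed_map["breed"]))
    presence = annot.breed_presence(dosage, sample_breeds, breed_order)
    summary = annot.category_summary(annotated, presence, breed_order)

    header = f"# {cfg.params_header()}\n"
    with open(os.path.join(cfg.outdir, "annotated.tsv"), "w") as fh:
        fh.write(header)
        annotated.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    with open(os.path.join(cfg.outdir, "category_summary.tsv"), "w") as fh:
        fh.write(header)
        summary.to_csv(fh, sep="\t")
    annot.write_annotated_vcf(
        cfg.vcf, annotated, os.path.join(cfg.outdir, "annotated.vcf")
    )
    specific = annot.breed_specific_nssnps(annotated, presence, breed_order)
    with open(os.path.join(cfg.outdir, "breed_specific_nssnps.tsv"), "w") as fh:
        fh.write(header)
        rows = []
        for breed, df in specific.items():
            df = df.copy()
            df.insert(0, "breed", breed)
            rows.append(df)
        pd.concat(rows, ignore_index=True).to_csv(fh, sep="\t", index=False, float_format="%.6g")
    return annotated


def run_qc(cfg: PipelineConfig) -> dict:
    """Ti/Tv ratio per breed and overall, plus the novel fraction."""
    cfg.require("vcf", "breed_map")
    os.makedirs(cfg.outdir, exist_ok=True)
    breed_map = _load_common(cfg)
    samples, dosage, _haps, sites = popstruct.load_genotypes(cfg.vcf)
    sample_breeds = [
        breed_map.set_index("sample")["breed"].to_dict().get(s) for s in samples
    ]
    breed_order = list(dict.fromkeys(breed_map["breed"]))
    presence = annot.breed_presence(dosage, sample_breeds, breed_order)
    result: dict = {"titv": {}, "novel_fraction": None, "novel_fraction_by_breed": {}}
    tt = annot.titv(sites)
    result["titv"]["Total"] = tt.ratio
    for i, breed in enumerate(breed_order):
        result["titv"][breed] = annot.titv(sites, mask=presence[i]).ratio
    if cfg.known_sites:
        known = pd.read_csv(cfg.known_sites, sep="\t")
        flagged, frac = annot.novelty(
            sites, zip(known["chrom"].astype(str), known["pos"].astype(int))
        )
        result["novel_fraction"] = frac
        novel = flagged["novel"].to_numpy()
        for i, breed in enumerate(breed_order):
            seen = presence[i]
            result["novel_fraction_by_breed"][breed] = (
                float(novel[seen].mean()) if seen.any() else None
            )
    with open(os.path.join(cfg.outdir, "qc.json"), "w") as fh:
        json.dump(result, fh, indent=1)
    return result


def run_scan(cfg: PipelineConfig):
    """Per-breed pooled-heterozygosity scan; writes window tables, sweep
    call TSVs and BEDs."""
    cfg.require("vcf", "breed_map", "genome_table")
    os.makedirs(cfg.outdir, exist_ok=True)
    breed_map = _load_common(cfg)
    genome = sweep_scan.read_genome_table(cfg.genome_table)
    gene_models = (
        annot.load_gene_models(cfg.gene_models) if cfg.gene_models else None
    )
    try:
        stats, calls = sweep_scan.scan(
            cfg.vcf,
            breed_map,
            genome,
            window_size=cfg.window_size,
            step=cfg.step,
            maf_threshold=cfg.maf,
            min_snps=cfg.min_snps,
            zhp_threshold=cfg.zhp_threshold,
            gene_models=gene_models,
        )
    except ValueError as e:
        raise DataError(f"scan: {e}") from e
    for breed in stats:
        sweep_scan.write_window_table(
            stats[breed],
            os.path.join(cfg.outdir, f"windows_{breed}.tsv"),
            params=cfg.params_header(),
        )
        sweep_scan.write_window_table(
            calls[breed],
            os.path.join(cfg.outdir, f"sweeps_{breed}.tsv"),
            params=cfg.params_header(),
        )
        sweep_scan.write_sweep_bed(
            calls[breed], os.path.join(cfg.outdir, f"sweeps_{breed}.bed")
        )
    return stats, calls


def run_structure(cfg: PipelineConfig):
    """Similarity matrix and K2P neighbour-joining tree (one tip per animal)."""
    cfg.require("vcf", "breed_map")
    os.makedirs(cfg.outdir, exist_ok=True)
    samples, dosage, haps, sites = popstruct.load_genotypes(cfg.vcf)
    try:
        sim = popstruct.similarity_matrix(dosage, samples)
        dm, pq = popstruct.pairwise_k2p(haps, sites, samples, return_pq=True)
        newick = popstruct.nj_tree(dm)
    except ValueError as e:
        raise DataError(f"structure: {e}") from e
    sim.to_csv(os.path.join(cfg.outdir, "similarity.tsv"), sep="\t", float_format="%.6f")
    pq.to_csv(os.path.join(cfg.outdir, "k2p_pq.tsv"), sep="\t", index=False, float_format="%.8f")
    with open(os.path.join(cfg.outdir, "nj_tree.nwk"), "w") as fh:
        fh.write(newick + "\n")
    return sim, dm, newick


def run_concord(cfg: PipelineConfig) -> pd.DataFrame:
    """Chip-vs-sequencing per-animal concordance report."""
    cfg.require("vcf", "chip_table")
    os.makedirs(cfg.outdir, exist_ok=True)
    chip = conc.read_chip_table(cfg.chip_table)
    seq = conc.seq_genotypes_from_vcf(cfg.vcf)
    reference = None
    if cfg.reference_fasta:
        from pyfaidx import Fasta

        reference = Fasta(cfg.reference_fasta)
    try:
        report = conc.concordance(
            chip,
            seq,
            absent_as_homref=cfg.absent_as_homref,
            reference=reference,
        )
    except ValueError as e:
        raise DataError(f"concord: {e}") from e
    with open(os.path.join(cfg.outdir, "concordance.tsv"), "w") as fh:
        fh.write(f"# {cfg.params_header()}\n")
        report.to_csv(fh, sep="\t", index=False, float_format="%.6f")
    return report


def run_all(cfg: PipelineConfig) -> dict:
    """Annotation -> QC -> sweep scan -> structure -> concordance, with a
    JSON summary of the headline numbers of every stage."""
    _setup_run_logging(cfg.outdir)
    logger.info("parameters: %s", cfg.params_header())
    param_keys = (
        "window_size", "step", "maf", "min_snps", "zhp_threshold",
        "sift_threshold", "absent_as_homref",
    )
    summary: dict = {"parameters": {k: getattr(cfg, k) for k in param_keys}}

    annotated = run_annotate(cfg)
    cat_counts = annotated["category"].value_counts().to_dict()
    summary["annotation"] = {
        "n_snps": int(len(annotated)),
        "categories": {c: int(cat_counts.get(c, 0)) for c in annot.CATEGORIES},
    }
    qc = run_qc(cfg)
    summary["qc"] = qc
    stats, calls = run_scan(cfg)
    summary["scan"] = {
        breed: {
            "windows": int(len(stats[breed])),
            "retained": int((~stats[breed]["excluded"]).sum()),
            "excluded": int(stats[breed]["excluded"].sum()),
            "sweep_calls": int(len(calls[breed])),
        }
        for breed in stats
    }
    _sim, _dm, newick = run_structure(cfg)
    summary["structure"] = {"newick_file": "nj_tree.nwk", "n_tips": newick.count(",") + 1}
    if cfg.chip_table:
        report = run_concord(cfg)
        summary["concordance"] = {
            "mean_rate": float(report["rate"].mean()),
            "min_rate": float(report["rate"].min()),
            "max_rate": float(report["rate"].max()),
        }
    with open(os.path.join(cfg.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    logger.info("pipeline complete: %s", os.path.join(cfg.outdir, "summary.json"))
    return summary
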