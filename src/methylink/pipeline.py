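"""End-to-end orchestration from a single validated config.

Stages: (optional) simulate -> qc -> dm-call -> annotate -> integrate ->
deconvolve, each writing its outputs into the run directory, with a
manifest recording parameters, seeds and SHA-256 checksums of every input
and output so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .deconvolution import NNLSDeconvolver
from .dm import DifferentialMethylation, annotate_sites, classify_gene_meth_status
from .integration import RegulatoryPotentialIntegrator
from .io import (
    read_bismark_cov,
    read_de_table,
    read_gene_annotation,
    read_matrix_tsv,
    write_bed_peaks,
    write_bismark_cov,
    write_matrix_tsv,
)
from .qc import PromoterOutlierQC
from .simulate import (
    SimulationConfig,
    config_to_dict,
    make_signature,
    simulate_de,
    simulate_genome,
    simulate_methylation,
    simulate_mixtures,
)

log = logging.getLogger("methylink")

__all__ = ["PipelineConfig", "run_pipeline", "default_synthetic_config"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Defaults mirror the published analysis settings: q 0.05, diff 10
    points, 100 kb window, df 0.05, c 0.05, 100,000 permutations.
    """

    outdir: str = "methylink_run"
    seed: int = 0
    # inputs (paths); when ``simulate`` is set they are generated instead
    cov_files: dict = field(default_factory=dict)  # sample -> path
    design: dict = field(default_factory=dict)  # sample -> group
    genes: str | None = None
    genes_format: str = "bed12"
    de_table: str | None = None
    signature: str | None = None
    bulk: str | None = None
    simulate: dict | None = None
    # stage parameters
    q_threshold: float = 0.05
    diff_threshold: float = 10.0
    method: str = "logistic"
    min_total_coverage: int = 10
    min_per_sample: int = 1
    promoter_upstream: int = 1000
    promoter_downstream: int = 1000
    window: int = 100_000
    df: float = 0.05
    c: float = 0.05
    n_permutations: int = 100_000
    direction_filter: str = "none"
    max_sites: int | None = None
    n_pcs: int = 2
    qc_alpha: float = 0.001
    qc_n_permutations: int = 999
    run_qc: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_synthetic_config(seed: int = 0, outdir: str = "methylink_run") -> PipelineConfig:
    """The default fully-synthetic run profile.

    Simulation sizes are the package's desk-scale study conditions (2,000
    genes, ~20,000 CpGs, 3 samples per group) and the permutation count is
    the scaled-down 10,000 used throughout the synthetic analyses.
    """
    return PipelineConfig(
        outdir=outdir,
        seed=seed,
        simulate={},
        n_permutations=10_000,
        qc_n_permutations=499,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": config.to_dict(),
        "stages": [],
        "checksums": {},
    }

    # ---- gather or generate inputs -------------------------------------
    if config.simulate is not None:
        sim_raw = dict(config.simulate)
        sim_raw.setdefault("seed", config.seed)
        known = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(sim_raw) - known
        if unknown:
            raise ValueError(
                f"unknown simulate key(s): {', '.join(sorted(unknown))}"
            )
        sim = SimulationConfig(**sim_raw)
        manifest["parameters"]["simulate"] = config_to_dict(sim)
        indir = out / "inputs"
        indir.mkdir(exist_ok=True)
        catalog = simulate_genome(sim)
        samples, design, _sites, truth = simulate_methylation(catalog, sim)
        de = simulate_de(catalog, truth, sim)
        signature = make_signature(sim)
        bulk, props = simulate_mixtures(signature, sim)
        catalog.to_bed12(indir / "genes.bed12")
        for name, cov in samples.items():
            write_bismark_cov(cov, indir / f"{name}.cov")
        de.rename(columns={"log2fc": "log2FC"}).to_csv(
            indir / "de.tsv", sep="\t", index=False
        )
        write_matrix_tsv(signature, indir / "signature.tsv")
        write_matrix_tsv(bulk, indir / "bulk.tsv")
        write_matrix_tsv(props, indir / "true_proportions.tsv")
        truth.to_json(indir / "truth.json")
        for p in sorted(indir.iterdir()):
            manifest["checksums"][f"inputs/{p.name}"] = _sha256(p)
        log.info("simulate: %d genes, %d samples", len(catalog), len(samples))
        manifest["stages"].append("simulate")
    else:
        missing = []
        if not config.cov_files:
            missing.append("cov_files")
        if not config.design:
            missing.append("design")
        if config.genes is None:
            missing.append("genes")
        if missing:
            raise ValueError(
                f"missing required input(s) for the pipeline: "
                f"{', '.join(missing)}"
            )
        catalog = read_gene_annotation(config.genes, format=config.genes_format)
        samples = {s: read_bismark_cov(p) for s, p in config.cov_files.items()}
        design = dict(config.design)
        de = read_de_table(config.de_table) if config.de_table else None
        signature = read_matrix_tsv(config.signature) if config.signature else None
        bulk = read_matrix_tsv(config.bulk) if config.bulk else None
        for s, p in config.cov_files.items():
            manifest["checksums"][f"input:{s}"] = _sha256(Path(p))

    pw = (config.promoter_upstream, config.promoter_downstream)

    # ---- qc -------------------------------------------------------------
    if config.run_qc:
        qc = PromoterOutlierQC(
            n_pcs=config.n_pcs,
            alpha=config.qc_alpha,
            n_permutations=config.qc_n_permutations,
            random_state=config.seed,
        ).fit(samples, design, catalog, promoter_window=pw)
        qc.report_.to_json(out / "qc.json")
        n_flagged = int(qc.report_.flags["flag"].sum())
        log.info("qc: %d/%d samples flagged", n_flagged, len(samples))
        manifest["stages"].append("qc")

    # ---- dm-call + annotate ---------------------------------------------
    dm = DifferentialMethylation(
        min_total_coverage=config.min_total_coverage,
        min_per_sample=config.min_per_sample,
        method=config.method,
        q_threshold=config.q_threshold,
        diff_threshold=config.diff_threshold,
    ).fit(samples, design)
    log.info(
        "dm-call: %d sites dropped at merge, %d at coverage filter, "
        "%d tested, %d DM",
        dm.n_dropped_sites_,
        dm.n_filtered_sites_,
        len(dm.results_),
        len(dm.dm_sites_),
    )
    dm.dm_sites_.to_csv(out / "dm_sites.tsv", sep="\t", index=False)
    write_bed_peaks(dm.dm_sites_, out / "dm_sites.bed")
    annotated = annotate_sites(dm.dm_sites_, catalog, promoter_window=pw)
    annotated.to_csv(out / "dm_annotated.tsv", sep="\t", index=False)
    classify_gene_meth_status(annotated, scope="whole_gene").to_csv(
        out / "gene_meth_status.tsv", sep="\t", index=False
    )
    manifest["stages"] += ["dm-call", "annotate"]

    # ---- integrate --------------------------------------------------------
    if de is not None:
        integ = RegulatoryPotentialIntegrator(
            window=config.window,
            df=config.df,
            c=config.c,
            direction_filter=config.direction_filter,
            max_sites=config.max_sites,
            n_permutations=config.n_permutations,
            random_state=config.seed,
        ).fit(dm.dm_sites_, de, catalog)
        targets = integ.targets_
        if hasattr(integ, "perm_p_"):
            targets = targets.merge(integ.perm_p_, on="gene_id", how="left")
        targets.to_csv(out / "targets.tsv", sep="\t", index=False)
        with open(out / "function_test.json", "w") as fh:
            json.dump(integ.function_test_.to_dict(), fh, indent=1, sort_keys=True)
        summary = integ.targets_.loc[
            integ.targets_["target_class"] != "non_target",
            ["gene_id", "target_class", "s_g", "k", "n_hypo", "n_hyper",
             "mean_abs_tss_distance", "rank_product_score"],
        ]
        summary.to_csv(out / "target_summary.tsv", sep="\t", index=False)
        n_act = int((integ.targets_["target_class"] == "activated").sum())
        n_rep = int((integ.targets_["target_class"] == "repressed").sum())
        log.info("integrate: %d activated, %d repressed targets", n_act, n_rep)
        manifest["stages"].append("integrate")

    # ---- deconvolve -------------------------------------------------------
    if signature is not None and bulk is not None:
        props, residuals = (
            NNLSDeconvolver().fit(signature).transform(bulk),
            None,
        )
        write_matrix_tsv(props, out / "proportions.tsv")
        log.info("deconvolve: %d samples", props.shape[1])
        manifest["stages"].append("deconvolve")

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["checksums"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
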