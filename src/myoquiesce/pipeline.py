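"""End-to-end pipeline: signature -> PCA projection -> phenotype calls ->
enrichment -> ratio/ROC -> correlated panel, with seeded reproducibility.

A run either loads on-disk inputs (counts/samples/ct/gmt TSVs) or simulates a
cohort, then writes seven TSV outputs plus a JSON manifest. All outputs are
byte-identical for a fixed config + seed; run logs (including stage timings)
go to stderr only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    ANCHOR_DENOMINATOR,
    ANCHOR_NUMERATOR,
    GeneSetCollection,
    read_counts,
    read_ct_table,
    read_gmt,
    read_sample_table,
    write_gmt,
    write_table,
)
from .simulate import (
    RNG_ALGORITHM,
    SimulationConfig,
    make_gene_sets,
    simulate_cohort,
)
from .clinical import score_table
from .de import log2_normalized, signature_filter, size_factors, test_de
from .pca import QuiescencePhenotyper, correlate_clinical, project
from .enrichment import gsea
from .ratio import correlated_panel, ratio_from_counts, ratio_from_ct, roc

logger = logging.getLogger(__name__)

OUTPUT_FILES = ("de.tsv", "scores.tsv", "phenotypes.tsv", "gsea.tsv",
                "ratios.tsv", "roc.tsv", "panel.tsv")


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of a full run; serializable to/from a YAML file."""

    # inputs (either simulate=True or a counts+samples pair)
    simulate: bool = True
    counts: str | None = None
    samples: str | None = None
    ct: str | None = None
    gmt: str | None = None
    outdir: str = "myoquiesce_run"
    seed: int = 0
    log_level: str = "INFO"
    # stage parameters
    min_fc: float = 1.5
    max_fdr: float = 0.1
    use_batch: bool = True
    scale_pca: bool = False
    transitional_band: float = 0.0
    nperm: int = 1000
    gsea_size_min: int = 15
    gsea_size_max: int = 500
    r_min: float = 0.95
    threshold: float | None = None  # fixed ratio threshold override
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)


def load_config(path: str) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected."""
    errors = validate_config(path)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(f"  - {e}" for e in errors))
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("simulation", {}) or {}
    sim = SimulationConfig(**sim_raw)
    cfg = PipelineConfig(**raw, simulation=sim)
    return cfg


def validate_config(path: str) -> list[str]:
    """Return all schema violations at once (empty list means ok)."""
    errors: list[str] = []
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except OSError as exc:
        return [f"unreadable config file: {exc}"]
    except yaml.YAMLError as exc:
        return [f"malformed YAML: {exc}"]
    if raw is None:
        return ["empty config file"]
    if not isinstance(raw, dict):
        return ["config must be a mapping"]
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
    for key in raw:
        if key not in known:
            errors.append(f"unknown key: {key}")
    sim_raw = raw.get("simulation") or {}
    if not isinstance(sim_raw, dict):
        errors.append("simulation section must be a mapping")
        sim_raw = {}
    for key in sim_raw:
        if key not in sim_known:
            errors.append(f"unknown key: simulation.{key}")
    if "nperm" in raw and (not isinstance(raw["nperm"], int) or raw["nperm"] < 1):
        errors.append("nperm must be a positive integer")
    if "seed" in raw and not isinstance(raw["seed"], int):
        errors.append("seed must be an integer")
    for prob_key in ("max_fdr", "transitional_band"):
        if prob_key in raw:
            try:
                v = float(raw[prob_key])
                if not 0 <= v <= 1:
                    errors.append(f"{prob_key} must lie in [0, 1]")
            except (TypeError, ValueError):
                errors.append(f"{prob_key} must be a number")
    if not raw.get("simulate", True):
        for needed in ("counts", "samples"):
            if not raw.get(needed):
                errors.append(f"{needed} path is required when simulate is false")
    if errors:
        return errors
    try:
        SimulationConfig(**sim_raw)
    except (TypeError, ValueError) as exc:
        errors.append(f"simulation: {exc}")
    return errors


def _file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest dict. Partial outputs are
    retained on failure and the manifest records the failure point."""
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "tool": "myoquiesce",
        "version": __version__,
        "seed": config.seed,
        "rng_algorithm": RNG_ALGORITHM,
        "config": _config_echo(config),
        "inputs": {},
        "stages": {},
    }
    provenance = [f"myoquiesce {__version__}", f"seed {config.seed}"]
    t_start = time.perf_counter()

    def stage_done(name: str) -> None:
        manifest["stages"][name] = "ok"
        logger.info("stage %s done (%.1f s elapsed)", name, time.perf_counter() - t_start)

    try:
        # ------------------------------------------------------------ inputs
        truth = None
        gene_sets: GeneSetCollection | None = None
        if config.simulate:
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            cohort = simulate_cohort(sim_cfg)
            counts, samples, ct = cohort.counts, cohort.samples, cohort.ct
            truth = cohort
            gene_sets = make_gene_sets(cohort.gene_truth, rng=np.random.default_rng(config.seed + 1))
        else:
            for path, label in ((config.counts, "counts"), (config.samples, "samples")):
                if path is None or not os.path.exists(path):
                    raise FileNotFoundError(f"{label} file not found: {path}")
                manifest["inputs"][label] = _file_sha256(path)
            counts = read_counts(config.counts)
            samples = read_sample_table(config.samples)
            ct = None
            if config.ct:
                if not os.path.exists(config.ct):
                    raise FileNotFoundError(f"ct file not found: {config.ct}")
                manifest["inputs"]["ct"] = _file_sha256(config.ct)
                ct = read_ct_table(config.ct)
        if config.gmt:
            if not os.path.exists(config.gmt):
                raise FileNotFoundError(f"gmt file not found: {config.gmt}")
            manifest["inputs"]["gmt"] = _file_sha256(config.gmt)
            gene_sets = read_gmt(config.gmt)
        if config.simulate and gene_sets is not None:
            write_gmt(gene_sets, os.path.join(config.outdir, "sets.gmt"))
            write_table(samples, os.path.join(config.outdir, "samples.tsv"))
        stage_done("load")

        # --------------------------------------------------- reference labels
        samples = samples.set_index("sample_id", drop=False).loc[counts.samples]
        labels = samples.get("phenotype_label", pd.Series("", index=samples.index)).fillna("")
        reference = labels.isin(["Q", "NQ"])
        if reference.sum() < 4:
            raise ValueError("need >= 4 labeled reference samples (phenotype_label Q/NQ)")

        # ------------------------------------------------------- DE signature
        ref_ids = samples.index[reference].tolist()
        ref_counts = counts.subset_samples(ref_ids)
        batch = None
        if config.use_batch and "batch" in samples.columns:
            ref_batch = samples.loc[ref_ids, "batch"]
            if ref_batch.nunique() > 1:
                batch = ref_batch.to_numpy()
        de_res = test_de(ref_counts, labels[reference].to_numpy(), contrast=("NQ", "Q"),
                         batch=batch)
        signature = signature_filter(de_res, min_fc=config.min_fc, max_fdr=config.max_fdr)
        de_out = de_res.reset_index()
        de_out["passes_filter"] = de_out["gene"].isin(signature.genes)
        de_out["direction"] = np.where(
            de_out["gene"].isin(signature.up), "up",
            np.where(de_out["gene"].isin(signature.down), "down", ""))
        _write_tsv(de_out, os.path.join(config.outdir, "de.tsv"),
                   provenance + ["contrast NQ:Q on labeled reference samples"])
        if len(signature) < 2:
            raise ValueError("signature is empty; cannot fit the phenotyping PCA")
        stage_done("de")

        # ------------------------------------------------------ PCA phenotype
        factors = size_factors(counts)
        expr = log2_normalized(counts, factors).T  # samples x genes
        model = QuiescencePhenotyper(
            signature_genes=signature.genes, scale=config.scale_pca,
            transitional_band=config.transitional_band,
        ).fit(expr.loc[ref_ids], labels[reference].to_numpy())
        scores = project(model, expr)
        scores.insert(0, "sample_id", scores.index)
        calls = model.assign(scores["PC1"].to_numpy())
        pheno = pd.DataFrame({
            "sample_id": scores["sample_id"],
            "PC1": scores["PC1"],
            "phenotype_call": calls,
            "dist_to_NQ": np.abs(scores["PC1"] - model.centroids_["NQ"]),
            "dist_to_Q": np.abs(scores["PC1"] - model.centroids_["Q"]),
            "is_reference": reference.to_numpy(),
        })
        evr = model.explained_variance_ratio_
        _write_tsv(scores, os.path.join(config.outdir, "scores.tsv"),
                   provenance + [f"PC1 explained variance {evr[0]:.4f}"])

        clin_cols = {"ga_weeks", "contractions_raw", "dilation_cm", "membranes",
                     "triple_i", "spontaneous_onset", "provider_initiated"}
        clinical_corr = None
        if clin_cols.issubset(samples.columns):
            clin_scores = score_table(samples)
            clinical_corr = correlate_clinical(
                pd.Series(scores["PC1"].to_numpy(), index=scores["sample_id"]), clin_scores)
            manifest["clinical_correlations"] = {
                row["variable"]: None if pd.isna(row["rho"]) else round(row["rho"], 6)
                for _, row in clinical_corr.iterrows()
            }
        _write_tsv(pheno, os.path.join(config.outdir, "phenotypes.tsv"), provenance)
        manifest["pc1_explained_variance_ratio"] = round(float(evr[0]), 6)
        stage_done("pca")

        # --------------------------------------------------------- enrichment
        if gene_sets is not None and len(gene_sets):
            gsea_res = gsea(
                log2_normalized(counts, factors).loc[:, ref_ids], labels[reference].to_numpy(),
                gene_sets, nperm=config.nperm, size_min=config.gsea_size_min,
                size_max=config.gsea_size_max, seed=config.seed, group_a="NQ",
            )
        else:
            gsea_res = pd.DataFrame(columns=["set", "size", "es", "nes", "p", "q",
                                             "leading_edge"])
        _write_tsv(gsea_res, os.path.join(config.outdir, "gsea.tsv"),
                   provenance + [f"nperm {config.nperm}"])
        stage_done("gsea")

        # -------------------------------------------------------- ratio / ROC
        ratios = ratio_from_counts(counts)
        if ct is not None:
            qpcr = ratio_from_ct(ct)
            qpcr = qpcr.assign(numerator=np.nan, denominator=np.nan)
            ratios = pd.concat([ratios, qpcr[ratios.columns.intersection(qpcr.columns)]],
                               ignore_index=True)
        _write_tsv(ratios, os.path.join(config.outdir, "ratios.tsv"), provenance)

        rna = ratios[ratios["source"] == "rnaseq_raw"].set_index("sample_id")
        call_map = pd.Series(pheno["phenotype_call"].to_numpy(),
                             index=pheno["sample_id"])
        usable = call_map[call_map.isin(["Q", "NQ"])]
        roc_res = roc(rna.loc[usable.index, "ratio"].to_numpy(), usable.to_numpy())
        tau = config.threshold if config.threshold is not None else roc_res.threshold
        curve = roc_res.curve.copy()
        _write_tsv(curve, os.path.join(config.outdir, "roc.tsv"), provenance + [
            f"auc {roc_res.auc:.4f}", f"threshold {tau:.4f}",
            "rule: call NQ iff ratio <= threshold",
        ])
        manifest["rnaseq_auc"] = round(roc_res.auc, 6)
        manifest["rnaseq_threshold"] = round(tau, 6)
        stage_done("roc")

        # -------------------------------------------------------------- panel
        panels = []
        for anchor in (ANCHOR_NUMERATOR, ANCHOR_DENOMINATOR):
            panel = correlated_panel(log2_normalized(counts, factors), anchor,
                                     r_min=config.r_min)
            panel.insert(0, "anchor", anchor)
            panels.append(panel)
        panel_out = pd.concat(panels, ignore_index=True)
        _write_tsv(panel_out, os.path.join(config.outdir, "panel.tsv"),
                   provenance + [f"r_min {config.r_min}"])
        stage_done("panel")

        if truth is not None:
            truth_out = truth.gene_truth
            _write_tsv(truth_out, os.path.join(config.outdir, "truth.tsv"), provenance)
        manifest["status"] = "ok"
    except Exception as exc:  # record the failure point, keep partial outputs
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(manifest, config.outdir)
        raise
    _write_manifest(manifest, config.outdir)
    return manifest


def _config_echo(config: PipelineConfig) -> dict:
    echo = dataclasses.asdict(config)
    echo["simulation"] = config.simulation.to_dict()
    return echo


def _write_manifest(manifest: dict, outdir: str) -> None:
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
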