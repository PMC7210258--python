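"""Config-driven orchestration: simulate/load -> QC -> estimate -> calls -> context.

A single :class:`PipelineConfig` (YAML-serializable) drives every stage;
all randomness flows through the one seed it carries. The result bundle
holds every intermediate table plus per-stage probe counts, and
:func:`run_pipeline` can write the bundle to disk with a reproducibility
manifest (config, seed, versions).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import context as ctx
from . import differential as diff
from . import hmc, io, preprocess, synthetic
from .datamodel import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "detp": 0.01,          # detection p-value cutoff per cell
    "max_fail_frac": 0.10, # probe removed if failing in more than this fraction of samples
    "peak_delta": 0.10,    # minimum BS-oxBS delta for a 5hmC peak
    "dhmp_delta": 0.20,    # minimum |delta beta| for a DhMP/DMP call
    "region_delta": 0.10,  # delta threshold for region membership
    "alpha": 0.05,         # FDR significance level
    "maxgap": 1000,        # bp between consecutive region CpGs
    "min_cpgs": 3,         # minimum CpGs per region
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    seed: int = 1
    simulation: dict = field(default_factory=dict)   # kwargs of the simulator
    inputs: dict = field(default_factory=dict)       # or: paths to on-disk inputs
    thresholds: dict = field(default_factory=dict)
    contrasts: list = field(default_factory=lambda: [
        ("differentiating", "proliferative"),
        ("ifc", "proliferative"),
        ("ifc", "differentiating"),
    ])
    normalize: bool = False

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        unknown = set(self.thresholds) - set(merged)
        if unknown:
            raise ValidationError(f"unknown thresholds: {sorted(unknown)}")
        merged.update(self.thresholds)
        self.thresholds = merged
        if not self.contrasts:
            raise ValidationError("at least one contrast is required")
        self.contrasts = [tuple(c) for c in self.contrasts]
        t = self.thresholds
        if not (0 < t["detp"] < 1 and 0 < t["max_fail_frac"] < 1):
            raise ValidationError("detp and max_fail_frac must be in (0, 1)")
        if not (0 <= t["alpha"] <= 1):
            raise ValidationError("alpha must be in [0, 1]")
        if t["maxgap"] < 1 or t["min_cpgs"] < 1:
            raise ValidationError("maxgap and min_cpgs must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contrasts"] = [list(c) for c in self.contrasts]
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute all stages in order and return the result bundle.

    The bundle maps stage names to their tables; ``bundle["counts"]``
    records per-stage probe counts (input, post-QC, testable, significant,
    regions per contrast). When ``out_dir`` is given the tables are
    written as TSV/BED with a JSON manifest.
    """
    counts: dict = {}
    bundle: dict = {"config": config, "counts": counts}

    # --- data ------------------------------------------------------------
    if config.inputs:
        annotation = _load_inputs_annotation(config.inputs)
        bs = io.load_beta_matrix(config.inputs["beta_bs"], config.inputs["detp_bs"],
                                 coverage=config.inputs.get("coverage_bs", 1000), channel="BS")
        oxbs = io.load_beta_matrix(config.inputs["beta_oxbs"], config.inputs["detp_oxbs"],
                                   coverage=config.inputs.get("coverage_oxbs", 1000), channel="oxBS")
        sheet = io.load_sample_sheet(config.inputs["samples"])
        truth = None
    else:
        sim_kwargs = dict(config.simulation)
        n_genes = sim_kwargs.pop("n_genes", 50)
        chrom_length = sim_kwargs.pop("chrom_length", 5_000_000)
        sim_config = synthetic.SimulationConfig(seed=config.seed, **sim_kwargs)
        annotation, truth, bs, oxbs, sheet = _simulate(sim_config, n_genes, chrom_length)
        bundle["truth"] = truth
    bundle.update(annotation=annotation, sample_sheet=sheet)
    counts["input_probes"] = bs.n_probes
    logger.info("input: %d probes, %d samples", bs.n_probes, bs.n_samples + oxbs.n_samples)

    # --- QC / normalization ----------------------------------------------
    t = config.thresholds
    bs, oxbs, removal = _qc(bs, oxbs, t)
    bundle["qc_report"] = removal
    counts["post_qc_probes"] = bs.n_probes
    if config.normalize:
        bs = preprocess.normalize_stratified_quantile(bs)
        oxbs = preprocess.normalize_stratified_quantile(oxbs)
    bundle.update(bs=bs, oxbs=oxbs)

    # --- estimation -------------------------------------------------------
    delta, estimate, loss = _estimate(bs, oxbs, sheet)
    bundle.update(delta=delta, estimate=estimate, global_hmc_loss=loss)

    # --- peaks ------------------------------------------------------------
    peaks = _peaks(delta, sheet, t)
    bundle["peaks"] = peaks
    counts["peaks"] = {cond: int(grp["is_peak"].sum())
                       for cond, grp in peaks.groupby("condition")}

    # --- differential -----------------------------------------------------
    design = estimate.pairs["condition"]
    oxbs_sheet = sheet[sheet["channel"] == "oxBS"]
    m_design = pd.Series(oxbs_sheet["condition"].to_numpy(), index=oxbs_sheet["sample_id"])
    probes = estimate.probes
    dhmp, dmp, regions = {}, {}, {}
    for target, reference in config.contrasts:
        key = f"{target}_vs_{reference}"
        dh = _differential(estimate.h_hat, design, (target, reference), t)
        dm = _differential(oxbs.beta, m_design, (target, reference), t)
        for frame in (dh, dm):
            frame.insert(0, "chrom", probes["chrom"])
            frame.insert(1, "pos", probes["pos"])
        region_member = dh["testable"] & (dh["fdr"] < t["alpha"]) & (
            dh["delta_beta"].abs() >= t["region_delta"])
        positions = dh.assign(significant=region_member)
        regions[key] = diff.call_regions(positions, maxgap=t["maxgap"], min_cpgs=t["min_cpgs"])
        dhmp[key], dmp[key] = dh, dm
        counts[key] = {
            "testable": int(dh["testable"].sum()),
            "dhmp": int(dh["significant"].sum()),
            "dmp": int(dm["significant"].sum()),
            "regions": len(regions[key]),
        }
        logger.info("contrast %s: %s", key, counts[key])
    bundle.update(dhmp=dhmp, dmp=dmp, regions=regions)

    # --- genomic context --------------------------------------------------
    bundle.update(_context(estimate, annotation, design, dhmp, t))

    if out_dir is not None:
        bundle["paths"] = _write(bundle, config, out_dir)
    return bundle


@_stage("simulate")
def _simulate(sim_config, n_genes, chrom_length):
    return synthetic.simulate_dataset(sim_config, n_genes=n_genes, chrom_length=chrom_length)


@_stage("qc")
def _qc(bs, oxbs, t):
    return preprocess.filter_probes(bs, oxbs, detp_threshold=t["detp"],
                                    sample_frac=t["max_fail_frac"])


@_stage("estimate")
def _estimate(bs, oxbs, sheet):
    delta = hmc.naive_delta(bs, oxbs, sheet)
    estimate = hmc.estimate_methylome(bs, oxbs, sheet)
    loss = hmc.global_hmc_loss(bs, oxbs, sheet)
    return delta, estimate, loss


@_stage("peaks")
def _peaks(delta, sheet, t):
    return hmc.call_hmc_peaks(delta, sheet, min_delta=t["peak_delta"], alpha=t["alpha"])


@_stage("differential")
def _differential(values, design, contrast, t):
    return diff.differential_positions(values, design, contrast,
                                       delta_min=t["dhmp_delta"], alpha=t["alpha"])


@_stage("context")
def _context(estimate, annotation, design, dhmp, t):
    probe_context = ctx.annotate_positions(estimate.probes, annotation)
    summary, tests = ctx.gene_body_summary(estimate, annotation, context=probe_context)
    enrichment = {}
    for key, dh in dhmp.items():
        fg = dh.index[dh["significant"].astype(bool)]
        if len(fg):
            enrichment[key] = ctx.enrichment_vs_background(
                fg, dh.index, probe_context["feature"])
    metagene = {}
    for cond in design.unique():
        cols = design.index[design == cond]
        signal = estimate.h_hat[cols].mean(axis=1)
        metagene[cond] = ctx.metagene_profile(signal, estimate.probes, annotation)
    return {
        "probe_context": probe_context,
        "gene_body_summary": summary,
        "gene_body_tests": tests,
        "enrichment": enrichment,
        "metagene": metagene,
    }


def _load_inputs_annotation(inputs):
    return io.load_annotation(inputs["gff"], inputs["cgi"], inputs["states"],
                              inputs["gene_sets"], inputs.get("chrom_sizes"))


@_stage("write")
def _write(bundle, config, out_dir):
    tables = {
        "qc_report": bundle["qc_report"],
        "global_hmc_loss": bundle["global_hmc_loss"].to_frame(),
        "peaks": bundle["peaks"],
        "gene_body_summary": bundle["gene_body_summary"],
        "gene_body_tests": bundle["gene_body_tests"],
    }
    for key, frame in bundle["dhmp"].items():
        tables[f"dhmp_{key}"] = frame
    for key, frame in bundle["dmp"].items():
        tables[f"dmp_{key}"] = frame
    for key, frame in bundle["regions"].items():
        tables[f"regions_{key}"] = frame
    for key, frame in bundle["enrichment"].items():
        tables[f"enrichment_{key}"] = frame
    for cond, profiles in bundle["metagene"].items():
        for gs, frame in profiles.items():
            tables[f"metagene_{cond}_{gs}"] = frame
    manifest = {"config": config.to_dict(), "config_digest": config.digest(),
                "seed": config.seed, "counts": _jsonable(bundle["counts"])}
    return io.write_results(tables, out_dir, manifest=manifest)


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=str))
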