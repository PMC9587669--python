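"""End-to-end orchestration: simulate -> SE calling -> signatures ->
expression/dependency/survival statistics -> GSEA -> synergy.

One YAML config drives everything; all randomness flows from its single
seed. Stages whose inputs are absent are skipped with a log entry, and a
machine-readable manifest (artifact paths, sha256 checksums, config
snapshot) is written at the end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from .core import GeneSignature, SurvivalTable
from .expression import (
    dependency_fraction,
    differential_expression,
    gsea_multi,
    gsva_scores,
    signature_enrichment_fractions,
)
from .se_calling import SuperEnhancerCaller, build_te_control_signature
from .signatures import (
    NC_CONTRAST,
    SUBTYPE_CONTRAST,
    VSECriteria,
    filter_vse,
    intersect_signatures,
    recurrent_signature,
)
from .simulate import SimulationConfig, generate_survival, simulate_study
from .survival import median_split_logrank
from .synergy import combination_table, median_effect_fit

logger = logging.getLogger("secircuit")


def _build(cls, data: dict, context: str):
    """Construct a dataclass from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{context}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            if dataclasses.is_dataclass(f.type) or (
                isinstance(f.default_factory, type)
                and dataclasses.is_dataclass(f.default_factory)
            ):
                v = _build(f.default_factory, v, f"{context}.{f.name}")
            kwargs[f.name] = v
    return cls(**kwargs)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    seed: int = 0
    outdir: str = "secircuit_out"
    stitch_distance: int = 12_500
    promoter_flank: int = 2_500
    gene_window: int = 50_000
    recurrence_min_lines: int = 3
    nc_enrichment_log2fc_cut: float = 1.0
    subtype_enrichment_log2fc_cut: float = 0.5
    enrichment_fdr_cut: float = 0.05
    ceres_cut: float = -0.1
    gsea_n_perm: int = 1_000
    gsea_weight_p: float = 1.0
    vse: VSECriteria = field(default_factory=VSECriteria)
    simulate: SimulationConfig | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulate", None)
        cfg = _build(cls, data, "pipeline")
        if sim is not None:
            sim_cfg = _build(SimulationConfig, {**sim, "seed": data.get("seed", 0)},
                             "pipeline.simulate")
            cfg = dataclasses.replace(cfg, simulate=sim_cfg)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage whose inputs exist; return the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    skipped: list[str] = []

    if config.simulate is None:
        sim_cfg = SimulationConfig(seed=config.seed)
    else:
        sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
    logger.info("[simulate] generating synthetic study (seed=%d)", sim_cfg.seed)
    study = simulate_study(sim_cfg)

    # --- SE calling per cell line ------------------------------------------
    per_line_sets: dict[str, set[str]] = {}
    caller = SuperEnhancerCaller(
        stitch_distance=config.stitch_distance,
        promoter_flank=config.promoter_flank,
        gene_window=config.gene_window,
    )
    te_control = None
    for line, peaks in study.chipseq.items():
        logger.info("[call-se] %s: %d peaks", line, len(peaks))
        caller.fit(peaks, tss_table=study.annotation)
        per_line_sets[line] = set(caller.se_genes_)
        table_path = outdir / f"enhancers_{line}.tsv"
        sio.write_enhancer_table(
            caller.enhancers_, table_path, bed_path=outdir / f"se_{line}.bed"
        )
        artifacts += [table_path, outdir / f"se_{line}.bed"]
        if te_control is None:  # first line doubles as the TE-control donor
            te_control = build_te_control_signature(
                caller.se_genes_, caller.te_genes_ranked_,
                name=f"{line}_TE_control",
            )

    # --- signatures ---------------------------------------------------------
    cse = recurrent_signature(per_line_sets, min_lines=config.recurrence_min_lines)
    tse = GeneSignature("tSE", frozenset(study.tissue_se_genes),
                        provenance="tissue-level SE gene list")
    ose = intersect_signatures(cse, tse, name="oSE")

    de_tables: dict[str, tuple[str, pd.DataFrame]] = {}
    for ds, matrix in study.expression.items():
        if ds in study.nc_datasets:
            de_tables[f"{ds}_nc"] = (
                NC_CONTRAST, differential_expression(matrix, "G3", "NC")
            )
        others = [g for g in matrix.groups.unique() if g not in {"G3", "NC"}]
        de_tables[f"{ds}_subtype"] = (
            SUBTYPE_CONTRAST, differential_expression(matrix, "G3", others)
        )

    vse, evidence = filter_vse(ose, de_tables, study.dependency, config.vse)
    gmt_path = outdir / "signatures.gmt"
    sio.write_gene_sets(
        {s.name: set(s.genes) for s in (cse, tse, ose, vse, te_control)}, gmt_path
    )
    evidence_path = outdir / "vse_evidence.tsv"
    evidence.to_csv(evidence_path, sep="\t")
    artifacts += [gmt_path, evidence_path]

    # --- enrichment fractions ----------------------------------------------
    frac_rows = []
    for ds_key, (contrast, de) in de_tables.items():
        cut = (config.nc_enrichment_log2fc_cut if contrast == NC_CONTRAST
               else config.subtype_enrichment_log2fc_cut)
        for sig in (cse, tse, ose):
            _, frac = signature_enrichment_fractions(
                de, sig, log2fc_cut=cut, fdr_cut=config.enrichment_fdr_cut
            )
            frac_rows.append({"dataset": ds_key, "signature": sig.name,
                              "fraction_up": frac})
    dep_frac = dependency_fraction(study.dependency, ose, ceres_cut=config.ceres_cut)
    frac_path = outdir / "enrichment_fractions.tsv"
    pd.DataFrame(frac_rows).to_csv(frac_path, sep="\t", index=False)
    dep_path = outdir / "dependency_fractions.tsv"
    dep_frac.rename("fraction_dependent").to_csv(dep_path, sep="\t")
    artifacts += [frac_path, dep_path]

    # --- GSVA scoring + survival -------------------------------------------
    first_ds = study.nc_datasets[0] if study.nc_datasets else next(iter(study.expression))
    matrix = study.expression[first_ds]
    scores = gsva_scores(matrix, [ose])
    scores_path = outdir / "gsva_scores.tsv"
    scores.to_csv(scores_path, sep="\t")
    artifacts.append(scores_path)

    surv = generate_survival(sim_cfg, scores.loc["oSE"])
    result, labels = median_split_logrank(surv)
    surv_path = outdir / "survival.json"
    surv_path.write_text(json.dumps({
        "logrank_chi2": result.statistic, "logrank_p": result.p,
        "n_high": int((labels == "high").sum()),
        "n_low": int((labels == "low").sum()),
    }, indent=2))
    sio.write_survival_table(surv, outdir / "survival_table.tsv")
    artifacts += [surv_path, outdir / "survival_table.tsv"]

    # --- GSEA of the drug-perturbed design ----------------------------------
    de_drug = differential_expression(study.treatment, "treated", "control")
    sets = {s.name: set(s.genes) for s in (cse, tse, ose, vse, te_control)
            if len(s.genes) >= 2}
    gsea_res = gsea_multi(
        de_drug["log2fc"], sets,
        weight_p=config.gsea_weight_p, n_perm=config.gsea_n_perm,
        seed=config.seed,
    )
    gsea_path = outdir / "gsea.tsv"
    pd.DataFrame([dataclasses.asdict(r) for r in gsea_res.values()]).to_csv(
        gsea_path, sep="\t", index=False
    )
    artifacts.append(gsea_path)

    # --- synergy -------------------------------------------------------------
    dr = study.dose_response
    if dr:
        fits = {
            drug: median_effect_fit(
                dr[f"single_{drug}"]["dose"], dr[f"single_{drug}"]["viability"],
                drug_id=drug,
            )
            for drug in ("drug1", "drug2")
        }
        ci = combination_table(fits["drug1"], fits["drug2"], dr["combination"])
        fits_path = outdir / "median_effect_fits.json"
        fits_path.write_text(json.dumps(
            {d: dataclasses.asdict(f) for d, f in fits.items()}, indent=2
        ))
        ci_path = outdir / "combination_index.tsv"
        ci.to_csv(ci_path, sep="\t", index=False)
        artifacts += [fits_path, ci_path]
    else:
        logger.info("[synergy] no dose-response inputs; stage skipped")
        skipped.append("synergy")

    manifest = {
        "config": dataclasses.asdict(config),
        "skipped_stages": skipped,
        "artifacts": {
            str(p.relative_to(outdir)): _sha256(p) for p in artifacts
        },
        "summary": {
            "n_cse": len(cse), "n_tse": len(tse),
            "n_ose": len(ose), "n_vse": len(vse),
            "logrank_p": result.p,
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("[done] manifest at %s", manifest_path)
    return manifest
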