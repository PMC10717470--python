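"""End-to-end orchestration: simulate/load -> QC -> matrices -> fits ->
ratios -> LR validation -> model comparison, driven by one YAML config.

Outputs are a pure function of (input files, config, seeds): every
stochastic stage draws from a named seed recorded in the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .compare import comparison_report
from .grm import (
    InbreedingVector,
    additive_grm,
    dominance_grm,
    epistatic_grm,
    genomic_inbreeding,
    pedigree_inbreeding,
)
from .pedigree import Pedigree, simulate_pedigree
from .qc import allele_frequencies, apply_qc, read_genotypes
from .reml import (
    MODEL_CATALOGUE,
    PhenotypeTable,
    build_design,
    fit_reml,
    model_spec,
    variance_ratios,
)
from .simulate import SimulationTruth, simulate_genotypes, simulate_phenotypes
from .validation import cross_validate, make_folds

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration (see `RunConfig.from_yaml`)."""

    models: list[str]
    output_dir: str
    seed: int = 0
    simulation: dict | None = None
    genotype_path: str | None = None
    genotype_dialect: str = "tsv"
    phenotype_path: str | None = None
    pedigree_path: str | None = None
    trait: str = "y"
    factors: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    qc: dict = field(default_factory=dict)
    inbreeding_source: str = "genomic"
    cv_folds: int = 0
    cv_seed: int = 0
    reference_model: str | None = None
    fit_options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in self.models:
            if m not in MODEL_CATALOGUE:
                raise ValueError(f"unknown model {m!r} in config")
        if self.simulation is None and (self.genotype_path is None or self.phenotype_path is None):
            raise ValueError("config needs either a simulation block or genotype+phenotype paths")
        if self.inbreeding_source not in ("pedigree", "genomic"):
            raise ValueError("inbreeding_source must be 'pedigree' or 'genomic'")
        if self.reference_model is None:
            self.reference_model = self.models[0]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _simulate_inputs(cfg: RunConfig):
    sim = dict(cfg.simulation or {})
    ped_block = sim.pop("pedigree", None)
    pedigree = None
    if ped_block:
        pedigree = simulate_pedigree(seed=cfg.seed, **ped_block)
    truth = SimulationTruth(
        true_variances=sim.get("true_variances", {"additive": 0.3, "residual": 0.7}),
        inbreeding_depression_b=sim.get("inbreeding_depression_b", 0.0),
        fixed_effect_values=sim.get("fixed_effect_values", {}),
        records_per_animal=sim.get("records_per_animal", 1),
        seed=cfg.seed,
    )
    genotypes = simulate_genotypes(
        pedigree if pedigree is not None else sim.get("n_individuals", 200),
        n_snps=sim.get("n_snps", 1000),
        mode=sim.get("mode", "gene_drop" if pedigree is not None else "hwe"),
        missing_rate=sim.get("missing_rate", 0.0),
        seed=cfg.seed + 1,
    )
    phenotypes, _ = simulate_phenotypes(
        genotypes, truth, pedigree=pedigree, seed=cfg.seed + 2
    )
    return genotypes, phenotypes, pedigree, truth


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every configured stage; returns the output directory."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("epiblup")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(cfg, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, outdir: Path) -> Path:
    truth = None
    pedigree = None
    if cfg.simulation is not None:
        genotypes, phenotypes, pedigree, truth = _simulate_inputs(cfg)
    else:
        genotypes = read_genotypes(cfg.genotype_path, cfg.genotype_dialect)
        df = pd.read_csv(cfg.phenotype_path, sep="\t", dtype={"animal_id": str})
        phenotypes = PhenotypeTable(df, cfg.trait, cfg.factors, cfg.covariates)
        if cfg.pedigree_path:
            pedigree = Pedigree.read_csv(cfg.pedigree_path)

    genotypes, qc_report = apply_qc(genotypes, **cfg.qc)
    (outdir / "qc_report.txt").write_text(qc_report.to_text() + "\n")

    # keep only genotyped animals' records
    keep = phenotypes.data["animal_id"].astype(str).isin(genotypes.sample_ids)
    phenotypes = PhenotypeTable(
        phenotypes.data.loc[keep].reset_index(drop=True),
        phenotypes.trait, phenotypes.factors, phenotypes.covariates,
    )

    freqs = allele_frequencies(genotypes)
    needed = {k for m in cfg.models for k in _kinds_for(m)}
    matrices = {}
    ga = additive_grm(genotypes, freqs)
    matrices["A"] = ga
    if {"D", "AD", "DD"} & needed:
        matrices["D"] = dominance_grm(genotypes, freqs)
    if "AA" in needed:
        matrices["AA"] = epistatic_grm(ga, ga, "AA")
    if "AD" in needed:
        matrices["AD"] = epistatic_grm(ga, matrices["D"], "AD")
    if "DD" in needed:
        matrices["DD"] = epistatic_grm(matrices["D"], matrices["D"], "DD")

    if cfg.inbreeding_source == "pedigree":
        if pedigree is None:
            raise ValueError("pedigree inbreeding requested but no pedigree available")
        ped_F = pedigree_inbreeding(pedigree)
        F_map = pd.Series(ped_F.F, index=ped_F.sample_ids)
        inbreeding = InbreedingVector(
            F_map.loc[genotypes.sample_ids].to_numpy(), "pedigree", list(genotypes.sample_ids)
        )
    else:
        inbreeding = genomic_inbreeding(ga)

    fits = []
    var_rows, ratio_rows = [], []
    for name in cfg.models:
        spec = model_spec(name)
        ds = build_design(
            phenotypes, spec, matrices, inbreeding if spec.use_inbreeding else None
        )
        fit = fit_reml(ds, spec, **cfg.fit_options)
        fits.append(fit)
        for term in (*fit.term_labels, "residual"):
            var_rows.append(
                {
                    "model": name,
                    "term": term,
                    "estimate": fit.variances[term],
                    "se": fit.standard_errors[term],
                    "converged": fit.converged,
                }
            )
        vr = variance_ratios(fit, "total_genetic_extras")
        row = {"model": name}
        for term, (est, se) in vr.ratios.items():
            row[f"h2_{term}"] = est
            row[f"h2_{term}_se"] = se
        if vr.d_over_g:
            row["d_over_g"] = vr.d_over_g[0]
        if vr.aa_over_g:
            row["aa_over_g"] = vr.aa_over_g[0]
        ratio_rows.append(row)

    pd.DataFrame(var_rows).to_csv(outdir / "variance_components.tsv", sep="\t", index=False)
    pd.DataFrame(ratio_rows).to_csv(outdir / "variance_ratios.tsv", sep="\t", index=False)

    validation = None
    if cfg.cv_folds >= 2:
        folds = make_folds(genotypes.sample_ids, cfg.cv_folds, cfg.cv_seed)
        validation = {}
        val_frames = []
        for fit in fits:
            if not fit.converged:
                continue
            stats = cross_validate(
                phenotypes,
                fit.spec,
                matrices,
                inbreeding if fit.spec.use_inbreeding else None,
                folds,
                accuracy_inbreeding=inbreeding,
                whole_fit=fit,
                **cfg.fit_options,
            )
            validation[fit.spec.name] = stats
            val_frames.append(stats.to_frame(fit.spec.name))
        pd.concat(val_frames).to_csv(outdir / "validation.tsv", sep="\t", index=False)

    report = comparison_report(fits, cfg.reference_model, validation)
    report.write_tsv(outdir)

    manifest = {
        "software": "epiblup",
        "version": __version__,
        "seed": cfg.seed,
        "cv_seed": cfg.cv_seed,
        "models": cfg.models,
        "non_converged": report.non_converged,
        "config_hash": hashlib.sha256(
            json.dumps(cfg.__dict__, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    if truth is not None:
        manifest["simulation_truth"] = json.loads(truth.to_json())
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir


def _kinds_for(model_name: str) -> set[str]:
    from .reml import TERM_KINDS

    spec = model_spec(model_name)
    return {TERM_KINDS[t] for t in spec.random_terms if TERM_KINDS[t] != "IDENTITY"}
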