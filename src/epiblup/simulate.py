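"""Synthetic genotype and phenotype generation with known truth.

Genotypes are drawn either independently under Hardy-Weinberg
proportions or by gene-dropping founder alleles through a pedigree
(which creates identity-by-descent consistent with pedigree inbreeding).
Phenotypes are composed exactly as the fitted models assume:

    y = X beta + f b + Z a + Z d + Z e_aa (+ ad, dd) + Z pe + eps,

with every genetic vector drawn from a zero-mean multivariate normal
whose covariance is the corresponding genomic relationship matrix times
its true variance. Simulating from the model's own covariance
structures (rather than per-SNP effect draws) keeps the fitted model
correctly specified, which makes parameter recovery a clean test
surface. Repeated records share the animal's genetic and permanent
environmental values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grm import (
    additive_grm,
    dominance_grm,
    epistatic_grm,
    genomic_inbreeding,
    pedigree_inbreeding,
    symmetric_factor,
)
from .pedigree import Pedigree
from .qc import MISSING, GenotypeMatrix, allele_frequencies
from .reml import GENETIC_TERMS, PhenotypeTable

_TERM_ORDER = ("additive", "dominance", "aa", "ad", "dd", "pe", "residual")


@dataclass
class SimulationTruth:
    """Generating parameters of one synthetic trait.

    ``true_variances`` maps term labels (additive, dominance, aa, ad, dd,
    pe, residual) to variances in trait units; ``inbreeding_depression_b``
    is the phenotypic regression on the inbreeding coefficient (trait
    units per unit F). ``fixed_effect_values`` maps "factor:level" keys
    (or "intercept") to fixed-effect values.
    """

    true_variances: dict[str, float]
    inbreeding_depression_b: float = 0.0
    fixed_effect_values: dict[str, float] = field(default_factory=dict)
    records_per_animal: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for term, v in self.true_variances.items():
            if term not in _TERM_ORDER:
                raise ValueError(f"unknown variance term {term!r}")
            if v < 0:
                raise ValueError(f"variance of {term!r} must be non-negative")
        if self.true_variances.get("residual", 0.0) <= 0:
            raise ValueError("residual variance must be positive")
        if self.records_per_animal < 1:
            raise ValueError("records_per_animal must be positive")
        if self.true_variances.get("pe", 0.0) == 0 and self.records_per_animal != 1:
            raise ValueError("repeated records require a permanent environmental variance")

    def variance(self, term: str) -> float:
        return float(self.true_variances.get(term, 0.0))

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_variances": self.true_variances,
                "inbreeding_depression_b": self.inbreeding_depression_b,
                "fixed_effect_values": self.fixed_effect_values,
                "records_per_animal": self.records_per_animal,
                "seed": self.seed,
            },
            indent=2,
        )


def default_freq_sampler(rng: np.random.Generator, size: int) -> np.ndarray:
    """Uniform(0.05, 0.5) allele frequencies: all SNPs clear a 1% MAF filter."""
    return rng.uniform(0.05, 0.5, size=size)


def simulate_genotypes(
    target: Pedigree | int,
    n_snps: int,
    freq_sampler=None,
    mode: str = "hwe",
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate biallelic genotypes under HWE or by pedigree gene-dropping.

    ``hwe`` draws each call Binomial(2, p_j) independently; ``gene_drop``
    assigns two founder alleles per SNP (Bernoulli(p_j)) and transmits one
    random parental allele per meiosis down the pedigree, creating
    identity-by-descent consistent with pedigree inbreeding.
    """
    if n_snps <= 0:
        raise ValueError("n_snps must be positive")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    if mode not in ("hwe", "gene_drop"):
        raise ValueError("mode must be 'hwe' or 'gene_drop'")
    if mode == "gene_drop" and not isinstance(target, Pedigree):
        raise ValueError("gene_drop mode requires a Pedigree")

    rng = np.random.default_rng(seed)
    if freq_sampler is None:
        freq_sampler = default_freq_sampler
    p = np.asarray(freq_sampler(rng, n_snps), dtype=float)
    if ((p <= 0.0) | (p >= 1.0)).any():
        raise ValueError("freq_sampler must emit frequencies strictly inside (0, 1)")

    if isinstance(target, Pedigree):
        sample_ids = target.animal_ids
        n = target.n_animals
    else:
        n = int(target)
        if n < 1:
            raise ValueError("n_individuals must be positive")
        sample_ids = [f"I{i + 1:05d}" for i in range(n)]

    if mode == "hwe":
        calls = rng.binomial(2, p, size=(n, n_snps)).astype(np.int8)
    else:
        index = {a: i for i, a in enumerate(sample_ids)}
        alleles = np.zeros((n, 2, n_snps), dtype=np.int8)
        for animal, sire, dam in target.records:
            i = index[animal]
            for slot, parent in enumerate((sire, dam)):
                if parent is None:
                    alleles[i, slot] = rng.random(n_snps) < p
                else:
                    pick = rng.integers(0, 2, size=n_snps)
                    alleles[i, slot] = alleles[index[parent], pick, np.arange(n_snps)]
        calls = alleles.sum(axis=1).astype(np.int8)

    if missing_rate > 0:
        mask = rng.random((n, n_snps)) < missing_rate
        calls[mask] = MISSING
    snp_ids = [f"snp{j + 1:05d}" for j in range(n_snps)]
    return GenotypeMatrix(sample_ids, snp_ids, calls)


def _genetic_structures(genotypes: GenotypeMatrix, labels: list[str]) -> dict[str, np.ndarray]:
    """Relationship matrices needed for the requested genetic terms."""
    freqs = allele_frequencies(genotypes)
    out: dict[str, np.ndarray] = {}
    need_a = any(t in labels for t in ("additive", "aa", "ad"))
    need_d = any(t in labels for t in ("dominance", "ad", "dd"))
    ga = additive_grm(genotypes, freqs) if need_a else None
    gd = dominance_grm(genotypes, freqs) if need_d else None
    if "additive" in labels:
        out["additive"] = ga.values
    if "dominance" in labels:
        out["dominance"] = gd.values
    if "aa" in labels:
        out["aa"] = epistatic_grm(ga, ga, "AA").values
    if "ad" in labels:
        out["ad"] = epistatic_grm(ga, gd, "AD").values
    if "dd" in labels:
        out["dd"] = epistatic_grm(gd, gd, "DD").values
    return out


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    truth: SimulationTruth,
    pedigree: Pedigree | None = None,
    design: pd.DataFrame | None = None,
    seed: int | None = None,
) -> tuple[PhenotypeTable, dict[str, np.ndarray]]:
    """Simulate phenotypes on top of the given genotypes.

    Returns the phenotype table (with the per-animal inbreeding
    coefficient as covariate ``f``) and the true per-animal effect
    vectors for each simulated term (plus the per-record residual),
    for parameter- and prediction-recovery tests.

    ``design``, if given, holds one row per record with factor columns;
    factor-level effects are looked up in ``truth.fixed_effect_values``
    under ``"column:level"`` keys.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n = genotypes.n_individuals
    r = truth.records_per_animal
    n_rec = n * r

    genetic = [t for t in GENETIC_TERMS if truth.variance(t) > 0]
    structures = _genetic_structures(genotypes, genetic)

    true_effects: dict[str, np.ndarray] = {}
    for term in genetic:
        L = symmetric_factor(structures[term])
        true_effects[term] = np.sqrt(truth.variance(term)) * (
            L @ rng.standard_normal(n)
        )
    if truth.variance("pe") > 0:
        true_effects["pe"] = np.sqrt(truth.variance("pe")) * rng.standard_normal(n)

    if pedigree is not None:
        F = pedigree_inbreeding(pedigree).F
    else:
        ga = additive_grm(genotypes)
        F = genomic_inbreeding(ga).F

    animal_of_record = np.repeat(np.arange(n), r)
    y = np.full(n_rec, truth.fixed_effect_values.get("intercept", 0.0))
    factors: list[str] = []
    if design is not None:
        if len(design) != n_rec:
            raise ValueError(f"design must have {n_rec} rows (one per record)")
        factors = list(design.columns)
        for col in factors:
            levels = design[col].astype(str)
            y += np.array(
                [truth.fixed_effect_values.get(f"{col}:{lev}", 0.0) for lev in levels]
            )
    y += truth.inbreeding_depression_b * F[animal_of_record]
    for term, u in true_effects.items():
        y += u[animal_of_record]
    residual = np.sqrt(truth.variance("residual")) * rng.standard_normal(n_rec)
    y += residual
    true_effects["residual"] = residual

    data = pd.DataFrame(
        {
            "record_id": [f"r{i + 1:06d}" for i in range(n_rec)],
            "animal_id": [genotypes.sample_ids[i] for i in animal_of_record],
            "y": y,
            "f": F[animal_of_record],
        }
    )
    if design is not None:
        for col in factors:
            data[col] = design[col].to_numpy()
    pt = PhenotypeTable(data, trait="y", factors=factors, covariates=[])
    return pt, true_effects


def save_dataset(
    outdir,
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    truth: SimulationTruth,
    pedigree: Pedigree | None = None,
) -> None:
    """Write genotype TSV, phenotype TSV, truth JSON and pedigree CSV."""
    from .qc import write_genotypes

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotypes(genotypes, outdir / "genotypes.tsv")
    phenotypes.write_tsv(outdir / "phenotypes.tsv")
    (outdir / "truth.json").write_text(truth.to_json() + "\n")
    if pedigree is not None:
        pedigree.write_csv(outdir / "pedigree.csv")
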