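"""Genotype storage, file dialects, allele frequencies and quality control.

Genotypes are stored as counts of the reference allele A1 (0/1/2) with a
sentinel for missing calls. QC applies the conventional marker filters —
call rate, minor allele frequency, and a 1-df chi-square test for extreme
Hardy-Weinberg departure — after an optional individual call-rate filter.
Filters are applied in a single pass: individuals first, then SNP filters,
each evaluated on the matrix as it enters that filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ComputationError, FormatError

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1

_VALID_CALLS = frozenset({-1, 0, 1, 2})


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs matrix of A1-allele counts with missingness.

    ``calls[i, j]`` is the number of copies of allele A1 carried by
    individual ``sample_ids[i]`` at marker ``snp_ids[j]``, or ``MISSING``.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        if self.calls.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if not np.isin(self.calls, (-1, 0, 1, 2)).all():
            bad = np.unique(self.calls[~np.isin(self.calls, (-1, 0, 1, 2))])
            raise ValueError(f"genotype calls outside {{0,1,2,MISSING}}: {bad}")
        self.calls = self.calls.astype(np.int8)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicated sample ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise FormatError("duplicated SNP ids")

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask.mean(axis=0)

    def individual_call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask.mean(axis=1)

    def subset(self, individuals=None, snps=None) -> "GenotypeMatrix":
        """Row/column subset by boolean mask or integer index array."""
        rows = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        cols = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        if cols.dtype == bool:
            cols = np.flatnonzero(cols)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in rows],
            [self.snp_ids[j] for j in cols],
            self.calls[np.ix_(rows, cols)],
        )


@dataclass
class AlleleFrequencySet:
    """Per-SNP frequency of allele A1, computed over non-missing calls."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.p, self.q)


@dataclass
class QCReport:
    """Per-filter removal tallies for one `apply_qc` pass."""

    n_individuals_in: int
    n_snps_in: int
    removed_individuals_call_rate: int = 0
    removed_snps_call_rate: int = 0
    removed_snps_monomorphic: int = 0
    removed_snps_maf: int = 0
    removed_snps_hwe: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def n_individuals_out(self) -> int:
        return self.n_individuals_in - self.removed_individuals_call_rate

    @property
    def n_snps_out(self) -> int:
        return self.n_snps_in - (
            self.removed_snps_call_rate
            + self.removed_snps_monomorphic
            + self.removed_snps_maf
            + self.removed_snps_hwe
        )

    def to_text(self) -> str:
        lines = [
            "genotype QC report",
            f"  individuals: {self.n_individuals_in} -> {self.n_individuals_out} "
            f"(call rate removed {self.removed_individuals_call_rate})",
            f"  SNPs: {self.n_snps_in} -> {self.n_snps_out}",
            f"    removed by call rate:   {self.removed_snps_call_rate}",
            f"    removed monomorphic:    {self.removed_snps_monomorphic}",
            f"    removed by MAF:         {self.removed_snps_maf}",
            f"    removed by HWE:         {self.removed_snps_hwe}",
            f"  thresholds: {self.thresholds}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genotypes(path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from ``tsv`` or ``plink_raw`` dialect.

    tsv: header row of SNP ids, first column sample id, cells 0/1/2 or NA.
    plink_raw: whitespace-separated PLINK ``--recode A`` export
    (FID IID PAT MAT SEX PHENOTYPE then one column per SNP, named
    ``<snp>_<counted allele>``); sample id taken from IID.

    Unparseable cells become MISSING, with the count logged.
    """
    if dialect == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        except pd.errors.ParserError as exc:
            raise FormatError(f"cannot parse genotype TSV {path}: {exc}") from exc
        sample_ids = [str(s) for s in df.index]
        snp_ids = [str(s) for s in df.columns]
        raw = df.to_numpy()
    elif dialect == "plink_raw":
        try:
            df = pd.read_csv(path, sep=r"\s+", dtype=str)
        except pd.errors.ParserError as exc:
            raise FormatError(f"cannot parse PLINK .raw {path}: {exc}") from exc
        meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if list(df.columns[: len(meta)]) != meta:
            raise FormatError(f"PLINK .raw header must start with {' '.join(meta)}")
        sample_ids = [str(s) for s in df["IID"]]
        snp_cols = list(df.columns[len(meta):])
        # strip the counted-allele suffix PLINK appends (e.g. snp1_A -> snp1)
        snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
        raw = df[snp_cols].to_numpy()
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")

    numeric = pd.to_numeric(pd.Series(raw.ravel()), errors="coerce").to_numpy()
    n_bad = int(np.isnan(numeric).sum() - pd.isna(raw.ravel()).sum())
    if n_bad > 0:
        logger.warning("%d unparseable genotype cells set to MISSING", n_bad)
    calls = np.where(np.isnan(numeric), MISSING, numeric).reshape(raw.shape)
    if not np.isin(calls, (-1, 0, 1, 2)).all():
        raise FormatError("genotype calls outside {0,1,2,NA}")
    return GenotypeMatrix(sample_ids, snp_ids, calls.astype(np.int8))


def write_genotypes(g: GenotypeMatrix, path, dialect: str = "tsv") -> None:
    """Companion writer to `read_genotypes` (lossless round-trip)."""
    vals = g.calls.astype(object)
    vals[g.calls == MISSING] = "NA"
    if dialect == "tsv":
        df = pd.DataFrame(vals, index=g.sample_ids, columns=g.snp_ids)
        df.to_csv(path, sep="\t", index_label="sample_id")
    elif dialect == "plink_raw":
        df = pd.DataFrame(vals, columns=[f"{s}_A" for s in g.snp_ids])
        df.insert(0, "PHENOTYPE", -9)
        df.insert(0, "SEX", 0)
        df.insert(0, "MAT", 0)
        df.insert(0, "PAT", 0)
        df.insert(0, "IID", g.sample_ids)
        df.insert(0, "FID", g.sample_ids)
        df.to_csv(path, sep=" ", index=False)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencySet:
    """A1 frequency per SNP: (sum of calls) / (2 x non-missing count)."""
    observed = g.calls != MISSING
    n_obs = observed.sum(axis=0)
    if (n_obs == 0).any():
        bad = [g.snp_ids[j] for j in np.flatnonzero(n_obs == 0)]
        raise ComputationError(f"all calls missing for SNP(s) {bad}")
    total = np.where(observed, g.calls, 0).sum(axis=0)
    return AlleleFrequencySet(total / (2.0 * n_obs))


def hwe_chi_square(counts) -> tuple[float, float]:
    """1-df goodness-of-fit chi-square against Hardy-Weinberg proportions.

    ``counts`` is the (n_AA, n_Aa, n_aa) genotype count triple; expected
    counts use the allele frequency observed in the same sample. No
    continuity correction is applied.
    """
    n_aa1, n_het, n_aa2 = counts
    if min(n_aa1, n_het, n_aa2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa1 + n_het + n_aa2
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_aa1 + n_het) / (2 * n)
    q = 1.0 - p
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    observed = np.array([n_aa1, n_het, n_aa2], dtype=float)
    if p in (0.0, 1.0):  # monomorphic: observed == expected by construction
        return 0.0, 1.0
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def hwe_p_values(g: GenotypeMatrix) -> np.ndarray:
    """Vector of HWE chi-square p-values, one per SNP."""
    out = np.empty(g.n_snps)
    for j in range(g.n_snps):
        col = g.calls[:, j]
        col = col[col != MISSING]
        counts = (int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum()))
        out[j] = hwe_chi_square(counts)[1]
    return out


def impute_mean(g: GenotypeMatrix, freqs: AlleleFrequencySet | None = None) -> np.ndarray:
    """Float dosage matrix with missing calls replaced by 2p (their mean)."""
    if freqs is None:
        freqs = allele_frequencies(g)
    dosage = g.calls.astype(float)
    miss = g.missing_mask
    dosage[miss] = np.broadcast_to(2.0 * freqs.p, g.calls.shape)[miss]
    return dosage


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def apply_qc(
    g: GenotypeMatrix,
    snp_call_rate_min: float = 0.90,
    maf_min: float = 0.01,
    hwe_p_min: float | None = 1e-5,
    individual_call_rate_min: float | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Single-pass genotype QC: individuals first, then SNP filters.

    SNP filters (call rate, monomorphism, MAF, HWE) are each evaluated on
    the matrix entering that filter, i.e. after individual removal.
    Monomorphic SNPs are always removed: they contribute nothing to any
    relationship-matrix denominator and break the dominance coding.
    """
    for name, thr in (
        ("snp_call_rate_min", snp_call_rate_min),
        ("maf_min", maf_min),
        ("hwe_p_min", hwe_p_min),
        ("individual_call_rate_min", individual_call_rate_min),
    ):
        if thr is not None and not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {thr}")

    report = QCReport(
        n_individuals_in=g.n_individuals,
        n_snps_in=g.n_snps,
        thresholds={
            "snp_call_rate_min": snp_call_rate_min,
            "maf_min": maf_min,
            "hwe_p_min": hwe_p_min,
            "individual_call_rate_min": individual_call_rate_min,
        },
    )

    if individual_call_rate_min is not None:
        keep = g.individual_call_rate() >= individual_call_rate_min
        report.removed_individuals_call_rate = int((~keep).sum())
        g = g.subset(individuals=keep)

    keep_snps = g.snp_call_rate() >= snp_call_rate_min
    report.removed_snps_call_rate = int((~keep_snps).sum())
    g = g.subset(snps=keep_snps)

    freqs = allele_frequencies(g) if g.n_snps else AlleleFrequencySet(np.empty(0))
    poly = (freqs.p > 0.0) & (freqs.p < 1.0)
    report.removed_snps_monomorphic = int((~poly).sum())
    g = g.subset(snps=poly)
    freqs = AlleleFrequencySet(freqs.p[poly])

    keep_maf = freqs.maf >= maf_min
    report.removed_snps_maf = int((~keep_maf).sum())
    g = g.subset(snps=keep_maf)

    if hwe_p_min is not None and g.n_snps:
        keep_hwe = hwe_p_values(g) >= hwe_p_min
        report.removed_snps_hwe = int((~keep_hwe).sum())
        g = g.subset(snps=keep_hwe)

    if g.n_snps == 0:
        raise ComputationError("QC removed every SNP")
    logger.info("%s", report.to_text())
    return g, report


class GenotypeQC(BaseEstimator, TransformerMixin):
    """Transformer-style wrapper around `apply_qc`.

    ``fit`` records nothing beyond parameters; ``transform`` filters a
    `GenotypeMatrix` and stores the resulting `QCReport` as ``report_``.
    """

    def __init__(
        self,
        snp_call_rate_min: float = 0.90,
        maf_min: float = 0.01,
        hwe_p_min: float | None = 1e-5,
        individual_call_rate_min: float | None = None,
    ):
        self.snp_call_rate_min = snp_call_rate_min
        self.maf_min = maf_min
        self.hwe_p_min = hwe_p_min
        self.individual_call_rate_min = individual_call_rate_min

    def fit(self, X: GenotypeMatrix, y=None):
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        filtered, self.report_ = apply_qc(
            X,
            snp_call_rate_min=self.snp_call_rate_min,
            maf_min=self.maf_min,
            hwe_p_min=self.hwe_p_min,
            individual_call_rate_min=self.individual_call_rate_min,
        )
        return filtered
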