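"""Genomic and pedigree relationship structures.

Builds the additive genomic relationship matrix (VanRaden centering),
the dominance matrix (Vitezica coding), and the epistatic matrices as
trace-normalized Hadamard products; computes pedigree inbreeding by the
tabular numerator-relationship recursion and genomic inbreeding as
diag(G_A) - 1.

Allele frequencies used for centering are the observed frequencies of
the analyzed sample, which makes the rows of G_A sum to zero exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ComputationError
from .pedigree import Pedigree
from .qc import AlleleFrequencySet, GenotypeMatrix, allele_frequencies, impute_mean

logger = logging.getLogger(__name__)

KINDS = ("A", "D", "AA", "AD", "DD", "IDENTITY")


@dataclass
class RelationshipMatrix:
    """Tagged symmetric covariance structure over a fixed animal ordering."""

    kind: str
    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match sample_ids")
        scale = max(np.abs(self.values).max(), 1.0)
        if np.abs(self.values - self.values.T).max() > 1e-10 * scale:
            raise ValueError("relationship matrix is not symmetric")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class InbreedingVector:
    """Per-animal inbreeding coefficients from pedigree or genomic source."""

    F: np.ndarray
    source: str
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.source not in ("pedigree", "genomic"):
            raise ValueError("source must be 'pedigree' or 'genomic'")
        if self.source == "pedigree" and ((self.F < 0) | (self.F >= 1)).any():
            raise ValueError("pedigree inbreeding must lie in [0, 1)")
        if self.source == "genomic" and (self.F < -1).any():
            raise ValueError("genomic inbreeding is bounded below by -1")

    @property
    def mean_F(self) -> float:
        return float(self.F.mean())


def identity_matrix(sample_ids: list[str]) -> RelationshipMatrix:
    return RelationshipMatrix("IDENTITY", np.eye(len(sample_ids)), list(sample_ids))


def additive_grm(
    g: GenotypeMatrix, freqs: AlleleFrequencySet | None = None
) -> RelationshipMatrix:
    """VanRaden additive GRM: G_A = MM' / (2 * sum p_i q_i).

    M holds (2-2p), (1-2p), (-2p) for the A1A1, A1A2, A2A2 genotypes, i.e.
    the dosage centered at 2p. Missing calls enter at their mean (2p),
    contributing zero after centering.
    """
    if freqs is None:
        freqs = allele_frequencies(g)
    p = freqs.p
    if not ((p > 0) & (p < 1)).any():
        raise ComputationError("no polymorphic SNP available for G_A")
    denom = 2.0 * float((p * (1.0 - p)).sum())
    if denom <= 0:
        raise ComputationError("sum p_i q_i is zero; cannot scale G_A")
    m = impute_mean(g, freqs) - 2.0 * p
    return RelationshipMatrix("A", (m @ m.T) / denom, list(g.sample_ids))


def dominance_grm(
    g: GenotypeMatrix, freqs: AlleleFrequencySet | None = None
) -> RelationshipMatrix:
    """Dominance GRM of Vitezica et al.: G_D = WW' / (4 * sum p_i^2 q_i^2).

    W holds (-2q^2), (2pq), (-2p^2) for A1A1, A1A2, A2A2; under HWE these
    have mean zero, so missing calls enter as zeros.
    """
    if freqs is None:
        freqs = allele_frequencies(g)
    p, q = freqs.p, freqs.q
    denom = 4.0 * float((p**2 * q**2).sum())
    if denom <= 0:
        raise ComputationError("sum p_i^2 q_i^2 is zero; cannot scale G_D")
    calls = g.calls
    w = np.zeros(calls.shape)
    w[calls == 2] = np.broadcast_to(-2.0 * q**2, calls.shape)[calls == 2]
    w[calls == 1] = np.broadcast_to(2.0 * p * q, calls.shape)[calls == 1]
    w[calls == 0] = np.broadcast_to(-2.0 * p**2, calls.shape)[calls == 0]
    return RelationshipMatrix("D", (w @ w.T) / denom, list(g.sample_ids))


_EPISTATIC_PARENTS = {"AA": ("A", "A"), "AD": ("A", "D"), "DD": ("D", "D")}


def epistatic_grm(
    left: RelationshipMatrix, right: RelationshipMatrix, kind: str
) -> RelationshipMatrix:
    """Hadamard-product epistatic GRM scaled so its trace equals n.

    G_AA = (G_A o G_A) / (tr(G_A o G_A)/n), and analogously for AD and DD.
    """
    if kind not in _EPISTATIC_PARENTS:
        raise ValueError(f"epistatic kind must be one of {tuple(_EPISTATIC_PARENTS)}")
    want = _EPISTATIC_PARENTS[kind]
    if (left.kind, right.kind) != want:
        raise ValueError(f"kind {kind} needs parents {want}, got ({left.kind}, {right.kind})")
    if left.sample_ids != right.sample_ids:
        raise ValueError("sample orderings of the two parent matrices differ")
    raw = left.values * right.values
    trace = float(np.trace(raw))
    if trace <= 0:
        raise ComputationError("raw Hadamard product has non-positive trace")
    n = left.n
    return RelationshipMatrix(kind, raw * (n / trace), list(left.sample_ids))


def pedigree_inbreeding(ped: Pedigree) -> InbreedingVector:
    """Pedigree inbreeding by the tabular numerator-relationship recursion.

    Builds A in topological order (founders unrelated and non-inbred) and
    returns F = diag(A) - 1, the Wright path-counting coefficients.
    """
    ids = ped.animal_ids
    index = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for i, (animal, sire, dam) in enumerate(ped.records):
        s = index[sire] if sire is not None else None
        d = index[dam] if dam is not None else None
        if s is not None and d is not None:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        for j in range(i):
            a_js = A[j, s] if s is not None else 0.0
            a_jd = A[j, d] if d is not None else 0.0
            A[i, j] = A[j, i] = 0.5 * (a_js + a_jd)
    return InbreedingVector(np.diag(A) - 1.0, "pedigree", list(ids))


def genomic_inbreeding(ga: RelationshipMatrix) -> InbreedingVector:
    """Genomic inbreeding as diag(G_A) - 1 (VanRaden-consistent)."""
    if ga.kind != "A":
        raise ValueError(f"genomic inbreeding requires an additive GRM, got kind {ga.kind}")
    return InbreedingVector(np.diag(ga.values) - 1.0, "genomic", list(ga.sample_ids))


def clip_psd(values: np.ndarray, rel_floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping.

    Eigenvalues below ``-rel_floor * lambda_max`` are treated as numerical
    noise (Hadamard products can be semidefinite only up to rounding); all
    negative eigenvalues are clipped at zero. The raw minimum eigenvalue
    is logged.
    """
    vals, vecs = np.linalg.eigh(np.asarray(values, dtype=float))
    lam_max = float(vals.max()) if vals.size else 0.0
    lam_min = float(vals.min()) if vals.size else 0.0
    if lam_min < -rel_floor * max(lam_max, 1.0):
        logger.warning("clipping negative eigenvalue %.3e (max %.3e)", lam_min, lam_max)
    else:
        logger.debug("minimum eigenvalue %.3e (max %.3e)", lam_min, lam_max)
    clipped = np.clip(vals, 0.0, None)
    return (vecs * clipped) @ vecs.T


def symmetric_factor(values: np.ndarray, rel_floor: float = 1e-8) -> np.ndarray:
    """L with LL' = PSD-clipped ``values``, via eigen-decomposition."""
    vals, vecs = np.linalg.eigh(np.asarray(values, dtype=float))
    lam_min = float(vals.min()) if vals.size else 0.0
    if lam_min < -rel_floor * max(float(vals.max()), 1.0):
        logger.warning("factorizing semidefinite matrix: clipped eigenvalue %.3e", lam_min)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def write_matrix_tsv(rm: RelationshipMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(rm.values, index=rm.sample_ids, columns=rm.sample_ids).to_csv(
        path, sep="\t", index_label=f"kind={rm.kind}"
    )


def read_matrix_tsv(path) -> RelationshipMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    kind = str(df.index.name).split("=", 1)[1] if "=" in str(df.index.name) else "A"
    return RelationshipMatrix(kind, df.to_numpy(), [str(c) for c in df.columns])


def write_inbreeding_tsv(iv: InbreedingVector, path) -> None:
    import pandas as pd

    pd.DataFrame({"animal_id": iv.sample_ids, "F": iv.F}).to_csv(path, sep="\t", index=False)
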