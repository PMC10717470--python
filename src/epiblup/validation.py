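"""Linear Regression (LR) method of predictive-ability assessment.

Breeding values predicted from a partial dataset (records of a fold of
animals set missing) are compared with those from the whole dataset:

    bias       mu_wp  = mean(u_p) - mean(u_w)
    dispersion b_w,p  = cov(u_p, u_w) / var(u_p)
    accuracy   acc_p  = sqrt( cov(u_p, u_w) / ((1 - F_bar) * sigma_a^2) )

where F_bar is the mean inbreeding coefficient of the masked animals and
sigma_a^2 the additive variance estimated from the whole data. Folding is
by animal (all of an animal's records masked together) and statistics are
computed over the masked animals only, which prevents leakage through
repeated records. Variance components are re-estimated in each partial
fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ComputationError
from .grm import InbreedingVector, RelationshipMatrix
from .reml import ModelSpec, PhenotypeTable, REMLFit, build_design, fit_reml

logger = logging.getLogger(__name__)


@dataclass
class FoldAssignment:
    """Partition of the animal set into k near-equal folds."""

    k: int
    fold_of: dict[str, int]
    seed: int

    def animals_in(self, fold: int) -> list[str]:
        return [a for a, f in self.fold_of.items() if f == fold]


@dataclass
class LRStats:
    """Bias, dispersion and accuracy of partial-vs-whole GEBV comparisons."""

    bias: float
    dispersion: float
    accuracy: float
    mean_F: float
    sigma_a2_whole: float
    per_fold: list["LRStats"] = field(default_factory=list)
    skipped_folds: list[int] = field(default_factory=list)

    def to_frame(self, model: str = "") -> pd.DataFrame:
        rows = [
            {
                "model": model,
                "fold": i,
                "bias": s.bias,
                "dispersion": s.dispersion,
                "accuracy": s.accuracy,
            }
            for i, s in enumerate(self.per_fold)
        ]
        rows.append(
            {
                "model": model,
                "fold": "aggregate",
                "bias": self.bias,
                "dispersion": self.dispersion,
                "accuracy": self.accuracy,
            }
        )
        return pd.DataFrame(rows)


def make_folds(animal_ids, k: int, seed: int = 0) -> FoldAssignment:
    """Uniform random partition into k folds with sizes differing by <= 1."""
    ids = list(animal_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError("k cannot exceed the number of animals")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    fold_of = {ids[j]: int(i % k) for i, j in enumerate(perm)}
    return FoldAssignment(k, fold_of, seed)


def lr_statistics(
    u_partial: np.ndarray,
    u_whole: np.ndarray,
    F_bar: float,
    sigma_a2: float,
) -> LRStats:
    """LR statistics for one fold from aligned partial/whole GEBV vectors.

    A negative partial-whole covariance leaves the accuracy undefined
    (reported as NaN with a log entry); an accuracy above 1 is clipped,
    with the raw value logged.
    """
    u_p = np.asarray(u_partial, dtype=float)
    u_w = np.asarray(u_whole, dtype=float)
    if u_p.shape != u_w.shape:
        raise ValueError("partial and whole GEBV vectors must be aligned")
    if sigma_a2 <= 0:
        raise ValueError("sigma_a2 must be positive")
    var_p = float(np.var(u_p, ddof=1))
    if var_p <= 0:
        raise ComputationError("var(u_partial) is zero; dispersion undefined")
    cov_pw = float(np.cov(u_p, u_w, ddof=1)[0, 1])
    bias = float(u_p.mean() - u_w.mean())
    dispersion = cov_pw / var_p
    if cov_pw < 0:
        logger.warning("negative partial-whole covariance (%.4g); accuracy undefined", cov_pw)
        accuracy = float("nan")
    else:
        raw = float(np.sqrt(cov_pw / ((1.0 - F_bar) * sigma_a2)))
        if raw > 1.0:
            logger.info("accuracy %.4f above 1 clipped", raw)
        accuracy = min(raw, 1.0)
    return LRStats(bias, dispersion, accuracy, float(F_bar), float(sigma_a2))


def cross_validate(
    pt: PhenotypeTable,
    spec: ModelSpec,
    matrices: dict[str, RelationshipMatrix],
    inbreeding: InbreedingVector | None,
    folds: FoldAssignment,
    accuracy_inbreeding: InbreedingVector | None = None,
    whole_fit: REMLFit | None = None,
    **fit_options,
) -> LRStats:
    """k-fold LR validation of one model.

    For each fold, every record of the fold's animals is removed, the
    model is refitted (variances re-estimated), and the masked animals'
    GEBVs are compared with the whole-data GEBVs. Per-fold statistics
    are averaged arithmetically. ``accuracy_inbreeding`` supplies the F
    used in the accuracy denominator (defaults to the model's own
    inbreeding source when present, else zero). Non-convergent folds are
    skipped with a log entry and flagged.
    """
    ds = build_design(pt, spec, matrices, inbreeding)
    if whole_fit is None:
        whole_fit = fit_reml(ds, spec, **fit_options)
    if not whole_fit.converged:
        raise ComputationError("whole-data fit did not converge")
    sigma_a2 = whole_fit.variances["additive"]
    gebv_w = whole_fit.gebv

    F_source = accuracy_inbreeding if accuracy_inbreeding is not None else inbreeding
    F_by_animal = (
        pd.Series(F_source.F, index=F_source.sample_ids)
        if F_source is not None
        else pd.Series(0.0, index=gebv_w.index)
    )

    per_fold: list[LRStats] = []
    skipped: list[int] = []
    animal_col = pt.data["animal_id"].astype(str)
    for fold in range(folds.k):
        masked = set(folds.animals_in(fold))
        keep = ~animal_col.isin(masked)
        pt_fold = PhenotypeTable(
            pt.data.loc[keep].reset_index(drop=True),
            trait=pt.trait,
            factors=pt.factors,
            covariates=pt.covariates,
        )
        ds_fold = build_design(pt_fold, spec, matrices, inbreeding)
        fit_p = fit_reml(ds_fold, spec, **fit_options)
        if not fit_p.converged:
            logger.warning("fold %d fit did not converge; skipped", fold)
            skipped.append(fold)
            continue
        ids = sorted(masked)
        stats = lr_statistics(
            fit_p.gebv.loc[ids].to_numpy(),
            gebv_w.loc[ids].to_numpy(),
            float(F_by_animal.loc[ids].mean()),
            sigma_a2,
        )
        per_fold.append(stats)

    if not per_fold:
        raise ComputationError("no fold converged; LR statistics unavailable")
    agg = LRStats(
        bias=float(np.mean([s.bias for s in per_fold])),
        dispersion=float(np.mean([s.dispersion for s in per_fold])),
        accuracy=float(np.nanmean([s.accuracy for s in per_fold])),
        mean_F=float(np.mean([s.mean_F for s in per_fold])),
        sigma_a2_whole=sigma_a2,
        per_fold=per_fold,
        skipped_folds=skipped,
    )
    return agg
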