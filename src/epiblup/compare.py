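"""Model comparison: AIC, likelihood-ratio tests, GEBV re-ranking.

Likelihood-ratio tests compare nested models with identical fixed
structure (models with and without the inbreeding covariate are never
tested against each other); the statistic is referred to a chi-square
with df = difference in variance-parameter counts. Because variance
components sit on the boundary of the parameter space under the null,
this reference distribution is conservative — rejection rates below the
nominal level are expected, which is documented rather than corrected.

Re-ranking is summarized by Spearman's rank correlation between each
model's GEBVs and a reference model's, and by the percentage of
commonly selected animals in the top 1/5/10/20% of each ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError
from .reml import REMLFit, model_aic
from .validation import LRStats

logger = logging.getLogger(__name__)

DEFAULT_FRACTIONS = (0.01, 0.05, 0.10, 0.20)


def likelihood_ratio_test(reduced: REMLFit, complete: REMLFit) -> tuple[float, int, float]:
    """LRT = -2 (loglik_reduced - loglik_complete) against chi-square(df).

    Requires identical fixed structure (same inbreeding usage) and the
    reduced model's random terms to nest inside the complete model's.
    A negative statistic (optimizer failure) is clipped at zero with a
    log entry.
    """
    if reduced.spec.use_inbreeding != complete.spec.use_inbreeding:
        raise ValueError("LRT requires identical fixed structures (inbreeding covariate)")
    if not set(reduced.term_labels) < set(complete.term_labels):
        raise ValueError(
            f"{reduced.spec.name} random terms do not nest strictly inside "
            f"{complete.spec.name}"
        )
    stat = -2.0 * (reduced.reml_loglik - complete.reml_loglik)
    if stat < 0:
        # tiny negatives are convergence-tolerance ties (boundary nulls);
        # larger ones indicate a failed optimization of the complete model
        if stat < -1e-6 * max(1.0, abs(complete.reml_loglik)):
            logger.warning("negative LRT statistic %.4g clipped at 0 (optimizer failure?)", stat)
        else:
            logger.debug("negative LRT statistic %.4g clipped at 0 (numerical tie)", stat)
        stat = 0.0
    df = len(complete.variances) - len(reduced.variances)
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return float(stat), int(df), p


def spearman_rank_correlation(gebv_a, gebv_b) -> float:
    """Spearman rho with average ranks for ties."""
    a = np.asarray(gebv_a, dtype=float)
    b = np.asarray(gebv_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two aligned vectors of size >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ComputationError("constant GEBV vector; rank correlation undefined")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def top_fraction_overlap(
    gebv_ref, gebv_alt, fractions=DEFAULT_FRACTIONS
) -> dict[float, float]:
    """Percentage of commonly selected animals at each selection fraction.

    Each vector selects its ceil(fraction * n) highest-GEBV animals;
    overlap = 100 * |intersection| / selection size. Ties are broken by
    stable animal-index order (logged when present).
    """
    ref = np.asarray(gebv_ref, dtype=float)
    alt = np.asarray(gebv_alt, dtype=float)
    if ref.shape != alt.shape:
        raise ValueError("GEBV vectors must be aligned")
    n = ref.size
    out: dict[float, float] = {}
    for frac in fractions:
        if not 0.0 < frac <= 1.0:
            raise ValueError(f"fraction {frac} outside (0, 1]")
        size = math.ceil(frac * n)
        # lexsort: primary key descending GEBV, stable in index for ties
        top_ref = set(np.lexsort((np.arange(n), -ref))[:size])
        top_alt = set(np.lexsort((np.arange(n), -alt))[:size])
        if len(np.unique(ref)) < n or len(np.unique(alt)) < n:
            logger.info("GEBV ties at fraction %g broken by stable animal order", frac)
        out[float(frac)] = 100.0 * len(top_ref & top_alt) / size
    return out


@dataclass
class ComparisonReport:
    """Assembled AIC/LRT/re-ranking tables across a model battery."""

    aic_table: pd.DataFrame
    lrt_table: pd.DataFrame
    spearman_table: pd.DataFrame
    overlap_table: pd.DataFrame
    reference: str
    non_converged: list[str] = field(default_factory=list)

    def write_tsv(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.aic_table.to_csv(outdir / "aic.tsv", sep="\t", index=False)
        self.lrt_table.to_csv(outdir / "lrt.tsv", sep="\t", index=False)
        self.spearman_table.to_csv(outdir / "spearman.tsv", sep="\t", index=False)
        self.overlap_table.to_csv(outdir / "overlap.tsv", sep="\t", index=False)


def comparison_report(
    fits: list[REMLFit],
    reference: str,
    validation: dict[str, LRStats] | None = None,
    fractions=DEFAULT_FRACTIONS,
    alpha: float = 0.05,
) -> ComparisonReport:
    """Compare fitted models against a reference (usually the additive model).

    Produces the AIC table, LRTs of every model that strictly nests the
    reference (same fixed structure), Spearman correlations of GEBVs
    with the reference, and top-fraction selection overlaps.
    Non-converged fits are listed and excluded from the LRT block.
    """
    if not fits:
        raise ValueError("empty fit list")
    by_name = {f.spec.name: f for f in fits}
    if reference not in by_name:
        raise ValueError(f"reference model {reference!r} not among fits")
    ref_fit = by_name[reference]
    non_converged = [f.spec.name for f in fits if not f.converged]

    aic_rows = [
        {
            "model": f.spec.name,
            "loglik": f.reml_loglik,
            "n_params": len(f.variances),
            "aic": model_aic(f),
            "converged": f.converged,
        }
        for f in fits
    ]

    lrt_rows = []
    for f in fits:
        if f.spec.name == reference or not f.converged or not ref_fit.converged:
            continue
        if f.spec.use_inbreeding != ref_fit.spec.use_inbreeding:
            continue
        if not set(ref_fit.term_labels) < set(f.term_labels):
            continue
        stat, df, p = likelihood_ratio_test(ref_fit, f)
        lrt_rows.append(
            {
                "reduced": reference,
                "complete": f.spec.name,
                "statistic": stat,
                "df": df,
                "p_value": p,
                f"significant_at_{alpha}": p < alpha,
            }
        )

    ref_gebv = ref_fit.gebv
    sp_rows, ov_rows = [], []
    for f in fits:
        if not f.converged or len(f.blup) == 0:
            continue
        gebv = f.gebv.loc[ref_gebv.index].to_numpy()
        sp_rows.append(
            {
                "model": f.spec.name,
                "rho": spearman_rank_correlation(gebv, ref_gebv.to_numpy()),
            }
        )
        row = {"model": f.spec.name}
        for frac, pct in top_fraction_overlap(ref_gebv.to_numpy(), gebv, fractions).items():
            row[f"top_{frac:g}"] = pct
        if validation and f.spec.name in validation:
            v = validation[f.spec.name]
            row.update(bias=v.bias, dispersion=v.dispersion, accuracy=v.accuracy)
        ov_rows.append(row)

    return ComparisonReport(
        aic_table=pd.DataFrame(aic_rows),
        lrt_table=pd.DataFrame(
            lrt_rows,
            columns=["reduced", "complete", "statistic", "df", "p_value",
                     f"significant_at_{alpha}"],
        ),
        spearman_table=pd.DataFrame(sp_rows, columns=["model", "rho"]),
        overlap_table=pd.DataFrame(ov_rows),
        reference=reference,
        non_converged=non_converged,
    )
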