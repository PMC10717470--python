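"""Multi-component REML engine for genomic variance-component models.

Fits mixed models of the form

    y = X beta + f b + Z a + Z d + Z e_aa + Z e_ad + Z e_dd + Z pe + eps

by restricted maximum likelihood, where each random vector has covariance
(relationship matrix) x (its variance component). Estimation uses
average-information (AI) updates with an expectation-maximization fallback
for any component an AI step would drive below the boundary constant.
Standard errors come from the inverse AI matrix at the optimum and BLUP
solutions from the mixed-model structure at the final variances; the BLUP
of the additive term is the GEBV used everywhere downstream.

The named model catalogue reproduces the conventional battery: MA (additive
only) through MAIDE3 (inbreeding covariate + dominance + all three
epistatic terms) plus the repeatability variants MAIpe..MAIDEpe with a
permanent environmental effect for repeated records. An "I" in the name
means the inbreeding coefficient enters as a fixed covariate whose
regression is the inbreeding depression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator

from .errors import ComputationError
from .grm import InbreedingVector, RelationshipMatrix

logger = logging.getLogger(__name__)

#: term label -> relationship-matrix kind carrying its covariance
TERM_KINDS = {
    "additive": "A",
    "dominance": "D",
    "aa": "AA",
    "ad": "AD",
    "dd": "DD",
    "pe": "IDENTITY",
}

GENETIC_TERMS = ("additive", "dominance", "aa", "ad", "dd")


@dataclass
class PhenotypeTable:
    """Phenotype records with fixed factors and covariates.

    ``data`` must carry an ``animal_id`` column and the trait column;
    ``factors`` and ``covariates`` name further columns used as fixed
    effects. A factor name of the form ``"f1:f2"`` denotes the
    concatenation (cross-product level) of columns ``f1`` and ``f2``.
    """

    data: pd.DataFrame
    trait: str = "y"
    factors: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "animal_id" not in self.data.columns:
            raise ValueError("phenotype table needs an 'animal_id' column")
        if self.trait not in self.data.columns:
            raise ValueError(f"trait column {self.trait!r} missing")
        y = self.data[self.trait].to_numpy(dtype=float)
        if not np.isfinite(y).all():
            raise ValueError("trait values must be finite")

    @property
    def n_records(self) -> int:
        return len(self.data)

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model definition: random terms + inbreeding covariate."""

    name: str
    random_terms: tuple[str, ...]
    use_inbreeding: bool = False

    def __post_init__(self) -> None:
        if len(set(self.random_terms)) != len(self.random_terms):
            raise ValueError("random term labels must be unique")
        for t in self.random_terms:
            if t not in TERM_KINDS:
                raise ValueError(f"unknown random term {t!r}")

    @property
    def n_variance_params(self) -> int:
        return len(self.random_terms) + 1  # + residual


#: The named model battery. "I" = inbreeding covariate; D = dominance;
#: E/E1 = additive-by-additive; E2 adds additive-by-dominance; E3 adds
#: dominance-by-dominance; "pe" = permanent environment (repeatability).
MODEL_CATALOGUE: dict[str, ModelSpec] = {
    "MA": ModelSpec("MA", ("additive",)),
    "MAI": ModelSpec("MAI", ("additive",), True),
    "MAE": ModelSpec("MAE", ("additive", "aa")),
    "MAIE": ModelSpec("MAIE", ("additive", "aa"), True),
    "MAD": ModelSpec("MAD", ("additive", "dominance")),
    "MAID": ModelSpec("MAID", ("additive", "dominance"), True),
    "MADE1": ModelSpec("MADE1", ("additive", "dominance", "aa")),
    "MAIDE1": ModelSpec("MAIDE1", ("additive", "dominance", "aa"), True),
    "MADE2": ModelSpec("MADE2", ("additive", "dominance", "aa", "ad")),
    "MAIDE2": ModelSpec("MAIDE2", ("additive", "dominance", "aa", "ad"), True),
    "MADE3": ModelSpec("MADE3", ("additive", "dominance", "aa", "ad", "dd")),
    "MAIDE3": ModelSpec("MAIDE3", ("additive", "dominance", "aa", "ad", "dd"), True),
    "MAIpe": ModelSpec("MAIpe", ("additive", "pe"), True),
    "MAIDpe": ModelSpec("MAIDpe", ("additive", "dominance", "pe"), True),
    "MAIEpe": ModelSpec("MAIEpe", ("additive", "aa", "pe"), True),
    "MAIDEpe": ModelSpec("MAIDEpe", ("additive", "dominance", "aa", "pe"), True),
}


def model_spec(name: str) -> ModelSpec:
    try:
        return MODEL_CATALOGUE[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; catalogue: {sorted(MODEL_CATALOGUE)}"
        ) from None


@dataclass
class DesignSystem:
    """Assembled y, X, Z and per-term covariance structures for one model."""

    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    Z: np.ndarray
    term_labels: tuple[str, ...]
    G: dict[str, np.ndarray]
    animal_ids: list[str]

    _structures: list[np.ndarray] | None = None

    @property
    def n_records(self) -> int:
        return self.y.shape[0]

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    def term_structures(self) -> list[np.ndarray]:
        """Record-level covariance structure Z G Z' per random term (cached)."""
        if self._structures is None:
            self._structures = [
                self.Z @ self.G[t] @ self.Z.T for t in self.term_labels
            ]
        return self._structures


def _dummy_code(levels: pd.Series, name: str) -> tuple[np.ndarray, list[str]]:
    cats = sorted(pd.unique(levels.astype(str)))
    cols, names = [], []
    for lev in cats[1:]:  # reference (first sorted) level dropped
        cols.append((levels.astype(str) == lev).to_numpy(dtype=float))
        names.append(f"{name}[{lev}]")
    return (np.column_stack(cols) if cols else np.empty((len(levels), 0))), names


def build_design(
    pt: PhenotypeTable,
    spec: ModelSpec,
    matrices: dict[str, RelationshipMatrix],
    inbreeding: InbreedingVector | None = None,
) -> DesignSystem:
    """Assemble the design system for one model.

    Fixed design = intercept + dummy-coded factors (reference level
    dropped) + covariates (+ per-animal inbreeding if the model uses it).
    Rank-deficient columns are dropped via pivoted QR, with a log entry.
    Z maps records to animal columns in the relationship matrices'
    ordering; repeated records of one animal share a column.
    """
    if spec.use_inbreeding and inbreeding is None:
        raise ValueError(f"model {spec.name} needs an inbreeding vector")
    if not spec.use_inbreeding and inbreeding is not None:
        inbreeding = None  # ignored by models without the covariate

    ref = None
    for t in spec.random_terms:
        kind = TERM_KINDS[t]
        if kind == "IDENTITY":
            continue
        if kind not in matrices:
            raise ValueError(f"model {spec.name} needs a kind-{kind} matrix for term {t!r}")
        if ref is None:
            ref = matrices[kind]
        elif matrices[kind].sample_ids != ref.sample_ids:
            raise ValueError("relationship matrices have inconsistent sample orderings")
    if ref is None:
        raise ValueError("model has no genomic random term; nothing to anchor animals to")
    animal_ids = list(ref.sample_ids)
    index = {a: i for i, a in enumerate(animal_ids)}

    df = pt.data
    unknown = set(df["animal_id"].astype(str)) - set(animal_ids)
    if unknown:
        raise ValueError(f"records for animals absent from the matrices: {sorted(unknown)[:5]}")

    y = df[pt.trait].to_numpy(dtype=float)
    n = len(y)

    cols = [np.ones(n)]
    names = ["intercept"]
    for fac in pt.factors:
        if ":" in fac:
            parts = fac.split(":")
            levels = df[parts[0]].astype(str)
            for p in parts[1:]:
                levels = levels + "|" + df[p].astype(str)
        else:
            levels = df[fac].astype(str)
        if levels.nunique() < 2:
            logger.info("factor %r has a single level; dropped", fac)
            continue
        block, bnames = _dummy_code(levels, fac)
        cols.append(block)
        names.extend(bnames)
    for cov in pt.covariates:
        cols.append(df[cov].to_numpy(dtype=float).reshape(-1, 1))
        names.append(cov)

    row_animal = np.array([index[a] for a in df["animal_id"].astype(str)])
    Z = np.zeros((n, len(animal_ids)))
    Z[np.arange(n), row_animal] = 1.0

    if spec.use_inbreeding:
        assert inbreeding is not None
        if list(inbreeding.sample_ids) != animal_ids:
            raise ValueError("inbreeding vector ordering does not match the matrices")
        cols.append((Z @ inbreeding.F).reshape(-1, 1))
        names.append("f")

    X = np.column_stack([np.atleast_2d(c.T).T for c in cols])
    # pivoted QR rank reduction
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > diag.max() * max(X.shape) * np.finfo(float).eps).sum())
    if rank < X.shape[1]:
        dropped = [names[j] for j in piv[rank:]]
        logger.info("dropping rank-deficient fixed-effect columns: %s", dropped)
        keep = np.sort(piv[:rank])
        X = X[:, keep]
        names = [names[j] for j in keep]

    if "pe" in spec.random_terms and np.bincount(row_animal).max() < 2:
        raise ValueError("permanent environmental term requires repeated records")

    G = {}
    for t in spec.random_terms:
        kind = TERM_KINDS[t]
        if kind == "IDENTITY":
            G[t] = np.eye(len(animal_ids))
        else:
            G[t] = matrices[kind].values
    return DesignSystem(y, X, names, Z, tuple(spec.random_terms), G, animal_ids)


# ---------------------------------------------------------------------------
# Restricted likelihood
# ---------------------------------------------------------------------------

def _reml_core(ds: DesignSystem, theta: np.ndarray) -> dict:
    """Likelihood, projection matrix and Py at variance vector ``theta``.

    ``theta`` is ordered (random terms..., residual). Returns the
    restricted log-likelihood -1/2 [log|V| + log|X'V^-1 X| + y'Py].
    """
    structures = ds.term_structures()
    n = ds.n_records
    V = np.eye(n) * theta[-1]
    for sig, S in zip(theta[:-1], structures):
        V += sig * S
    try:
        c, low = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        cond = np.linalg.cond(V)
        raise ComputationError(f"V numerically singular (cond ~ {cond:.2e})") from exc
    logdet_v = 2.0 * float(np.log(np.diag(c)).sum())
    Vi = linalg.cho_solve((c, low), np.eye(n))
    ViX = Vi @ ds.X
    XtViX = ds.X.T @ ViX
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise ComputationError("X'V^-1X not positive definite")
    XtViX_inv = np.linalg.inv(XtViX)
    beta = XtViX_inv @ (ViX.T @ ds.y)
    P = Vi - ViX @ XtViX_inv @ ViX.T
    Py = P @ ds.y
    ll = -0.5 * (logdet_v + logdet_x + float(ds.y @ Py))
    return {"ll": ll, "P": P, "Py": Py, "beta": beta, "XtViX_inv": XtViX_inv}


def reml_loglikelihood(ds: DesignSystem, variances) -> float:
    """Restricted log-likelihood at the given (terms..., residual) variances."""
    theta = np.asarray(variances, dtype=float)
    if theta.shape != (len(ds.term_labels) + 1,):
        raise ValueError(
            f"expected {len(ds.term_labels) + 1} variances "
            f"({', '.join(ds.term_labels)}, residual)"
        )
    if (theta <= 0).any():
        raise ValueError("variances must be positive")
    return _reml_core(ds, theta)["ll"]


def _grad_ai(ds: DesignSystem, core: dict) -> tuple[np.ndarray, np.ndarray]:
    """REML gradient and average-information matrix at the current point."""
    structures = ds.term_structures()
    P, Py = core["P"], core["Py"]
    k = len(structures) + 1
    t_vecs = [S @ Py for S in structures] + [Py]
    grad = np.empty(k)
    for i, (S, t) in enumerate(zip(structures + [None], t_vecs)):
        tr_PS = float(P.trace()) if S is None else float((P * S).sum())
        grad[i] = -0.5 * (tr_PS - float(Py @ t))
    Pt = [P @ t for t in t_vecs]
    ai = 0.5 * np.array([[float(t_vecs[i] @ Pt[j]) for j in range(k)] for i in range(k)])
    ai = 0.5 * (ai + ai.T)
    return grad, ai


def _em_update(theta_i: float, n: int, yPSPy: float, tr_PS: float) -> float:
    """EM-flavoured update, guaranteed to respect the parameter space."""
    return theta_i + (theta_i**2 / n) * (yPSPy - tr_PS)


@dataclass
class REMLFit:
    """Fitted variance components, likelihood, and BLUP solutions."""

    spec: ModelSpec
    term_labels: tuple[str, ...]
    variances: dict[str, float]
    standard_errors: dict[str, float]
    fixed_solutions: pd.Series
    blup: dict[str, np.ndarray]
    animal_ids: list[str]
    reml_loglik: float
    converged: bool
    n_iterations: int
    at_boundary: set[str]
    ai_covariance: np.ndarray | None
    boundary: float

    @property
    def aic(self) -> float:
        return model_aic(self)

    @property
    def gebv(self) -> pd.Series:
        """BLUP of the additive term — the genomic estimated breeding values."""
        return pd.Series(self.blup["additive"], index=self.animal_ids, name="gebv")

    @property
    def inbreeding_depression(self) -> float | None:
        return float(self.fixed_solutions["f"]) if "f" in self.fixed_solutions else None

    @classmethod
    def from_components(cls, name: str, components: dict[str, float]) -> "REMLFit":
        """Wrap externally obtained variance components (e.g. printed tables)
        so ratio arithmetic can be applied to them; carries no likelihood,
        SEs or BLUPs."""
        if "residual" not in components:
            raise ValueError("components must include 'residual'")
        labels = tuple(t for t in components if t != "residual")
        spec = ModelSpec(name, labels, use_inbreeding="I" in name)
        return cls(
            spec=spec,
            term_labels=labels,
            variances=dict(components),
            standard_errors={t: float("nan") for t in components},
            fixed_solutions=pd.Series(dtype=float),
            blup={},
            animal_ids=[],
            reml_loglik=float("nan"),
            converged=True,
            n_iterations=0,
            at_boundary=set(),
            ai_covariance=None,
            boundary=0.0,
        )

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t, "estimate": self.variances[t], "se": self.standard_errors[t]}
            for t in (*self.term_labels, "residual")
        ]
        return pd.DataFrame(rows)


def fit_reml(
    ds: DesignSystem,
    spec: ModelSpec | None = None,
    max_iter: int = 200,
    convergence_tol: float = 1e-8,
    boundary_scale: float = 1e-8,
    em_fallback: bool = True,
    start: np.ndarray | None = None,
) -> REMLFit:
    """Fit variance components by AI-REML with EM fallback.

    Starts from an equal split of the phenotypic variance across all
    components. Any AI update that would drive a component below the
    boundary constant (``boundary_scale`` x sample phenotypic variance)
    is replaced by an EM step for that component, then clamped at the
    boundary if still below it. Convergence requires both a relative
    log-likelihood change < ``convergence_tol`` and a maximum relative
    parameter change < 10 x ``convergence_tol``.
    """
    if spec is None:
        spec = ModelSpec("custom", ds.term_labels)
    k = len(ds.term_labels) + 1
    n, p = ds.n_records, ds.X.shape[1]
    if n <= p + 1:
        raise ValueError("need n_records > rank(X) + 1")
    var_y = float(np.var(ds.y, ddof=1))
    bound = boundary_scale * var_y
    theta = np.full(k, var_y / k) if start is None else np.asarray(start, dtype=float)

    structures = ds.term_structures()

    def _quadratics(core: dict) -> tuple[np.ndarray, np.ndarray]:
        """y'P S_i P y and tr(P S_i) for every component (residual last)."""
        P, Py = core["P"], core["Py"]
        yPSPy = np.empty(k)
        tr_PS = np.empty(k)
        for i in range(k):
            S = structures[i] if i < k - 1 else None
            yPSPy[i] = float(Py @ (S @ Py)) if S is not None else float(Py @ Py)
            tr_PS[i] = float((P * S).sum()) if S is not None else float(P.trace())
        return yPSPy, tr_PS

    core = _reml_core(ds, theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad, ai = _grad_ai(ds, core)
        yPSPy, tr_PS = _quadratics(core)
        # components pinned at the boundary whose gradient points outward are
        # held fixed during the Newton solve
        pinned = (theta <= bound * (1.0 + 1e-6)) & (grad < 0)
        active = np.flatnonzero(~pinned)
        delta = np.zeros(k)
        if active.size:
            try:
                delta[active] = np.linalg.solve(
                    ai[np.ix_(active, active)], grad[active]
                )
            except np.linalg.LinAlgError:
                delta[active] = (grad * theta**2 / n)[active]  # EM direction

        def propose(step: np.ndarray) -> np.ndarray:
            # an AI update below the boundary lands on the boundary; the
            # ascent check below rejects it if that was too greedy, in
            # which case the EM fallback takes over
            return np.maximum(theta + step, bound)

        new_theta = propose(delta)
        new_core = _reml_core(ds, new_theta)
        halvings = 0
        while new_core["ll"] < core["ll"] - 1e-10 and halvings < 12:
            delta = delta / 2.0
            new_theta = propose(delta)
            new_core = _reml_core(ds, new_theta)
            halvings += 1
        if new_core["ll"] < core["ll"] - 1e-10 and em_fallback:
            # halving failed: take a guaranteed-ascent EM step instead
            new_theta = np.maximum(_em_update(theta, n, yPSPy, tr_PS), bound)
            new_core = _reml_core(ds, new_theta)

        ll_change = abs(new_core["ll"] - core["ll"]) / (abs(core["ll"]) + 1.0)
        param_change = np.max(np.abs(new_theta - theta) / (theta + bound))
        theta, core = new_theta, new_core
        logger.debug("iter %d: ll=%.8f theta=%s", it, core["ll"], theta)
        if ll_change < convergence_tol and param_change < 10 * convergence_tol:
            converged = True
            break

    grad, ai = _grad_ai(ds, core)
    free = theta > bound * (1.0 + 1e-6)
    gnorm = float(np.linalg.norm(grad[free])) if free.any() else 0.0
    logger.info(
        "REML %s: converged=%s iterations=%d loglik=%.6f gradient-norm=%.3e",
        spec.name, converged, it, core["ll"], gnorm,
    )
    try:
        C = np.linalg.pinv(ai)
        ses = np.sqrt(np.clip(np.diag(C), 0.0, None))
    except np.linalg.LinAlgError:
        C = None
        ses = np.full(k, np.nan)

    labels = (*ds.term_labels, "residual")
    ZtPy = ds.Z.T @ core["Py"]
    blup = {
        t: theta[i] * (ds.G[t] @ ZtPy) for i, t in enumerate(ds.term_labels)
    }
    at_boundary = {labels[i] for i in range(k) if theta[i] <= bound * (1.0 + 1e-6)}
    return REMLFit(
        spec=spec,
        term_labels=ds.term_labels,
        variances={labels[i]: float(theta[i]) for i in range(k)},
        standard_errors={labels[i]: float(ses[i]) for i in range(k)},
        fixed_solutions=pd.Series(core["beta"], index=ds.x_names),
        blup=blup,
        animal_ids=list(ds.animal_ids),
        reml_loglik=float(core["ll"]),
        converged=converged,
        n_iterations=it,
        at_boundary=at_boundary,
        ai_covariance=C,
        boundary=bound,
    )


def model_aic(fit: REMLFit) -> float:
    """AIC = -2 loglik + 2t, t = number of estimated variance parameters."""
    t = len(fit.variances)
    return -2.0 * fit.reml_loglik + 2.0 * t


# ---------------------------------------------------------------------------
# Variance ratios
# ---------------------------------------------------------------------------

@dataclass
class VarianceRatios:
    """Heritability-type ratios of variance components.

    ``ratios`` maps each genetic term to (estimate, SE) relative to the
    phenotypic variance; ``d_over_g``/``aa_over_g`` are shares of the
    total genetic variance sigma_g^2 = sigma_a^2 + sigma_d^2 + sigma_aa^2.
    """

    ratios: dict[str, tuple[float, float]]
    sigma_p2: float
    sigma_g2: float
    d_over_g: tuple[float, float] | None = None
    aa_over_g: tuple[float, float] | None = None

    def __getitem__(self, term: str) -> tuple[float, float]:
        return self.ratios[term]


def _delta_se(num_idx, labels, theta, C, denom_idx) -> float:
    """Delta-method SE of theta[num]/sum(theta[denom]) given covariance C."""
    if C is None:
        return float("nan")
    S = theta[denom_idx].sum()
    g = np.zeros(len(labels))
    g[denom_idx] -= theta[num_idx] / S**2
    g[num_idx] += 1.0 / S
    var = float(g @ C @ g)
    return float(np.sqrt(max(var, 0.0)))


def variance_ratios(fit: REMLFit, denominator: str = "phenotypic") -> VarianceRatios:
    """Variance-component ratios of a fit.

    ``phenotypic``: each genetic term over the sum of all estimated
    variances (including pe and residual). ``total_genetic_extras``
    additionally reports dominance and additive-by-additive shares of
    sigma_g^2 = sigma_a^2 + sigma_d^2 + sigma_aa^2.
    """
    if denominator not in ("phenotypic", "total_genetic_extras"):
        raise ValueError("denominator must be 'phenotypic' or 'total_genetic_extras'")
    labels = list(fit.variances)
    theta = np.array([fit.variances[t] for t in labels])
    if theta.sum() <= 0:
        raise ComputationError("zero phenotypic variance; ratios undefined")
    C = fit.ai_covariance
    all_idx = np.arange(len(labels))
    sigma_p2 = float(theta.sum())

    ratios: dict[str, tuple[float, float]] = {}
    for term in GENETIC_TERMS:
        if term in labels:
            i = labels.index(term)
            ratios[term] = (
                float(theta[i] / sigma_p2),
                _delta_se(i, labels, theta, C, all_idx),
            )

    g_terms = [t for t in ("additive", "dominance", "aa") if t in labels]
    g_idx = np.array([labels.index(t) for t in g_terms])
    sigma_g2 = float(theta[g_idx].sum()) if len(g_idx) else 0.0

    d_over_g = aa_over_g = None
    if denominator == "total_genetic_extras":
        if sigma_g2 <= 0:
            raise ComputationError("zero total genetic variance; ratios undefined")
        if "dominance" in labels:
            i = labels.index("dominance")
            d_over_g = (float(theta[i] / sigma_g2), _delta_se(i, labels, theta, C, g_idx))
        if "aa" in labels:
            i = labels.index("aa")
            aa_over_g = (float(theta[i] / sigma_g2), _delta_se(i, labels, theta, C, g_idx))
    return VarianceRatios(ratios, sigma_p2, sigma_g2, d_over_g, aa_over_g)


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

class GBLUP(BaseEstimator):
    """Genomic BLUP with optional non-additive terms, as an estimator.

    Parameters name a model from the catalogue (or a custom ModelSpec) and
    control the AI-REML optimizer. ``fit`` consumes a `PhenotypeTable`,
    a dict of relationship matrices keyed by kind, and (for "I" models)
    an `InbreedingVector`; fitted state lives in trailing-underscore
    attributes, with the full `REMLFit` under ``result_``.
    """

    def __init__(
        self,
        model: str | ModelSpec = "MA",
        max_iter: int = 200,
        convergence_tol: float = 1e-8,
        boundary_scale: float = 1e-8,
        em_fallback: bool = True,
    ):
        self.model = model
        self.max_iter = max_iter
        self.convergence_tol = convergence_tol
        self.boundary_scale = boundary_scale
        self.em_fallback = em_fallback

    def fit(
        self,
        phenotypes: PhenotypeTable,
        matrices: dict[str, RelationshipMatrix],
        inbreeding: InbreedingVector | None = None,
    ) -> "GBLUP":
        spec = self.model if isinstance(self.model, ModelSpec) else model_spec(self.model)
        ds = build_design(phenotypes, spec, matrices, inbreeding)
        self.result_ = fit_reml(
            ds,
            spec,
            max_iter=self.max_iter,
            convergence_tol=self.convergence_tol,
            boundary_scale=self.boundary_scale,
            em_fallback=self.em_fallback,
        )
        self.variances_ = self.result_.variances
        self.loglik_ = self.result_.reml_loglik
        self.aic_ = self.result_.aic
        self.converged_ = self.result_.converged
        self.gebv_ = self.result_.gebv
        return self

    def predict(self, animal_ids=None) -> np.ndarray:
        """GEBV (additive BLUP) for the requested animals (default: all)."""
        if not hasattr(self, "result_"):
            raise AttributeError("GBLUP instance is not fitted yet")
        gebv = self.result_.gebv
        if animal_ids is None:
            return gebv.to_numpy()
        return gebv.loc[list(animal_ids)].to_numpy()
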