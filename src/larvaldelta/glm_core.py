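"""Single-GLM layer: design matrices, fits, likelihoods, AIC, deviance tables.

Four error families, all with the canonical links used throughout the
analysis: binomial with logit link for presence/absence, and gamma, Poisson
and negative-binomial with log link for positive frequencies.  Coefficients
are maximum-likelihood via iteratively reweighted least squares
(`statsmodels.GLM`); log-likelihoods are evaluated from the written density /
mass functions, with the gamma shape estimated by profile maximum likelihood
given the mean fit and the NB dispersion theta profiled by an outer
one-dimensional search.  AIC is 2k − 2ℓ where k counts regression
coefficients plus one for an estimated gamma shape or NB theta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

logger = logging.getLogger("larvaldelta")

FAMILIES = ("binomial_logit", "gamma_log", "poisson_log", "negbin_log")
POSITIVE_FAMILIES = ("gamma_log", "negbin_log", "poisson_log")

#: IRLS convergence: relative deviance-change tolerance and iteration cap.
IRLS_TOL = 1e-8
IRLS_MAXITER = 100
#: NB dispersion (theta) profile-search bounds; boundary hits are flagged.
NB_THETA_BOUNDS = (1e-3, 1e6)


class ModelError(ValueError):
    """Invalid model specification or response for the requested family."""


class AliasingError(ModelError):
    """The design matrix is rank-deficient (aliased columns)."""


class ConvergenceError(RuntimeError):
    """The fitting iteration failed to converge or separated."""


@dataclass(frozen=True)
class ModelSpec:
    """A response, an ordered term list, and an error family.

    Terms are main effects (a continuous covariate name such as
    ``"abundance"``, or a categorical name such as ``"species"``) and
    interactions written ``"a:b"``; every interaction's parents must appear
    as main effects.
    """

    response: str
    terms: Tuple[str, ...]
    family: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ModelError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if len(set(self.terms)) != len(self.terms):
            raise ModelError(f"duplicate terms in {self.terms}")
        mains = {t for t in self.terms if ":" not in t}
        for t in self.terms:
            if ":" in t:
                for parent in t.split(":"):
                    if parent not in mains:
                        raise ModelError(
                            f"interaction {t!r} lacks main-effect parent {parent!r}"
                        )
        object.__setattr__(self, "terms", tuple(self.terms))

    def drop(self, term: str) -> "ModelSpec":
        """Spec without ``term`` (and without interactions containing it)."""
        parts = set(term.split(":"))
        kept = tuple(
            t for t in self.terms if t != term and not (set(t.split(":")) & parts and ":" in t)
        ) if ":" not in term else tuple(t for t in self.terms if t != term)
        return ModelSpec(self.response, kept, self.family)

    def with_family(self, family: str) -> "ModelSpec":
        return ModelSpec(self.response, self.terms, family)


# Each design column is a product of parts; a part is (variable, level) for a
# categorical indicator or (variable, None) for a continuous covariate.
ColumnDef = Tuple[str, Tuple[Tuple[str, Optional[str]], ...]]


@dataclass
class DesignMatrix:
    """Treatment-coded design matrix with per-column provenance.

    ``column_defs`` describes every assembled column (before dropping);
    ``kept`` masks the columns retained after removing all-zero and aliased
    ones, so new covariate rows can be embedded in exactly the fitted basis
    and flagged not-estimable when they load on a dropped column or an
    unseen factor level.
    """

    values: np.ndarray
    columns: List[str]
    terms: Tuple[str, ...]
    column_defs: List[ColumnDef]
    kept: np.ndarray  # bool mask over column_defs
    levels: Dict[str, List[str]]  # per categorical variable, all levels seen
    reference: Dict[str, str]
    dropped_columns: List[str]
    term_columns: Dict[str, List[str]] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


def _is_categorical(series: pd.Series) -> bool:
    return series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype) or series.dtype.kind in "US"


def _part_column(rows: pd.DataFrame, var: str, level: Optional[str]) -> np.ndarray:
    if level is None:
        return rows[var].to_numpy(dtype=float)
    return (rows[var].astype(str) == level).to_numpy(dtype=float)


def _column_name(parts: Sequence[Tuple[str, Optional[str]]]) -> str:
    return ":".join(v if lvl is None else f"{v}[{lvl}]" for v, lvl in parts)


def build_design(rows: pd.DataFrame, spec: ModelSpec, on_alias: str = "drop") -> DesignMatrix:
    """Build a full-rank treatment-coded design matrix for ``spec``.

    The alphabetically-first level of each categorical variable is the
    reference; interaction columns are products of parent indicator /
    continuous columns.  Columns that are identically zero (factor level
    absent from the data) are dropped and logged; exactly collinear
    (aliased) columns are dropped with ``on_alias="drop"`` (the behaviour of
    R's ``glm``, which is what gives a species:area interaction 3 df when
    one species is missing from one area) or raised with
    ``on_alias="raise"``.
    """
    for term in spec.terms:
        for var in term.split(":"):
            if var not in rows.columns:
                raise ModelError(f"variable {var!r} not present in the data")
    levels: Dict[str, List[str]] = {}
    reference: Dict[str, str] = {}
    for term in spec.terms:
        for var in term.split(":"):
            if var not in levels and _is_categorical(rows[var]):
                lvls = sorted(rows[var].astype(str).unique())
                levels[var] = lvls
                reference[var] = lvls[0]

    column_defs: List[ColumnDef] = [("Intercept", ())]
    def_term: List[Optional[str]] = [None]
    for term in spec.terms:
        vars_ = term.split(":")
        part_sets = []
        for var in vars_:
            if var in levels:
                part_sets.append([(var, lvl) for lvl in levels[var][1:]])
            else:
                part_sets.append([(var, None)])
        combos = [[]]
        for ps in part_sets:
            combos = [c + [p] for c in combos for p in ps]
        for combo in combos:
            parts = tuple(combo)
            column_defs.append((_column_name(parts), parts))
            def_term.append(term)

    cols = np.column_stack(
        [np.ones(len(rows))]
        + [
            np.prod([_part_column(rows, v, l) for v, l in parts], axis=0)
            for _, parts in column_defs[1:]
        ]
        if len(column_defs) > 1
        else [np.ones(len(rows))]
    )

    kept = np.ones(len(column_defs), dtype=bool)
    dropped: List[str] = []
    # all-zero columns: factor level (or combination) absent from the data
    for j in range(1, len(column_defs)):
        if not np.any(cols[:, j] != 0.0):
            kept[j] = False
            dropped.append(column_defs[j][0])
            logger.info("design: dropping all-zero column %s", column_defs[j][0])
    # aliased columns: greedy Gram-Schmidt, keep earlier columns
    basis: List[np.ndarray] = []
    for j in range(len(column_defs)):
        if not kept[j]:
            continue
        v = cols[:, j].astype(float).copy()
        norm0 = np.linalg.norm(v)
        for b in basis:
            v -= (b @ cols[:, j]) * b
        if np.linalg.norm(v) <= 1e-8 * max(norm0, 1.0):
            if on_alias == "raise":
                raise AliasingError(f"aliased design column(s): {column_defs[j][0]}")
            kept[j] = False
            dropped.append(column_defs[j][0])
            logger.info("design: dropping aliased column %s", column_defs[j][0])
        else:
            basis.append(v / np.linalg.norm(v))

    names = [column_defs[j][0] for j in range(len(column_defs)) if kept[j]]
    term_columns: Dict[str, List[str]] = {t: [] for t in spec.terms}
    for j in range(1, len(column_defs)):
        if kept[j]:
            term_columns[def_term[j]].append(column_defs[j][0])
    return DesignMatrix(
        values=cols[:, kept],
        columns=names,
        terms=spec.terms,
        column_defs=column_defs,
        kept=kept,
        levels=levels,
        reference=reference,
        dropped_columns=dropped,
        term_columns=term_columns,
    )


def design_row(design: DesignMatrix, cell: dict) -> Tuple[np.ndarray, bool, str]:
    """Embed one covariate record into the fitted column basis.

    Returns ``(vector, estimable, note)``; not estimable when the record
    references a factor level never seen by this design or loads on a
    dropped (absent/aliased) column.
    """
    estimable, note = True, ""
    full = np.zeros(len(design.column_defs))
    full[0] = 1.0
    # a level never seen in the fitted data is not estimable even when the
    # factor contributed no columns (single observed level)
    for var, lvls in design.levels.items():
        obs = str(cell[var])
        if obs not in lvls:
            return full[design.kept], False, f"level {var}={obs} absent from fit"
    for j, (name, parts) in enumerate(design.column_defs[1:], start=1):
        val = 1.0
        for var, lvl in parts:
            if lvl is None:
                val *= float(cell[var])
            else:
                obs = str(cell[var])
                if obs not in design.levels.get(var, []):
                    return full[design.kept], False, f"level {var}={obs} absent from fit"
                val *= 1.0 if obs == lvl else 0.0
        full[j] = val
        if val != 0.0 and not design.kept[j]:
            estimable, note = False, f"loads on dropped column {name}"
    return full[design.kept], estimable, note


# ---------------------------------------------------------------------------
# Likelihoods and nuisance-parameter estimation
# ---------------------------------------------------------------------------

def _gamma_loglik(y: np.ndarray, mu: np.ndarray, shape: float) -> float:
    a = shape
    return float(
        np.sum(a * np.log(a) - special.gammaln(a) - a * np.log(mu) + (a - 1.0) * np.log(y) - a * y / mu)
    )


def _gamma_shape_mle(y: np.ndarray, mu: np.ndarray) -> float:
    """Profile-ML gamma shape given fitted means: log a − ψ(a) = c."""
    c = float(np.mean(np.log(mu / y) + y / mu - 1.0))
    if c <= 1e-12:
        return 1e8  # degenerate perfect fit
    f = lambda a: np.log(a) - special.digamma(a) - c
    lo, hi = 1e-8, 1e12
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def _family_loglik(family: str, y: np.ndarray, mu: np.ndarray, aux: float) -> float:
    if family == "binomial_logit":
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return float(np.sum(np.where(y > 0, np.log(mu), np.log1p(-mu))))
    if family == "poisson_log":
        return float(stats.poisson.logpmf(y, mu).sum())
    if family == "gamma_log":
        return _gamma_loglik(y, mu, aux)
    if family == "negbin_log":
        th = aux
        return float(stats.nbinom.logpmf(y, th, th / (th + mu)).sum())
    raise ModelError(f"unknown family {family!r}")


_SM_FAMILIES = {
    "binomial_logit": lambda: sm.families.Binomial(),
    "gamma_log": lambda: sm.families.Gamma(link=sm.families.links.Log()),
    "poisson_log": lambda: sm.families.Poisson(),
}


@dataclass
class GLMFit:
    """One fitted GLM: estimates, covariance, fit statistics, provenance."""

    family: str
    design: DesignMatrix
    params: np.ndarray
    cov: np.ndarray
    log_likelihood: float
    deviance: float
    df_residual: int
    aic: float
    dispersion_or_shape: float  # gamma shape / NB theta; 1 for binomial, Poisson
    converged: bool
    n_obs: int
    theta_at_boundary: bool = False
    spec: Optional[ModelSpec] = None

    @property
    def columns(self) -> List[str]:
        return self.design.columns

    @property
    def k_parameters(self) -> int:
        """AIC parameter count: coefficients + 1 for gamma shape / NB theta."""
        return len(self.params) + (1 if self.family in ("gamma_log", "negbin_log") else 0)

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov))
        z = self.params / se
        if self.family == "gamma_log":
            p = 2.0 * stats.t.sf(np.abs(z), df=self.df_residual)
            stat = "t"
        else:
            p = 2.0 * stats.norm.sf(np.abs(z))
            stat = "z"
        return pd.DataFrame(
            {"coefficient": self.columns, "estimate": self.params, "std_error": se,
             f"{stat}_value": z, "p_value": p}
        )


def _validate_response(family: str, y: np.ndarray) -> None:
    if family == "binomial_logit":
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ModelError("binomial response must be 0/1")
    elif family == "gamma_log":
        if np.any(y <= 0):
            raise ModelError("gamma response must be strictly positive")
    else:
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ModelError(f"{family} response must be nonnegative integers")


def _irls(y: np.ndarray, X: np.ndarray, sm_family) -> "sm.GLM":
    try:
        res = sm.GLM(y, X, family=sm_family).fit(maxiter=IRLS_MAXITER, tol=IRLS_TOL)
    except Exception as exc:  # separation, non-finite weights
        raise ConvergenceError(f"IRLS failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise ConvergenceError("IRLS produced non-finite coefficients")
    return res


def fit_glm(
    design: DesignMatrix,
    response: Sequence[float],
    family: str,
    spec: Optional[ModelSpec] = None,
) -> GLMFit:
    """Maximum-likelihood GLM fit for one family.

    Binomial fits can separate completely (a factor level with only zeros or
    only ones); this surfaces as a :class:`ConvergenceError` carrying the
    statsmodels diagnostic.
    """
    y = np.asarray(response, dtype=float)
    X = design.values
    if X.shape[0] <= X.shape[1]:
        raise ModelError(f"need n_rows > n_cols, got {X.shape[0]} rows, {X.shape[1]} columns")
    _validate_response(family, y)

    theta_boundary = False
    if family == "negbin_log":
        y_int = y.astype(int)
        lo, hi = np.log(NB_THETA_BOUNDS[0]), np.log(NB_THETA_BOUNDS[1])

        def profile_negloglik(log_theta: float) -> float:
            fam = sm.families.NegativeBinomial(alpha=1.0 / np.exp(log_theta))
            res = _irls(y, X, fam)
            return -_family_loglik("negbin_log", y_int, res.mu, np.exp(log_theta))

        opt = optimize.minimize_scalar(
            profile_negloglik, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        theta = float(np.exp(opt.x))
        if opt.x - lo < 1e-3 or hi - opt.x < 1e-3:
            theta_boundary = True
            logger.warning("NB theta profile hit search boundary (theta=%.4g)", theta)
        res = _irls(y, X, sm.families.NegativeBinomial(alpha=1.0 / theta))
        mu = res.mu
        ll = _family_loglik("negbin_log", y_int, mu, theta)
        cov = np.asarray(res.cov_params()) / res.scale  # ML: scale fixed at 1
        aux = theta
    else:
        res = _irls(y, X, _SM_FAMILIES[family]())
        mu = res.mu
        if family == "gamma_log":
            aux = _gamma_shape_mle(y, mu)
            ll = _gamma_loglik(y, mu, aux)
            # expected information: cov = phi * (X'WX)^{-1} with phi = 1/shape
            cov = np.asarray(res.cov_params()) / res.scale * (1.0 / aux)
        else:
            aux = 1.0
            ll = _family_loglik(family, y if family == "binomial_logit" else y.astype(int), mu, 1.0)
            cov = np.asarray(res.cov_params())
    if not np.isfinite(ll):
        raise ConvergenceError("non-finite log-likelihood at the optimum")
    converged = bool(getattr(res, "converged", True))
    k_coef = X.shape[1]
    k = k_coef + (1 if family in ("gamma_log", "negbin_log") else 0)
    return GLMFit(
        family=family,
        design=design,
        params=np.asarray(res.params, dtype=float),
        cov=cov,
        log_likelihood=ll,
        deviance=float(res.deviance),
        df_residual=int(X.shape[0] - k_coef),
        aic=2.0 * k - 2.0 * ll,
        dispersion_or_shape=float(aux),
        converged=converged,
        n_obs=int(X.shape[0]),
        theta_at_boundary=theta_boundary,
        spec=spec,
    )


def fit_spec(rows: pd.DataFrame, spec: ModelSpec, on_alias: str = "drop") -> GLMFit:
    """Convenience: build the design from tidy rows and fit ``spec``."""
    design = build_design(rows, spec, on_alias=on_alias)
    return fit_glm(design, rows[spec.response].to_numpy(dtype=float), spec.family, spec=spec)


def aic(fit: GLMFit) -> float:
    """Akaike information criterion, 2k − 2ℓ (k per :attr:`GLMFit.k_parameters`)."""
    if not np.isfinite(fit.log_likelihood):
        raise ModelError("AIC undefined: non-finite log-likelihood")
    return 2.0 * fit.k_parameters - 2.0 * fit.log_likelihood


def analysis_of_deviance(rows: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Type-II likelihood-ratio table, one row per term.

    Each main effect is tested by dropping it from the model containing all
    other main effects (interactions excluded); each interaction by dropping
    it from the full model.  LR = 2(ℓ_full − ℓ_reduced) against chi-square
    with the difference in coefficient counts; gamma shape / NB theta are
    re-estimated in every sub-fit.  A sub-fit that fails is reported with
    ``failed=True`` rather than dropped.
    """
    mains = tuple(t for t in spec.terms if ":" not in t)
    interactions = tuple(t for t in spec.terms if ":" in t)
    out = []
    cache: Dict[Tuple[str, ...], GLMFit] = {}

    def fit_terms(terms: Tuple[str, ...]) -> GLMFit:
        if terms not in cache:
            cache[terms] = fit_spec(rows, ModelSpec(spec.response, terms, spec.family))
        return cache[terms]

    for term in spec.terms:
        try:
            if ":" in term:
                full = fit_terms(spec.terms)
                reduced = fit_terms(tuple(t for t in spec.terms if t != term))
            else:
                full = fit_terms(mains)
                reduced = fit_terms(tuple(t for t in mains if t != term))
            lr = 2.0 * (full.log_likelihood - reduced.log_likelihood)
            lr = max(lr, 0.0)  # guard tiny negative round-off
            df = len(full.params) - len(reduced.params)
            p = float(stats.chi2.sf(lr, df)) if df > 0 else np.nan
            out.append(
                {"term": term, "likelihood_ratio": lr, "df": int(df), "p_value": p, "failed": False}
            )
        except (ConvergenceError, ModelError) as exc:
            logger.warning("deviance row for %s failed: %s", term, exc)
            out.append(
                {"term": term, "likelihood_ratio": np.nan, "df": 0, "p_value": np.nan, "failed": True}
            )
    return pd.DataFrame(out)
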