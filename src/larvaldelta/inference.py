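"""Model selection and comparison: AIC family table, 2-step forward
selection, and pairwise factor contrasts on the positive sub-model.

The selection procedure mirrors the two-part structure: because the combined
density is the product of two independently fitted sub-models, no single
F-test spans both parts.  Step (i) adds candidate terms one at a time and
retains a term iff at least one of its coefficients is significant (Wald,
two-sided) in at least one sub-model; step (ii) resolves declared groups of
competing explanatory variables (e.g. the categorical season vs the
continuous larval abundance) by joint AIC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .delta_model import DeltaModel, delta_aic, fit_delta
from .glm_core import ConvergenceError, GLMFit, ModelError, ModelSpec

logger = logging.getLogger("larvaldelta")

#: Family label order used for AIC ties.
FAMILY_ORDER = ("gamma_log", "negbin_log", "poisson_log")


def _term_pvalues(fit: GLMFit, term: str) -> Dict[str, Tuple[float, float]]:
    """Wald statistic and two-sided p for each kept coefficient of ``term``.

    Gamma fits use a t reference with residual df; the other families use
    the normal (z) reference.
    """
    se = np.sqrt(np.diag(fit.cov))
    out = {}
    for col in fit.design.term_columns.get(term, []):
        j = fit.design.columns.index(col)
        z = float(fit.params[j] / se[j])
        if fit.family == "gamma_log":
            p = float(2.0 * stats.t.sf(abs(z), df=fit.df_residual))
        else:
            p = float(2.0 * stats.norm.sf(abs(z)))
        out[col] = (z, p)
    return out


def compare_families(
    rows: pd.DataFrame,
    response: Sequence[float],
    presence_spec: ModelSpec,
    positive_spec: ModelSpec,
) -> pd.DataFrame:
    """Delta-model AIC for each positive family, sorted ascending.

    Non-integer positive responses make the count families (Poisson, NB)
    inapplicable; those rows are flagged rather than fitted.  Fit failures
    are likewise flagged and the comparison proceeds on the rest.
    """
    y = np.asarray(response, dtype=float)
    pos = y[y > 0]
    integer_ok = bool(np.all(pos == np.round(pos)))
    out = []
    for family in FAMILY_ORDER:
        note = ""
        value = np.nan
        if family in ("poisson_log", "negbin_log") and not integer_ok:
            note = "not_applicable: non-integer positive response"
        else:
            try:
                model = fit_delta(rows, y, presence_spec, positive_spec.with_family(family))
                value = delta_aic(model)
            except (ConvergenceError, ModelError, ValueError) as exc:
                note = f"fit_failed: {exc}"
                logger.warning("family %s failed: %s", family, exc)
        out.append({"family": family, "delta_aic": value, "note": note})
    frame = pd.DataFrame(out)
    order = {f: i for i, f in enumerate(FAMILY_ORDER)}
    frame = frame.sort_values(
        by=["delta_aic", "family"],
        key=lambda s: s.map(order) if s.name == "family" else s,
        na_position="last",
    ).reset_index(drop=True)
    frame["rank"] = np.where(frame["delta_aic"].notna(), np.arange(1, len(frame) + 1), np.nan)
    return frame


@dataclass
class SelectionStep:
    candidate: Union[str, Tuple[str, ...]]
    presence_stats: Dict[str, Tuple[float, float]]
    positive_stats: Dict[str, Tuple[float, float]]
    retained: bool
    reason: str  # significant_in_presence | significant_in_positive |
    #              not_significant | aic_preferred | aic_rejected | fit_failed
    detail: str = ""


@dataclass
class SelectionTrace:
    steps: List[SelectionStep]
    presence_spec: Optional[ModelSpec]
    positive_spec: Optional[ModelSpec]
    alpha: float

    def to_records(self) -> list:
        return [
            {
                "candidate": s.candidate if isinstance(s.candidate, str) else list(s.candidate),
                "presence_stats": {k: list(v) for k, v in s.presence_stats.items()},
                "positive_stats": {k: list(v) for k, v in s.positive_stats.items()},
                "retained": s.retained,
                "reason": s.reason,
                "detail": s.detail,
            }
            for s in self.steps
        ]


def forward_select(
    rows: pd.DataFrame,
    response: Sequence[float],
    candidate_terms: Sequence[str],
    alpha: float = 0.05,
    competing_groups: Optional[Sequence[Sequence[Union[str, Tuple[str, ...]]]]] = None,
    positive_family: str = "gamma_log",
) -> SelectionTrace:
    """The 2-step iterative selection over both delta-model parts.

    Step (i): candidates are added in the given order and a term is retained
    iff any of its coefficients has two-sided Wald p < alpha in the presence
    or the positive sub-model (both parts refitted at each step; no
    adjustment across the two parts — the retention rule is the stated
    union).  Step (ii): within each competing group, the alternative (a term
    or term tuple) achieving the lowest joint AIC replaces the others.
    Every decision is recorded in the trace; a failing sub-fit marks the
    step failed and selection continues.
    """
    if not candidate_terms:
        raise ValueError("candidate_terms must be nonempty")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    y = np.asarray(response, dtype=float)
    steps: List[SelectionStep] = []
    retained: List[str] = []

    def _fit(terms: Sequence[str]) -> DeltaModel:
        return fit_delta(
            rows, y,
            ModelSpec("response", tuple(terms), "binomial_logit"),
            ModelSpec("response", tuple(terms), positive_family),
        )

    for term in candidate_terms:
        trial = retained + [term]
        if ":" in term and any(p not in retained for p in term.split(":")):
            steps.append(SelectionStep(term, {}, {}, False, "fit_failed",
                                       "interaction parent not retained"))
            continue
        try:
            model = _fit(trial)
        except (ConvergenceError, ModelError, ValueError) as exc:
            logger.warning("selection step for %s failed: %s", term, exc)
            steps.append(SelectionStep(term, {}, {}, False, "fit_failed", str(exc)))
            continue
        pres = _term_pvalues(model.presence_fit, term)
        posi = _term_pvalues(model.positive_fit, term)
        sig_pres = any(p < alpha for _, p in pres.values())
        sig_posi = any(p < alpha for _, p in posi.values())
        if sig_pres or sig_posi:
            retained.append(term)
            reason = "significant_in_presence" if sig_pres else "significant_in_positive"
        else:
            reason = "not_significant"
        steps.append(SelectionStep(term, pres, posi, sig_pres or sig_posi, reason))

    for group in competing_groups or []:
        alts = [tuple([a]) if isinstance(a, str) else tuple(a) for a in group]
        live = [a for a in alts if all(t in retained for t in a)]
        if len(live) < 2:
            continue
        group_terms = {t for a in alts for t in a}
        base = [t for t in retained if t not in group_terms]
        scored = []
        for alt in live:
            terms = base + [t for t in retained if t in alt]
            try:
                scored.append((delta_aic(_fit(terms)), alt))
            except (ConvergenceError, ModelError, ValueError) as exc:
                steps.append(SelectionStep(alt, {}, {}, False, "fit_failed", str(exc)))
        if not scored:
            continue
        scored.sort(key=lambda t: t[0])
        best_aic, best = scored[0]
        for aic_val, alt in scored:
            win = alt == best
            steps.append(
                SelectionStep(alt, {}, {}, win,
                              "aic_preferred" if win else "aic_rejected",
                              f"delta_aic={aic_val:.4f}")
            )
            if not win:
                retained = [t for t in retained if t not in alt]

    final_terms = tuple(retained)
    return SelectionTrace(
        steps=steps,
        presence_spec=ModelSpec("response", final_terms, "binomial_logit"),
        positive_spec=ModelSpec("response", final_terms, positive_family),
        alpha=alpha,
    )


def pairwise_contrasts(
    positive_fit: GLMFit,
    factor: str,
    method: str = "single_step",
    seed: int = 20210112,
    ndraws: int = 100_000,
    all_levels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """All pairwise level contrasts of ``factor`` on the link scale.

    Estimates are differences of linear-predictor contributions (the
    treatment reference level contributes zero), with SE from c'Σc and a
    normal (z) reference.  ``single_step`` adjusts by the joint max-|z|
    distribution of all estimable contrasts, sampled (seeded) from the
    multivariate normal implied by the coefficient covariance — the
    conventional joint-normal multiple-comparison adjustment;
    ``bonferroni`` multiplies by the number of pairs; ``none`` leaves the
    unadjusted p.  ``all_levels`` may extend the pair grid to the full
    factor vocabulary: pairs involving a level absent from the positive fit
    are emitted flagged not estimable rather than silently omitted.
    """
    if method not in ("single_step", "bonferroni", "none"):
        raise ValueError("method must be single_step, bonferroni or none")
    design = positive_fit.design
    if factor not in design.levels:
        raise ModelError(f"{factor!r} is not a categorical term of this fit")
    levels = list(design.levels[factor])
    if all_levels is not None:
        levels = sorted(set(levels) | set(all_levels))
    if len(levels) < 2:
        raise ModelError(f"{factor!r} has fewer than 2 levels in the fit")
    ncol = len(design.columns)

    def level_vector(lvl: str) -> Optional[np.ndarray]:
        v = np.zeros(ncol)
        if lvl == design.reference[factor]:
            return v
        name = f"{factor}[{lvl}]"
        if name in design.columns:
            v[design.columns.index(name)] = 1.0
            return v
        return None  # dropped: level absent from the fitted data

    vecs = {lvl: level_vector(lvl) for lvl in levels}
    rows, contrasts = [], []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = levels[j], levels[i]  # later level minus earlier level
            label = f"{a}–{b}"
            va, vb = vecs[a], vecs[b]
            if va is None or vb is None:
                rows.append({"pair": label, "estimate": np.nan, "std_error": np.nan,
                             "z_value": np.nan, "p_unadjusted": np.nan,
                             "p_adjusted": np.nan, "estimable": False})
                continue
            c = va - vb
            est = float(c @ positive_fit.params)
            se = float(np.sqrt(c @ positive_fit.cov @ c))
            z = est / se
            p = float(2.0 * stats.norm.sf(abs(z)))
            rows.append({"pair": label, "estimate": est, "std_error": se,
                         "z_value": z, "p_unadjusted": p, "p_adjusted": p,
                         "estimable": True})
            contrasts.append(c)
    frame = pd.DataFrame(rows)
    est_mask = frame["estimable"].to_numpy()
    m = int(est_mask.sum())
    if m and method == "bonferroni":
        frame.loc[est_mask, "p_adjusted"] = np.minimum(1.0, frame.loc[est_mask, "p_unadjusted"] * m)
    elif m and method == "single_step":
        C = np.vstack(contrasts)
        ses = frame.loc[est_mask, "std_error"].to_numpy()
        rng = np.random.default_rng(seed)
        # sample coefficient deviations, convert to contrast z-scores
        L = np.linalg.cholesky(positive_fit.cov + 1e-12 * np.eye(ncol))
        draws = rng.standard_normal((ndraws, ncol)) @ L.T @ C.T / ses
        maxabs = np.abs(draws).max(axis=1)
        zabs = np.abs(frame.loc[est_mask, "z_value"].to_numpy())
        p_adj = [(float(np.mean(maxabs >= z))) for z in zabs]
        frame.loc[est_mask, "p_adjusted"] = np.maximum(
            p_adj, frame.loc[est_mask, "p_unadjusted"]
        )
    return frame
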