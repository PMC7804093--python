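"""Two-part delta model: presence × positive sub-models and their combination.

Zero-heavy frequency data are modelled as a probability mass at zero plus a
distribution for positive values: a binomial-logit GLM on the 0/1 presence
indicator over all cells, and a gamma / negative-binomial / Poisson log-link
GLM on the positive cells only.  The two likelihoods factorize, so the fits
are independent and the joint AIC is the sum of the sub-model AICs.  A
cell-level density estimate combines the parts by the Aitchison–Pennington
product rule:

    d̂_c = p̂ · d̂_p,    v(d̂_c) = p̂² · v(d̂_p) + v(p̂) · d̂_p²
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .glm_core import (
    ConvergenceError,
    DesignMatrix,
    GLMFit,
    ModelError,
    ModelSpec,
    aic,
    build_design,
    design_row,
    fit_glm,
)

logger = logging.getLogger("larvaldelta")


class DegenerateDataError(ValueError):
    """The response leaves one part of the delta model unfittable."""


@dataclass
class DeltaModel:
    presence_fit: GLMFit
    positive_fit: GLMFit
    presence_spec: ModelSpec
    positive_spec: ModelSpec
    n_total: int
    n_positive: int


@dataclass(frozen=True)
class DeltaEstimate:
    """One cell's presence probability, positive mean, and combined density."""

    p_hat: float
    var_p: float
    dp_hat: float
    var_dp: float
    dc_hat: float
    var_dc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_hat <= 1.0:
            raise ValueError(f"p_hat={self.p_hat} outside [0, 1]")
        if self.var_p < 0 or self.var_dp < 0:
            raise ValueError("variances must be nonnegative")


def combine_estimate(p_hat: float, var_p: float, dp_hat: float, var_dp: float) -> DeltaEstimate:
    """Aitchison–Pennington combination of independent presence and positive parts."""
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError(f"p_hat={p_hat} outside [0, 1]")
    if var_p < 0 or var_dp < 0:
        raise ValueError("variances must be nonnegative")
    if dp_hat <= 0:
        raise ValueError("positive-part mean must be > 0")
    dc = p_hat * dp_hat
    var_dc = p_hat ** 2 * var_dp + var_p * dp_hat ** 2
    return DeltaEstimate(p_hat=p_hat, var_p=var_p, dp_hat=dp_hat, var_dp=var_dp,
                         dc_hat=dc, var_dc=var_dc)


def fit_delta(
    rows: pd.DataFrame,
    response: Sequence[float],
    presence_spec: ModelSpec,
    positive_spec: ModelSpec,
) -> DeltaModel:
    """Fit the presence sub-model on all rows and the positive one on d > 0 rows.

    The sub-fits share no parameters; refitting one never alters the other.
    """
    if presence_spec.family != "binomial_logit":
        raise ModelError("presence sub-model must use the binomial_logit family")
    if positive_spec.family not in ("gamma_log", "negbin_log", "poisson_log"):
        raise ModelError("positive sub-model must use a log-link positive family")
    y = np.asarray(response, dtype=float)
    if np.any(y < 0):
        raise ModelError("response must be nonnegative")
    pos_mask = y > 0
    n_pos = int(pos_mask.sum())
    if n_pos == 0:
        raise DegenerateDataError("all-zero response: positive sub-model unfittable")
    if n_pos == len(y):
        raise DegenerateDataError("all-positive response: presence sub-model unfittable")

    presence_design = build_design(rows, presence_spec)
    presence_fit = fit_glm(presence_design, pos_mask.astype(float), "binomial_logit",
                           spec=presence_spec)
    pos_rows = rows.loc[pos_mask].reset_index(drop=True)
    positive_design = build_design(pos_rows, positive_spec)
    positive_fit = fit_glm(positive_design, y[pos_mask], positive_spec.family,
                           spec=positive_spec)
    return DeltaModel(
        presence_fit=presence_fit,
        positive_fit=positive_fit,
        presence_spec=presence_spec,
        positive_spec=positive_spec,
        n_total=int(len(y)),
        n_positive=n_pos,
    )


def delta_aic(model: DeltaModel) -> float:
    """Joint AIC = AIC(presence) + AIC(positive) (factorized likelihood)."""
    if not (model.presence_fit.converged and model.positive_fit.converged):
        raise ConvergenceError("delta AIC undefined: a sub-fit did not converge")
    return aic(model.presence_fit) + aic(model.positive_fit)


def _linear_predictor(fit: GLMFit, cell: dict):
    x, estimable, note = design_row(fit.design, cell)
    eta = float(x @ fit.params)
    var_eta = float(x @ fit.cov @ x)
    return eta, var_eta, estimable, note


def predict_cells(
    model: DeltaModel,
    cells: pd.DataFrame,
    p_var_method: str = "delta",
) -> pd.DataFrame:
    """Per-cell delta estimates with delta-method standard errors.

    ``p̂`` is the inverse-logit of the presence linear predictor with
    ``v(p̂) = [p̂(1−p̂)]² · v(η)``; ``d̂_p = exp(η_pos)`` with
    ``v(d̂_p) = d̂_p² · v(η_pos)``.  ``p_var_method="binomial"`` instead uses
    the classical p̂(1−p̂)/n form (intercept-only presence models only).
    Cells referencing a factor level absent from the positive fit are
    flagged not estimable rather than extrapolated.
    """
    if p_var_method not in ("delta", "binomial"):
        raise ValueError("p_var_method must be 'delta' or 'binomial'")
    if p_var_method == "binomial" and len(model.presence_fit.params) != 1:
        raise ValueError("binomial p-variance applies to intercept-only presence models")
    out = []
    for _, cell in cells.iterrows():
        c = cell.to_dict()
        eta_p, var_eta_p, ok_p, note_p = _linear_predictor(model.presence_fit, c)
        p = float(expit(eta_p))
        if p_var_method == "binomial":
            var_p = p * (1.0 - p) / model.n_total
        else:
            var_p = (p * (1.0 - p)) ** 2 * var_eta_p
        eta_d, var_eta_d, ok_d, note_d = _linear_predictor(model.positive_fit, c)
        dp = float(np.exp(eta_d))
        var_dp = dp ** 2 * var_eta_d
        estimable = ok_p and ok_d
        if estimable:
            est = combine_estimate(p, var_p, dp, var_dp)
            rec = {
                "p_hat": est.p_hat, "se_p": np.sqrt(est.var_p),
                "dp_hat": est.dp_hat, "se_dp": np.sqrt(est.var_dp),
                "dc_hat": est.dc_hat, "se_dc": np.sqrt(est.var_dc),
            }
        else:
            rec = {k: np.nan for k in ("p_hat", "se_p", "dp_hat", "se_dp", "dc_hat", "se_dc")}
        rec.update(c)
        rec["estimable"] = estimable
        rec["note"] = "; ".join(s for s in (note_p, note_d) if s)
        out.append(rec)
    lead = list(cells.columns) + ["p_hat", "se_p", "dp_hat", "se_dp", "dc_hat", "se_dc",
                                  "estimable", "note"]
    return pd.DataFrame(out)[lead]
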