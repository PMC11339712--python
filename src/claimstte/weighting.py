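"""Stabilized inverse-probability-of-treatment weights and balance diagnostics.

Baseline randomization is emulated by weighting each patient by
``P(arm) / P(arm | covariates)``, where the denominator comes from a
maximum-likelihood logistic propensity model on the full baseline covariate
design and the numerator is the marginal arm share (stabilization, so the
weights average ~1 and the pseudo-population preserves arm sizes).  Weights
are truncated at an upper percentile of the pooled distribution.  Balance
is summarised as weighted/unweighted mean differences: absolute proportion
differences for categorical covariates and standardized mean differences
(pooled unweighted SD denominator) for continuous ones, flagged at the
conventional 0.10 threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger("claimstte")

#: covariates entering the propensity design, in order; categorical
#: antihypertensive count expands to indicator columns
DESIGN_BINARY = [
    "sex_male", "race_nonwhite", "obesity", "cad", "cerebrovascular",
    "heart_failure", "afib", "ckd_1_3", "copd", "diabetes", "insulin",
    "beta_blocker", "statin", "antiplatelet", "cilostazol", "anticoagulant",
    "prior_male", "prior_mace", "rest_pain", "tissue_loss", "febuxostat",
    "prior_steroid",
]
DESIGN_CONTINUOUS = ["age", "elixhauser", "calendar_blocks", "enrol_blocks",
                     "gout_encounters"]

BALANCE_CONTINUOUS = ["age", "elixhauser", "calendar_blocks", "enrol_blocks"]

IMBALANCE_THRESHOLD = 0.10


class PropensityError(RuntimeError):
    """Propensity fit failed (separation or non-convergence)."""


class PositivityError(ValueError):
    """A fitted treatment probability of 0 or 1 makes weights undefined."""


def design_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Main-effects covariate design (no intercept column)."""
    X = pd.DataFrame(index=cohort.index)
    X["age"] = cohort["age"].astype(float)
    for c in DESIGN_BINARY:
        X[c] = cohort[c].astype(float)
    for j, name in ((1, "antihtn_1"), (2, "antihtn_2"), (3, "antihtn_3p")):
        X[name] = (cohort["antihtn_count"] == j).astype(float)
    for c in ("elixhauser", "calendar_blocks", "enrol_blocks", "gout_encounters"):
        X[c] = cohort[c].astype(float)
    return X


@dataclass
class PropensityModel:
    columns: list[str]
    params: pd.Series
    bse: pd.Series
    fitted: np.ndarray          # P(colchicine | covariates) per patient
    converged: bool
    dropped: list[str] = field(default_factory=list)


def fit_propensity(cohort: pd.DataFrame) -> PropensityModel:
    """ML logistic fit of the colchicine-arm indicator on the covariate design.

    Constant covariate columns are dropped with a logged warning.  Raises
    :class:`PropensityError` on separation or non-convergence, naming the
    covariates with runaway coefficients.
    """
    y = (cohort["arm"] == "colchicine").to_numpy(dtype=float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise PropensityError("need at least 2 patients per arm")
    X = design_matrix(cohort)
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    # a binary covariate with an empty covariate-by-arm cell separates the
    # likelihood (infinite MLE); drop it like a constant column
    for col in X.columns:
        if col in dropped or X[col].nunique() > 2:
            continue
        x = X[col].to_numpy()
        lo = x == x.min()
        cells = [(lo & (y == a)).sum() for a in (0, 1)] + \
                [(~lo & (y == a)).sum() for a in (0, 1)]
        if min(cells) == 0:
            dropped.append(col)
    if dropped:
        logger.warning("dropping constant or separating covariate columns: %s",
                       dropped)
        X = X.drop(columns=dropped)
    Xc = sm.add_constant(X, has_constant="add")
    try:
        res = sm.Logit(y, Xc).fit(disp=0, maxiter=100)
    except Exception as exc:  # PerfectSeparationError, LinAlgError
        raise PropensityError(f"propensity fit failed: {exc}") from exc
    p = np.asarray(res.predict(Xc))
    runaway = [c for c, b in res.params.items() if c != "const" and abs(b) > 15]
    if not res.mle_retvals.get("converged", True) or runaway:
        raise PropensityError(
            f"propensity fit did not converge; suspect covariates: {runaway}")
    return PropensityModel(columns=list(Xc.columns), params=res.params,
                           bse=res.bse, fitted=p, converged=True,
                           dropped=dropped)


@dataclass
class WeightSet:
    weights: np.ndarray            # stabilized, possibly truncated
    raw_weights: np.ndarray        # pre-truncation
    propensity: np.ndarray
    truncation_percentile: float | None = None

    def validate(self) -> None:
        if (self.weights <= 0).any():
            raise ValueError("weights must be positive")
        if (self.weights > self.raw_weights + 1e-12).any():
            raise ValueError("truncated weights exceed raw weights")


def stabilized_weights(model: PropensityModel, arms: pd.Series | np.ndarray) -> WeightSet:
    """Stabilized IPT weights: P(arm)/p_i for colchicine, (1-P(arm))/(1-p_i)
    for the comparator arm."""
    treated = np.asarray(arms) == "colchicine"
    p = model.fitted
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise PositivityError("fitted treatment probability of 0 or 1")
    share = treated.mean()
    w = np.where(treated, share / p, (1.0 - share) / (1.0 - p))
    return WeightSet(weights=w.copy(), raw_weights=w, propensity=p)


def truncate_weights(ws: WeightSet, percentile: float = 99.0) -> WeightSet:
    """Cap weights at the pooled upper ``percentile`` (one-sided)."""
    if not 0.0 < percentile <= 100.0:
        raise ValueError("percentile must be in (0, 100]")
    # order-statistic cap ("higher") so truncation is idempotent
    cap = np.percentile(ws.raw_weights, percentile, method="higher")
    w = np.minimum(ws.raw_weights, cap)
    out = WeightSet(weights=w, raw_weights=ws.raw_weights,
                    propensity=ws.propensity, truncation_percentile=percentile)
    out.validate()
    return out


def _categorical_rows(cohort: pd.DataFrame) -> dict[str, np.ndarray]:
    rows = {c: cohort[c].to_numpy(dtype=float) for c in DESIGN_BINARY}
    for j, name in ((0, "antihtn_0"), (1, "antihtn_1"), (2, "antihtn_2"),
                    (3, "antihtn_3p")):
        rows[name] = (cohort["antihtn_count"] == j).to_numpy(dtype=float)
    rows["gout_encounters"] = (cohort["gout_encounters"] > 0).to_numpy(dtype=float)
    return rows


def mean_difference(x_treated: np.ndarray, x_control: np.ndarray,
                    w_treated: np.ndarray | None = None,
                    w_control: np.ndarray | None = None,
                    pooled_sd: float | None = None) -> float:
    """|weighted mean difference|, standardized by ``pooled_sd`` if given."""
    m1 = np.average(x_treated, weights=w_treated)
    m0 = np.average(x_control, weights=w_control)
    d = abs(m1 - m0)
    if pooled_sd is not None:
        d = d / pooled_sd if pooled_sd > 0 else d
    return float(d)


def balance_table(cohort: pd.DataFrame, weights: WeightSet) -> pd.DataFrame:
    """Covariate balance before and after weighting.

    Continuous covariates use the unweighted pooled SD
    sqrt((s1^2 + s0^2)/2) in both columns so pre/post values share a
    denominator; zero-SD covariates are flagged and reported unstandardized.
    """
    treated = (cohort["arm"] == "colchicine").to_numpy()
    w = weights.weights
    records = []
    for name, x in _categorical_rows(cohort).items():
        d_un = mean_difference(x[treated], x[~treated])
        d_w = mean_difference(x[treated], x[~treated], w[treated], w[~treated])
        records.append((name, "categorical",
                        np.mean(x[treated]), np.mean(x[~treated]), d_un,
                        np.average(x[treated], weights=w[treated]),
                        np.average(x[~treated], weights=w[~treated]), d_w))
    for name in BALANCE_CONTINUOUS:
        x = cohort[name].to_numpy(dtype=float)
        s1, s0 = np.std(x[treated], ddof=1), np.std(x[~treated], ddof=1)
        pooled = np.sqrt((s1**2 + s0**2) / 2.0)
        if pooled <= 0:
            logger.warning("zero pooled SD for %s; reporting unstandardized", name)
            pooled = None
        d_un = mean_difference(x[treated], x[~treated], pooled_sd=pooled)
        d_w = mean_difference(x[treated], x[~treated], w[treated], w[~treated],
                              pooled_sd=pooled)
        records.append((name, "continuous",
                        np.mean(x[treated]), np.mean(x[~treated]), d_un,
                        np.average(x[treated], weights=w[treated]),
                        np.average(x[~treated], weights=w[~treated]), d_w))
    tab = pd.DataFrame(records, columns=[
        "covariate", "kind", "mean_treated", "mean_control", "diff_unweighted",
        "wmean_treated", "wmean_control", "diff_weighted"])
    tab["flag_unweighted"] = tab["diff_unweighted"] > IMBALANCE_THRESHOLD
    tab["flag_weighted"] = tab["diff_weighted"] > IMBALANCE_THRESHOLD
    return tab


def compute_weights(cohort: pd.DataFrame, truncate_pct: float = 99.0
                    ) -> tuple[WeightSet, PropensityModel]:
    """Fit propensity, stabilize and truncate in one call."""
    model = fit_propensity(cohort)
    ws = stabilized_weights(model, cohort["arm"])
    ws = truncate_weights(ws, truncate_pct)
    return ws, model
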