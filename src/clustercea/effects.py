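"""Covariate-adjusted between-arm differences under the cluster design.

The primary estimator is a linear mixed model with a village random
intercept, township fixed effects (matching the stratified
randomization), the baseline value of the outcome, age and sex as fixed
covariates, fit by REML — with a documented fallback to OLS with
cluster-robust (village) standard errors when the random-intercept
variance estimate degenerates or the fit fails. Analyses are
intention-to-treat with complete-case handling of missing outcome waves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import ValidationError

logger = logging.getLogger("clustercea")

#: columns a participant-level analysis frame must provide
FRAME_COLUMNS = ("participant_id", "arm", "village", "township", "age", "sex")


@dataclass(frozen=True)
class EffectEstimate:
    """An adjusted (or raw) arm difference: intervention minus control."""

    outcome: str
    delta: float
    se: float
    ci95: tuple[float, float]
    n_by_arm: dict[str, int]
    method: str

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValidationError("standard error must be >= 0")
        if not self.ci95[0] <= self.delta <= self.ci95[1]:
            raise ValidationError("ci95 must contain delta")


def _check_frame(data: pd.DataFrame, outcome: str) -> pd.DataFrame:
    missing = [c for c in FRAME_COLUMNS if c not in data.columns]
    if missing:
        raise ValidationError(f"analysis frame missing column(s): {missing}")
    if outcome not in data.columns:
        raise ValidationError(f"outcome column {outcome!r} not in frame")
    arms = set(data["arm"].unique())
    if arms != {"intervention", "control"}:
        raise ValidationError(f"need both arms present, got {sorted(arms)}")
    return data


def _design(df: pd.DataFrame, baseline: str | None) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, arm, township dummies, baseline, age, sex."""
    cols: list[np.ndarray] = [np.ones(len(df)), (df["arm"] == "intervention").to_numpy(float)]
    names = ["const", "arm"]
    towns = sorted(df["township"].unique())
    for t in towns[1:]:
        cols.append((df["township"] == t).to_numpy(float))
        names.append(f"township[{t}]")
    if baseline is not None:
        cols.append(df[baseline].to_numpy(float))
        names.append(baseline)
    cols.append(df["age"].to_numpy(float))
    names.append("age")
    cols.append(df["sex"].to_numpy(float))
    names.append("sex")
    return np.column_stack(cols), names


def _complete_cases(data, outcome, baseline):
    cols = [outcome] + ([baseline] if baseline else [])
    cc = data.dropna(subset=cols)
    dropped = len(data) - len(cc)
    if dropped:
        logger.info("%s: %d incomplete case(s) excluded", outcome, dropped)
    return cc


def _validate_design(df: pd.DataFrame, adjusted: bool) -> None:
    per_arm = df.groupby("arm")["village"].nunique()
    if per_arm.min() < 2:
        raise ValidationError(
            f"need >= 2 villages per arm, got {per_arm.to_dict()}"
        )
    if adjusted:
        one_armed = [
            t for t, g in df.groupby("township") if g["arm"].nunique() < 2
        ]
        if one_armed:
            raise ValidationError(
                f"township stratum(s) entirely one arm: {one_armed}"
            )


def adjusted_difference(
    data: pd.DataFrame,
    outcome: str,
    baseline: str | None = None,
    method: str = "reml",
) -> EffectEstimate:
    """Adjusted arm difference from the mixed multilevel model.

    ``data`` is a participant-level frame (see :data:`FRAME_COLUMNS`)
    with one row per participant. ``baseline`` names the baseline value
    of the outcome (e.g. baseline SBP for SBP change), included as a
    fixed covariate. ``method`` is ``"reml"`` (mixed model, the
    default), ``"ols_cluster"`` (fixed effects only, village-clustered
    robust SEs) or ``"ols_point"`` (fast point estimate, SE from
    clustered OLS formulas skipped — used internally by the bootstrap).
    """
    data = _check_frame(data, outcome)
    cc = _complete_cases(data, outcome, baseline)
    _validate_design(cc, adjusted=True)
    y = cc[outcome].to_numpy(float)
    X, names = _design(cc, baseline)
    j = names.index("arm")
    n_by_arm = cc.groupby("arm").size().to_dict()

    if method == "reml":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = sm.MixedLM(y, X, groups=cc["village"].to_numpy())
                fit = md.fit(reml=True)
            delta, se = float(fit.params[j]), float(fit.bse[j])
            if not (np.isfinite(delta) and np.isfinite(se) and se > 0):
                raise np.linalg.LinAlgError("degenerate mixed-model fit")
            used = "reml"
        except (np.linalg.LinAlgError, ValueError):
            logger.warning("%s: REML fit failed; cluster-robust OLS fallback", outcome)
            delta, se = _ols_cluster(y, X, j, cc["village"].to_numpy())
            used = "ols_cluster"
    elif method == "ols_cluster":
        delta, se = _ols_cluster(y, X, j, cc["village"].to_numpy())
        used = "ols_cluster"
    else:
        raise ValueError(f"unknown method {method!r}")

    z = stats.norm.ppf(0.975)
    return EffectEstimate(
        outcome=outcome,
        delta=delta,
        se=se,
        ci95=(delta - z * se, delta + z * se),
        n_by_arm=n_by_arm,
        method=used,
    )


def _ols_cluster(y, X, j, groups) -> tuple[float, float]:
    fit = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": groups})
    return float(fit.params[j]), float(fit.bse[j])


def unadjusted_difference(data: pd.DataFrame, outcome: str) -> EffectEstimate:
    """Raw arm mean difference with villages treated as independent units."""
    data = _check_frame(data, outcome)
    cc = _complete_cases(data, outcome, None)
    per_arm = cc.groupby("arm")["village"].nunique()
    if per_arm.min() < 2:
        raise ValidationError(
            f"cluster-robust SE undefined with a single village per arm: {per_arm.to_dict()}"
        )
    y = cc[outcome].to_numpy(float)
    X = np.column_stack([np.ones(len(cc)), (cc["arm"] == "intervention").to_numpy(float)])
    delta, se = _ols_cluster(y, X, 1, cc["village"].to_numpy())
    z = stats.norm.ppf(0.975)
    return EffectEstimate(
        outcome=outcome,
        delta=delta,
        se=se,
        ci95=(delta - z * se, delta + z * se),
        n_by_arm=cc.groupby("arm").size().to_dict(),
        method="raw_cluster",
    )


def fast_adjusted_delta(
    data: pd.DataFrame, outcome: str, baseline: str | None = None
) -> float:
    """Point estimate of the adjusted arm difference by plain least squares.

    Same fixed-effect design as :func:`adjusted_difference`; used where
    thousands of refits are needed (bootstrap replications, repeated-
    simulation studies) and only the coefficient is wanted.
    """
    cc = data.dropna(subset=[outcome] + ([baseline] if baseline else []))
    y = cc[outcome].to_numpy(float)
    X, names = _design(cc, baseline)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[names.index("arm")])
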