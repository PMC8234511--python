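"""Discrimination and calibration metrics for external validation.

Given predicted risks and observed binary outcomes this module computes the
C statistic (with a seeded nonparametric bootstrap interval), the Brier
score, the predicted-to-observed ratio, the calibration intercept and slope
on the log-odds scale, and a decile calibration table, bundled into a
:class:`ValidationReport`.

Two notions of "calibration-in-the-large" circulate.  The primary one here
is the log-odds offset definition: the intercept of a logistic fit of the
outcome on the prognostic index with the slope fixed at 1 (negative values
signal systematic overprediction).  The simple difference of mean observed
and mean predicted risk is exposed separately as
:func:`calibration_in_the_large_risk_difference`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import rankdata

from .registry import RiskPredictions

__all__ = [
    "CStatistic",
    "ValidationReport",
    "c_statistic",
    "brier",
    "predicted_to_observed",
    "calibration_intercept_slope",
    "calibration_in_the_large_risk_difference",
    "decile_table",
    "validate",
    "plot_calibration",
]

RISK_CLIP = 1e-12  # risks are clipped to [RISK_CLIP, 1 - RISK_CLIP] before logit


def _coerce(preds, outcomes) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(preds, RiskPredictions):
        risk = np.asarray(preds.risk, dtype=float)
    else:
        risk = np.asarray(preds, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if risk.shape != y.shape:
        raise ValueError(f"length mismatch: {risk.shape[0]} predictions vs {y.shape[0]} outcomes")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    return risk, y


@dataclass(frozen=True)
class CStatistic:
    value: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0

    def __float__(self) -> float:
        return self.value


def _c_value(risk: np.ndarray, y: np.ndarray) -> float:
    # Mann-Whitney form: concordant event/non-event pairs, ties counting 1/2.
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = rankdata(risk)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def c_statistic(preds, outcomes, n_boot: int = 2000, seed: int = 0) -> CStatistic:
    """C statistic (AUC): probability that a random event case is ranked
    above a random non-event case, tied risks counting one half.

    The interval is a seeded percentile bootstrap (default 2,000 resamples);
    pass ``n_boot=0`` to skip it.  Raises if only one outcome class is
    present (the statistic is undefined).
    """
    risk, y = _coerce(preds, outcomes)
    if y.min() == y.max():
        raise ValueError("C statistic undefined: only one outcome class present")
    value = _c_value(risk, y)
    if n_boot <= 0:
        return CStatistic(value=value)
    rng = np.random.default_rng(seed)
    n = len(y)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():  # degenerate resample: redraw once, then skip
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.min() == yb.max():
                stats[b] = np.nan
                continue
        stats[b] = _c_value(risk[idx], yb)
    lo, hi = np.nanpercentile(stats, [2.5, 97.5])
    return CStatistic(value=value, ci_low=float(lo), ci_high=float(hi), n_boot=n_boot)


def brier(preds, outcomes) -> float:
    """Mean squared difference between predicted risk and outcome."""
    risk, y = _coerce(preds, outcomes)
    return float(np.mean((risk - y) ** 2))


def predicted_to_observed(preds, outcomes) -> float:
    """Mean predicted risk divided by the observed event proportion."""
    risk, y = _coerce(preds, outcomes)
    observed = y.mean()
    if observed == 0:
        raise ValueError("predicted-to-observed ratio undefined with zero observed events")
    return float(risk.mean() / observed)


def calibration_in_the_large_risk_difference(preds, outcomes) -> float:
    """Mean observed risk minus mean predicted risk (probability scale)."""
    risk, y = _coerce(preds, outcomes)
    return float(y.mean() - risk.mean())


def _prognostic_index(preds, risk: np.ndarray) -> np.ndarray:
    if isinstance(preds, RiskPredictions):
        return np.asarray(preds.prognostic_index, dtype=float)
    return logit(np.clip(risk, RISK_CLIP, 1 - RISK_CLIP))


def calibration_intercept_slope(preds, outcomes) -> tuple[float, float]:
    """Calibration intercept and slope on the log-odds scale.

    The slope is the coefficient of the prognostic index in a logistic fit
    of outcome on the index; the intercept comes from a logistic fit with
    the index entered as a fixed offset (slope held at 1).  A perfectly
    calibrated model gives (0, 1); a negative intercept signals systematic
    overprediction.
    """
    risk, y = _coerce(preds, outcomes)
    if y.min() == y.max():
        raise ValueError("calibration undefined: only one outcome class present")
    pi = _prognostic_index(preds, risk)
    try:
        slope_fit = sm.Logit(y, sm.add_constant(pi)).fit(
            method="newton", tol=1e-8, maxiter=100, disp=0
        )
        offset_fit = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=pi).fit(
            tol=1e-8, maxiter=100
        )
    except Exception as exc:  # statsmodels raises on perfect separation
        raise ValueError(
            "calibration fit failed (possible perfect separation); "
            "consider a penalized fit"
        ) from exc
    if not slope_fit.mle_retvals.get("converged", True):
        raise ValueError("calibration slope fit did not converge")
    return float(offset_fit.params[0]), float(slope_fit.params[1])


def decile_table(preds, outcomes, n_groups: int = 10) -> pd.DataFrame:
    """Calibration table over tenths of increasing predicted risk.

    Subjects are ranked by predicted risk with a stable ordering (ties keep
    input order) and split into ``n_groups`` near-equal groups; when n is
    not divisible, the remainder is allocated to the lowest-risk groups.
    Columns: ``group, n, mean_predicted, observed_proportion``.
    """
    risk, y = _coerce(preds, outcomes)
    n = len(y)
    if n < n_groups:
        raise ValueError(f"need at least {n_groups} subjects for {n_groups} groups, got {n}")
    order = np.argsort(risk, kind="stable")
    base, rem = divmod(n, n_groups)
    sizes = [base + 1 if g < rem else base for g in range(n_groups)]
    rows, start = [], 0
    for g, size in enumerate(sizes, start=1):
        idx = order[start : start + size]
        rows.append(
            {
                "group": g,
                "n": size,
                "mean_predicted": float(risk[idx].mean()),
                "observed_proportion": float(y[idx].mean()),
            }
        )
        start += size
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Discrimination and calibration summary for one model on one cohort."""

    model_name: str
    n: int
    n_events: int
    c_statistic: CStatistic
    brier: float
    predicted_to_observed: float
    calibration_intercept: float
    calibration_slope: float
    decile_table: pd.DataFrame

    @property
    def prevalence(self) -> float:
        return self.n_events / self.n

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "n": self.n,
            "n_events": self.n_events,
            "c_statistic": self.c_statistic.value,
            "c_statistic_ci": [self.c_statistic.ci_low, self.c_statistic.ci_high],
            "brier": self.brier,
            "predicted_to_observed": self.predicted_to_observed,
            "calibration_intercept": self.calibration_intercept,
            "calibration_slope": self.calibration_slope,
        }

    def summary(self) -> str:
        d = self.to_dict()
        lines = [f"Validation of {self.model_name} (n={self.n}, events={self.n_events})"]
        for key in (
            "c_statistic",
            "brier",
            "predicted_to_observed",
            "calibration_intercept",
            "calibration_slope",
        ):
            lines.append(f"  {key:<24s} {d[key]:.3f}")
        return "\n".join(lines)


def validate(preds, outcomes, model_name: str = "", n_boot: int = 2000, seed: int = 0) -> ValidationReport:
    """Full discrimination/calibration work-up for one prediction set."""
    risk, y = _coerce(preds, outcomes)
    a, b = calibration_intercept_slope(preds, outcomes)
    name = model_name or (preds.model_name if isinstance(preds, RiskPredictions) else "")
    return ValidationReport(
        model_name=name,
        n=len(y),
        n_events=int(y.sum()),
        c_statistic=c_statistic(preds, outcomes, n_boot=n_boot, seed=seed),
        brier=brier(preds, outcomes),
        predicted_to_observed=predicted_to_observed(preds, outcomes),
        calibration_intercept=a,
        calibration_slope=b,
        decile_table=decile_table(preds, outcomes),
    )


def plot_calibration(report: ValidationReport | pd.DataFrame, ax=None):
    """Observed proportion vs mean predicted risk by tenths, identity dashed."""
    import matplotlib.pyplot as plt

    table = report.decile_table if isinstance(report, ValidationReport) else report
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    lim = max(table["mean_predicted"].max(), table["observed_proportion"].max()) * 1.1
    ax.plot([0, lim], [0, lim], linestyle="--", color="grey", linewidth=1)
    ax.plot(table["mean_predicted"], table["observed_proportion"], "o-", color="tab:blue")
    ax.set_xlabel("Mean predicted risk (by tenth)")
    ax.set_ylabel("Observed proportion")
    title = report.model_name if isinstance(report, ValidationReport) else ""
    if title:
        ax.set_title(title)
    return ax
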