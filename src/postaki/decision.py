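"""Decision curve analysis: net benefit of follow-up decision strategies.

Net benefit at a threshold probability p_t weighs true positives against
false positives::

    NB = TP/n - (FP/n) * p_t / (1 - p_t)

where a "positive" is a subject the strategy selects for targeted
follow-up.  The threshold encodes the harm-benefit tradeoff: at p_t = 0.1
one true positive balances nine false positives.  Strategies may be
model-guided (treat when predicted risk >= p_t, boundary inclusive) or
simple covariate rules (treat everyone, no one, anyone with AKI, AKI stage
2-3 only, or discharge eGFR < 30 mL/min/1.73 m2 as a proxy for
non-recovery).  The default threshold grid is 0.01-0.50 in steps of 0.01,
covering the prespecified 1%, 10% and 30% decision points; curves are not
smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .registry import ModelSpec

__all__ = [
    "DecisionStrategy",
    "ClassificationTable",
    "NetBenefitCurve",
    "RULE_NAMES",
    "net_benefit",
    "decision_curve",
    "classification_table",
    "exchange_rate",
    "default_threshold_grid",
    "plot_decision_curve",
]

_RULES: dict[str, Callable[[pd.DataFrame], np.ndarray]] = {
    "treat_all": lambda c: np.ones(len(c), dtype=bool),
    "treat_none": lambda c: np.zeros(len(c), dtype=bool),
    "any_aki": lambda c: c["aki_stage"].astype(int).to_numpy() >= 1,
    "aki_stage_2_or_3": lambda c: c["aki_stage"].astype(int).to_numpy() >= 2,
    "discharge_egfr_lt_30": lambda c: c["discharge_egfr"].to_numpy(dtype=float) < 30.0,
}

RULE_NAMES = tuple(_RULES)


@dataclass(frozen=True)
class DecisionStrategy:
    """A deterministic rule mapping each subject to treat / not treat.

    Either a model-guided strategy (``model`` set; treat when predicted risk
    >= the current threshold) or a named covariate rule from
    :data:`RULE_NAMES`.
    """

    label: str
    model: ModelSpec | None = None
    rule: str | None = None

    def __post_init__(self) -> None:
        if (self.model is None) == (self.rule is None):
            raise ValueError("a strategy is either model-guided or a named rule, not both")
        if self.rule is not None and self.rule not in _RULES:
            raise ValueError(f"unknown rule {self.rule!r}; known rules: {RULE_NAMES}")

    @classmethod
    def from_model(cls, model: ModelSpec, label: str | None = None) -> "DecisionStrategy":
        return cls(label=label or model.name, model=model)

    @classmethod
    def from_rule(cls, rule: str, label: str | None = None) -> "DecisionStrategy":
        return cls(label=label or rule, rule=rule)

    def treat_mask(self, cohort: pd.DataFrame, threshold: float) -> np.ndarray:
        _check_threshold(threshold)
        if self.model is not None:
            return self.model.predict_risk(cohort) >= threshold
        return _RULES[self.rule](cohort)  # type: ignore[index]


@dataclass(frozen=True)
class ClassificationTable:
    """2x2 classification of a strategy against the outcome at one threshold."""

    strategy: str
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def percent_correct(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def net_benefit(self) -> float:
        w = self.threshold / (1.0 - self.threshold)
        return self.tp / self.n - (self.fp / self.n) * w

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"outcome": [1, 0], "treated": [self.tp, self.fp], "untreated": [self.fn, self.tn]}
        ).set_index("outcome")


@dataclass
class NetBenefitCurve:
    """Net benefit per strategy over a grid of threshold probabilities."""

    thresholds: np.ndarray
    series: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, **self.series})


def _check_threshold(threshold: float) -> None:
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold probability must lie strictly in (0, 1); got {threshold}")


def _outcome_array(cohort: pd.DataFrame, outcome) -> np.ndarray:
    y = cohort[outcome].to_numpy(dtype=float) if isinstance(outcome, str) else np.asarray(outcome, float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    return y


def classification_table(
    strategy: DecisionStrategy, cohort: pd.DataFrame, threshold: float, outcome
) -> ClassificationTable:
    """Full 2x2 with percent correctly classified and net benefit."""
    y = _outcome_array(cohort, outcome)
    treat = strategy.treat_mask(cohort, threshold)
    return ClassificationTable(
        strategy=strategy.label,
        threshold=float(threshold),
        tp=int((treat & (y == 1)).sum()),
        fp=int((treat & (y == 0)).sum()),
        tn=int((~treat & (y == 0)).sum()),
        fn=int((~treat & (y == 1)).sum()),
    )


def net_benefit(
    strategy: DecisionStrategy, cohort: pd.DataFrame, threshold: float, outcome
) -> float:
    """Net benefit of one strategy at one threshold probability."""
    return classification_table(strategy, cohort, threshold, outcome).net_benefit


def default_threshold_grid() -> np.ndarray:
    return np.round(np.arange(0.01, 0.505, 0.01), 2)


def decision_curve(
    strategies: Sequence[DecisionStrategy],
    cohort: pd.DataFrame,
    outcome,
    thresholds: Iterable[float] | None = None,
) -> NetBenefitCurve:
    """One net-benefit series per strategy over the threshold grid.

    Model-guided strategies are re-thresholded at every grid point.
    """
    if not strategies:
        raise ValueError("at least one decision strategy is required")
    grid = np.asarray(list(thresholds) if thresholds is not None else default_threshold_grid(), float)
    for t in grid:
        _check_threshold(t)
    y = _outcome_array(cohort, outcome)
    n = len(y)
    curve = NetBenefitCurve(thresholds=grid)
    for strat in strategies:
        values = np.empty(len(grid))
        if strat.model is not None:
            risk = strat.model.predict_risk(cohort)
            for i, t in enumerate(grid):
                treat = risk >= t
                tp = (treat & (y == 1)).sum()
                fp = (treat & (y == 0)).sum()
                values[i] = tp / n - (fp / n) * t / (1 - t)
        else:
            treat = strat.treat_mask(cohort, grid[0])
            tp = (treat & (y == 1)).sum()
            fp = (treat & (y == 0)).sum()
            values = tp / n - (fp / n) * grid / (1 - grid)
        curve.series[strat.label] = values
    return curve


def exchange_rate(threshold: float) -> float:
    """Acceptable false positives per true positive at a threshold: (1-p)/p."""
    _check_threshold(threshold)
    return (1.0 - threshold) / threshold


def plot_decision_curve(curve: NetBenefitCurve, ax=None, ylim_floor: float | None = None):
    """Net benefit vs threshold probability, one line per strategy."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, values in curve.series.items():
        ax.plot(curve.thresholds, values, label=label)
    ax.axhline(0.0, color="grey", linewidth=0.8)
    ax.set_xlabel("Threshold probability")
    ax.set_ylabel("Net benefit")
    if ylim_floor is not None:
        ax.set_ylim(bottom=ylim_floor)
    ax.legend(fontsize=8)
    return ax
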