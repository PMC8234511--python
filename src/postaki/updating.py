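"""Model updating for a new population: logistic recalibration and refitting.

Logistic recalibration fits the outcome on the prognostic index alone
(outcome ~ a + b*PI) and folds the fitted intercept a and slope b back into
the model equation, so every coefficient is multiplied by b and the
intercept becomes a + b*beta0.  Recalibration is a monotone transform of
the index, so discrimination is preserved exactly; by construction the
recalibrated model is perfectly calibrated on the cohort used to fit it.

Refitting re-estimates the coefficients de novo by maximum likelihood over
exactly the original term structure — the same codings, scale divisors and
polynomial terms, with no added variables (deliberately, to avoid apparent
performance gains from saturating the model).  No shrinkage or penalization
is applied; for small cohorts this is a documented limitation.

Fits use Newton-Raphson (iteratively reweighted least squares), declaring
convergence when the maximum coefficient change drops below 1e-8, and
failing with diagnostics after 100 iterations.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .registry import ModelSpec, Term

__all__ = ["logistic_recalibration", "refit", "log_likelihood"]

_TOL = 1e-8
_MAXITER = 100


def _outcome_vector(model: ModelSpec, cohort: pd.DataFrame, outcome: str | None) -> np.ndarray:
    col = outcome or model.outcome_label
    if col not in cohort.columns:
        raise KeyError(f"cohort is missing the outcome column {col!r}")
    y = cohort[col].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"outcome column {col!r} must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("cohort must contain both outcome classes")
    return y


def _cohort_hash(cohort: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(cohort, index=False).to_numpy().tobytes()
    ).hexdigest()[:16]


def _fit_logit(y: np.ndarray, X: np.ndarray, what: str):
    try:
        res = sm.Logit(y, X).fit(method="newton", tol=_TOL, maxiter=_MAXITER, disp=0)
    except Exception as exc:
        raise ValueError(f"{what} failed (possible separation): {exc}") from exc
    retvals = res.mle_retvals
    if not retvals.get("converged", True):
        raise ValueError(
            f"{what} did not converge within {_MAXITER} iterations "
            f"(iterations={retvals.get('iterations')})"
        )
    return res


def logistic_recalibration(
    model: ModelSpec, cohort: pd.DataFrame, outcome: str | None = None
) -> ModelSpec:
    """Recalibrate ``model`` to ``cohort`` via the prognostic index.

    Returns a new :class:`ModelSpec` whose coefficients are the original
    ones multiplied by the fitted calibration slope, with the baseline risk
    shifted by the fitted calibration intercept.  The fitted (intercept,
    slope) and fit diagnostics are recorded in the returned model's
    ``metadata``.
    """
    y = _outcome_vector(model, cohort, outcome)
    pi = model.linear_predictor(cohort)
    res = _fit_logit(y, sm.add_constant(pi), "logistic recalibration")
    a, b = float(res.params[0]), float(res.params[1])
    updated = model.rescaled(intercept_shift=a, slope_factor=b, name=f"{model.name}_recalibrated")
    updated.metadata.update(
        {
            "updating_method": "logistic_recalibration",
            "parent_model": model.name,
            "calibration_intercept": a,
            "calibration_slope": b,
            "cohort_hash": _cohort_hash(cohort),
            "n": int(len(cohort)),
            "iterations": int(res.mle_retvals.get("iterations", -1)),
            "converged": True,
        }
    )
    return updated


def refit(model: ModelSpec, cohort: pd.DataFrame, outcome: str | None = None) -> ModelSpec:
    """Refit the model's exact term structure on ``cohort`` by maximum likelihood.

    An empty categorical level (or any other rank deficiency) is reported as
    an error naming the offending design column rather than silently dropped.
    """
    y = _outcome_vector(model, cohort, outcome)
    X = model.design_matrix(cohort)
    degenerate = [
        label
        for label in X.columns[1:]
        if np.ptp(X[label].to_numpy()) == 0.0
    ]
    if degenerate:
        raise ValueError(
            "design matrix is rank deficient: no variation in "
            + ", ".join(repr(c) for c in degenerate)
            + " (empty categorical level or constant predictor)"
        )
    res = _fit_logit(y, X.to_numpy(), "refit")
    params = dict(zip(X.columns, map(float, res.params)))
    new_terms: list[Term] = []
    for t in model.terms:
        if t.kind == "categorical":
            new_terms.append(
                Term(
                    predictor=t.predictor,
                    kind=t.kind,
                    reference=t.reference,
                    level_coefficients={
                        lvl: params[f"{t.predictor}[{lvl}]"] for lvl in t.level_coefficients  # type: ignore[union-attr]
                    },
                )
            )
        else:
            new_terms.append(
                Term(
                    predictor=t.predictor,
                    kind=t.kind,
                    coefficient=params[t.column_labels()[0]],
                    scale=t.scale,
                    degree=t.degree,
                )
            )
    refitted = ModelSpec(
        name=f"{model.name}_refit",
        outcome_label=model.outcome_label,
        intercept=params["(intercept)"],
        terms=tuple(new_terms),
        metadata={
            "updating_method": "refit",
            "parent_model": model.name,
            "cohort_hash": _cohort_hash(cohort),
            "n": int(len(cohort)),
            "iterations": int(res.mle_retvals.get("iterations", -1)),
            "converged": True,
            "log_likelihood": float(res.llf),
        },
    )
    return refitted


def log_likelihood(model: ModelSpec, cohort: pd.DataFrame, outcome: str | None = None) -> float:
    """Bernoulli log-likelihood of the cohort outcomes under the model."""
    y = _outcome_vector(model, cohort, outcome)
    p = np.clip(model.predict_risk(cohort), 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
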