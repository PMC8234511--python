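"""Published logistic prediction models stored as data, and scoring of cohorts.

A :class:`ModelSpec` is a fully specified logistic regression equation: an
intercept plus coded predictor terms on the log-odds scale.  The package ships
four models relevant to follow-up care after acute kidney injury (AKI):

``aberdeen_original`` / ``aberdeen_refit``
    90-day death-or-readmission models for all hospital survivors
    (derivation and refitted validation coefficient sets).
``alberta_original`` / ``alberta_refit``
    1-year CKD G4-G5 progression models for AKI survivors with preserved
    baseline kidney function.

Shipped coefficients are the natural logs of the published odds ratios at
their printed precision; no attempt is made to recover unrounded derivation
coefficients.  Two published oddities are kept verbatim and merely flagged
here: the readmissions model's age odds ratio (1.17 "per year older") is
implausibly large for a 1-year unit, and its residential-care point estimate
(1.37) lies below its printed confidence bound.  Users who want different
behaviour can supply their own spec; see ``models/`` for the schema.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

__all__ = [
    "Term",
    "ModelSpec",
    "RiskPredictions",
    "available_models",
    "load_model",
    "linear_predictor",
    "predicted_risk",
]

_TERM_KINDS = ("binary", "count", "continuous", "categorical")


@dataclass(frozen=True)
class Term:
    """One coded predictor term of a logistic model.

    ``kind`` is one of:

    - ``binary``: 0/1 indicator, ``coefficient`` per unit.
    - ``count``: nonnegative integer count, ``coefficient`` per unit.
    - ``continuous``: value coded as ``(x / scale) ** degree``.
    - ``categorical``: full level set with a declared reference level
      (implicit coefficient 0) and one coefficient per non-reference level.
    """

    predictor: str
    kind: str
    coefficient: float | None = None
    scale: float = 1.0
    degree: int = 1
    reference: str | None = None
    level_coefficients: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in _TERM_KINDS:
            raise ValueError(f"unknown term kind {self.kind!r}; expected one of {_TERM_KINDS}")
        if self.kind == "categorical":
            if self.reference is None or not self.level_coefficients:
                raise ValueError(
                    f"categorical term {self.predictor!r} needs a reference level "
                    "and per-level coefficients"
                )
            if any(not math.isfinite(c) for c in self.level_coefficients.values()):
                raise ValueError(f"non-finite coefficient in term {self.predictor!r}")
        else:
            if self.coefficient is None or not math.isfinite(self.coefficient):
                raise ValueError(f"term {self.predictor!r} needs a finite coefficient")

    @property
    def levels(self) -> tuple[str, ...]:
        """Full level set of a categorical term (reference first)."""
        if self.kind != "categorical":
            raise AttributeError("levels only defined for categorical terms")
        return (str(self.reference), *self.level_coefficients)  # type: ignore[misc]

    def column_labels(self) -> list[str]:
        if self.kind == "categorical":
            return [f"{self.predictor}[{lvl}]" for lvl in self.level_coefficients]  # type: ignore[union-attr]
        if self.kind == "continuous" and self.degree != 1:
            return [f"{self.predictor}^{self.degree}"]
        return [self.predictor]

    def coefficients(self) -> list[float]:
        if self.kind == "categorical":
            return [float(c) for c in self.level_coefficients.values()]  # type: ignore[union-attr]
        return [float(self.coefficient)]  # type: ignore[arg-type]

    def coded_columns(self, data: pd.DataFrame, model_name: str = "model") -> list[np.ndarray]:
        """Numeric design columns for this term, in ``column_labels`` order."""
        if self.predictor not in data.columns:
            raise KeyError(
                f"cohort is missing required predictor {self.predictor!r} "
                f"for model {model_name!r}"
            )
        col = data[self.predictor]
        if self.kind == "categorical":
            values = col.astype(str)
            known = set(self.levels)
            unknown = set(values.unique()) - known
            if unknown:
                raise ValueError(
                    f"predictor {self.predictor!r} has unknown levels {sorted(unknown)}; "
                    f"declared levels are {list(self.levels)}"
                )
            return [
                (values == lvl).to_numpy(dtype=float)
                for lvl in self.level_coefficients  # type: ignore[union-attr]
            ]
        x = col.to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"predictor {self.predictor!r} contains missing values")
        if self.kind == "continuous":
            return [(x / self.scale) ** self.degree]
        return [x]


@dataclass
class ModelSpec:
    """A published (or fitted) logistic model: intercept plus coded terms."""

    name: str
    outcome_label: str
    intercept: float
    terms: tuple[Term, ...]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.terms = tuple(self.terms)
        if not math.isfinite(self.intercept):
            raise ValueError("model intercept must be finite")

    # -- scoring ---------------------------------------------------------

    def required_predictors(self) -> list[str]:
        seen: list[str] = []
        for t in self.terms:
            if t.predictor not in seen:
                seen.append(t.predictor)
        return seen

    def coefficient_labels(self) -> list[str]:
        labels = ["(intercept)"]
        for t in self.terms:
            labels.extend(t.column_labels())
        return labels

    def coefficient_vector(self) -> np.ndarray:
        coefs = [self.intercept]
        for t in self.terms:
            coefs.extend(t.coefficients())
        return np.asarray(coefs, dtype=float)

    def design_matrix(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Design matrix (including the constant column) for this term structure."""
        cols: dict[str, np.ndarray] = {"(intercept)": np.ones(len(cohort))}
        for t in self.terms:
            for label, values in zip(t.column_labels(), t.coded_columns(cohort, self.name)):
                cols[label] = values
        return pd.DataFrame(cols, index=cohort.index)

    def linear_predictor(self, cohort: pd.DataFrame | Mapping[str, Any]) -> np.ndarray:
        cohort = _as_frame(cohort)
        X = self.design_matrix(cohort)
        return X.to_numpy() @ self.coefficient_vector()

    def predict_risk(self, cohort: pd.DataFrame | Mapping[str, Any]) -> np.ndarray:
        return expit(self.linear_predictor(cohort))

    def rescaled(self, intercept_shift: float, slope_factor: float, name: str | None = None) -> "ModelSpec":
        """Model with every coefficient scaled by ``slope_factor`` and intercept
        mapped to ``intercept_shift + slope_factor * intercept`` (logistic
        recalibration of the equation itself)."""
        new_terms = []
        for t in self.terms:
            if t.kind == "categorical":
                new_terms.append(
                    replace(
                        t,
                        level_coefficients={
                            k: slope_factor * v for k, v in t.level_coefficients.items()  # type: ignore[union-attr]
                        },
                    )
                )
            else:
                new_terms.append(replace(t, coefficient=slope_factor * t.coefficient))  # type: ignore[arg-type]
        return ModelSpec(
            name=name or f"{self.name}_rescaled",
            outcome_label=self.outcome_label,
            intercept=intercept_shift + slope_factor * self.intercept,
            terms=tuple(new_terms),
            metadata=dict(self.metadata),
        )

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        terms = []
        for t in self.terms:
            d: dict[str, Any] = {"predictor": t.predictor, "kind": t.kind}
            if t.kind == "categorical":
                d["reference"] = t.reference
                d["coefficients"] = {k: float(v) for k, v in t.level_coefficients.items()}  # type: ignore[union-attr]
            else:
                d["coefficient"] = float(t.coefficient)  # type: ignore[arg-type]
                if t.kind == "continuous":
                    d["scale"] = float(t.scale)
                    d["degree"] = int(t.degree)
            terms.append(d)
        return {
            "name": self.name,
            "outcome": self.outcome_label,
            "intercept": float(self.intercept),
            "terms": terms,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelSpec":
        terms = [_term_from_dict(td) for td in d["terms"]]
        return cls(
            name=d["name"],
            outcome_label=d["outcome"],
            intercept=float(d["intercept"]),
            terms=tuple(terms),
            metadata=dict(d.get("metadata") or {}),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _term_from_dict(d: Mapping[str, Any]) -> Term:
    kind = d["kind"]
    if kind == "categorical":
        if "odds_ratios" in d:
            coefs = {str(k): math.log(float(v)) for k, v in d["odds_ratios"].items()}
        else:
            coefs = {str(k): float(v) for k, v in d["coefficients"].items()}
        return Term(
            predictor=d["predictor"],
            kind=kind,
            reference=str(d["reference"]),
            level_coefficients=coefs,
        )
    if "odds_ratio" in d:
        coef = math.log(float(d["odds_ratio"]))
    else:
        coef = float(d["coefficient"])
    return Term(
        predictor=d["predictor"],
        kind=kind,
        coefficient=coef,
        scale=float(d.get("scale", 1.0)),
        degree=int(d.get("degree", 1)),
    )


@dataclass
class RiskPredictions:
    """Per-subject prognostic index (log-odds) and predicted risk."""

    prognostic_index: np.ndarray
    risk: np.ndarray
    model_name: str = ""

    def __len__(self) -> int:
        return len(self.risk)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"prognostic_index": self.prognostic_index, "risk": self.risk}
        )


# -- packaged model specs -------------------------------------------------


def _models_dir():
    return resources.files("postaki") / "models"


def available_models() -> list[str]:
    return sorted(p.name[: -len(".yaml")] for p in _models_dir().iterdir() if p.name.endswith(".yaml"))


def load_model(name: str) -> ModelSpec:
    """Load one of the packaged model specs by name."""
    res = _models_dir() / f"{name}.yaml"
    if not res.is_file():
        raise ValueError(
            f"unknown model {name!r}; available models: {', '.join(available_models())}"
        )
    return ModelSpec.from_dict(yaml.safe_load(res.read_text()))


def _as_frame(subject: pd.DataFrame | Mapping[str, Any]) -> pd.DataFrame:
    if isinstance(subject, pd.DataFrame):
        return subject
    if isinstance(subject, pd.Series):
        return subject.to_frame().T
    return pd.DataFrame([dict(subject)])


def linear_predictor(model: ModelSpec, subject: pd.DataFrame | Mapping[str, Any]) -> np.ndarray | float:
    """Prognostic index: intercept + sum of coefficient x coded value.

    Accepts a cohort table or a single subject mapping; for a single subject a
    scalar is returned.  A missing required predictor raises ``KeyError``
    naming the predictor — there is no silent imputation.
    """
    frame = _as_frame(subject)
    pi = model.linear_predictor(frame)
    if not isinstance(subject, pd.DataFrame) and len(pi) == 1:
        return float(pi[0])
    return pi


def predicted_risk(model: ModelSpec, cohort: pd.DataFrame | Mapping[str, Any]) -> RiskPredictions:
    """Score a cohort: prognostic index and inverse-logit risk per subject."""
    frame = _as_frame(cohort)
    pi = model.linear_predictor(frame)
    return RiskPredictions(prognostic_index=pi, risk=expit(pi), model_name=model.name)
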