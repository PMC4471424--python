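"""Log-link linear warfarin dose models.

A :class:`DoseModelSpec` is an intercept plus named-term coefficients under a
fixed log link: ``dose = exp(intercept + sum_v coef_v * x_v)`` in mg/wk. The
package bundles the two published clinical equations (Model I, baseline
exp(2.85332) ~ 17.35 mg/wk, and Model II, baseline exp(3.44056) ~ 31.20
mg/wk) and the fixed-dose comparator (35 mg/wk, i.e. 5 mg/day).

Race (codes 1-3) and age (decade codes 1-9) enter numerically, multiplied by
their coefficients exactly as the equations are written; no dummy coding is
applied. New class-specific models are refitted by ordinary least squares of
``ln(dose)`` on the same term lists.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg

from .cohort import Cohort, PatientRecord
from .errors import ValidationError
from .schema import DOSE

_FORMAT_VERSION = 1


@dataclass
class DoseModelSpec:
    """Intercept + named-term coefficients of a log-link linear dose model."""

    name: str
    intercept: float
    terms: dict[str, float] = field(default_factory=dict)
    link: str = "log"

    def __post_init__(self) -> None:
        if self.link != "log":
            raise ValidationError("only the log link is supported")

    def linear_predictor(self, values: Mapping[str, float]) -> float:
        total = self.intercept
        for term, coef in self.terms.items():
            v = values.get(term)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise ValidationError(f"missing covariate {term!r} for model {self.name!r}")
            total += coef * float(v)
        return total

    def to_file(self, path) -> None:
        """Write as structured text; float values round-trip bit-exactly."""
        payload = {
            "format_version": _FORMAT_VERSION,
            "name": self.name,
            "link": self.link,
            "intercept": self.intercept,
            "terms": self.terms,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_file(cls, path) -> "DoseModelSpec":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format_version") != _FORMAT_VERSION:
            raise ValidationError(f"unsupported model format in {path}")
        return cls(
            name=payload["name"],
            intercept=float(payload["intercept"]),
            terms={k: float(v) for k, v in payload["terms"].items()},
            link=payload.get("link", "log"),
        )


#: Clinical equation with the lower baseline (exp(2.85332) = 17.35 mg/wk).
MODEL_I = DoseModelSpec(
    name="model_I",
    intercept=2.85332,
    terms={
        "race": -0.07370,
        "age_decade": -0.06513,
        "dvt_pe": 0.10246,
        "diabetes": 0.05766,
        "valve_replacement": 0.03742,
        "lovastatin": -0.08763,
        "amiodarone": -0.12542,
        "target_inr": 0.13207,
        "enzyme": 0.12403,
        "bsa": 0.34487,
    },
)

#: Clinical equation with the higher baseline (exp(3.44056) = 31.20 mg/wk).
MODEL_II = DoseModelSpec(
    name="model_II",
    intercept=3.44056,
    terms={
        "race": -0.03649,
        "age_decade": -0.04820,
        "dvt_pe": 0.05059,
        "aspirin": -0.03060,
        "amiodarone": -0.06150,
        "antifungal_azoles": -0.20356,
        "smoker": 0.05744,
        "enzyme": 0.10923,
        "bsa": 0.24601,
    },
)

#: Constant 35 mg/wk (5 mg/day) comparator regimen.
FIXED_DOSE_35 = DoseModelSpec(name="fixed_dose", intercept=math.log(35.0), terms={})

_BUNDLED = {"model_I": MODEL_I, "model_II": MODEL_II, "fixed_dose": FIXED_DOSE_35}


def bundled_model(which: str) -> DoseModelSpec:
    """Return a copy of a bundled model: ``model_I``, ``model_II`` or ``fixed_dose``."""
    if which not in _BUNDLED:
        raise ValidationError(f"unknown bundled model {which!r}; choose from {sorted(_BUNDLED)}")
    src = _BUNDLED[which]
    return DoseModelSpec(src.name, src.intercept, dict(src.terms), src.link)


def predict_dose(spec: DoseModelSpec, p) -> float:
    """Predicted weekly dose (mg/wk) for one patient.

    ``p`` may be a :class:`PatientRecord`, mapping, or pandas Series; every
    term of the model must be present and non-missing.
    """
    if isinstance(p, PatientRecord):
        values = dict(p.items())
    elif isinstance(p, pd.Series):
        values = p.to_dict()
    else:
        values = dict(p)
    return float(np.exp(spec.linear_predictor(values)))


def predict_dose_frame(spec: DoseModelSpec, data: "pd.DataFrame | Cohort") -> np.ndarray:
    """Vectorized :func:`predict_dose` over a cohort or DataFrame."""
    df = data.data if isinstance(data, Cohort) else data
    eta = np.full(len(df), spec.intercept, dtype=float)
    for term, coef in spec.terms.items():
        if term not in df.columns:
            raise ValidationError(f"missing covariate {term!r} for model {spec.name!r}")
        col = df[term].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise ValidationError(f"missing values in covariate {term!r} for model {spec.name!r}")
        eta += coef * col
    return np.exp(eta)


def _collinear_terms(X: np.ndarray, names: list[str]) -> list[str]:
    """Identify a set of columns completing a rank-deficient design (pivoted QR)."""
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    return [names[i] for i in sorted(piv[rank:])]


def fit_loglinear(
    c: "Cohort | pd.DataFrame",
    term_names: list[str],
    min_n: int | None = None,
    name: str = "refit",
) -> DoseModelSpec:
    """Ordinary least squares of ``ln(dose)`` on ``[1 | terms]``.

    Records must be complete in the requested terms and carry a positive
    dose; ``min_n`` defaults to ``len(term_names) + 2``.
    """
    df = c.data if isinstance(c, Cohort) else c
    if min_n is None:
        min_n = len(term_names) + 2
    if DOSE not in df.columns:
        raise ValidationError("cohort has no dose column; cannot fit a dose model")
    missing_terms = [t for t in term_names if t not in df.columns]
    if missing_terms:
        raise ValidationError(f"terms absent from cohort: {missing_terms}")
    if len(df) < min_n:
        raise ValidationError(f"need at least {min_n} records, got {len(df)}")
    dose = df[DOSE].to_numpy(dtype=float)
    # column-by-column build keeps repeated term names as repeated columns
    X = np.column_stack([df[t].to_numpy(dtype=float) for t in term_names])
    if np.isnan(X).any() or np.isnan(dose).any():
        raise ValidationError("records must be complete in the model terms and dose")
    if (dose <= 0).any():
        raise ValidationError("all doses must be strictly positive")
    design = np.hstack([np.ones((len(X), 1)), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_terms(design, ["(intercept)"] + list(term_names))
        raise ValidationError(f"rank-deficient design; collinear terms: {bad}")
    fit = sm.OLS(np.log(dose), design).fit()
    coefs = fit.params
    return DoseModelSpec(
        name=name,
        intercept=float(coefs[0]),
        terms={t: float(coefs[i + 1]) for i, t in enumerate(term_names)},
    )
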