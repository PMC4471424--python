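"""Cohort schema: the clinical and demographic covariates of the warfarin cohort.

The default schema carries the variables used throughout the package: target
INR, body surface area (m²), race code (1-3), age-decade code (1-9), gender,
comorbidity and co-medication indicators, smoker status, enzyme-inducer
status, and the therapeutic weekly warfarin dose in mg/wk (the response,
optional on any given record).

Column-name matching is forgiving: header names are compared case-insensitively
with punctuation and whitespace stripped, so ``"Target INR"``, ``target_inr``
and ``TargetINR`` all resolve to the same variable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .errors import SchemaError

DOSE = "dose_mg_wk"

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


def _normalize(name: str) -> str:
    """Lower-case and strip everything but letters and digits."""
    return re.sub(r"[^a-z0-9]", "", name.lower())


@dataclass(frozen=True)
class VariableSpec:
    """One schema variable: its kind and, for categoricals, the legal codes."""

    name: str
    kind: str  # "continuous" or "categorical"
    codes: tuple[int, ...] | None = None
    positive: bool = False  # continuous variable constrained to > 0

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise SchemaError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.kind == CATEGORICAL and not self.codes:
            raise SchemaError(f"categorical variable {self.name!r} needs a code set")


@dataclass
class Schema:
    """Ordered map of variable name -> :class:`VariableSpec`."""

    variables: dict[str, VariableSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_norm = {_normalize(n): n for n in self.variables}

    def __contains__(self, name: str) -> bool:
        return name in self.variables

    def __getitem__(self, name: str) -> VariableSpec:
        return self.variables[name]

    def __iter__(self):
        return iter(self.variables)

    @property
    def names(self) -> list[str]:
        return list(self.variables)

    @property
    def covariate_names(self) -> list[str]:
        return [n for n in self.variables if n != DOSE]

    def resolve(self, header: str) -> str:
        """Map a raw column header to the canonical variable name."""
        key = _normalize(header)
        if key not in self._by_norm:
            raise SchemaError(f"unknown column {header!r}")
        return self._by_norm[key]

    def subset(self, names: list[str]) -> "Schema":
        missing = [n for n in names if n not in self.variables]
        if missing:
            raise SchemaError(f"variables not in schema: {missing}")
        return Schema({n: self.variables[n] for n in names})

    def to_dict(self) -> dict:
        out = {}
        for v in self.variables.values():
            entry: dict = {"kind": v.kind}
            if v.codes is not None:
                entry["codes"] = list(v.codes)
            if v.positive:
                entry["positive"] = True
            out[v.name] = entry
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"variables": self.to_dict()}, fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "Schema":
        variables = {}
        for name, entry in d.items():
            codes = tuple(entry["codes"]) if "codes" in entry else None
            variables[name] = VariableSpec(
                name=name,
                kind=entry["kind"],
                codes=codes,
                positive=bool(entry.get("positive", False)),
            )
        return cls(variables)

    @classmethod
    def from_yaml(cls, path) -> "Schema":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict) or "variables" not in payload:
            raise SchemaError(f"{path}: expected a mapping with a 'variables' key")
        return cls.from_dict(payload["variables"])


def _load_marginals() -> dict:
    text = resources.files("warfdose.data").joinpath("default_cohort.yaml").read_text()
    return yaml.safe_load(text)


#: Raw marginal description bundled with the package (percent frequencies,
#: truncated-normal parameters, HRD class prevalence).
TABLE_MARGINALS: dict = _load_marginals()


def default_schema() -> Schema:
    """Schema mirroring the cohort-description table plus the dose column."""
    variables: dict[str, VariableSpec] = {}
    for name in TABLE_MARGINALS["continuous"]:
        variables[name] = VariableSpec(name, CONTINUOUS, positive=True)
    for name, freq in TABLE_MARGINALS["categorical_percent"].items():
        variables[name] = VariableSpec(name, CATEGORICAL, codes=tuple(sorted(freq)))
    variables[DOSE] = VariableSpec(DOSE, CONTINUOUS, positive=True)
    return Schema(variables)


DEFAULT_SCHEMA = default_schema()

#: Names the printed dose equations use, mapped to schema variable names.
EQUATION_NAME_MAP = {
    "Race": "race",
    "Age": "age_decade",
    "DVTPE": "dvt_pe",
    "Diabetes": "diabetes",
    "VR": "valve_replacement",
    "Lovastatin": "lovastatin",
    "Amiodarone": "amiodarone",
    "TargetINR": "target_inr",
    "Enzyme": "enzyme",
    "BSA": "bsa",
    "Aspirin": "aspirin",
    "AfungalAzoles": "antifungal_azoles",
    "Smoker": "smoker",
}
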