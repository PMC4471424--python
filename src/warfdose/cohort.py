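"""Read, validate, impute, and split patient cohorts.

A :class:`Cohort` wraps a pandas DataFrame (one column per schema variable,
``NaN`` marking missing cells) together with its :class:`~warfdose.schema.Schema`.
Preparation follows the usual clinical-data pipeline: drop variables with too
many missing values, impute the rest with a k-nearest-neighbour donor scheme
over a Gower-style mixed-type distance, then split into learning and testing
halves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .schema import CATEGORICAL, CONTINUOUS, DEFAULT_SCHEMA, DOSE, Schema

logger = logging.getLogger(__name__)

_NA_STRINGS = ("", "NA")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's encoded covariates plus the optional therapeutic dose.

    ``None`` marks a missing value. Categorical codes are validated against
    the default code sets on construction.
    """

    target_inr: float | None = None
    bsa: float | None = None
    race: int | None = None
    age_decade: int | None = None
    gender: int | None = None
    dvt_pe: int | None = None
    diabetes: int | None = None
    chf: int | None = None
    valve_replacement: int | None = None
    aspirin: int | None = None
    simvastatin: int | None = None
    atorvastatin: int | None = None
    fluvastatin: int | None = None
    lovastatin: int | None = None
    pravastatin: int | None = None
    rosuvastatin: int | None = None
    amiodarone: int | None = None
    carbamazepine: int | None = None
    phenytoin: int | None = None
    rifampin: int | None = None
    sulfonamide_abx: int | None = None
    macrolide_abx: int | None = None
    antifungal_azoles: int | None = None
    smoker: int | None = None
    enzyme: int | None = None
    dose_mg_wk: float | None = None

    def __post_init__(self) -> None:
        for name, value in self.items():
            if value is None:
                continue
            spec = DEFAULT_SCHEMA[name]
            if spec.kind == CATEGORICAL and int(value) not in spec.codes:
                raise ValidationError(
                    f"{name}={value!r} outside code set {spec.codes}"
                )
        if self.dose_mg_wk is not None and not self.dose_mg_wk > 0:
            raise ValidationError(f"dose_mg_wk must be positive, got {self.dose_mg_wk}")

    def items(self) -> Iterator[tuple[str, float | int | None]]:
        for name in DEFAULT_SCHEMA.names:
            yield name, getattr(self, name)

    @classmethod
    def from_mapping(cls, mapping) -> "PatientRecord":
        kwargs = {}
        for name in DEFAULT_SCHEMA.names:
            if name in mapping:
                v = mapping[name]
                kwargs[name] = None if v is None or (isinstance(v, float) and np.isnan(v)) else v
        return cls(**kwargs)


@dataclass
class Cohort:
    """Ordered collection of patient records with schema and missingness mask."""

    data: pd.DataFrame
    schema: Schema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        extra = [c for c in self.data.columns if c not in self.schema]
        if extra:
            raise SchemaError(f"columns not in schema: {extra}")
        self.data = self.data.astype(float)
        _validate_values(self.data, self.schema)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def records(self) -> list[PatientRecord]:
        return [PatientRecord.from_mapping(row) for row in self.data.to_dict("records")]

    def covariates(self) -> pd.DataFrame:
        """The covariate columns (everything except the dose)."""
        cols = [c for c in self.data.columns if c != DOSE]
        return self.data[cols]

    def equals(self, other: "Cohort") -> bool:
        return self.data.equals(other.data) and self.variables == other.variables

    def copy(self) -> "Cohort":
        return Cohort(self.data.copy(), self.schema)


def _validate_values(df: pd.DataFrame, schema: Schema) -> None:
    for col in df.columns:
        spec = schema[col]
        series = df[col]
        observed = series.dropna()
        if spec.kind == CATEGORICAL:
            bad = observed[~observed.isin([float(c) for c in spec.codes])]
            if len(bad):
                row = bad.index[0]
                raise ValidationError(
                    f"row {row}, column {col!r}: value {bad.iloc[0]!r} outside "
                    f"code set {spec.codes}"
                )
        else:
            if not np.isfinite(observed.to_numpy()).all():
                raise ValidationError(f"column {col!r} contains non-finite values")
            if spec.positive and (observed <= 0).any():
                row = observed[observed <= 0].index[0]
                raise ValidationError(
                    f"row {row}, column {col!r}: value must be strictly positive"
                )


def read_cohort(path, schema: Schema | None = None) -> Cohort:
    """Read a delimited-text cohort (comma-separated, header row).

    Header names are matched case-insensitively with punctuation stripped;
    empty cells and ``NA`` are treated as missing. Row order is preserved.
    """
    schema = schema or DEFAULT_SCHEMA
    df = pd.read_csv(path, na_values=list(_NA_STRINGS), keep_default_na=False)
    df.columns = [schema.resolve(c) for c in df.columns]
    if len(set(df.columns)) != len(df.columns):
        raise SchemaError(f"{path}: duplicate columns after name resolution")
    return Cohort(df, schema)


def write_cohort(c: Cohort, path) -> None:
    """Write a cohort back to delimited text (missing cells as empty strings)."""
    out = c.data.copy()
    # categoricals are held as floats internally; write them as integers
    for col in out.columns:
        if c.schema[col].kind == CATEGORICAL:
            out[col] = out[col].astype("Int64")
    out.to_csv(path, index=False, na_rep="")


def drop_sparse_variables(c: Cohort, max_missing_frac: float = 0.5) -> Cohort:
    """Drop variables whose missing fraction exceeds ``max_missing_frac``.

    The dose column may never be dropped: if its missingness exceeds the
    threshold an error is raised instead. Dropped names are logged.
    """
    if not 0 < max_missing_frac <= 1:
        raise ValidationError("max_missing_frac must be in (0, 1]")
    frac = c.missing_mask.mean(axis=0)
    to_drop = [v for v in c.variables if frac[v] > max_missing_frac]
    if DOSE in to_drop:
        raise ValidationError(
            f"dose column exceeds the missingness threshold "
            f"({frac[DOSE]:.2f} > {max_missing_frac}); the response may not be dropped"
        )
    if to_drop:
        logger.warning("dropping sparse variables: %s", ", ".join(to_drop))
    kept = [v for v in c.variables if v not in to_drop]
    return Cohort(c.data[kept].copy(), c.schema.subset(kept))


def _gower_distances(data: pd.DataFrame, schema: Schema) -> np.ndarray:
    """Pairwise Gower-style distances over covariate columns.

    Continuous coordinates contribute |xi - xj| / sd (sd over observed values);
    categoricals contribute 0/1 mismatch. Each pair is averaged over the
    coordinates observed in both records; pairs sharing no coordinate get inf.
    The dose column never enters the distance.
    """
    cols = [c for c in data.columns if c != DOSE]
    n = len(data)
    num = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for col in cols:
        x = data[col].to_numpy(dtype=float)
        obs = ~np.isnan(x)
        both = np.outer(obs, obs)
        if schema[col].kind == CONTINUOUS:
            sd = np.nanstd(x, ddof=1)
            if not np.isfinite(sd) or sd == 0:
                d = np.zeros((n, n))
            else:
                d = np.abs(x[:, None] - x[None, :]) / sd
        else:
            d = (x[:, None] != x[None, :]).astype(float)
        d = np.where(both, d, 0.0)
        num += np.nan_to_num(d)
        cnt += both
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = num / cnt
    dist[cnt == 0] = np.inf
    return dist


def knn_impute(c: Cohort, k: int = 1) -> Cohort:
    """Fill missing cells from the k nearest donor records.

    Donors must observe the target variable; distances are Gower-style over
    the covariates observed in both records (the dose is excluded). With
    ``k=1`` the donor's value is copied; for ``k>1`` continuous cells take the
    donor mean and categorical cells the donor mode (ties -> smallest code).
    Distance ties are broken by lowest record index. Imputed values are always
    taken from originally observed data, so the operation is idempotent.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    mask = c.missing_mask
    if not mask.to_numpy().any():
        return c.copy()
    nowhere = [v for v in c.variables if mask[v].all()]
    if nowhere:
        raise ValidationError(f"variables observed in no record, unimputable: {nowhere}")
    dist = _gower_distances(c.data, c.schema)
    np.fill_diagonal(dist, np.inf)
    out = c.data.copy()
    positions = {v: i for i, v in enumerate(c.variables)}
    values = c.data.to_numpy(dtype=float)
    for col in c.variables:
        miss_rows = np.flatnonzero(mask[col].to_numpy())
        if miss_rows.size == 0:
            continue
        donors = np.flatnonzero(~mask[col].to_numpy())
        col_vals = values[:, positions[col]]
        categorical = c.schema[col].kind == CATEGORICAL
        for i in miss_rows:
            d = dist[i, donors]
            finite = np.isfinite(d)
            if not finite.any():
                raise ValidationError(
                    f"record {i}: no donor shares an observed coordinate for {col!r}"
                )
            usable = donors[finite]
            du = d[finite]
            order = np.argsort(du, kind="stable")  # stable sort -> lowest index on ties
            chosen = usable[order[: min(k, len(usable))]]
            vals = col_vals[chosen]
            if len(chosen) == 1:
                fill = vals[0]
            elif categorical:
                codes, counts = np.unique(vals, return_counts=True)
                fill = codes[np.argmax(counts)]  # unique is sorted -> smallest on tie
            else:
                fill = float(np.mean(vals))
            out.iat[i, positions[col]] = fill
    return Cohort(out, c.schema)


def split_cohort(c: Cohort, frac: float = 0.5, seed: int = 0) -> tuple[Cohort, Cohort]:
    """Randomly partition a cohort into two disjoint parts.

    The first part receives ``round(frac * n)`` records (round-half-up); the
    same seed always yields the same partition. Original row order is kept
    within each part, so concatenating the parts and sorting by index
    reconstructs the input exactly.
    """
    if not 0 < frac < 1:
        raise ValidationError("frac must be in (0, 1)")
    n = c.n
    if n < 2:
        raise ValidationError("need at least 2 records to split")
    n1 = int(np.floor(frac * n + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    first = np.sort(perm[:n1])
    second = np.sort(perm[n1:])
    return (
        Cohort(c.data.iloc[first].copy(), c.schema),
        Cohort(c.data.iloc[second].copy(), c.schema),
    )
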