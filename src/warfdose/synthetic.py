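"""Synthetic warfarin cohorts with the published marginal structure.

Covariates are sampled independently from the bundled marginal description:
truncated normals for target INR and BSA, categorical draws for everything
else (age enters as a decade code with its printed frequencies). Doses come
from a two-component log-linear mechanism: each record draws a latent class
(Bernoulli, or optionally an indicator on a covariate), the class's
:class:`~warfdose.dose_models.DoseModelSpec` gives the log-scale location, a
shared calibration offset shifts both components, and log-normal noise is
added. :func:`calibrate_offset` tunes the offset by bisection so the fraction
of doses above 30 mg/wk matches a target prevalence (default: the published
high-required-dose share, 50.18%).

Covariates are sampled independently because only marginals are published; the
mechanism is a testing device, not an estimate of real covariate-dose effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .dose_models import DoseModelSpec, bundled_model, predict_dose_frame
from .errors import NumericError, ValidationError
from .schema import DEFAULT_SCHEMA, DOSE, TABLE_MARGINALS, Schema

#: Published prevalence of the high-required-dose class (dose > 30 mg/wk).
DEFAULT_P_HRD = TABLE_MARGINALS["hrd_class_percent"] / 100.0

#: The dose threshold (mg/wk) defining the high-required-dose class.
HRD_THRESHOLD = 30.0


@dataclass
class DoseMechanism:
    """Two-component log-linear dose-generating mechanism.

    By default the latent class is Bernoulli(``mix_p_hrd``); setting
    ``class_var``/``class_cut`` instead ties the class to a covariate
    (class 1 iff ``record[class_var] > class_cut``), which produces cohorts
    whose dose classes are separable from the covariates.
    """

    lrd_spec: DoseModelSpec = field(default_factory=lambda: bundled_model("model_I"))
    hrd_spec: DoseModelSpec = field(default_factory=lambda: bundled_model("model_II"))
    mix_p_hrd: float = DEFAULT_P_HRD
    noise_sd_log: float = 0.25
    calibration_offset: float = 0.0
    class_var: str | None = None
    class_cut: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.mix_p_hrd <= 1:
            raise ValidationError("mix_p_hrd must lie in [0, 1]")
        if not self.noise_sd_log > 0:
            raise ValidationError("noise_sd_log must be positive")
        if (self.class_var is None) != (self.class_cut is None):
            raise ValidationError("class_var and class_cut must be set together")


@dataclass
class CohortSpec:
    """Sampling specification: size, marginals, dose mechanism, seed."""

    n: int
    continuous: dict[str, dict[str, float]]
    categorical: dict[str, dict[int, float]]
    dose_mechanism: DoseMechanism = field(default_factory=DoseMechanism)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError("n must be non-negative")
        for name, params in self.continuous.items():
            if not params["sd"] > 0:
                raise ValidationError(f"{name}: sd must be positive")
            if not params["min"] < params["max"]:
                raise ValidationError(f"{name}: min must be below max")
        for name, probs in self.categorical.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"{name}: probabilities sum to {total}, not 1")


def default_cohort_spec(n: int = 1000, seed: int = 0) -> CohortSpec:
    """The bundled specification transcribing the published cohort marginals.

    Printed percentage frequencies are normalized to probabilities (the age
    rows sum to 99.99% from rounding in the source table).
    """
    continuous = {k: dict(v) for k, v in TABLE_MARGINALS["continuous"].items()}
    categorical = {}
    for name, freq in TABLE_MARGINALS["categorical_percent"].items():
        total = sum(freq.values())
        categorical[name] = {int(c): p / total for c, p in freq.items()}
    return CohortSpec(n=n, continuous=continuous, categorical=categorical, seed=seed)


def _truncnorm_rejection(rng, params: dict[str, float], size: int) -> np.ndarray:
    """Truncated-normal draws by rejection inside [min, max]."""
    lo, hi = params["min"], params["max"]
    mass = stats.norm.cdf(hi, params["mean"], params["sd"]) - stats.norm.cdf(
        lo, params["mean"], params["sd"]
    )
    if mass < 1e-12:
        raise ValidationError(
            f"truncation window [{lo}, {hi}] carries no probability mass "
            f"under N({params['mean']}, {params['sd']}^2)"
        )
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(params["mean"], params["sd"], size=max(size - filled, 16))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def sample_covariates(spec: CohortSpec, schema: Schema | None = None) -> Cohort:
    """Draw a covariate-only cohort (no dose column) from the marginals."""
    schema = schema or DEFAULT_SCHEMA
    rng = np.random.default_rng(spec.seed)
    cols: dict[str, np.ndarray] = {}
    for name in schema.covariate_names:
        if name in spec.continuous:
            cols[name] = _truncnorm_rejection(rng, spec.continuous[name], spec.n)
        elif name in spec.categorical:
            probs = spec.categorical[name]
            codes = np.array(sorted(probs), dtype=float)
            p = np.array([probs[int(c)] for c in codes])
            cols[name] = rng.choice(codes, size=spec.n, p=p)
        else:
            raise ValidationError(f"no marginal specified for schema variable {name!r}")
    df = pd.DataFrame(cols)
    return Cohort(df, schema.subset(list(df.columns)))


def _latent_class(c: Cohort, mech: DoseMechanism, rng) -> np.ndarray:
    if mech.class_var is not None:
        if mech.class_var not in c.data.columns:
            raise ValidationError(f"class_var {mech.class_var!r} not in cohort")
        return (c.data[mech.class_var].to_numpy(dtype=float) > mech.class_cut).astype(int)
    return (rng.random(c.n) < mech.mix_p_hrd).astype(int)


def sample_dose(c: Cohort, mech: DoseMechanism, seed: int = 0) -> Cohort:
    """Attach mechanism-generated doses to a complete covariate cohort."""
    if c.missing_mask.to_numpy().any():
        raise ValidationError("cohort must be complete before dose generation")
    rng = np.random.default_rng(seed)
    cls = _latent_class(c, mech, rng)
    ln_lo = np.log(predict_dose_frame(mech.lrd_spec, c))
    ln_hi = np.log(predict_dose_frame(mech.hrd_spec, c))
    ln_pred = np.where(cls == 1, ln_hi, ln_lo) + mech.calibration_offset
    noise = rng.normal(0.0, mech.noise_sd_log, size=c.n)
    dose = np.exp(ln_pred + noise)
    df = c.data.copy()
    df[DOSE] = dose
    names = list(c.data.columns) + [DOSE]
    return Cohort(df, DEFAULT_SCHEMA.subset(names) if DOSE not in c.schema else c.schema.subset(names))


def calibrate_offset(
    spec: CohortSpec,
    target_p_hrd: float = DEFAULT_P_HRD,
    tol: float = 0.01,
    n_mc: int = 20000,
    bounds: tuple[float, float] = (-3.0, 3.0),
) -> float:
    """Bisect the calibration offset so ``P(dose > 30)`` hits a target.

    Uses a seeded Monte-Carlo cohort of ``n_mc`` records with common random
    numbers across offsets, so the empirical exceedance probability is a
    monotone non-decreasing function of the offset and bisection converges.
    """
    if not 0 < target_p_hrd < 1:
        raise ValidationError("target_p_hrd must lie strictly in (0, 1)")
    mc_spec = replace(spec, n=n_mc)
    cov = sample_covariates(mc_spec)
    mech = spec.dose_mechanism
    rng = np.random.default_rng(spec.seed + 1)
    cls = _latent_class(cov, mech, rng)
    ln_lo = np.log(predict_dose_frame(mech.lrd_spec, cov))
    ln_hi = np.log(predict_dose_frame(mech.hrd_spec, cov))
    base = np.where(cls == 1, ln_hi, ln_lo) + rng.normal(0.0, mech.noise_sd_log, n_mc)
    ln_tau = math.log(HRD_THRESHOLD)

    def p_exceed(offset: float) -> float:
        return float(np.mean(base + offset > ln_tau))

    lo, hi = bounds
    if p_exceed(lo) > target_p_hrd or p_exceed(hi) < target_p_hrd:
        raise NumericError(
            f"offset bounds {bounds} do not bracket the target prevalence "
            f"{target_p_hrd}; widen the bounds"
        )
    mid = 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        p = p_exceed(mid)
        if abs(p - target_p_hrd) <= tol:
            return mid
        if p < target_p_hrd:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    if abs(p_exceed(mid) - target_p_hrd) > tol:
        raise NumericError("calibration failed to reach the target tolerance")
    return mid


def inject_missingness(c: Cohort, rates: dict[str, float], seed: int = 0) -> Cohort:
    """Independently mask cells at per-variable rates. The dose is never masked."""
    if DOSE in rates:
        raise ValidationError("the dose column may not be masked")
    for name, r in rates.items():
        if name not in c.data.columns:
            raise ValidationError(f"unknown variable {name!r}")
        if not 0 <= r <= 1:
            raise ValidationError(f"rate for {name!r} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    df = c.data.copy()
    for name in c.data.columns:  # fixed column order keeps masks reproducible
        r = rates.get(name, 0.0)
        if r > 0:
            mask = rng.random(c.n) < r
            df.loc[mask, name] = np.nan
    return Cohort(df, c.schema)


def separable_cohort_spec(
    n: int = 800,
    seed: int = 0,
    low_dose: float = 16.5,
    high_dose: float = 45.0,
    noise_sd_log: float = 0.15,
) -> CohortSpec:
    """A cohort spec whose dose distribution is bimodal and separable at 30 mg/wk.

    The latent class is tied to body surface area (class 1 iff BSA exceeds the
    population mean), and each class's dose concentrates around a constant
    well away from 30 mg/wk, so the 30 mg/wk labeling is recoverable from the
    covariates: labelings at thresholds inside the gap coincide with the
    latent class, while thresholds cutting through either dose cluster flip
    labels by noise that no covariate can explain. Used to exercise threshold
    selection and the two-phase pipeline under a known class structure.
    """
    spec = default_cohort_spec(n=n, seed=seed)
    bsa_mean = spec.continuous["bsa"]["mean"]
    spec.dose_mechanism = DoseMechanism(
        lrd_spec=DoseModelSpec("low_cluster", math.log(low_dose), {}),
        hrd_spec=DoseModelSpec("high_cluster", math.log(high_dose), {}),
        noise_sd_log=noise_sd_log,
        class_var="bsa",
        class_cut=bsa_mean,
    )
    return spec


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Covariates plus doses in one call (dose stream seeded from spec.seed)."""
    cov = sample_covariates(spec)
    return sample_dose(cov, spec.dose_mechanism, seed=spec.seed + 1)
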