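"""Synthetic two-group cohort generator.

Emulates the case-control structure of a diabetic-retinopathy cohort:
150 subjects with retinopathy (outcome 1) and 150 without (outcome 0),
described by 19 routine clinical indicators.  Continuous variables are
drawn per group from Gaussians matched to published group means/SDs,
truncated to clinically plausible ranges; binary variables are Bernoulli
with the published per-group proportions.  An optional correlation
matrix over the continuous block supports robustness testing.

The generator is the test bed for every downstream stage (screening,
logistic modelling, hyperparameter evolution); what it does and does not
emulate about real cohorts is discussed in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

CONTINUOUS = "continuous"
BINARY = "binary"
OUTCOME = "outcome"


@dataclass(frozen=True)
class VariableProfile:
    name: str
    display: str
    kind: str  # continuous | binary
    units: str = ""
    group1_mean: Optional[float] = None
    group1_sd: Optional[float] = None
    group0_mean: Optional[float] = None
    group0_sd: Optional[float] = None
    group1_proportion: Optional[float] = None
    group0_proportion: Optional[float] = None
    plausible_range: tuple[float, float] = (-np.inf, np.inf)

    def __post_init__(self):
        lo, hi = self.plausible_range
        if not lo < hi:
            raise ValueError(f"{self.name}: plausible_range low must be < high")
        if self.kind == CONTINUOUS:
            if self.group1_sd is None or self.group1_sd <= 0 \
                    or self.group0_sd is None or self.group0_sd <= 0:
                raise ValueError(f"{self.name}: continuous variables need sd > 0")
        elif self.kind == BINARY:
            for p in (self.group1_proportion, self.group0_proportion):
                if p is None or not 0.0 <= p <= 1.0:
                    raise ValueError(f"{self.name}: proportions must lie in [0, 1]")
        else:
            raise ValueError(f"{self.name}: kind must be continuous or binary")


@dataclass(frozen=True)
class CohortProfile:
    variables: tuple[VariableProfile, ...]
    n_per_group: int = 150
    correlation: Optional[np.ndarray] = None  # over continuous variables

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.correlation is not None:
            R = np.asarray(self.correlation, dtype=float)
            k = len(self.continuous_names)
            if R.shape != (k, k) or not np.allclose(R, R.T):
                raise ValueError("correlation must be symmetric over the "
                                 f"{k} continuous variables")
            if np.min(np.linalg.eigvalsh(R)) <= 0:
                raise ValueError("correlation matrix must be positive definite")
            object.__setattr__(self, "correlation", R)

    @property
    def continuous_names(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == CONTINUOUS]

    @property
    def binary_names(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == BINARY]

    def variable_types(self) -> dict[str, str]:
        return {v.name: v.kind for v in self.variables}


@dataclass
class CohortTable:
    """Subjects x (19 predictors + outcome) with per-column type metadata."""

    frame: pd.DataFrame
    types: dict[str, str]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, types: Optional[dict[str, str]] = None) -> "CohortTable":
        frame = pd.read_csv(path)
        if types is None:
            types = infer_types(frame)
        return cls(frame=frame, types=types)


def infer_types(frame: pd.DataFrame) -> dict[str, str]:
    types = {}
    for col in frame.columns:
        if col == OUTCOME:
            continue
        vals = frame[col].dropna().unique()
        types[col] = BINARY if set(np.unique(vals)) <= {0, 1} else CONTINUOUS
    return types


# --------------------------------------------------------- default profile

def _c(name, display, units, m1, s1, m0, s0, rng):
    return VariableProfile(name=name, display=display, kind=CONTINUOUS,
                           units=units, group1_mean=m1, group1_sd=s1,
                           group0_mean=m0, group0_sd=s0, plausible_range=rng)


def _b(name, display, p1, p0):
    return VariableProfile(name=name, display=display, kind=BINARY,
                           group1_proportion=p1, group0_proportion=p0,
                           plausible_range=(0.0, 1.0 + 1e-12))


def default_profile(n_per_group: int = 150,
                    correlation: Optional[np.ndarray] = None) -> CohortProfile:
    """The published two-group univariate summary, transcribed verbatim.

    Group 1 = retinopathy (n=150), group 0 = no retinopathy (n=150).
    Binary variables are coded 1 = male / yes; non-pharmacological
    treatment is coded 1 = receives it, so its effect is protective.
    Glucose units are carried as printed in the source table ("umol/L",
    plausibly mmol/L) — see docs/methods.md.
    """
    variables = (
        _b("gender_male", "Gender (male)", 97 / 150, 64 / 150),
        _c("age_years", "Age", "years", 64.18, 8.43, 60.87, 9.04, (18.0, 100.0)),
        _c("diabetes_duration_years", "Duration of diabetes", "years",
           10.87, 6.01, 9.11, 5.19, (0.0, 60.0)),
        _b("smoking_history", "Smoking history", 71 / 150, 52 / 150),
        _b("drinking_history", "Drinking history", 37 / 150, 33 / 150),
        _b("non_pharmacological_treatment", "Non-pharmacological treatment",
           54 / 150, 91 / 150),
        _c("serum_creatinine_umol_l", "Serum creatinine", "umol/L",
           82.13, 33.19, 77.65, 41.06, (20.0, 400.0)),
        _c("sbp_mmhg", "Systolic blood pressure", "mmHg",
           140.18, 19.83, 135.23, 15.74, (70.0, 250.0)),
        _c("dbp_mmhg", "Diastolic blood pressure", "mmHg",
           83.12, 9.13, 82.49, 9.58, (40.0, 150.0)),
        _c("fasting_glucose", "Fasting blood glucose", "umol/L (as printed)",
           7.84, 2.15, 7.33, 1.76, (2.0, 30.0)),
        _c("postprandial_2h_glucose", "2-hour postprandial blood glucose",
           "umol/L (as printed)", 12.45, 2.43, 11.88, 1.81, (2.0, 40.0)),
        _c("bmi_kg_m2", "Body mass index", "kg/m2",
           25.41, 3.41, 25.56, 3.61, (12.0, 60.0)),
        _c("hba1c_percent", "Glycosylated hemoglobin", "%",
           7.43, 1.31, 6.11, 0.75, (3.0, 20.0)),
        _c("hdl_mmol_l", "High-density lipoprotein cholesterol", "mmol/L",
           1.31, 0.81, 1.91, 1.05, (0.1, 8.0)),
        _c("ldl_mmol_l", "Low-density lipoprotein cholesterol", "mmol/L",
           3.71, 1.13, 3.43, 0.83, (0.3, 12.0)),
        _c("total_cholesterol_mmol_l", "Total cholesterol", "mmol/L",
           5.48, 1.31, 5.52, 1.04, (1.0, 15.0)),
        _c("triglyceride_mmol_l", "Triglyceride", "mmol/L",
           2.84, 1.03, 2.71, 0.99, (0.1, 15.0)),
        _c("bun_mmol_l", "Blood urea nitrogen", "mmol/L",
           5.45, 1.74, 5.01, 1.66, (1.0, 30.0)),
        _c("uacr_mg_g", "Urinary albumin/creatinine ratio", "mg/g",
           21.24, 6.28, 6.32, 2.76, (0.1, 100.0)),
    )
    return CohortProfile(variables=variables, n_per_group=n_per_group,
                         correlation=correlation)


def clinical_correlation_preset() -> np.ndarray:
    """Optional correlation over the 15 continuous variables.

    Introduces SBP-DBP 0.6, fasting-glucose-HbA1c 0.6 and TC-LDL 0.7;
    engineering choices for robustness testing, not published facts.
    """
    names = default_profile().continuous_names
    R = np.eye(len(names))
    pairs = [("sbp_mmhg", "dbp_mmhg", 0.6),
             ("fasting_glucose", "hba1c_percent", 0.6),
             ("total_cholesterol_mmol_l", "ldl_mmol_l", 0.7)]
    for a, b, r in pairs:
        i, j = names.index(a), names.index(b)
        R[i, j] = R[j, i] = r
    return R


# ---------------------------------------------------------------- sampling

def truncated_mean(v: VariableProfile, group: int) -> float:
    """Analytic mean of the truncated Gaussian actually sampled."""
    mu = v.group1_mean if group == 1 else v.group0_mean
    sd = v.group1_sd if group == 1 else v.group0_sd
    lo, hi = v.plausible_range
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(sps.truncnorm.mean(a, b, loc=mu, scale=sd))


def generate(profile: CohortProfile, seed: int) -> CohortTable:
    """Draw a cohort table; deterministic given the seed.

    With the default identity correlation each continuous variable is an
    exact truncated normal.  With a supplied correlation matrix the
    continuous block is multivariate normal and values are clipped to the
    plausible range (clipping, not resampling, so the correlation target
    is only approximate near range edges).
    """
    rng = np.random.default_rng(seed)
    cont = [v for v in profile.variables if v.kind == CONTINUOUS]
    frames = []
    for group in (1, 0):
        n = profile.n_per_group
        cols: dict[str, np.ndarray] = {}
        if profile.correlation is not None:
            mus = np.array([v.group1_mean if group == 1 else v.group0_mean
                            for v in cont])
            sds = np.array([v.group1_sd if group == 1 else v.group0_sd
                            for v in cont])
            cov = profile.correlation * np.outer(sds, sds)
            Z = rng.multivariate_normal(mus, cov, size=n,
                                        method="cholesky")
            for j, v in enumerate(cont):
                lo, hi = v.plausible_range
                cols[v.name] = np.clip(Z[:, j], lo, hi)
        for v in profile.variables:
            if v.kind == BINARY:
                p = v.group1_proportion if group == 1 else v.group0_proportion
                cols[v.name] = (rng.uniform(size=n) < p).astype(int)
            elif profile.correlation is None:
                mu = v.group1_mean if group == 1 else v.group0_mean
                sd = v.group1_sd if group == 1 else v.group0_sd
                lo, hi = v.plausible_range
                a, b = (lo - mu) / sd, (hi - mu) / sd
                cols[v.name] = sps.truncnorm.rvs(a, b, loc=mu, scale=sd,
                                                 size=n, random_state=rng)
        ordered = {v.name: cols[v.name] for v in profile.variables}
        ordered[OUTCOME] = np.full(n, group, dtype=int)
        frames.append(pd.DataFrame(ordered))
    frame = pd.concat(frames, ignore_index=True)
    return CohortTable(frame=frame, types=profile.variable_types())


def inject_missing(table: CohortTable, rate: float, seed: int) -> CohortTable:
    """Set each predictor cell missing independently with probability rate.

    The outcome column is never masked.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    frame = table.frame.copy()
    if rate > 0.0:
        rng = np.random.default_rng(seed)
        predictors = [c for c in frame.columns if c != OUTCOME]
        mask = rng.uniform(size=(len(frame), len(predictors))) < rate
        values = frame[predictors].to_numpy(dtype=float)
        values[mask] = np.nan
        frame[predictors] = values
    return CohortTable(frame=frame, types=dict(table.types))


# -------------------------------------------------------------- YAML round trip

def profile_to_yaml(profile: CohortProfile, path) -> None:
    payload = {
        "n_per_group": profile.n_per_group,
        "correlation": (None if profile.correlation is None
                        else np.asarray(profile.correlation).tolist()),
        "variables": [
            {k: (list(v) if isinstance(v := getattr(var, k), tuple) else v)
             for k in ("name", "display", "kind", "units", "group1_mean",
                       "group1_sd", "group0_mean", "group0_sd",
                       "group1_proportion", "group0_proportion",
                       "plausible_range")}
            for var in profile.variables
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def profile_from_yaml(path) -> CohortProfile:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    variables = tuple(
        VariableProfile(**{**spec, "plausible_range": tuple(spec["plausible_range"])})
        for spec in payload["variables"]
    )
    corr = payload.get("correlation")
    return CohortProfile(variables=variables,
                         n_per_group=payload["n_per_group"],
                         correlation=None if corr is None else np.asarray(corr))
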