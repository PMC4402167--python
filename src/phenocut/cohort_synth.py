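"""Synthetic two-gender cohort generator with a six-phenotype metabolic structure.

The generator emulates an adult urban cohort stratified by body-mass index
(BMI) and metabolic health: healthy normal weight (HNW), metabolically obese
normal weight (MONW), healthy and metabolically disturbed overweight
(OW_HEALTHY / OW_SICK), metabolically healthy obese (MHO) and metabolically
disturbed obese (MDO).  Each phenotype has its own per-gender prevalence and
per-variable location/scale for waist circumference (WC, cm), HOMA2-IR,
triglycerides (TAG, mg/dL), HDL cholesterol (mg/dL) and mean arterial
pressure (MAP, mmHg).  Right-skewed variables (HOMA2-IR, TAG) are drawn from
moment-matched lognormals; the rest from truncated normals with physiologic
minima.  BMI is drawn uniformly inside the WHO band that defines each
phenotype's stratum, so stratification is consistent with phenotype identity
by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PHENOTYPES = ("HNW", "MONW", "OW_HEALTHY", "OW_SICK", "MHO", "MDO")
GENDERS = ("F", "M")

#: continuous variables carried by a PhenotypeSpec, with distribution family
VARIABLES = ("wc_cm", "homa2ir", "tag", "hdl", "map", "glucose", "homa2b", "tchol")

#: physiologic lower truncation bounds for normally drawn variables
_TRUNCATION = {
    "wc_cm": 40.0,
    "map": 40.0,
    "hdl": 5.0,
    "glucose": 40.0,
    "homa2b": 5.0,
    "tchol": 50.0,
}

COHORT_CSV_COLUMNS = [
    "id", "gender", "age_y", "bmi", "wc_cm", "sbp", "dbp", "glucose",
    "insulin", "homa2ir", "homa2b", "homa2s", "tchol", "tag", "hdl",
    "true_phenotype",
]


@dataclass
class PhenotypeSpec:
    """Per-phenotype prevalence and marginal distributions.

    ``variable_params`` maps a variable name to ``(loc, scale, family)`` where
    ``family`` is ``"normal"`` or ``"lognormal"``; ``loc``/``scale`` are the
    target mean/SD on the original measurement scale in both cases.
    """

    name: str
    prevalence_by_gender: Mapping[str, float]
    variable_params: Mapping[str, tuple[float, float, str]]

    def __post_init__(self) -> None:
        if self.name not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.name!r}")
        for var, (loc, scale, family) in self.variable_params.items():
            if scale <= 0:
                raise ValueError(f"{self.name}/{var}: scale must be > 0, got {scale}")
            if family not in ("normal", "lognormal"):
                raise ValueError(f"{self.name}/{var}: unknown family {family!r}")
        for g, p in self.prevalence_by_gender.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: prevalence for {g} outside [0,1]")


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    ``bmi_bands`` maps a phenotype to a list of ``(low, high, weight)`` BMI
    bands (kg/m²); a subject's BMI is drawn uniformly within a band chosen
    with the given weights.
    """

    n_total: int
    gender_fraction_female: float
    phenotypes: list[PhenotypeSpec]
    bmi_bands: Mapping[str, Sequence[tuple[float, float, float]]]
    seed: int | None = None
    copula_rho: float = 0.0
    age_mean: float = 38.70
    age_sd: float = 15.06

    def __post_init__(self) -> None:
        if self.n_total < 0:
            raise ValueError("n_total must be >= 0")
        if not 0.0 <= self.gender_fraction_female <= 1.0:
            raise ValueError("gender_fraction_female must be in [0, 1]")
        if not -0.99 <= self.copula_rho <= 0.99:
            raise ValueError("copula_rho must be in [-0.99, 0.99]")
        for g in GENDERS:
            total = sum(p.prevalence_by_gender.get(g, 0.0) for p in self.phenotypes)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"prevalences for gender {g} sum to {total}, expected 1"
                )

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        payload = asdict(self)
        payload["phenotypes"] = [asdict(p) for p in self.phenotypes]
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        payload = json.loads(text)
        phenos = [
            PhenotypeSpec(
                name=p["name"],
                prevalence_by_gender=p["prevalence_by_gender"],
                variable_params={
                    k: tuple(v) for k, v in p["variable_params"].items()
                },
            )
            for p in payload.pop("phenotypes")
        ]
        bands = {k: [tuple(b) for b in v] for k, v in payload.pop("bmi_bands").items()}
        return cls(phenotypes=phenos, bmi_bands=bands, **payload)


# ---------------------------------------------------------------------------
# Default parameterization
# ---------------------------------------------------------------------------

# Phenotype counts per gender in the reference cohort (n = 1902; 992 women,
# 910 men).  Obese healthy/sick counts are pooled over WHO obesity classes.
PHENOTYPE_COUNTS = {
    "F": {"HNW": 336, "MONW": 28, "OW_HEALTHY": 240, "OW_SICK": 76,
          "MHO": 101, "MDO": 211},
    "M": {"HNW": 202, "MONW": 36, "OW_HEALTHY": 294, "OW_SICK": 66,
          "MHO": 112, "MDO": 200},
}
GENDER_TOTALS = {"F": 992, "M": 910}

# Per-phenotype (mean, SD) by gender for the five phenotype-specific
# variables.  Keyed [variable][phenotype] -> {gender: (mean, sd)}.
_PHENOTYPE_MOMENTS = {
    "wc_cm": {
        "HNW": {"F": (79.27, 8.24), "M": (81.54, 6.87)},
        "MONW": {"F": (77.20, 7.07), "M": (86.98, 7.62)},
        "OW_HEALTHY": {"F": (89.69, 6.88), "M": (94.82, 6.59)},
        "OW_SICK": {"F": (90.27, 7.59), "M": (97.76, 6.10)},
        "MHO": {"F": (104.40, 10.55), "M": (109.17, 11.94)},
        "MDO": {"F": (105.50, 10.07), "M": (116.04, 15.32)},
    },
    "homa2ir": {
        "HNW": {"F": (1.47, 0.48), "M": (1.15, 0.44)},
        "MONW": {"F": (3.56, 1.36), "M": (2.54, 1.47)},
        "OW_HEALTHY": {"F": (1.45, 0.51), "M": (1.49, 0.58)},
        "OW_SICK": {"F": (3.12, 1.14), "M": (3.57, 1.41)},
        "MHO": {"F": (1.24, 0.37), "M": (1.40, 0.41)},
        "MDO": {"F": (3.14, 1.54), "M": (3.39, 1.42)},
    },
    "tag": {
        "HNW": {"F": (86.49, 52.06), "M": (84.65, 38.44)},
        "MONW": {"F": (120.61, 155.70), "M": (180.99, 124.76)},
        "OW_HEALTHY": {"F": (112.97, 68.92), "M": (131.01, 80.97)},
        "OW_SICK": {"F": (131.32, 93.03), "M": (173.92, 106.29)},
        "MHO": {"F": (120.12, 73.96), "M": (143.08, 118.27)},
        "MDO": {"F": (144.57, 95.54), "M": (184.60, 121.59)},
    },
    "hdl": {
        "HNW": {"F": (49.29, 11.81), "M": (46.00, 11.16)},
        "MONW": {"F": (51.61, 11.54), "M": (39.50, 11.84)},
        "OW_HEALTHY": {"F": (48.17, 11.65), "M": (41.91, 12.88)},
        "OW_SICK": {"F": (44.43, 10.84), "M": (38.45, 8.39)},
        "MHO": {"F": (45.57, 13.01), "M": (40.15, 9.91)},
        "MDO": {"F": (44.13, 11.45), "M": (36.71, 8.48)},
    },
    "map": {
        "HNW": {"F": (83.80, 9.60), "M": (87.28, 9.92)},
        "MONW": {"F": (87.00, 13.17), "M": (88.28, 10.54)},
        "OW_HEALTHY": {"F": (89.20, 11.33), "M": (93.44, 11.77)},
        "OW_SICK": {"F": (88.85, 10.46), "M": (91.45, 10.39)},
        "MHO": {"F": (95.78, 13.91), "M": (96.38, 13.17)},
        "MDO": {"F": (95.10, 12.07), "M": (98.01, 12.47)},
    },
}

# Variables with no per-phenotype breakdown available: pooled per-gender
# moments are used for every phenotype (flagged in the methods note).
_POOLED_MOMENTS = {
    "glucose": {"F": (98.20, 31.01), "M": (99.09, 32.73)},
    "homa2b": {"F": (136.97, 58.67), "M": (137.25, 65.83)},
    "tchol": {"F": (193.77, 44.41), "M": (187.32, 47.33)},
}

_LOGNORMAL_VARS = frozenset({"homa2ir", "tag"})

# WHO BMI bands per phenotype; obese phenotypes split 60/25/15 across
# classes I/II/III, mirroring the reference cohort's obesity-class mix.
_DEFAULT_BMI_BANDS = {
    "HNW": [(18.5, 25.0, 1.0)],
    "MONW": [(18.5, 25.0, 1.0)],
    "OW_HEALTHY": [(25.0, 30.0, 1.0)],
    "OW_SICK": [(25.0, 30.0, 1.0)],
    "MHO": [(30.0, 35.0, 0.60), (35.0, 40.0, 0.25), (40.0, 47.5, 0.15)],
    "MDO": [(30.0, 35.0, 0.60), (35.0, 40.0, 0.25), (40.0, 47.5, 0.15)],
}

#: share of women in the reference cohort (992 of 1902)
DEFAULT_FEMALE_FRACTION = 0.5215


def default_spec(n_total: int = 1902, seed: int | None = None,
                 copula_rho: float = 0.0) -> CohortSpec:
    """Cohort spec parameterized from the reference cohort's tables.

    Gender-specific phenotype prevalences are the published phenotype counts
    divided by gender totals; per-phenotype WC, HOMA2-IR, TAG, HDL-C and MAP
    moments are the published means/SDs.  Glucose, HOMA2-%B and total
    cholesterol fall back to pooled per-gender moments.
    """
    phenos = []
    for name in PHENOTYPES:
        prev = {g: PHENOTYPE_COUNTS[g][name] / GENDER_TOTALS[g] for g in GENDERS}
        params: dict[str, dict[str, tuple[float, float, str]]] = {}
        # variable_params keyed per gender is not in the dataclass contract;
        # instead one PhenotypeSpec per gender would duplicate names.  We key
        # params as "<var>@<gender>" internally and unpack at draw time.
        for var in VARIABLES:
            family = "lognormal" if var in _LOGNORMAL_VARS else "normal"
            for g in GENDERS:
                if var in _PHENOTYPE_MOMENTS:
                    loc, scale = _PHENOTYPE_MOMENTS[var][name][g]
                else:
                    loc, scale = _POOLED_MOMENTS[var][g]
                params[f"{var}@{g}"] = (loc, scale, family)
        phenos.append(PhenotypeSpec(name=name, prevalence_by_gender=prev,
                                    variable_params=params))
    return CohortSpec(
        n_total=n_total,
        gender_fraction_female=DEFAULT_FEMALE_FRACTION,
        phenotypes=phenos,
        bmi_bands=_DEFAULT_BMI_BANDS,
        seed=seed,
        copula_rho=copula_rho,
    )


# Backwards-friendly alias used throughout the pipeline.
default_spec_from_tables = default_spec


# ---------------------------------------------------------------------------
# Drawing
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a lognormal: return (mu, sigma) of the underlying normal."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _draw_from_uniforms(u: np.ndarray, var: str, loc: float, scale: float,
                        family: str) -> np.ndarray:
    """Map Uniform(0,1) draws through the variable's marginal quantile function."""
    if family == "lognormal":
        mu, sigma = _lognormal_params(loc, scale)
        return np.exp(stats.norm.ppf(u, loc=mu, scale=sigma))
    lo = _TRUNCATION.get(var)
    if lo is None:
        return stats.norm.ppf(u, loc=loc, scale=scale)
    a = (lo - loc) / scale
    return stats.truncnorm.ppf(u, a, np.inf, loc=loc, scale=scale)


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort table from ``spec``; identical seeds give identical tables.

    Returns a DataFrame with the cohort CSV columns plus boolean
    ``diabetes_flag`` / ``insulin_missing`` columns (all False; exclusion
    logic is exercised by setting them downstream) and the hidden
    ``true_phenotype`` label used by recovery tests.
    """
    if seed is None:
        seed = spec.seed if spec.seed is not None else 0
    rng = np.random.default_rng(seed)
    n = spec.n_total
    if n == 0:
        cols = COHORT_CSV_COLUMNS + ["diabetes_flag", "insulin_missing"]
        return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})

    gender = np.where(rng.random(n) < spec.gender_fraction_female, "F", "M")
    phenotype = np.empty(n, dtype=object)
    pheno_by_name = {p.name: p for p in spec.phenotypes}
    names = [p.name for p in spec.phenotypes]
    for g in GENDERS:
        mask = gender == g
        probs = np.array([pheno_by_name[nm].prevalence_by_gender[g] for nm in names])
        phenotype[mask] = rng.choice(names, size=int(mask.sum()), p=probs)

    out = pd.DataFrame(index=np.arange(n))
    out["id"] = np.arange(1, n + 1)
    out["gender"] = gender
    out["true_phenotype"] = phenotype
    for var in VARIABLES:
        out[var] = np.nan
    out["bmi"] = np.nan

    m = len(VARIABLES)
    for g in GENDERS:
        for name in names:
            mask = (gender == g) & (phenotype == name)
            ng = int(mask.sum())
            if ng == 0:
                continue
            ps = pheno_by_name[name]
            # uniforms per variable; optionally coupled through a Gaussian copula
            if spec.copula_rho != 0.0:
                cov = np.full((m, m), spec.copula_rho)
                np.fill_diagonal(cov, 1.0)
                z = rng.multivariate_normal(np.zeros(m), cov, size=ng,
                                            method="cholesky")
                u = stats.norm.cdf(z)
            else:
                u = rng.random((ng, m))
            for j, var in enumerate(VARIABLES):
                key = f"{var}@{g}" if f"{var}@{g}" in ps.variable_params else var
                loc, scale, family = ps.variable_params[key]
                out.loc[mask, var] = _draw_from_uniforms(u[:, j], var, loc,
                                                         scale, family)
            # BMI uniform within the phenotype's WHO band(s)
            bands = list(spec.bmi_bands[name])
            w = np.array([b[2] for b in bands], dtype=float)
            w = w / w.sum()
            which = rng.choice(len(bands), size=ng, p=w)
            lo = np.array([bands[i][0] for i in which])
            hi = np.array([bands[i][1] for i in which])
            out.loc[mask, "bmi"] = lo + rng.random(ng) * (hi - lo)

    # plumbing variables derived from the phenotype-specific draws
    age_a = (18.0 - spec.age_mean) / spec.age_sd
    out["age_y"] = stats.truncnorm.ppf(rng.random(n), age_a, np.inf,
                                       loc=spec.age_mean, scale=spec.age_sd)
    pp = stats.truncnorm.ppf(rng.random(n), (20.0 - 42.4) / 10.0, np.inf,
                             loc=42.4, scale=10.0)  # pulse pressure, mmHg
    out["dbp"] = out["map"] - pp / 3.0
    out["sbp"] = out["map"] + 2.0 * pp / 3.0
    out["insulin"] = out["homa2ir"] * 7.2 * np.exp(rng.normal(0.0, 0.15, n))
    out["homa2s"] = 100.0 / out["homa2ir"]
    out["diabetes_flag"] = False
    out["insulin_missing"] = False

    cols = COHORT_CSV_COLUMNS + ["diabetes_flag", "insulin_missing"]
    # `map` is regenerated downstream from sbp/dbp; keep it out of the frame
    return out[cols].copy()


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=COHORT_CSV_COLUMNS)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_CSV_COLUMNS if c not in df.columns
               and c != "true_phenotype"]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    if "diabetes_flag" not in df.columns:
        df["diabetes_flag"] = False
    if "insulin_missing" not in df.columns:
        df["insulin_missing"] = False
    return df
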