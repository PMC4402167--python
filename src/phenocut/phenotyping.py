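"""Stratified clustering and six-phenotype assignment.

Each gender x BMI stratum is clustered independently with the two-step
procedure on its own predictor set (insulin-resistance indices, plus
triglycerides for men; waist circumference is never a predictor because it
is the quantity under evaluation).  Clusters are labeled metabolically
healthy when their mean HOMA2-IR on the original scale is below the
population cutpoint 2.00, and the (stratum, health) pair maps onto one of
six phenotypes: HNW, MONW, OW_HEALTHY, OW_SICK, MHO, MDO.  Obese subjects
are clustered per WHO obesity class and the health labels pooled into single
obese healthy/sick groups; underweight subjects carry no phenotype and are
excluded with a logged count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_synth import PHENOTYPES
from .preprocessing import classify_bmi_series, log_transform_if_nonnormal
from .twostep_cluster import ClusterModel, assign_by_centroids, fit_twostep

__all__ = [
    "HOMA2IR_CUTPOINT",
    "StratumResult",
    "stratum_predictors",
    "label_clusters",
    "run_phenotyping",
    "assign_phenotypes",
]

#: population-specific HOMA2-IR cutpoint separating healthy from sick clusters
HOMA2IR_CUTPOINT = 2.00

#: per-(gender, base stratum) predictor sets
_PREDICTORS = {
    ("F", "normal"): ["homa2ir", "homa2b"],
    ("M", "normal"): ["homa2ir", "homa2b", "tag"],
    ("F", "overweight"): ["homa2ir", "homa2b"],
    ("M", "overweight"): ["homa2ir", "homa2b", "tag"],
    ("F", "obese"): ["homa2ir"],
    ("M", "obese"): ["homa2ir"],
}

#: clustering strata; obese WHO classes are clustered separately
_STRATA = ("normal", "overweight", "obese_1", "obese_2", "obese_3")

_BASE_OF = {"normal": "normal", "overweight": "overweight",
            "obese_1": "obese", "obese_2": "obese", "obese_3": "obese"}

_PHENOTYPE_OF = {
    ("normal", "healthy"): "HNW",
    ("normal", "sick"): "MONW",
    ("overweight", "healthy"): "OW_HEALTHY",
    ("overweight", "sick"): "OW_SICK",
    ("obese", "healthy"): "MHO",
    ("obese", "sick"): "MDO",
}


def stratum_predictors(gender: str, bmi_stratum: str) -> list[str]:
    """Predictor set for one gender and BMI stratum.

    ``bmi_stratum`` accepts base names (normal / overweight / obese) or
    obese sub-classes (obese_1 / obese_2 / obese_3).
    """
    base = _BASE_OF.get(bmi_stratum, bmi_stratum)
    key = (gender, base)
    if key not in _PREDICTORS:
        raise ValueError(f"unknown stratum {(gender, bmi_stratum)!r}")
    return list(_PREDICTORS[key])


def label_clusters(homa2ir_means, cutpoint: float = HOMA2IR_CUTPOINT) -> list[str]:
    """Healthy iff the cluster's mean HOMA2-IR (original scale) is < cutpoint."""
    means = np.asarray(homa2ir_means, dtype=float)
    if means.size == 0 or np.any(~np.isfinite(means)):
        raise ValueError("cluster HOMA2-IR means missing or non-finite")
    return ["healthy" if m < cutpoint else "sick" for m in means]


@dataclass
class StratumResult:
    """Fitted clustering of one gender x BMI stratum with health labels."""

    gender: str
    stratum: str                     # normal / overweight / obese_1..3
    predictors: list[str]
    model: ClusterModel
    health_labels: list[str]         # per cluster
    homa2ir_means: np.ndarray        # per cluster, original scale
    record_index: np.ndarray         # positional index into the input table
    cluster_of_record: np.ndarray
    transform_log: dict

    @property
    def base_stratum(self) -> str:
        return _BASE_OF[self.stratum]

    def to_dict(self) -> dict:
        return {
            "gender": self.gender,
            "stratum": self.stratum,
            "predictors": self.predictors,
            "health_labels": self.health_labels,
            "homa2ir_means": self.homa2ir_means.tolist(),
            "model": self.model.to_dict(),
        }


def _stratum_seed(seed: int, gender: str, stratum: str) -> int:
    idx = _STRATA.index(stratum) + (0 if gender == "F" else len(_STRATA))
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


def run_phenotyping(
    df: pd.DataFrame,
    *,
    seed: int = 0,
    cutpoint: float = HOMA2IR_CUTPOINT,
    alpha: float = 0.05,
    k: int | None = None,
    compute_quality: bool = False,
) -> tuple[pd.DataFrame, list[StratumResult], dict]:
    """Cluster every stratum and assign each subject a phenotype.

    Returns ``(table, stratum_results, info)`` where ``table`` is the input
    with ``bmi_class``, ``health`` and ``phenotype`` columns appended
    (underweight rows keep a null phenotype) and ``info`` counts excluded
    underweight subjects.  Skewed predictors are log-transformed per stratum
    before clustering (Geary-tested at ``alpha``); health labeling always
    uses original-scale HOMA2-IR means.
    """
    out = df.copy().reset_index(drop=True)
    out["bmi_class"] = classify_bmi_series(out["bmi"])
    out["phenotype"] = pd.NA
    out["health"] = pd.NA
    n_underweight = int((out["bmi_class"] == "underweight").sum())

    results: list[StratumResult] = []
    for gender in ("F", "M"):
        for stratum in _STRATA:
            mask = (out["gender"] == gender) & (out["bmi_class"] == stratum)
            idx = np.flatnonzero(mask.to_numpy())
            if idx.size == 0:
                continue
            predictors = stratum_predictors(gender, stratum)
            sub = out.loc[mask, predictors].reset_index(drop=True)
            if idx.size >= 8:
                sub_t, tlog = log_transform_if_nonnormal(sub, predictors,
                                                         alpha=alpha)
            else:
                sub_t, tlog = sub, {}
            force_k = k if k is not None else (1 if idx.size < 8 else None)
            # coarse BIC selection: stratum clusters are pooled into
            # healthy/sick afterwards, so over-partitioning is harmless
            # while missing a weak sick subgroup is not
            model = fit_twostep(sub_t, predictors, k=force_k, seed=
                                _stratum_seed(seed, gender, stratum),
                                compute_quality=compute_quality,
                                k_select="coarse")
            homa2ir = out.loc[mask, "homa2ir"].to_numpy(dtype=float)
            means = np.array([
                homa2ir[model.labels_ == c].mean() for c in range(model.k)
            ])
            health = label_clusters(means, cutpoint)
            record_health = np.array(health, dtype=object)[model.labels_]
            out.loc[mask, "health"] = record_health
            base = _BASE_OF[stratum]
            out.loc[mask, "phenotype"] = [
                _PHENOTYPE_OF[(base, h)] for h in record_health
            ]
            results.append(StratumResult(
                gender=gender, stratum=stratum, predictors=predictors,
                model=model, health_labels=health, homa2ir_means=means,
                record_index=idx, cluster_of_record=model.labels_,
                transform_log=tlog,
            ))
    info = {"n_underweight_excluded": n_underweight,
            "n_phenotyped": int(out["phenotype"].notna().sum())}
    return out, results, info


def assign_phenotypes(df: pd.DataFrame,
                      stratum_results: list[StratumResult],
                      *,
                      cutpoint: float = HOMA2IR_CUTPOINT) -> pd.DataFrame:
    """Phenotype new records using previously fitted stratum models.

    Records are routed to the stratum model matching their gender and BMI
    class, assigned to the nearest cluster by centroid distance, and given
    that cluster's health label.  Underweight records and records whose
    stratum has no fitted model keep a null phenotype.
    """
    out = df.copy().reset_index(drop=True)
    out["bmi_class"] = classify_bmi_series(out["bmi"])
    out["phenotype"] = pd.NA
    out["health"] = pd.NA
    by_key = {(r.gender, r.stratum): r for r in stratum_results}
    for (gender, stratum), res in by_key.items():
        mask = (out["gender"] == gender) & (out["bmi_class"] == stratum)
        if not mask.any():
            continue
        sub = out.loc[mask, res.predictors].copy()
        # replicate the training-time per-column log transform
        for col, entry in res.transform_log.items():
            if entry.get("transformed"):
                vals = sub[col].to_numpy(dtype=float)
                if np.any(~(vals > 0)):
                    raise ValueError(
                        f"column {col!r} has non-positive values; cannot "
                        f"apply the stratum's log transform")
                sub[col] = np.log(vals)
        labels, _ = assign_by_centroids(res.model, sub)
        health = np.array(res.health_labels, dtype=object)
        assigned = np.where(labels >= 0, health[np.clip(labels, 0, None)], None)
        out.loc[mask, "health"] = assigned
        base = _BASE_OF[stratum]
        out.loc[mask, "phenotype"] = [
            _PHENOTYPE_OF[(base, h)] if h is not None else pd.NA
            for h in assigned
        ]
    return out


def phenotype_prevalences(table: pd.DataFrame) -> pd.Series:
    """Fraction of phenotyped subjects in each of the six phenotypes."""
    counts = table["phenotype"].value_counts()
    total = int(counts.sum())
    return pd.Series({p: counts.get(p, 0) / total for p in PHENOTYPES})
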