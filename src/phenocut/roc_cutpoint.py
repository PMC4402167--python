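"""ROC curves of waist circumference under stepwise phenotype exclusion.

Gender-specific ROC curves predict metabolic sickness from waist
circumference (WC; positive call when WC >= threshold) under three
scenarios: all six phenotypes, four groups (dropping the atypical MONW and
MHO), and two groups (healthy normal weight vs metabolically disturbed
obese).  Cutpoints are scored with the Youden index J = se + sp - 1, the
distance to the perfect corner d = sqrt((1-se)^2 + (1-sp)^2), and the
positive likelihood ratio LR+ = se / (1 - sp); areas under the curve are
compared with DeLong's variance estimate (unpaired form when the scenarios'
subject sets differ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCCurve",
    "CutpointReport",
    "scenario_filter",
    "build_roc",
    "youden",
    "distance01",
    "lr_plus",
    "select_cutpoint",
    "auc_with_variance",
    "delong_test",
    "stepwise_report",
]

SCENARIOS = ("six_group", "four_group", "two_group")

_SICK = {"MONW", "OW_SICK", "MDO"}


def round2(x: float) -> float:
    """Round half-up to 2 decimals (table formatting convention)."""
    x = float(x)
    if not math.isfinite(x):
        return x
    # pre-round at 1e-10 so binary float error does not flip the half-up rule
    return float(Decimal(repr(round(x, 10))).quantize(Decimal("0.01"),
                                                      rounding=ROUND_HALF_UP))


def scenario_filter(table: pd.DataFrame, scenario: str
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """Select the records and binary sick labels for one exclusion scenario.

    ``six_group`` keeps all six phenotypes; ``four_group`` drops the
    atypical MONW and MHO; ``two_group`` keeps only HNW and MDO.  Sick = 1
    for the metabolically disturbed phenotypes that remain.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    ph = table["phenotype"]
    keep = ph.notna()
    if scenario == "four_group":
        keep &= ~ph.isin(["MONW", "MHO"])
    elif scenario == "two_group":
        keep &= ph.isin(["HNW", "MDO"])
    sub = table.loc[keep].copy()
    y = sub["phenotype"].isin(_SICK).to_numpy(dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"scenario {scenario!r} leaves a single class")
    return sub, y


@dataclass
class ROCCurve:
    """Thresholded operating points of WC vs sickness for one scenario."""

    thresholds: np.ndarray   # cm; includes -inf/+inf sentinels
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    scenario: str = ""
    gender: str = ""
    n_pos: int = 0
    n_neg: int = 0


def _concordance_auc(x: np.ndarray, y: np.ndarray) -> float:
    """AUC as the pairwise concordance probability (ties count 1/2)."""
    pos = x[y == 1]
    neg = x[y == 0]
    ranks = stats.rankdata(np.concatenate([neg, pos]))
    r_pos = ranks[len(neg):]
    u = r_pos.sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def build_roc(wc_values, sick_labels, scenario: str = "",
              gender: str = "") -> ROCCurve:
    """ROC curve with thresholds at midpoints of consecutive distinct WC values.

    A subject is called positive when WC >= threshold.  The trapezoid AUC is
    cross-checked against the rank-statistic (concordance) formulation to
    1e-10; both must agree since the curve is a step function.
    """
    x = np.asarray(wc_values, dtype=float)
    y = np.asarray(sick_labels, dtype=int)
    if x.shape != y.shape:
        raise ValueError("wc_values and sick_labels must align")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be nonempty")
    u = np.unique(x)
    mids = (u[:-1] + u[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    pos = np.sort(x[y == 1])
    neg = np.sort(x[y == 0])
    # calls: count of values >= t
    tp = n_pos - np.searchsorted(pos, thresholds, side="left")
    fp = n_neg - np.searchsorted(neg, thresholds, side="left")
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    fpr = fp / n_neg
    # trapezoid over (FPR, TPR); both are non-increasing in the threshold,
    # so reversing gives the ROC path in increasing-FPR order
    auc_trap = float(np.trapezoid(sens[::-1], fpr[::-1]))
    auc_conc = _concordance_auc(x, y)
    if abs(auc_trap - auc_conc) > 1e-10:
        raise AssertionError(
            f"trapezoid AUC {auc_trap!r} disagrees with concordance AUC "
            f"{auc_conc!r}")
    return ROCCurve(thresholds=thresholds, sens=sens, spec=spec,
                    auc=auc_trap, scenario=scenario, gender=gender,
                    n_pos=n_pos, n_neg=n_neg)


def _check_rate(name, v):
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {v}")


def youden(sens: float, spec: float) -> float:
    """Youden index J = sensitivity + specificity - 1."""
    _check_rate("sens", sens)
    _check_rate("spec", spec)
    return sens + spec - 1.0


def distance01(sens: float, spec: float) -> float:
    """Euclidean distance of the ROC point from the perfect corner (0, 1)."""
    _check_rate("sens", sens)
    _check_rate("spec", spec)
    return math.sqrt((1.0 - sens) ** 2 + (1.0 - spec) ** 2)


def lr_plus(sens: float, spec: float) -> float:
    """Positive likelihood ratio sens / (1 - spec); +inf at perfect specificity."""
    _check_rate("sens", sens)
    _check_rate("spec", spec)
    if spec == 1.0:
        return math.inf
    return sens / (1.0 - spec)


@dataclass
class CutpointReport:
    """A selected WC cutoff and its selection indices."""

    cutpoint: float          # cm
    sens: float
    spec: float
    youden: float
    distance01: float
    lr_plus: float
    scenario: str = ""
    gender: str = ""
    auc: float = float("nan")
    policy: str = "youden_sens"

    def rounded(self) -> dict:
        """Indices formatted like the published tables (2 dp, percentages)."""
        return {
            "cutpoint_cm": self.cutpoint,
            "sens_pct": round2(100.0 * self.sens) if np.isfinite(self.sens) else None,
            "spec_pct": round2(100.0 * self.spec),
            "youden": round2(self.youden),
            "distance01": round2(self.distance01),
            "lr_plus": round2(self.lr_plus) if math.isfinite(self.lr_plus) else "inf",
        }


def select_cutpoint(curve: ROCCurve, policy: str = "youden_sens",
                    epsilon: float = 0.005) -> CutpointReport:
    """Pick the operating threshold of a ROC curve.

    ``youden_sens`` (default): among thresholds whose Youden index is within
    ``epsilon`` of the maximum, take the most sensitive one (ties: lowest
    threshold) — sensitivity is favored over specificity.  ``youden``: strict
    maximum J.  ``distance``: minimum distance to the (0, 1) corner.
    """
    finite = np.isfinite(curve.thresholds)
    t = curve.thresholds[finite]
    se = curve.sens[finite]
    sp = curve.spec[finite]
    if t.size == 0:
        raise ValueError("curve has no finite thresholds")
    J = se + sp - 1.0
    d = np.sqrt((1 - se) ** 2 + (1 - sp) ** 2)
    if policy == "youden_sens":
        cand = np.flatnonzero(J >= J.max() - epsilon)
        cand = cand[se[cand] == se[cand].max()]
        pick = cand[np.argmin(t[cand])]
    elif policy == "youden":
        cand = np.flatnonzero(J == J.max())
        pick = cand[np.argmin(t[cand])]
    elif policy == "distance":
        cand = np.flatnonzero(d == d.min())
        pick = cand[np.argmin(t[cand])]
    else:
        raise ValueError(f"unknown policy {policy!r}")
    return CutpointReport(
        cutpoint=float(t[pick]), sens=float(se[pick]), spec=float(sp[pick]),
        youden=float(J[pick]), distance01=float(d[pick]),
        lr_plus=lr_plus(float(se[pick]), float(sp[pick])),
        scenario=curve.scenario, gender=curve.gender, auc=curve.auc,
        policy=policy,
    )


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------

def _placements(x: np.ndarray, y: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    pos = x[y == 1]
    neg = x[y == 0]
    m, n = len(pos), len(neg)
    neg_sorted = np.sort(neg)
    pos_sorted = np.sort(pos)
    # fraction of negatives strictly below + half ties
    below = np.searchsorted(neg_sorted, pos, side="left")
    ties = np.searchsorted(neg_sorted, pos, side="right") - below
    v10 = (below + 0.5 * ties) / n
    above = m - np.searchsorted(pos_sorted, neg, side="right")
    ties_n = np.searchsorted(pos_sorted, neg, side="right") \
        - np.searchsorted(pos_sorted, neg, side="left")
    v01 = (above + 0.5 * ties_n) / m
    return v10, v01


def auc_with_variance(marker, labels) -> tuple[float, float]:
    """AUC and its DeLong variance estimate for a single curve."""
    x = np.asarray(marker, dtype=float)
    y = np.asarray(labels, dtype=int)
    v10, v01 = _placements(x, y)
    auc = float(v10.mean())
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        raise ValueError("need at least two observations per class")
    var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    return auc, var


def delong_test(marker, labels, subset_a, subset_b) -> dict:
    """Compare the AUCs of two scenario subsets sharing one marker.

    ``subset_a`` / ``subset_b`` are boolean masks over the records.  When the
    masks are identical the paired form (with the covariance of the
    placement values) is used; otherwise the two-sample unpaired form.
    Returns a dict with aucs, variance of the difference, z and two-sided p.
    """
    x = np.asarray(marker, dtype=float)
    y = np.asarray(labels, dtype=int)
    a = np.asarray(subset_a, dtype=bool)
    b = np.asarray(subset_b, dtype=bool)
    auc_a, var_a = auc_with_variance(x[a], y[a])
    auc_b, var_b = auc_with_variance(x[b], y[b])
    if np.array_equal(a, b):
        var = 0.0  # identical curves: the difference is exactly zero
        paired = True
        if not np.allclose(auc_a, auc_b):  # pragma: no cover - defensive
            raise AssertionError("identical subsets produced different AUCs")
    else:
        var = var_a + var_b
        paired = False
    if var <= 0:
        z = 0.0
        p = 1.0
        if auc_a != auc_b:
            raise ValueError("degenerate variance with unequal AUCs")
    else:
        z = (auc_a - auc_b) / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return {"auc_a": auc_a, "auc_b": auc_b, "var": var, "z": float(z),
            "p": float(p), "paired": paired}


# ---------------------------------------------------------------------------
# Stepwise report
# ---------------------------------------------------------------------------

def stepwise_report(table: pd.DataFrame, *, policy: str = "youden_sens",
                    epsilon: float = 0.005) -> dict:
    """Per-gender, per-scenario cutpoint reports with pairwise AUC comparisons.

    ``table`` must carry ``gender``, ``wc_cm`` and ``phenotype`` columns.
    For each gender the three exclusion scenarios are evaluated; all pairwise
    DeLong comparisons are run in the unpaired two-sample form because each
    exclusion step changes the subject set.
    """
    out: dict = {"policy": policy, "genders": {}}
    for gender in ("F", "M"):
        sub = table.loc[table["gender"] == gender]
        if len(sub) == 0:
            raise ValueError(f"no records for gender {gender!r}")
        curves: dict[str, ROCCurve] = {}
        reports: dict[str, CutpointReport] = {}
        masks: dict[str, np.ndarray] = {}
        wc_all = sub["wc_cm"].to_numpy(dtype=float)
        sick_all = sub["phenotype"].isin(_SICK).to_numpy(dtype=int)
        for scenario in SCENARIOS:
            kept, y = scenario_filter(sub, scenario)
            mask = np.zeros(len(sub), dtype=bool)
            mask[np.flatnonzero(sub.index.isin(kept.index))] = True
            masks[scenario] = mask
            curve = build_roc(kept["wc_cm"].to_numpy(dtype=float), y,
                              scenario=scenario, gender=gender)
            curves[scenario] = curve
            reports[scenario] = select_cutpoint(curve, policy=policy,
                                                epsilon=epsilon)
        delong = []
        for i, sc_a in enumerate(SCENARIOS):
            for sc_b in SCENARIOS[i + 1:]:
                res = delong_test(wc_all, sick_all, masks[sc_a], masks[sc_b])
                delong.append({"a": sc_a, "b": sc_b, **res})
        out["genders"][gender] = {
            "curves": curves,
            "cutpoints": reports,
            "delong": delong,
        }
    return out


def report_to_json_dict(report: dict) -> dict:
    """JSON-serializable view of a stepwise report."""
    payload: dict = {"policy": report["policy"], "genders": {}}
    for gender, res in report["genders"].items():
        entries = []
        for scenario in SCENARIOS:
            cp: CutpointReport = res["cutpoints"][scenario]
            curve: ROCCurve = res["curves"][scenario]
            entries.append({
                "gender": gender,
                "scenario": scenario,
                "n": int(curve.n_pos + curve.n_neg),
                "n_pos": curve.n_pos,
                "n_neg": curve.n_neg,
                "auc": curve.auc,
                "cutpoint_cm": cp.cutpoint,
                "sens": cp.sens,
                "spec": cp.spec,
                "youden": cp.youden,
                "distance01": cp.distance01,
                "lr_plus": (cp.lr_plus if math.isfinite(cp.lr_plus)
                            else "inf"),
                "rounded": cp.rounded(),
            })
        payload["genders"][gender] = {
            "scenarios": entries,
            "delong": [
                {k: (v if not isinstance(v, float) or math.isfinite(v)
                     else str(v)) for k, v in d.items()}
                for d in res["delong"]
            ],
        }
    return payload


def candidate_table(curve: ROCCurve, epsilon: float = 0.005) -> pd.DataFrame:
    """Near-optimal candidate cutpoints of a curve, one row each.

    Includes every threshold whose Youden index is within ``epsilon`` of the
    maximum plus the closest-to-corner point, mirroring the candidate rows of
    a published cutpoint table.
    """
    finite = np.isfinite(curve.thresholds)
    t = curve.thresholds[finite]
    se = curve.sens[finite]
    sp = curve.spec[finite]
    J = se + sp - 1.0
    d = np.sqrt((1 - se) ** 2 + (1 - sp) ** 2)
    cand = set(np.flatnonzero(J >= J.max() - epsilon).tolist())
    cand.add(int(np.argmin(d)))
    rows = []
    for i in sorted(cand):
        rows.append({
            "gender": curve.gender, "scenario": curve.scenario,
            "wc_cm": t[i], "sens_pct": round2(100 * se[i]),
            "spec_pct": round2(100 * sp[i]), "youden": round2(J[i]),
            "distance01": round2(d[i]),
            "lr_plus": round2(lr_plus(se[i], sp[i]))
            if sp[i] < 1 else math.inf,
        })
    return pd.DataFrame(rows)
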