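"""Split-half cross-validation of the clustering with Cohen's kappa.

The cohort is split into a training half (S1) and a testing half (S2).  S2
subjects are labeled two ways: by proximity to the S1 cluster centroids and
by clustering S2 independently.  After aligning the two labelings (the
column permutation maximizing agreement), chance-corrected agreement is
summarized by Cohen's kappa with a large-sample significance test.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_synth import PHENOTYPES
from .phenotyping import assign_phenotypes, run_phenotyping

__all__ = [
    "split",
    "build_confusion",
    "align_labels",
    "cohens_kappa",
    "cross_validate_clustering",
    "cross_validate_phenotypes",
]


def split(df: pd.DataFrame, fraction: float = 0.5, seed: int | None = None,
          stratify_by: str | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive, seeded split into (S1, S2).

    ``fraction`` is the share assigned to S1.  With ``stratify_by`` the
    split keeps each group's share within one subject of ``fraction``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(df)
    if n < 2:
        raise ValueError("need at least two records to split")
    rng = np.random.default_rng(seed)
    take = np.zeros(n, dtype=bool)
    if stratify_by is None:
        order = rng.permutation(n)
        take[order[: int(round(fraction * n))]] = True
    else:
        groups = df[stratify_by].to_numpy()
        for g in pd.unique(groups):
            pos = np.flatnonzero(groups == g)
            order = rng.permutation(pos.size)
            take[pos[order[: int(round(fraction * pos.size))]]] = True
    return df.iloc[take].copy(), df.iloc[~take].copy()


def build_confusion(labels_a, labels_b,
                    categories: Sequence | None = None) -> np.ndarray:
    """Square count matrix: rows = method A, columns = method B."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    if categories is None:
        categories = sorted(set(a) | set(b))
    cat_index = {c: i for i, c in enumerate(categories)}
    k = len(categories)
    M = np.zeros((k, k), dtype=int)
    for x, y in zip(a, b):
        M[cat_index[x], cat_index[y]] += 1
    return M


def align_labels(confusion: np.ndarray) -> tuple[tuple[int, ...], np.ndarray]:
    """Column permutation maximizing the diagonal sum of a square count matrix.

    Returns ``(perm, aligned)`` where ``aligned[:, j] = confusion[:, perm[j]]``.
    Ties are broken by the lexicographically smallest permutation; solved by
    exhaustive search for small k (k <= 8), by optimal assignment otherwise.
    """
    M = np.asarray(confusion)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("confusion matrix must be square")
    k = M.shape[0]
    if k <= 8:
        best_perm, best_sum = None, -1
        for perm in itertools.permutations(range(k)):
            s = sum(M[i, perm[i]] for i in range(k))
            if s > best_sum:
                best_perm, best_sum = perm, s
        perm = best_perm
    else:
        from scipy.optimize import linear_sum_assignment
        _, cols = linear_sum_assignment(-M)
        perm = tuple(int(c) for c in cols)
    return perm, M[:, list(perm)]


def cohens_kappa(confusion: np.ndarray) -> tuple[float, float, float]:
    """Cohen's kappa with a large-sample z test against independence.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o and chance
    agreement p_e from the marginals.  Returns ``(kappa, z, p)``.
    """
    M = np.asarray(confusion, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("confusion matrix must be square")
    n = M.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(M) / n
    rows = M.sum(axis=1) / n
    cols = M.sum(axis=0) / n
    pe = float(rows @ cols)
    if pe >= 1.0:
        raise ValueError("kappa undefined: chance agreement is 1")
    kappa = (po - pe) / (1.0 - pe)
    # variance under the null of independent assignments
    var0 = (pe + pe ** 2 - float(np.sum(rows * cols * (rows + cols)))) \
        / (n * (1.0 - pe) ** 2)
    from scipy import stats
    if var0 <= 0:
        z, p = np.inf if kappa > 0 else 0.0, 0.0 if kappa > 0 else 1.0
    else:
        z = kappa / np.sqrt(var0)
        p = 2.0 * stats.norm.sf(abs(z))
    return float(kappa), float(z), float(p)


def cross_validate_clustering(
    data: pd.DataFrame,
    predictors: Sequence[str],
    *,
    fraction: float = 0.5,
    seed: int = 0,
    force_same_k: bool = True,
) -> dict:
    """Cluster-level cross-validation of one stratum.

    Fits the two-step model on S1, assigns S2 both by S1 centroids and by an
    independent S2 clustering (with S1's cluster count when
    ``force_same_k``), aligns the labelings and reports kappa.
    """
    from .twostep_cluster import assign_by_centroids, fit_twostep

    s1, s2 = split(data, fraction=fraction, seed=seed)
    m1 = fit_twostep(s1, predictors, seed=seed, compute_quality=False)
    by_centroid, _ = assign_by_centroids(m1, s2)
    m2 = fit_twostep(s2, predictors, k=m1.k if force_same_k else None,
                     seed=seed + 1, compute_quality=False)
    M = build_confusion(by_centroid, m2.labels_,
                        categories=list(range(max(m1.k, m2.k))))
    perm, aligned = align_labels(M)
    kappa, z, p = cohens_kappa(aligned)
    return {"confusion": aligned, "permutation": perm, "kappa": kappa,
            "z": z, "p": p, "n": int(aligned.sum()),
            "k_train": m1.k, "k_test": m2.k}


def cross_validate_phenotypes(
    df: pd.DataFrame,
    *,
    fraction: float = 0.5,
    seed: int = 0,
    stratify_by: str | None = None,
) -> dict:
    """Cohort-level cross-validation through the full phenotyping pipeline.

    S2 subjects are phenotyped (a) via the stratum models fitted on S1 and
    (b) by phenotyping S2 independently.  Phenotype labels carry their own
    meaning, so no alignment step is needed; agreement over the six
    phenotypes is summarized by Cohen's kappa.
    """
    s1, s2 = split(df, fraction=fraction, seed=seed, stratify_by=stratify_by)
    _, results_s1, _ = run_phenotyping(s1, seed=seed)
    via_s1 = assign_phenotypes(s2, results_s1)
    own_s2, _, _ = run_phenotyping(s2, seed=seed + 1)
    a = via_s1["phenotype"].to_numpy()
    b = own_s2["phenotype"].to_numpy()
    ok = pd.notna(a) & pd.notna(b)
    M = build_confusion(a[ok], b[ok], categories=list(PHENOTYPES))
    kappa, z, p = cohens_kappa(M)
    return {"confusion": M, "kappa": kappa, "z": z, "p": p,
            "n": int(M.sum()), "categories": list(PHENOTYPES)}
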