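"""Two-group differential expression / differential peak activity.

The pipeline compares luminal and basal sample groups on log2-CPM values
with a Welch t statistic.  For very small designs the p-value comes from
the exact permutation distribution of the group labels; once the number
of label orderings (n!) exceeds ``max_exact_permutations`` the Welch t
reference distribution is used instead.  Multiple testing is controlled
by Benjamini-Hochberg.  This is a deliberately transparent substitute
for negative-binomial GLM packages: the claims downstream are about
pipeline structure and calibration, not about matching any particular
count-model fit, and the substitution is noted in the output header.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ActivityMatrix, SampleDesign, ValidationError, samples_of

DE_CALLS = ("A_up", "B_up", "ns")


def normalize_counts(counts: pd.DataFrame, pseudocount: float = 1.0) -> ActivityMatrix:
    """log2 counts-per-million: value = log2(1e6 * count / column_sum + pc)."""
    values = counts.to_numpy()
    if np.any(values < 0):
        raise ValidationError("counts must be non-negative")
    colsums = values.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        raise ValidationError(
            f"zero library size for sample(s): {[counts.columns[i] for i in zero]}")
    cpm = 1e6 * values / colsums
    return ActivityMatrix(
        pd.DataFrame(np.log2(cpm + pseudocount), index=counts.index,
                     columns=counts.columns))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch t and Satterthwaite df over rows (features)."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    # zero variance in both groups: t is 0 when means agree, +/-inf otherwise
    with np.errstate(invalid="ignore"):
        t = np.where(se2 == 0,
                     np.where(ma == mb, 0.0,
                              np.where(ma > mb, np.inf, -np.inf)), t)
    df = np.where(np.isfinite(df), df, 1.0)
    return t, df


def differential_test(matrix: ActivityMatrix, design: Sequence[SampleDesign],
                      group_a: str, group_b: str,
                      max_exact_permutations: int = 10_000) -> pd.DataFrame:
    """Per-feature two-group test on a log-scale activity matrix.

    Returns a DataFrame with columns ``feature_id, log2fc, stat, p, q``
    where ``log2fc`` is mean(A) - mean(B) on the log2 scale.
    """
    ids_a = samples_of(design, group_a)
    ids_b = samples_of(design, group_b)
    for label, ids in ((group_a, ids_a), (group_b, ids_b)):
        if len(ids) < 2:
            raise ValidationError(
                f"group {label!r} has {len(ids)} samples; need >= 2 for a variance")
        missing = [s for s in ids if s not in matrix.data.columns]
        if missing:
            raise ValidationError(f"samples missing from matrix: {missing}")
    a = matrix.data[ids_a].to_numpy()
    b = matrix.data[ids_b].to_numpy()
    t_obs, df = _welch_t(a, b)
    # In a balanced design the Welch statistic coincides with the pooled
    # two-sample statistic, whose exact null distribution is t(n-2); the
    # Satterthwaite df approximation is kept for unbalanced designs only.
    if len(ids_a) == len(ids_b):
        df = np.full_like(df, len(ids_a) + len(ids_b) - 2)
    n = len(ids_a) + len(ids_b)
    if math.factorial(n) <= max_exact_permutations:
        pooled = np.concatenate([a, b], axis=1)
        combos = list(itertools.combinations(range(n), len(ids_a)))
        exceed = np.zeros(a.shape[0])
        for combo in combos:
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            t_perm, _ = _welch_t(pooled[:, mask], pooled[:, ~mask])
            exceed += np.abs(t_perm) >= np.abs(t_obs) - 1e-12
        # exhaustive enumeration includes the observed labelling, so the
        # minimum attainable two-sided p is 2/N_distinct, never 0
        p = exceed / len(combos)
    else:
        p = 2.0 * stats.t.sf(np.abs(t_obs), df)
        p = np.where(np.isinf(t_obs), 0.0, p)
        p = np.where((t_obs == 0) & ~np.isfinite(p), 1.0, np.clip(p, 0.0, 1.0))
    return pd.DataFrame({
        "feature_id": matrix.feature_ids,
        "log2fc": a.mean(axis=1) - b.mean(axis=1),
        "stat": t_obs,
        "p": p,
        "q": bh_adjust(p),
    })


def call_subtype_features(results: pd.DataFrame, lfc_min: float = 1.0,
                          q_max: float = 0.05) -> tuple[set[str], set[str]]:
    """Threshold test results into (A-up, B-up) feature sets.

    A feature is A-up iff log2fc >= lfc_min, log2fc > 0 and q <= q_max;
    B-up is symmetric.  Exact zero fold-changes are never called.
    """
    if len(results) == 0:
        return set(), set()
    lfc = results["log2fc"]
    q = results["q"]
    a_up = set(results.loc[(lfc >= lfc_min) & (lfc > 0) & (q <= q_max),
                           "feature_id"])
    b_up = set(results.loc[(lfc <= -lfc_min) & (lfc < 0) & (q <= q_max),
                           "feature_id"])
    return a_up, b_up


def annotate_calls(results: pd.DataFrame, lfc_min: float = 1.0,
                   q_max: float = 0.05) -> pd.DataFrame:
    """Add a ``call`` column ({A_up, B_up, ns}) to a results frame."""
    a_up, b_up = call_subtype_features(results, lfc_min, q_max)
    call = np.where(results["feature_id"].isin(a_up), "A_up",
                    np.where(results["feature_id"].isin(b_up), "B_up", "ns"))
    out = results.copy()
    out["call"] = call
    return out
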