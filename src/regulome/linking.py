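"""Enhancer-gene linking by activity-expression correlation.

Candidate links are all (enhancer, gene) pairs on the same chromosome
with the enhancer midpoint within ``window`` bp of the TSS.  Each pair
is scored by the Pearson correlation of enhancer activity and gene
expression across shared samples.  Significance comes from a pooled
empirical null of cross-chromosome pairs: with a handful of samples,
label permutations are far too few to resolve p < 0.01, so the null is
built from pairs that cannot be physically linked.  A link passes with
r >= r_min and one-sided empirical p < p_max (positive coupling only;
anti-correlated pairs are reported but never pass).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (ActivityMatrix, GeneAnnotation, GenomicInterval,
                      ValidationError)
from .diffexp import bh_adjust


def _aligned(enh_activity: ActivityMatrix, expression: ActivityMatrix,
             min_shared: int = 3) -> tuple[np.ndarray, np.ndarray]:
    shared = [s for s in enh_activity.sample_ids if s in set(expression.sample_ids)]
    if len(shared) < min_shared:
        raise ValidationError(
            f"only {len(shared)} shared samples between activity and expression "
            f"matrices; need >= {min_shared}")
    return (enh_activity.data[shared].to_numpy(),
            expression.data[shared].to_numpy())


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    return centered, norms


def select_variable_enhancers(enh_activity: ActivityMatrix,
                              coords: Mapping[str, GenomicInterval],
                              n_top: int) -> list[str]:
    """Top-N enhancers by descending cross-sample variance of log activity.

    Ties break by ascending (chrom, start) so the ranking is a
    deterministic total order.
    """
    ids = enh_activity.feature_ids
    if n_top > len(ids):
        raise ValidationError(
            f"n_top={n_top} exceeds catalog size {len(ids)}")
    var = enh_activity.values.var(axis=1, ddof=1)
    order = sorted(range(len(ids)),
                   key=lambda i: (-var[i], coords[ids[i]].chrom,
                                  coords[ids[i]].start))
    return [ids[i] for i in order[:n_top]]


def correlate_links(enh_activity: ActivityMatrix,
                    coords: Mapping[str, GenomicInterval],
                    expression: ActivityMatrix,
                    genes: Sequence[GeneAnnotation],
                    window: int = 500_000) -> pd.DataFrame:
    """Pearson r for every same-chromosome pair within ``window`` bp.

    Zero-variance vectors give r = 0 and are flagged ``degenerate``.
    Returns columns enhancer_id, gene_id, distance, r, degenerate.
    """
    act, expr = _aligned(enh_activity, expression)
    za, na = _standardize(act)
    zg, ng = _standardize(expr)
    gene_ids = expression.feature_ids
    gene_by_id = {g.gene_id: g for g in genes}
    missing = [gid for gid in gene_ids if gid not in gene_by_id]
    if missing:
        raise ValidationError(f"genes missing TSS annotation: {missing[:5]}")

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {gene_by_id[g].chrom for g in gene_ids}:
        rows = [(gene_by_id[g].tss, i) for i, g in enumerate(gene_ids)
                if gene_by_id[g].chrom == chrom]
        rows.sort()
        by_chrom[chrom] = (np.array([t for t, _ in rows]),
                           np.array([i for _, i in rows]))

    rows_out = []
    for e_idx, eid in enumerate(enh_activity.feature_ids):
        iv = coords[eid]
        if iv.chrom not in by_chrom:
            continue
        tss, g_rows = by_chrom[iv.chrom]
        mid = iv.midpoint
        lo = int(np.searchsorted(tss, mid - window, side="left"))
        hi = int(np.searchsorted(tss, mid + window, side="right"))
        for k in range(lo, hi):
            g_idx = int(g_rows[k])
            if na[e_idx] == 0 or ng[g_idx] == 0:
                r, degenerate = 0.0, True
            else:
                r = float(za[e_idx] @ zg[g_idx] / (na[e_idx] * ng[g_idx]))
                degenerate = False
            rows_out.append((eid, gene_ids[g_idx], int(abs(mid - tss[k])),
                             r, degenerate))
    return pd.DataFrame(rows_out, columns=["enhancer_id", "gene_id", "distance",
                                           "r", "degenerate"])


def empirical_null(enh_activity: ActivityMatrix,
                   coords: Mapping[str, GenomicInterval],
                   expression: ActivityMatrix,
                   genes: Sequence[GeneAnnotation],
                   n_null: int, seed: int) -> np.ndarray:
    """Null correlation sample from uniform cross-chromosome pairs."""
    if n_null <= 0:
        raise ValidationError("n_null must be positive")
    act, expr = _aligned(enh_activity, expression)
    za, na = _standardize(act)
    zg, ng = _standardize(expr)
    gene_by_id = {g.gene_id: g for g in genes}
    enh_chrom = np.array([coords[e].chrom for e in enh_activity.feature_ids])
    gene_chrom = np.array([gene_by_id[g].chrom for g in expression.feature_ids])
    if len(set(enh_chrom) | set(gene_chrom)) < 2:
        raise ValidationError(
            "cross-chromosome null undefined with a single chromosome")
    rng = np.random.default_rng(seed)
    out = np.empty(n_null)
    filled = 0
    while filled < n_null:
        m = max(2 * (n_null - filled), 1000)
        ei = rng.integers(0, len(enh_chrom), m)
        gi = rng.integers(0, len(gene_chrom), m)
        keep = enh_chrom[ei] != gene_chrom[gi]
        ei, gi = ei[keep], gi[keep]
        denom = na[ei] * ng[gi]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.einsum("ij,ij->i", za[ei], zg[gi]) / denom
        r = np.where(denom == 0, 0.0, r)
        take = min(len(r), n_null - filled)
        out[filled:filled + take] = r[:take]
        filled += take
    return out


def score_links(links: pd.DataFrame, null_sample: np.ndarray,
                r_min: float = 0.5, p_max: float = 0.01) -> pd.DataFrame:
    """Attach one-sided empirical p, BH q and the pass flag to links.

    p_emp = (1 + #{null >= r}) / (1 + |null|); monotone non-increasing
    in r for a fixed null.
    """
    if len(null_sample) == 0:
        raise ValidationError("empty null sample")
    null_sorted = np.sort(np.asarray(null_sample, dtype=float))
    n = len(null_sorted)
    r = links["r"].to_numpy()
    exceed = n - np.searchsorted(null_sorted, r, side="left")
    out = links.copy()
    out["p_emp"] = (1.0 + exceed) / (1.0 + n)
    out["q"] = bh_adjust(out["p_emp"]) if len(out) else []
    out["passes"] = (r >= r_min) & (out["p_emp"] < p_max) & ~out["degenerate"]
    return out
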