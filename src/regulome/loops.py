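"""Loop subtype assignment, annotation, tumor support, APA, TF enrichment.

Loops arrive with per-sample probability scores from an upstream loop
caller.  A loop is called subtype-specific when it is confidently
present (prob >= p_high) in every sample of one group and confidently
absent (prob <= p_low) in every sample of the other; confidently
present everywhere makes it shared.  Aggregate Peak Analysis averages
distance-normalised observed/expected windows centred on the loop list
and summarises collective loop strength as center over the lower-left
(near-diagonal) 3x3 corner mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core_io import ContactMatrix, GenomicInterval, Loop, SampleDesign, \
    ValidationError, samples_of
from .svmap import decay_curve

CATEGORIES = ("E-P", "E-E", "P-P", "E-N", "P-N", "None")
SUBTYPE_CALLS = ("luminal", "basal", "shared", "unassigned")


@dataclass
class ApaResult:
    aggregate: np.ndarray      # (2w+1) x (2w+1) mean observed/expected
    score: float               # center / mean(lower-left 3x3 corner)
    n_used: int
    n_skipped: int


def assign_subtype_loops(loops: Sequence[Loop], design: Sequence[SampleDesign],
                         p_high: float = 0.8, p_low: float = 0.5,
                         group_a: str = "luminal",
                         group_b: str = "basal") -> list[Loop]:
    """Set ``subtype_call`` on every loop from per-sample probabilities."""
    if p_low >= p_high:
        raise ValidationError(f"p_low ({p_low}) must be < p_high ({p_high})")
    ids_a, ids_b = samples_of(design, group_a), samples_of(design, group_b)
    all_ids = ids_a + ids_b
    for lp in loops:
        missing = [s for s in all_ids if s not in lp.probs]
        if missing:
            raise ValidationError(
                f"loop {lp.key()} lacks probability for sample(s) {missing}")
        pa = [lp.probs[s] for s in ids_a]
        pb = [lp.probs[s] for s in ids_b]
        if all(p >= p_high for p in pa) and all(p <= p_low for p in pb):
            lp.subtype_call = group_a
        elif all(p >= p_high for p in pb) and all(p <= p_low for p in pa):
            lp.subtype_call = group_b
        elif all(p >= p_high for p in pa + pb):
            lp.subtype_call = "shared"
        else:
            lp.subtype_call = "unassigned"
    return list(loops)


def annotate_loops(loops: Sequence[Loop],
                   promoters: Sequence[GenomicInterval],
                   enhancers: Sequence[GenomicInterval]) -> list[Loop]:
    """Label each loop E-P/E-E/P-P/E-N/P-N/None from anchor overlaps.

    An anchor is P if it overlaps any promoter element (promoter beats
    enhancer on dual overlap), else E if it overlaps any enhancer,
    else N.
    """
    forests = {}
    for key, ivs in (("P", promoters), ("E", enhancers)):
        forest: dict[str, IntervalTree] = {}
        for iv in ivs:
            forest.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        forests[key] = forest

    def label(anchor: GenomicInterval) -> str:
        for key in ("P", "E"):
            tree = forests[key].get(anchor.chrom)
            if tree is not None and tree.overlap(anchor.start, anchor.end):
                return key
        return "N"

    for lp in loops:
        pair = tuple(sorted((label(lp.anchor1), label(lp.anchor2))))
        lp.category = {
            ("E", "P"): "E-P", ("E", "E"): "E-E", ("P", "P"): "P-P",
            ("E", "N"): "E-N", ("N", "P"): "P-N", ("N", "N"): "None",
        }[pair]
    return list(loops)


def category_fractions(loops: Sequence[Loop]) -> dict[str, float]:
    """Fraction of loops per category; sums to 1 for a nonempty set."""
    if not loops:
        raise ValidationError("no loops to summarise")
    counts = {c: 0 for c in CATEGORIES}
    for lp in loops:
        if lp.category is None:
            raise ValidationError("loops must be annotated first")
        counts[lp.category] += 1
    return {c: counts[c] / len(loops) for c in CATEGORIES}


def tumor_support(cellline_loops: Sequence[Loop],
                  tumor_loop_sets: Sequence[Sequence[Loop]],
                  slack_bins: int = 1) -> dict[str, float]:
    """Per-subtype fraction of cell-line loops seen in any tumor set.

    A loop is supported when some tumor loop on the same chromosome
    pair has both anchors within ``slack_bins`` bins.
    """
    resolutions = {lp.resolution for lp in cellline_loops}
    for ts in tumor_loop_sets:
        resolutions |= {lp.resolution for lp in ts}
    if len(resolutions) > 1:
        raise ValidationError(f"resolution mismatch across loop sets: "
                              f"{sorted(resolutions)}")
    anchors: dict[tuple[str, str], list[np.ndarray]] = {}
    for ts in tumor_loop_sets:
        for lp in ts:
            anchors.setdefault((lp.chrom_a, lp.chrom_b), []).append(
                np.array([lp.bin_a, lp.bin_b]))
    stacked = {k: np.vstack(v) for k, v in anchors.items()}

    counts: dict[str, list[int]] = {}
    for lp in cellline_loops:
        call = lp.subtype_call or "unassigned"
        tally = counts.setdefault(call, [0, 0])
        cand = stacked.get((lp.chrom_a, lp.chrom_b))
        supported = bool(
            cand is not None
            and np.any((np.abs(cand[:, 0] - lp.bin_a) <= slack_bins)
                       & (np.abs(cand[:, 1] - lp.bin_b) <= slack_bins)))
        tally[0] += supported
        tally[1] += 1
    return {call: hit / total for call, (hit, total) in counts.items()}


# ---------------------------------------------------------------------------
# Aggregate Peak Analysis
# ---------------------------------------------------------------------------

def _apa_windows(contacts: ContactMatrix, loops: Sequence[Loop], w: int,
                 min_diag_bins: int,
                 expected: np.ndarray | None = None) -> tuple[list[np.ndarray], int]:
    if contacts.chrom_a != contacts.chrom_b:
        raise ValidationError("APA requires an intra-chromosomal matrix")
    values = contacts.values
    n = contacts.n_bins
    if expected is None:
        expected = decay_curve(contacts)
    windows, skipped = [], 0
    for lp in loops:
        if lp.chrom_a != contacts.chrom_a or lp.chrom_b != contacts.chrom_a:
            skipped += 1
            continue
        b1, b2 = lp.bin_a, lp.bin_b
        if (b2 - b1 < min_diag_bins or b1 - w < 0 or b2 - w < 0
                or b1 + w >= n or b2 + w >= n):
            skipped += 1
            continue
        obs = values[b1 - w:b1 + w + 1, b2 - w:b2 + w + 1]
        i_idx, j_idx = np.meshgrid(np.arange(b1 - w, b1 + w + 1),
                                   np.arange(b2 - w, b2 + w + 1), indexing="ij")
        exp = expected[np.abs(j_idx - i_idx)]
        with np.errstate(divide="ignore", invalid="ignore"):
            windows.append(np.where(exp > 0, obs / exp, np.nan))
    return windows, skipped


def apa(contacts: ContactMatrix, loops: Sequence[Loop], w: int = 10,
        min_diag_bins: int | None = None,
        expected: np.ndarray | None = None) -> ApaResult:
    """Aggregate Peak Analysis of a loop list on one chromosome.

    Each loop contributes its (2w+1)^2 observed window divided by the
    distance-stratified expected (mean of each diagonal of the matrix,
    or a caller-supplied expected-per-distance vector).  Loops closer
    than ``min_diag_bins`` (default 2w+2) to the diagonal or touching a
    matrix edge are skipped.  Score is the center pixel over the mean
    of the lower-left (near-diagonal) 3x3 corner of the aggregate.
    """
    return apa_pooled([(contacts, loops)], w=w, min_diag_bins=min_diag_bins,
                      expected=expected)


def apa_pooled(pairs: Sequence[tuple[ContactMatrix, Sequence[Loop]]],
               w: int = 10, min_diag_bins: int | None = None,
               expected: np.ndarray | None = None) -> ApaResult:
    """APA pooling windows across several (matrix, loops) pairs."""
    if min_diag_bins is None:
        min_diag_bins = 2 * w + 2
    windows: list[np.ndarray] = []
    skipped = 0
    for contacts, loops in pairs:
        win, skip = _apa_windows(contacts, loops, w, min_diag_bins, expected)
        windows.extend(win)
        skipped += skip
    if not windows:
        raise ValidationError("all loops were skipped (too close to the "
                              "diagonal or to matrix edges)")
    aggregate = np.nanmean(np.stack(windows), axis=0)
    corner = aggregate[2 * w - 2:2 * w + 1, 0:3]
    score = float(aggregate[w, w] / corner.mean())
    return ApaResult(aggregate=aggregate, score=score,
                     n_used=len(windows), n_skipped=skipped)


# ---------------------------------------------------------------------------
# TF-site enrichment at loop anchors
# ---------------------------------------------------------------------------

def anchor_enrichment(loops: Sequence[Loop],
                      tf_sites: Sequence[GenomicInterval],
                      chrom_sizes: Mapping[str, int],
                      n_shuffles: int = 1000,
                      seed: int = 0) -> tuple[float, float]:
    """Fold enrichment (and empirical p) of TF sites at loop anchor bins.

    The null re-places every site uniformly within its chromosome
    ``n_shuffles`` times; fold = observed / mean(null),
    p = (1 + #{null >= observed}) / (1 + n_shuffles).
    """
    if not loops or not tf_sites:
        raise ValidationError("need at least one loop and one site")
    resolution = loops[0].resolution
    missing = {s.chrom for s in tf_sites} - set(chrom_sizes)
    if missing:
        raise ValidationError(f"site chromosome(s) missing from chrom_sizes: "
                              f"{sorted(missing)}")
    anchor_mask: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        anchor_mask[chrom] = np.zeros(size // resolution + 2, dtype=bool)
    for lp in loops:
        for chrom, b in ((lp.chrom_a, lp.bin_a), (lp.chrom_b, lp.bin_b)):
            if chrom in anchor_mask and b < len(anchor_mask[chrom]):
                anchor_mask[chrom][b] = True

    def count_overlaps(starts: np.ndarray, lengths: np.ndarray,
                       mask: np.ndarray) -> np.ndarray:
        first = starts // resolution
        last = (starts + lengths - 1) // resolution
        return (mask[first] | mask[np.minimum(last, len(mask) - 1)])

    rng = np.random.default_rng(seed)
    observed = 0
    null = np.zeros(n_shuffles)
    for chrom in sorted({s.chrom for s in tf_sites}):
        sites = [s for s in tf_sites if s.chrom == chrom]
        starts = np.array([s.start for s in sites])
        lengths = np.array([s.width for s in sites])
        mask = anchor_mask[chrom]
        observed += int(count_overlaps(starts, lengths, mask).sum())
        max_start = np.maximum(chrom_sizes[chrom] - lengths, 1)
        rand = rng.integers(0, max_start, size=(n_shuffles, len(sites)))
        hits = mask[rand // resolution] | mask[
            np.minimum((rand + lengths[None, :] - 1) // resolution,
                       len(mask) - 1)]
        null += hits.sum(axis=1)
    fold = observed / null.mean() if null.mean() > 0 else np.inf
    p_emp = (1.0 + np.sum(null >= observed)) / (1.0 + n_shuffles)
    return float(fold), float(p_emp)
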