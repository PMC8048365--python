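"""Promoter/distal peak classification, enhancer catalog, co-binding classes.

Peaks are classified by the distance from their midpoint to the nearest
annotated TSS: within ``promoter_window`` they are promoters, otherwise
distal.  Distal H3K27ac-style peaks serve as the active-enhancer proxy;
per-sample activity over the merged catalog feeds the enhancer-gene
linking stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core_io import (ActivityMatrix, GeneAnnotation, GenomicInterval,
                      ValidationError)

COBIND_LABELS = ("A_only", "B_only", "co_bound")


@dataclass
class RegulatoryElement:
    interval: GenomicInterval
    klass: str                 # "promoter" | "distal"
    nearest_gene: str
    tss_distance: int          # signed bp, + downstream of the gene's TSS


@dataclass(frozen=True)
class CobindClass:
    element: GenomicInterval
    label: str                 # one of COBIND_LABELS


def _interval_forest(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    forest: dict[str, IntervalTree] = {}
    for iv in intervals:
        forest.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return forest


def _hits(forest: Mapping[str, IntervalTree], iv: GenomicInterval) -> bool:
    tree = forest.get(iv.chrom)
    return bool(tree is not None and tree.overlap(iv.start, iv.end))


def classify_peaks(peaks: Sequence[GenomicInterval],
                   genes: Sequence[GeneAnnotation],
                   promoter_window: int = 2500) -> list[RegulatoryElement]:
    """Assign each peak promoter/distal status relative to the nearest TSS.

    Distance is measured from the peak midpoint, signed by gene strand
    (positive downstream of the TSS).  Ties on |distance| break toward
    the smaller TSS coordinate, then the smaller gene_id, so the
    partition is deterministic.
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    tss_arrays = {}
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: (g.tss, g.gene_id))
        tss_arrays[chrom] = np.array([g.tss for g in gs])

    orphans = [p for p in peaks if p.chrom not in by_chrom]
    if orphans:
        desc = ", ".join(f"{p.chrom}:{p.start}-{p.end}" for p in orphans[:10])
        raise ValidationError(
            f"{len(orphans)} peak(s) on chromosomes without annotated genes: {desc}")

    out: list[RegulatoryElement] = []
    for peak in peaks:
        gs = by_chrom[peak.chrom]
        tss = tss_arrays[peak.chrom]
        mid = peak.midpoint
        j = int(np.searchsorted(tss, mid))
        best = None
        for k in (j - 1, j, j + 1):
            if 0 <= k < len(gs):
                cand = (abs(mid - gs[k].tss), gs[k].tss, gs[k].gene_id, gs[k])
                if best is None or cand[:3] < best[:3]:
                    best = cand
        gene = best[3]
        signed = (mid - gene.tss) if gene.strand == "+" else (gene.tss - mid)
        klass = "promoter" if abs(signed) <= promoter_window else "distal"
        out.append(RegulatoryElement(peak, klass, gene.gene_id, int(signed)))
    return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of overlapping intervals, sorted by (chrom, start)."""
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ordered:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def element_id(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def build_enhancer_catalog(
        peaks_by_sample: Mapping[str, Sequence[GenomicInterval]],
) -> tuple[list[GenomicInterval], ActivityMatrix]:
    """Merge per-sample distal peaks into a union catalog with activity.

    Per merged element and sample, activity is the mean score of that
    sample's peaks overlapping the element (0 where the sample has no
    peak), then log2(x + 1).  Peak scores must be present (BED score
    column); they stand in for the peak's signal level.
    """
    catalog = merge_intervals(iv for peaks in peaks_by_sample.values()
                              for iv in peaks)
    forest: dict[str, IntervalTree] = {}
    for idx, iv in enumerate(catalog):
        forest.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)

    sample_ids = list(peaks_by_sample)
    sums = np.zeros((len(catalog), len(sample_ids)))
    counts = np.zeros_like(sums)
    for s_idx, sid in enumerate(sample_ids):
        for peak in peaks_by_sample[sid]:
            if peak.score is None:
                raise ValidationError(
                    f"peak {element_id(peak)} in sample {sid} has no signal score")
            tree = forest.get(peak.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(peak.start, peak.end):
                sums[hit.data, s_idx] += peak.score
                counts[hit.data, s_idx] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    activity = ActivityMatrix(pd.DataFrame(
        np.log2(mean + 1.0), index=[element_id(iv) for iv in catalog],
        columns=sample_ids))
    return catalog, activity


def overlap_fraction(set_a: Sequence[GenomicInterval],
                     set_b: Sequence[GenomicInterval]) -> float:
    """Fraction of A elements overlapping at least one B element."""
    if len(set_a) == 0:
        raise ValidationError("overlap_fraction undefined for empty A set")
    forest = _interval_forest(set_b)
    return sum(_hits(forest, iv) for iv in set_a) / len(set_a)


def cobinding_partition(elements: Sequence[GenomicInterval],
                        sites_a: Sequence[GenomicInterval],
                        sites_b: Sequence[GenomicInterval]) -> list[CobindClass]:
    """Partition elements into A-only / B-only / co-bound by site overlap.

    Elements overlapping sites from neither factor are omitted.
    """
    forest_a = _interval_forest(sites_a)
    forest_b = _interval_forest(sites_b)
    out: list[CobindClass] = []
    for el in elements:
        has_a, has_b = _hits(forest_a, el), _hits(forest_b, el)
        if has_a and has_b:
            out.append(CobindClass(el, "co_bound"))
        elif has_a:
            out.append(CobindClass(el, "A_only"))
        elif has_b:
            out.append(CobindClass(el, "B_only"))
    return out
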