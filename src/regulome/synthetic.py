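"""Synthetic two-subtype regulome study with known ground truth.

Generates an internally consistent mock study: negative-binomial gene
expression with planted subtype effects, an enhancer catalog whose true
links are linearly coupled to their target gene's log expression,
chromatin loops with per-sample caller probabilities, distance-decay
Hi-C matrices with planted loop dots, TF sites enriched at loop
anchors, planted co-binding classes, peak sequences with a planted
motif, and a planted rearrangement with its true derivative contact
map.  Every planted feature is recorded in truth tables so downstream
stages can be scored by recall/FDR.

The generative laws are deliberately simple stand-ins (documented in
docs/methods.md); nothing here is fit to any real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (ActivityMatrix, ContactMatrix, GeneAnnotation,
                      GenomicInterval, Loop, SampleDesign, ValidationError,
                      samples_of, write_bed, write_contact_matrix,
                      write_design_tsv, write_fasta, write_genes_tsv,
                      write_loops_bedpe)
from .diffexp import normalize_counts
from .motifs import PWM, reverse_complement, write_jaspar

TRUTH_HEADER = ("# synthetic ground truth: generative stand-in with planted "
                "effects, not fit to any real dataset\n")

# fixed per-stage seed-stream labels so stages are individually reproducible
_STAGES = {"genes": 11, "expression": 23, "regulome": 37, "loops": 47,
           "contacts": 59, "sv": 67, "tf": 79}


@dataclass
class SimConfig:
    """Study conditions for the synthetic regulome.

    Defaults mirror a compact desk-scale study: two chromosomes of
    10 Mb at 10 kb bins, two transcriptional subtypes with two samples
    each, 10% of genes differentially expressed at |log2FC| = 2 with
    negative-binomial dispersion 0.1, enhancer activity coupled to the
    linked gene at a relative noise level giving population r ~ 0.9,
    power-law contact decay with 3-fold planted loop dots, 5-fold TF
    site enrichment at loop anchors, and a motif planted in 50% of
    foreground vs 5% of background peaks.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 10_000_000
    resolution: int = 10_000
    n_genes: int = 2000
    n_enhancers: int = 2200
    n_true_links: int = 200
    n_samples_per_group: int = 2
    nb_dispersion: float = 0.1
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    link_noise_sd: float = 0.45      # relative to the gene's expression sd
    link_window: int = 500_000
    promoter_window: int = 2500
    enhancer_width: int = 500
    loop_count: int = 120
    loop_enrichment: float = 3.0
    min_loop_distance_bins: int = 30
    max_loop_distance_bins: int = 200
    decay_exponent: float = 1.0
    contact_scale: float = 100.0
    trans_background: float = 0.2
    tf_anchor_fold: float = 5.0
    n_tf_sites: int = 1000
    tf_site_width: int = 10
    n_cobind_each: int = 100
    motif_fg_rate: float = 0.5
    motif_bg_rate: float = 0.05
    n_fg_peaks: int = 200
    n_bg_peaks: int = 2000
    peak_seq_len: int = 150
    n_decoy_pwms: int = 10
    sv_flank_bins: int = 100

    def validate(self) -> None:
        counts = [self.n_chroms, self.chrom_len, self.resolution, self.n_genes,
                  self.n_enhancers, self.n_samples_per_group,
                  self.loop_count, self.n_tf_sites, self.n_fg_peaks,
                  self.n_bg_peaks, self.peak_seq_len]
        if any(c <= 0 for c in counts):
            raise ValidationError("all counts in SimConfig must be positive")
        if self.n_true_links < 0 or self.n_cobind_each < 0:
            raise ValidationError("planted feature counts must be >= 0")
        for rate in (self.de_fraction, self.motif_fg_rate, self.motif_bg_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValidationError(f"rate {rate} outside [0, 1]")
        if self.loop_enrichment <= 1.0:
            raise ValidationError("loop_enrichment must exceed 1")
        if self.tf_anchor_fold < 1.0:
            raise ValidationError("tf_anchor_fold must be >= 1")
        if self.min_loop_distance_bins <= 2:
            raise ValidationError("loops must sit > 2 bins off the diagonal")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed,
                                   spawn_key=(_STAGES[stage],)))

    @property
    def chroms(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def n_bins(self) -> int:
        return self.chrom_len // self.resolution


@dataclass
class TruthTables:
    true_de_genes: pd.DataFrame | None = None
    true_links: pd.DataFrame | None = None
    true_subtype_loops: pd.DataFrame | None = None
    planted_breakpoints: pd.DataFrame | None = None
    cobinding: pd.DataFrame | None = None


def make_design(cfg: SimConfig) -> list[SampleDesign]:
    n = cfg.n_samples_per_group
    return ([SampleDesign(f"lum_{i + 1}", "luminal") for i in range(n)]
            + [SampleDesign(f"bas_{i + 1}", "basal") for i in range(n)])


def make_genes(cfg: SimConfig) -> list[GeneAnnotation]:
    """Gene TSS positions; deterministic in cfg so every stage can rebuild
    the identical annotation without passing it around."""
    rng = cfg.rng("genes")
    chrom_idx = rng.integers(0, cfg.n_chroms, cfg.n_genes)
    tss = rng.integers(0, cfg.chrom_len, cfg.n_genes)
    strand = rng.choice(["+", "-"], cfg.n_genes)
    order = np.lexsort((tss, chrom_idx))
    return [GeneAnnotation(f"g{k + 1:05d}", cfg.chroms[chrom_idx[i]],
                           int(tss[i]), str(strand[i]))
            for k, i in enumerate(order)]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB counts (genes x samples) plus the planted-DE truth table.

    Baseline means are log10-uniform in [10, 1e4]; a ``de_fraction`` of
    genes gets a +/- ``de_log2fc`` group effect (half up in each
    group); library sizes are jittered +/-20%; counts are negative
    binomial with variance mu + dispersion * mu^2.
    """
    cfg.validate()
    rng = cfg.rng("expression")
    genes = make_genes(cfg)
    design = make_design(cfg)
    n_samples = len(design)
    base = 10.0 ** rng.uniform(1, 4, cfg.n_genes)

    n_de = int(round(cfg.n_genes * cfg.de_fraction)) if cfg.de_log2fc != 0 else 0
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False) if n_de else \
        np.array([], dtype=int)
    up_luminal = de_idx[: n_de // 2]
    up_basal = de_idx[n_de // 2:]

    lum_cols = [i for i, s in enumerate(design) if s.group == "luminal"]
    bas_cols = [i for i, s in enumerate(design) if s.group == "basal"]
    mean = np.tile(base[:, None], (1, n_samples))
    mean[np.ix_(up_luminal, lum_cols)] *= 2.0 ** cfg.de_log2fc
    mean[np.ix_(up_basal, bas_cols)] *= 2.0 ** cfg.de_log2fc
    mean = mean * rng.uniform(0.8, 1.2, n_samples)

    if cfg.nb_dispersion > 0:
        r = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    else:
        counts = rng.poisson(mean)
    counts_df = pd.DataFrame(counts, index=[g.gene_id for g in genes],
                             columns=[s.sample_id for s in design])

    gene_ids = np.array([g.gene_id for g in genes])
    truth = pd.DataFrame({
        "gene_id": np.concatenate([gene_ids[up_luminal], gene_ids[up_basal]]),
        "log2fc": np.concatenate([np.full(len(up_luminal), cfg.de_log2fc),
                                  np.full(len(up_basal), -cfg.de_log2fc)]),
        "up_group": ["luminal"] * len(up_luminal) + ["basal"] * len(up_basal),
    }).sort_values("gene_id").reset_index(drop=True)
    return counts_df, truth


# ---------------------------------------------------------------------------
# regulome (enhancers + activity + true links)
# ---------------------------------------------------------------------------

@dataclass
class RegulomeSim:
    enhancers: list[GenomicInterval]           # name = enhancer id
    activity: ActivityMatrix
    promoters: list[GenomicInterval]
    true_links: pd.DataFrame                   # enhancer_id, gene_id, coupling


def _outside_promoters(pos: np.ndarray, prom_starts: np.ndarray,
                       prom_ends: np.ndarray, width: int) -> np.ndarray:
    """True where [pos, pos+width) misses every promoter window."""
    j = np.searchsorted(prom_starts, pos + width, side="left") - 1
    inside = (j >= 0) & (pos < prom_ends[np.maximum(j, 0)])
    return ~inside


def simulate_regulome(cfg: SimConfig,
                      expression_counts: pd.DataFrame) -> RegulomeSim:
    """Place enhancers and couple the true links to gene expression.

    True-link enhancer activity is z_g + eps with eps ~ N(0,
    link_noise_sd * sd(z_g)), where z_g is the gene's log2-CPM profile,
    so the population activity-expression correlation is
    1/sqrt(1 + link_noise_sd^2) for every link.  Decoys get independent
    noise with matched marginal variance.
    """
    cfg.validate()
    rng = cfg.rng("regulome")
    genes = make_genes(cfg)
    zdf = normalize_counts(expression_counts).data
    zdf = zdf.reindex([g.gene_id for g in genes])
    if zdf.isna().any().any():
        raise ValidationError("expression counts do not cover the annotation")
    z = zdf.to_numpy()
    sample_ids = list(expression_counts.columns)
    n_samples = len(sample_ids)

    sd = z.std(axis=1, ddof=1)
    sd_floor = np.median(sd[sd > 0]) if np.any(sd > 0) else 1.0
    sd = np.where(sd > 0, sd, sd_floor)

    prom_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    promoters: list[GenomicInterval] = []
    for chrom in cfg.chroms:
        tss = np.array(sorted(g.tss for g in genes if g.chrom == chrom))
        starts = np.maximum(tss - cfg.promoter_window, 0)
        ends = np.minimum(tss + cfg.promoter_window + 1, cfg.chrom_len)
        # merge overlapping windows so the exclusion test is a simple scan
        keep_s, keep_e = [], []
        for s, e in zip(starts, ends):
            if keep_e and s <= keep_e[-1]:
                keep_e[-1] = max(keep_e[-1], e)
            else:
                keep_s.append(s)
                keep_e.append(e)
        prom_by_chrom[chrom] = (np.array(keep_s), np.array(keep_e))
        promoters.extend(GenomicInterval(chrom, int(s), int(e))
                         for s, e in zip(keep_s, keep_e))

    if cfg.n_true_links > cfg.n_enhancers:
        raise ValidationError("n_true_links exceeds n_enhancers")
    width = cfg.enhancer_width

    # enhancers are kept mutually disjoint, as in a merged peak catalog
    import bisect
    occupied: dict[str, list[int]] = {c: [] for c in cfg.chroms}

    def free(chrom: str, pos: int) -> bool:
        taken = occupied[chrom]
        j = bisect.bisect_left(taken, pos - width)
        return not (j < len(taken) and taken[j] < pos + width)

    def claim(chrom: str, pos: int) -> None:
        bisect.insort(occupied[chrom], pos)

    def place_near(gene: GeneAnnotation) -> int:
        starts, ends = prom_by_chrom[gene.chrom]
        lo = max(gene.tss - cfg.link_window, 0)
        hi = min(gene.tss + cfg.link_window, cfg.chrom_len - width)
        if hi <= lo:
            raise ValidationError(
                f"no room for a linked enhancer near {gene.gene_id}")
        for _ in range(200):
            pos = int(rng.integers(lo, hi))
            if _outside_promoters(np.array([pos]), starts, ends, width)[0] \
                    and free(gene.chrom, pos):
                claim(gene.chrom, pos)
                return pos
        raise ValidationError(
            f"could not place a linked enhancer near {gene.gene_id}: "
            "window saturated by promoter regions")

    linked_gene_idx = rng.integers(0, cfg.n_genes, cfg.n_true_links)
    records = []            # (chrom, start, is_link, gene_idx)
    for gi in linked_gene_idx:
        gene = genes[gi]
        records.append((gene.chrom, place_near(gene), True, int(gi)))
    n_decoys = cfg.n_enhancers - cfg.n_true_links
    placed = 0
    while placed < n_decoys:
        m = 2 * (n_decoys - placed) + 10
        chrom_idx = rng.integers(0, cfg.n_chroms, m)
        pos = rng.integers(0, cfg.chrom_len - width, m)
        for ci, p in zip(chrom_idx, pos):
            chrom = cfg.chroms[ci]
            starts, ends = prom_by_chrom[chrom]
            if _outside_promoters(np.array([p]), starts, ends, width)[0] \
                    and free(chrom, int(p)):
                claim(chrom, int(p))
                records.append((chrom, int(p), False, -1))
                placed += 1
                if placed == n_decoys:
                    break

    records.sort(key=lambda r: (r[0], r[1]))
    enhancers, rows_act, link_rows = [], [], []
    for k, (chrom, start, is_link, gi) in enumerate(records):
        eid = f"enh_{k + 1:05d}"
        enhancers.append(GenomicInterval(chrom, start, start + width, ".", eid))
        if is_link:
            noise = rng.normal(0.0, cfg.link_noise_sd * sd[gi], n_samples)
            rows_act.append(z[gi] + noise)
            link_rows.append((eid, genes[gi].gene_id, 1.0))
        else:
            template = int(rng.integers(0, cfg.n_genes))
            scale = sd[template] * np.sqrt(1.0 + cfg.link_noise_sd ** 2)
            rows_act.append(z[template].mean() + rng.normal(0.0, scale, n_samples))
    activity = ActivityMatrix(pd.DataFrame(
        np.array(rows_act), index=[iv.name for iv in enhancers],
        columns=sample_ids))
    true_links = pd.DataFrame(link_rows,
                              columns=["enhancer_id", "gene_id", "coupling"])
    return RegulomeSim(enhancers, activity, promoters, true_links)


# ---------------------------------------------------------------------------
# loops and contacts
# ---------------------------------------------------------------------------

def simulate_loops(cfg: SimConfig) -> tuple[list[Loop], pd.DataFrame]:
    """Planted loops with per-sample caller probabilities.

    Subtypes cycle shared -> luminal -> basal; present samples score
    U(0.85, 0.95), absent samples U(0.05, 0.15).  Returns the loops and
    the subtype truth table.
    """
    cfg.validate()
    rng = cfg.rng("loops")
    design = make_design(cfg)
    lum = set(samples_of(design, "luminal"))
    n_bins = cfg.n_bins
    w_margin = 12                      # keep APA windows inside the matrix
    if cfg.max_loop_distance_bins + 2 * w_margin >= n_bins:
        raise ValidationError("chromosome too short for the loop distance range")
    per_chrom = [cfg.loop_count // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.loop_count % cfg.n_chroms):
        per_chrom[i] += 1
    loops: list[Loop] = []
    truth_rows = []
    kinds = ("shared", "luminal", "basal")
    k = 0
    for chrom, n_loops in zip(cfg.chroms, per_chrom):
        seen: set[tuple[int, int]] = set()
        made = 0
        while made < n_loops:
            d = int(rng.integers(cfg.min_loop_distance_bins,
                                 cfg.max_loop_distance_bins + 1))
            b1 = int(rng.integers(w_margin, n_bins - d - w_margin))
            if (b1, b1 + d) in seen:
                continue
            seen.add((b1, b1 + d))
            kind = kinds[k % 3]
            k += 1
            probs = {}
            for s in design:
                present = kind == "shared" or (
                    kind == "luminal") == (s.sample_id in lum)
                probs[s.sample_id] = float(rng.uniform(0.85, 0.95) if present
                                           else rng.uniform(0.05, 0.15))
            loops.append(Loop(chrom, b1, chrom, b1 + d, cfg.resolution,
                              probs=probs))
            truth_rows.append((chrom, b1, chrom, b1 + d, kind))
            made += 1
    truth = pd.DataFrame(truth_rows, columns=["chrom_a", "bin_a", "chrom_b",
                                              "bin_b", "subtype"])
    return loops, truth


def _base_expected(cfg: SimConfig) -> np.ndarray:
    d = np.abs(np.subtract.outer(np.arange(cfg.n_bins), np.arange(cfg.n_bins)))
    return cfg.contact_scale * (1.0 + d) ** (-cfg.decay_exponent)


def simulate_contacts(cfg: SimConfig, loops: Sequence[Loop],
                      loop_truth: pd.DataFrame,
                      design: Sequence[SampleDesign] | None = None,
                      samples: Sequence[str] | None = None,
                      ) -> dict[tuple[str, str], ContactMatrix]:
    """Poisson contact matrices with group-specific planted dots.

    Expected background is contact_scale * (1+|i-j|)^-alpha; planted
    loop pixels are multiplied by loop_enrichment in samples of the
    loop's group (shared loops in all samples), with the 3x3
    neighbourhood boosted at half strength.  The upper triangle is
    Poisson-sampled and mirrored, so matrices are exactly symmetric.
    """
    cfg.validate()
    rng = cfg.rng("contacts")
    if design is None:
        design = make_design(cfg)
    wanted = set(samples) if samples is not None else \
        {s.sample_id for s in design}
    subtype_of = {(r.chrom_a, r.bin_a, r.bin_b): r.subtype
                  for r in loop_truth.itertuples()}
    for lp in loops:
        if lp.bin_b - lp.bin_a <= 2:
            raise ValidationError(
                f"loop {lp.key()} within 2 bins of the diagonal; rejected")
    base = _base_expected(cfg)
    half = 1.0 + (cfg.loop_enrichment - 1.0) / 2.0
    out: dict[tuple[str, str], ContactMatrix] = {}
    iu = np.triu_indices(cfg.n_bins)
    for sample in [s for s in design if s.sample_id in wanted]:
        for chrom in cfg.chroms:
            exp = base.copy()
            for lp in loops:
                if lp.chrom_a != chrom:
                    continue
                kind = subtype_of[(lp.chrom_a, lp.bin_a, lp.bin_b)]
                if kind != "shared" and kind != sample.group:
                    continue
                b1, b2 = lp.bin_a, lp.bin_b
                exp[b1 - 1:b1 + 2, b2 - 1:b2 + 2] *= half
                exp[b1, b2] *= cfg.loop_enrichment / half
            upper = rng.poisson(exp[iu])
            values = np.zeros_like(exp)
            values[iu] = upper
            values.T[iu] = upper
            out[(chrom, sample.sample_id)] = ContactMatrix(
                chrom, chrom, cfg.resolution, values)
    return out


# ---------------------------------------------------------------------------
# rearrangement
# ---------------------------------------------------------------------------

@dataclass
class SVSim:
    breakpoint: "object"
    derivative: ContactMatrix          # Poisson-sampled truth map
    derivative_expected: ContactMatrix  # noiseless decay law on der. coords
    intra_a: ContactMatrix
    intra_b: ContactMatrix
    trans_ab: ContactMatrix
    truth_table: pd.DataFrame


def simulate_rearrangement(cfg: SimConfig, intra_a: ContactMatrix,
                           intra_b: ContactMatrix) -> SVSim:
    """Plant a translocation joining chrom A (left of pos_a) to chrom B
    (right of pos_b) and emit what a caller would observe.

    The derivative-locus matrix is sampled directly from the decay law
    on derivative coordinates (that is the ground truth); the observed
    intra/trans matrices have the corresponding blocks overwritten so a
    reconstruction from the separated pieces can be checked bit-exactly.
    """
    from .svmap import Breakpoint
    cfg.validate()
    rng = cfg.rng("sv")
    na, nb = intra_a.n_bins, intra_b.n_bins
    pa, pb = (na * 3) // 5, (nb * 2) // 5
    if not (0 < pa < na and 0 < pb < nb):
        raise ValidationError("breakpoint outside chromosome")
    m = pa + (nb - pb)
    d = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    exp = cfg.contact_scale * (1.0 + d) ** (-cfg.decay_exponent)
    iu = np.triu_indices(m)
    der = np.zeros_like(exp)
    upper = rng.poisson(exp[iu])
    der[iu] = upper
    der.T[iu] = upper

    ia_vals = intra_a.values.copy()
    ib_vals = intra_b.values.copy()
    ia_vals[:pa, :pa] = der[:pa, :pa]
    ib_vals[pb:, pb:] = der[pa:, pa:]
    trans = rng.poisson(cfg.trans_background, size=(na, nb)).astype(float)
    trans[:pa, pb:] = der[:pa, pa:]

    res = cfg.resolution
    bp = Breakpoint(intra_a.chrom_a, pa * res, "left",
                    intra_b.chrom_a, pb * res, "right",
                    flank=min(cfg.sv_flank_bins, pa, nb - pb))
    truth = pd.DataFrame([{
        "chrom_a": bp.chrom_a, "pos_a": bp.pos_a, "side_a": bp.side_a,
        "chrom_b": bp.chrom_b, "pos_b": bp.pos_b, "side_b": bp.side_b,
        "flank": bp.flank}])
    der_name = f"der({intra_a.chrom_a},{intra_b.chrom_a})"
    return SVSim(
        breakpoint=bp,
        derivative=ContactMatrix(der_name, der_name, res, der),
        derivative_expected=ContactMatrix(der_name, der_name, res, exp),
        intra_a=ContactMatrix(intra_a.chrom_a, intra_a.chrom_a, res, ia_vals),
        intra_b=ContactMatrix(intra_b.chrom_a, intra_b.chrom_a, res, ib_vals),
        trans_ab=ContactMatrix(intra_a.chrom_a, intra_b.chrom_a, res, trans),
        truth_table=truth)


# ---------------------------------------------------------------------------
# TF sites, co-binding, sequences and motifs
# ---------------------------------------------------------------------------

PLANTED_CONSENSUS = "ACGGAAGT"


def planted_pwm(name: str = "planted") -> PWM:
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    mat = np.full((4, len(PLANTED_CONSENSUS)), 0.01)
    for j, b in enumerate(PLANTED_CONSENSUS):
        mat[base_idx[b], j] = 0.97
    return PWM(name, mat)


@dataclass
class TFSim:
    anchor_sites: list[GenomicInterval]        # fold-enriched at anchors
    cobind_sites: dict[str, list[GenomicInterval]]   # factors "A" and "B"
    cobinding_truth: pd.DataFrame              # enhancer_id, label
    fg_seqs: dict[str, str]
    bg_seqs: dict[str, str]
    pwms: list[PWM]                            # planted first, then decoys


def simulate_tf_and_motifs(cfg: SimConfig, enhancers: Sequence[GenomicInterval],
                           loops: Sequence[Loop]) -> TFSim:
    cfg.validate()
    rng = cfg.rng("tf")
    n_bins, res = cfg.n_bins, cfg.resolution

    # --- anchor-enriched factor: per-bin mixture weights ------------------
    weights = []
    anchor_bins: dict[str, set[int]] = {c: set() for c in cfg.chroms}
    for lp in loops:
        anchor_bins[lp.chrom_a].add(lp.bin_a)
        anchor_bins[lp.chrom_b].add(lp.bin_b)
    for chrom in cfg.chroms:
        w = np.ones(n_bins)
        if anchor_bins[chrom]:
            w[np.array(sorted(anchor_bins[chrom]))] = cfg.tf_anchor_fold
        weights.append(w)
    flat = np.concatenate(weights)
    flat = flat / flat.sum()
    picks = rng.choice(len(flat), size=cfg.n_tf_sites, p=flat)
    offsets = rng.integers(0, res - cfg.tf_site_width, cfg.n_tf_sites)
    anchor_sites = []
    for pick, off in zip(picks, offsets):
        chrom = cfg.chroms[pick // n_bins]
        start = int((pick % n_bins) * res + off)
        anchor_sites.append(GenomicInterval(chrom, start,
                                            start + cfg.tf_site_width))

    # --- co-binding classes planted on distinct enhancers -----------------
    need = 3 * cfg.n_cobind_each
    if need > len(enhancers):
        raise ValidationError(
            f"need {need} enhancers for co-binding classes, have {len(enhancers)}")
    chosen = rng.choice(len(enhancers), size=need, replace=False)
    groups = {"A_only": chosen[:cfg.n_cobind_each],
              "B_only": chosen[cfg.n_cobind_each:2 * cfg.n_cobind_each],
              "co_bound": chosen[2 * cfg.n_cobind_each:]}

    def site_in(iv: GenomicInterval) -> GenomicInterval:
        start = int(rng.integers(iv.start, max(iv.end - cfg.tf_site_width,
                                               iv.start + 1)))
        return GenomicInterval(iv.chrom, start, start + cfg.tf_site_width)

    cobind_sites: dict[str, list[GenomicInterval]] = {"A": [], "B": []}
    truth_rows = []
    for label, idxs in groups.items():
        for i in idxs:
            iv = enhancers[int(i)]
            if label in ("A_only", "co_bound"):
                cobind_sites["A"].append(site_in(iv))
            if label in ("B_only", "co_bound"):
                cobind_sites["B"].append(site_in(iv))
            truth_rows.append((iv.name, label))
    cobinding_truth = pd.DataFrame(truth_rows, columns=["enhancer_id", "label"])

    # --- peak sequences with the planted motif ----------------------------
    def random_seqs(n: int, rate: float, prefix: str) -> dict[str, str]:
        seqs = {}
        for i in range(n):
            chars = rng.choice(list("ACGT"), size=cfg.peak_seq_len)
            seq = "".join(chars)
            if rng.random() < rate:
                motif = PLANTED_CONSENSUS if rng.random() < 0.5 else \
                    reverse_complement(PLANTED_CONSENSUS)
                pos = int(rng.integers(0, cfg.peak_seq_len - len(motif) + 1))
                seq = seq[:pos] + motif + seq[pos + len(motif):]
            seqs[f"{prefix}_{i + 1:05d}"] = seq
        return seqs

    fg = random_seqs(cfg.n_fg_peaks, cfg.motif_fg_rate, "fg")
    bg = random_seqs(cfg.n_bg_peaks, cfg.motif_bg_rate, "bg")

    pwms = [planted_pwm()]
    planted = pwms[0]
    made = 0
    while made < cfg.n_decoy_pwms:
        perm = rng.permutation(planted.length)
        decoy = PWM(f"decoy_{made + 1:02d}", planted.matrix[:, perm])
        if decoy.consensus != planted.consensus:
            pwms.append(decoy)
            made += 1
    return TFSim(anchor_sites, cobind_sites, cobinding_truth, fg, bg, pwms)


# ---------------------------------------------------------------------------
# full study writer
# ---------------------------------------------------------------------------

def _write_truth(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(TRUTH_HEADER)
        df.to_csv(fh, sep="\t", index=False)


def write_study(cfg: SimConfig, out_dir: str | Path) -> TruthTables:
    """Generate and write the complete synthetic study directory."""
    cfg.validate()
    out = Path(out_dir)
    (out / "contacts").mkdir(parents=True, exist_ok=True)
    (out / "sv").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    design = make_design(cfg)
    genes = make_genes(cfg)
    write_design_tsv(design, out / "design.tsv")
    write_genes_tsv(genes, out / "genes.tsv")

    counts, truth_de = simulate_expression(cfg)
    counts.to_csv(out / "expression_counts.tsv", sep="\t",
                  index_label="gene_id")
    reg = simulate_regulome(cfg, counts)
    write_bed(reg.enhancers, out / "enhancers.bed")
    write_bed(reg.promoters, out / "promoters.bed")
    reg.activity.to_tsv(out / "activity.tsv")

    loops, truth_loops = simulate_loops(cfg)
    sample_ids = [s.sample_id for s in design]
    write_loops_bedpe(loops, sample_ids, out / "loops.bedpe")
    contacts = simulate_contacts(cfg, loops, truth_loops, design)
    for (chrom, sample), cm in contacts.items():
        write_contact_matrix(cm, out / "contacts" / f"{chrom}_{sample}.txt")

    first_sample = sample_ids[0]
    sv = simulate_rearrangement(cfg, contacts[(cfg.chroms[0], first_sample)],
                                contacts[(cfg.chroms[1], first_sample)])
    write_contact_matrix(sv.intra_a, out / "sv" / "intra_a.txt")
    write_contact_matrix(sv.intra_b, out / "sv" / "intra_b.txt")
    write_contact_matrix(sv.trans_ab, out / "sv" / "trans_ab.txt")
    write_contact_matrix(sv.derivative, out / "truth" / "derivative.txt")
    write_contact_matrix(sv.derivative_expected,
                         out / "truth" / "derivative_expected.txt")

    tf = simulate_tf_and_motifs(cfg, reg.enhancers, loops)
    write_bed(tf.anchor_sites, out / "tf_anchor.bed")
    write_bed(tf.cobind_sites["A"], out / "tf_factorA.bed")
    write_bed(tf.cobind_sites["B"], out / "tf_factorB.bed")
    write_fasta({**tf.fg_seqs, **tf.bg_seqs}, out / "peaks.fasta")
    write_jaspar(tf.pwms, out / "pwms.jaspar")

    _write_truth(truth_de, out / "truth" / "de_genes.tsv")
    _write_truth(reg.true_links, out / "truth" / "links.tsv")
    _write_truth(truth_loops, out / "truth" / "loops.tsv")
    _write_truth(sv.truth_table, out / "truth" / "breakpoints.tsv")
    _write_truth(tf.cobinding_truth, out / "truth" / "cobinding.tsv")
    return TruthTables(true_de_genes=truth_de, true_links=reg.true_links,
                       true_subtype_loops=truth_loops,
                       planted_breakpoints=sv.truth_table,
                       cobinding=tf.cobinding_truth)
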