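"""Truth-recovery benchmark experiments on the synthetic study.

Each function regenerates a study under fixed conditions, runs the
relevant pipeline stage, and scores the result against the generator's
truth tables.  These are the package's standing calibration and power
experiments; ``scripts/acceptance.py`` and the acceptance test suite
both call them.  Problem sizes are chosen so every experiment runs in
seconds on one CPU (see docs/methods.md for the design reasoning).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .core_io import samples_of
from .diffexp import call_subtype_features, differential_test, normalize_counts
from .linking import correlate_links, empirical_null, score_links
from .loops import anchor_enrichment, apa_pooled, assign_subtype_loops
from .motifs import motif_enrichment
from .synthetic import (SimConfig, make_design, make_genes,
                        simulate_contacts, simulate_expression, simulate_loops,
                        simulate_regulome, simulate_tf_and_motifs)

DEFAULT_SEEDS = (1, 2, 3, 4, 5)


def _sub_seed(seed: int, label: str) -> int:
    ss = np.random.SeedSequence(entropy=seed,
                                spawn_key=(sum(ord(c) for c in label),))
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def de_config(seed: int, **overrides) -> SimConfig:
    """2000 genes, 4 vs 4, 10% planted at |log2FC| = 2."""
    return SimConfig(seed=seed, n_samples_per_group=4, **overrides)


def de_recovery(seeds: Iterable[int] = DEFAULT_SEEDS) -> dict:
    """Recall / empirical FDR of planted DE genes at default thresholds,
    pooled over seeds."""
    tp = n_truth = n_called = 0
    for seed in seeds:
        cfg = de_config(seed)
        counts, truth = simulate_expression(cfg)
        res = differential_test(normalize_counts(counts), make_design(cfg),
                                "luminal", "basal")
        a_up, b_up = call_subtype_features(res)
        truth_a = set(truth.loc[truth.up_group == "luminal", "gene_id"])
        truth_b = set(truth.loc[truth.up_group == "basal", "gene_id"])
        tp += len(a_up & truth_a) + len(b_up & truth_b)
        n_truth += len(truth)
        n_called += len(a_up) + len(b_up)
    return {"recall": tp / n_truth,
            "fdr": (n_called - tp) / max(n_called, 1),
            "n_truth": n_truth, "n_called": n_called}


def de_null_calibration(seed: int = 7) -> dict:
    """Fraction of null genes with p below nominal alpha levels."""
    cfg = de_config(seed, de_log2fc=0.0)
    counts, _ = simulate_expression(cfg)
    res = differential_test(normalize_counts(counts), make_design(cfg),
                            "luminal", "basal")
    return {"frac_p_below_05": float((res["p"] < 0.05).mean()),
            "frac_p_below_01": float((res["p"] < 0.01).mean()),
            "n_genes": len(res)}


# ---------------------------------------------------------------------------
# enhancer-gene linking
# ---------------------------------------------------------------------------

def link_config(seed: int, **overrides) -> SimConfig:
    """200 true links / 2000 decoys, 8 samples, population r ~ 0.9.

    Gene density is 1.5 genes/Mb so that the expected number of false
    passes at p < 0.01 (~1% of tested within-window pairs) stays well
    below the planted-link count.
    """
    base = dict(n_genes=150, chrom_len=50_000_000, n_samples_per_group=4,
                n_enhancers=2200, n_true_links=200)
    base.update(overrides)
    return SimConfig(seed=seed, **base)


def _run_linking(cfg: SimConfig, n_null: int = 100_000):
    counts, _ = simulate_expression(cfg)
    reg = simulate_regulome(cfg, counts)
    genes = make_genes(cfg)
    coords = {iv.name: iv for iv in reg.enhancers}
    expr = normalize_counts(counts)
    links = correlate_links(reg.activity, coords, expr, genes,
                            window=cfg.link_window)
    null = empirical_null(reg.activity, coords, expr, genes, n_null,
                          seed=_sub_seed(cfg.seed, "null"))
    return score_links(links, null), reg.true_links


def link_recovery(seeds: Iterable[int] = DEFAULT_SEEDS) -> dict:
    """Recall / empirical FDR of planted links at r >= 0.5, p < 0.01."""
    tp = n_truth = n_pass = n_tested = 0
    for seed in seeds:
        links, truth = _run_linking(link_config(seed))
        truth_pairs = set(map(tuple, truth[["enhancer_id", "gene_id"]]
                              .itertuples(index=False)))
        passed = set(map(tuple, links.loc[links["passes"],
                         ["enhancer_id", "gene_id"]].itertuples(index=False)))
        tp += len(passed & truth_pairs)
        n_truth += len(truth_pairs)
        n_pass += len(passed)
        n_tested += len(links)
    return {"recall": tp / n_truth, "fdr": (n_pass - tp) / max(n_pass, 1),
            "n_truth": n_truth, "n_pass": n_pass, "n_tested": n_tested}


def link_null_pass_rate(seed: int = 7) -> dict:
    """Pass rate with no planted links and no subtype effect."""
    cfg = link_config(seed, n_true_links=0, de_log2fc=0.0)
    links, _ = _run_linking(cfg)
    return {"pass_rate": float(links["passes"].mean()),
            "n_tested": len(links)}


# ---------------------------------------------------------------------------
# loops
# ---------------------------------------------------------------------------

def loop_config(seed: int, **overrides) -> SimConfig:
    base = dict(loop_count=300)        # 100 shared / 100 luminal / 100 basal
    base.update(overrides)
    return SimConfig(seed=seed, **base)


def loop_subtype_recovery(seed: int = 1) -> dict:
    """Planted luminal-specific loops recovered; false basal calls."""
    cfg = loop_config(seed)
    loops, truth = simulate_loops(cfg)
    assign_subtype_loops(loops, make_design(cfg))
    calls = {(lp.chrom_a, lp.bin_a, lp.bin_b): lp.subtype_call for lp in loops}
    planted = truth.loc[truth.subtype == "luminal"]
    recovered = sum(calls[(r.chrom_a, r.bin_a, r.bin_b)] == "luminal"
                    for r in planted.itertuples())
    false_basal = sum(calls[(r.chrom_a, r.bin_a, r.bin_b)] == "basal"
                      for r in truth.loc[truth.subtype != "basal"].itertuples())
    return {"recovered_fraction": recovered / len(planted),
            "n_planted": len(planted), "false_basal_calls": false_basal}


def apa_recovery(seeds: Iterable[int] = DEFAULT_SEEDS) -> dict:
    """APA score of planted dots (enrichment 3.0) under Poisson noise."""
    scores = []
    for seed in seeds:
        cfg = SimConfig(seed=seed)     # defaults: 120 loops, enrichment 3
        loops, truth = simulate_loops(cfg)
        design = make_design(cfg)
        sample = samples_of(design, "luminal")[0]
        contacts = simulate_contacts(cfg, loops, truth, design,
                                     samples=[sample])
        subtype = {(r.chrom_a, r.bin_a, r.bin_b): r.subtype
                   for r in truth.itertuples()}
        present = [lp for lp in loops
                   if subtype[(lp.chrom_a, lp.bin_a, lp.bin_b)] != "basal"]
        pairs = [(contacts[(chrom, sample)],
                  [lp for lp in present if lp.chrom_a == chrom])
                 for chrom in cfg.chroms]
        res = apa_pooled(pairs, w=10)
        scores.append(res.score)
    return {"mean_score": float(np.mean(scores)),
            "scores": [float(s) for s in scores],
            "n_loops_each": res.n_used}


def anchor_fold_recovery(seed: int = 1, n_shuffles: int = 500) -> dict:
    """Estimate of the planted 5-fold TF-site enrichment at anchors."""
    cfg = SimConfig(seed=seed, n_cobind_each=0, n_fg_peaks=1, n_bg_peaks=1)
    loops, _ = simulate_loops(cfg)
    tf = simulate_tf_and_motifs(cfg, [], loops)
    sizes = {c: cfg.chrom_len for c in cfg.chroms}
    fold, p = anchor_enrichment(loops, tf.anchor_sites, sizes, n_shuffles,
                                seed=_sub_seed(seed, "anchor"))
    return {"fold": fold, "p_emp": p, "n_sites": len(tf.anchor_sites)}


def anchor_null_calibration(seeds: Sequence[int] = tuple(range(1, 21)),
                            n_shuffles: int = 300) -> dict:
    """With fold 1 the anchor test should be null-calibrated."""
    folds, ps = [], []
    for seed in seeds:
        cfg = SimConfig(seed=seed, tf_anchor_fold=1.0, n_fg_peaks=1,
                        n_bg_peaks=1, n_cobind_each=0)
        loops, _ = simulate_loops(cfg)
        tf = simulate_tf_and_motifs(cfg, [], loops)
        sizes = {c: cfg.chrom_len for c in cfg.chroms}
        fold, p = anchor_enrichment(loops, tf.anchor_sites, sizes, n_shuffles,
                                    seed=_sub_seed(seed, "anchor"))
        folds.append(fold)
        ps.append(p)
    return {"mean_fold": float(np.mean(folds)),
            "frac_p_above_05": float(np.mean(np.array(ps) > 0.05)),
            "n_runs": len(seeds)}


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------

def motif_recovery(seeds: Iterable[int] = DEFAULT_SEEDS) -> dict:
    """Rank and p of the planted motif among 11 PWMs, per seed."""
    ranks, ps = [], []
    for seed in seeds:
        cfg = SimConfig(seed=seed, n_cobind_each=0)
        loops, _ = simulate_loops(cfg)
        tf = simulate_tf_and_motifs(cfg, [], loops)
        enr = motif_enrichment(tf.fg_seqs, tf.bg_seqs, tf.pwms)
        row = enr.loc[enr["pwm"] == "planted"].iloc[0]
        ranks.append(int(row["rank"]))
        ps.append(float(row["p"]))
    return {"ranks": ranks, "worst_rank": max(ranks),
            "max_p": max(ps), "n_pwms": len(tf.pwms)}


# ---------------------------------------------------------------------------
# SV reconstruction
# ---------------------------------------------------------------------------

def stitch_exactness(seed: int = 1) -> dict:
    """Max |error| of reassembling the planted derivative map from the
    separated intra/trans blocks (0 when reconstruction is bit-exact)."""
    from .svmap import stitch_map
    from .synthetic import simulate_rearrangement
    cfg = SimConfig(seed=seed, chrom_len=3_000_000, loop_count=12,
                    n_cobind_each=0, max_loop_distance_bins=100,
                    sv_flank_bins=60)
    loops, truth = simulate_loops(cfg)
    contacts = simulate_contacts(cfg, loops, truth, samples=["lum_1"])
    sv = simulate_rearrangement(cfg, contacts[(cfg.chroms[0], "lum_1")],
                                contacts[(cfg.chroms[1], "lum_1")])
    out = stitch_map(sv.intra_a, sv.intra_b, sv.trans_ab, sv.breakpoint)
    f = sv.breakpoint.flank
    pa = sv.breakpoint.pos_a // sv.derivative.resolution
    window = sv.derivative.values[pa - f:pa + f, pa - f:pa + f]
    return {"max_abs_error": float(np.abs(out.values - window).max()),
            "flank_bins": f}
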