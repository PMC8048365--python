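import dataclasses
import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from regulome.core_io import ValidationError, read_bed
from regulome.diffexp import normalize_counts
from regulome.motifs import reverse_complement, scan_pwm
from regulome.synthetic import (PLANTED_CONSENSUS, SimConfig, make_design,
                                make_genes, planted_pwm, simulate_contacts,
                                simulate_expression, simulate_loops,
                                simulate_regulome, simulate_tf_and_motifs,
                                write_study)


def tiny_cfg(**overrides):
    base = dict(seed=1, n_genes=200, n_enhancers=240, n_true_links=30,
                chrom_len=4_000_000, loop_count=24, n_cobind_each=20,
                n_fg_peaks=40, n_bg_peaks=80, n_tf_sites=200,
                max_loop_distance_bins=120)
    base.update(overrides)
    return SimConfig(**base)


class TestExpression:
    def test_fixed_seed_reproduces_counts_exactly(self):
        c1, t1 = simulate_expression(tiny_cfg())
        c2, t2 = simulate_expression(tiny_cfg())
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_null_model_has_no_planted_genes_and_equal_group_means(self):
        cfg = tiny_cfg(de_log2fc=0.0, n_genes=2000, n_samples_per_group=4)
        counts, truth = simulate_expression(cfg)
        assert truth.empty
        z = normalize_counts(counts).data
        lum = z[[c for c in z.columns if c.startswith("lum")]].mean(axis=1)
        bas = z[[c for c in z.columns if c.startswith("bas")]].mean(axis=1)
        # shared library-normalisation noise leaves a small common offset
        assert abs((lum - bas).mean()) < 0.1

    def test_planted_effect_size_recovered_at_4v4(self):
        cfg = tiny_cfg(n_genes=2000, n_samples_per_group=4)
        counts, truth = simulate_expression(cfg)
        assert len(truth) == 200
        z = normalize_counts(counts).data
        lum_cols = [c for c in z.columns if c.startswith("lum")]
        bas_cols = [c for c in z.columns if c.startswith("bas")]
        up_lum = truth.loc[truth.up_group == "luminal", "gene_id"]
        lfc = (z.loc[up_lum, lum_cols].mean(axis=1)
               - z.loc[up_lum, bas_cols].mean(axis=1))
        assert lfc.mean() == pytest.approx(2.0, abs=0.2)


class TestRegulome:
    def test_noiseless_links_correlate_perfectly(self):
        cfg = tiny_cfg(link_noise_sd=0.0, n_samples_per_group=4)
        counts, _ = simulate_expression(cfg)
        reg = simulate_regulome(cfg, counts)
        z = normalize_counts(counts).data
        act = reg.activity.data
        for row in reg.true_links.itertuples():
            r = np.corrcoef(act.loc[row.enhancer_id], z.loc[row.gene_id])[0, 1]
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_decoy_gene_pairs_average_zero_correlation(self):
        cfg = tiny_cfg(n_samples_per_group=4, n_enhancers=1040,
                       n_true_links=40)
        counts, _ = simulate_expression(cfg)
        reg = simulate_regulome(cfg, counts)
        z = normalize_counts(counts).data.to_numpy()
        decoys = reg.activity.data.drop(
            index=reg.true_links["enhancer_id"]).to_numpy()
        rng = np.random.default_rng(0)
        e_idx = rng.integers(0, len(decoys), 10_000)
        g_idx = rng.integers(0, len(z), 10_000)
        a = decoys[e_idx] - decoys[e_idx].mean(1, keepdims=True)
        g = z[g_idx] - z[g_idx].mean(1, keepdims=True)
        denom = np.linalg.norm(a, axis=1) * np.linalg.norm(g, axis=1)
        r = np.einsum("ij,ij->i", a, g) / np.where(denom == 0, 1, denom)
        assert abs(r.mean()) < 0.05

    def test_truth_table_size_and_window_constraint(self):
        cfg = tiny_cfg()
        counts, _ = simulate_expression(cfg)
        reg = simulate_regulome(cfg, counts)
        assert len(reg.true_links) == cfg.n_true_links
        coords = {iv.name: iv for iv in reg.enhancers}
        genes = {g.gene_id: g for g in make_genes(cfg)}
        for row in reg.true_links.itertuples():
            enh = coords[row.enhancer_id]
            gene = genes[row.gene_id]
            assert enh.chrom == gene.chrom
            assert abs(enh.midpoint - gene.tss) <= cfg.link_window + 300

    def test_enhancers_disjoint_and_outside_promoters(self):
        cfg = tiny_cfg()
        counts, _ = simulate_expression(cfg)
        reg = simulate_regulome(cfg, counts)
        by_chrom = {}
        for iv in reg.enhancers:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))
        for prom in reg.promoters:
            for iv in by_chrom.get(prom.chrom, []):
                assert iv.end <= prom.start or prom.end <= iv.start


class TestContacts:
    def test_planted_dot_enrichment_recovered(self):
        cfg = tiny_cfg(loop_count=102, chrom_len=10_000_000,
                       min_loop_distance_bins=40, max_loop_distance_bins=60)
        loops, truth = simulate_loops(cfg)
        contacts = simulate_contacts(cfg, loops, truth, samples=["lum_1"])
        ratios = []
        for r in truth.itertuples():
            if r.subtype == "basal":
                continue               # absent from luminal samples
            cm = contacts[(r.chrom_a, "lum_1")]
            d = r.bin_b - r.bin_a
            expect = cfg.contact_scale * (1.0 + d) ** -cfg.decay_exponent
            ratios.append(cm.values[r.bin_a, r.bin_b] / expect)
        assert len(ratios) >= 60
        assert np.mean(ratios) == pytest.approx(3.0, abs=0.5)

    def test_no_signal_limit_is_pure_decay(self):
        cfg = tiny_cfg(loop_count=100, loop_enrichment=1.0 + 1e-12)
        loops, truth = simulate_loops(cfg)
        contacts = simulate_contacts(cfg, loops, truth, samples=["lum_1"])
        ratios = []
        for r in truth.itertuples():
            cm = contacts[(r.chrom_a, "lum_1")]
            d = r.bin_b - r.bin_a
            expect = cfg.contact_scale * (1.0 + d) ** -cfg.decay_exponent
            ratios.append(cm.values[r.bin_a, r.bin_b] / expect)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)

    def test_matrices_symmetric_and_deterministic(self):
        cfg = tiny_cfg()
        loops, truth = simulate_loops(cfg)
        a = simulate_contacts(cfg, loops, truth, samples=["bas_1"])
        b = simulate_contacts(cfg, loops, truth, samples=["bas_1"])
        for key in a:
            np.testing.assert_array_equal(a[key].values, b[key].values)
            np.testing.assert_array_equal(a[key].values, a[key].values.T)


class TestTFAndMotifs:
    def test_anchor_site_fraction_matches_mixture_closed_form(self):
        # anchors covering ~10% of bins at fold 5 -> P(site in anchor)
        # = 0.1*5 / (0.1*5 + 0.9) ~ 0.357
        cfg = tiny_cfg(chrom_len=5_000_000, loop_count=50, n_tf_sites=4000,
                       n_cobind_each=0, min_loop_distance_bins=30,
                       max_loop_distance_bins=100)
        loops, _ = simulate_loops(cfg)
        tf = simulate_tf_and_motifs(cfg, [], loops)
        anchor_bins = {(lp.chrom_a, lp.bin_a) for lp in loops} | \
            {(lp.chrom_b, lp.bin_b) for lp in loops}
        coverage = len(anchor_bins) / (cfg.n_chroms * cfg.n_bins)
        expect = coverage * 5 / (coverage * 5 + (1 - coverage))
        res = cfg.resolution
        frac = np.mean([
            (s.chrom, s.start // res) in anchor_bins for s in tf.anchor_sites])
        assert frac == pytest.approx(expect, abs=0.03)

    def test_fold_one_means_uniform_density(self):
        cfg = tiny_cfg(tf_anchor_fold=1.0, n_tf_sites=4000, n_cobind_each=0)
        loops, _ = simulate_loops(cfg)
        tf = simulate_tf_and_motifs(cfg, [], loops)
        anchor_bins = {(lp.chrom_a, lp.bin_a) for lp in loops} | \
            {(lp.chrom_b, lp.bin_b) for lp in loops}
        coverage = len(anchor_bins) / (cfg.n_chroms * cfg.n_bins)
        res = cfg.resolution
        frac = np.mean([
            (s.chrom, s.start // res) in anchor_bins for s in tf.anchor_sites])
        assert frac == pytest.approx(coverage, abs=0.02)

    def test_full_foreground_rate_plants_consensus_everywhere(self):
        cfg = tiny_cfg(motif_fg_rate=1.0, motif_bg_rate=0.0, n_fg_peaks=30,
                       n_bg_peaks=10)
        counts, _ = simulate_expression(cfg)
        reg = simulate_regulome(cfg, counts)
        loops, _ = simulate_loops(cfg)
        tf = simulate_tf_and_motifs(cfg, reg.enhancers, loops)
        rc = reverse_complement(PLANTED_CONSENSUS)
        assert all(PLANTED_CONSENSUS in s or rc in s
                   for s in tf.fg_seqs.values())
        pwm = planted_pwm()
        assert all(scan_pwm(s, pwm) for s in tf.fg_seqs.values())

    def test_decoy_pwms_have_distinct_consensus(self):
        cfg = tiny_cfg()
        counts, _ = simulate_expression(cfg)
        reg = simulate_regulome(cfg, counts)
        loops, _ = simulate_loops(cfg)
        tf = simulate_tf_and_motifs(cfg, reg.enhancers, loops)
        assert len(tf.pwms) == cfg.n_decoy_pwms + 1
        assert all(p.consensus != PLANTED_CONSENSUS for p in tf.pwms[1:])


class TestStudyWriter:
    def test_output_directory_byte_identical_across_runs(self, tmp_path):
        cfg = tiny_cfg(loop_count=12, n_tf_sites=50, n_fg_peaks=10,
                       n_bg_peaks=20, n_cobind_each=10)
        a, b = tmp_path / "a", tmp_path / "b"
        write_study(cfg, a)
        write_study(cfg, b)
        files = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
        assert files
        for rel in files:
            assert filecmp.cmp(a / rel, b / rel, shallow=False), rel

    def test_truth_ids_resolve_to_emitted_features(self, small_study):
        study, truth = small_study
        enh_ids = {iv.name for iv in read_bed(study / "enhancers.bed")}
        genes = set(pd.read_csv(study / "genes.tsv", sep="\t")["gene_id"])
        assert set(truth.true_links["enhancer_id"]) <= enh_ids
        assert set(truth.true_links["gene_id"]) <= genes
        assert set(truth.true_de_genes["gene_id"]) <= genes
        assert set(truth.cobinding["enhancer_id"]) <= enh_ids
        counts = pd.read_csv(study / "expression_counts.tsv", sep="\t",
                             index_col=0)
        assert set(counts.index) == genes

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(loop_enrichment=0.5).validate()
        with pytest.raises(ValidationError):
            SimConfig(de_fraction=1.5).validate()
        with pytest.raises(ValidationError):
            SimConfig(n_genes=0).validate()
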