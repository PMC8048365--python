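"""End-to-end orchestration: simulate (or ingest) then run every stage.

Stage order: differential expression -> element classification ->
enhancer-gene linking -> loop subtype assignment and annotation -> APA
-> TF anchor enrichment -> motif enrichment -> SV map reconstruction.
Each stage persists its outputs under the run directory and contributes
to a machine-readable ``summary.json``; a manifest records config,
seed and version.  A fixed labelled sub-seed per stage makes every
stage individually reproducible, and the whole summary is byte
identical under a repeated (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import (ActivityMatrix, ValidationError, read_bed,
                      read_contact_matrix, read_design_tsv, read_fasta,
                      read_genes_tsv, read_loops_bedpe, samples_of,
                      write_contact_matrix, write_loops_bedpe)
from .diffexp import annotate_calls, differential_test, normalize_counts
from .elements import classify_peaks
from .linking import (correlate_links, empirical_null, score_links,
                      select_variable_enhancers)
from .loops import (anchor_enrichment, apa_pooled, assign_subtype_loops,
                    annotate_loops, category_fractions)
from .motifs import motif_enrichment, read_jaspar
from .svmap import read_breakpoints_tsv, stitch_map
from .synthetic import SimConfig, write_study


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """One config, one seed, one report directory."""

    seed: int = 0
    out_dir: str = "regulome_run"
    sim: SimConfig | None = None       # simulate when set ...
    study_dir: str | None = None       # ... else ingest this directory
    group_a: str = "luminal"
    group_b: str = "basal"
    promoter_window: int = 2500
    top_n: int = 10_000
    window: int = 500_000
    r_min: float = 0.5
    p_max: float = 0.01
    n_null: int = 100_000
    lfc_min: float = 1.0
    q_max: float = 0.05
    p_high: float = 0.8
    p_low: float = 0.5
    apa_w: int = 10
    shuffles: int = 1000
    score_frac: float = 0.8

    def validate(self) -> None:
        if self.sim is None and self.study_dir is None:
            raise ValidationError("config needs either sim settings or a "
                                  "study directory")
        if not (0.0 < self.r_min <= 1.0):
            raise ValidationError(f"r_min {self.r_min} outside (0, 1]")
        if not (0.0 < self.p_max < 1.0):
            raise ValidationError(f"p_max {self.p_max} outside (0, 1)")
        if not (0.0 < self.score_frac <= 1.0):
            raise ValidationError(f"score_frac {self.score_frac} outside (0, 1]")
        if self.p_low >= self.p_high:
            raise ValidationError("p_low must be < p_high")
        if self.lfc_min < 0 or self.q_max <= 0 or self.q_max > 1:
            raise ValidationError("bad DE thresholds")
        if min(self.top_n, self.window, self.n_null, self.apa_w,
               self.shuffles, self.promoter_window) <= 0:
            raise ValidationError("all stage sizes must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg


def _stage_seed(seed: int, label: str) -> int:
    ss = np.random.SeedSequence(entropy=seed,
                                spawn_key=(sum(ord(c) for c in label),))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _log(msg: str) -> None:
    print(f"[{time.strftime('%H:%M:%S')}] {msg}", file=sys.stderr)


def _round(obj: Any) -> Any:
    if isinstance(obj, float):
        return round(obj, 10)
    if isinstance(obj, dict):
        return {k: _round(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v) for v in obj]
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns the summary dict (also on disk)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {}
    stage = "setup"
    try:
        if cfg.sim is not None:
            stage = "simulate"
            _log("simulating study")
            sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
            study = out / "study"
            truth = write_study(sim, study)
        else:
            study = Path(cfg.study_dir)
            truth = None

        stage = "load"
        design = read_design_tsv(study / "design.tsv")
        genes = read_genes_tsv(study / "genes.tsv")
        counts = pd.read_csv(study / "expression_counts.tsv", sep="\t",
                             index_col=0)
        enhancers = read_bed(study / "enhancers.bed")
        promoters = read_bed(study / "promoters.bed")
        activity = ActivityMatrix.from_tsv(study / "activity.tsv")
        sample_ids = [s.sample_id for s in design]

        stage = "diffexp"
        _log("differential expression")
        de = annotate_calls(
            differential_test(normalize_counts(counts), design,
                              cfg.group_a, cfg.group_b),
            cfg.lfc_min, cfg.q_max)
        de_dir = out / "de"
        de_dir.mkdir(exist_ok=True)
        with open(de_dir / "de_results.tsv", "w") as fh:
            fh.write("# two-group test on log2-CPM (Welch statistic, exact "
                     "balanced-df reference or exhaustive label permutations); "
                     "BH FDR\n")
            de.to_csv(fh, sep="\t", index=False)
        summary["de"] = {
            "n_features": int(len(de)),
            f"{cfg.group_a}_up": int((de["call"] == "A_up").sum()),
            f"{cfg.group_b}_up": int((de["call"] == "B_up").sum()),
        }
        if truth is not None and truth.true_de_genes is not None:
            t = truth.true_de_genes
            truth_a = set(t.loc[t.up_group == cfg.group_a, "gene_id"])
            truth_b = set(t.loc[t.up_group == cfg.group_b, "gene_id"])
            called_a = set(de.loc[de["call"] == "A_up", "feature_id"])
            called_b = set(de.loc[de["call"] == "B_up", "feature_id"])
            tp = len(called_a & truth_a) + len(called_b & truth_b)
            n_called = len(called_a) + len(called_b)
            summary["de"]["recall"] = tp / max(len(truth_a) + len(truth_b), 1)
            summary["de"]["fdr"] = (n_called - tp) / max(n_called, 1)

        stage = "elements"
        _log("classifying peaks")
        union = list(enhancers) + list(promoters)
        elements = classify_peaks(union, genes, cfg.promoter_window)
        el_dir = out / "elements"
        el_dir.mkdir(exist_ok=True)
        pd.DataFrame(
            [(e.interval.chrom, e.interval.start, e.interval.end, e.klass,
              e.nearest_gene, e.tss_distance) for e in elements],
            columns=["chrom", "start", "end", "klass", "nearest_gene",
                     "tss_distance"],
        ).to_csv(el_dir / "elements.tsv", sep="\t", index=False)
        n_prom = sum(e.klass == "promoter" for e in elements)
        summary["elements"] = {
            "n_peaks": len(elements),
            "promoter_fraction": n_prom / len(elements),
            "distal_fraction": (len(elements) - n_prom) / len(elements),
        }

        stage = "linking"
        _log("enhancer-gene linking")
        coords = {iv.name: iv for iv in enhancers}
        expr = normalize_counts(counts)
        top = select_variable_enhancers(activity, coords,
                                        min(cfg.top_n, len(activity.feature_ids)))
        act_top = ActivityMatrix(activity.data.loc[top])
        links = correlate_links(act_top, coords, expr, genes, cfg.window)
        null = empirical_null(act_top, coords, expr, genes, cfg.n_null,
                              _stage_seed(cfg.seed, "link_null"))
        links = score_links(links, null, cfg.r_min, cfg.p_max)
        link_dir = out / "links"
        link_dir.mkdir(exist_ok=True)
        links.to_csv(link_dir / "links.tsv", sep="\t", index=False)
        summary["links"] = {"n_tested": int(len(links)),
                            "n_pass": int(links["passes"].sum())}
        if truth is not None and truth.true_links is not None:
            truth_pairs = set(map(tuple, truth.true_links[
                ["enhancer_id", "gene_id"]].itertuples(index=False)))
            passed = set(map(tuple, links.loc[links["passes"],
                             ["enhancer_id", "gene_id"]].itertuples(index=False)))
            tp = len(passed & truth_pairs)
            summary["links"]["recall"] = tp / max(len(truth_pairs), 1)
            summary["links"]["fdr"] = (len(passed) - tp) / max(len(passed), 1)

        stage = "loops"
        _log("loop subtype assignment and annotation")
        loops = read_loops_bedpe(study / "loops.bedpe", sample_ids,
                                 resolution=_study_resolution(study))
        assign_subtype_loops(loops, design, cfg.p_high, cfg.p_low,
                             cfg.group_a, cfg.group_b)
        annotate_loops(loops, promoters, enhancers)
        loop_dir = out / "loops"
        loop_dir.mkdir(exist_ok=True)
        write_loops_bedpe(loops, sample_ids, loop_dir / "loops_annotated.bedpe",
                          with_annotation=True)
        calls = pd.Series([lp.subtype_call for lp in loops]).value_counts()
        summary["loops"] = {
            "n_loops": len(loops),
            "subtype_counts": {k: int(v) for k, v in sorted(calls.items())},
            "category_fractions": category_fractions(loops),
        }

        stage = "apa"
        _log("aggregate peak analysis")
        contacts = {}
        for path in sorted((study / "contacts").glob("*.txt")):
            chrom, sample = path.stem.split("_", 1)
            contacts[(chrom, sample)] = read_contact_matrix(path)
        apa_sample = samples_of(design, cfg.group_a)[0]
        apa_loops = [lp for lp in loops
                     if lp.subtype_call in (cfg.group_a, "shared")]
        pairs = [(contacts[(chrom, apa_sample)],
                  [lp for lp in apa_loops if lp.chrom_a == chrom])
                 for chrom in sorted({lp.chrom_a for lp in apa_loops})]
        apa_res = apa_pooled(pairs, w=cfg.apa_w)
        np.savetxt(loop_dir / "apa_aggregate.tsv", apa_res.aggregate,
                   fmt="%.6g", delimiter="\t")
        summary["apa"] = {"score": apa_res.score, "n_used": apa_res.n_used,
                          "n_skipped": apa_res.n_skipped,
                          "sample": apa_sample}

        stage = "anchor_enrichment"
        _log("TF-site enrichment at loop anchors")
        sites = read_bed(study / "tf_anchor.bed")
        chrom_sizes = {chrom: cm.n_bins * cm.resolution
                       for (chrom, _), cm in contacts.items()}
        fold, p_emp = anchor_enrichment(loops, sites, chrom_sizes,
                                        cfg.shuffles,
                                        _stage_seed(cfg.seed, "anchor"))
        summary["anchor_enrichment"] = {"fold": fold, "p_emp": p_emp}

        stage = "motifs"
        _log("motif enrichment")
        seqs = read_fasta(study / "peaks.fasta")
        fg = {k: v for k, v in seqs.items() if k.startswith("fg_")}
        bg = {k: v for k, v in seqs.items() if k.startswith("bg_")}
        pwms = read_jaspar(study / "pwms.jaspar")
        enr = motif_enrichment(fg, bg, pwms, cfg.score_frac)
        motif_dir = out / "motifs"
        motif_dir.mkdir(exist_ok=True)
        enr.to_csv(motif_dir / "enrichment.tsv", sep="\t", index=False)
        summary["motifs"] = {
            "top_pwm": str(enr.iloc[0]["pwm"]),
            "top_p": float(enr.iloc[0]["p"]),
        }
        if "planted" in set(enr["pwm"]):
            summary["motifs"]["planted_rank"] = int(
                enr.loc[enr["pwm"] == "planted", "rank"].iloc[0])

        stage = "svmap"
        _log("SV map reconstruction")
        sv_dir = out / "sv"
        sv_dir.mkdir(exist_ok=True)
        bps = read_breakpoints_tsv(study / "truth" / "breakpoints.tsv") \
            if (study / "truth" / "breakpoints.tsv").exists() else []
        if bps:
            bp = bps[0]
            stitched = stitch_map(
                read_contact_matrix(study / "sv" / "intra_a.txt"),
                read_contact_matrix(study / "sv" / "intra_b.txt"),
                read_contact_matrix(study / "sv" / "trans_ab.txt"), bp)
            write_contact_matrix(stitched, sv_dir / "stitched.txt")
            summary["sv"] = {"flank_bins": bp.flank}
            der_path = study / "truth" / "derivative.txt"
            if der_path.exists():
                der = read_contact_matrix(der_path)
                f = bp.flank
                pa = bp.pos_a // der.resolution
                window = der.values[pa - f:pa + f, pa - f:pa + f]
                summary["sv"]["max_abs_error_vs_truth"] = float(
                    np.abs(stitched.values - window).max())

        stage = "report"
        summary = _round(summary)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, sort_keys=True, indent=1)
            fh.write("\n")
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "config": _round(_config_dict(cfg)),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, sort_keys=True, indent=1)
            fh.write("\n")
        _log("done")
        return summary
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc


def _config_dict(cfg: PipelineConfig) -> dict[str, Any]:
    d = dataclasses.asdict(cfg)
    return d


def _study_resolution(study: Path) -> int:
    paths = sorted((study / "contacts").glob("*.txt"))
    if paths:
        return read_contact_matrix(paths[0]).resolution
    return 10_000
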