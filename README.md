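# regulome

A toolkit for dissecting subtype-specific gene regulation from matched
multi-omics data, modelled on the analysis of luminal vs basal
muscle-invasive bladder cancer: two transcriptional subtypes, a handful
of cell lines per subtype, and per-sample expression, enhancer
activity (distal H3K27ac), open-chromatin sequence, chromatin-loop
calls with machine-learning probability scores, and binned Hi-C contact
matrices.

Because the real deep-sequencing inputs are large and access
controlled, the package ships a first-class **synthetic study
generator** with planted, recorded ground truth for every downstream
stage, so the whole pipeline is testable end-to-end by truth recovery.

## What it computes

| Stage | Method |
|---|---|
| Differential expression / activity | log2-CPM, Welch statistic (exact balanced-df t reference, or the exhaustive label-permutation distribution for tiny designs), BH FDR, fold-change + q thresholds |
| Promoter vs distal classification | peak-midpoint distance to nearest TSS within a ±2.5 kb window |
| Enhancer catalog | union-merge of distal peaks, per-sample mean signal, log2(x+1) |
| Enhancer–gene linking | top-N most variable enhancers; Pearson r of activity vs expression for all same-chromosome pairs within ±500 kb; one-sided empirical p from a pooled cross-chromosome null; passes at r ≥ 0.5 and p < 0.01 |
| Loop subtype assignment | probability ≥ p_high in every sample of one group and ≤ p_low in every sample of the other (defaults 0.8 / 0.5); shared when high everywhere |
| Loop annotation | anchors labelled P/E/N by element overlap (P beats E), giving E-P, E-E, P-P, E-N, P-N, None |
| Aggregate Peak Analysis | mean distance-normalised observed/expected window over loops; score = centre / lower-left 3×3 corner mean |
| TF-site anchor enrichment | observed anchor-bin overlaps vs uniform per-chromosome shuffles; fold and empirical p |
| Motif enrichment | log2-odds PWM scanning of both strands at a fraction-of-max threshold; one-sided Fisher exact test on peaks-with-hit counts, BH across motifs |
| SV map reconstruction | stitch the local Hi-C map across a known breakpoint from intra- and inter-chromosomal blocks, with a decay-law fill when the trans block is missing |

Formulas, assumptions, defaults and their rationale are in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate a default study (two 10 Mb chromosomes at 10 kb bins, 2000
genes, 2200 enhancers with 200 true links, 120 loops, four samples per
subtype) and run every stage:

```python
from regulome import SimConfig, PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=11, out_dir="run",
                     sim=SimConfig(n_samples_per_group=4))
summary = run_pipeline(cfg)
```

or equivalently `regulome run --seed 11 --out run` from the shell.
The run directory contains per-stage TSV/BED/BEDPE outputs plus
`summary.json`; with seed 11 the summary reads (abridged):

```json
{
 "de":   {"luminal_up": 87, "basal_up": 83, "recall": 0.85, "fdr": 0.0},
 "links": {"n_tested": 212507, "n_pass": 2157, "recall": 0.985, "fdr": 0.909},
 "loops": {"subtype_counts": {"luminal": 40, "basal": 40, "shared": 40}},
 "apa":  {"score": 3.32, "n_used": 80},
 "anchor_enrichment": {"fold": 3.33, "p_emp": 0.000999},
 "motifs": {"top_pwm": "planted", "planted_rank": 1},
 "sv":   {"max_abs_error_vs_truth": 0.0}
}
```

Reading the numbers: the 170 subtype-specific genes called at
|log2FC| ≥ 1, q ≤ 0.05 are all planted ones (FDR 0.0) and recover 85%
of the 200 planted effects; all 40 planted luminal-specific and 40
basal-specific loops are recovered from their probability scores; the
APA score ≈ 3.3 matches the planted 3-fold dot enrichment; the planted
TF shows a ~3.3-fold anchor enrichment (the planted 5-fold density
compressed by anchors covering ~12% of the genome); the planted motif
ranks first of 11; and the derivative Hi-C map reassembled across the
planted translocation equals the generator's truth matrix exactly.
The raw link pass list at this gene density is dominated by correlated
bystander genes (`fdr` 0.909) — exactly how a raw p < 0.01 cut behaves
genome-wide; the `q` column in `links.tsv` is provided for
FDR-controlled use, and the calibration experiment below uses a
sparser design where the pass list is mostly true links.

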