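# sortscreen

Analysis and simulation of **FACS-sorted pooled CRISPRi reporter screens**.

In this screen design, a cell population carrying a fluorescent
transcriptional reporter (e.g. a CRE-driven GFP reading out GPCR/cAMP
signaling) is transduced with a CRISPRi sgRNA library at MOI < 1, stimulated,
and sorted into three fractions on reporter fluorescence: the small
left-shifted non-responding peak becomes the **low** gate, and the large
right-shifted responding peak is split into two equal halves, **medium** and
**high**. Genes whose silencing shifts reporter output change their guides'
relative abundance across the gates, and sequencing the sorted fractions
turns that into a statistical readout. `sortscreen` is for functional
genomicists who need a tested, reusable implementation of this analysis — and
a matching screen simulator with known ground truth for validating it.

## The statistics

For one pairwise comparison of sorted fractions (numerator *s₁* over
denominator *s₂*), per library:

- **Frequencies.** `f(i, s) = (c(i, s) + ψ) / Σⱼ (c(j, s) + ψ)` with
  pseudocount ψ (default 1 read).
- **Guide L2FC.** `L2FC(i) = log₂ f(i, s₁) / f(i, s₂)`, then centered by
  subtracting the median L2FC of the library's non-targeting controls (NTCs).
- **Gene phenotype score.** `ε(g) = mean of the 3 most extreme` (largest
  absolute centered) `L2FCs of g's 5 guides`, with sign retained.
- **Significance.** Two-sided Mann–Whitney U of the gene's guide L2FCs
  against all NTC L2FCs (exact null when min(n, m) ≤ 8 without ties,
  tie-corrected normal approximation otherwise).
- **Hit strength.** `HS(g) = ε(g) × (−log₁₀ p)`.
- **Empirical FDR.** "Quasi-genes" — groups of 5 NTC guides drawn with
  replacement — are scored identically; at a cutoff *t*,
  `FDR(t) = [Q(t)/N_Q] / [R(t)/N_R]` where Q and R count quasi and real
  genes with |HS| ≥ t. The hit threshold is the smallest attained real |HS|
  whose FDR (and that of every attained value above it) stays < 0.10.
- **Classification.** With the numerator being the lower-fluorescence
  fraction, ε > 0 marks a **positive regulator** (silencing lowers reporter
  output) and ε < 0 a **negative regulator**. Hits from low-vs-high are
  **high-confidence**; genes hit only in a comparison involving the medium
  fraction are **putative**. Hit-set overlap is tested with the
  hypergeometric (one-sided Fisher's exact) tail, and multi-TSS genes
  collapse to the TSS with the most extreme hit strength.

The simulator (`sortscreen.simulate`) generates the whole chain — library,
ground-truth gene effects with per-guide knockdown activities, single-guide
cells from a two-component lognormal fluorescence mixture, valley-based
gating, and multinomial sequencing — so every stage of the analysis can be
checked against a known truth. See `docs/methods.md` for the model and its
assumptions.

## Worked example

Simulate a 500-gene screen with 10 positive and 10 negative regulators
(|β| = 0.6 log₁₀ units), then run the full three-comparison analysis:

```bash
cat > sim.yaml <<EOF
n_genes: 500
n_ntc: 100
coverage: 100
depth: 500000
seed: 7
effects:
  fraction_positive: 0.02
  fraction_negative: 0.02
  beta_magnitude: 0.6
EOF
sortscreen simulate --config sim.yaml --out-dir screen_demo
sortscreen report --counts screen_demo/counts.tsv \
                  --library screen_demo/library.tsv \
                  --seed 7 --out-dir report_demo
```

This prints (abbreviated):

```json
{
  "comparisons": {
    "low_vs_high":    {"threshold": 1.643, "achieved_fdr": 0.0,   "n_hits": 21},
    "medium_vs_high": {"threshold": 0.849, "achieved_fdr": 0.045, "n_hits": 22},
    "medium_vs_low":  {"threshold": 1.652, "achieved_fdr": 0.077, "n_hits": 13}
  },
  "n_high_confidence": 21,
  "n_putative": 2,
  "n_shared": 20,
  "overlap": {"count": 20, "p_value": 1.81e-32}
}
```

21 genes pass the FDR < 0.10 cutoff in the strong (low-vs-high) comparison
and 2 more appear only in the medium comparisons; all 20 planted regulators
are among the 23 called hits. The top row of `report_demo/hits.tsv` is the
strongest positive regulator (ε = +7.02, p = 2.1×10⁻⁸, hit strength 53.9 —
its guides pile up in the low gate when the gene is silenced):

```
library_id  target    tss_id         epsilon  p_value    hit_strength  n_sgrnas  regulator_sign  comparison   confidence_class
SIM1        GENE0039  GENE0039_TSS1  7.021    2.07e-08   53.94         5         positive        low_vs_high  high_confidence
```

`report_demo/` also contains per-comparison volcano tables
(`volcano_low_vs_high.tsv`, ...) with ε against −log₁₀ p for plotting.

Raw reads are supported too: `sortscreen count --fastq F --library L
--crop-offset N --max-mismatch {0,1} --out counts.tsv` assigns each read to
the unique spacer within the chosen Hamming distance of its cropped window
(ambiguous reads are discarded).

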