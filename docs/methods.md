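# Methods

## Scoring model

The analysis treats a sorted-fraction screen as a competition experiment:
each guide's abundance in a sorted gate, relative to the other gates,
carries the phenotypic signal, and the library's non-targeting controls
(NTCs) define both the zero point and the null distribution.

All scoring is done per library. Libraries carry their own NTC sets, and
batch effects between separately cloned and sequenced sub-libraries make a
shared reference unsafe, so normalization, centering, the Mann–Whitney
reference, and quasi-gene construction all use only the library the gene
belongs to. Score tables from multiple libraries are concatenated before a
single hit threshold per comparison is chosen, since the threshold is a
property of the experiment, not of one sub-library.

Counts are converted to frequencies with a pseudocount, default ψ = 1 read
per guide per sample. This is the minimal-influence convention: it
guarantees finite log fold changes for dropout guides while perturbing a
well-covered guide (hundreds of reads at the recommended coverage and
depth) by well under 1%.

The gene phenotype score ε averages the 3 most extreme of a gene's 5
centered guide L2FCs, selected by absolute value with sign retained. Ties
in absolute value are broken by ascending guide id so results are
deterministic. "Most extreme by absolute value" (rather than most extreme
in a fixed direction) keeps ε sign-interpretable for both regulator classes
with one rule; the directional alternative would need a per-tail pass.
Centering to the NTC median is applied before extreme-guide selection
(configurable via `center=False`), so a global abundance drift in a gate
cannot masquerade as a phenotype.

The Mann–Whitney p-value compares the gene's guide L2FC values against all
NTC L2FC values. The exact null distribution is used when min(n, m) ≤ 8
and the pooled values are tie-free — which covers the standard 5-guide
gene against any NTC set — and the tie-corrected normal approximation
otherwise. p is clamped into (0, 1] so hit strength ε × (−log₁₀ p) is
always finite; p = 1 gives hit strength exactly 0.

## Empirical FDR

Quasi-genes are groups of 5 NTC guide ids drawn uniformly with replacement,
scored exactly like real genes (ε over the member L2FCs, Mann–Whitney
against all NTC L2FCs). The number of quasi-genes defaults to the number of
real targets so the exceedance-fraction ratio

    FDR(t) = [Q(t)/N_Q] / [R(t)/N_R]

is on the unit scale; both counts use |hit strength| ≥ t, and FDR is 0 when
no quasi-gene passes. Candidate thresholds are the attained real |hit
strength| values only, giving a finite exact search. The reported threshold
is the smallest candidate t such that FDR stays strictly below the target
(default 0.10, matching the screen's convention) at t **and at every
attained value above it**; the monotone-acceptance rule prevents an
isolated dip of the empirical FDR curve below the target from dragging the
cutoff down past a region where it is violated. If even the most extreme
real gene fails, the threshold is +∞ and zero hits is the (valid) result.
One threshold serves both tails, with the regulator sign recorded per gene
from the sign of ε and the orientation of the comparison; when the
comparison's numerator is the higher-fluorescence fraction of the pair, the
sign-to-class mapping flips accordingly.

Strict inequality (FDR < target) is used throughout. A consequence worth
noting: with a vacuous target of exactly 1.0 and identical real/quasi
distributions, the minimum attained value itself has FDR = 1 and does not
qualify.

## Counting

Reads are assigned by exact or 1-mismatch Hamming matching of the cropped
read window `[crop_offset, crop_offset + spacer_length)` against the
library's spacers, via an exact-window dictionary plus a
position-wildcarded dictionary for distance-1 lookups (O(L) dictionary
probes per read, any alphabet in the read). This replaces short-read
alignment: for libraries of unique spacers the two are equivalent, and
dictionary matching is deterministic and dependency-free. Reads tied
between multiple spacers at the minimal distance are counted ambiguous and
discarded — fractional assignment would break count integrality for no
practical gain. Reads shorter than the window are unassigned. Quality
strings are ignored. The crop offset depends on the sequencing primer
layout and has no universal default; it is a required configuration value.

## Simulator

The generator emulates the screen's study conditions; its defaults are the
design values where the screen design fixes them (5 guides per gene, 250
NTCs per library, coverage ≥ 100 sorted cells per library element — the
simulator draws 3 × coverage × library-size cells so each of the three
gates can satisfy the coverage floor, sequencing depth 2×10⁶ reads per
fraction) and field-typical choices where it does not:

| parameter | default | meaning |
|---|---|---|
| `mu_induced` | 3.0 | mean log₁₀ fluorescence of responding cells |
| `mu_off` | 1.5 | mean log₁₀ fluorescence of the non-responding peak |
| `sigma` | 0.25 | within-peak log₁₀ SD |
| `pi_off` | 0.10 | baseline non-responder fraction |

The 1.5 log₁₀-unit separation (~30-fold) reflects a high-dynamic-range
reporter; σ = 0.25 gives clearly resolved but overlapping peaks typical of
a clonal line; π_off = 0.10 makes the left-shifted peak "small" as the
design requires. Sorted-fraction proportions are not fixed by the design,
so π_off is a free parameter.

Each cell carries exactly one guide (MOI < 1), drawn uniformly — no
growth-based dropout is modelled, mirroring a screen without bottlenecking;
a non-uniform abundance vector can be emulated by passing a pre-built
library and effects. A cell is a non-responder with probability π_off
(log₁₀ F = μ_off + σz); otherwise log₁₀ F = μ_induced + aᵢ·β_g + σz, where
β_g is the gene's effect in log₁₀ units (negative = positive regulator:
silencing lowers reporter output) and aᵢ ∈ [0, 1] the guide's knockdown
activity, Beta(5, 1) by default (most guides potent, a minority weak). NTC
cells have β = 0.

Gating finds the valley between the two largest modes of a 256-bin
histogram of log₁₀ fluorescence smoothed with a Gaussian kernel (Silverman
bandwidth); the histogram is virtually padded so a mode in the first or
last bin still counts, and a flat valley resolves to its middle bin. Cells
below the valley are "low"; the rest are split at their median into equal
"medium" and "high" halves (sizes differing by at most 1, ties broken by
cell index for exactness). If fewer than two modes are found the gate falls
back to a quantile (default 0.15) with a logged warning. Because gating
operates on log fluorescence, a multiplicative rescaling of all intensities
leaves memberships unchanged.

Sequencing is a multinomial draw of `depth` reads per fraction with
probabilities proportional to the fraction's per-guide cell tallies, so
each column sums to the depth exactly; an empty fraction yields a zero
column with a warning. One top-level seed is split per stage
(library, effects, cells, sequencing) via `numpy.random.SeedSequence`.

**What the simulator does not model:** PCR amplification bias and
sequencing error, guide off-targets, selection dynamics (puromycin,
cell-cycle or fitness effects), sorter impurity/spillover, and
guide-specific toxicity. Tests passing on simulated screens therefore
validate the statistical machinery under the assumed generative model, not
robustness to these real-data artifacts.

## Test and validation problem sizes

The statistical validation suite simulates screens of 2,000 genes × 5
guides + 250 NTCs at coverage 100 and depth 2×10⁶ (3.075 M cells) for null
calibration and spike-in recovery over 10 fixed seeds, and 1,000-gene
screens for the full-block-gene ranking check; the acceptance script uses
the same per-screen sizes with 5 seeds per quantity. These sizes match a
sub-genome library screen; unit tests use much smaller screens.

## Known limitations

- On an all-null screen the hit count at FDR < 0.10 is typically 0 but
  occasionally 1–few: whenever the most extreme real gene happens to exceed
  the most extreme quasi-gene, the top candidate has empirical FDR 0 and is
  accepted. This is inherent to empirical-null thresholding with
  N_Q = N_R.
- Quasi-gene scores are resamples of one library's NTC guide values (250 by
  default). Their hit-strength distribution therefore carries the sampling
  error of that finite pool: with thousands of real genes, a two-sample KS
  test can distinguish quasi from real null scores even when the screen is
  truly null. The quasi-gene null is a calibration device for tail
  exceedance counts, not an exact replica of the null score distribution.
- The exact Mann–Whitney path assumes tie-free L2FCs; heavily discretized
  counts (very low depth) push all genes onto the tie-corrected
  approximation.
- Multi-TSS collapsing keeps a single most-extreme TSS per gene and
  discards secondary-TSS signal.
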