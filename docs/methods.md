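# Methods

## Statistics implemented

**Per-array Z scores.** Raw hybridization intensities are
log-transformed (base 10 by default) and standardized within each array:
`Z_gj = (log x_gj − mean_g log x_gj) / sd_g log x_gj`. The sample SD
(denominator n−1) is used here and everywhere else in the package; a
single convention beats mixed ones, and the manifest records it. Z
scores are invariant to the log base, so the base option is cosmetic and
kept only for transparency of intermediate files. Nonpositive or missing
intensities are errors, never silently floored or imputed.

**Z ratios.** For a comparison EXP−CTRL, the per-gene difference of
group-mean Z scores is divided by the SD of those differences over the
gene universe. The universe is all genes by default; when the optional
expression filter is enabled (one-way ANOVA of replicate Z scores across
all four groups, p < 0.05, closed-form F), the SD is computed over the
surviving genes, and the manifest records which mode was used. The
original method's descriptions leave the order of filtering and ratio
computation ambiguous; both modes are exposed rather than guessing one.

**Per-gene significance.** The selection rule pairs the |Z ratio| ≥ 1.5
cutoff with a per-gene p < 0.05, but the underlying test is not pinned
down in the sources that describe the rule (a statistics package is
cited, not a formula). We use a Welch two-sample t-test on the replicate
Z scores: it is the smallest-assumption two-group test, and with n = 3
per group its conjunction with the ratio cutoff keeps the null selection
rate well below 0.05 (measured ≈ 0.02 on 20 000-gene null simulations).
Degenerate cases are conventions, not errors: both groups constant with
equal means gives p = 1, with unequal means p = 0. No multiple-testing
correction is applied, matching the raw-p selection rule the method
defines; the acceptance of that choice is exactly what the null
calibration quantifies.

**PAGE.** `Z_S = (Sm − μ)·√m / δ` with μ, δ the mean and sample SD of
the background Z ratios and m the number of set members present in the
background (unmeasured members are dropped; empty intersections are
reported with m = 0 and call `excluded`, as are sets below
`min_set_size` = 5, a configurable default chosen because singleton and
near-singleton "sets" are not meaningful pathway calls). The two-sided
normal p-value makes the joint rule's p-criterion (|Z| > 1.96) binding
over the 1.5 cutoff — worth knowing when comparing printed Z-score
thresholds. The statistic is invariant under affine rescaling of the
ratios and strictly increasing in m for fixed Sm > μ; both are tested.

**Cross-comparison classification.** Items significant only in the
baseline comparison are "normalized", only in the second "new";
coincident items split by sign into concordant and opposite. "Opposite"
therefore requires significance in *both* comparisons — the reading
consistent with Venn legends that count opposed changes separately from
shared up/up and down/down regions. Fractions are always reported with
their denominators.

**Clustering and PCA.** Top-k sets ranked by max |Z| across comparisons
(ties by set id); agglomerative clustering with Euclidean distance and
average linkage (neither is canonical for enrichment heatmaps, these are
the common defaults; both configurable and recorded in the manifest).
Rows are presented to the linkage in lexicographic id order so distance
ties resolve identically across runs. PCA runs on per-group replicate
averages, centered across groups, via SVD; at most (groups − 1)
components exist. Component signs are fixed by making the
largest-magnitude gene loading positive so outputs are reproducible; a
zero-variance configuration (all group means equal) is flagged
degenerate with zero coordinates rather than erroring.

## The synthetic generator

`simdata` emulates the 2×2 strain × treatment design: per-gene log10
baselines ~ N(2.5, 0.5²) (typical chip-scale intensity spread),
factorial effects added to the positionally defined strain/treatment/
interaction groups, and i.i.d. normal replicate noise with per-gene SDs
drawn from a mean-preserving log-normal centred on 0.2 (spread 0.25).
Defaults mirror the study conditions: 24 613 genes, 4 groups × 3
replicates, 1688 gene sets. Effect defaults (5% strain, 5% treatment, 2%
interaction, magnitudes 0.15/0.3 log10 with random sign, 10% coherent
sets shifted by 0.1) are calibration conveniences on the order of the
reported differential-expression yield, not estimates of any real
biology. Coherent sets shift their members through the strain factor,
making them detectable in the strain comparisons; interaction effects
generate strain-discordant treatment responses, the mechanism behind
"opposite direction" pathways.

Randomness derives from one root seed split into four named streams
(gene parameters → factorial effects → set membership → replicate
noise), so changing the set configuration cannot perturb the expression
noise; identical configs are bit-reproducible.

What the generator does **not** model: probe/bead-level chemistry,
background correction, batch or chip effects, intensity-dependent
variance beyond the log-normal SD spread, and correlated noise between
genes. Passing calibration tests therefore demonstrates that the
*selection rules* behave as claimed under clean factorial signal plus
independent noise — not that they are robust to real-chip artifacts.

A note on one generator check: with n = 3 replicates the mean of
per-gene sample SDs is biased (E[s] = c₄(3)·σ ≈ 0.886σ), so the noise
scale is verified as the pooled RMS within-group SD,
`sqrt(mean variance)`, which is unbiased for σ².

## Problem sizes and numerical choices

The test suite runs desk-scale instances: 300-gene experiments for
pipeline round trips, 20 000-gene null simulations for calibration
(seconds), 4000-gene × 40-set batches over effect sizes
{0, 0.25, 0.5, 1.0} (log10 shift) for power, 100 random 50-gene
instances for oracle equivalence at 1e-12, and 5000 random sets for the
uniform-p KS check. These sizes give stable Monte-Carlo estimates while
keeping the suite fast; the statistics themselves are scale-free.

Floats in output TSVs use 6 significant digits, except Z ratios and
gene-set Z scores with 4 decimals (matching the precision such scores
are conventionally printed with); expression matrices are written with
17 significant digits so round trips are bit-exact. NaN is rendered
`NA`. Gene ids match case-sensitively between GMT and expression data.

## Known limitations

- The expression filter implements one defensible reading of an
  under-specified "significant Z score" criterion; it is optional and
  off by default.
- No moderated-variance (empirical-Bayes) testing; with n = 3 a limma
  style test would be more powerful, but would no longer be the method
  being reproduced.
- Venn/heatmap rendering is left to downstream tools; the package emits
  region counts and ordered tables only.
- Only full 2×2 designs are generated; the analysis functions
  themselves accept any ≥ 2-group design.
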