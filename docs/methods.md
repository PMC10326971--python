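# Methods

## The allelic-series model

The core statistic is a per-protein ordinary-least-squares fit of the
cumulative-indicator model over the nested receptor-knockout series

    Y_i = β0 + β1·x_i1 + β2·x_i2 + β3·x_i3 + β4·x_i4 + ε_i,

where Y_i is the WT-centered log₂ protein abundance of sample *i* and
x_ik = 1 iff sample *i* contains the knockouts added at step *k*
(WT→DKO: FAM134A/C; DKO→TKO: FAM134B; TKO→QKO: TEX264; QKO→PKO: CCPG1).
The coding is cumulative — a deeper mutant "contains" every earlier
deletion, so its earlier indicators stay on — which makes the genotype →
indicator map lower triangular. Two consequences the tests rely on:

* in a balanced design, β̂ₖ equals the successive genotype group-mean
  difference (DKO−WT, TKO−DKO, QKO−TKO, PKO−QKO) exactly;
* the fitted means telescope: β0 is the WT fitted mean, β0+Σβₖ the PKO one.

Inference is classical OLS: coefficient standard errors from the residual
variance and diag((XᵀX)⁻¹), two-sided p-values on t with residual_df =
n − 5. With 2 replicates per genotype residual_df = 5; the default
generators use 3–4. Benjamini–Hochberg correction is applied across
proteins **separately for each of the four coefficients** (four families),
matching how individual step coefficients are called significant at
q < 0.05. The family choice is a genuine design decision — correcting
across all 4·P tests jointly would be more conservative; per-coefficient
families keep each step's discovery set interpretable on its own.

The intercept is fitted by default even though WT centering drives it to
≈ 0: centering is a statement about the intercept's *value*, not its
presence, and keeping it makes the fit invariant to the centering constant.
A no-intercept variant is available behind `fit_intercept=False`.
Zero-variance (exact-fit) proteins receive p = 0 for non-zero coefficients
and p = 1 otherwise, by convention.

## PSM processing

* **Filter**: strict inequalities (summed SNR > 200, isolation purity >
  0.5); records exactly at a threshold are removed. Both thresholds are
  parameters.
* **Sum normalization**: factor_c = median_c(total) / total_c computed over
  the PSM table; every channel total afterwards equals the
  pre-normalization median total (relative 1e-9 is asserted in tests; the
  arithmetic is exact up to float rounding). A zero-total channel is an
  error naming the channel. Normalization totals are computed on
  *surviving* PSMs by default (`filter_first=True`); the opposite order is
  supported because the processing description does not pin it down.
* **Roll-up**: plain per-protein, per-channel sum of surviving normalized
  PSM intensities — a signal-weighted average. Proteins with no surviving
  PSMs are absent, not zero-filled; proteins with a non-positive intensity
  in any used channel are dropped (with a report) at the log₂ step rather
  than pseudo-counted, since imputation would invent signal.

Shared-peptide ambiguity is out of scope: input PSMs carry a single
protein assignment from the upstream search.

## Pairwise testing

Pooled-variance (Student's) two-sample t-test on centered log₂ values;
log2fc is the difference of group means. BH family = all proteins of one
contrast. Degenerate zero-variance cases: p = 1 when means are equal,
p = 0 otherwise.

## Keima flux

Flux per sample = mean(acidic-excitation signal) / mean(neutral-excitation
signal) over events passing three rectangular gates (live scatter, singlet
scatter, Keima-positive level), then divided by the matched
Bafilomycin-A1-treated sample's ratio. Division (fold over the
lysosome-inhibited baseline) is the default because the flux readout is a
fold-type quantity; subtraction is available behind `mode="subtract"`.
The Keima-positive gate acts on a dedicated reporter-level covariate in the
synthetic tables; which physical channel carries that gate on a real
instrument is an acquisition detail the event-table schema abstracts away.
Real instrument gating hierarchies (polygon gates, FCS parsing,
compensation) are out of scope; event tables arrive as CSV/TSV.

## Synthetic data: what it emulates, and what it does not

The generator plants a known truth — per-protein baseline log₂ abundance
(Normal(16, 1.5²)), per-step log₂ effects assigned class-wise
(each configured ER subcompartment class gets a Bernoulli(fraction) subset
with Normal(mean, sd) effects), additive Gaussian replicate noise on the
log₂ scale (default sd 0.2, a free parameter: no replicate-variance
estimate was available to match), channel loading imbalance
(log-normal, ≈7% CV) removed later by sum normalization, and a
multiplicative log-normal partition of each protein's intensity across its
PSMs (shares renormalized to sum to 1, so summed roll-up inverts the split
exactly). SNR is proportional to summed PSM intensity with log-normal
noise; purity ~ Beta(8, 2); a planted 5% of PSMs falls below each filter
threshold so filter tests are never vacuous. All generators are
deterministic given their seed, to the byte.

The **paper-like preset** encodes the study conditions: an 18-plex-style
design (five allelic genotypes + ATG12-null control × 3 replicates),
organelle proportions with an ER share of ~30% split into curvature /
associated / membrane / lumen / receptor classes, step-1 accumulation
concentrated in ER-membrane proteins, a lumenal subset that accumulates
only at step 4 (the CCPG1 step), and four fixed sentinels: a FAM134A-like
receptor with step effects (−2.5, 0, 0, 0) and three REEP-like curvature
proteins depleted at step 1 (−1.5/−1.3/−1.2). Flow conditions place the
acidic-population fraction at 0.05/0.179/0.307 for day 0/4/12 of
differentiation over a BafA floor of 0.02, which yields normalized flux
folds of ≈1.3/2.5/4.0.

Not emulated: chromatographic fractionation, co-isolation interference
chemistry, spectral-level data, missing-not-at-random dropout, batch
effects between plexes (fits treat one design table as one batch — batch
correction is the caller's responsibility), and real gating hierarchies.
Passing tests therefore demonstrate the *estimator and pipeline contracts*,
not robustness to every artifact of real acquisitions.

### A note on compositional bias

Sum normalization equalizes channel *totals*. When planted effects are
one-sided (ER proteins accumulate in knockout channels) and the affected
fraction of the simulated proteome is large (~30% ER here, versus a few
percent of a real deep proteome), normalization reabsorbs part of the
planted signal as a small common negative offset on all proteins in the
affected channels (≈0.05–0.1 log₂ units in the default preset). This is a
property of total-intensity normalization itself, visible here because the
synthetic proteome is small. Between-category comparisons are unaffected
(the offset is common), which is why category-level checks are stated as
contrasts; estimator-calibration studies (bias, SE, null FDR) generate the
protein-level response directly so they measure the estimator, not the
normalization.

## Problem sizes and numerical choices

Test and acceptance runs use 600–2,000 proteins, 2–4 PSMs per protein, and
10,000–30,000 flow events per sample — sizes at which every Monte-Carlo
envelope used (3 binomial/MC SDs, 15% SE-ratio band) is comfortably
discriminating while the whole suite runs in seconds. Rounding of category
counts uses largest-remainder allocation with ties broken by category name
(deterministic, seed-free); rankings break ties by protein identifier;
medians over an even number of channels are the mean of the two middle
totals. All randomness flows through `numpy.random.default_rng(seed)`.

## Known limitations

* No moderated-variance (empirical-Bayes) testing and no mixed-effects or
  shrinkage variants of the allelic fit — plain OLS and plain t-tests are
  the contract.
* No GO/KEGG enrichment; annotations are supplied tables (the package
  ships only synthetic ones).
* Flow statistics beyond the flux ratio (e.g. Welch-ANOVA across
  conditions) are delegated to the pairwise-testing machinery.
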