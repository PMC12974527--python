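# Methods

## Decay model and inference

Protein abundance during the chase is modeled as first-order decay,
A(t) = A₀·e^(−kt).  Fitting happens on the log₂ scale, where the model
is the straight line log₂A = β₀ + β₁t; the slope carries the kinetics
(k = −β₁·ln 2 per hour, t½ = 1/(−β₁) hours for β₁ < 0).  We fit by
ordinary least squares rather than nonlinear least squares on the raw
scale: multiplicative (lognormal) measurement error is the dominant
error mode in isobaric-label quantification, so the log-scale residuals
are the ones that are approximately homoscedastic and Gaussian, and the
linear form makes the variance-moderation machinery exact.  Replicate
channels enter as independent observations — averaging before fitting
would discard residual degrees of freedom that the shrinkage estimator
needs.  Proteins with fewer than `min_obs` (default 4) finite
observations, or fewer than two distinct time points, are excluded and
counted, never imputed.

Degenerate traces are handled explicitly: a constant trace has slope 0,
infinite half-life and R² defined as 0 (the total sum of squares is
zero, so the usual ratio is indeterminate); increasing traces get
k = 0 and infinite half-life and can never be called unstable.

### Variance moderation

With five time points and two replicates a fit leaves 8 residual df —
enough to be unstable, not enough to be trusted alone.  Residual
variances are therefore squeezed toward a prior: assuming
s² | σ² ~ σ²·χ²_df/df with σ² drawn from a scaled inverse chi-square
prior (d₀, s₀²), the marginal of s²/s₀² is F(df, d₀).  The prior is
estimated by moment matching on e = log s² − ψ(df/2) + log(df/2): the
excess of Var(e) over the theoretical ψ′(df/2) determines d₀ through
the inverse trigamma (solved by Newton iteration), and s₀² follows from
the mean.  When the observed dispersion does not exceed the theoretical
minimum, the prior is degenerate — d₀ = ∞ and s₀² is the mean sample
variance, so every protein shares one variance.  The estimator is
cross-checked in the test suite against the Bioconductor limma
implementation of the same moment-matching scheme, to 10⁻⁶ relative
agreement on both the prior and the per-protein posterior variances.

The moderated statistic t = β₁/(u·s̃), with u = 1/√Sxx the slope's
unscaled standard-error factor and s̃² = (d₀s₀² + df·s²)/(d₀ + df), is
referred to a t distribution with df + d₀ degrees of freedom (normal in
the d₀ = ∞ limit; the ordinary t statistic in the d₀ → 0 limit).
P values are two-sided; direction is imposed at the calling stage
(β₁ < 0), not in the test.

### Calling thresholds

Defaults: FDR α = 0.05, R² > 0.5 for the high-confidence tier, and a
half-life cutoff equal to the observation window length (4 h or 8 h
designs) — i.e. the rate constant that yields a twofold drop over the
experiment.  Classifier labels use the union rule across screens:
positive iff q < 0.05 **and** window log₂ fold change < −0.5 in at
least one screen.  The window fold change is the fitted slope times the
window length rather than the observed endpoint ratio, which makes it
robust to endpoint noise; this is an interpretive choice and is the one
the label rule uses throughout.

## Normalization

Raw intensities are log₂-transformed (zeros become missing under the
default policy) and normalized by cyclic loess: for every unordered
channel pair, a degree-1 robust loess of M = xᵢ − xⱼ on
A = (xᵢ + xⱼ)/2 is fit over complete cases and half the fitted trend is
subtracted from one channel and added to the other; three full cycles
over all pairs with span 0.7 are the defaults (standard practice for
this normalization; the method itself fixes no parameters).  Cells
missing in either channel of a pair are left untouched by that pair, so
the missingness pattern is invariant.  Each pair must share at least 10
complete proteins.

Per-protein scaling to the mean t = 0 abundance exists for display
(heatmap-style normalization to initial abundance) but is *not* part of
the fitting path: the linear model's free intercept absorbs A₀, so
initial scaling would only propagate t = 0 noise into every residual.

Whether normalization should run within or across multiplexed plexes is
left to the caller; the pipeline normalizes whatever single matrix it
is given, and no between-plex bridging correction is attempted.

## Annotation mining

The miner is deliberately a deterministic rule system.  Sentences are
split on terminal punctuation with an abbreviation exception list
("E. coli", "et al.", …) — no trained tokenizer, no downloads — and a
sentence is a candidate iff it contains (a) a whole-token gene-symbol
match and (b) a degradation-term match.  Gene matching defaults to a
first-letter-insensitive policy (pdeH/PdeH), because short bacterial
symbols embedded in English words are the dominant false-positive mode
for substring matching; term matching defaults to case-insensitive
prefix stemming ("degrad" covers degraded/degradation).  The query-term
list ships as configuration and is a stand-in: any production use
should curate its own term list.  Candidate review happens through a
TSV round trip (export candidates, re-import approve/reject decisions)
rather than a GUI; undecided candidates stay `mined_pending` and do not
count as annotated.  Curated status always wins over mined status for a
shared protein, and the reported expansion fraction is
|approved mined proteins not already curated| / |curated|.

## Enrichment and rank statistics

The 2×2 hit × annotated table is tested with Fisher's exact test
(two-sided by probability-mass ordering of the hypergeometric
outcomes — the convention of the standard R/scipy implementations,
matched in the tests against a from-scratch log-factorial enumeration
to 10⁻¹²).  The odds ratio is the sample cross-product (ad)/(bc) with a
Haldane +0.5 correction applied to all cells only when a cell is zero;
the conditional MLE would be defensible but the cross-product is what
printed hit-count captions are consistent with, and the choice is
recorded in the result object.  Mann–Whitney U uses midranks, exact
enumeration when n₁+n₂ ≤ 12 without ties, and the tie-corrected normal
approximation with continuity correction otherwise; a fully degenerate
comparison (all values identical) returns p = 1 with a warning.
Cross-screen rate agreement is the Pearson correlation of signed
slope-derived rate constants over the shared proteins, optionally
restricted to cataloged substrates.

## Classifier

Four families are compared: L1 logistic regression, random forest, a
single-hidden-layer perceptron (the field gives no architecture, so one
hidden layer with early stopping is the least-assuming choice), and
gradient-boosted trees.  Default grids are compact stand-ins (C ∈
{0.01, 0.1, 1, 10}; forest {200, 500} trees × depth {∞, 8}; hidden
layer {32, 128}; boosted depth {3, 6} × η {0.05, 0.1} × {200, 500}
rounds) — they are configuration, not a claim about the optimal search
space.  Evaluation is repeated nested CV: each round reshuffles a
stratified outer split; inner stratified grid search maximizes mean
inner average precision; the winner is refit on the outer training set
and scored held-out.  Imputation (median) and scaling live inside the
estimator pipeline and are refit per training fold, so no statistic is
ever learned from held-out data; a canary test verifies that a
deliberately leaky protocol inflates null average precision while this
pipeline does not.

Class imbalance is addressed by inverse-class-frequency sample weights
normalized to mean one, passed to every estimator that accepts them;
the scikit-learn perceptron does not support per-sample weights and
trains unweighted (stratification still applies).  MAP is reported as
the grand mean over all round × fold average precisions (primary) and
as the mean of round means (also reported); the baseline is the
positive prevalence.  The final model is selected by MAP, refit on all
labeled data with a full-data grid search reusing the inner-fold
scheme, serialized with a feature manifest and seed, and refuses to
score tables with missing manifest features or any overlap with its
training ids.

Sequence features come from Biopython's ProtParam (length, molecular
weight, isoelectric point, GRAVY, aromaticity, composition) plus
terminal-residue one-hots — the N-terminal residue is taken after the
initiator-Met removal rule by default — and binary degron-motif flags
scanned over the first/last 25 residues with optional `^`/`$` anchors
and `X` wildcards.  External knowledge-base exports join by protein id;
their absences stay missing (never zero) with paired indicator columns,
and a reduced mode drops all external columns so the model can run from
sequence alone.

## Synthetic data: what it emulates and what it does not

The decay generator reproduces the statistical structure the inference
assumes: initial abundances log-uniform over four decades, a stable
majority with an unstable minority whose half-lives are log-uniform
over 0.5–8 h, multiplicative lognormal noise (Gaussian on log₂, default
SD 0.1), a per-channel additive log₂ offset shared by all proteins
(default design: 5 time points × 2 replicates, one channel each — the
plex layout is a stand-in, since real designs vary), and dropout that
preferentially removes the lowest intensities.  Fractional design
counts round half away from zero.  A truth table can be fed back in to
simulate a second growth phase sharing kinetics with the first.

It does **not** emulate peptide-to-protein rollup, isobaric ratio
compression, co-isolation interference, enrichment chemistry, or
correlated (batch) noise; passing tests therefore demonstrate that the
inference is correct under its own assumptions and calibrated under the
null — not that those assumptions hold for any particular instrument.
The corpus generator plants gene+term sentences among distractors that
contain at most one of the two, which makes perfect recall/precision a
construction-level check of the matching rules, not a claim about
free-text literature.  The feature generator plants Gaussian
class-mean shifts; real feature tables are mixed-type, collinear and
block-missing in ways it does not model.

## Problem sizes and numerical choices

Validation runs use 500-protein screens (20 simulation replicates of
300 proteins for null calibration), 60-document corpora, and nested CV
at 3 rounds × 3 outer × 3 inner folds on 2,000-example null and
800-example separable sets — sizes chosen so the full validation
completes in minutes on a single core while leaving every estimator in
its intended regime.  The full 10×10×10 scheme is a constructor
argument away.  Inverse-trigamma Newton iteration converges to 10⁻¹⁰
relative tolerance; zero sample variances are offset to 10⁻⁵ of the
median before the log (an error is raised if more than half are zero);
BH adjustment and Fisher enumeration are exact.  All generators and the
CV machinery are deterministic given their seeds; XGBoost runs
single-threaded with `hist` trees for reproducibility.

## Known limitations

- The moderated test assumes a common variance model across proteins;
  strongly heteroscedastic acquisition (e.g. intensity-dependent
  variance) would call for a trended prior, which is not implemented.
- Cyclic loess adjusts only complete pairs; under extreme missingness
  channels could retain residual bias.
- The mining stage is dictionary-bound: genes absent from the alias map
  and degradation phrasings outside the term list are invisible to it.
- Probabilities from the classifier are uncalibrated scores; the 0.5
  class threshold is a convention, not an optimized operating point.
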