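# protstab

Pulse-chase proteome turnover analysis for bacteria: estimate
per-protein decay rates from multiplexed (TMT) time-series abundances,
call unstable proteins with empirical-Bayes moderated statistics,
validate hit sets against a literature-mined catalog of protease
substrates, and train a classifier that predicts in vivo instability
for proteins the screens never quantified.

The package is aimed at proteomics groups running metabolic-labeling
(e.g. BONCAT) pulse-chase experiments in *E. coli* or similar
organisms, and at anyone who wants a tested, fully synthetic-data-backed
reimplementation of this style of turnover analysis.

## The model

Each protein's chase trace is assumed to follow first-order decay,
A(t) = A₀·e^(−kt).  On the log₂ scale this is linear,

    log₂ A(t) = β₀ + β₁·t,       k = −β₁·ln 2,     t½ = 1/(−β₁)  [h],

so the rate constant comes from ordinary least squares of normalized
log₂ abundance on time.  Raw intensities are log₂-transformed and
normalized by cyclic loess (pairwise MA-trend removal across channels).
Because short traces leave few residual degrees of freedom, the slope
test borrows strength across proteins: residual variances are squeezed
toward an empirical prior (d₀, s₀²) estimated by moment matching of the
log variances against a scaled F distribution, and the moderated
t statistic β₁/(u·s̃) is referred to a t distribution with df + d₀
degrees of freedom, followed by Benjamini–Hochberg FDR adjustment.
A protein is a **screen hit** when t½ is below the observation window
(the rate giving a twofold drop over the experiment), q < 0.05 and
β₁ < 0; **high confidence** additionally requires R² > 0.5.

Hit sets are checked for enrichment of annotated protease substrates
(Fisher's exact test on the 2×2 hit × annotated table), where the
annotation catalog combines a manually curated list with candidates
mined from a document corpus (sentences containing both a gene symbol
and a degradation term).  Finally, hits across screens define binary
labels (q < 0.05 and window log₂ fold change < −0.5 in either screen)
for a classifier — L1 logistic regression, random forest, a
single-hidden-layer perceptron, and gradient-boosted trees — evaluated
by repeated stratified nested cross-validation optimizing average
precision, and used to assign instability probabilities to unseen
proteins.

## Worked example

```python
import protstab as ps

spec = ps.DecaySimSpec(n_proteins=1000, frac_unstable=0.15, noise_sd=0.1,
                       channel_bias_sd=0.3, missing_rate=0.05, seed=42)
matrix, truth = ps.simulate_decay_matrix(spec)
norm = ps.normalize_pipeline(matrix)                  # log2 + cyclic loess
results, summary = ps.analyze_matrix(norm)            # fit, moderate, call
print("tier counts:", summary["tiers"])
print("prior: d0=%.1f  s0^2=%.4f" % (summary["prior_d0"], summary["prior_s0_2"]))

cat = ps.AnnotationCatalog(entries=truth.loc[truth.is_unstable, ["protein_id"]]
                           .assign(gene_name=lambda d: d.protein_id,
                                   status="curated", evidence="truth"))
print(ps.fisher_enrichment(results, cat).caption())
```

prints

```
tier counts: {'stable': 889, 'high_confidence': 107}
prior: d0=86.3  s0^2=0.0114
107 annotated substrates and 0 unannotated substrates exceeding these thresholds (odds ratio = 4509.7, P-value = 1.2e-110)
```

Of the 150 simulated unstable proteins, the 107 with half-lives inside
the 4 h observation window are all recovered at high confidence (the
remainder decay too slowly to yield a twofold drop); the large prior
degrees of freedom d₀ reflect the homogeneous simulated noise, and the
Fisher table confirms hits are drawn almost exclusively from the
planted unstable class.

The same stages are available from the shell:

```sh
protstab simulate decay --spec decay.yaml --seed 1 --out-prefix sim
protstab normalize --in sim_abundance.tsv --design sim_design.tsv --out norm.tsv
protstab fit-decay --in norm.tsv --design sim_design.tsv --out-prefix fit
protstab mine-corpus --corpus corpus.jsonl --genes genes.tsv --terms terms.txt --out cands.tsv
protstab train --features X.tsv --labels y.tsv --out-model model.bin --out-report report.json
```

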