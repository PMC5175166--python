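# Methods

## The enrichment model

The package infers a TF's activity change between two conditions from
the placement of its target genes in a ranked differential-expression
list.  Let the universe be the *N* genes tested, ranked by a per-gene
statistic (descending, condition A minus condition B).  For a target
set *T*, each gene contributes a Bernoulli observation y_g = 1[g ∈ T]
and a predictor x_g = (N − r_g + 1)/N, the normalized reverse rank, so
x is near 1 at the top of the list and near 0 at the bottom.  The model

    logit P(y_g = 1) = β₀ + β₁ x_g

is fit by maximum likelihood (IRLS, log-likelihood tolerance 1e-8, at
most 100 iterations) and the null β₁ = 0 is tested with the Wald
statistic (β̂₁/se)² against χ²₁.  The sign of β̂₁ is the direction of
the activity change.  This is a *competitive* test: it asks whether
targets sit asymmetrically relative to the rest of the universe, not
whether they moved in absolute terms.

**Choice of predictor.** The rank-based coding is scale-free and robust
to heavy-tailed statistics; fitting on the raw statistic instead is
available (`predictor="statistic"`) but shares the statistic's scale
sensitivity.  Ties in the statistic receive midranks, so genes the
statistic cannot distinguish contribute no placement signal; in the
degenerate limit of a fully tied list the slope is pinned at 0 and p at
1, since no asymmetry is observable.  The *order* of the output list
still breaks ties lexicographically by gene id so results are
reproducible byte-for-byte.

**Separation.** When all targets outrank all non-targets (or nearly so)
the ML slope diverges and its Wald statistic collapses towards zero —
the Hauck–Donner effect — which would make exactly the strongest
signals undetectable.  Fits that separate completely, or that saturate
(|β̂₁| · range(x) > 20), are refit with Firth's Jeffreys-prior penalty
and tested with the penalized likelihood ratio (the `logistf`
convention); these results carry `separated=True` and their `wald`
field holds the likelihood-ratio chi-square.  The regular path is
untouched, which the null-calibration and ML-oracle checks confirm.

**Multiplicity.** Benjamini–Hochberg step-up FDR is computed across the
*tested* TFs only; TFs with fewer than `min_targets` (default 10)
members in the universe are reported untested with NA p-values rather
than diluting the adjustment.  The floor exists because the Wald test
is unreliable for very sparse responses.

## Normalization and ranking

Between-sample normalization is the trimmed mean of M-values: against a
reference sample (the one whose upper-quartile count fraction is
closest to the mean upper quartile), log2 expression ratios are trimmed
by 30% on M and 5% on A, averaged with inverse delta-method-variance
weights, exponentiated, and geometric-mean centred so factors multiply
to one.  Expression is then log2-CPM with effective library sizes
(library size × factor) and a prior count of 0.5:
log2((c + 0.5)/(L_eff + 1) · 10⁶).

The default two-group statistic is the Welch t on log2-CPM (≥ 2 samples
per group; a gene constant in both groups scores 0).  The statistic is
deliberately pluggable: any externally computed per-gene statistic —
e.g. a moderated t from an empirical-Bayes pipeline — can be supplied
as a two-column TSV (`tftea enrich --rank-file`), because the
enrichment layer needs only a ranked list.  Variance moderation is
therefore out of scope here, not approximated badly.

## Target-set construction

A gene is a potential target of a TF if a binding-site interval of the
TF overlaps the gene's promoter window by at least 1 bp.  The window
runs from `upstream` bp (default 5000) 5′ of the gene's outermost TSS
through the 3′ end of the first exon, on the transcribed strand, clipped
at position 0.  For multi-transcript genes the outermost TSS is the most
5′ transcript start on the gene's strand and the first exon comes from
that same transcript.  Coordinates are 0-based half-open internally;
GFF3 (1-based closed) is converted on read, BED is used as-is.  TFs that
end with no targets are omitted; sites on chromosomes absent from the
annotation are skipped with a warning.  The ≥1 bp overlap rule is a
deliberate choice where the window definition alone is ambiguous about
edge-straddling sites.

The bundled catalogue lists the 52 Ensembl (GRCh38.p3) TFs of the
original study by name only — real target membership depends on the
annotation + TFBS build above.  A companion toy catalogue with
**synthetic** members exists for demos and tests.

## Per-sample activity

With ≥ 2 normal samples, the reference profile holds each gene's mean
m_g and standard deviation s_g (n−1 denominator) of normalized
expression across normals.  A tumour sample's per-gene score is

    F_cg = (v_cg − m_g) / s_g

i.e. a z-score against normal tissue, interpretable as a standardized
fold change on the log scale.  Genes with s_g = 0 have no defined
standardization; they are dropped from that sample's universe and
recorded in a drop log rather than imputed, so no pseudo-signal enters.
Each sample's genes are ranked by decreasing F_cg and the enrichment
test runs per sample; the reported activity is the signed Wald z,
sign(β̂₁)·√(chi-square).  BH adjustment is per sample across TFs — the
decision unit is one patient's TF profile, not the cohort.  For paired
designs, F_cg is the direct tumour − normal difference on the
normalized log scale.  The subtraction (rather than ratio) reading of
"compared with the reference" is the only one coherent with the
subsequent division by a standard deviation.

## Survival linkage

*Screening.* For each TF, patients split at the median activity (ties
to the low group; any quantile is accepted).  The two-sample log-rank
statistic is the classic Σ(O−E) over distinct event times with the
hypergeometric variance, referred to χ²₁.  TFs with fewer than
`min_events` (default 10) total deaths, or with no possible split, are
flagged untested; BH runs across tested TFs only.  Because the split
depends only on the ordering, the test is invariant under any strictly
monotone transform of activity.

*Joint model.* Candidate covariates are the continuous per-sample
activities (plus `PURITY`, the tumour-purity fraction, when present and
requested).  The Cox partial likelihood uses Breslow tie handling and
is maximized by Newton–Raphson with step halving.  Model search is
bidirectional stepwise on AIC = −2·logPL + 2k starting from the empty
model: at each step the single add or drop that most decreases AIC is
applied, ties between moves broken by variable name, stopping when no
move improves AIC.  The empty start avoids an overfitted
initialization when candidates are many relative to events (a warning
fires when events < 2 × candidates).  Constant candidates and
candidates perfectly collinear with an included variable are dropped
and logged.  The final AIC can never exceed the null model's.

Note AIC-based selection admits a null variable with probability
P(χ²₁ > 2) ≈ 0.157; an empty final model under the null is therefore
*not* the typical outcome once several candidates compete, and the
package reports per-variable and family-wise null selection rates
rather than pretending otherwise.

## The simulator

`simulate_cohort` draws gene baseline means from a log-normal
(default meanlog 5, sdlog 1.5 — median ≈ 150 counts, a realistic bulk
RNA-seq depth profile) and counts from a negative binomial with
Var = μ + φμ² (φ = 0.2, typical biological variability for bulk
tissue).  Default design: 2000 genes, 20 TFs × 50 targets drawn without
replacement (overlaps between TFs allowed), 30 tumour vs 30 normal
samples, one active TF with a +1 log2 fold change on its targets.
Per-sample effect multipliers ~ N(1, 0.3) give tumours heterogeneous
true activity; survival times are exponential with log-hazard equal to
a coefficient (default 1.0) times the standardized per-sample total
activity, plus an optional purity term, under independent exponential
censoring.  Purity is Beta(4.3, 1.41), matching a consensus-purity-like
mean of 0.75 with sd ≈ 0.17.  Purity does not act on counts —
expression deconvolution is out of scope — it exists to exercise the
Cox covariate.  Everything derives from one seed.

Two lighter generators serve specific layers: `simulate_shifted_samples`
plants a +k·s_g target shift directly on the normalized scale (the
natural units of the per-sample layer), and `simulate_survival_data`
draws i.i.d. standard-normal candidate activities with exponential
times for covariate-level Cox experiments.

**What the simulator does not emulate:** gene–gene correlation beyond
shared TF targets, batch effects, isoform structure, purity-driven
expression dilution, and non-proportional hazards.  Passing tests
demonstrate calibration and recovery under the assumed generative
model; on real cohorts, correlated targets and annotation false
positives will reduce power relative to these figures.

## Problem sizes and numerical choices

Validation runs use 2000-gene universes, 50-cohort planted-recovery
sweeps, 100-sample personalized batches and 100-replicate Cox
simulations of n = 200–300 — sizes at which the Monte-Carlo error of
the reported rates is a few percent while the whole suite completes in
a couple of minutes.  IRLS and the Firth fit clip linear predictors
(±30) purely to avoid overflow in the saturation regime; the log-rank
variance term is skipped when a risk set has a single subject; BH is
computed by the step-up min-accumulation and capped at 1; the Cox
Newton step is halved until the partial likelihood does not decrease.

## Known limitations

- The enrichment test treats genes as independent observations;
  correlated expression among targets makes the effective sample size
  smaller than N and p-values somewhat optimistic on real data.
- Activity is identified only up to the quality of the target sets;
  false-positive binding sites dilute signal towards the null.
- The stepwise-AIC search is greedy and inherits AIC's liberal
  inclusion behaviour; selected coefficients carry the usual
  post-selection optimism.
- Proportional-hazards diagnostics are out of scope; the Cox layer
  assumes them.
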