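# Methods

This note documents the models, defaults and numerical choices behind
`btcprof`, what the synthetic generator does and does not emulate, and the
known limitations.

## Data model

A cohort is five TSV tables keyed by `sample_id`: somatic variants (minimal
MAF dialect, 1-based inclusive coordinates, classes
missense/nonsense/frameshift_indel/inframe_indel/splice/synonymous/
TERT_promoter/other_noncoding), gene-level copy-number calls, fusions,
clinical records (subtype ICC/ECC/GBC, stage, hepatitis, platform WES/TPS,
MSI status, EGFR IHC flag, germline pathogenic gene list) and therapy
outcomes (RECIST best response, PFS1/PFS2). TERT promoter mutations are
carried as `variant_class=TERT_promoter` on gene TERT. Missing values are
empty strings; booleans are `true`/`false`. Validation is strict and never
drops rows silently; referential errors name the offending sample ids.
Annotation of raw variants (VCF → gene/class) is assumed upstream.

## Tumor mutation burden

TMB = counted mutations / region size (Mut/Mb). The default counting rule
includes nonsynonymous SNVs and indels and excludes synonymous and
noncoding classes; the rule and an optional VAF floor are configurable
because counting conventions differ between assays. Region sizes are
mandatory inputs (defaults in the pipeline config: WES 38 Mb, panel
1.5 Mb) — there is no universal value, so none is silently assumed.
Hypermutation thresholds are fixed constants per platform (WES ≥ 9.36,
TPS ≥ 16.1 Mut/Mb, boundary inclusive); their derivation is out of scope
and they are not re-estimated. Platform concordance is the squared Pearson
correlation of paired measurements.

## Mutational signatures

**Catalog.** SBS counts on the 96 pyrimidine-centered trinucleotide
channels. Channel order is frozen (substitution classes C>A, C>G, C>T,
T>A, T>C, T>G; flanks alphabetical within each class) and guarded by an
md5 checksum so catalogs, profiles and reference files can never silently
disagree on ordering. Hypermutated samples are excluded from extraction by
default (their substitution spectra differ systematically); a flag
re-includes them.

**Factorization.** `V ≈ WH` is fitted by Lee–Seung multiplicative updates
for the generalized KL divergence. Choices: 50 random uniform
non-negative initializations by default (pipeline uses 20), best final
objective kept; up to 500 iterations per run; convergence when the
relative objective change over 10 iterations falls below 1e-6; the
objective is asserted non-increasing (numerical slack 1e-6 relative) every
10 iterations, so a monotonicity violation fails loudly instead of
degrading the fit. After fitting, profiles are column-normalized and the
scale moved into exposures; signatures are ordered by total exposure.
All randomness flows through `numpy.random.SeedSequence` spawns of the
caller's seed.

**Rank selection.** For each candidate rank k, `n_restarts` fits are run;
fit improvement is the relative decrease in best KL objective as k grows,
and stability is the mean silhouette (cosine metric) of the pooled restart
profiles clustered into k groups by k-means. Ranks are accepted while each
step improves the objective by ≥ 5% (relative); among accepted ranks the
largest with silhouette ≥ 0.9 wins — the usual consensus-clustering
convention: grow the rank while the factorization both fits better and
stays reproducible across restarts. A near-exact fit stops the search, so
an exactly rank-1 catalog selects k = 1. Degenerate (all-zero) catalogs
return the smallest candidate with a warning.

**Reference matching.** Each fitted profile is assigned the
maximum-cosine reference signature. The shipped reference is a toy
5-signature catalog (SBS1-, SBS2-, SBS5-, SBS22- and SBS40-like profiles,
built parametrically — it is synthetic, not COSMIC); real analyses should
point `reference_catalog_path` at a full COSMIC SBS TSV with the same
channel ordering.

**Per-sample attribution.** The observed statistic is the target
signature's exposure fraction from a non-negative KL re-fit of the
sample's counts onto fixed profiles. The null removes the target
component from that fit, renormalizes the remaining mixture into channel
probabilities, draws `n_null` (default 200) multinomial resamples of the
same total count, re-fits each, and takes the add-one-corrected fraction
of null target fractions at or above the observed one as the p-value;
Benjamini–Hochberg across samples, positive iff q < 0.05. Whether the
original FDR construction in the literature was a likelihood ratio or a
resampling scheme is not stated anywhere we could verify; this null
directly operationalizes "having" versus "not having" the signature and
is exactly calibrated when the fixed profiles equal the generating ones.

Because de-novo profiles estimated from ~50-mutation exomes carry enough
noise to inflate the per-sample test (misfit between the true background
and the fitted profiles is absorbed by the target component), the
*pipeline* performs attribution against the reference profiles matched by
the de-novo signatures (the deconstructSigs-style assignment) rather than
the fitted profiles themselves; `attribution_profiles="fitted"` restores
the de-novo route. With matched-reference profiles the null positive rate
on pure-null synthetic cohorts sits at or below the nominal FDR.

## Association statistics

Two-sided Fisher exact p-values follow the "probability mass at or below
the observed table" convention (the common implementation choice;
two-sided conventions differ, so it is pinned and oracle-tested by full
hypergeometric enumeration). Odds ratios are the sample ad/bc with
±infinity on zero cells; a Haldane 0.5 correction is available by flag but
off by default. BH adjustment is order-invariant, monotone and capped at
1. Group TMB comparisons use the Welch (unequal-variance) two-sided
t-test — the robust default where only "unpaired" is specified; at cohort
sample sizes the difference from the pooled test is negligible. Direction
calls: co-occurrent if OR > 1 and q < 0.05, exclusive if OR < 1 and
q < 0.05. Permutation-based exclusivity methods with weighted row nulls
are out of scope.

## DDR classification

A sample is DDR-mutant iff it carries ≥ 1 nonsynonymous variant in a
mapped gene. The shipped map has 47 genes: TP53 in its own category plus
eight functional families. Only the genes named in the primary literature
are fixed; the remaining members are placeholders from standard DDR gene
lists, clearly marked non-canonical in the YAML, and the map is fully
user-overridable (strict loading enforces the 47/8 shape). The four-way
status (wild-type / TP53-only / non-TP53 / both) is kept internally;
cohort summaries pool "both" with non-TP53, so TP53-attributed +
non-TP53 = all DDR mutants — the only accounting under which the
published counts (526 mutants = 284 + 242) are arithmetically consistent
with a TP53 frequency above 35%.

## Actionability

The knowledge base is a YAML of (target, alteration class) entries with an
OncoKB level, an ESCAT tier, an optional genomic locus window and a drug
hint; entries lacking both evidence labels are rejected. The shipped base
names 19 PAT genes plus MSI-H; genes beyond those named in the primary
literature are placeholders to be reconciled with a curated source.
PAT definition: OncoKB ∈ {L1, L2, L3A} or ESCAT ∈ {IA, IB, IC, IIA, IIB}.

The two evidence scales are incommensurate, so prioritization uses a
single merged order, by default
`IA < L1 < IB < IC < L2 < IIA < IIB < L3A < L3B < IIIA < IIIB < L4 < IV < V`
— the minimal interleaving consistent with the MTB convention that ESCAT
I-C (MSI-H, pembrolizumab) outranks OncoKB level-2 (ERBB2 amplification);
the full order is config-overridable. Old-nomenclature labels (e.g.
"level-2B") are stored verbatim alongside the normalized enum.
Variant-class mapping: missense/in-frame → activating, nonsense/
frameshift/splice → truncating; synonymous and noncoding never match.
The EGFR entry carries an exon 18–21 genomic window (GRCh37), with the
alternative exon 17–20 window noted in the file; EGFR calls additionally
require IHC 2+/3+ overexpression at prioritization (rule III). Off-PAT
evidence (OncoKB L3B / ESCAT III) is emitted with `is_pat=false` and
surfaced only on request. Ties break alphabetically by target, making the
ordering total and deterministic.

## Therapy outcomes

Responders are CR or PR; ORR is reported as a half-up one-decimal percent
(matching the printed style of values like 26.1% and 56.8%; 12% renders
from 12.0 in paper-style display). The PFS2/PFS1 ratio is computed on
observed durations, boundary inclusive at 1.3; patients with unmeasurable
PFS1 have an undefined ratio and leave the benefit denominator. Censored
PFS2 values are excluded from the ratio (with a logged count) but retained
in Kaplan–Meier curves; KM uses the product-limit estimator with
events-before-censorings at ties, the median is the first time with
S(t) ≤ 0.5, and the median CI is the Brookmeyer–Crowley-style interval
from the log-log survival band (lifelines). Log-rank is the standard
1-df test; with no events at all the statistic is 0 and p = 1 by
convention. Overall survival and multivariate Cox modeling are out of
scope.

## Synthetic cohort generator

Defaults encode the study-like conditions: 803-cohort subtype proportions
(ICC 475/803, ECC and GBC 164/803 each), platform split (WES 160/803),
log-normal background TMB with median 1.23 Mut/Mb and σ from the printed
IQR 0.7–2.34, hypermutated fraction 33/803 from a separate tail component,
driver frequencies TP53 0.53, KRAS 0.26, ARID1A 0.18, LRP1B/CDKN2A 0.14
(plus DDR and actionable genes at realistic rates), MSI-H 10/803, germline
carrier gene rates summing to a 12% any-carrier probability, AA-positive
fraction 53/148 among non-hypermutated WES ICCs, and outcome parameters
(responder fraction 12/46, PFS1 missing 9/46, median PFS2 5.0 months,
treated fraction 46/204 of PAT carriers).

Specific constructions:

- **Identifiable hypermutation labels.** Background TMB is truncated below
  80% of the platform threshold and the hypermutated component starts at
  1.1× the threshold (times 1 + an exponential factor), so planted labels
  are recoverable rather than ambiguous at the boundary.
- **Mutation counts** are TMB × region size with stochastic rounding;
  driver mutations are added on top (a negligible perturbation on the
  38 Mb exome; panel TMB is not used for distribution recovery).
  85% of counted mutations are SNVs carrying channels drawn from the
  planted signature mixture; 15% are indels; ~30% extra synonymous rows
  exercise the counting filter.
- **Pairwise co-mutation** is planted through the Plackett construction:
  given both marginals and a log-odds, the unique 2×2 joint with that odds
  ratio is solved in closed form and pairs are drawn from it, so marginal
  frequencies are preserved exactly. Pairs must be disjoint.
- **Exposures.** AA-negative samples mix the non-target signatures with
  Dirichlet(2, 2) weights; AA-positive samples draw the target exposure
  uniformly from [0.35, 0.75]. The per-sample exposure law is a modeling
  choice (no empirical distribution is published); the concentration is
  exposed in the config.
- **Outcomes.** PFS2 ~ Exponential(median 5.0), censored by an independent
  exponential with 4× the median. Conditional on being event-observed,
  PFS2 is exponential with rate inflated by (1 + 1/censor_ratio); solving
  P(PFS2/PFS1 ≥ 1.3) = b for independent exponentials gives the default
  PFS1 median `median_pfs2 · (1 − b) / (1.3 · b · (1 + 1/censor_ratio))`
  ≈ 2.34 months at b = 21/37, so the planted benefit probability among
  ratio-evaluable patients equals the published fraction.

What it does **not** emulate: realistic genomic positions (arbitrary
unique integers except the EGFR window), linkage between MSI-H and
hypermutation, subtype-specific TMB or signature differences, subclonal
structure / VAF biology (VAF is an independent Beta draw), indel or
doublet signatures, and fusion partner biology. Passing recovery tests
therefore demonstrates that the estimators invert this generative model
at the stated sample sizes — not that they are robust to every real-data
artifact.

## Problem sizes and tolerances in the test suite

Recovery tests run at n = 500–2000 samples with 3-binomial-SD bands around
planted prevalences; signature recovery uses 150 samples with ≥ 50 SBS
each (cosine ≥ 0.95 after Hungarian matching); attribution calibration
uses 400 pure-null samples with 200 resamples each; the Fisher oracle
enumerates every 2×2 table with total ≤ 30. These sizes keep the whole
suite under a minute of compute beyond the enumeration while leaving the
statistical checks well-powered.

## Known limitations

- The 47-gene DDR map and 19-gene PAT knowledge base ship with
  non-canonical placeholder members and must be reconciled against curated
  sources before use on real cohorts.
- The toy reference catalog is synthetic; cosine matches against it are
  meaningful only for the planted profiles. Published reference cosines
  (signature A↔SBS1 0.871, B↔SBS22 0.945, C↔SBS40 0.875) are reproducible
  only with the full COSMIC catalog and the original cohort, and are
  recorded here as documentation, not asserted by tests.
- Attribution p-values are conditional on the fixed profiles; profile
  estimation uncertainty is handled by the matched-reference default, not
  propagated into the null.
- MAF import covers a minimal dialect; exotic MAF column variants need the
  explicit mapping config.
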