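# Methods

This note records the models, the numerical conventions and the genuinely
open design choices in `mirti`, and what the synthetic study conditions do —
and do not — establish about real data.

## Site calling from PAR-CLIP reads

Reads are analyzed in transcript space, 0-based half-open; genomic input must
be projected through the annotation (and reverse-complemented for minus-strand
transcripts) before ingest, so that T-to-C status is assessed on the
transcribed strand.  Clustering is transitive single-linkage requiring ≥1 bp
overlap among reads longer than 20 nt, with no gap allowance.  Retained
clusters need ≥5 reads and ≥20% crosslinked (≥1 T-to-C) reads.  The crosslink
center is the conversion position with the highest read support; ties go to
the 5′-most position.  CCRs span ±20 nt around the center (41 nt); windows
crossing a transcript edge are clipped, never padded, flagged `truncated`,
and still scanned for sites.

Seed-site definitions for a family with seed s (miRNA positions 2–8, RNA):
8mer = revcomp(s)+A, 7mer-m8 = revcomp(s), 7mer-1A = revcomp(s[2–7])+A, and
the 7-nt perfect match to miRNA positions 1–7 (reported as `6mer-1-7`), which
requires a mature sequence because the family seed does not carry position 1;
families without mature sequences simply yield no such calls.  All four types
contain the hexamer complementary to seed positions 2–7; occurrences are
grouped by that core's target position and reported once with the most
specific type (8mer > 7mer-m8 > 7mer-1A > 6mer-1-7).  This de-duplication
rule is our choice; an independent brute-force substring oracle in the test
suite enforces it symmetrically.

K-mer enrichment compares observed counts of all 4^k k-mers (default k=7)
against complete CCR sets shuffled by the Altschul–Erickson Eulerian-walk
construction, which preserves each sequence's exact dinucleotide multiset and
its terminal residues.  Empirical p-values use the add-one rule
(1 + exceedances)/(B + 1) so p ∈ [1/(B+1), 1]; z-scores are reported alongside
(z = 0 where the shuffle SD is 0) because at desk-scale B the p floor is
coarse and BH-adjusted q-values saturate; ordering by z is then the sharper
readout, and both are exposed.  BH correction runs across all 4^k k-mers.

Region annotation labels a cluster by the transcript region holding the
majority of its span, ties to the 3′-most region.  The expressed-miRNA
selector returns the smallest descending-RRF prefix reaching the coverage
target (default 95%), including ties at the cut.

## Expression preprocessing

Two-color abundance A = log2(sqrt(R·G)).  Probe condensation averages probes
of a gene when **all pairwise** Pearson correlations exceed 0.8 (average
correlation to the gene mean is a configurable alternative; the all-pairwise
reading is stricter); groups failing the rule keep the probe with the highest
mean abundance — a rule we fixed because the source convention is silent.
RRF normalization divides miRNA counts by per-sample totals; the detection
filter keeps entities with strictly more than `min_reads` reads in at least
`ceil(frac · n_samples)` samples.  Zero RPKM values are imputed to the
per-sample minimum non-zero value before log2.

## Correlation shift

Family expression is the **sum** of member RRFs (preserves the RRF scale;
"max member" is available).  The background group is every thresholded
(family, gene) pair not in the target map.  Default abundance thresholds:
mean family RRF > 1e-4, mean mRNA A > 6.5; sequencing mRNA uses the detection
filter only.  The Wilcoxon rank-sum test is two-sided, exact when both groups
have ≤50 tie-free values, otherwise the normal approximation with continuity
correction.  Zero-variance entities are excluded from correlations rather
than assigned r = 0.  Subtype analyses drop samples per-analysis, never
globally.  The intronic-miRNA/host-gene check bins pairs by miRNA mean
abundance (quantile bins) and tests for an increasing trend of per-bin mean
correlation with a one-sided Jonckheere-style permutation test.

## Elastic-net interaction classifier

Candidates are prediction pairs whose family and gene pass the expression
thresholds and whose gene owns ≥1 retained cluster; the label is positive iff
a seed-matched PAR-CLIP site exists for the pair.  The 16 features are the
conservation score, total context score, conserved/non-conserved site totals,
six per-site-type counts, miRNA/mRNA means and variances, and two interaction
terms (miRNA mean × mRNA mean, with and without the sign of the gene's mean
log2 fold-change; the two coincide for cohorts without fold-change data).
Features are standardized; the transform is stored in the model.

The mixing parameter α defaults to 0.5 (the LASSO/ridge midpoint) and is not
cross-validated; λ is selected by 10-fold stratified CV minimizing held-out
binomial deviance over a glmnet-style geometric grid.  λ = ∞ short-circuits
to the analytic null model (zero coefficients, intercept = logit prevalence).
The train/test split is random-stratified at fraction 0.5 with a fixed seed;
gene-grouped splitting is available to avoid gene-level leakage.  Pairs
without crosslink evidence are excluded from training but scored at
prediction time — that is what produces "additional" model-only targets —
and the MP-PCLIP set is the union of PAR-CLIP pairs and pairs with posterior
≥ 0.5, each tagged parclip/model/both.  AUC uses the midrank statistic;
PPV(c) = TP/(TP+FP) among pairs with posterior ≥ c and FDR = 1 − PPV.

## Global Test

The Global Test is implemented as a permutation-calibrated quadratic score
statistic, Q = (1/m) Σ_j (x_jᵀ r)², with x_j the standardized covariates and
r residuals of the intercept-only null model: centered response (linear),
y − mean(y) (logistic), stacked one-vs-rest logistic residuals with Q summed
over classes (multinomial — the reference formulation names multinomial
regression without a formula), and martingale residuals δ_i − H(t_i) from the
Nelson–Aalen cumulative hazard (Cox).  Significance is by permutation of
sample labels with the add-one rule; all n! permutations are enumerated when
requested at n ≤ 8.  B defaults to 9,999 in the API; tests and the acceptance
script use B between 199 and 2,000 — with 1,000-replicate calibration runs
this resolves the 0.05 level exactly while keeping runs at desk scale.
Q is invariant to covariate order and sign flips, which the suite checks.

In adjusted survival mode the null-model residuals come from a lifelines Cox
fit on the clinical covariates, so the test measures association beyond
grade/size/node status.  Permuting residuals in this mode treats the clinical
fit as fixed — a standard approximation whose calibration is verified in the
suite (hazard driven by an observed covariate yields a null adjusted test).

## Rank aggregation

Evidence columns are p-values per family.  Within a column, families are
ranked ascending with average ranks for ties and the worst rank for missing
values; the combined score is the unweighted mean rank (all sources weighted
equally).  Significance shuffles each column independently across families B
times: p = (1 + #{permuted score ≤ observed})/(B + 1).  The referenced rank
test is not specified in the source; this mean-rank scheme is our
reimplementation choice.  Activity evidence: GT of the family vs its
MP-PCLIP targets; the minimum GT p over gene sets containing ≥1 MP-PCLIP
target of the family; GT vs the cancer-gene set.  Phenotype evidence: GT of
each phenotype vs family-plus-target expression (the family's own expression
is included by default, excludable by flag).  BH correction runs within each
family across gene sets, and across families within each evidence column.

## Synthetic study conditions

The generator's defaults are the package's study conditions: 20 families
(one member each), 200 genes (100/300/400 nt UTR5/CDS/UTR3), 8 targets per
family, cohorts of 80 basal-like + 25 HER2 + 25 luminal A samples, repression
β = 1 log2 unit per unit relative family abundance (family RRF divided by its
subtype mean) with mRNA noise σ = 0.25, three active families per subtype,
log-normal library sizes (~5·10⁴ reads, so RRF ≠ counts), 20 reads per
planted cluster at crosslink probability 0.8 (the mRNA conversion-rate regime),
plus crosslinked background clusters without seed sites and sub-threshold
decoy clusters so every filter path is exercised.  An 8mer site is planted in
each target's 3′UTR with a crosslinkable T two bases upstream, exclusion
zones keeping neighbouring clusters separable.  Prediction-table features of
true pairs are shifted by 1 baseline SD; decoy pairs set the class balance
near 11% positives, the regime of the biochemistry-anchored labeling.
Survival uses an exponential hazard h₀·HR^z with h₀ = 0.1, HR = 2 per SD of
the planted signature score and uniform censoring to ~50% events; phenotypes
use logistic/proportional-odds links on the same score.  The cancer-gene set
deliberately samples a couple of targets per family (cancer genes are
enriched among miRNA targets), keeping that evidence source informative.

Two condition choices deserve emphasis.  First, the correlation-shift
*power* condition plants repression on every tested target pair (all
families active in the stratum): it isolates the statistic's sensitivity at
β = 1, σ = 0.25, n = 80, whereas subtype-specific activity — where target
pairs of inactive families dilute the shift — is exercised by the subtype
and ranking analyses.  Second, because RRFs are compositional (they sum to 1
per sample), hazard driven by one abundant family's targets induces genuine
correlated signal in other families' signatures; the survival driver reaches
the permutation floor but may share it, which the analysis driver reports
explicitly.

What passing these tests shows: the statistics are calibrated (type-I error
at nominal level, uniform null p-values), and each stage recovers structure
it was designed to detect at realistic effect sizes.  What they do not show:
robustness to features of real cohorts the generator omits — batch and
platform effects, mRNA measurement saturation, isomiRs and multi-copy
miRNAs, copy-number confounding, non-canonical (seedless) binding sites, and
read-level sequencing error.

## Degenerate inputs and tie-breaks (summary)

Zero-variance covariates/features are dropped with warnings (error if none
remain); empty target or background correlation groups raise; all-zero
samples raise with the sample named; shuffle of a length-<2 or non-ACGT
sequence raises; Cox tests require ≥1 event (≥10 for signatures); empirical
p-values never reach 0 by construction.  Tie rules: 5′-most major conversion,
3′-most region label, average ranks in rank tests, ties included at the
expressed-miRNA coverage cut.
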