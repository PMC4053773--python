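# mirti

Identification of microRNA targets and subtype-specific miRNA regulatory
activity by combining biochemical AGO2 binding-site data (PAR-CLIP) with
patient-paired miRNA/mRNA expression.

## The problem

Individual miRNA-target predictions are noisy, and direct repression in tumor
tissue is subtle: it is detectable only for abundantly expressed miRNAs and
reliably quantified mRNAs, and often only within molecular subtypes where the
regulating miRNA actually varies.  `mirti` implements an analysis chain that
addresses this for breast-cancer-style cohorts:

1. **Biochemical site calling.**  PAR-CLIP reads carry T-to-C conversions at
   crosslink sites.  Overlapping reads (>20 nt) are clustered; clusters with
   <5 reads or <20% crosslinked reads are discarded; a 41-nt crosslink-centered
   region (CCR) is cut ±20 nt around each cluster's major conversion.  All
   4⁷ = 16,384 7-mers inside CCRs are scored against dinucleotide-preserving
   shuffles (Altschul–Erickson), and canonical seed-complementary sites
   (8mer, 7mer-m8, 7mer-1A, and the 7-nt match to positions 1–7) are called
   per miRNA seed family.
2. **Abundance-thresholded correlation shift.**  With miRNA abundance as
   relative read frequency (RRF, threshold 1e-4) and mRNA abundance as the
   two-color A-value `log2(sqrt(R*G))` (threshold 6.5) or log2 RPKM, the
   statistic is the difference of medians between Pearson correlations of
   (family, predicted-target) pairs and all remaining (family, gene) pairs,
   tested two-sided by Wilcoxon rank-sum, overall and per subtype.
3. **"PAR-CLIP-like" classifier (MP-PCLIP).**  Crosslinked candidate pairs are
   labeled by PAR-CLIP seed-match evidence and a binomial elastic net
   (α = 0.5, λ by 10-fold CV) is fit on 16 features (TargetScan-style
   conservation/context scores, per-site-type counts, expression moments,
   interaction terms).  The MP-PCLIP target set is the union of PAR-CLIP pairs
   and pairs with posterior ≥ 0.5.
4. **Association and ranking.**  A permutation-calibrated Global Test
   `Q = (1/m) Σ_j (x_jᵀ r)²` (linear, logistic, multinomial or Cox
   martingale-residual responses) associates family expression with its
   targets, KEGG-style gene sets and a cancer-gene set; per-family evidence
   p-values are combined by equal-weight mean rank with permutation
   significance, for regulatory activity and for phenotype association.
5. **Prognostic signatures.**  Cox-mode Global Tests of family-plus-target
   signatures against survival, optionally adjusted for clinical covariates.

Cohort-scale inputs are not shipped; a first-class synthetic-data generator
(`mirti.simulate`) emulates every input with planted ground truth — seed sites
inside crosslinked clusters, subtype-specific repression proportional to
regulator abundance, feature-label coupling for the classifier, and
signature-driven survival — so the full pipeline is exercisable and testable
end to end.

## Worked example

The numbered drivers under `analysis/` run the pipeline on the default
synthetic study (20 families, 200 genes, 130 samples in three subtypes,
repression β = 1 log2 unit per unit relative abundance) and write their
tables under `results/pipeline/`:

```sh
python analysis/02_parclip_sites.py --seed 1
```

prints (output of the run with seed 1):

```
3751 reads -> 186 retained clusters (80.3% of reads crosslinked)
cluster region fractions: utr3: 93.5%, cds: 4.8%, utr5: 1.6%
seed sites recover 156/156 planted interactions
top enriched 7-mers by z-score (expected: complements of planted seeds):
   kmer  observed_count  shuffle_mean   z_score  p_value
GCACGAA              11          0.44 13.790085 0.009901
...
12/20 of the top-z 7-mers are exact seed complements (the rest overlap ...)
```

i.e. every planted interaction is recovered by the site caller, ~80% of reads
are crosslinked (the generator's crosslink probability), and the 7-mer
enrichment surfaces the planted seed complements.  Continuing,

```sh
python analysis/03_abundance_correlation.py --seed 1
python analysis/04_interaction_model.py --seed 1
python analysis/05_association_ranking.py --seed 1
```

report a negative target-vs-background correlation shift (−0.0067,
Wilcoxon p = 5.2e-3, strongest in the subtypes with planted activity), an
elastic-net test AUC of 0.93 on 953 labeled pairs with conserved site counts
and conservation score as the most label-associated features, and an activity
ranking whose top three families in the basal-like stratum are exactly the
three planted active families (rank-test p ≤ 0.008).  The CLI exposes the
same stages (`mirti run --config cfg.yaml --out DIR --seed 1`).

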