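# Methods

## The TF-occupancy model of allele-specific regulation

A cis-regulatory variant that changes a TF's binding affinity produces an
eQTL whose effect size depends on TF abundance. We model per-allele
transcriptional output with a Michaelis–Menten-style occupancy curve,

    output(T; K) = basal + (max − basal) · T / (T + K),

the simplest monotone saturating form: `T` is TF level (arbitrary units),
`K` the TF level at half-maximal site occupancy, `basal` the TF-independent
output and `max` the saturated output, all in transcripts per allele. Three
allelic mechanisms are implemented (`ModelKind`):

- **affinity_change** — both alleles carry the site with different scales
  `K_ref > K_alt`. The log2 allelic fold change (aFC) is zero at `T = 0`
  (neither allele bound), rises to a unique interior maximum, and returns to
  zero at saturation (both alleles fully occupied) — the non-monotone hill.
- **additive_site / multiplicative_site** — the alternate allele gains a
  second site whose output adds to, or amplifies, the shared site's output;
  the aFC is monotone in `T` and saturates at a nonzero plateau.

A sample with dosage `d` expresses
`(2 − d)·output(T; K_ref) + d·output(T; K_alt)`, times lognormal noise with
log-scale sd `noise_sd` — multiplicative noise is the natural choice given
the downstream rank/log-scale analyses.

## Synthetic cohorts

`generate_study(ScenarioConfig(), seed)` emits a complete multi-tissue
cohort: genotypes, per-tissue expression with covariates, TF expression,
protein medians, a genome with planted motif instances, ChIP-peak BEDs,
credible sets, ASB flags, regulons, GxE genes, colocalization rows,
knockdown allelic counts, and a truth table.

Key default conditions (all configurable):

| parameter | default | why |
|---|---|---|
| individuals / tissues / genes / TFs | 300 / 10 / 100 / 5 | a mid-sized multi-tissue cohort where both discovery modes have realistic but not trivial power |
| samples per tissue | 250 | tissues subsample the genotyped individuals |
| fraction of genes with a true TF-eQTL | 0.2 | leaves a large null set for FDR assessment |
| occupancy parameters | basal 1, max 9, K_ref 10, K_alt ∈ [0.5, 2] | ~3-fold peak allelic fold change, in the range of strong human eQTLs |
| tissue TF medians | log-spaced over 0.02–0.8 | the rising limb of the aFC curve, so effect size increases with tissue TF level |
| within-tissue TF spread | lognormal sd 0.8 | several-fold inter-individual TF variation, as seen in bulk expression |
| expression noise | lognormal sd 0.2 | biological + technical noise after normalization |
| variants per gene (one LD block) | 3, flip prob 0.03 | exercises the effective-test (meff) correction without heavy LD structure |
| null-gene eQTLs | 50% of null genes, log2 aFC ~ N(0, 0.5) | TF-independent eQTLs make the eQTL-significance filter non-trivial |
| composition confound | 10% of null genes + one decoy TF driven by a latent cell-type variable; one tissue with exaggerated spread | produces TF–expression correlations without genotype interactions, and a tissue that the cell-type-variance screen must catch |

Where the underlying study design gives no magnitudes for its implied
generative model, these values were chosen once, during generator design, so
that the default scenario gives the pipeline non-trivial power (dual-evidence
sensitivity ≈ 0.9–1.0 at observed FDR ≈ 0 across seeds), and then frozen.

What the generator deliberately does **not** emulate: realistic human LD and
allele-frequency spectra (LD is blockwise flips, not coalescent), read-level
RNA-seq (expression is lognormal around the model mean), overdispersed
allelic counts (knockdown reads are binomial given true ratios), trans
effects, and shared covariance between tissues of one individual. Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under the stated model, not performance on real cohorts.

## Candidate-variant filtering

Variants enter testing only if: minor allele frequency ≥ 5% (boundary
configurable; computed from dosages with missing genotypes excluded);
membership in a fine-mapping credible set for ≥ 1 gene; overlap with ≥ 1
TF's merged ChIP-peak union (1-based position `p` overlaps 0-based
half-open `[s, e)` iff `s < p ≤ e`); and an IUPAC consensus motif match for
≥ 1 TF. Motif consensi are trimmed iteratively from each end while the
terminal letter is 3- or 4-fold degenerate (B/D/H/V/N) — an interior
degenerate letter shielded by a confident one is kept — and scanned, forward
and reverse-complement, in the ±(L−1) window around the variant with each
allele substituted at the center. Indels are skipped (allele substitution in
a fixed-length window is only well-defined for SNVs). By default the peak
TF and motif TF need not coincide; a strict same-TF mode exists.

## Within-tissue interaction testing

Expression and TF level are rank-based inverse-normal transformed
(`Φ⁻¹((rank − 0.5)/n)`, average ties), the GTEx-style convention; OLS of
expression on `[1, dosage, TF, dosage·TF, covariates]` with a two-sided
t-test on the interaction term. Per gene, the minimum nominal p across its
candidate variants is Bonferroni-multiplied by the gene's effective test
count: the number of leading eigenvalues of the variant dosage correlation
matrix needed to reach 95% of total variance. Constant and exactly
duplicated dosage columns are dropped first (a duplicated variant adds no
test; this also makes meff exactly invariant to duplication). BH adjustment
runs across genes within each (tissue, TF) analysis; a discovery must also
be a significant eQTL (top variant, same tissue — a built-in
dosage-regression + BH caller supplies this for synthetic runs) and the gene
must not be the TF itself.

Tissues whose cell-type composition varies too much are excluded before
analysis: per tissue, the maximum across-sample variance over retained
cell-type scores (unstable estimates such as aDC/iDC dropped) is compared to
0.04 (population variance; scores in [0, 1]). Representative-tissue
selection is available via Ward clustering (scipy's `ward`, i.e. the
minimum-variance update on Euclidean profile distances) of median-TPM
vectors, picking the largest-sample non-excluded tissue per cluster.

## Cross-tissue correlation

Per tissue, aFC is estimated by regressing `log2(TPM + pseudocount)`
(covariate-residualized; pseudocount default 1) on dosage; aFC is twice the
slope, clipped to ±log2(100) with a `capped` flag. Positive aFC means the
alternate allele is more expressed; flipping allele labels flips the sign
exactly. For each (TF, gene), every candidate variant's aFC profile is
Spearman-correlated with the TF's per-tissue level (median TPM, or median
protein with a ≥ 20-unique-values filter per TF), restricted to tissues with
median target-gene TPM > 0 and pairwise-complete values, requiring ≥ 5
points. For n ≤ 10 without ties the p-value is exact (the tie-free
permutation null of Spearman's statistic is tabulated once per n by full
enumeration); with ties, or n > 10, the t approximation is used. Gene-level
correction and BH follow the within-tissue scheme.

## Evidence integration and validation statistics

A (TF, gene) pair is **dual-evidence** iff supported by ≥ 2 tissues, or by
the cross-tissue expression correlation plus ≥ 1 tissue; protein-based
correlations are recorded but never counted. Binding-site and ASB
enrichment use the expectation/observation statistic
`S_fg = o_fg − v_g·p_f` (observed minus expected annotated variants among
the gene's tested variants), averaged per TF and pooled as a
gene-count-weighted mean — algebraically the plain mean over all (TF, gene)
units, so `100·S` is the number of extra annotated variants per 100 TF-eQTL
genes (asserted as an identity in the report). For ASB, the universe is
restricted to assayed variants and genes without assayed variants drop out;
the unmatched mode uses a TF-agnostic ASB probability, the matched mode
per-TF probabilities. Significance comes from shuffling each TF's
annotation flags independently across the tested-variant universe
(consistent with per-TF `p_f`) and recomputing the pooled statistic 10⁴
times; the two-sided p doubles the smaller exceedance tail, counts ties as
exceedances (conservative for discrete statistics), adds one and truncates
at 1, so its floor is 2/n_perm. An alternative `both-sum` tail
(`#{|null| ≥ |obs|}`) is available for sensitivity analysis.

Knockdown validation filters coding sites on condition-pooled counts
(> 60 reads, each allele > 5%, other alleles < 5%, all strict), pools reads
per condition, and applies a two-sided Fisher exact test of condition ×
allele; a gene is *validated* only when nominally significant (α = 0.05, no
multiple-testing correction by default, BH optional) **and** the cell line
is heterozygous for an implicated regulatory variant — significance without
heterozygosity is classed untestable. With several passing coding SNPs the
highest-coverage one is used. Overlap analyses (dataset sharing, regulons,
GxE genes, GWAS colocalization) are two-sided Fisher exact tests against an
explicit background universe — never defaulted silently; the sample odds
ratio is reported, with zero-cell tables flagged as 0/∞ rather than
continuity-corrected. Colocalization rows require regional conditional
probability strictly > 0.5 and the LD filter requires r² strictly > 0.4
between top TF-eQTL and lead colocalization variants (squared Pearson
correlation of dosages, pairwise-complete; monomorphic variants are
undefined and rows with unresolvable lead variants are flagged, not
dropped).

## Numerical and design notes

- OLS uses `lstsq` with an explicit rank check; rank deficiency or n ≤ p
  signals an untestable unit rather than producing garbage coefficients.
- BH is statsmodels' step-up implementation; it reproduces the textbook
  example p = (0.01, 0.02, 0.03, 0.04) → all 0.04.
- The exact Spearman null for n = 10 enumerates 10! permutations once per
  process (a few seconds, ~30 MB transient) and is cached.
- Permutation tests, genotype generation and every generator stage draw from
  a single seeded `numpy` Generator; a fixed (config, seed) pair reproduces
  a study byte for byte.
- Test-suite and acceptance-script problem sizes (e.g. 20 recovery seeds at
  the default scenario; reduced null cohorts for calibration checks) are the
  package's own benchmark choices, balancing Monte-Carlo resolution against
  a desk-scale run.

## Known limitations

- The aFC estimator is a log-linear regression approximation, not a
  haplotype/ASE-based estimator; no confidence intervals are produced.
- The per-gene meff is shared between within- and cross-tissue stages and
  computed on the full genotyped cohort, not per-tissue subsamples.
- Protein-based discovery is implemented but structurally underpowered in
  the default scenario (10 tissues < the 20-unique-values filter), mirroring
  its role as a secondary, weaker line of evidence.
- Enrichment permutations ignore LD between variants of different genes
  (annotations are shuffled marginally), which matches the stated null but
  is anti-conservative if annotations cluster along the genome beyond the
  tested structure.
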