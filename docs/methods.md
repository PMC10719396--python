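# Methods

This note documents the models and procedures implemented in
`syncom-metatx`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-community benchmarks
do and do not demonstrate.

## The synthetic community generator

`simulate.SimConfig` defines the study conditions; `simulate_all` produces
a catalog, counts, reads, a paired DNA profile, and a `TruthSet`.

**Catalog.** `n_strains` strains with `genes_per_strain` coding sequences
each (random ACGT, lengths uniform in `gene_length_range`, default
200–400 bp), plus `n_host_genes` host genes. The first `n_orthogroups`
gene slots of every strain map to the same shared orthogroup, so those
families span all strains; remaining genes sit in private orthogroups.
Duplication is planted verbatim: `frac_interstrain_duplicate` of each
strain's genes (rounded) take an identical sequence across all strains
(at shared-OG slots), and `frac_within_strain_paralog` of genes (rounded
down to an even count) form identical within-strain pairs sharing one
orthogroup. Strains carry a coarse taxon label (`n_taxa` groups,
round-robin) used as the "taxonomy" factor in variance partitioning.

**Expression.** Count for gene g in sample j is drawn from
NB(mean = L_j · RA_{s(g),c(j)} · q_g · 2^{x_j β_g}, dispersion α_g) with
x_j = 1 for root samples. Strain relative abundances RA are independent
log-normals per compartment (`strain_logRA_sd`, default 1.0 — the
within-community abundance spread is a modeling choice, not an empirical
fit; real communities are typically at least this uneven). Within-strain
expression shares q_g are log-normal (`gene_logq_sd`). A fraction
`de_fraction` of genes is truly differentially expressed at
β = ±`de_log2fc` (half up, half down in roots); optionally
`n_conserved_ogs` shared orthogroups get a consistent +`de_log2fc`
response in a `conserved_strain_frac` share of strains (placed only in
duplication-free families, since reads cannot attribute identical
sequences to strains). Dispersion follows the trend α_g = a0 + a1/mean
(defaults 0.05 and 1.0), i.e. Var = μ + αμ². Root samples lose
`host_dilution_root` (default 0.5) of their read budget to host genes,
mirroring the strong host-read dilution of root metatranscriptomes; matrix
samples lose `host_dilution_matrix` (default 0).

**Reads.** Error-free, uniform-position substrings (default 75 bp), one
per simulated count, named after their origin gene so assignment can be
scored exactly. Sequencing error, rRNA carryover, GC bias and ITS
copy-number variation are deliberately out of scope: the assignment
contract is exact k-mer compatibility, and the benchmarks measure the
pipeline's bookkeeping and statistics, not robustness to base errors.

**DNA profile.** Per sample, each strain is dropped with probability
`amplicon_dropout`, then `amplicon_reads` are drawn multinomially around
the true RA of surviving strains — a minimal stand-in for amplicon
profiling's lower sensitivity.

Everything derives from `seed` through per-stage child streams, so outputs
are bit-reproducible and independent of call order.

## Identity classes and read assignment

Genes are partitioned by exact sequence equality into identity classes
(`unique`, `within_strain_paralog`, `interstrain_duplicate`, or `mixed`
when a multi-strain class also has within-strain copies; representative =
smallest gene id). The k-mer index (default k = 31, the standard
pseudo-alignment size, far below simulated gene lengths) maps every k-mer
of every sequence to the set of classes containing it. A read's
compatibility set is the intersection of its k-mers' class sets; the
reverse complement is tried if the forward orientation is incompatible.
No mismatch tolerance or skipping heuristics: reads are simulated
error-free, and the full intersection keeps the contract exact.

`unique_only` counts only reads with singleton compatibility sets. `em`
additionally splits multi-compatible reads by iterating
c_i ← Σ_ec n_ec · c_i/Σ_{j∈ec} c_j from uniform weights until
max|Δc| < 1e-6 or 100 iterations; counts stay non-negative and sum to the
assignable reads at every iteration. On duplicate-free catalogs both modes
coincide.

Counting happens at class level: reads can never distinguish identical
sequences, so per-gene tables attribute each class count to its
representative and zero to other members, with the class map retained.
The per-strain matrices then drop `interstrain_duplicate` and `mixed`
classes entirely (their strain of origin is unknowable), while identical
within-strain paralogs are kept, counted once. The community-scale matrix
keeps everything, so total counts are conserved exactly.

## Profiling

RNA-based RA of strain s in sample j is 100 × (reads of s)/(microbial
reads); host features are excluded from both numerator and denominator. A
strain (or gene) is *detected* in a compartment when some single replicate
reaches `detection_min` = 1.0 — the "at least one read" rule, carried over
to fractional EM counts by requiring a full read's worth of weight. Focal
strains must have > `min_genes` (default 1000) genes detected in both
compartments and are ranked by mean root RA (the ranking key is a design
choice; abundance at the root is what makes a strain's transcriptome
interpretable), truncated to `top_n` = 20. TPM is computed within each
strain's gene set: 1e6 · (k/L) / Σ(k/L).

## Differential expression

Two-group (matrix vs root) NB model per feature, positive log₂FC = higher
in roots.

- **Size factors**: median-of-ratios over genes detected in all samples,
  rescaled to geometric mean 1. A strain with fewer than `min_ref_genes`
  (default 10) such genes is ineligible and reported with the reason
  rather than silently skipped.
- **Dispersions**: method of moments on normalized counts,
  α̂ = max(α_min, (v̂−m̂)/m̂²) with α_min = 1e-8, where v̂ is the *pooled
  within-group* variance — using the total variance would let a real
  expression difference masquerade as overdispersion and makes the Wald
  test conservative. A trend α(m) = a₀ + a₁/m is fitted by least squares
  over genes with informative α̂. The final value is a log-scale weighted
  average of raw and trend with weights resid_df : `prior_df` (default 16).
  The prior weight reflects that the trend pools thousands of genes while
  a 3+3 design leaves 4 residual df per gene; with equal weights the test
  is anti-conservative, because genes whose raw estimate lands at the
  α_min floor (within-group variance below the mean — common at 4 df)
  would contribute log(α_min) → −∞ of spurious precision. Floor genes
  instead fall back to the trend, and genes more than `outlier_mult` = 8×
  above the trend keep their raw estimate so genuine dispersion outliers
  are not shrunk into false positives. Measured on the generator's own
  study conditions (2000 genes, 3+3), this estimator puts the raw-p
  rejection rate at nominal 5% within [0.043, 0.063] across seeds.
- **Wald test**: per-gene NB GLM log μ = log s_j + β₀ + β₁x with fixed
  α_g, fit by IRLS vectorized across genes (shared 2-column design,
  closed-form 2×2 solve; convergence max|Δβ| < 1e-8, cap 100 iterations —
  non-converged genes are reported untested). SE from the observed
  information; p = 2(1−Φ(|β₁|/SE)). The implementation agrees with
  statsmodels' NB GLM to ~1e-6 per gene (cross-checked in the tests) but
  runs thousands of genes in milliseconds.
- **LFC shrinkage**: normal-prior empirical Bayes. The prior SD τ is the
  upper quartile of |log₂FC| over well-estimated genes (SE below the
  median); shrunk = mle · τ²/(τ² + SE²). This keeps precise estimates and
  pulls noisy low-count ones toward zero — the qualitative behavior that
  matters for ranking — without heavier adaptive-prior machinery, whose
  numerical reproduction is a non-goal here.
- **BH**: standard step-up with NaN passthrough; a feature is a DEG when
  adjusted p < 0.05. Independent filtering is not applied; all-zero genes
  are simply untested, keeping the tested universe explicit for
  enrichment.
- A housekeeping QC hook flags user-designated stable genes that come out
  differentially expressed.

## Orthogroup analyses

Per-strain OG counts are member-gene sums within the strain (unmapped
genes become singleton OGs); OG-level DE reuses the gene-level machinery.
Community-scale DE pools *unfiltered* counts of every bacterial gene of an
OG across strains — interstrain duplicates are included here because
pooling makes strain attribution irrelevant — and runs one DE analysis.

The conserved-response statistic is the cumulative log₂FC: the sum over
focal strains of an OG's *shrunken* log₂FC (shrinkage first, so low-count
strains do not dominate the sum), with absent or untested entries
contributing 0 — a rule that neither rewards nor penalizes absence; the
full table keeps NaN so absence remains visible. Ranking is descending,
ties broken by community log₂FC then OG id, making it deterministic. A
curated-orthology control (e.g. KEGG ortholog groups) is the same code
path with a different gene→group map.

## Functional analyses

An OG inherits the annotation of its most-annotated member (ties: longest
sequence, then smallest gene id) — a desk-scale stand-in for
profile-based representative selection, which needs external HMM
databases. Enrichment is classic per-term one-sided Fisher (hypergeometric
tail) over target vs universe OGs, BH-corrected, with terms under
`min_count` = 3 universe members skipped; no GO-graph decorrelation
(out of scope). The category summary is the mean shrunken log₂FC of
top-ranked OGs per COG category per strain; the function–abundance model
is OLS of log₁₀ mean root RA on a category's column across strains
(pseudo-count: half the smallest nonzero RA), reporting slope, R² and the
two-sided slope test, plus a pairwise Pearson correlogram between
categories.

## Transcriptome structure

Each (strain, sample) pair is one unit; its OG counts are normalized to
relative abundances (all-zero units dropped with a log entry). Distances
are Bray–Curtis. PCoA is classical scaling on the Gower-centered matrix;
axes with positive eigenvalues are kept and negative eigenvalues are
reported unaltered, so the user can judge how non-Euclidean the
dissimilarity is. PERMANOVA decomposes tr(HG) sequentially (type-I) in
user-controlled term order (default compartment + taxonomy + interaction),
with pseudo-F per term and p-values from free permutation of unit labels,
always counting the identity permutation so p ≥ 1/(1+n_perm). Strata and
type-II/III decompositions are not implemented; term order is exposed
instead. An exhaustive mode enumerates all distinct relabelings for small
designs and is used as the exact oracle in tests.

Note the granularity of permutation p-values: with 4+4 units only 35
distinct partitions exist, so rejection below ~1/35 is impossible; the
calibration benchmark uses 10 units (126 partitions), where the achievable
level at 0.05 is 6/126 ≈ 0.048.

## RNA vs DNA comparison

Detection is "at least one read in one sample" per method; the report
gives per-compartment counts and overlap relative to the inoculum.
Abundance agreement is the correlation of log mean RA across strains
detected by both methods; Pearson is the default, Spearman available —
the two conventions coexist in the field and the choice is exposed rather
than resolved.

## Benchmark problem sizes

The acceptance battery runs, per seed: duplicate-rule exactness (6
strains × 40 genes, 1e4 reads/sample), EM fidelity (1e4 reads/sample,
2% L1 bound), RA recovery (20 strains, 1e5 reads/sample, r > 0.95), DE
calibration (2000 genes, 3+3; null rejection in [0.035, 0.065], FDR ≤ 0.10,
power ≥ 0.7 at baseMean ≥ 50), shrinkage benefit (RMSE at baseMean < 10),
conserved-OG recall (2000 OGs × 20 strains, 20 planted, ≥16 in top-200),
PERMANOVA type-I (1000 null sims × 999 permutations), regression recovery
(R² constructed at exactly 0.5 over 20 strains, recovered within ±0.15)
and byte-identical pipeline reruns. These sizes keep the whole battery
under a minute while leaving each check statistically meaningful.

## What passing does and does not show

The generator's reads are error-free and its dispersions follow the same
trend family the estimator fits, so the benchmarks validate the
*bookkeeping and statistical contracts* — duplicate handling, count
conservation, calibration, recovery — under a well-specified model. They
do not demonstrate robustness to sequencing error, mis-specified
dispersion structure, rRNA contamination, compositional artifacts of very
uneven communities, or orthology errors (the OG map is an input, never
inferred). Real-data use should treat those as open validation questions.
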