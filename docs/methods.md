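# Methods

This note records the statistical models, defaults and numerical choices
behind each `seedvigor` module, what the synthetic-data generators do and
do not emulate, and the package's known limitations.

## Population-genetic selection scan (`seedvigor.popgen`)

**Data model.**  Haploid biallelic calls (0/1, −1 missing) at strictly
increasing 1-based positions with a two-group population label per
haplotype.  Diploid VCF genotypes are split into two haplotypes at face
value; the scan is therefore a haplotype-level analysis and does not model
phasing uncertainty.

**F_ST estimator.**  Weir & Cockerham's (1984) variance-component
estimator specialized to haploid calls.  With per-site pairwise-complete
sample sizes n₁, n₂ and allele frequencies p₁, p₂:

    MSP = n₁(p₁ − p̄)² + n₂(p₂ − p̄)²,
    MSG = (n₁p₁q₁ + n₂p₂q₂) / (n₁ + n₂ − 2),
    n_c = (n₁ + n₂) − (n₁² + n₂²)/(n₁ + n₂),
    a   = (MSP − MSG)/n_c,    b = MSG.

Site F_ST is a/(a+b); windows report the ratio of sums Σa/Σ(a+b), which is
the standard way to stabilize small-window estimates.  Negative per-site
components are retained; a window F_ST slightly below 0 is reported as
computed (clamp only when plotting).  A Hudson-type estimator
(1 − H_w/H_b) is available via `estimator="hudson"` for sensitivity
checks.  Monomorphic sites contribute (0, 0) and are excluded from window
site counts.

**Diversity.**  θ_π = Σ_sites 2p̂q̂·n/(n−1) divided by the window span in
bp, i.e. a per-site quantity that includes invariant positions in the
denominator.  Missing data enter through per-site n.

**Windows.**  Anchored at the first variant position, [start,
start+window) half-open, default 3000 bp sliding by 100 bp.  Windows with
fewer than `min_sites` (default 3) usable sites keep their coordinates but
carry NaN statistics, so downstream tables stay rectangular.  A region
shorter than one window yields a single truncated window with a warning.

**Null thresholds.**  Two nulls are provided.  (1) Permutation: population
labels are shuffled n_perm times, the maximum window F_ST of each rescan
recorded, and the threshold is the empirical (1−α) quantile (linear
interpolation, `numpy.quantile` default) of the maxima — a familywise
bound under exchangeability.  (2) Bottleneck model: n_sim independent
neutral windows are simulated under a two-population coalescent in which
the crop lineage passes through a domestication bottleneck; thresholds are
the (1−α) quantiles of window F_ST and of θ_π,wild/θ_π,crop.  Windows with
zero crop diversity are excluded from the ratio distribution and counted
in the log.

**Demographic defaults.**  N_anc = N_wild = N_crop,now = 150,000 diploids;
crop bottleneck to 5% of N_anc (7,500) for 1,000 generations ending 9,000
generations ago; µ = 3×10⁻⁸ per bp per generation; r configurable
(default 0).  These are literature-typical maize-domestication values and
are exposed as plain configuration on `DemographicModel`; they are
assumptions of the null, not estimates produced by this package.
Internally msprime is run with ploidy-1 samples and population sizes 2N so
that E[pairwise TMRCA] = 2N generations and E[π] = 4Nµ, matching the
diploid-N convention of the model fields.

**Scale used in the test suite.**  Coalescent calibration uses 2,000
replicate windows (mean π within 5% of 4Nµ); permutation type-I
calibration uses 50 datasets × 100 permutations; bottleneck direction
checks use 500 windows per model.  These sizes give Monte-Carlo error
comfortably inside the asserted tolerances while keeping the default test
run short.

## Binding kinetics (`seedvigor.binding`)

**Plate geometry.**  `plan_serial_dilution` encodes the assay's dilution
arithmetic: well k holds `stock × mix_fraction / fold^(k−1)` of every
co-diluted reagent, with `mix_fraction = 0.5` for equal-volume target
addition.  The planner is exact; the printed concentrations of any
protocol following this scheme fall out of the formula.

**Isotherm.**  The labelled target sits at ~89 nM, which is not negligible
against dissociation constants below ~1 µM, so fraction bound uses the
single-site depletion quadratic in its cancellation-free form
FB = 2L/(L+T+K_D+√((L+T+K_D)²−4LT)).  This reduces to L/(L+K_D) as T→0 and
is monotone in each argument (property-tested).

**Fitting.**  fnorm = unbound + (bound−unbound)·FB is linear in the two
levels given K_D, so the fit profiles them out by least squares and
searches 1-D over log K_D, multi-started from a 7-point log-spaced grid
spanning [min ladder/10, max ladder×10] with bounded local refinement in
each grid cell; ties break to the lower residual, then the lower K_D.
Standard errors: replicate spread (sd/√n over per-replicate fits) when ≥3
legitimate replicates; otherwise the curvature of the SSR profile,
Var(K_D) ≈ 2σ̂²/(d²SSR/dK_D²).

**Legitimacy.**  An estimate is reported legitimate only if the fit
converged, the fitted amplitude |bound − unbound| is at least 3× the
residual SD, and K_D lies inside the searched range.  This rule is this
package's own stand-in for the proprietary screening heuristics of
commercial instrument software; it reproduces the qualitative behaviour
(dash entries for early-timepoint aged protein) without claiming to mirror
any vendor's internals.

**Well QC.**  Outliers are detected by studentized deleted residuals: each
clean well is predicted from a provisional fit to the other clean wells,
deleted residuals are scaled by 1.4826×MAD, and only the single worst well
above the threshold (default z = 4, conservative because a 12-point MAD is
itself noisy) is flagged per pass, iterating to convergence.  Deleting
before predicting prevents high-leverage plateau wells from masking
themselves; one-at-a-time removal prevents a gross outlier from corrupting
the scale used to judge the others.  An optional initial-fluorescence
column drives a homogeneity flag (> 20% deviation from the ladder median).
If more than half the wells end up flagged the series is unusable.
Robust detection has a breakdown point: with ≳40% of wells corrupted no
residual rule can be trusted, and such plates should be discarded on the
homogeneity/scan criteria instead.

**Comparisons.**  One-way ANOVA within strata; Scheffé simultaneous
pairwise contrasts rendered as compact letter displays (insert-and-absorb
with splits on significant pairs); Dunnett many-to-one comparisons with
adjusted p-values from 10⁵ Monte-Carlo draws of the joint multivariate-t
null at a fixed internal seed (reproduces the printed two-sided critical
value 2.86 at k = 2, df = 6, α = 0.05 within ~0.01).  The three-replicate
resampling helper returns the pairwise SEs (|x−y|/2) used when replicate
scatter itself is the quantity compared.

## Translatome (`seedvigor.translatome`)

Per gene, counts y follow NB(µ, α) with log µ = log(libsize) + β₀ +
β_g·group + β_a·assay + β_ga·(group×assay).  The RNA effect is β_g fitted
on RNA samples alone; the TE effect is β_ga from the full paired model —
proportional RNA/RNC shifts cancel in it by construction.  Both are tested
by likelihood-ratio χ²₁ at a common dispersion, estimated by method of
moments on library-size-normalized counts within design cells (median of
positive per-gene estimates, floored at 10⁻⁴).  A single common dispersion
is used rather than a fitted mean–dispersion trend: the package's
generator plants one dispersion, and on real data the common value is the
conservative simplification; the `dispersion=` argument accepts any
externally estimated value.  P-values are BH-adjusted separately within
the RNA and TE families (the two volcano plots an analyst would draw), and
categories follow the fixed rule: significant RNA only → Transcription;
significant TE only → Translation; both, same sign → Homodirection; both,
opposite sign → Opposite; else Unchanged.  The per-gene IRLS solver is a
small fixed-dispersion Fisher-scoring routine (step-halved, offset-aware)
that matches statsmodels GLM NegativeBinomial to ~10⁻⁵ and runs ~0.7 ms per
gene; statsmodels is kept as the independent oracle in the tests.

All-zero genes are dropped with a logged count.  Unpaired RNA/RNC
replicates are a hard error naming the offending samples.

## Methylation (`seedvigor.methylation`)

**McrBC-qPCR.**  Per replicate, ΔCt = Ct(digested) − Ct(undigested) for
the region and for the mean of two unmethylated reference genes;
ΔΔCt = ΔCt_region − ΔCt_ref; remaining template 2^(−ΔΔCt); score
1 − remaining, averaged over replicates with sd/√n as SE and clamped to
[0, 1] after averaging (negative means are logged as
unmethylated-with-noise).

**Bisulfite calling.**  Contexts are assigned from the reference: CG, CHG,
CHH with H ∈ {A, C, T}; cytosines lacking 1–2 downstream bases, or with a
non-ACGT base in the triplet, are indeterminate and excluded.  Clones are
assumed gap-free and pre-aligned (Sanger sequencing of a fixed amplicon;
no aligner is included).  Clone base C = methylated, T = converted;
anything else at a cytosine position is flagged, excluded from the
denominator and counted.  Bottom-strand loci are handled by
reverse-complementing before calling, since locus-specific bisulfite PCR
interrogates one strand.  Conversion efficiency is not estimated or
corrected; raw percentages are reported, and the generator models
incomplete conversion as upward bias (C retained), matching its direction
in real data.

## Phenotype statistics (`seedvigor.phenotype`)

Germination curves are cumulative percent per replicate, summarized as
mean ± SE per timepoint; per-timepoint comparisons default to Welch's
t-test (an equal-variance flag exists because published legends often just
say "Student's t-test"), with the conventional star thresholds 0.05 /
0.01 / 0.001.  Zero variance in both groups with equal means reports
p = 1.  Dunnett comparisons of final germination against a control reuse
the Monte-Carlo machinery above.  Haplotype calls are a pure function of
amplicon length: within ±50 bp of the 365-bp product → insertion-free
haplotype, within ±50 bp of 2,682 bp → insertion haplotype, else "other";
the 50-bp tolerance is a gel-resolution-motivated default, not a measured
quantity.  The Bonferroni helper returns α/m with α = 1 as the documented
default (the 1/m convention used for expression-GWAS thresholds in the
maize association literature); pass α = 0.05 for the textbook familywise
level.

## Phylogeny (`seedvigor.phylogeny`)

Complete deletion removes every column containing a gap or ambiguous
residue.  Distances are Poisson-corrected protein distances
d = −ln(1 − p); p = 1 (saturation) is an error rather than an infinite
branch.  Neighbor joining follows Saitou & Nei's Q-criterion with two
details fixed for determinism (classical descriptions leave them open):
Q-ties break to the lowest (i, j) index pair, and negative branch lengths
are clamped to zero with the excess moved to the sibling branch so the
joined pair's path length is preserved.  Bootstrap supports are the
percentage of B column-resampled replicates containing each bipartition of
the full-data tree (supports mapped onto that tree, not a majority-rule
consensus), and internal branches under the collapse threshold (default
50%) are contracted to multifurcations after mapping.  Saturated
bootstrap resamples are given a large finite distance so replicates never
abort.  Output is newick with supports as internal node labels.

## Synthetic data (`seedvigor.synthetic`)

Every generator takes one integer seed and derives per-replicate
substreams by fixed offsets (`default_rng([seed, k])`), so output is
byte-identical across runs and replicates are individually reproducible.

* **Binding plates** put every well exactly on the depletion isotherm and
  add i.i.d. Gaussian noise; the default scenario in tests uses 1% of the
  fluorescence amplitude, chosen to give replicate scatter of the same
  order as published K_D standard errors (the instruments publish no noise
  magnitudes, so this is a qualitative calibration only).
* **RNA/RNC counts** are NB with a common dispersion (default 0.1,
  a typical RNA-seq biological-replicate value); RNA means shift by
  rna_log2fc between groups and RNC means by rna_log2fc + te_log2fc, so
  planted TE effects are invisible to the RNA test by construction.
  Library sizes default to 500 reads per gene on average — the per-gene
  coverage of a 20–40M-read library over ~40k genes — so that desk-scale
  panels of a few thousand genes keep realistic per-gene power.
  Inconsistent truth tables (e.g. a Translation gene with te_log2fc = 0)
  are rejected.
* **Bisulfite clones** keep each cytosine as C with probability
  p_ctx + (1 − p_ctx)·conversion_failure; everything else copies verbatim.
* **Germination** draws one uniform per seed and thresholds it against a
  scaled logistic F(t) = (max_pct/100)/(1+exp(−slope·(t−t50))); counts are
  binomial around the curve at each time and exactly monotone within a
  replicate; an infinite slope gives a step at t50.  Defaults (t50 = 60 h,
  slope 0.15 h⁻¹, max 95%, 3 replicates of 50 seeds) match the shape of
  standard maize germination assays.
* **Genotypes** come from msprime under the bottleneck model above.

What the generators do **not** emulate: read-level sequencing error or
mapping bias (counts are drawn at gene level), fluorescence time-domain
traces, GC/coverage trends, linkage to unmodelled selection, clone
chimeras or alignment errors, and replicate-level random effects in the
count model.  Passing tests therefore demonstrate correctness of the
estimators and calibration under these idealized designs — not robustness
to the artifacts real instruments add upstream.

## Known limitations

* The scan assumes biallelic sites and two populations; multiallelic
  records are rejected rather than decomposed.
* The TE test has no gene-specific dispersion shrinkage; for deeply
  replicated real data an external dispersion estimate (e.g. from an
  empirical-Bayes tool) can be passed in.
* The legitimacy rule and well QC are documented stand-ins for proprietary
  instrument screening, selected for qualitative agreement.
* NJ is O(n³) pure Python/numpy and intended for the tens-of-taxa protein
  trees of this domain, not genome-scale phylogenomics.
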