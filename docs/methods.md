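# Methods

## Pathway activity scoring

Compound abundances are first normalized per compound to ratios against
the compound's mean over strains (missing cells excluded from the mean;
all-missing or zero-mean compounds dropped with a warning). The activity
of pathway *j* in strain *i* is the coverage-weighted sum over *detected*
compounds — compounds measured in every strain —

    PA_ij = (1/K_j) · Σ_{c ∈ j, detected} I_ic

with K_j the total number of compounds annotated to the pathway. Pathway
activity profiling methods differ in sign conventions and internal
weighting; this package fixes the rule above as its single scoring
backend because the downstream per-pathway min–max normalization makes
any monotone affine per-pathway rescaling equivalent: rankings cannot
depend on the 1/K_j factor (asserted by a test). Users preferring the
inverse-flux reading (high metabolite pools ⇒ low flux through the
pathway) can negate scores with `--invert-activity`; this is equivalent
to flipping the expectation E.

Pathways with no detected compound yield no activity column and are
reported as "unused" rather than silently dropped.

## Ranking

PAN is the per-pathway min–max normalization; a degenerate column
(constant activity) is set to 0.5 for every strain — it then contributes
a constant to every fused score and cannot influence the relative
ranking, which matches the intuition that a non-discriminating pathway is
uninformative. PAT = 1 − |E − PAN| with E ∈ {0, 0.5, 1}; the formula
admits any E ∈ [0, 1] and a power-user flag (`allow_any_expectation`)
lifts the closed-set validation, but the three labels are the supported
interface. Universal pathways (ten broad KEGG maps such as "Metabolic
pathways") default to weight 0.

WBF's Borda count uses strict inequality, ties sharing the count, and the
final ranking breaks ties by strain ID ascending — both choices are for
determinism; any tie rule consistent with the weak order would be equally
defensible. WASF is the default algorithm.

## Pathway correlation

All unordered pairs of non-universal activity columns are tested with
Pearson's r (two-sided P from the t transform, via scipy). P values are
Bonferroni-adjusted over the tested pairs and reported as "Q values",
following the source tool's terminology; significance is Q < 0.05.
Constant columns make r undefined, so such pairs are skipped with a
warning and excluded from the multiplicity family.

## Mixed-model association

Phenotype = one pathway's activity vector; genotypes are haploid 0/1.
Variants are filtered at minor presence frequency 0.05 (both rare
presence and rare absence removed — at n = 21 this removes singletons and
keeps doubletons). Kinship is identity-by-state over the filtered
variants, K_ab = fraction of variants with equal alleles; missing calls
are imputed as reference for K only. K is a scaled Gram matrix, hence
positive semidefinite with unit diagonal.

The single-marker model is y = β₀ + βg + u + ε with u ~ N(0, σ_g²K),
ε ~ N(0, σ_e²I). Writing δ = σ_e²/σ_g² and eigendecomposing K = U S Uᵀ
once per scan, the rotated model has diagonal covariance σ_g²(S + δ).
δ is estimated per variant by REML: a 100-point log-spaced grid over
[1e−5, 1e5] followed by 40 golden-section iterations on the bracketing
interval (vectorized across variants). β is then tested by generalized
least squares with a two-sided t-test on n − 2 degrees of freedom.
Numerical guards: eigenvalues clipped at 0 with a warning if K is not
PSD; residual sums of squares floored at 1e−300 inside logs. At K = I
the weights are constant and the procedure reduces *exactly* to the OLS
t-test — the test suite asserts agreement to 1e−6 against
`scipy.stats.linregress` (observed agreement is machine precision).

Monomorphic variants are skipped. Variants with missing calls take a
slow path: affected strains are dropped and the subset kinship is
re-decomposed for that variant alone.

Permutation adjustment permutes the phenotype B times (seeded,
default B = 1000; smaller B in tests) and reports, per variant,
(1 + #{b : P_b ≤ P_obs}) / (1 + B). This is a pointwise per-variant
adjustment; a family-wise min-P flavor is available via `family_wise`.

**Calibration.** Under null synthetic panels (n = 21) the scan's type-I
error at nominal 0.05 is ≈ 0.038–0.039: slightly conservative, because
the kinship matrix is estimated from the very markers being tested, so K
absorbs part of each marker's own signal (the proximal-contamination
effect familiar from mixed-model association at small n with few
markers). Leave-one-chromosome-out kinship would remove this at the cost
of per-chromosome decompositions; with the small marker panels targeted
here the conservative bias is mild and on the safe side, so the simpler
all-marker kinship is kept.

## LD blocks and gene scores

The four-gamete rule is applied to each adjacent variant pair within a
chromosome (variants sorted by position): recombination is declared when
all four two-marker haplotypes occur with frequency ≥ 0.01 (the
Haploview default) among strains with complete calls. Blocks are maximal
runs of adjacent pairs without recombination; adjacent-pair detection
(rather than all pairs in a window) is the simplest rule consistent with
the method's name and is verified against a brute-force enumerator.

Gene regions are the gene body plus 800 bp upstream (strand-aware: 5′ of
the start on +, beyond the end coordinate on −, truncated at position 1).
A gene's P value is the minimum association P over **all** variants in LD
blocks overlapping its region — block expansion lets a regulatory variant
outside the body count for the gene, and can only lower the gene P
relative to body-only scoring. Only the block-minimum rule is
implemented; proxy-cluster refinements beyond blocks are out of scope.

The accumulated score is AS_i = Σ_j −log₁₀ P_ij / L_i over significant
variants (adjusted P < 0.05) in the gene region, L_i the region length in
bp. Log base 10 is the package's convention (configurable call-site
arithmetic; the definition leaves the base open). The adjusted P enters
both the significance cut and the sum, so the score is internally
consistent; P = 0 is clipped to the smallest positive float with a
warning. AS is invariant to non-significant variants and strictly
increases when a significant variant is added.

Target levels 0–4 scope the report: 0 none; 1 genes of reactions
involving target compounds (compound input only; local compound → gene
map); 2 genes inside target pathways; 3 plus genes of significantly
correlated pathways, scored against the correlated pathway's own
activity; 4 genome-wide against the target pathway's activity. Levels
are cumulative. Pathway and compound gene membership come from local TSV
maps (stand-ins for online pathway-database lookups). Each section
reports top-3 genes by ascending gene P and by descending AS.

## Flux-based evaluation

For a gene-deletion × reaction flux matrix with wild-type reference,
reactions never perturbed in any deletion are removed, then
Z_dr = (F_dr − wt_r)/sd_r with sd_r = sqrt(mean_d (F_dr − wt_r)²) — the
deviation scale anchored at the wild-type flux as the population mean
(the alternative, centering at the deletion mean, would absorb systematic
shifts; the wild-type-anchored form is this package's documented
reading). Two-sided normal P values; per (deletion, pathway) the
proportion of the pathway's reactions with P < 0.05; pathways with fewer
than 6 retained reactions are dropped. Top-ranked genes' deletion
proportions are pooled across pathways and compared with the remaining
deletions by a Welch t-test (unequal variances, unspecified in the
original description).

## Synthetic panels

The generator emulates a small yeast panel with paired data; its defaults
are the study conditions for every statistical test here:

- **21 strains** — the size regime of the published paired panels this
  tool family targets; power statements are honest at this n.
- **Genotypes**: each chromosome is split into LD segments by
  recombination hotspots (default every 5 markers). Within a segment each
  strain copies one of two complementary founder haplotypes (fair
  Bernoulli assignment, independent across segments) with per-site
  mutation rate 0.01. In-segment adjacent pairs thus show ≤ 2 ancestral
  gametes (no four-gamete signal except via rare mutations), while
  hotspot-flanking pairs mix all four with high probability — so the
  planted block structure is recoverable by the four-gamete rule.
- **Abundances**: lognormal, per-compound baselines ~ LogNormal(log 100,
  0.5), multiplicative noise sigma = 0.25 (typical CV ≈ 25% for
  metabolomic replicates). A planted association multiplies the target
  pathway's compounds by exp(η·g) with η = effect · σ/√K_p, a first-order
  calibration making the induced shift in the pathway activity phenotype
  approximately the requested number of phenotype SDs.
- **Flux table**: deviations around wild type at 10% relative scale,
  inflated 3× for each pathway's planted "strong" gene, emulating
  regulators whose deletion broadly perturbs their pathway.

What the panels do **not** emulate: real genome coordinates or gene
structure, KEGG pathway content, compound-sharing between pathways,
population structure beyond the two-founder segments, diploidy or
heterozygosity, batch effects, or missing-data patterns of real
metabolomics. Passing tests therefore demonstrate correctness and
calibration of the algorithms under controlled conditions — not
biological performance on real panels.

## Problem sizes and determinism

Tests and the acceptance script run at deliberately small sizes chosen as
a package design point: 12–100 variants, 5–6 pathways, 21 strains, 30–200
permutations, 2000 null replicates, 50-seed recovery studies. All
randomness flows through `numpy.random.default_rng` seeds; fixture
generation, scans and reports are byte-reproducible under a fixed seed
(asserted end-to-end).

## Known limitations

- The mixed-model scan is mildly conservative at small n (see
  Calibration above).
- E is restricted to three levels at the interface; the transfer formula
  supports a continuum.
- Heterozygous diploid VCF calls collapse to presence (any alt allele);
  dosage information is discarded.
- Gene-level P inherits LD-block granularity: neighboring genes sharing a
  block receive identical P and are separated only by AS and tie-breaks.
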