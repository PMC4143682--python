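# Methods

## The testing problem

A region (gene) holds M biallelic markers with dosages x ∈ {0,1,2} for the
minor allele, and a quantitative trait is measured on pedigree members or on
unrelated individuals.  The null hypothesis is that no variant in the region
is associated with the trait.  Because most region variants are rare,
per-variant tests are hopeless at realistic sample sizes; every test here
aggregates the region into one statistic.

## Family-based tests

### Conditioning and scores

Given both parental genotypes at a marker, the offspring genotype is a
Mendelian draw: each parent transmits the minor allele with probability
(dosage)/2, independently.  This conditional distribution supplies the mean
e and variance v of the offspring dosage, and the family score at marker m is

    U_im = Σ_{offspring j} T_j (x_jm − e_jm),

with T the adjusted trait residual.  E[U] = 0 under the null *by
construction*, whatever the trait distribution or population structure —
the classic transmission-disequilibrium argument extended to quantitative
traits.  Offspring contribute nothing at a marker when either parent or the
offspring genotype is missing or Mendelian-inconsistent there; genotypes are
never imputed on the family side.  The Rabinowitz–Laird sufficient-statistic
construction for partially missing parents is deliberately not implemented:
families with an ungenotyped parent are skipped at that marker and counted
in the diagnostics.  This costs information in sparsely genotyped pedigrees
but keeps the conditioning exact; fully genotyped cohorts lose nothing.

### The four region statistics

* **Burden (fbat_v).**  Markers are summed per offspring before scoring
  (equivalently U and its variance are summed over markers), giving a single
  Z.  Powerful when effects share a direction; unweighted by design, since
  no defensible weighting scheme is implied by the problem.
* **Multivariate (fbat_m).**  Q = U'V⁻U with the Moore–Penrose pseudoinverse
  (eigenvalue cutoff 1e−8 relative to the largest) and df = rank(V).
  Spends a degree of freedom per independent marker, so it dilutes quickly
  in large regions.
* **Linear combination (fbat_l).**  Z = w'U / √(w'Vw) with per-marker
  weights w_m estimated as the covariance between the trait residual and the
  *between-family* genotype information: the offspring conditional means
  e_jm, pooled with the observed genotypes of persons who appear only as
  parents.  Both are functions of parental genotypes and traits, hence
  independent of the within-family transmissions that randomize U — the
  test stays valid with estimated weights (the calibration suite verifies
  this empirically rather than assuming it).  Weights estimated from fewer
  than 10 observations are set to zero; if all weights vanish the test falls
  back to the unweighted burden with a warning.
* **Variance-component style (fbat_lmm).**  Q = Σ_m (Σ_i U_im)².  Squaring
  per marker before summing makes the statistic direction-agnostic, so
  protective and deleterious effects add instead of cancelling.  The exact
  original formulation is unpublished; this quadratic form is this package's
  reading of a variance-component test inside the score framework.  P-values
  come from Mendelian re-draw permutations: each round redraws every
  offspring's genotype from its conditional distribution (markers redrawn
  independently — see the linkage-equilibrium approximation below), and
  p = (1 + #{Q* ≥ Q}) / (1 + n_perm), ties counted as exceedances
  (conservative).  Default n_perm = 1000; the evaluation presets use 200,
  which resolves p-values down to 1/201 and is sufficient at α = 0.05.
  Scores are kept per nuclear family without pedigree aggregation,
  mirroring the known limitation that this test does not adjust for
  multiple families within an extended pedigree; the result flags this in
  its diagnostics.

### Model-based vs empirical variance

The model-based variance Σ_j T_j² v_jm treats nuclear families as
independent and transmissions as independent across markers (a
linkage-equilibrium-within-family approximation; parental phase is not
observed, and no LD-aware family variance is attempted).  Both assumptions
fail together in extended pedigrees when the region is linked to trait loci:
sibs and grandchildren share transmitted haplotypes, and their traits are
correlated through the same haplotypes, so per-family scores within a
pedigree co-vary positively and the model variance undercounts.

The empirical variance first sums family score vectors within each pedigree,
Ũ_p = Σ_{i∈p} U_i, and uses Σ_p Ũ_p Ũ_p' (no centering — the scores are
mean-zero by construction; at least two pedigrees required).  This is the
standard robust ("-e") estimator and is the recommended mode for extended
pedigrees.  With ~200 pedigrees its own sampling noise leaves a small
residual anticonservatism (observed null Z standard deviation ≈ 1.03), which
is inherent to sandwich estimators at this many independent units.

## Population-based tests

Both run on a pairwise-unrelated subset (founders by default, or a greedy
maximal kinship-zero set) and mean-impute missing dosages per marker —
standard for kernel methods, and harmless because imputation at the column
mean only shrinks marker variance.

* **Weighted-kernel score test.**  With OLS residuals r of the trait on
  covariates and σ̂² their residual variance, Q = r'Kr/(2σ̂²).  The default
  kernel is K = GW²G' with w_m the Beta(1,25) density at the marker MAF —
  the conventional rare-variant upweighting (the shape pair (0,25) sometimes
  quoted for this weighting is not a proper density; (1,25) is the standard
  reading).  IBS and Gaussian kernels are available for nonlinear allelic
  effects; all kernels are checked symmetric PSD.  Under the null Q is
  distributed as Σ λ_k χ²₁ with λ the eigenvalues of ½·P₀KP₀ (P₀ the
  covariate projection; σ̂² cancels).
* **Mixture-of-chi-squares tail.**  Computed exactly by the
  Ruben–Farebrother expansion: P(Q ≤ q) = Σ_j a_j F_{k+2j}(q/β) with
  β = 0.90625·λ_min; the coefficients are nonnegative and sum to one, so the
  truncation error is bounded by the untaken mass and the series is run to a
  1e−10 bound.  One distinct eigenvalue (or all equal) reduces to a plain
  chi-square.  When the eigenvalue spread makes the geometric convergence
  rate impractical (common under Beta(1,25) weights, where weights span many
  orders of magnitude), the kurtosis-matched noncentral-chi-square
  approximation of Liu–Tang–Zhang is used and flagged in the result — the
  same fallback hierarchy practitioners use when Davies-type inversion
  fails to converge.
* **Region variance component.**  A = ZZ'/M with
  z = (g − 2p)/√(2p(1−p)), REML of y = Xβ + u + ε, u ~ N(0, σ²_g A), by
  profiling the restricted likelihood over h² = σ²_g/σ²_tot on [0,1): a
  deterministic 26-point grid brackets the optimum and bounded scalar
  minimization refines it to 1e−10, with the h² = 0 boundary always
  evaluated.  The LRT uses the boundary mixture ½χ²₀ + ½χ²₁.
  Nonconvergence returns a flagged diagnostic record, never a silent drop.

Genotype principal components (allele-frequency-standardized SVD, component
signs fixed by the largest-magnitude loading) can be passed to the
residualization step as stratification covariates.

## Phenotype adjustment

Trait residualization regresses each exam's measurement on an intercept plus
caller-chosen covariates (the canonical blood-pressure set is age, sex
(0/1), age×sex, and antihypertensive-medication use (0/1); trait-like
simulated phenotypes use age and sex only) and standardizes the residuals to
unit variance.  Multi-exam traits are averaged per person over available
exams and re-standardized; standardization is applied both per exam and
after averaging (the order is a design choice — it changes nothing when all
persons have all exams and maximizes comparability otherwise).  Degenerate
(fully explained) traits and rank-deficient designs are hard errors naming
the collinear columns.

## Variant prioritization

A variant is kept if any route fires: functional class in {splice, stop};
nonsynonymous with deleteriousness score strictly above 0.5 ("above"
implies an open interval); or eQTL evidence with −log₁₀p at or inclusively
above 3.4 (a "cutoff … used" implies closure).  Unannotated variants fail.
Monomorphic variants may pass the filter — functional evidence is
genotype-free — but every statistic drops them, as they carry no
information and break standardization.  MAF stratification counts strict
inequalities (MAF < bound) and reports percentages to one decimal.

## The simulator

`gene_drop` assigns founder haplotype alleles independently per locus at the
requested MAFs (linkage equilibrium across founders) and transmits one
random parental haplotype per locus per meiosis.  Two segregation modes:

* independent (default): loci segregate independently — matching the family
  tests' own cross-marker approximation;
* co-segregating region (`linked=True`): the whole locus block travels
  un-recombined through each meiosis, the faithful picture of a small gene
  region.

The trait model is y = Σ_c β_c g_c + a_linked + a_unlinked + δ'c + ε with
unit total genetic-plus-environmental variance.  `a_unlinked` is a
pedigree-correlated polygenic deviate MVN(0, σ²_a·2Φ).  `a_linked` comes
from hidden causal loci (default 8 at MAF 0.25) co-segregating with the
region: founder alleles independent of the marker alleles, so the trait is
*linked but not associated* — the textbook regime in which conditioning
keeps single-offspring (trio) tests exactly valid while multi-offspring and
multi-generation pedigrees require the empirical variance.  A mild, known
amount of age and sex leaks into the trait so the adjustment step is
exercised.

Scenario presets fix the study conditions:

* **Q1-like null**: 28 markers at the printed MAFs of the filtered region
  table (three monomorphic), no causal marker, total heritability 0.628
  with 0.3 of it linked to the region, 200 pedigrees, 200 replicates,
  α = 0.05.  Trio pedigrees are the calibration case; the three-generation
  template (grandparent couple, three middle-generation sibships of three —
  17 members, four nuclear families, sized to resemble large extended study
  pedigrees) is the inflation case.  The linked share of 0.3 is a
  deliberate major-linked-locus stress design: a genome-wide polygenic
  trait would place only a small share on one region, producing the same
  failure mode more slowly.
* **MAP4-like power**: same markers, 8 causal (the five rarest polymorphic
  plus three common — mixed architecture), equal variance shares summing to
  a region h² of 0.12, polygenic 0.3, trios.  `mixed_signs` flips every
  other effect negative, the regime where the direction-agnostic test beats
  the burden.

The harness reseeds each replicate from (seed, replicate) and reports
rejection counts with exact Clopper–Pearson intervals, so reports are
byte-identical across runs at a fixed seed.

### What the simulator does not emulate

Population LD between markers, ascertainment of pedigrees, genotyping
error, dosage uncertainty, population stratification (available only
indirectly via the PC machinery on constructed subpopulations), and
non-Gaussian trait tails.  Passing tests therefore demonstrate correctness
of the conditioning, variances and null distributions under clean Mendelian
data — not robustness to artifacts of real sequencing studies.

## Scan

Gene intervals are 0-based half-open; a variant at 1-based position p
belongs to every gene with start ≤ p−1 < end (overlapping and nested genes
each receive it — union assignment is conservative for discovery).  The
Bonferroni threshold is α divided by the number of genes with at least one
testable post-filter marker; genes emptied by filtering are reported
untested and excluded from the denominator.  Per-gene failures are recorded
as NA without stopping the scan.

## Evaluation sizes

The shipped evaluation scale — 200 replicates, 200 pedigrees, permutation
count 200 in the presets, 100 variance-component fits at n = 500 / M = 30,
50 scan replicates — was chosen so a full calibration-and-power pass
completes in minutes on a single core while keeping the binomial acceptance
bands meaningful (the exact 95% band at 200 trials and α = 0.05 is 4–16
rejections).

## Known limitations

* Missing-parent families are dropped per marker rather than recovered via
  sufficient statistics.
* The model-based cross-marker variance assumes within-family linkage
  equilibrium; use the empirical mode whenever markers are tightly linked
  (which a gene region always is).
* `fbat_lmm` treats nuclear families as independent; extended-pedigree use
  inflates it by design, and results carry a diagnostic flag.
* Dichotomous traits, X-linked inheritance, phased or dosage-format
  genotypes, and multiallelic sites are out of scope.
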