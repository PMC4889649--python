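# Methods

This note records the models behind `lanctk`, the parameters that
matter, the numerical conventions, and what the synthetic-data tests do
and do not demonstrate.

## Masked-haplotype ancestry-specific PCA

**Model.** To examine population structure *within* one ancestral
component of admixed genomes, alleles on haplotype segments not called
as the target ancestry are set to missing.  Because the missingness
pattern lives on haplotypes, not genotypes, the analysis is per
haplotype: both copies of every retained individual enter as separate
rows.  Pairwise Euclidean distances (alleles as 0/1 coordinates) are
computed over the positions where both haplotypes are non-missing and
scaled up proportionally,

d(i,j) = √((M/s)·Σ_shared (x−y)²),   s = shared non-missing sites of M,

which equals the missing-value convention of R's `dist()` (verified
against it during development).  A pair sharing no positions gets the
mean of all defined off-diagonal distances, assigned in one pass after
the defined pairs are computed — no iteration.  Classical (Torgerson)
MDS then double-centers the squared distances and eigendecomposes;
coordinates are eigenvectors scaled by √eigenvalue.

**Assumptions and rationale.** When no data are missing, classical MDS
of Euclidean distances is *exactly* PCA of the centered allele matrix,
so the unmasked limit is standard PCA (tested to |r| > 0.999 per
component).  The proportional (M/s) scaling makes the expected squared
distance independent of how much of a pair was masked, which is what
prevents heavily masked haplotypes from collapsing toward the origin
and forming artifactual clusters.  An `scaled=False` flag exposes the
unscaled √Σ alternative for sensitivity analysis.

**Pipeline defaults.** Excluded-relative list is an input (kinship
estimation is out of scope); inclusion requires ≥ 50 % global target
ancestry (inclusive ≥; individuals below it retain too little data
after masking and produce noisy PCs); markers are thinned to 10,000
sites before distance computation to damp local LD and bound the O(H²M)
distance cost.  Thinning is deterministic: sites are apportioned to
chromosomes by largest-remainder rounding of their site counts and
chosen evenly spaced by index within each chromosome.  LD-aware pruning
was deliberately not implemented — even spacing is reproducible,
needs no genotype pass, and at ~10k sites residual LD has little
leverage on the top components.  Reference individuals, when supplied,
pass through the same thinning but unmasked.

**Numerical conventions.** Eigencolumn signs are fixed by making each
column's largest-magnitude entry positive, so results do not depend on
the LAPACK backend.  Only positive eigenvalues yield coordinates; if
fewer than k exist the remaining columns are zero and `n_positive`
reports the shortfall (squared distances that are not Euclidean-
embeddable legitimately produce negative eigenvalues).  A panel where
*no* pair shares a site is an error rather than an all-imputed matrix.

## Mendelian inconsistency of ancestry calls

Consistency is evaluated on **unordered** call multisets: statistically
inferred phase is not reliable enough across individuals to support a
phased check, and the unordered predicate is phase-invariant by
construction.  A pair (one parent observed) is consistent iff the child
shares at least one call with the parent — the unobserved parent is
unconstrained — so pair rates are a strict relaxation of trio rates;
with both parents the child's pair must split into one maternal and one
paternal call, multiset-aware (a child {A,A} needs A in both parents).
On X, sons and fathers carry single calls: a son's call must be
maternal; a daughter must carry the father's call, and the *remaining*
daughter call (one instance of the father's removed) must be maternal.

Rates pool all (family, site) cells equally within each configuration
rather than averaging per-family rates; with near-balanced site counts
the two differ negligibly, and pooling matches a single-number-per-
configuration report.  Any family member missing at a site removes that
cell from numerator and denominator.  The predicates are verified
exhaustively against brute-force transmission enumeration (36 pair, 216
trio, and all X configurations).

## X-chromosome male codings

Coding a haploid reference male as homozygous diploid doubles the
apparent frequency of his haplotype in a reference panel, so reference
males are instead paired into phased pseudodiploids within each
continental group, in input order (an optional seeded shuffle exists;
the pairing order is statistically irrelevant because downstream callers
do not rephase the reference), discarding the final male of an odd
group.  Three admixed-cohort schemes are built on this: (1) separate
haploid-male (known phase) and diploid-female analyses; (2) one analysis
with admixed males homozygous; (3) everyone homozygous, no pairing.
Options 2 and 3 encode admixed individuals identically and differ only
in the reference; this is asserted as an invariant.  The module emits
encoded panels plus a manifest; it does not run any ancestry caller.
Input sites are assumed to be non-pseudoautosomal.

## Synthetic admixed genomes

The generator emulates the data shapes above with known truth:

- **Drift**: ancestral frequencies Uniform(0.05, 0.95) per site;
  continental frequencies Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F)
  with F_cont = 0.15 (continental-scale differentiation); nested
  subpopulations re-apply the construction around the continental
  frequency with F_sub = 0.05 (within-continent scale).
- **Tracts**: ancestry switch points as a Poisson process of g = 8
  per Morgan (generations since admixture) on a uniform genetic map
  (default 1 Morgan across `n_sites` markers); tract ancestries i.i.d.
  from pi = (0.14, 0.31, 0.55) African/Amerindian/European, the
  three-way proportions typical of the motivating cohorts.  No Markov
  dependence between adjacent tracts is modelled.
- **Trios**: parents are admixed diploids; children arise by explicit
  meiosis (crossovers Poisson at 1/Morgan) copying alleles *and*
  ancestry labels from the active parental haplotype, so truth calls are
  Mendelian-consistent at every site by construction.  X families give
  sons one maternal recombinant X and daughters the paternal X unchanged
  plus one maternal recombinant.
- **Call corruption**: each cell independently flipped to a uniformly
  random different ancestry with probability ε, for studying the
  inconsistency-rate response.

All randomness flows through one `numpy.random.Generator`; a fixed seed
reproduces byte-identical outputs across platforms.

**What passing tests do not show.** Sites are independent given
frequencies — there is no background LD, so the thinning step is never
stress-tested against correlated markers; allele frequencies contain no
ascertainment bias; tract lengths are exponential rather than
empirically calibrated; corruption is i.i.d., unlike real caller errors,
which concentrate near tract boundaries and low-divergence ancestry
pairs.  Results on real call sets will be noisier in all these respects.

## Problem sizes in tests and the acceptance script

Stochastic checks run at sizes chosen to make their target quantities
estimable with comfortable margins while keeping the default suite
quick: 2,000 sites per chromosome, 200 haplotypes for the MDS/PCA
experiments, 50 trios × 2,000 sites for corruption-response rates
(500k trio-site cells per seed), 100 admixed diploids for subpopulation
recovery, with multiple seeds wherever a property is distributional.
Tolerances on stochastic quantities are stated in standard errors of the
estimator involved.  The masking-robustness classifier is scored by
5-fold cross-validation; training-set accuracy of even a null model
overfits at n = 200 and would not measure predictability.

## Design choices that were genuinely open

- **Distance scaling under missingness** (√((M/s)Σ) vs √Σ): chosen to
  match the named R implementation; the alternative is exposed by flag.
- **Thinning rule** (even spacing vs random vs LD pruning): even
  spacing, for determinism (see above).
- **Pooling vs per-family averaging** of inconsistency rates: pooling.
- **Male pairing order** for pseudodiploids: input order, optional
  seeded shuffle.
- **Concordance with missing calls**: a site enters a sample's
  cross-tabulation only if all four calls (two per call set) are
  observed, keeping the two-way alignment well defined.
- **Q-matrix filtering**: an individual is retained iff its maximum
  fraction over non-excluded clusters is ≥ 0.9 (inclusive); an
  individual dominated by an excluded cluster is thereby dropped.

## Known limitations

No BCF or dosage input; biallelic SNPs only; no phasing, no kinship
estimation, no local-ancestry calling (call files are inputs); plotting
is limited to what users build from the coordinate TSVs; the simulator
is a testing substrate, not a population-genetic inference model.
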