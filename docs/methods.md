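# Methods

## Setting and scope

The package analyses a population with discrete, non-overlapping
generations: a base phase of random mating with a fixed sex ratio followed
by a split into two reproductively closed lines kept under a constant
mating design for many generations. All genotyped animals belong to the
"selection" phase; the first selection generation is the **reference
population** — its allele frequencies anchor the frequency-dependent
estimators and its mean inbreeding anchors the 0-adjusted estimators. The
selection criterion itself (a trait) is deliberately out of scope: every
quantity computed here depends only on the mating structure, so the
simulator thins candidates at random where the real experiment selected on
a trait.

## Pedigree inbreeding

`pedigree.inbreeding_meuwissen_luo` computes F with the Meuwissen & Luo
ancestor-tracing recursion: for animal *i* with both parents known,
1 + F_i = Σ_j L_j² D_j over ancestors *j*, where L accumulates halving
contributions down the pedigree and D_j = 0.5 − 0.25(F_s + F_d) is the
Mendelian-sampling variance coefficient (0.75 − 0.25 F for one known
parent, 1 for founders). Animals with an unknown parent get F = 0; the
unknown side is treated as an unrelated, non-inbred founder. The recursion
is validated against the dense tabular relationship-matrix recursion in
the test suite, never used as the implementation. A numba JIT accelerates
the O(N · ancestors) trace; a pure-Python fallback keeps the package
importable without numba.

Two rates derive from F:

* ΔF_PEDt = (F_t − F̄_par)/(1 − F̄_par), the classic parent-referenced
  rate. Animals with an unknown parent yield a missing value by default
  (a complete experimental pedigree is the expectation; missing parents
  signal data problems); a flag treats the unknown side as F = 0 instead.
* ΔF_PEDi = 1 − (1 − F)^{1/(t−1)} with t = generation index + 1, i.e. the
  animal's discrete generation counted from the pedigree founders. The
  exponent convention makes one generation of inbreeding satisfy ΔF = F
  (founders' offspring, t = 2, use exponent 1); founders themselves have
  no rate. The rendering of this exponent is typographically ambiguous in
  parts of the literature; the fractional form is used consistently here.

Ne = 1/(2·mean ΔF) per generation cohort, reported signed and unclamped —
negative cohort means produce negative Ne, which is meaningful (gain of
diversity after a change in mating policy). Sex-ratio Ne_s = 4MF/(M+F),
and the founder distance t = ln(1 − F_ref)/ln(1 − ΔF) inverts the
exponential homozygosity-accumulation model.

## Marker-based estimators

All five GRM-diagonal estimators are per-individual functions of the
reference-allele count x ∈ {0,1,2} and (except F_NEJ) the reference
population frequency p per SNP. Per-individual sums and means run only
over that individual's non-missing SNPs — no imputation. That choice keeps
each individual's estimate unbiased but means implementations that
mean-impute will differ slightly on missing data. SNPs fixed in the
reference population (possible through drift after the MAF filter was
applied there) are excluded from the VR2/YAN per-SNP-standardised sums
with a logged count rather than raised as errors. Frequencies default to
the reference generation, matching the convention that F_L&H/F_VR1/F_VR2/
F_YAN are "intrinsically adjusted" to a reference population; whole-data
frequencies are available as a sensitivity switch by passing a different
subset to `allele_frequencies`.

The 0-adjustment F0 = (F − m)/(1 − m), with m the reference-generation
mean of the raw coefficient, makes the reference cohort average exactly
zero (a property the tests check to 1e−12) and leaves F = 1 fixed. On
complete data F_NEJ0 and F_L&H0 are the *same* affine transformation of
observed homozygosity, which is why their Ne series are expected to agree
to well under 1%.

Expected homozygosity applies the per-SNP transform first and averages
second: F_EXP = mean_j [1 − 2p_j(1 − p_j)] with p computed within the
cohort (generation, optionally within line). Averaging p before the
transform would differ by Jensen's inequality; the per-SNP form is the one
with the population-genetic meaning (expected homozygote frequency under
within-cohort Hardy–Weinberg).

## ROH detection

The scanner implements the sliding-window dialect of PLINK `--homozyg`
with these defaults: 50-SNP windows, ≤ 1 heterozygote and ≤ 5 missing
calls per homozygous window, per-SNP window hit rate ≥ 0.5 (ties pass),
minimum 100 SNPs and 1,000 kb per segment, density ≤ 50 kb/SNP (boundary
equality passes), segments split where adjacent in-run SNPs lie > 1,000 kb
apart, and *no* per-segment heterozygote cap — hets enter only through the
window rule. SNPs near chromosome ends are covered by fewer windows and
the hit rate uses the actual overlap count; chromosomes shorter than one
window produce no calls rather than an error. Segment coordinates are the
bp positions of the first and last in-run SNP.

A consequence worth knowing: with a 0.5 hit-rate threshold the in-run
interior of a homozygous block shrinks by about half a window on each
side, so a block must exceed the minimum-SNP count by roughly one window
length before it is reported. The scanner is verified by exact segment-set
equality against an exhaustive enumeration oracle across three
parameterisations.

F_ROH is the McQuillan genome fraction: summed segment length over the
total autosomal map length (per chromosome, last minus first SNP bp on the
ROH marker set, which keeps maximum coverage by applying no MAF filter).

## Quality control

A fixed order, each step idempotent: (1) drop individuals with call rate
strictly below 0.97 (exactly 97% is kept — "lower than" is read strictly);
(2) ROH marker set: autosomal SNPs with missingness ≤ 0.03, no MAF filter;
(3) GRM marker set: from the ROH set, drop SNPs with MAF strictly below
0.05 in the reference population, then drop remnants with MAF strictly
below 0.05 over all individuals. The first allele listed in .bim/.map is
the counted reference allele; the hand-written .ped reader orients by the
alphabetically smallest observed allele so text round-trips are
deterministic. The binary codec implements the standard SNP-major .bed
layout (00 hom-A1, 01 missing, 10 het, 11 hom-A2) bit-exactly.

## Rates and Ne from markers

Molecular ΔF_i = 1 − (1 − F_i)^{1/t} with t = selection generation − 1:
the reference cohort sits at t = 0 and therefore has no molecular rate
(the per-generation tables show missing values there). Negative F gives a
base above 1 and a negative rate — allowed and propagated. F ≥ 1 (possible
only numerically) is clamped with a warning and maps to ΔF = 1. The
overall mean/SD of Ne across generations excludes undefined entries.
Ne_EXP differences the expected-homozygosity series:
ΔF_EXP,t = (F_EXP,t − F_EXP,t−1)/(1 − F_EXP,t−1).

## Correlations

Pearson r over pairwise-complete observations (listwise deletion would
discard the whole reference generation for every estimator whose rate is
undefined there), with the paired count reported per cell and cells under
3 pairs suppressed. Generation groups default to initial (1–4),
intermediate (16–19) and recent (23–26) selection generations. Figures are
rendered from the written tables, never from in-memory state, so the
tables are the single source of truth.

## The breeding simulator and its truth

Haplotypes are founder-origin mosaics; meiosis is a Poisson crossover
process on the genetic map (no interference, no mutation, autosomes only).
Two label layers are maintained:

* **line labels**: which fully inbred founder line a stretch descends
  from. Since each line is a single homozygous haplotype, line identity is
  what marker homozygosity and ROH can detect, and a one-line design is
  correctly fully autozygous at this layer.
* **pedigree-copy labels**: at the pedigree-founder generation (after the
  unrecorded burn-in) each founder's two gametes get fresh unique labels.
  Matching copy labels is IBD relative to the recorded pedigree — the
  exact quantity pedigree F estimates, so gene-dropping theory guarantees
  E[autozygosity_ibd | pedigree] = F_PED and the regression of truth on
  F_PED has slope 1.

Both quantities are recorded per genotyped animal (`autozygosity_ibd`,
`autozygosity_line`). A single "true autozygosity" cannot serve both
purposes: line labels carry the pre-pedigree IBS/IBD baseline that copy
labels deliberately reset. The 0-adjustment cancels exactly that baseline,
which is why F_NEJ0 tracks reference-adjusted line autozygosity with unit
slope.

### Stated-world defaults

* Founder pool: 3 fully inbred lines mixed into 96 animals, 40 generations
  of unrecorded panmixia; the post-burn-in generation becomes the recorded
  pedigree's founders (32♂/64♀) so the five recorded random-mating
  generations of 32♂ × 64♀ (two females per male) follow immediately.
* Selection phase: 2 closed lines, 43 dams and 13 sires per line (the
  sire count is not stated by the experiment's description — "43 females
  mated to one male" is read as one male per female cohort slot — and 13
  ≈ 30% of male candidates is adopted and flagged as an assumption), at
  most 2 parturitions per dam, litter size 5, and a random 30% thinning
  standing in for selection, which yields ≈ 129 recorded (genotyped)
  animals per line per generation. Matings avoid pairs sharing any
  grandparent; the dam-to-sire assignment is solved exactly as bipartite
  b-matching (augmenting paths with a per-sire capacity), and when a drawn
  breeder sample admits no feasible plan, replacement breeders are
  re-drawn a bounded number of times — as a breeder would replace an
  unusable male — before an error suggests a census increase.
* Genome: 5 chromosomes × 10 Mb × 1,000 evenly spaced SNPs (10 kb
  spacing), 1 cM/Mb, genotype missingness 0.2%. This is a deliberate
  scale-down of a 616k mouse array for desk-scale runtimes; the 10 kb
  spacing keeps the 100-SNP and 1,000-kb ROH minima consistent with each
  other, as they roughly are on the real array. 70% of SNPs are
  line-discriminating (independent Bernoulli(½) allele per line) so the
  reference-generation MAF spectrum survives the 0.05 filter.
* `random_union=True` switches the offspring-to-pair assignment from
  balanced round-robin to uniform random (idealised multinomial family
  sizes); the drift-variance and Ne-recovery tests use it, since the
  sex-ratio Ne formula describes that idealised world.

### What a green synthetic test does not establish

The simulator has no genotyping error, no mutation, no sex chromosomes,
no map heterogeneity, no trait and hence no genuine selection response,
and its genome is ~2% of a real mouse genome, so absolute values of
marker-based estimators (e.g. baseline homozygosity ≈ 0.65 rather than
the published ≈ 0.6, founder distances ≈ 170/116 generations rather than
162/133) are design-dependent. The tests therefore check identities,
oracle equivalence, and parameter *recovery* (slopes, stabilisation,
agreement between routes), not the published real-data table values,
which require the original deposit.

## Numerical choices

* Strict-below thresholds for call rate and MAF; boundary equality kept.
* ROH hit-rate threshold ties (= 0.5) count as in-run; density boundary
  equality passes.
* Mean ΔF of exactly 0 yields an undefined (NaN) Ne with a warning.
* All randomness flows from a single `numpy.random.Generator` seeded by
  the user; equal seeds give byte-identical fixtures and tables.
* Pairwise correlation cells need ≥ 3 paired observations.

## Known limitations

* The .ped text reader determines the reference allele from observed data
  (alphabetically smallest); a SNP where only the alternate allele is
  observed is re-oriented relative to the writer. The binary route (.bim
  carries both alleles) is lossless and preferred.
* `delta_f_pedt` loops in Python and is the slowest pedigree routine on
  very large pedigrees (~10⁵ animals); acceptable at this package's scale.
* Grandparent-avoidance re-draws the breeder *sample* when infeasible but
  never relaxes the constraint, so pathologically small censuses still
  fail; the error message says so explicitly.
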