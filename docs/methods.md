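# Methods

This note documents the models behind each module, the conventions and
numerical choices the implementation commits to, what the synthetic-data
generators do and do not emulate, and known limitations.

## Genotype model

Genotypes are unordered pairs of integer fragment lengths (base pairs);
the two slots are sorted on construction so a/b ≡ b/a, and a half-missing
call is treated as fully missing. GenePop is read in the 2- and 3-digit
dialects and written in 3-digit form (microsatellite fragments exceed
99 bp). GenePop carries no population names, so the writer encodes the
site code as an individual-name prefix (`CODE_id`) and the reader recovers
it from that prefix, falling back to `popN` numbering.

Clone detection (identical multi-locus genotypes, interpreted as ramets of
one genet) compares individuals only at mutually scored loci and requires
at least one shared scored locus — the permissive convention of multi-locus
matching tools. Because missing data can make pairwise matching
non-transitive, groups are the transitive closure (union-find) of pairwise
matches, which keeps the result a partition. Deduplication keeps the
first-encountered member of each group, deterministic in input order; the
alternative (most-complete genotype) was considered and rejected to keep
the operation order-stable and idempotent.

## Synthetic data

`sample_spectrum` draws a symmetric Dirichlet whose concentration is set by
the closed-form inverse of E[Σp²] = (α+1)/(kα+1), then rescales the draw
along the line through the uniform spectrum: gene diversity is quadratic in
the line parameter, so the target is hit *exactly* (draws whose rescale
would make a frequency non-positive are redrawn, bounded at 1000 attempts).
`study_spectra` mixes ⌊A⌋- and ⌈A⌉-allele loci to average a target allele
count, e.g. the high-diversity remnant profile (He 0.69, 6.6 alleles over
10 loci) and the low-diversity profile (He 0.42, 3.1 alleles).

Structured populations use the Balding–Nichols compound-Dirichlet: local
frequencies ~ Dirichlet(base · (1−F)/F), chosen because F maps directly to
the expected F<sub>ST</sub>. Pedigreed pairs are built by explicit gamete
transmission, which realises the IBD-share probabilities (k₀,k₁,k₂)
exactly rather than in expectation. Spatial layouts are full-sib families
with isotropic Gaussian scatter around family centres in local planar
metres — planar coordinates deliberately avoid geodesy in tests.
Equilibrium populations for the bottleneck null are Ewens-sampling draws
(Hoppe's urn) paired at random into diploids.

What the generators do **not** emulate: genotyping error and allelic
dropout, null alleles, mutation during drift (mutation appears only in the
bottleneck module's equilibrium simulator), linkage, selection, selfing,
overlapping generations, and spatially continuous isolation by distance
within populations. Passing tests therefore demonstrate estimator and
simulator correctness under clean HWE-based sampling models, not
robustness to real-data artefacts.

## Diversity and structure statistics

* Expected heterozygosity is Nei's unbiased gene diversity
  (2n/(2n−1))(1 − Σp²); cells with fewer than two scored gene copies are
  excluded rather than NaN-propagated.
* Allelic richness uses hypergeometric rarefaction
  r = Σ[1 − C(2n−Nᵢ, G)/C(2n, G)], computed in log-space for stability.
  G defaults, per locus, to twice the smallest per-population sample with
  data (the FSTAT convention); a fixed G can be supplied, and a G larger
  than a population's gene count is an error naming that population. The
  rarefaction size used for published-style tables is therefore
  data-driven, since no single convention is universal.
* θ follows Weir & Cockerham (1984) exactly, summing per-allele variance
  components over alleles and loci; negative estimates are reported as
  computed. The CI is a percentile bootstrap over loci (default 1000
  resamples); with a single polymorphic locus the CI is degenerate and a
  warning is issued. Per-population F<sub>IS</sub> is 1 − H̄ₒ/H̄ₑ with
  means over loci (the convention of standard summary tables); the global
  Weir–Cockerham small-f is also returned from the b, c components.
* Permutation p-values use add-one smoothing, (hits+1)/(B+1), which keeps
  them strictly positive and super-uniform.
* Isolation by distance regresses θ/(1−θ) on ln(great-circle distance),
  haversine on a 6371-km sphere (the metric is a convention; the study
  region spans ~300 km where the choice is immaterial). The Mantel test is
  implemented directly (joint row/column permutation, two-sided) because
  linearised-FST matrices legitimately contain negative entries that
  strict distance-matrix containers reject; it is cross-checked against
  scikit-bio's implementation on valid matrices in the test suite.
  θ = 1 pairs are excluded from linearisation with a warning.
* Brookfield's formula-1 null-allele estimate (Hₑ−Hₒ)/(1+Hₑ) is floored at
  zero: heterozygote excess carries no null-allele signal.
* FDR control is Benjamini–Hochberg step-up (statsmodels), default q = 0.05.

## Relatedness and spatial autocorrelation

Reference allele frequencies are taken from the full analysed sample with
no leave-one-out, and include the pair itself. An allele absent from a
supplied reference is given frequency 1/(2N+1) with a warning. Note the
reference matters: judged against its own family's frequencies a sib pair
is "unrelated"; estimator-recovery checks therefore use samples containing
many independent pairs, or pass the generating spectra explicitly.

Queller–Goodnight sums numerators and denominators across loci before
dividing and averages the two directional forms; a zero denominator in one
direction falls back to the other, and a pair informative in neither
direction is NaN. Lynch–Ritland uses the published locus weights;
Loiselle's kinship includes the p(1−p)/(n−1) small-sample term with n the
reference gene-copy count (expected ≈ r/2 for non-inbred pairs). A
vectorised all-pairs matrix path (complete data) is verified against the
per-pair functions to 1e-10.

ML classification maximises Π over loci of k₀·P(gx)P(gy) + k₁·P(gx)T(gy|gx)
+ k₂·P(gx)·[gx=gy] over U/HS/FS/PO; ties break toward the less related
label (U first), so uninformative data default to "unrelated".

The autocorrelogram uses pairwise squared genetic distances equal to half
the squared Euclidean distance between allele-dosage vectors (this
reproduces the conventional codominant values: AA–AB 1, AB–CD 2, AA–BC 3,
AA–BB 4), double-centred into a covariance matrix; the class coefficient is
the ratio of summed off-diagonal to pairing-weighted diagonal entries.
"Equal sample size" classes cut the sorted pair distances into
equal-count classes with ties kept together; exact-zero distances
(co-located stems) form their own leading class. In multi-location mode
the covariance is centred within each location and only within-location
pairs are pooled — the exchangeability null then permutes coordinates
within locations. Null envelopes are the 2.5/97.5 percentiles over
permutations (9,999 by default; tests use a few hundred). Missing
genotypes are mean-dosage imputed for this analysis only.

Per-class relatedness profiles refuse to run (with a full report) when a
class violates the standard diagnostics — more than 100 pairs,
participation above 50%, CV of participation below 1 — unless explicitly
overridden; deviation tests are two-sided with add-one smoothing.

## Drift simulation

The founding pool (t = 1, default 500 individuals) is built by random
union of gametes from the source's allele pool, erasing family structure
while preserving allele frequencies in expectation. Each replicate draws N
individuals the same way (t = 2) and then resamples itself — two alleles
per locus with replacement, free recombination, no selfing restriction —
for non-overlapping generations. He is the same unbiased estimator as the
statistics module, computed on the N simulated individuals; the allele
metric is the plain mean allele count over loci (not rarefied), matching
how simulation outputs are conventionally reported alongside a founding
pool of fixed size. Confidence bands are mean ± z·SD over replicates
(default 95%; a `ci` flag gives 99%).

Defaults follow the motivating study design: N ∈ {20, 50, 100, 500},
T = 200 generations, R = 100 replicates, mixing draws of 20 individuals
from each source and mixed-population sizes 250 and 400.

Two numerical notes. First, all replicates run through one master-seeded
generator, vectorised as an (R × loci × 2N) state tensor — same
reproducibility guarantee as per-replicate seed offsets, two orders of
magnitude faster. Second, the *unbiased* estimator at generation t has
expectation (2N/(2N−1))·(raw diversity), so the exact decay law
E[Ĥ(t)]/E[Ĥ(1)] = (1−1/2N)^(t−1) holds for the uncorrected sample gene
diversity; oracle tests de-correct before comparing, and compare the
time-averaged relative deviation over the horizon where the law predicts
at least 10% retained diversity — the pointwise relative error of a
100-replicate mean is unbounded once the mean itself approaches zero.
Integer half-lives from 100-replicate means carry roughly ±1 generation of
replicate variability; headline checks aggregate over three independent
runs.

`half_life` returns the first generation at which the replicate-mean
metric is at most half its t = 1 value, and `None` when the horizon never
reaches it (e.g. N = 500). The halving reference for the allele metric is
the plain A(1)/2.

## Bottleneck test

Equilibrium gene diversities conditioned on the observed allele count k
use Cornuet–Luikart conditioning: θ is tuned so E[K] = k (closed form via
the Ewens expectation for IAM; simulation bisection for SMM/TPM), then
replicates are rejection-conditioned on exactly K = k, with an acceptance
budget of 100× the requested iterations and a diagnostic error beyond it.
Under the IAM the conditional distribution given k is θ-free (K is
sufficient), so the tuning affects only acceptance efficiency; the
simulated conditional mean matches an exact Ewens-enumeration oracle in
the test suite. IAM samples come from Hoppe's urn, vectorised across
replicates; SMM/TPM from a Kingman coalescent with Poisson(θt/2) mutations
per lineage interval. TPM mutations are single-step with probability 0.70
and otherwise geometric multi-step with variance 30 (the conventional
variance-30 parameterisation; both exposed as flags), signs symmetric.

Per polymorphic locus DH = (Hₑ,obs − mean Hₑq)/SD(Hₑq) is reported. The
one-tailed Wilcoxon signed-rank across loci is computed on deviations
centred at the simulated *median*: the conditional Hₑq distribution is
left-skewed, and centring at the mean makes the excess test
anti-conservative (measured ~7–12% type-I at nominal 5% over 1000
equilibrium datasets, versus 3–5% with median centring). Default 1000
iterations per locus; simulated (k, genes) distributions may be cached
across populations since they depend only on the configuration. Fewer than
four polymorphic loci triggers a small-sample warning rather than a
refusal. The mode-shift indicator pools within-population allele
frequencies across loci into ten classes ((0–0.1], …, (0.9–1.0]) and
labels the population L-shaped iff the lowest class is modal.

The sign and standardised-differences tests of the original toolkit are
deliberately omitted: with ~10 loci the Wilcoxon is the only test with
usable operating characteristics.

## Climate-suitability utilities

These consume already-computed suitability values; distribution-model
fitting is out of scope. Cohen's κ comes from scikit-learn; the
κ-maximising threshold scans a regular grid with ties broken toward the
lower threshold. Niche overlap is |current ∧ future| / |current| at the
threshold — asymmetric by design, answering how much of today's suitable
area survives — with Schoener's D as a continuous companion. Δ-CSI is
100·(future−current)/current rounded half-away-from-zero to one decimal,
the rounding that reproduces every cell of the bundled published site
table; a zero current index is an explicit error. The bundled tables
(site coordinates and census sizes, per-site diversity summaries, CSI
values for 22 fragmented and 3 unmodified sites) ship as plain TSVs under
`fragdrift/data/`.

## Pipeline

`run_pipeline` executes dedup → stats → fst → ibd → bottleneck → simulate →
niche from one YAML/dict configuration, each stage seeded by a SHA-256
derivation from the master seed, halting on the first failure with the
stage named and prior outputs retained. The manifest records inputs,
parameters, seed, package version and a SHA-256 digest of every output;
reruns with the same configuration are bit-identical.

## Problem sizes used in the checks

Test and acceptance runs use the study-scale designs: 10-locus pools of
500, T = 200, R = 100 for simulations; 22 populations × 25 individuals for
structure recovery; 2000 pairs for relatedness recovery; 200 exchangeable
datasets for permutation calibration (B = 399/199); 200 equilibrium and
100 crash datasets for the bottleneck operating characteristics, with the
drift-law oracle on a 40-locus pool to tighten Monte-Carlo error. The full
suite runs in under two minutes on one CPU.

## Known limitations

* The drift simulator has no mutation, migration (beyond one-shot mixing),
  selfing, seed banks or overlapping generations; simulated erosion rates
  are upper bounds on fidelity to real demography.
* Relatedness estimators assume the reference sample is large and mostly
  unrelated; in small family-structured samples the estimates are relative
  to the sample's own gene pool.
* The SMM/TPM coalescent is per-replicate Python and noticeably slower
  than the vectorised IAM path; TPM bisection adds simulation noise to the
  θ tuning (the conditional distribution under stepwise models is not
  θ-free, so tuning accuracy matters there).
* The autocorrelogram's mean-dosage imputation of missing genotypes
  slightly shrinks genetic distances for incomplete individuals.
* GenePop population labels are a naming convention, not part of the
  format; files from other tools fall back to positional labels.
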