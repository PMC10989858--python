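# Methods

## The generative model

The unit of observation is the unordered genotype pair of two diploid
individuals *A* and *B* at one locus with allele frequencies *p₁…p_k*
(k ≥ 2, all strictly positive, treated as known).  The joint ibd state of
the four genes is a condensed Jacquard mode Δ₁…Δ₉.  A condensed mode that
realises an identity event for only some gene pairings is expanded
**uniformly at random** over its detailed configurations: which gene of *B*
joins the within-*A* triplet (Δ₃, two configurations), which of the two
cross pairings holds (Δ₇), which one of the four cross pairs is ibd (Δ₈).
Every ibd class of the resulting partition receives one allele iid from the
frequency vector.  This uniform expansion is not optional: it is what makes
the Δ → coefficient map carry the ½ and ¼ factors (e.g. R = Δ₁ +
(Δ₃+Δ₅+Δ₇)/2 + Δ₈/4), and it is validated by the simulator/probability-model
cross tests.

Because the Δ → coefficient map is affine and invertible, every class
probability is affine in the eight coefficients.  The closed-form class
polynomials in `genoprob` were derived symbolically (sympy) from the mode
enumeration and are checked against it at machine precision in the test
suite.  The enumeration (`mode_pair_spectrum`, `spectrum_from_delta`) is
retained as the independent oracle and is never used by the analytic path.

### Transcription discrepancies

Published transcriptions of the four-gene class formulas contain visible
corruption.  Differences between the printed forms and the symbolically
derived forms implemented here:

| class | printed | derived (implemented) |
|-------|---------|------------------------|
| f_iiii | — | matches verbatim |
| f_ijij | −F_AB inside the leading bracket | +F_AB (sign) |
| f_iijj | counts both orientations (2× this package's single-orientation class) | single orientation; convention only |
| f_iiij | R term (p_i+p_j−4p_ip_j); R_AB, G_A, G_B terms with p_j dependence | R term 2p_i(1−2p_i); no p_j dependence in R/R_AB/G terms |
| f_iijk | +p_i F_AB | −q_i F_AB |
| f_ijik | — | matches verbatim |
| f_ijkl (four distinct) | 1−4R−2F+4G−8H | 1−F_A−F_B−4R+4G_A+4G_B+F_AB+2R_AB−6H |

The generative definition is authoritative: each derived form telescopes
correctly at full identity (f_iiii → p_i), reproduces Hardy–Weinberg at the
null, and sums to 1 over every complete spectrum.

### Three genes

The triplet (A's two genes plus one gene of B) is a four-component identity
mixture: all three ibd (weight *G*), the within-*A* pair only (*F − G*),
each cross pair (*R − G*), no identity (1 − *F* − 2*R* + 2*G*).  Parameter
combinations that make any weight negative (e.g. *G* > *F*) produce negative
class probabilities and are rejected with the offending class named.

## Estimators

Per-allele moment components invert a single class:

* R̂_ii = (f_ii − p²)/(pq) on a single cross-individual gene pair;
* Ĝ_iii = (f_iii − p³ − p²q(F+2R)) / (pq(1−2p)) on a gene triplet, with
  F and R supplied (they are estimated from the two-gene level);
* Ĥ_i = (f_iiii − f_iiii|_{H=0}) / (pq(1−6pq)) on a genotype pair.

The observation unit always matches the number of genes the coefficient
concerns.  Components combine with weights minimising w′Vw subject to
Σw = 1, where V is the exact covariance matrix of the components computed by
enumeration under a prior (default: all coefficients zero).  At zero prior
the two-gene weights reduce to the closed form w_i = (1−p_i)/(n−1); for
three- and four-gene targets no closed form is published and the numerical
minimiser is used throughout.  Estimates are never truncated to [0, 1]:
unbiasedness requires an unbounded estimator, and the covariance-bearing
F_AB, R_AB may legitimately exceed pure-probability bounds under mixtures;
out-of-range values and non-estimable components are flagged.

Singularity structure (exact, not numerical): three-gene components vanish
at p = 1/2 (denominator pq(1−2p)); the iiii-pattern H component at
pq = 1/6 (p ≈ 0.211, 0.789); the joint closed-form solvers below at
p = 1/3.

### Joint closed-form solvers

The 2×2 system maps (H, F_ab) to the excess frequencies of the
double-homozygote classes (f′_AAAA, f′_AAaa); its determinant factors as
−2p³q(p−1)(2p−1)(p+q−1), so it is singular exactly at p = 1/2 or when no
third allele exists.  The 3×3 system maps (H, F_ab, R_abab) to
(f′_AAAA, f′_AaAa, f′_AAaa) with determinant −8p³q²(p−1)(3p−1)(p+q−1)²:
p = 1/3 is noninformative.  Published closed-form solutions of these systems
carry factor-of-2 transcription errors; both solvers are implemented as
exact linear solves of the printed forward matrices, which guarantees the
inversion identity the closed forms were meant to express.  The parameter
labels of the 3×3 system follow its solution row labels (H, F_ab, R_abab).

The 8×8 joint system solves all eight coefficients from the residuals of
eight chosen classes (iiii, ijij, iijj, iiij, ijjj, iijk, ijkk, ijik over an
allele triple).  Its design matrix is **not** singular at p = 1/3 — the
p = 1/3 statement belongs to the closed-form solvers above — but it is
singular whenever two chosen alleles share a frequency; singularity is
therefore decided numerically (|det| relative to the column-norm scale) and
reported with the offending frequencies, alongside the condition number.

### Classic identity-disequilibrium estimator

R̂_AB = (a·f_AAAA − b·f_AA,aa)/c with a = 6(6pq−2p−2q+1), b = 1−6pq,
c = 6pq(1−p−q)(1−3p).  f_AA,aa is the double-homozygote frequency expected
with no zygotic association; the sign of c (it changes sign at p = 1/3) is
reported with the estimate.

## Maximum likelihood

The likelihood is multinomial over genotype-pair classes, independent across
loci.  EM runs on the Δ simplex — the latent variable of each observation is
its identity mode, so the E-step is a posterior over nine modes and the
M-step a weighted average — guaranteeing admissible estimates and a
non-decreasing log-likelihood (asserted on every fit).  The fitted Δ maps to
the coefficients.  Defaults: |Δ log L| < 1e-8 or 5,000 iterations;
multi-start from uniform Δ, an unrelated-heavy start (Δ₉ = 0.9), and a
moment-derived start (the per-locus 8×8 solve, clipped to the simplex),
keeping the best final likelihood.  EM here converges slowly near
boundaries; non-convergence and boundary components (Δ < 1e-6) are flagged.
Probabilities are floored at 1e-300 only after structurally impossible
observed classes have been reported.

## Simulator

`simulate_dataset` draws modes, configurations and class alleles exactly as
the generative model prescribes (vectorised; byte-identical output for a
given seed).  `simulate_mixture` assigns each **pair** to one mixture
component for all its loci; sharing the component across loci is what
creates the across-locus covariance of homozygosity (identity
disequilibrium).  The canonical two-population model uses biallelic
frequencies p ± a mixed equally; its across-locus homozygosity covariance
equals the across-component variance of Σᵢ p_{m,i}², which
`mixture_moments` computes by brute-force expectation over components.  The
transcribed closed form a⁴ + 6a²p² for this quantity could not be verified
against the brute force (the enumeration gives exactly 4a²p² for the
across-component variance of the focal-allele homozygosity p_m², and
4a²(1−2p)² for total biallelic homozygosity) and is recorded here without
being asserted anywhere.

What the simulator does **not** emulate: linkage between loci, genotyping
error, allele-frequency estimation error (frequencies are known), and
pedigree-induced correlation of modes across loci within a pair (modes are
iid across loci given Δ).  Passing tests therefore demonstrate correctness
of the model and estimators under the model's own assumptions, not
robustness to those real-data features.

## Exact variances

`exact_estimator_variance` enumerates the observation unit (6–10 genotypes,
up to 100 genotype pairs), weights by exact class probabilities at the
stated truth, and reports the estimator's exact mean and variance; the mean
is asserted equal to the truth (unbiasedness is a computed fact, not an
assumption).  Weighting variants: minimum-variance (default), zero-prior
(1−p_i)/(n−1), equal, inverse-variance, single-allele.  Enumerated variances
are cross-validated against 200,000-pair simulations in the test suite and
against a fresh simulation inside the acceptance script.

The reference single-locus variance table is only partially identifiable
from its published form.  The G columns are exactly the single-pattern
component variances — Var(Ĝ_iii) = 73.50 at p = 0.6 and Var(Ĝ_iij) = 74.33
at (0.6, 0.3) for the array (0.6, 0.3, 0.1); 0.193 and 7.797 for the
four-allele array with alleles designated in ascending order — and the "x"
cells are the p = 1/2 singularity.  `variance_table` therefore reports the
G columns under that convention (focal allele pair, default the first two
listed).  No construction tried — minimum-variance, zero-prior, equal,
inverse-variance or single-allele weightings of the per-allele components;
centered-indicator cumulant estimators; the 2×2/3×3 closed-form solvers
applied to single-pair indicators; the full 8×8 joint solve — reproduces the
published F, pairwise and H columns; the table's remaining cells report this
package's minimum-variance weighted estimator variances, and the
discrepancy is left standing rather than fitted.

## Numerical conventions

* Frequencies validated to sum to 1 within 1e-6, then renormalised exactly;
  Jacquard vectors within 1e-8.
* Spectra sum to 1 within 1e-10 (asserted in tests at 1e-12 for the
  analytic/enumeration comparison).
* Estimator inversion identity holds to 1e-10 on expected spectra.
* Singularity of closed-form solvers: |det| < 1e-12 (their determinants are
  exact polynomial factors, so this is a clean zero test); 8×8 design:
  |det| < 1e-12 × column-norm scale.
* Tie-breaks: genotypes are sorted within individuals everywhere; class
  spectra serialise in lexicographic key order.
* Recovery-study problem sizes: 200 replicates of 30 loci × 500 pairs with
  EM tolerance 1e-6 and single start for the simulation study; 100,000
  pairs for mixture identity-disequilibrium checks; 200,000 pairs for
  enumeration/Monte-Carlo cross-validation.

## Known limitations

* Frequencies are treated as known; sample-estimated frequencies (the CLI
  default when no table is supplied) introduce bias not corrected here.
* No linkage, no multi-locus composite likelihood beyond independent-locus
  products, no information-matrix standard errors (Monte-Carlo only).
* The 8×8 solve needs three alleles with pairwise-distinct frequencies at
  the chosen triple; SNP data (two alleles, occasionally three) supports
  the two-gene and focal-allele joint estimators instead.
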