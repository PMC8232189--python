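# Methods

This note documents the models behind `ryeqtl`: what is simulated, what is
estimated, the numerical choices, and what the passing test suite does and
does not demonstrate about real data.

## Meiosis model

Gametes are generated under a Haldane crossover process: crossover counts
per chromosome are Poisson with mean (length in cM)/100, positions
uniform, no interference.  Because only marker loci are observable, the
implementation uses the exactly equivalent marginal form: the parental
origin of a gamete flips between adjacent markers with independent
probability `(1 - exp(-2d/100)) / 2` for an inter-marker gap of `d` cM.
This is a modeling choice, not an approximation — the joint distribution
of origins at the marker positions is identical to simulating explicit
crossover positions, and it vectorizes over tens of thousands of gametes.

Map *estimation*, by contrast, uses the Kosambi function, which admits
partial interference.  The deliberate mismatch (Haldane meiosis, Kosambi
estimation) mirrors common practice — the true crossover process of a real
organism is not the estimation model either — and the test suite documents
its size: the estimated length of a simulated 120 cM chromosome stays
within 15 % of truth at n = 178.

## Gametophytic selection and multivalents

Selection is implemented by rejection sampling, matching the biological
narrative of inviable gametes being discarded:

* **Pollen-side *Z* selection.** A pollen gamete carrying the B
  (self-incompatibility) allele at *Z* cannot fertilize in a selfing
  context; it is discarded and a fresh gamete drawn.  Egg gametes are
  never filtered (the pistil is diploid; its genotype, not its gametes,
  decides).  The expected F2 ratio at *Z* is therefore 1 AA : 1 AB : 0 BB.
* **Stigma-side *S5* selection.** Self-fertility at *S5* is dominant: a
  plant selfs iff it carries at least one A allele.  BB plants contribute
  no selfed offspring.  With equal family sizes per selfable parent, the
  pooled F3 segregates 3:2:1 (A:H:B) at *S5*, a 2:1 parental allele ratio.
* **Multivalent co-segregation.** The ring multivalent is modeled as
  whole-chromosome disjunction: each homologous pair of the ring
  contributes one intact chromosome, independently and equiprobably, and a
  gamete is viable only when all ring chromosomes derive from one parental
  species — giving the `2^(1-n)` viable fraction (25 % for three pairs).
  Crossover within ring chromosomes is suppressed in this mode.  This is
  the strongest-coupling idealization: it exists so the inter-chromosome
  correlation screen has a positive control with near-perfect correlation,
  while marginal per-marker segregation stays 1:2:1.  Real multivalents
  recombine distally, which would weaken the correlation signature; the
  screen's sensitivity to such intermediate regimes is not characterized.

## Phenotype model

Plot values follow the randomized-complete-block trial model
`y_ijkl = mu + g_i + l_j + r_jk + (gl)_ij + e_ijkl`, every random term an
independent normal draw.  The genotype value `g_i` is the sum of planted
marker effects (codominant effect per B-allele copy plus a dominance
effect for heterozygotes) and a polygenic residual `N(0, sigma2_g_res)`
not attached to any marker.  Default variance presets use the scale of a
perennial-rye field trial: perenniality (0–9 score, two locations x two
clonal replicates) with components 0.22 / 0.08 / 1.18 / 1.39 for
location / replicate / genotype-by-location / residual and total genetic
variance 3.72; fertility (0–100 %, one location) with replicate 2.6,
residual 94.9, genetic 313.7.  Scores are clipped to their bounded scales
after noise; the clip count is recorded in the truth record.  Clipping and
the Gaussian error model are simplifications: real ordinal 0–9 scores and
percentage scores are neither continuous nor homoscedastic across their
range, so calibration results here do not certify behavior on strongly
censored real data.

## REML machinery

Variance components are estimated by direct maximization of the
restricted log-likelihood over log-variances (L-BFGS-B, three starts,
non-negativity enforced by the log scale with a floor at 1e-8 of the
phenotypic variance).  Three evaluation paths give identical results where
they overlap (tested to 1e-6):

* a **generic dense path** (Cholesky of the n x n covariance) for
  arbitrary designs and for models with plot-level marker fixed effects;
* a **spectral path for balanced complete designs**: all relevance
  matrices share the Kronecker mean/contrast eigenbasis, so one likelihood
  evaluation costs microseconds.  Used for the standard variance-component
  and BLUE fits, making 200-fold simulation studies cheap;
* a **genotype-covariate path**: with fixed effects constant within
  genotype (markers), the restricted likelihood factors exactly into
  closed-form subspace terms plus a G-dimensional compound-symmetric model
  on the scaled genotype means — used for explained-variance refits at
  arbitrary population sizes.

Cheap paths get a Nelder-Mead polish (xatol 1e-10) so that nested models
agree to the 1e-6 level the tests require.  Standard errors come from the
inverse numerical Hessian of the restricted likelihood at the optimum;
components at the zero boundary report NaN standard errors.  On balanced
data with all estimates interior, REML reproduces the classical ANOVA
expected-mean-square estimators exactly — the test suite asserts this
against an independently coded closed-form oracle.

BLUEs come from the genotype-fixed fit; `av.VD` is computed exactly as
the mean over genotype pairs of the variance of a BLUE difference (equal
to `2(sigma2_gl/L + sigma2_e/(LR))` in the balanced case), and
`LSD = t(0.975, residual df) * sqrt(av.VD)`.  The entry-mean heritability
is `H^2 = sigma2_g / (sigma2_g + av.VD/2)`.  With the fertility-scale
components (313.7, 94.9; one location, two replicates) this evaluates to
0.87; with the perenniality components the balanced approximation gives
0.80 — the exact av.VD of the original unbalanced data is not recoverable
from printed components alone, so a printed 0.81 can only be approximated.

The bivariate model stacks two traits per plot, with unstructured 2x2
genotype and residual covariance (log-Cholesky parameterized, so positive
semi-definiteness is structural) and diagonal replicate covariance; no
location effect is fitted because only plots with both traits enter.
Balanced paired designs use a four-subspace diagonalization of the same
likelihood.  The genetic correlation and the explained genetic covariance
`p_CovG` derive from the genetic covariance component.

## Scans

Markers enter as codominant dosage (0/1/2) and dominance indicator
(0/1/0) fixed effects, tested sequentially: incremental Wald chi-square
for the dosage (1 df), then the dominance term (1 df), the combined test
summing both on 2 df.  The sequence is fixed; order matters for
incremental tests.  Variance components are estimated once per trait from
the cofactor-free model and the resulting covariance is held fixed for the
per-marker GLS tests (two-stage scanning, as in mixed-model association
practice).  When a genotype class is empty — e.g. no BB at a Z-linked
marker — the dominance column is collinear with the dosage column; the d
effect is reported inestimable with p_d = 1 and a flag rather than
silently reparameterized.  Optional random marker-by-location terms are
re-estimated per marker; a term estimated at the zero boundary is dropped
and flagged.

The genome-wide threshold is simpleM: alpha = 0.05 divided by the number
of leading eigenvalues of the marker correlation matrix (codominant
coding) needed to explain 99.5 % of the variation.  Under the strong
linkage of an intercross this effective number is far below the marker
count (about 130–190 for the default 791-marker panel at n = 178) and the
procedure is mildly anti-conservative; the test suite bounds the
genome-wide null rejection rate at 0.10 against the nominal 0.05.

Cofactor scans: CM1 takes, per chromosome, the most significant marker
passing the threshold in a cofactor-free scan, and drops own-chromosome
cofactors when testing a marker; CM2 runs a forward/backward stepwise
search on the BLUEs with Schwarz BIC (penalty log N per parameter),
deterministic with ties broken to the lower marker index.  The BIC entry
hurdle at n = 178 corresponds to a ~2.3 % false-entry chance per candidate
marker — the relevant null-behavior scale for judging selection results.
A tested marker's own redundancy group is always excluded from its
cofactor set, so a cofactor is never reported as its own QTL.

Support intervals follow the 1-unit log10(p) drop rule: extend outward
from the peak while -log10(p) stays strictly within 1 of the peak; the
first marker at or beyond the drop bounds the interval.

`p_G`, the explained genetic variance of a marker set, is the reduction
in the REML genotype variance when the markers' codominant-plus-dominant
fixed effects are added, divided by the base genetic variance; negative
estimates are truncated to zero and flagged.  For unlinked QTLs the joint
`p_G` equals the sum of single-marker values up to finite-sample marker
correlations of order 1/sqrt(n); the additivity test therefore runs at
n = 20,000 simulated genotypes, where the property holds within 0.02.

Epistasis scans fit the fixed sequence `m1_cd + m2_cd + m1_d + m2_d +
m1_cd:m2_cd + m1_d:m2_d + m1_d:m2_cd` (the asymmetric d:cd term also in
the swapped orientation as a parallel sequence), each term an incremental
1-df Wald test, at the ordered-pair threshold `0.05 / (q_eff (q_eff-1))`.
Interaction cells with no observations are flagged inestimable.

## Problem sizes in the test suite

Simulation-backed checks use: 200 trials for variance-component and
effect recovery (n = 178, 2x2 design); 100 independent null traits x 20
markers for Wald calibration; 100 trials for bivariate correlation
recovery; 20 full-genome null scans (791 markers) for the genome-wide
error bound; n = 10,000 individuals for segregation-ratio checks (3
binomial SE); n = 20,000 for explained-variance additivity.  These sizes
keep every Monte-Carlo standard error well inside the asserted tolerance.

## Known limitations

* Two-point mapping only; no multipoint HMM refinement and no
  genotype-error correction during map construction.  Chromosome
  orientation is anchored to the input order's first marker (reversal is
  statistically unidentifiable).
* The scan holds base variance components fixed per trait; this is
  slightly conservative for very large marker effects.
* The simulator's Gaussian, homoscedastic plot error and hard clipping
  are idealizations of bounded ordinal scores.
* No interval mapping between markers, no permutation thresholds, no
  spatial field-trend modeling, no tetraploid genetics.
* Whether real multivalent rings disjoin by the independent model assumed
  here is an open biological question; the 25 % figure is reproduced under
  that stated assumption.
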