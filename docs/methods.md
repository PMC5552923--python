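# Methods

## The model

`ricomp` analyzes interspecific crossing tables in which each row is one
cross — a maternal species crossed to a paternal species — scored for a
reproductive-isolation (RI) response in roughly [0, 1], together with
predictors such as genetic distance, geographic context (sympatry vs.
allopatry), geographic distance, or floral trait distances.  Because a
species typically appears in many crosses, rows are not independent:
crosses sharing a parent, or involving closely related parents, resemble
each other through shared evolutionary history.  The model is the linear
mixed model

    y = X beta + Z_f u_f + Z_m u_m + e,
    u_f ~ N(0, sigma2_f * A_f),   u_m ~ N(0, sigma2_m * A_m),
    e ~ N(0, sigma2_e * I),

with one structured random effect per parental role.  Separate maternal
and paternal effects are used because many datasets do not use every
species in both roles; restricting each incidence matrix Z to the taxa
observed in that role keeps it dense and the variance estimates precise.
An interaction between the two phylogenetic effects is deliberately not
modeled: cross designs rarely pair distantly related species, so such a
matrix would be extremely sparse and near-unidentifiable.

The canonical two-predictor form is

    y_RI = mu + x1*beta_gendist + x2*gamma_sym + (x1*x2)*beta_int + Z_f f + Z_m m + e

where x1 is the genetic distance of the pair and x2 the sympatry dummy
(0 = allopatric, the reference).  For allopatric pairs the model reduces
to `mu + x1*beta_gendist`; for sympatric pairs to
`(mu + gamma_sym) + x1*(beta_gendist + beta_int)`.  Hypotheses about
sympatric crosses therefore concern sums of coefficients, which are
computed per draw (`posterior.contrast`), never from point estimates.
Categorical predictors with more than two levels (e.g. flower-colour
classes) dummy-code with k-1 columns against a declared reference.

The response is modeled as Gaussian even though RI indices live in
[0, 1].  This is a deliberate choice: coefficients stay on the RI scale
and are directly interpretable (an RI change per unit genetic distance,
per km, etc.).  The cost is that fitted values can leave [0, 1]; no link
function is offered.

## Relatedness matrices

The structured matrix A can come from two sources.

* **Ultrametric phylogeny.** `A_ij = depth(MRCA(i, j)) / T`, the shared
  fraction of root-to-tip history.  Dividing by the total depth T makes
  A a correlation-scaled matrix (unit diagonal, off-diagonals in [0, 1]),
  so the variance components sigma2 are comparable across trees with
  different depth units.  The construction is PSD.  Non-ultrametric
  trees are rejected; `ultrametricize` extends pendant edges to the
  maximum depth — internal (shared-history) branches, which are what A
  encodes, are never altered, which is why proportional depth scaling
  was not used.
* **Pairwise genetic distances.** `A = 1 - D`, mirroring the relatedness
  convention that values near 1 mean close relatives.  This matrix is
  not guaranteed PSD and is often singular (identical taxa, ties);
  `stable_inverse` therefore returns the Moore-Penrose pseudoinverse
  (and flags it) whenever the smallest eigenvalue falls below the
  numerical rank tolerance `max_dim * eps * s_max`.  Distances above 1
  give negative relatedness, kept with a warning (a flooring flag clamps
  at 0).  An optional diagonal-bending escape hatch was considered and
  deliberately left out of the default path: the pseudoinverse matches
  standard practice for this model family, and bending changes the
  stated prior.

`graft_clade` splices a better-resolved donor phylogeny into a backbone
tree: the backbone clade spanned by the named tips is replaced by the
donor topology with all donor branch lengths multiplied by
(backbone clade depth) / (donor depth), so the grafted clade keeps the
backbone's depth and the result stays ultrametric.  Zero-length internal
branches (polytomies written with 0-length edges) are allowed; they
simply merge MRCA depths.

## RI indices

Per-barrier strength is `RI_k = 1 - het/hom` comparing heterospecific to
homospecific success at one stage (fertilization, hatching, ...).  Two
aggregations are provided because published datasets use both and the
choice affects the granularity of the response:

* **composite**: the unweighted mean, which with k equally scored
  barriers lives on a 1/k grid;
* **sequential**: `RI_total = 1 - prod_k(1 - RI_k)`, with absolute
  contributions `AC_n = RI_n * prod_{i<n}(1 - RI_i)` that sum to the
  total exactly.  Each barrier only removes gene flow surviving earlier
  barriers, giving a more continuous response.

Negative strengths (heterospecific advantage) are tolerated in the
composite but rejected by the sequential form, whose multiplicative
bookkeeping requires [0, 1].

## Priors and sampling

Fixed effects get a Gaussian prior N(0, B0).  Default B0 is
`1e8 * I` — effectively flat.  A "correlated" mode sets the
off-diagonal entries for pairs of non-intercept continuous columns to
`beta_scale * r_jk`, with r_jk the empirical correlation of those design
columns, acknowledging multicollinearity among predictors such as
genetic, geographic and floral distance.  The exact off-diagonal values
in such a prior are a genuinely open design choice; the empirical
correlation is one defensible parameterization and is clipped to the
nearest PSD matrix if necessary.

Each variance component has a scaled inverse-gamma prior with scale
`V = var(y)/3` — splitting the total response variance evenly across
the three covariance components (maternal, paternal, residual) — and
belief nu = 1 by default.  nu is exposed because posterior sensitivity
to it is real when the number of species per role is small.

Sampling is a systematic-scan Gibbs sampler with fully conjugate block
updates: a joint multivariate-normal draw of beta (which mixes well for
correlated predictors), multivariate-normal draws of each u given the
precomputed A^-1, and inverse-gamma draws of the variances with shape
`(nu + count)/2` and scale `(nu*V + quad)/2`, where the quadratic form
is `u' A^-1 u` for a role and `e'e` for the residual.  Variances are
floored at 1e-12 to prevent absorbing-zero degeneracy when q is tiny.
Defaults: 20 000 iterations, 5 000 burn-in, thinning 10, two chains
with distinct seeds and over-dispersed starts (OLS +/- 2 standard
errors, alternating sign per chain).  Everything is bit-reproducible
given the chain seed.

## Convergence and inference

Convergence is assessed with the Gelman-Rubin potential scale reduction
factor.  The classic estimator is used,

    R^2 = ((n-1)/n * W + (1 + 1/m) * B/n) / W,

without the Brooks-Gelman degrees-of-freedom correction (the correction
is a second-order term on chains of this length; the simpler estimator
is documented here so the delta is known).  The multivariate statistic
replaces B/W by the largest eigenvalue of W^-1(B/n).  A fit warns if
any univariate PSRF exceeds 1.1, the conventional bound; converged
desk-scale fits here typically give univariate values below 1.01 and
multivariate below 1.02.  Parameters with zero within-chain variance
are reported as 1.0 (trivially converged) unless the chains disagree,
in which case the PSRF is infinite and a warning fires.

HPD intervals are computed exactly on the draws: the shortest window of
`ceil(prob*n)` consecutive order statistics, leftmost on ties.  A
parameter or contrast is flagged significant iff its 95% HPD excludes
zero.  Posterior modes come from a Gaussian KDE with Silverman
bandwidth on the pooled draws (modes feed best-fit lines; the method is
a documented choice, not canonical).  Summaries pool chains only after
the PSRF gate.

## Synthetic data

The generator draws from exactly the model above, so recovery tests are
well-posed.  `simulate_yule` grows a unit-depth pure-birth tree (rate 1
per lineage, one extra waiting time after the last split, all branches
divided by the total depth).  `simulate_crossing_data` samples ordered
distinct species pairs with replacement — reproducing the
species-reused-across-crosses structure that motivates the random
effects — and sets the genetic-distance predictor to the patristic
distance over twice the tree depth (= `1 - A_ij` on a unit-depth
ultrametric tree).  In empirical datasets the distance predictor comes
from independent assays, not from the tree used for A; the patristic
default is a synthetic convenience.

Default truth (the moderate-signal regime): mu = 0.2,
beta_gendist = 0.5, gamma_sym = 0.25, beta_int = 0.4, species-effect
standard deviations 0.05 per role (variances 0.0025) and residual
standard deviation 0.1 (variance 0.01); sympatry ~ Bernoulli(0.5),
independent of distance by default (a `sympatry_depth_bias` option
links them for differential-fusion explorations, not used in tests).
Extra continuous predictors are drawn through a Gaussian copula: genetic
distance is rank-transformed to normal scores, the other coordinates
are drawn from the conditional Gaussian at the configured correlation
matrix and mapped through the normal CDF, so they are marginally
Uniform(0, 1) with approximately the configured correlation.

Responses are *not* clipped to [0, 1] by default — the fitted model is
Gaussian and clipping would bias recovery tests; a `clip` flag exists
for realism experiments.  What passing tests show is therefore that the
machinery is correct under its own assumptions; they do not certify
behaviour under boundary pile-up, assay heterogeneity, or misspecified
trees, all of which real crossing datasets exhibit.

## Problem sizes and numerical choices

Test and validation runs use desk-scale problems chosen to make each
check sharp rather than big: convergence protocol on 30 taxa / 150
crosses at the default run length; GLS-oracle comparison on 50 crosses
with variances held fixed (there the beta draws are exact GLS posterior
samples, compared within 2 Monte-Carlo standard errors using an
autocorrelation-adjusted effective sample size); conditional-moment
checks at 25 000-100 000 draws against closed-form means and standard
deviations; HPD against an exhaustive-window oracle on vectors up to
n = 2000; coverage calibration over 10 recovery and 20 null replicates
with 4 000-iteration chains (run length does not enter the coverage
property once chains converge, and these short chains are checked by
the same PSRF gate).  Ultrametricity is enforced to a relative
tolerance of 1e-6 of the tree depth; relatedness symmetry to 1e-8;
square-matrix asymmetry up to 1e-8 is accepted, up to 1e-3 symmetrized
by averaging with a warning, beyond that rejected.

## Known limitations

* Gaussian response: no bounded or transformed-response family.
* Univariate responses only: the multi-response (covariance-matrix V)
  generalization is out of scope.
* No random-slope terms and no interaction between the two phylogenetic
  effects.
* Taxon matching between table and tree is exact (after whitespace
  normalization); no fuzzy matching of subspecies/race labels.
* The 1-D relatedness route can yield an indefinite A; the pseudoinverse
  then defines an improper working prior for u.  The fit proceeds (as is
  standard practice) but users should prefer a phylogeny when one exists.
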