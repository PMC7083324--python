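# Methods

## Model and assumptions

`ehrssm` fits a linear Gaussian state-space model to irregularly observed
annual check-up panels. Per participant k, a p-dimensional latent state
x<sub>k,t</sub> evolves as x<sub>t</sub> = A x<sub>t-1</sub> + G z<sub>t-1</sub> + v<sub>t</sub>,
v ~ N(0, Q), and the q blood-test values observed at attended visits are
y<sub>t</sub> = H x<sub>t</sub> + w<sub>t</sub>, w ~ N(0, R). Q and R are
diagonal: all cross-trait dependence is carried by the latent state.
x<sub>k,0</sub> ~ N(μ<sub>k,0</sub>, Σ<sub>0</sub>) is a pre-observation
anchor; the first attended visit is assimilated at t = 1 after one
transition. The model assumes linear dynamics with Gaussian noise,
time-invariant parameters shared across participants (heterogeneity enters
only through μ<sub>k,0</sub> and each participant's own covariate path),
and exogenous environmental factors z — z is a known input, not a modelled
state.

Visit indices map calendar years onto an annual grid: t = year −
first_year + 1, so a participant attending 2009, 2010, 2013, 2014 occupies
t ∈ {1, 2, 5, 6} with T_k = 6. Skipped visits are handled by exact
marginalization: the filter's update step is omitted, which equals
integrating the missing y out of the joint Gaussian (verified against dense
joint-Gaussian oracles in the tests). Element-wise missingness within an
attended visit subsets the rows of H and R, valid because R is diagonal.

Two indexing conventions worth noting:

- The transition into t = 1 needs z<sub>0</sub>, which predates the first
  visit. It is backfilled from the first observed z; later gaps are carried
  forward (environmental factors are slow-moving annual survey items). The
  synthetic generator uses the same convention, so generative model and
  filter agree exactly.
- Diagonal entries of A are constrained to |A<sub>ii</sub>| ≤ 0.8 − 1e-6.
  The upper bound keeps single-dimension dynamics away from a random walk;
  the symmetric lower bound (toggleable via `a_lower_bound`) is a package
  choice made for symmetry, since only an upper bound is inherent to the
  formulation.

## Estimation

The penalized log-likelihood is log L(Y | θ) minus row-wise L1 penalties
λ<sup>(s)</sup><sub>i</sub>(‖a<sub>i</sub>‖₁ + ‖g<sub>i</sub>‖₁) on the
system rows and λ<sup>(o)</sup><sub>i'</sub>‖h<sub>i'</sub>‖₁ on the
observation rows. EM alternates:

- **E-step** — Kalman filter + RTS smoother, batched over participants
  (states and covariances carried as (K, p) / (K, p, p) stacks; participants
  are grouped per time step by observation pattern so each group shares one
  innovation factorization). Lag-one cross-covariances use the identity
  Cov(x_t, x_{t-1} | Y) = P<sub>t|T</sub> J<sub>t-1</sub>'. Covariance
  updates are in Joseph form with re-symmetrization; innovations go through
  Cholesky solves, never explicit inverses.
- **M-step** — each row of [A | G] minimizes (1/(2Q<sub>ii</sub>)) times its
  expected squared residual plus its L1 penalty. Weighting by the *previous*
  iterate's Q<sub>ii</sub> keeps the row problems separable; multiplying
  through turns each into a standard lasso with effective penalty
  λQ<sub>ii</sub>, solved by cyclic coordinate descent with
  soft-thresholding and an active-set outer loop (full sweep → iterate the
  support to convergence → re-sweep until the support is stable). The
  A<sub>ii</sub> box is enforced by clipping the scalar soft-threshold
  solution, exact for the convex one-dimensional subproblem. Q, R and
  μ<sub>k,0</sub> then update in closed form. Each block maximizes the
  penalized expected complete-data log-likelihood given the others, so the
  generalized-EM guarantee holds: the penalized objective is non-decreasing
  (asserted at tolerance 1e-6 per iteration; a violation raises, carrying
  both iterates).

Row-subproblem optimality is verified by KKT checks in the test suite and
cross-checked against scikit-learn's `Lasso` on equivalent regression
designs; the unpenalized M-step is checked against the classical
generalized-least-squares update.

**Initialization.** A = 0.5·I, H = top-p principal directions of the pooled
(mean-filled) panel with sign fixed by the largest-magnitude loading,
G = 0, Q = R = 0.5·I, μ<sub>k,0</sub> = 0. Restarts add seeded N(0, 0.1²)
perturbations to A, G, H (restart 0 is unperturbed).

**Convergence.** The stopping rule is relative: stop when the objective
improves by less than tol·(1 + |objective|). The likelihood surface has a
nearly flat direction — the latent scale is pinned only weakly through the
fixed Σ<sub>0</sub> = I against free per-participant μ<sub>k,0</sub> — along
which EM crawls; fits used for BIC comparison are therefore run to a fixed
iteration budget (60–150 iterations at tol 1e-5 in the shipped studies),
which truncates all candidate dimensions identically and leaves the BIC
ranking stable (selection margins on synthetic cohorts are an order of
magnitude larger than the truncation slack).

**Penalty scale.** λ enters on the raw log-likelihood scale, so useful
values grow with the number of pooled transitions (λ of order 30–1000 for
cohorts with ~10³ observed visits). λ = 0 recovers unpenalized maximum
likelihood; above the per-row kill threshold A, G, H are exactly zero.

## Model selection

BIC = −2 log L(Y | θ) + df(θ)·log ν with the *unpenalized* likelihood,
ν = number of observed participant-visits, and df = count of non-zero
entries of A, G, H, plus the p + q noise variances, plus the K·p initial
means. Counting μ<sub>k,0</sub> is deliberate: they are free parameters of
θ, and omitting them lets every extra latent dimension hand each
participant an uncounted free level, which empirically drives BIC to keep
falling past the true dimension; with them counted, synthetic searches
recover the generating dimension with a wide margin. An `include_mu0=False`
flag restores the smaller count. The search fits every p on a grid from
`n_restarts` seeded initializations (restart seeds derived from the master
seed by counter, so runs are bit-for-bit reproducible), records numerical
failures as data rather than crashes, and breaks ties on (BIC, seed).

## Scenario simulation and prediction errors

Counterfactual predictions are pure mean propagation with no data
assimilation: x̂<sub>0</sub> = μ<sub>k,0</sub>, x̂<sub>t</sub> =
A x̂<sub>t-1</sub> + G z<sub>t-1</sub>, ŷ<sub>t</sub> = H x̂<sub>t</sub>.
A scenario overrides chosen factors in raw units over a visit window; the
override is standardized through the cohort's stored normalization (all z
columns, including binary ones such as smoking status, are standardized to
pooled mean 0 / variance 1, so raw-unit overrides land on the model's
scale). Non-overridden factors follow the participant's actual carried-
forward path (or are frozen at baseline under `base="flat-last-observed"`).
An optional warm start (filter to a cut time, then propagate) exists behind
a flag-equivalent (`cold_start` anchors out-of-fit participants at 0); the
default anchors at the fitted μ<sub>k,0</sub>. Four lifestyle presets
(healthy/unhealthy × male/female body-composition and smoking profiles)
ship as YAML data. Trajectory stability is guarded by a spectral-radius
warning on A.

Prediction errors are observed − predicted at observed cells, on the
standardized scale (comparable across traits, which is what the genetics
stage needs); raw-unit trajectories are available via the stored
normalization.

## Genetic association

Per-participant trait values are the means over that participant's observed
visits (repeat check-ups would otherwise inflate significance), then
rank-based inverse-normal transformed with the Blom offset,
Φ⁻¹((rank − 3/8)/(n + 1/4)), ties averaged, offset configurable. Each
(SNP, trait, inheritance coding) is an OLS regression of the transformed
trait on genotype dose plus age and BMI (complete cases), with the
two-sided dose p-value. Codings: additive 0/1/2, dominant 0/1/1, recessive
0/0/1 of minor-allele count. The Bonferroni threshold divides α by the
number of SNPs only (matching the convention of a 915-SNP array → 5.46e-5);
a `strict_family` flag divides additionally by traits × models. Age is age
at first visit and BMI the participant's mean over observed visits; sex is
handled by stratifying the input cohort rather than as a covariate.
Monomorphic doses and undersized samples yield undefined (NaN) results, not
exceptions. No population-structure correction is attempted.

## Synthetic cohorts

The generator emulates the structure the method assumes: a sparse stable A
(diagonals U(0.3, 0.7), sparse off-diagonal couplings, rejection-sampled to
spectral radius < 0.95), a block H in which each latent factor drives one
contiguous trait cluster with loadings U(0.7, 1.3) (emulating lipid-panel /
red-cell-index clusters), and a sparse G with planted effects of magnitude
0.5–1.0 on the standardized scale. Covariates are slow AR(1) processes
(coefficient 0.9, stationary unit variance) plus sticky Bernoulli binaries
(initial rate 0.3, flip rate 0.05). Visits between the forced first and
last are thinned by an attendance probability (default 0.8 ≈ 20% missing
visits); element-wise dropout is available on top. Genotypes are
Hardy–Weinberg binomial(2, MAF) draws; causal SNPs add coded-dose × effect
to a trait's observation residuals. Defaults (p = 3, q = 9, m = 5 with one
binary factor, K = 150, T = 8, Q = R = 0.1) are a deliberately small but
realistic panel: three well-separated trait clusters, noise at about a
third of trait variance, and attendance irregularity typical of voluntary
annual check-ups.

What the generator does *not* emulate: real marginal distributions (skewed
lab values, detection limits), medication effects, informative missingness
(attendance correlated with health), time-varying dynamics, or linkage
disequilibrium between SNPs. Passing tests therefore demonstrate
correctness of the machinery and recoverability under the model's own
assumptions, not robustness to their violation.

## Numerical choices and degenerate inputs

- Covariances are re-symmetrized after every update; innovation Cholesky
  failures raise with the visit index.
- Noise variances are floored at 1e-10 in the M-step.
- Coordinate descent stops at per-coordinate change < 1e-10 with a sweep
  cap; non-convergence raises.
- Standardization uses pooled sample moments (ddof = 1) over non-missing
  cells; zero-variance or <2-value columns are errors naming the column.
- Spearman matrices mark cells with fewer than 3 complete pairs undefined;
  difference correlations use only consecutive-attended visit pairs.
- A cohort with no observed cells has log-likelihood 0 (empty product);
  BIC on an empty cohort is an error (ν = 0).
- Exclusion counts partition the input by construction and are checked.

## Problem sizes in the shipped studies

The acceptance studies use 25 random small instances (K ≤ 3, T ≤ 5, p ≤ 3,
q ≤ 4) for the likelihood oracle; ten K = 100 cohorts for EM monotonicity;
ten replicate K = 150, T = 8 cohorts with a 1..6 dimension grid and ten
restarts for model-order recovery; one K = 200 cohort and a four-point λ
path for support recovery; and K = 400 cohorts with 500 null SNPs / twenty
planted-effect replicates for association calibration and power. These
sizes were chosen as the smallest at which the respective effects are
comfortably resolved on a single CPU.

## Known limitations

- The latent scale/rotation is identified only up to the weak Σ<sub>0</sub>
  anchor; comparisons against a reference parameterization require the
  provided Hungarian alignment on |H| columns.
- λ is a user choice (optionally scored by BIC alongside p); no theory-based
  default is claimed.
- The EM tail is slow along the scale ridge (see above); reported objective
  values at a fixed iteration budget are slightly below the local optimum.
- Exact VCF support is minimal (biallelic, GT-only, unphased).
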