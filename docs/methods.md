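# Methods

## Problem and notation

A current study of size $n$ produces IID data $\mathcal D$ whose model is
indexed by $\omega = (\theta, \eta)$: $\theta \in \mathbb R^p$ is the
target of inference, $\eta \in \mathbb R^q$ stacks $K$ parameters for which
historical estimates $\hat\eta_1,\dots,\hat\eta_K$ exist, from independent
studies of sizes $m_1,\dots,m_K$ ($m = \sum_j m_j$). Users supply each
study's *finite-sample* covariance (squared standard errors, plus optional
within-study covariances); the $\sqrt{m_j}$-scale matrix is derived
internally as $\Sigma_j = m_j \cdot \mathrm{cov}_j$, because that is how
published studies report uncertainty. All asymptotic covariances in the
package live on the $\sqrt n$ scale; `per_study_scale` divides by $n$ to
recover finite-sample variances. The finite-sample plug-ins for the
limiting ratios are $\rho = n/m$, $\gamma = n/(n+m)$ and
$\kappa_j = m/m_j$.

Interchangeability is assumed throughout: historical and current units are
drawn from one population, so differences in response are attributable to
treatment alone. Heterogeneous (random-effects) borrowing is out of scope.

## Estimators

*Plug-in.* When $\mathcal D$ identifies only $\theta$, solve
$\Psi(\theta,\hat\eta)=0$, $\Psi = n^{-1}\sum_i \psi(\theta,\eta,Y_i)$.
The limiting covariance has $\theta$-block
$D_\theta^{-1}[\Sigma_\psi + \rho D_\eta\Sigma D_\eta^T]D_\theta^{-T}$;
the second term, the plug-in penalty, decomposes across studies as
$\rho\sum_j \kappa_j D_j \Sigma_j D_j^T$ and vanishes as $\rho \to 0$.
If the data would support re-estimating $\eta$, a warning notes that the
plug-in analysis is asymptotically inferior.

*Two-step.* Solve $(\Psi,\Gamma)=0$ jointly for
$(\tilde\theta,\tilde\eta)$ with sandwich covariance $\tilde\Upsilon$,
pool $\bar\eta$ by inverse-variance (GLS) weighting of $\tilde\eta$ and
$\hat\eta$, and re-solve $\Psi(\theta,\bar\eta)=0$. The pooling weights
$W_1, W_2$ satisfy $W_1 + W_2 = I$ exactly; the $\eta$-block of the
limiting covariance is the pooled kernel
$(\Upsilon_{\eta\eta}^{-1} + (\rho\Sigma)^{-1})^{-1}$, which is dominated
by both information sources and is monotone in $\rho$.

*Summary combination.* When only $(\tilde\theta,\tilde\eta,\tilde\Upsilon)$
are available, $\bar\theta_C = \tilde\theta - R(\tilde\eta - \bar\eta)$
with $R = \tilde\Upsilon_{\theta\eta}\tilde\Upsilon_{\eta\eta}^{-1}$. Its
covariance is computed twice — once as $MVM^T$ with the weight-matrix
representation, once from the closed-form blocks — and the two routes are
asserted to agree to $10^{-10}$; a disagreement raises, flagging an
implementation bug rather than a data problem. In small samples a poorly
estimated $R$ can make the combination worse than the current-only
estimator; the package quantifies this only through the Monte-Carlo
harness.

*Augmented system.* The one-shot alternative augments the $\eta$-equation
with the pseudo-score of the normal approximation to the historical
estimate. The augmentation $m\hat\Sigma^{-1}(\hat\eta-\eta)$ is a
sum-scale quantity; since the package's estimating functions are
per-observation averages, the implemented equation is
$\Gamma(\theta,\eta) + (m/n)\hat\Sigma^{-1}(\hat\eta - \eta) = 0$. The
historical $\hat\Sigma$ is used as supplied, not re-estimated. In linear
normal models the augmented and two-step solutions coincide exactly
*when pooling uses the model/design-based $\Upsilon_{\eta\eta}$* (both
reduce to the same GLS problem); with the default empirical sandwich they
differ by $O_p(n^{-1})$, which the test suite checks as a rate property.
`estimate_type_b` therefore accepts an `upsilon` override for
known-variance designs.

## Numerical choices

- Root solving: damped Newton with a central finite-difference Jacobian,
  step-halving line search (up to 30 halvings), tolerance $10^{-10}$ on
  $\lVert F\rVert_\infty$, at most 100 iterations. All systems in scope are
  smooth and low-dimensional; affine systems converge in one step.
- Finite differences: central scheme with step
  $h = \sqrt{\varepsilon}\,\max(1,|x|)$, used identically for Jacobians,
  sandwich breads and delta-method gradients.
- Limit matrices ($D_\theta$, $D_\eta$, $\Sigma_\psi$) are sample averages
  at the plugged-in parameter values — standard sandwich practice.
- Matrix inverses are linear solves; every symmetric result is
  re-symmetrized as $(M+M^T)/2$. Positive definiteness of user-supplied
  covariances is checked by Cholesky and failures name the offending study.
- Loewner comparisons use a relative tolerance: $V_1 \preceq V_2$ is
  declared when the smallest eigenvalue of $V_2 - V_1$ is at least
  $-10^{-8}\max(1,\mathrm{tr}\,V_2)$.
- Warm starts: the plug-in and second-step solves start from the joint
  solution when available, else from the user's initial value, else zeros.

## Factorial application

The 2×2 trial has mean structure
$E(Y\mid T_1,T_2) = \eta_0 + \eta_1 T_1 + \eta_2 T_2 + \theta T_1T_2$ with
homoscedastic variance $\sigma^2$. The two historical studies share the
control mean $\eta_0$, so they are pre-aggregated before entering the
general machinery: the control arms are pooled by size weighting and the
covariance of the reconstructed $(\hat\eta_0,\hat\eta_1,\hat\eta_2)$
follows from the explicit linear map of four independent arm means (in the
balanced equal-size case it is
$\sigma^2[[2,-2,-2],[-2,6,2],[-2,2,6]]$). The design covariance
$\Upsilon(\xi)$ is likewise built from the defining contrasts of the four
arm means with variances $\sigma^2/\xi_{ij}$ — this construction is
manifestly symmetric under relabeling the two treatments, which resolves an
asymmetry in one commonly printed form of the matrix.

The optimal-design search is an exhaustive grid over
$(\xi_{10}, \xi_{11})$ with $\xi_{01}=\xi_{10}$ (optimal under a symmetric
historical covariance; an `allow_asymmetric` escape hatch searches the full
simplex at a coarser step) and $\xi_{00} = 1 - 2\xi_{10} - \xi_{11}$
constrained to at least 0.02 — the design covariance is singular at
$\xi_{00}=0$, and the floor is a configurable default rather than a
constant. Step size defaults to 0.001; the $\eta$-kernel does not involve
$\xi_{11}$, so the search vectorizes into batched 3×3 inversions and runs
in about a second. Ties are broken toward larger $\xi_{11}$, then larger
$\xi_{10}$, for determinism.

The three-arm (no-control) design pools the two single-treatment arm means
$S$, with $E(S) = A\eta$, against the historical estimate via the linear
GLS formula; as $\xi_{01}=\xi_{10}\to 0$ its variance rises to the plug-in
value $\sigma^2(1+10\rho)$, so for small $\rho$ the all-combination design
is effectively optimal.

## Drug-interaction application

Under Bliss independence the combination's no-effect probability is
$\theta = \eta_1\eta_2$; the interaction is measured by
$\Phi = \log\theta - \log\eta_1 - \log\eta_2$ with large-sample variance
$\frac{1}{n_{12}}\frac{1-\theta}{\theta}
+ \frac{1}{n_1+m_1}\frac{1-\eta_1}{\eta_1}
+ \frac{1}{n_2+m_2}\frac{1-\eta_2}{\eta_2}$.
Design evaluation plugs in $\hat\eta_1, \hat\eta_2$ and
$\theta = \hat\eta_1\hat\eta_2$ — the estimate under the independence
null — with no shrinkage or continuity correction. The objective is
separable in the three integer counts with strictly decreasing marginal
gains, so the greedy allocator (assign each unit to the arm with the
largest variance reduction; the first unit is forced into the combination
arm, where the variance is otherwise infinite) attains the exact integer
optimum; the test suite confirms this against exhaustive enumeration. The
optimum need not be unique — ties are broken combination arm first, then
arm 1, then arm 2. Because greedy paths are nested in $n$, the smallest
study size at which a historical arm is replicated ($n_{\min}$) is read off
a single greedy trace. Counts are integers throughout; no continuous
relaxation is returned.

## Synthetic data and Monte-Carlo validation

The generators emulate the assumed models exactly: normal outcomes with
the factorial mean structure and arm counts $\mathrm{round}(n\xi)$ (an arm
with positive fraction that rounds to zero is an error), and binomial
no-effect counts for the interaction study. Historical data are two
balanced single-treatment studies of $m/4$ units per arm, analysed as a
real meta-analysis would be: arm means, a pooled residual-variance
estimate, and the back-calculated covariance — the *estimated* covariance,
not the oracle, is what flows downstream. Randomness is organized as one
generator stream per replication, derived from `(seed, rep)`, so
replications are order-independent.

For the normal model the arm means and within-arm sums of squares are
sufficient statistics with exactly known distributions (normal, scaled
chi-square), so the Monte-Carlo harness draws them directly instead of raw
observations; this is distributionally identical and keeps thousands of
replications inside seconds. Default problem sizes — 2000 replications at
$n = m = 400$ for the exact-variance check and $n = m = 1000$ for
coverage — were chosen so that three jackknife Monte-Carlo standard errors
give informative windows. Acceptance windows are 3 MC-SE throughout; the
theory proves limits, not finite-$n$ bands, so the windows must come from
the simulation itself.

What passing these checks does and does not show: the generators match the
assumed models perfectly — IID sampling, exact normality or binomial arms,
homoscedasticity, perfectly interchangeable populations. Real data deviate
from all of these; the Monte-Carlo results validate the formulas and the
code, not robustness to model misspecification, dependence, or
between-study heterogeneity.

## Known limitations

- IID current data only; no clustered/longitudinal meat corrections.
- Historical parameters must be distinct across studies; overlapping
  parameters (like the shared control mean) must be pre-aggregated, as the
  factorial module does.
- No automatic differentiation: derivatives are numerical, so extremely
  ill-scaled estimating functions may need user-supplied scaling.
- Small-sample behaviour of the summary-combination estimator (noisy
  regression matrix $R$) is surfaced only through simulation, not
  corrected.
- A printed variant of the design covariance and of the three-arm noise
  matrix order the two treatment labels inconsistently; the implementation
  derives both from the explicit linear maps, which is label-symmetric.
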