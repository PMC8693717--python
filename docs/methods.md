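# Methods

## The model

For a continuous phenotype $Y$ measured on $n$ subjects together with $q$
environmental exposures $E$, $m$ clinical covariates $C$ and $p$ genetic
measurements $X$ (continuous expression or 0/1/2 allele dosages), the
package fits one small regression per gene $j$:

$$
Y_i \;=\; E_i\alpha + C_i\gamma + X_{ij}\beta_j + \tilde W_i \eta_j
          + \epsilon_i ,
\qquad \tilde W_i = (X_{ij}E_{i1},\dots,X_{ij}E_{iq}),
$$

so each gene contributes one main-effect coefficient $\beta_j$ and $q$
gene–environment interaction coefficients $\eta_{j1},\dots,\eta_{jq}$.
This *marginal* formulation scans the genome one gene at a time — the
standard paradigm in G×E association work — rather than fitting one joint
model over all $p$ genes.

## Robust likelihood (Bayesian LAD)

Phenotypes in genetic epidemiology are frequently heavy-tailed or
contaminated.  The robust samplers assume Laplace errors,
$f(\epsilon\mid\tau) = \tfrac{\tau}{2}e^{-\tau|\epsilon|}$, the Bayesian
analogue of least-absolute-deviation regression.  Using the
Kozumi–Kobayashi scale-mixture representation at quantile level
$\theta=\tfrac12$,

$$
\epsilon_i = \tau^{-1/2}\,\xi_2 \sqrt{v_i}\, z_i,
\qquad v_i\mid\tau \sim \mathrm{Exp}(\tau),\quad z_i\sim N(0,1),
\qquad \xi_2^2 = \tfrac{2}{\theta(1-\theta)} = 8 ,
$$

every full conditional becomes conjugate: coefficients are normal given
the latent scales, $\tau$ is Gamma, and $1/v_i$ is inverse-Gaussian.  The
machinery supports general $\theta$ through $\xi_1,\xi_2$, but only the
LAD case is exercised.

## Sparsity: spike-and-slab over the Bayesian LASSO slab

The genetic coefficients carry two-component priors,

$$
\beta_j \mid s_1,\pi_1 \sim (1-\pi_1)\,N(0,s_1) + \pi_1\,\delta_0,
\qquad
s_1 \mid \varphi_1^2 \sim \mathrm{Exp}(\varphi_1^2/2),
$$

and analogously for each $\eta_{jk}$ with $(s_{2k},\pi_2,\varphi_2^2)$.
Integrating the exponential mixing density makes the slab a Laplace
(Bayesian LASSO) prior; the point mass yields exact zeros and a posterior
inclusion indicator per effect.  Conjugate hyperpriors close the
hierarchy: $\pi_1,\pi_2\sim\mathrm{Beta}(1,1)$,
$\varphi_1^2,\varphi_2^2,\tau \sim \mathrm{Gamma}(1,1)$, and $N(0,1)$
priors on $\alpha_k,\gamma_t$.  All prior constants default to 1.

The spike probability of a coefficient given the rest is

$$
l \;=\; \frac{\pi}{\pi + (1-\pi)\, s^{-1/2}\sigma\,
        \exp\{\mu^2/(2\sigma^2)\}},
$$

with $(\mu,\sigma^2)$ the slab conditional's moments.  The exponent
overflows for strong signals, so $l$ is evaluated in log space as a
sigmoid of the log odds; this changes nothing analytically.

The conditional for a slab variance $s$ is Exponential(rate
$\varphi^2/2$) when the coefficient is exactly zero, and otherwise
$1/s \sim \mathrm{IG}\!\big(\sqrt{\varphi^2/c^2},\, \varphi^2\big)$ in the
(mean, shape) parametrization with density
$\propto x^{-3/2}\exp\{-\lambda(x-\mu)^2/(2\mu^2x)\}$.  Similarly
$1/v_i \sim \mathrm{IG}\big(\sqrt{2\xi_2^2/r_i^2},\, 2\tau\big)$ with
$r_i$ the current residual.  Two guards handle conditionals that are
improper at isolated points: $r_i^2$ is floored at $10^{-12}$ and
$|c|$ at $10^{-10}$.

The mixing-weight conditionals are $\pi_1\sim\mathrm{Beta}(r_1 + 1 -
I(\beta\neq0),\, u_1 + I(\beta\neq0))$ and, counting $k$ nonzero
interactions among the $q$ slots,
$\pi_2\sim\mathrm{Beta}(r_2 + q - k,\, u_2 + k)$ — the conjugate
Beta–Bernoulli count update implied by the $q$-component mixture prior.

## The four samplers

| name    | likelihood       | genetic prior      |
|---------|------------------|--------------------|
| LADBLSS | Laplace (LAD)    | spike-and-slab     |
| LADBL   | Laplace (LAD)    | Laplace (no spike) |
| BLSS    | Gaussian         | spike-and-slab     |
| BL      | Gaussian         | Laplace (no spike) |

The Gaussian-likelihood variants drop the latent scales: observation
weights become $1/\sigma^2$ and $\sigma^2$ has a conjugate
Inverse-Gamma(1, 1) conditional.  This is the package's own construction
of the comparators, the canonical Gaussian hierarchy that parallels the
LAD one (coefficient priors and hyperpriors unchanged).  The no-spike
variants are realized by pinning $\pi_1=\pi_2=0$ inside the *same*
sampler, which reduces every coefficient conditional to its slab and —
deliberately — leaves the RNG call sequence untouched, so LADBL is
bit-for-bit the pinned LADBLSS chain.  The test suite relies on this
reduction.

### Sweep order and implementation

One sweep updates, in fixed order: each $\alpha_k$, each $\gamma_t$,
$\beta_j$, each $\eta_{jk}$, $s_1$, each $s_{2k}$, $\varphi_1^2$,
$\varphi_2^2$, $\pi_1$, $\pi_2$, then $\tau$ and $v$ (or $\sigma^2$).
The scan order is a free choice (any systematic scan is valid); fixing it
gives reproducibility.  Partial residuals follow the usual
leave-one-coefficient-out convention and are maintained incrementally.
Regression parameters initialize at 1 (the protocol's stated starting
value); unstated latents start at neutral values ($v_i=s=\tau=\varphi^2=1$,
$\pi=1/2$).  No thinning is applied.  Predictors are used as provided —
no internal centering or scaling.

Because the $p$ marginal models share no parameters, the engine stacks
them along a trailing gene axis and advances all of them in one
vectorized sweep.  The sweep's fused einsum arithmetic makes exactly the
same sequence of RNG calls as the straightforward composition of the
public update functions, and a test asserts bit-equality of the two
paths; a full 500-gene scan at the default 10,000 iterations runs in
roughly two minutes on one core.

## Selection and evaluation

For spike methods, each effect's score is its posterior inclusion
probability $p_j = H^{-1}\sum_h \phi_j^{(h)}$ over the $H$ stored sweeps.
For no-spike methods an effect is "identified" at credible level $c$ when
its equal-tailed $c$-interval excludes zero; its ranking score is the
average identification over the level grid 0.01–0.99 (step 0.01).
Posterior medians estimate coefficients.

Sweeping the cutoff (inclusion-probability grid 0–1 in 101 steps, or the
credible-level grid) against simulation ground truth yields TPR/FPR and a
trapezoidal AUC anchored at (0,0) and (1,1); selection is strict
(`score > cutoff`), so nothing is selected at cutoff 1.  Top-$k$ counts
the true signals among the $k$ highest-scoring candidates of a kind,
with ties broken by larger |posterior median| and then by index.  Both
grids are fixed constants so the AUC is reproducible; when the cutoff set
contains every distinct score the AUC equals the Mann–Whitney pairwise
concordance exactly, which the tests verify.

## Convergence diagnostics

The potential scale reduction factor is computed per parameter from three
overdispersed chains (regression initials 1, 0, −1) using the
Gelman–Rubin between/within variance ratio with the Brooks–Gelman
degrees-of-freedom correction and its upper 97.5% limit; the decision
rule is PSRF ≤ 1.1.  Identical chains sit at the finite-sample floor
$\sqrt{(L-1)/L}\approx1$ and zero-variance chains are reported as the
defined limit 1.  PSRF targets the main/interaction coefficients and
$\tau$; the $n$ latent scales are nuisance quantities and excluded.

## Simulated study conditions

The generator reproduces the study design: $n=200$, $p=500$, $q=4$,
$m=3$; $E$ and $C$ multivariate normal with unit marginals and AR(1)
correlation $\rho=0.5$; 8 true genetic main effects and 12 true
interactions; all nonzero coefficients (environmental, clinical, genetic,
interaction) drawn iid from Unif[0.1, 0.5]; five error laws — N(0,1),
t(2), LogNormal(0,2) (log-scale variance 2, not centered), and 90/10 and
80/20 normal–Cauchy mixtures.  Genetic designs: continuous AR(1)
expression (setting 1); SNP codes from quartile trichotomization, value
< Q1 → 0, in [Q1, Q3) → 1, ≥ Q3 → 2 (setting 2); and SNPs with pairwise
LD built from haplotype frequencies $p_{AB}=q_1q_2+\delta$ etc., with
$\delta = r\sqrt{q_1(1-q_1)q_2(1-q_2)}$, Hardy–Weinberg genotypes at the
first locus and per-haplotype conditional allele draws thereafter
(settings 3; MAF 0.3, $r=0.6$).  SNP codes enter the regression as
additive 0/1/2 dosages.

Open choices, decided once and exposed in `SimConfig`:

* **Effect-size law for G/G×E.**  Unstated in the protocol; the default
  keeps the same Unif[0.1, 0.5] used for $E$/$C$.  Note this implies
  roughly a quarter of true effects have marginal associations too weak
  to detect at $n=200$, which caps achievable AUC well below 1 (see
  "What the synthetic data do and do not show").
* **Truth placement.**  True main effects occupy the leading genes
  1–8 ("block", the bookkeeping convention of this simulation
  literature), interactions sit on the main-effect genes first (weak
  hierarchy friendly, one random environmental slot each) with the
  surplus on genes 9–12; `truth_placement="random"` scatters them.
* **LogNormal errors** are not centered (median 1); the model has no
  intercept, so LAD absorbs nothing — this is deliberate and matches the
  stated error law.

## Study orchestration

`run_study` crosses methods × replicates for one setting/error cell,
evaluates AUC (all $p(1+q)$ candidates pooled) and Top-100 per kind, and
writes per-replicate plus mean/sd summary CSVs.  Replicate and method
seeds derive deterministically from the base seed via `SeedSequence`, so
re-runs reproduce outputs exactly.  One RNG stream drives all genes of a
(replicate, method) fit — the batched sweep *is* the serial execution, so
there is no parallel/serial discrepancy to reconcile.  The OLS prescreen
used on real data keeps a gene when at least two of its $1+q$ genetic
coefficients have two-sided $p<0.05$ in the marginal linear fit.

Default problem sizes for the acceptance runs: AUC-only designs use
$p=100$ with 3 replicates; Top-100 designs need the full 500-gene pool
and use $p=500$ with 1–2 replicates; the 10,000-iteration / 5,000-burn-in
protocol is never reduced.

## What the synthetic data do and do not show

The generator emulates the structure of cohort SNP data (continuous
phenotype, 0/1/2 dosages, a handful of exposures) but not allele-frequency
spectra, missingness, population stratification, or non-linear
interactions.  Passing the simulation gates shows the samplers rank
truly associated effects far above null ones and that the LAD likelihood
retains that ranking under gross contamination where the Gaussian
variants collapse; it does not certify calibration of inclusion
probabilities on real cohorts.

Two quantitative caveats, established with an oracle analysis during
development: under iid Unif[0.1, 0.5] effect draws, (i) any marginal
statistic — Bayesian or frequentist — is information-bounded near AUC
0.85–0.95 because each marginal model carries the other ~19 true effects
as extra noise (the marginal $t$-statistic saturates near
$\sqrt{n/(19\cdot\mathrm{E[term\ var]})}\approx 3$ at $n=200$ no matter
how large a common effect size is), and (ii) the replicate-to-replicate
spread of AUC is dominated by how many weak effects a replicate happens
to draw.  Reported reference values near AUC 0.99 with sd $\sim$0.003
therefore imply a stronger, stabler effect-size law than the one adopted
here; the evaluation gates treat method *orderings* as the robust,
reproducible signal and report absolute cells with that caveat.

## Known limitations

* Quantile levels $\theta\neq\tfrac12$, binary/survival outcomes, and
  strong-hierarchy refitting are out of scope.
* The no-spike methods' credible-interval selection depends on the level
  grid only through a fixed, documented constant.
* The comparator hierarchy (BL/BLSS) is the package's canonical
  construction; other Gaussian-LASSO parametrizations (e.g. scaling the
  coefficient prior by $\sigma^2$) would differ in small samples.
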