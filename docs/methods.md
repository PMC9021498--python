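# Methods

## The models

The package estimates latent interdependence models for *round-robin*
psychometric data: every member of an `n`-person group rates every other
member on `T` continuous items, the items partitioning into `L` subscales
(trait dimensions) of `I` items each.  A directed response of sender `S`
about receiver `R` on item `i` (measuring dimension `l`) is modeled as

    Model 1:  y_iSR = beta0 + betaS_i * theta_S[l] + betaR_i * theta_R[l] + xi_i
    Model 2:  y_iSR = beta0 + betaS_i * theta_S[l] + betaR_i * theta_R[l]
                            + betaD_i * E_SR + xi_i

with `xi_i ~ N(0, sigma_i^2)` independent across directed responses, and
`E_SR = ||theta_S - theta_R||` the Euclidean distance between the two
members' full `L`-dimensional trait vectors.  Each person has one trait
score per dimension, used in both the sender and the receiver role; an
item's loadings (`betaS_i`, `betaR_i`, and under Model 2 the penalty
`betaD_i < 0`) are shared by all dyads.  Model 1 is Model 2 with all
`betaD_i = 0`.

Identification: receiver effects are positive with unit prior scale,
trait rows have a unit-diagonal equicorrelation covariance (off-diagonal
`rho_theta`), and the sender-receiver effect dependence is carried by the
regression slope `lam` of `betaS` on `betaR` together with the marginal
sender scale `sigma_bS`, giving `rho_beta = lam * sigma_bR / sigma_bS`.

### Residual structure

Within a dyad the two directed residuals are modeled as independent,
matching the likelihood that factorizes over both column vectors of the
dyadic response matrix.  A shared-residual reading (equal residuals for
the two directions of a dyad) would contradict that factorization and is
not implemented.

### Priors (defaults)

| parameter | prior | note |
|---|---|---|
| `beta0` | N(0, 10) | second argument is a **variance** throughout |
| `betaR_i` | N(0, 1) truncated to (0, inf) | `sigma_bR = 1` fixed |
| `betaS_i | betaR_i` | N(`lam * betaR_i`, `sigma_bS^2 - lam^2`) | coherent bivariate-normal conditional |
| `lam` | N(0, 1000), `|lam| < sigma_bS` | |
| `sigma_bS` | U(1, 1000) | marginal sender-effect scale |
| `-betaD_i` | Lognormal(0, 10) | log-scale variance 10 |
| trait rows | N(0, equicorr(`rho_theta`)) | unit variances |
| `rho_theta` | U(0, 1) | |
| `1/sigma_i^2` | Gamma(0.01, 0.01) | |

`PriorSpec(scales_are_precisions=True)` switches the scale-type second
parameters to the precision convention of BUGS-family samplers.  The
conditional SD of `betaS` given `betaR` is taken as
`sigma_bS * sqrt(1 - rho_beta^2)` — the only reading that makes the
hyperparameters a coherent bivariate-normal system; writing `sigma_bR`
in that position would be dimensionally inconsistent with the marginal
constraint `sigma_bR = 1`.

## Estimation

Posterior sampling is a Gibbs-within-slice scheme JIT-compiled with
numba.  Conjugate updates: grand mean and sender effects (normal),
receiver effects (truncated normal — positivity holds by construction),
residual precisions (gamma), and trait rows under Model 1 (bivariate
normal).  Slice updates (stepping-out, Neal-style): distance effects on
the scale `g = log(-betaD)` (the lognormal prior is exactly normal in
`g`), trait coordinates under Model 2 (the distance term breaks
conjugacy), `rho_theta` inside (0, 1), and the hyperparameters `lam` and
`sigma_bS` inside their joint support.  No step-size adaptation is
needed; `FitConfig.adaptation` sweeps are folded into burn-in for
compatibility with configurations that specify them.

One non-obvious but essential move: a Metropolis *reflection* proposal
that negates an entire trait column together with its subscale's sender
effects.  The receiver-positivity constraint makes the reflected
configuration improbable rather than impossible, and coordinate-wise
updates cannot cross between the two configurations; without this move
chains started on the wrong side stay there (R-hat well above 6 in
testing).  The proposal is a valid involution and leaves the posterior
invariant.  Sign alignment across chains is thereby achieved by the
sampler itself, not forced in post-processing.

Chains start from mildly overdispersed points (traits and sender effects
from unit normals, receiver effects from folded normals, data-centered
grand mean); fully prior-drawn starts are impractical because the
hyperpriors are diffuse by design.  Each chain's RNG seed derives
deterministically from `FitConfig.seed` via `SeedSequence`, so every fit
is exactly reproducible.

Default configurations: 4 chains x 3,000 sweeps (1,000 burn-in) for
interactive use; `FitConfig.reduced()` (2 chains x 1,300 sweeps, 500
burn-in) for replicated recovery studies, where the posterior-mean Monte
Carlo error (~0.02 on a trait score) is negligible against posterior
spread; `FitConfig.reference_settings()` (2 chains x 100,000, 50,000
burn-in, thinning 2) for definitive single fits.  Convergence is
summarized by the classic potential-scale-reduction factor and a
Geyer-truncated autocorrelation ESS (pooled across chains, capped at the
total draw count); these textbook estimators — not the rank-normalized
split variants of modern libraries — are implemented directly so they
can be verified against their defining formulas, and are cross-checked
against arviz in the test suite.

EAP estimates are posterior means over all retained draws, chains
pooled.

## Synthetic-data generator

`SimConfig` defaults encode the reference study conditions: `L = 2`
trait dimensions measured by `I = 4` items each, network sizes 5-100,
and truths drawn per replication as `beta0 ~ N(0,1)`; `betaR_i ~ N(0,1)`
truncated positive; `betaS_i` from the bivariate conditional given
`betaR_i` with a replication-level `rho_beta ~ U(0.1, 0.3)` and unit
marginal scales; trait rows bivariate normal with replication-level
`rho_theta ~ U(0.2, 0.3)`; `betaD_i ~ U(-0.4, 0)` under Model 2; unit
residual SDs.  `rho_beta` and `rho_theta` are replication-level, not
item-level, quantities.  Responses are model means plus independent
Gaussian noise.  Replication seeds are spawned from a master seed so any
single replication is reproducible in isolation.

What the generator does *not* emulate about real rating data: bounded
Likert scales (responses are unbounded Gaussian), item-specific
means beyond the shared grand mean, missing or partial designs, and
shared dyadic residual components.  Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the model's
own assumptions, not robustness to these real-data features.

## Recovery studies

For each condition (network size x generating model x fitted model) the
driver pools (truth, EAP) pairs per parameter class across replications
and elements and reports RMSE, NRMSE, bias, and R-squared, plus mean
R-hat and ESS.  NRMSE normalizes by the SD of the *estimates*; the
conventional SD-of-truth variant is available via
`denominator="truth"`.

Two metric caveats are structural, not incidental:

* R-squared in the ratio form `1 - SSE/SST` is undefined for a class
  whose truths are constant (the residual scales, all 1.0 by design) and
  uninformative for classes confined to a narrow interval (the two
  correlations, drawn from 0.1-0.3-wide bands): the denominator does not
  represent meaningful dispersion.  The driver flags these and reports a
  condition-level R-squared pooling every pair of the model, which is
  the headline recovery quality number.
* Item-effect recovery carries an irreducible scale floor: the
  likelihood identifies only products (effect x trait), the prior pins
  the trait variance at 1, and the realized trait sample SD deviates
  from 1 by ~`1/sqrt(2nL)`.  That deviation transfers inversely onto
  every effect of a replication, so e.g. receiver-effect RMSE cannot
  fall below roughly `E[betaR]/sqrt(2nL)` no matter how long the chains
  run.

Cross-estimation (fitting each model to data generated by the other)
reports the classes both models share meaningfully — trait scores and
the trait correlation.  Fitting the distance model to main-effects data
in very small networks (n = 5) measurably inflates trait errors: the
weakly identified negative distance effect absorbs dyad-level variance.
This is a property of the posterior (verified with 8 chains and 6x chain
lengths), and it is the dominant contribution to the crossed-robustness
bound reported by `scripts/acceptance.py`.

Default study sizes are deliberately reduced — tens of replications with
`FitConfig.reduced()` chains rather than hundreds with reference-length
chains — chosen so a full study runs in minutes on one core while
leaving Monte Carlo error well below the effects of interest; the
full-scale design remains available through `replications` and
`fit_cfg`.

## Trait-level networks

A fitted model predicts each directed response without measurement
error; summing predictions within a subscale gives the weight of the
trait-level tie from sender to receiver in original response-scale
units.  Under Model 2 the prediction includes the distance penalty —
it is part of the model mean.  Weights are computed at the EAP point by
default; posterior-draw networks can be built by constructing
`LidmParameters` from individual draws.  "Excluding measurement error"
means omitting the residual, not shrinking it.

## Degenerate inputs and numerical choices

Incomplete round robins, self-ratings, and duplicated directed cells are
rejected at construction (missing-data handling is out of scope by
design).  Estimation requires n >= 3.  Gamma precision draws at the tiny
prior shape (prior-only runs) are floored at 1e-280 to avoid underflow
to zero.  R-hat is floored at 1 (values below 1 are estimation noise).
ESS of a constant chain is reported as undefined, never silently 0.
Slice samplers use fixed step widths (0.25-1.0 matched to each
parameter's posterior scale) with stepping-out capped at 64 doublings
and shrinkage capped at 128 — caps never reached in practice.

## Known limitations

Continuous responses only (no link functions); Euclidean distance only;
every item loads on exactly one trait; complete designs only; no Bayes
factors or marginal likelihoods (model comparison is out of scope); the
correlations `rho_beta` and `rho_theta` are weakly identified in small
networks and their EAPs shrink visibly toward their prior centers —
interpret them cautiously below n = 20.
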