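# Methods

## Model

Two engineered populations share one well-mixed bioreactor. Yeast (`c1`)
and bacteria (`c2`) grow logistically against a common carrying capacity
`cmax` and are killed by a fixed concentration of a growth-control
antibiotic Gc at rate `k3·Gc/(1 + α·Res)` per cell, where Res is the
species' resistance protein and α (molecules⁻¹) sets how little Res is
needed to neutralize the drug. Each species constitutively produces a
quorum signal (AHL1 by yeast, AHL2 by bacteria, first order in the
population); the partner's signal binds a constitutively expressed receptor
pool (fourth order overall: two signal molecules and two receptors per
complex) and the complex induces resistance expression with Hill kinetics.
The yeast branch interposes a pre-resistance intermediate (`preRes1`,
maturation rate `k8`) to represent the slower eukaryotic gene-expression
cascade; the bacterial branch induces Res2 directly. All molecular species
degrade first order. An optional first-order *E. coli* lysis channel
(rate `d`) converts the mutualism into predator–prey-like antagonism.

Unit scheme: all nine state variables are stored as counts. Rate laws
printed in concentration units are converted with the compartment factors
Ω1 = V1·Na (yeast-side reactions: AHL2 binding and preRes1 induction) and
Ω2 = V2·Na (bacterial side). The receptor pools (0.5 µM each) and Gc are
treated as fixed and folded into effective constants k6″ = k6·[AHLR2]²,
k9″ = k9·[AHLR1]², k3″ = k3·Gc. The induction reactions are catalytic in
the inducing complex (the complex is removed only by its own degradation
channel): Hill-type production models transcriptional induction, not
stoichiometric consumption. Signals, complexes and resistance proteins are
single reactor-wide pools, as the printed rate laws imply.

Because α is stated ambiguously (a per-molecule value in the parameter
table, per-nM values in the sensitivity analysis), the parameter set keeps
per-species coefficients `alpha1`/`alpha2` (default 5e4 molecules⁻¹ each)
and `Parameters.with_alpha(value, unit="nM^-1")` converts per compartment
(alpha_i = value/(1e-9·Ω_i)); sweep APIs require the unit tag explicitly.

## Integration

The chemical Langevin equation is advanced by Euler–Maruyama with one
independent standard-normal increment per reaction channel per step; the
noise multiplier ε (default 1) scales every diffusion term, and ε = 0 is
bit-identical to explicit Euler on the drift (the deterministic mode).
Defaults: dt = 0.005 h, chosen so the fastest first-order rate in the
default set (k8 = 5 h⁻¹) satisfies k·dt = 0.025; halving dt moves the
deterministic 50 h endpoint of the default co-culture by < 0.5% (tested).
After each step states are clamped at zero (negative excursions are a
discretization artifact, not reflected) and populations below one cell are
absorbed at zero. Absorption is permanent because every production channel
of a population carries a factor of that population, so survival queries
may terminate early once both populations absorb. Ensembles simulate
replicate colonies with seeds `base_seed + i`; means and sample (n−1) SDs
are accumulated with Welford's algorithm (stable at 1e9-cell magnitudes)
over *all* replicates including extinct ones, with survivor-only views
available from the stored per-replicate first-extinction times.

Steady-state detection: the trailing 5 h running mean of each population
must change by less than 1% per window from some time onward; the reported
time is the earliest such time. The criterion and its defaults are this
package's operationalization.

## Ecological regimes and threshold searches

A regime label derives from three survival outcomes (each monoculture and
the co-culture, 5e4-cell inocula, population above the absorption threshold
at the horizon): both monocultures survive → facultative mutualism; only
bacteria → commensalism (bacteria); neither alone but together → obligatory
mutualism; co-culture fails → extinction. The closed label set is made
total with the symmetric commensalism-for-yeast case, unreachable at the
default growth rates but valid for user parameter sets.

Monoculture Gc boundaries are deterministic bisections; with no partner
there is no rescue and the boundary approaches the analytic forms k1/k3
(58.5 nM) and k2/k3 (234 nM). A finite horizon T biases the measured
boundary upward by ln(inoculum)/(k3·T); the default horizon of 2000 h keeps
that bias at ≈1.35 nM, within the printed rounding of the reference values.

The co-culture lethal boundary is a *stochastic* quantity. Whether a
colony survives high Gc is decided by a race between antibiotic killing and
the noise-seeded build-up of the induction cascade, and colonies with full
CLE noise survive roughly tenfold beyond the drift-only collapse point
(~2.5 µM deterministic vs ~20 µM stochastic). The search therefore bisects
on "no replicate of n = 10 survives 200 h" under common random numbers;
the deterministic variant remains available as an option.

Minimum-viability searches (carrying capacity, equal inocula, single-species
inocula) are ensemble statements: integer or log-grid bisection on "all n
replicates survive the horizon" with shared seeds per candidate, which
makes the monotone bisection well defined under stochasticity.

## Oscillation analysis

The bifurcation scan along d runs on the deterministic part. Interior
coexistence fixed points are found by an exact reduction: given (c1, c2)
the molecular subsystem equilibrates in closed form (the signal pools solve
a quadratic balance of decay plus pairwise binding; everything downstream
is explicit), leaving the two per-capita balances k1·L = killing1 and
k2·L = killing2 + d, solved by nested bracketing (inner: c2, strictly
monotone; outer: log c1). This remains well-posed where the near-vanishing
logistic factor makes generic 9-D root-finding ill-conditioned. Stability
comes from central finite-difference Jacobians (per-component relative
steps) and their eigenvalues; the Hopf point is the smallest grid d whose
leading complex pair crosses into the right half-plane, cross-validated
against a transient classification (post-transient peak-to-trough swings of
a 2000 h run: stable swings → sustained, decaying → damped, absorption →
extinct); disagreements are flagged per row, never dropped. Oscillation
period is the dominant FFT peak of the mean-removed post-transient signal
with sub-bin quadratic peak interpolation, cross-checked by an independent
autocorrelation estimator; both populations share the period.

A caveat at d = 0: the drift there has no root near the
bacteria-dominated state the trajectories visit. That state is a
quasi-steady state on an ultra-slow manifold (per-capita yeast imbalance
~1e-7 h⁻¹ and decaying); the true interior root is yeast-dominant with an
essentially zero leading eigenvalue. Fixed-point machinery reports the
root; the observed 16–24 h "steady state" is the operational quantity
measured by the steady-state detector. For d ≥ 0.1 the degeneracy is gone.

The noise-robustness scan at fixed d runs CLE ensembles across a grid of
ε, with common random numbers, and reports the largest ε at which every
replicate survives the horizon *and* survivors keep oscillating at the
deterministic period within 10%. Single-trajectory spectral peaks wander
with the stochastic amplitude, so the stochastic period is the median FFT
period over all surviving replicates at that ε; the survival-only
threshold is reported alongside.

## What the simulations do and do not show

The generator of all study conditions is the model itself at its default
parameter set (Table-accurate constants, 5e4 + 5e4 inocula, Gc = 0.3 µM,
cmax = 1e9, 100 colonies for ensemble figures, 25 for viability searches,
20 for noise scans). The chemical Langevin approximation treats molecule
counts as continuous; at inocula of a few cells and sub-molecule resistance
levels this is a modeling idealization, not a claim about discrete
single-molecule reality — the minimum-inoculum results in particular
quantify the CLE's rescue race, not a jump-process one. Known limitation:
under this reconstruction the minimum carrying capacity at which all
colonies persist for 3000 h is ~2e3 cells, far below the ~2e5 reference
value; at 1e4–1e5 cells the quasi-equilibrium propensities are too small
for CLE fluctuations to drive absorption, and no reading of the printed
rate laws changes that. The corresponding acceptance check is left failing
by design. No spatial structure, no explicit inter-compartment diffusion,
no discrete (Gillespie) backend, no adaptive or implicit SDE schemes.
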