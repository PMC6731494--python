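# Methods

## Model

One generation of a discrete-generation single-species population is modelled
as continuous within-generation growth interrupted by impulsive kill events.
Growth follows the piecewise-constant-argument construction that yields the
classic Ricker map: on a segment starting at density M the per-capita rate is
held at r(1 − M/K). A kill pulse at fraction θ of the generation multiplies
the density by the survival p ∈ (0, 1] and starts a new segment, refreshing
the density argument. For a single pulse this composes to the closed form

    f(N) = p N exp[ r (1 − (N/K)(θ + (1−θ) p e^{rθ(1−N/K)})) ],

which collapses to p N e^{r(1−pN/K)} at θ = 0 and p N e^{r(1−N/K)} at θ = 1.
The multi-pulse map iterates the same segment recursion

    M_0 = N,   M_i = p_i M_{i−1} e^{r(1−M_{i−1}/K)(θ_i − θ_{i−1})},

returning M_k e^{r(1−M_k/K)(1−θ_k)}; at k = 1 this is algebraically identical
to the closed form, which pins its parenthesization.

**Zero-dose convention.** A pulse with survival exactly 1 kills nothing, and
we treat it as no event: the density-argument refresh accompanies an actual
kill. Without this convention the closed form at p = 1 and interior θ would
still refresh at θ and would *not* be the classic Ricker generation (its
equilibrium at K would remain stable up to r = 1/(θ(1−θ)) ≥ 4 instead of
r = 2), contradicting the model's own normalization of the untreated
homeostatic state. The cost is that the q → 0⁺ limit of the map differs from
the q = 0 map away from N = K; attractor levels remain continuous at q = 0
wherever the untreated equilibrium is stable (r < 2), and dose grids treat
q = 0 as the untreated baseline.

**Beverton–Holt control model.** The same pulse applied to *exact logistic*
growth N(t) = K N₀ e^{rt} / (K + N₀(e^{rt} − 1)) gives the compensatory
analogue. Because the logistic solution has no overcompensation and its flow
property makes the segment composition exact, this map's equilibrium never
increases with dose — it is the negative control for every hormesis claim.

## Equilibria and stability

Positive fixed points are located by sampling f(N) − N at 2000 points on
(10⁻⁹ K, 3K] (configurable; all observed attractors sit below ~2K), polishing
each sign-change bracket with Brent's method, and merging roots closer than
10⁻⁸ K. Stability uses the analytic map derivative (|f′(N*)| < 1); a root
with |f′| within 10⁻⁴ of 1 is flagged *marginal* (near-tangency) and not
claimed stable. The extinction state N = 0 always exists and is reported
separately from the positive set. Tangencies appear as single merged roots.

Analytic thresholds: the critical growth rate
r_c(θ, p) = (1/θ)[ln(θ/((1−θ)p)) + 2], defined for θ ∈ (0, 1), below which
(given the necessary condition f(K) > K) a low dose can move the population
to a higher equilibrium; and the stability boundary r + ln p = 2, which the
map reproduces exactly at the boundary timings θ ∈ {0, 1} (numerically
verified; at interior θ the boundary differs — see Limitations).

## Sensitivities and bifurcation atlases

Equilibrium sensitivities dN*/dc for c ∈ {q, θ} use implicit
differentiation, −(∂f/∂c)/(∂f/∂N − 1) at the fixed point, with a central
(boundary-aware one-sided) finite difference of step 10⁻⁶ for ∂f/∂c and the
analytic ∂f/∂N; the computation is refused within 10⁻⁸ of a tangency
(∂f/∂N = 1), where it is undefined. Signs are thresholded at 10⁻⁹.

One-dimensional sweeps track branches by nearest-neighbour continuation with
a jump tolerance of 0.2K (branches are well separated at working
resolutions). Saddle-node events are flagged where the positive-root count
changes and refined by bisection in the swept parameter to 10⁻⁶; flip events
where a continued branch's multiplier crosses −1 (exact −1 on a grid node
counts as a crossing). Two-dimensional sweeps classify each cell by
equilibrium structure plus sensitivity signs into the colour-legend
vocabulary (green, magenta, cyan, red, blue, plus white/grey stability-only
codes and an explicit `other`); codes are exhaustive and mutually exclusive.
Default grids are 201 points per axis, configurable; tests use coarser grids.

## Attractor response curves and hormesis classification

Dose (q) and timing (θ) response curves follow the long-run attractor across
a grid: 500 discarded transient iterations, then the time average of 200
recorded iterates (for a stable equilibrium this is the equilibrium; for
periodic/chaotic attractors it is the orbit average, an extension beyond
plotting only stable equilibria, and marked as such). `continuation` mode
warm-starts each grid point from the previous final state, which respects
hysteresis in bistable windows; `cold` mode restarts from K. Orbits
exceeding 50K are flagged invalid. Catastrophic shifts are marked where a
grid step's |ΔN| exceeds 5× the local median step.

A curve is *hormetic* when its level exceeds baseline·(1 + 10⁻³) somewhere
and falls below baseline·(1 − 10⁻³) at a larger control value; the baseline
is the q = 0 attractor with the same timing structure. Zone endpoints and
the inhibition threshold are linearly interpolated between grid points.
Invalid cells inside the candidate zone make the verdict indeterminate.

**Cumulative pulses.** For k equal pulses the small-q slope of the
equilibrium response decomposes per pulse as r(1−θ_i) − 1 (scaled by the
stability denominator), so *early* pulses steepen the rise while late
pulses (θ_i > 1 − 1/r) weaken it. The packaged comparison regime therefore
uses early-clustered timings (0.1, 0.2, 0.3) at r = 2.5, where the initial
rise strictly steepens and the inhibition threshold strictly falls as k goes
1 → 3. Timing sets straddling the generation midpoint need not show the
steepening.

## Field fitting

Field series are modelled as one impulsive generation per inter-observation
interval [t_i, t_{i+1}], with growth rate r_i = r̄·shape(t_i + τ)·(t_{i+1} −
t_i). The seasonal `shape` is a host-plant curve over days into the season:
users supply (day, value) knots fitted by a clamped cubic spline; the
packaged default is a **synthetic** unimodal stand-in (Gaussian bump, peak
value 120 at day 40, width 25 days) for a cotton-squares curve whose source
data are not distributed with the package. A spray flagged at t_i applies
survival p at the start (θ = 0, configurable) of that interval — the
application follows immediately after the triggering observation. For the
packaged 2012 campaign, fits start at 17 July (the earliest spray date) with
the initial population pinned to the observed count there.

The estimator minimizes the unweighted SSE over (p, K, r̄, τ) with bounded
trust-region least squares from 32 scrambled-Sobol starting points (the SSE
surface is multimodal, especially in τ). Default bounds: p ∈ (10⁻³, 1],
K within (0.5, 10)× the observed maximum, r̄ ∈ [0, 0.05] per day per shape
unit, τ ∈ [0, 60] days.

## Dose–response fitting and design of experiments

Responses are modelled as `horizon` impulsive generations from N = K with
survival p = e^(−ρ·Ds); K is pinned by the zero-dose datum. A design caveat
discovered in the algebra: a *single* generation from N = K gives
f(K) = K p e^{r(1−θ)(1−p)}, so the data constrain only ρ and the product
r(1−θ) — (r, θ) lie on a ridge and cannot be separated. The recovery studies
therefore use horizon = 2, where the within-generation term e^{rθ(1−N/K)}
enters and all three parameters are identifiable (noise-free refits recover
them to machine precision). Single-window experimental designs should treat
θ as fixed by the protocol rather than estimated.

## Synthetic data

Generators emulate (a) model trajectories with observation noise, (b)
threshold-triggered spray campaigns on a dated template, and (c)
model-generated dose–response datasets. Noise applies to observations only;
the dynamics stay deterministic. The default noise is multiplicative
lognormal, mean-unbiased with the requested coefficient of variation
(counts are non-negative and roughly constant-CV); dose–response data use an
additive Gaussian option with sd = cv·level. All draws flow through a seeded
numpy PCG64 generator, so equal seeds reproduce datasets bit for bit, and
cv = 0 returns the deterministic values exactly.

The recovery-study campaign defaults — threshold 60 (the highest action
threshold in the field design), p = 0.5, K = 80, r̄ = 0.0016, τ = 15 d,
N₀ = 5, cv = 0.1 on the packaged date template — were chosen on
identifiability grounds: the carrying capacity must exceed the action
threshold so that unsprayed stretches visibly saturate at K, and sprays must
occur often enough to expose p. Designs whose sprays pin the population far
below K leave K essentially unidentified, which would turn recovery tests
into tests of the optimizer's bounds. What passing recovery tests show is
that the estimator works under these conditions; real campaigns with
low thresholds and strong kills can still leave K weakly identified.

The packaged field fixture (seven plots, 21 dates, counts of infested
cotton heads per 100 plants, May–September 2012, action thresholds 1–60)
ships as a plain CSV with spray-application flags; counts stay real-valued
throughout (they are per-100-plant rates). Two plots carry spray flags at
counts equal to, not exceeding, their nominal thresholds; the loader warns
rather than rejects, since operational spraying decisions need not follow
the nominal rule exactly.

## Limitations

- The r + ln p = 2 stability boundary is exact only at boundary pulse
  timings; interior-θ boundaries are located numerically, not analytically.
- Period-doubled and chaotic attractors are characterized by forward
  iteration and time-averaging, not by orbit continuation; no Lyapunov
  exponents are computed.
- The q → 0⁺ map limit differs from the q = 0 map when the untreated
  equilibrium is unstable (r > 2); dose-response baselines are defined at
  q = 0 exactly.
- Field fitting assumes one generation per observation interval with
  duration-scaled r; daily stepping is not implemented.
- The default seasonal shape is a synthetic stand-in; conclusions about any
  real field system require a measured host-plant curve.
- No confidence intervals beyond multistart dispersion; no demographic
  stochasticity; no multi-species interactions.
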