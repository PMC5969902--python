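# Methods

## The two-route dissociation model

A barbed-end-bound FH2 dimer waits in a rapid equilibrium between an
elongation-competent *open* state and an elongation-forbidding *closed*
state. Pulling force f tilts the equilibrium toward open over one
subunit size δ_step:

    p_open(f) = 1 / (1 + K_co · exp(−f·δ_step/kBT))

Only the open state adds subunits, so the elongation rate is

    v(f) = p_open(f) · k_on · [actin] · (1 + boost(profilin)) · (1 − π_sol)

where `boost(p) = B_max·p/(p + K_boost)` is the FH1 delivery enhancement
(zero without FH1 domains) and `π_sol = p/(p + K_PB)` is barbed-end
occupancy by solution profilin, which pauses elongation for every
construct. The profilin dependence of v is therefore biphasic when FH1
is present: delivery saturates while occupancy keeps rising.

Dissociation proceeds through two competing routes, each a Bell slip
bond `k(f) = k0 · exp(f·δ/kBT)`:

* **open route** — a first-order clock running while the dimer waits:
  `k_open(f) = p_open(f) · (1 − π_sol) · k_offO0 · exp(f·δ_O/kBT)`;
* **transition route** — each subunit addition puts the dimer in a
  short-lived dissociation-prone state that either dissociates
  (`k_offT(f)`) or decays back (`k_decay`), giving a per-addition exit
  probability `p_T(f) = k_offT(f)/(k_offT(f) + k_decay)` and a route rate
  `k_trans(f) = v(f) · p_T(f) · (1 − π_fh1)`, with
  `π_fh1 = p/(p + K_ring)` the FH1-profilin "ring complex" occupancy
  that exists only with FH1.

The observable rate is `k_off = k_open + k_trans`. Structural
consequences, all exercised by the test suite:

* at zero force the transition route dominates, so k_off rises
  (affinely) with actin concentration;
* with `π_fh1 = 0` (no FH1) the transition route depends on conditions
  only through v — FH2-only data collapse onto one k_off(v) curve
  regardless of how a given v was reached (the collapse is exact for the
  transition route; a small residual sits in the π_sol-gated open route,
  < 1% for the shipped parameter sets);
* with FH1, equal elongation rates reached with different profilin give
  different k_off — there is no universal k_off(v) scaling;
* if δ_O > δ_T the open route takes over at high force and k_off(f)
  curves for different actin concentrations **converge**; if δ_T > δ_O
  they stay **separated**. The classifier in `koff_force_family` compares
  the max/min spread across concentrations at the lowest and highest
  force of the grid and calls "converging" iff the high-force spread is
  strictly smaller (ties → "separated", the conservative call).

The mean filament length is `L̄ = (v/k_off) · 2.7 nm`, so
`L̄ · k_off / v` is one subunit size identically. A route with working
distance `δ = ln(10)·kBT/3 pN ≈ 3.15 nm` shortens filaments ten-fold per
3 pN — the closed-form decade scale used in the force-law study.

### Parameters

| parameter | units | meaning | mDia1-like default |
|---|---|---|---|
| k_on | 1/µM/s | association from the open state | 20 |
| K_co | — | closed:open at f = 0 | 1 |
| k_offO0 | 1/s | open route at f = 0 | 2·10⁻⁴ |
| k_offT0 | 1/s | transition route at f = 0 | 0.3 |
| k_decay | 1/s | transition-state decay | 1000 |
| δ_O, δ_T | nm | route working distances | 2.7, 0 |
| δ_step | nm | open/closed distance (one subunit) | 2.7 |
| K_PB | µM | solution profilin–barbed-end scale | 50 |
| K_ring | µM | FH1-mediated occupancy scale | 0.3 |
| B_max, K_boost | —, µM | FH1 delivery enhancement | 5, 2 |
| salt/label multipliers | — | phenomenological factors on both k0s | 1 |

kBT defaults to 4.11 pN·nm (25 °C) but lives in `Conditions` so cooler
room temperatures can be represented. The shipped constructs (mDia1-like,
mDia2-like, FH1(2PP), FH2-only) are illustrative calibrations that
reproduce the qualitative behaviours above, not fits to any dataset;
mDia2-like differs by slower elongation (k_on = 8) and lower dissociation
on both routes. `K_ring < K_boost/B_max` is required for ring protection
to beat delivery so that k_off decreases monotonically with profilin
while v still rises; the defaults satisfy this. A profilin mutant that
binds FH1 but not barbed ends is represented by sending K_PB and K_ring
to large values.

## Stochastic simulator

`simulate_filament` realizes the model exactly. Under a
length-proportional ramp (force κ·L re-evaluated after every event) it is
a Gillespie loop: waiting times are exponential in the instantaneous
total rate (additions + open route), each addition grows the filament by
2.7 nm and runs a Bernoulli transition trial at the post-addition force.
Under constant force the process is a homogeneous race, and the simulator
uses the equivalent direct construction: dissociation time ~
Exp(k_open + v·q), route chosen proportionally, non-lethal additions a
thinned Poisson count. The two constructions are distributionally
identical; the fast path stores only trajectory endpoints. A ramp with
κ = 0 routes through the constant path, so it reproduces zero-force
traces bit-for-bit at the same seed.

The open/closed flicker is not simulated (it is a rapid equilibrium;
p_open multiplies rates), and the transition state is instantaneous by
default. An `explicit_transition` mode draws a finite dwell with
competing k_offT / k_decay clocks for sensitivity checks; with the
default fast decay it agrees with the closed form to within sampling
error. Exponents f·δ/kBT above 700 raise an unphysical-parameter error
rather than overflowing.

Populations derive per-filament substreams by spawning a numpy
`SeedSequence` from the population seed; in ramp mode initial lengths are
log-normal with mean L0 and CV 0.2 by default (experiments report only
mean initial lengths; a 20% spread is typical of filament populations).

## Synthetic experiments

`generate_experiment` adds the observation layer: dissociation times are
quantized **up** to the next acquisition frame (a detachment is first
seen at the following image), filaments alive at the movie end are
right-censored at it. Default cadences follow typical acquisitions
(5 s seed-anchored, 10 s anchored-formin, one cycle for striped movies).

* *striped* mode alternates conditions on a (Δt1, Δt2, …) cycle;
  dissociation is a piecewise-homogeneous exponential race with
  per-segment rates, so composite rates are duration-weighted means of
  the per-condition rates — the identity the deconvolution inverts.
  Schedule durations must be at least one frame interval.
* *formin_anchored* mode models non-functional anchored formins: a
  (1 − functional_fraction) subset carries an extra failure clock,
  uniform over the movie, competing with the formin kinetics; the truth
  table marks those records spurious. Because the spurious clock only
  adds hazard, the observed detachment rate k_obs over-estimates the
  formin rate, which is precisely the premise of the correction
  `ff·k_obs ≤ k_off ≤ k_obs`.

Ground truth (true times, routes, final lengths) is written to a
separate `.truth.csv` sidecar so analysis code cannot consume it by
accident. What the generator does **not** emulate: imaging noise and
kymograph tracking, photobleaching, filament exclusion rules (overlaps,
surface sticking), the brief formin-capture phase, or depolymerization.
Tests passing on these synthetic data therefore validate the estimation
chain against a known truth, not the imaging pipeline of a real
experiment.

## Estimators

**Survival curves.** Product-limit (Kaplan–Meier) construction; censored
filaments stay in the risk set until their censor time. The uncensored
case reduces to the plain empirical step function.

**Exponential fit and its error bars.** S(t) is fitted by `exp(−k·t)`
with amplitude pinned at 1, by least squares on the survival fraction
sampled over a **uniform 50-point time grid** spanning the observation —
the way a fixed-frame movie samples S(t). This convention was fixed by
the Monte-Carlo calibration: simulating many N-filament experiments and
fitting each, the fraction of estimates within k0 ± k0/√N is 65–68% for
N between 20 and 50 (and the central-65% half-width is ≈ k0/√N), so the
quoted 65% interval is `k·(1 ± 1/√N)`. Fitting on the event-step points
instead gives a noisier estimator (≈61% coverage); a censoring-aware
maximum-likelihood mode (events / total time at risk) is provided as an
independent cross-check and agrees within 2k/√N on exponential data.

**Force ramps.** The local hazard −d(ln S)/dt is estimated by straight-
line fits of ln S over sliding windows of 10 survival points (window and
stride are exposed; overlapping windows are correlated — use
stride = window for independent points). The curve tail where fewer than
3 filaments remain at risk is trimmed first: the last product-limit
steps are large and erratic and slopes through them are inflated.
Each hazard point is mapped to
the population mean force `f = κ·(L0 + v·(t − Δframe/2))`; the half-frame
shift compensates the detection lag of frame quantization. Points from
all flow rates are pooled and grouped into 10 equal-count force bins
(bin means and SDs for both f and k), and the functional-fraction
correction brackets the formin rate per bin. The effective working
distance is the weighted log-linear slope of the binned k_obs(f) times
kBT; the zero-force rate takes the geometric midpoint √ff·exp(intercept)
of the corrected bounds.

**Striped deconvolution.** The algebraic inverse
`v1 = ((Δt1+Δt2)·v − Δt2·v2)/Δt1` (and identically for k). Negative
recovered rates — possible with noisy composites — are returned as-is
with a warning, never clipped.

## Study sizes and numerical choices

The ramp-recovery study simulates the three printed flow-rate designs
(κ = 0.051/0.204/0.501 pN/µm; L0 = 4.9/3.2/2.6 µm; N = 46/49/49) with 15
replicate experiments per flow rate — real campaigns pool independent
experiments per condition, and 15 gives per-bin rate noise of a few
percent so the corrected bounds (a +0/−26% band) are informative. Movie
durations of 560/280/170 s let 97–99% of functional formins dissociate
on camera while centring the expected spurious inflation of the observed
hazard near √(1/ff) ≈ 1.16, the geometric midpoint of the correction
band, so the bounds bracket the truth robustly. The generating truth is a
single-route Bell bond (δ = 2.7 nm, k_off(0) = 4×10⁻³ s⁻¹, open/closed
equilibrium pinned open) at 1 µM actin + 10 µM profilin, so both v and
the target law are analytically known. Recovered δ is typically within
5% of truth; the acceptance bar is 25%, the repeated-seed spread of the
estimator at these sizes.

The CI calibration uses M = 10 000 simulated experiments by default
(M = 2000 in the test suite and acceptance script; the binomial error on
a coverage estimate at M = 2000 is ~1%). All randomness flows through
numpy `SeedSequence`s derived from a single user-supplied seed; identical
seeds give identical outputs everywhere, including CLI runs.

Known limitations: no mechanistic model of ionic strength or labeling
(multiplicative factors only); profilin–actin speciation is not resolved
(total profilin is the proxy); no explicit polyproline-track FH1
kinetics; no filament mechanics beyond the anchoring-point force κ·L;
and the open/closed geometry (stair-stepping vs stepping-second) is not
resolved — the model only commits to a one-subunit working distance for
the equilibrium, which is compatible with either. Whether profilin
occupancy should also gate the open route is genuinely open; here it
does, via (1 − π_sol), which is what makes the FH2-only collapse
approximate rather than exact.
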