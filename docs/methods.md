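# Methods

## Model

`thalcort` simulates the refinement of thalamocortical connectivity in the
developing visual cortex before eye opening. A one-dimensional layer of
`Nu = 50` thalamic neurons feeds a layer of `Nv = 50` cortical neurons
through a nonnegative weight matrix `W` (both layers periodic to avoid edge
effects). Cortical cells are linear rate units,

    tau_m dv/dt = -v + W u + v_spon,      tau_m = 10 ms,

driven by two classes of spontaneous events:

* **L-events** (peripheral, retinal-wave driven): a contiguous block of
  20–80% of thalamic neurons fires at unit rate for ~0.15 s; inter-event
  intervals are exponential with mean 1.5 s.
* **H-events** (cortex-intrinsic, global): 80–100% of cortical cells
  receive an intrinsic drive `v_spon` with per-event amplitude drawn from
  N(6, 2), duration ~0.15 s, Gamma(3.5, 1.0) intervals.

All times are the 10×-shortened model-scale values; the synthetic
*recording* generator in the adaptation analysis uses the data-scale (×10)
counterparts.

Three plasticity rules act on `W`:

* **Hebbian covariance** — `tau_w dw_ji/dt = v_j (u_i - theta_u)`,
  `tau_w = 500 s`. The input threshold `theta_u` makes purely postsynaptic
  activation (H-events) uniformly depressing.
* **Adaptive H-events** — same rule, but each cell's intrinsic H-event rate
  is scaled by an activity trace `eta_j` obeying
  `tau_eta d eta/dt = -eta + v`, `tau_eta = 1 s` (`Hamp -> eta_j Hamp`).
* **BCM** — `tau_w dw_ji/dt = v_j u_i (v_j - theta_v_j)`, `tau_w = 1000 s`,
  with sliding threshold `tau_theta d theta_v/dt = -theta_v + v^2/v0`,
  `tau_theta = 20 s`. H-events act only through the threshold.

## Numerical scheme

Because `tau_m (0.01 s) << event duration (0.15 s) << tau_w (500 s)`, the
default loop is *event-driven*: the timeline is cut into elementary
segments on which the set of active events is constant (at most one per
train — within a train an onset is delayed to the previous event's end in
the rare case a sampled interval is shorter than a duration). Within a
segment `v` sits at its fixed point `W u + v_spon` and is exactly zero
between events. The adaptation trace is advanced with the exact exponential
update for piecewise-constant `v`; the BCM threshold uses Euler substeps
`dt = min(segment, tau_theta/20)` during activity and closed-form decay
between events. An H-event's effective amplitude is fixed at its onset.
The inner loop is numba-compiled; a pure-numpy mirror (`engine="numpy"`)
and a full explicit-Euler integrator (`run_simulation_euler`, dt = 2 ms,
membrane dynamics included) serve as oracles — quasi-static and Euler
final weights agree to <5% relative RMS on 500-s runs.

Inter-event intervals are measured onset-to-onset, so event counts equal
`T / mean interval` (33,333 L- and 14,286 H-events at the defaults over
`T = 50,000 s`).

### Weight bounds

Weights are confined to `[0, wmax] = [0, 0.5]`. The default is hard
clipping. We also implement two multiplicative ("soft") variants —
potentiation scaled by `(wmax - w)/wmax`, optionally depression by
`w/wmax`. The symmetric soft form makes the homogeneous weight state
linearly stable: the state-dependent damping `-(D_pot + D_dep)/wmax`
exceeds the growth rate of every spatial mode of the input covariance, so
no receptive fields form at any tested parameter setting. Hard clipping
preserves the competitive instability and reproduces the known
phenomenology of this model class (narrow selective band in `Hint` at
`theta_u = 0.4` for the non-adaptive rule; robust selectivity with
topography ≈ 0.9 across `Hint` 1.5–6 s at `theta_u = 0.5–0.6` with
adaptation; BCM refining without decoupling at moderate `Hint`), and is
therefore the default; the soft variants remain available via
`PlasticityParams(bounds=...)` for sensitivity checks.

A consequence of hard bounds is that total decoupling (`W = 0`) is
absorbing — with `v = W u = 0` no potentiation can restart. Adaptive grids
therefore show a small decoupled fraction at very frequent H-events
(mean `Hint` ≲ 1.3 s), concentrated at the extreme corner of the sampled
range.

## Receptive-field metrics

A weight is part of a cell's receptive field when `w > wmax/5`. RF size is
the suprathreshold fraction per cell averaged over non-decoupled cells
(0 if all cells decoupled). The RF center is the weighted least-squares
circular center: the minimizer of `sum_i w_i d(i, c)^2` under periodic
distance, found exactly by enumerating circular unwrappings (ties resolve
to the smallest index; validated against a dense grid search). Topography
is `1 - xi/Xi` with `xi` the mean squared periodic deviation of centers
from the matched diagonal and `Xi = Nu^2/12` the expected error of a
column receptive field; scores below 0 are clipped. Outcomes: RF size 0 →
decoupled, 1 → non-selective, otherwise selective (tolerance 1e-9).

## Two-dimensional reduction

The Hebbian dynamics are reduced to the mean in-RF weight `w_RF` (n = 25
contiguous weights centered on the topographic position) and the mean
complementary weight `w_C`. The drift is the exact expectation of the
per-event update over the L-event ensemble — integer sizes from
`round(p Nu)`, `p ~ U(0.2, 0.8)` with rounding-interval masses, positions
uniform on the ring, overlaps with the RF block enumerated exactly — plus
the mean H-event depression `-theta_u <R_H>/Lint * Ldur * <Hpct> / tau_w`,
where `<R_H> = (Lint/Hint) <Hamp>` is the dimensionless H-event strength
(durations and the unit L amplitude cancel). Basins are classified by
integrating a 50×50 lattice of initial conditions (2500 points) over
`[0, wmax]^2` with an adaptive-step explicit scheme until trajectories are
absorbed at a corner: `(wmax, 0)`/`(0, wmax)` selective, `(0, 0)`
decoupled, `(wmax, wmax)` non-selective; non-absorbed points at the step
cap are labelled by the nearest corner and counted as unresolved.

The reduced flow matches the seed-averaged `(w_RF, w_C)` trajectory of
full simulations at the reference setting (`theta_u = 0.53`, Table-scale
defaults) to well under 10% of `wmax`, and its basin label agrees with the
full simulation's outcome across parameter sets spanning all three
outcomes. Known limitation: inside the narrow fluctuation-driven selective
band of the non-adaptive rule (e.g. `theta_u ≈ 0.4`, `Hint ≈ 3.5 s`) the
deterministic reduction predicts decoupling while stochastic simulations
escape to selectivity — mean-field drift cannot capture selection seeded
by event-to-event fluctuations. For the same reason the quantitative
correspondence between the adapted H-event strength (measured over the
final 5% of fixed-interval adaptive runs) and the reduced system's
selectivity-maximizing strength band is only qualitative here: adaptation
compresses nominal strengths toward the selective regime (roughly 2–3×
reduction), but not every swept point lands inside the band that the
reduced flow maximizes.

## Event detection and sparsification

Simulated cortical traces are sampled at 0.01 s. A cell is active when its
rate exceeds `nu = vmax/8` (`vmax` the recording maximum); an event is a
maximal interval with any active cell; participation is the peak
simultaneous active fraction; event amplitude averages, over active cells,
each cell's mean rate during its own active samples (a `peak` option
exists). Sweeping `theta_u` over {0.45, 0.50, 0.60} as a proxy for
developmental age (adaptive rule, converged networks, 300-s recordings,
3 seeds per threshold) reproduces the sparsification trends: the
amplitude-vs-participation slope of >80% events, the mean pairwise
correlation, and the mean event size all fall, while 20–80% events become
more frequent with lower amplitude.

## Adaptation signature on event tables

For each H-event (participation > 80% when unlabelled) the amplitudes of
all events in the preceding `Tmax = 300 s` (onset-to-onset, concatenated
recordings of one animal) are weighted by `exp(-dt/tau_decay)`,
`tau_decay = 1000 s`, and averaged; the Pearson correlation between H
amplitude and this aggregate is the adaptation statistic. Events below 20%
participation are dropped and animals with fewer than 12 qualifying
H-events excluded. The 95% CI uses a standard with-replacement bootstrap
(1000 resamples); full-size resampling *without* replacement would
reproduce the original sample, so an 80%-subsample without-replacement
scheme is offered as the alternative.

The synthetic recording generator emulates sessions of eight ~300-s
recordings per animal separated by 1–4-min gaps, with data-scale event
statistics. H amplitudes are `baseline + gain * sd * z`, where `z` is the
standardized kernel-weighted history and the N(6, 2) baseline spread
doubles as measurement noise; the gain is therefore the history effect
size in baseline-SD units. What the generator does not emulate: calcium
indicator dynamics, detection jitter, cell dropout between recordings, or
slow excitability drifts — passing recovery tests shows the *pipeline* is
unbiased and monotone in the true gain, not that in vivo data meet these
assumptions.

## Monte Carlo grids

Grid experiments sample per-run parameters independently and uniformly:
`theta_u ~ U(0.3, 0.7)` and mean `Hint ~ U(1.0, 6.0) s` for the Hebbian
rules, `v0 ~ U(0.4, 1.0)` (bracketing the reference 0.7) and the same
`Hint` range for BCM; the Gamma shape 3.5 is kept and the scale set from
the sampled mean. Child seeds derive from the master seed via
`SeedSequence.spawn`, so any row is independently re-derivable. The
default protocol uses 500 runs per grid (the test suite uses 100-run grids
for speed); outcome percentages, selective-run topographies and the
two-sample KS comparison between rules are reported. The `theta_u`/`Hint`
ranges are the package's documented choice — outcome *splits* (especially
decoupled vs. non-selective) are sensitive to them, while the location of
the selective boundary is not.
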