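# Methods

This note documents the models behind `txtime`, the assumptions they make,
the parameters that matter, and the numerical choices, so that results can be
interpreted — and mistrusted — correctly.

## Dynamic-range beam-on-time model (`txtime.dr_engine`)

A treatment field is an ordered list of energy layers; a layer is a list of
line segments, each with an MU weight `mu_i` and a path length `L_i` (cm).
All segments of a layer are delivered at one dose rate `R` (MU/s); the scan
speed implied by segment *i* is `R · L_i / mu_i` and may not exceed the
machine maximum `Speed_max`.  The model is a four-step per-layer procedure:

1. **Baseline rate** `R_initial = min_i(mu_i/L_i) · Speed_max`.  The binding
   segment is the one minimizing `mu_i/L_i`; with uniform lengths this is the
   familiar `(MU_min/L) · Speed_max`.
2. **DR rate** `R_DR = (MU_max/L_ref) · Speed_max / DR`, `L_ref` the length
   of the MU_max segment, **but never below `R_initial`**: a DR looser than
   the layer's intrinsic `MU_max/MU_min` must not slow delivery relative to
   the unconstrained plan.  Without this guard a single-segment layer at
   DR = 100 would be slowed 100-fold, which no delivery system would do.
3. **Minimum-MU elevation** `mu_i ← max(mu_i, MU_max/DR)`.  This is a clamp,
   not a proportional rescale: segments already above the floor are
   untouched.  Total MU deliberately increases — that surplus is the
   modulation cost of the constraint, and this package does not model the
   re-optimization that would redistribute it.  A second, per-segment clamp
   `mu_i ≥ R·L_i/Speed_max` enforces the machine speed limit exactly when
   segment lengths are heterogeneous (it is a no-op for uniform lengths).
4. **Beam-on time** `BoT_i = mu_i_adjusted / R`; the layer BoT is the sum.

Properties relied on downstream (and enforced by tests): layer BoT is
non-increasing as DR decreases, the dose rate non-decreasing; BoT is bounded
below by `Σ L_i / Speed_max`, attained at DR = 1 — the machine plateau; an
unconstrained DR is bit-for-bit a no-op.

The model assumes a **fixed segment layout**: DR changes MU floors and dose
rates but never the number or position of segments or layers.  Real
optimizers occasionally restructure layers under extreme constraints; such
plans are outside this model's scope.

An optional machine dose-rate cap (`MachineSpec.max_dose_rate`, default
unbounded) can impose an additional plateau; the scanning-speed limit alone
already produces one.

### Worked reference layer

A five-segment layer (MUs 0.0013/0.0198/0.0178/0.0056/0.0010, each 0.6 cm,
`Speed_max` 2000 cm/s) is used as the package's frozen reference: baseline
rate 10/3 ≈ 3.33 MU/s pinned by the 0.0010 MU segment, baseline BoT
0.01365 s; at DR = 10 the rate is 6.6 MU/s, two segments clamp to the 0.00198
floor, and BoT drops to 0.007145 s — about 52% of baseline.  Computed from
4-decimal MU inputs, the DR = 10 rate differs by ~0.1% from values derived
from unrounded planning-system MUs (6.592 MU/s), and tests compare at
tolerances matching that rounding grain (1% relative on rates, 5e-4 s on
layer BoT, 1e-4 s per segment).

## Respiratory signal and gating (`txtime.respiration`)

The default breathing surrogate is the three-component sinusoid

    Sig(x) = [sin(x) + sin(2x + 0.7π) + sin(2x + π) − 5.4] / 2,  x = 2πt/T_R.

The constant offset and scale are irrelevant to amplitude gating, which
compares the signal to a threshold; the signal function is injectable on
`RespiratoryModel` so any surrogate (or an alternative reading of the
constants) is a one-line swap.  The gate opens while `Sig ≤ τ` (end-exhale
gating, the clinical norm for liver; a flag flips the sense).

`τ` is usually specified indirectly as a duty cycle: `threshold_for_duty`
bisects on `τ` against the occupancy fraction measured on a 20 000-sample
grid per period (duty recovered to ~1e-4).  Window boundaries are then
refined by bisection to below 1e-6 s and tiled exactly periodically.  Note a
non-obvious consequence of this surrogate's shape: at duty 0.3 the signal
dips below threshold **twice** per period, so there are two gate windows per
breath (≈0.26 s and ≈0.94 s at T_R = 4 s), not one.  Windows are half-open
`[on, off)`: an event exactly at a boundary belongs to the earlier state.

Defaults: `T_R = 4 s`, duty 0.3.  The duty cycle materially drives every
result and is echoed in all reports.  Irregular or drifting breathing is out
of scope; predictions are for the idealized periodic surrogate.

## Gated delivery simulation (`txtime.gated_delivery`)

Event-driven, layer by layer:

- A layer's remaining BoT is continuously divisible: the beam pauses at a
  gate-off edge and resumes at the next gate-on, carrying the residual.
  Segment granularity (≤ ms) is far below gating timescales, so the
  no-mid-segment-interruption subtlety is ignored.  An alternative
  whole-layer-deferral mode (`SimConfig(interruptible=False)`) starts a layer
  only in a window long enough to finish it, for sensitivity checks.
- A completed layer triggers a switch of duration `T_LS` immediately,
  running regardless of gate state (switching is exclusive with beam-on, not
  with gating) — this overlap is what makes switch/gate synchronization
  benefits possible.
- The next layer starts at the first instant both post-switch and gate-on; a
  switch ending exactly at gate-off waits for the next window (half-open
  convention).
- Clock starts at the respiratory-cycle origin plus a configurable
  `start_phase`; totals are reported from simulation start by default, with
  a first-beam-on origin as an option.

The decomposition `T_total = T_BoT + T_LS·(N−1) + T_dead` holds exactly by
construction (`T_dead` is defined as the remainder and asserted ≥ 0).  No
inter-field setup, beam ramping, or imaging time is modeled; fields are
simulated independently and reported per port.

**Independent oracle.**  `oracle_simulate` re-implements the same rules by
explicit time stepping (default 1 ms), sharing no machinery with the event
engine; steps are clipped at gate edges so boundary quantization cannot
drift the clock, and the phase-folded time is snapped onto an edge within
1e-9 s before the half-open test so both engines apply the same boundary
convention.  The suite cross-validates the two on random instances to within
2·dt.

## Synthetic plans (`txtime.synth`)

The generator emulates delivery structure only: 2–3 fields, tens of layers
stacked from high to low energy in 70–230 MeV, 100–500 segments per layer,
uniform 0.6 cm segment length, and within-layer MU drawn i.i.d. lognormal
(log-mean −4.5, log-sd 1.2), giving the 1e-3–1e-2 MU magnitudes and
multi-decade within-layer spread that make DR constraints bite.  Draws come
from named RNG streams keyed by (seed, field, layer), so plans are
reproducible and extending a plan never reshuffles earlier layers.

What it does **not** emulate: anatomy, dose, correlations between layer
depth and MU, segment positions, or any cohort's actual MU distribution
(none is published at that granularity).  Passing tests on synthetic plans
therefore validate the timing *mechanics* — monotonicity, decomposition,
plateau behavior — not cohort-level time predictions for real patients.

## Sweep and plateau (`txtime.sweep`)

The sweep grid defaults to unconstrained plus 200→10 in steps of 10.  The
plateau is the largest grid DR whose `T_total` is within ε of the grid
minimum, per field; the plan-level plateau is the largest per-field value (no
field over-constrained), and `none` is returned when only the smallest DR
qualifies — i.e., time is still falling at the foot of the grid.  ε defaults
to 1% of the minimum total and is overridable in seconds.  Detection uses
computed grid points only; the plot's piecewise-linear interpolation is
presentation.

## Numerical choices and problem sizes

- Event bookkeeping uses a 1e-12 s residual tolerance; timeline invariants
  are asserted at 1e-9 s.
- Gate boundary refinement: bisection to <1e-6 s; duty measurement grids of
  2×10⁴ (construction) vs 10⁶ samples (independent re-measurement in tests).
- The test suite exercises ~500 random gated timelines for the exact
  decomposition, 50 event-vs-oracle cross-validations at 1 ms, and 200
  random layers across the DR grid for monotonicity; these sizes keep the
  default suite in the tens of seconds while giving each property broad
  random coverage.
- Serialization uses `repr` floats (round-trip exact); canonical JSON key
  order makes save/load/save byte-stable.

## Known limitations

- No dosimetric modeling whatsoever: the trade-off between DR and
  normal-tissue dose must come from a planning system; this package only
  locates the efficiency plateau.
- Fixed segment layout assumption (above) can break at extreme DR values.
- Periodic-breathing idealization; gating efficiency with irregular traces
  will differ, though the DR mechanism itself is phase-independent.
- DICOM RT Ion Plan import is a documented extension point, not implemented;
  vendor spot-map conventions vary.
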