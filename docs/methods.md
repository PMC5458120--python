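# Methods

## Model

A simulated cell is a set of motor–clutch *modules* — protrusion-scale
units of rigid F-actin retracted by myosin motors and gripped by molecular
clutches — pulling on a central cell body. Each module `j` is a
one-dimensional chain along its axis:

    substrate spring (κ_s) — n_c,j clutches (κ_c each, in parallel)
        — rigid F-actin — n_m,j motors — cell spring (κ_cell) — cell body

* Clutches bind at a constant rate `k_on` and unbind at the Bell slip-bond
  rate `k_off = k*_off · exp(F_c / F_b)`, where `F_c` is the magnitude of
  the clutch spring force along the module axis.
* The motor ensemble follows the linear stall law
  `v_f = v*_m (1 − F / (n_m F_m))`, with `F = κ_s x_s` the force carried
  through the module chain. The velocity is clamped at zero so a
  super-stall transient between events cannot reverse the flow.
* F-actin polymerizes at the tip of uncapped modules at
  `v_p = v*_p · A_G / A_T` (proportional to the G-actin fraction) and is
  depolymerized at the motor position as it flows rearward, so module
  length changes at `v_p − v_f`. Clutch attachments that reach the motor
  position are forcibly unbound.
* Modules nucleate at rate `k_mod = k*_mod (A_G/A_T)^4` (nucleation is
  cooperative in G-actin), at a uniformly random direction, with initial
  length `l_in`, and with motors/clutches allocated proportionally to the
  free pools: `n_m,j = round(n*_m · n_m,free / n_m,tot)` (round half up,
  capped at the pool), and likewise for clutches. Modules cap at `k_cap`
  (polymerization stops) and are destroyed when shorter than `l_min`,
  returning all resources to the pools. Motors, clutches and actin are
  strictly conserved.
* `n_c,cell` clutches anchor the cell body itself to a central substrate
  spring; they use the same binding/Bell kinetics, loaded in 2-D by body
  motion only.

### Event loop

The stochastic events (clutch binding/unbinding, module birth, capping)
are drawn with the direct Gillespie algorithm: two uniform random numbers
per iteration give the exponential waiting time `ln(1/u₁)/Σk` and the
event index (first cumulative rate ≥ `u₂·Σk`). Between events the
mechanics advance explicitly at velocities held fixed over the interval
(retrograde flow stretches bound clutches; polymerization lengthens
uncapped modules). After each event the whole-cell force balance is
re-solved.

### Force balance

At fixed clutch engagement the spring network is linear. Each module
presents the chain stiffness
`k_eff = (1/κ_s + 1/(n_b κ_c) + 1/κ_cell)^-1` along its axis and the body
clutch ensemble `k_body = (1/κ_s + 1/(n_b,cell κ_c))^-1` isotropically, so
the body position solving `Σ_j F_j û_j + F_cell = 0` is found by a single
Newton step on a 2×2 system (exact up to round-off; the residual is
checked against `1e-6 · n_m,tot · F_m` after every solve). Internal
degrees of freedom (filament translation, substrate node, cell spring) are
then redistributed so the series balance
`κ_cell x_cell = Σ κ_c x_c,i = κ_s x_s` holds per module. When nothing is
bound the system is singular; the solver then moves the body only within
the range space (minimum-norm solution), which reduces to "no force, no
motion".

A cell starts as three modules of length `l_in` spaced 120° apart with no
clutches bound. Snapshots are recorded at exact multiples of the
recording interval; because inter-event motion is linear, recording during
the advance equals interpolation to the record time. If every kinetic
rate is zero the dynamics are integrated in record-interval chunks with
velocities refreshed per chunk.

### Implementation

The same algorithm exists twice: a readable operation-level reference
(`engine.py`, used by the unit tests and for custom states) and a
numba-compiled kernel (`_kernel.py`, default) that consumes the identical
random-number stream, so short runs agree event-for-event and
trajectory-for-trajectory to round-off. The kernel tracks conservation
and force-balance residual diagnostics every iteration.

## Parameters

Units: nm, pN, pN/nm, s; trajectory output in µm. Defaults (the "low"
cell):

| symbol | value | meaning |
|---|---|---|
| k_on | 1 s⁻¹ | clutch binding rate |
| k*_off | 0.1 s⁻¹ | unloaded clutch off-rate |
| F_b | 2 pN | bond rupture force scale |
| κ_c | 0.8 pN/nm | clutch spring constant |
| κ_s | swept | substrate spring constant |
| κ_cell | 10⁴ pN/nm | cell spring (near-rigid link) |
| F_m | 2 pN | motor stall force |
| v*_m | 120 nm/s | unloaded motor velocity |
| v*_p | 200 nm/s | max polymerization speed |
| k*_mod | 1 s⁻¹ | max module nucleation rate |
| k_cap | 10⁻³ s⁻¹ | capping rate |
| l_in / l_min | 5 µm / 0.5 µm | initial / minimum module length |
| n_m,tot / n_c,tot | 1000 / 750 | motor / clutch inventory ("low") |
| n*_m / n*_c | 100 / 75 | per-module maxima ("low") |
| n_c,cell | 10 | body clutches ("low") |
| A_T | 100 µm | total actin budget |

The single-unit kinetic and mechanical constants (k_on, k*_off, F_b, κ_c,
F_m, v*_m) are the established motor-clutch values for this model family.
The whole-cell values were chosen once as order-of-magnitude physiological
estimates: polymerization at ~75 monomers/s (200 nm/s), ~5 µm nascent
protrusions, a minute-scale module turnover via `k_cap`, an actin budget
supporting on the order of ten concurrent protrusions, and a cell spring
stiff enough to act as a rigid link. The "high" cell scales every
motor/clutch count (totals, per-module maxima, body clutches) by ten,
leaving kinetics, mechanics and the actin budget unchanged — the
high-expression counterpart of the same cell.

## Analysis procedures

* **Random motility coefficient.** Positions resampled to 15-min spacing;
  the first simulated hour is discarded as transient; interval
  displacements implying ≥ 1 µm/s (solver-jump artifacts) invalidate every
  MSD pair spanning them. The overlap-method MSD (all start times, lags up
  to 5 h) is fit through the origin, weighted by 1/SEM² per lag, over the
  first half of the lag list; `µ = slope/4` (2-D, `⟨r²⟩ = 4µt`),
  reported in µm²/min. Decisions where the procedure was underspecified:
  the exclusion drops the offending displacement (not the whole record);
  "first half" is by lag count; per-lag uncertainty is the standard error
  of the overlapping samples even though they are correlated.
* **Cell shape.** A 10 µm disc at the body, plus, per module, the triangle
  between the extended tip (module length + 10 µm from the centre, since
  modules start at the body's edge) and its two tangent points on the
  disc. Aspect ratio is the major/minor axis ratio of the moment-matched
  ellipse of the region rasterized at 0.1 µm (region-properties
  convention; resolution two orders below the body scale keeps the moments
  stable to <0.5%).
* **Flow and traction.** Per record: mean of module flow rates, and the
  sum of module force magnitudes plus the body force magnitude; both
  averaged over records after the transient exclusion.
* **Composite metric.** Each metric series is min–max scaled to [0, 1]
  (actin flow negated first, since its optimum is a minimum), averaged per
  stiffness, rescaled to [0, 1], and summarized by the peak of
  `A exp(−(log₁₀κ − µ)²/2σ²)` fit with unconstrained variance
  (initialized at the grid argmax with a one-decade width).
* **Bootstrap optimum-shift test.** At each (metric, stiffness) the two
  groups' measurements are pooled and randomly reassigned with the
  original group sizes, randomly swapped per shuffle; composites and
  log-Gaussian fits are recomputed and the |Δlog₁₀ peak| recorded; the
  p-value is the fraction of null distances ≥ the observed distance.

## What the synthetic conditions do and do not show

The sweeps simulate the model's own study conditions (the low/high
parameter sets over log-spaced κ_s grids with replicate seeds); they
contain no measurement noise, no cell-to-cell parameter variability, no
substrate viscoelasticity and no 3-D geometry, so passing tests establish
the emergent stiffness optima and their shift *within the model*, not
agreement with any particular experimental cell type.

## Problem sizes

Mean flow and traction equilibrate within minutes of simulated time
(load-and-fail cycle times range from ~0.1 s on stiff to ~10³ s on the
softest substrates), whereas motility needs ≥ 10 h of simulated time for
enough 15-min displacement samples. The shipped test suite and the
reproduction script therefore use, as this package's standard reduced
protocol: low-cell flow/traction sweeps at 1–2 h with the first
third-to-half discarded (2 replicates); high-cell sweeps at 5–15 min
with a similar fractional discard (1 replicate, the event rate being
~15× higher); and a single-replicate 5-h morphology/motility sweep for
the low cell only. Soft-substrate (0.01 pN/nm) traction in the high cell is
underestimated at these durations because its loading cycle (~1,700 s)
is not fully sampled; peak locations should be read with that in mind.

## Known limitations

* Module direction is fixed at birth; modules translate rigidly with the
  body (no bending, no lateral substrate loading).
* Clutches are taken to engage F-actin at the module tip, so the forced
  unbinding rule ("attachment passes the motor") triggers only after a
  full module length of flow.
* The stiff-substrate flow limit saturates at a frictional-slippage
  plateau below v*_m (single clutches loaded at rate ~κ_c·v rupture
  quickly); only the soft limit approaches v*_m.
* Capped modules with stalled motors can persist until their clutches
  release; no explicit module aging exists beyond capping + `l_min`.
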