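# Methods

## Model

An ensemble of `m_bar` kinesin-1 motors is permanently bound to one
cargo and can engage with a periodic microtubule lattice (period
`d_s = 8 nm`).  The state of the system is the occupancy `z_k` of each
lattice site.  Three elementary events change it: a motor steps one
site forward, detaches, or re-attaches.  Backward steps and
cargo–motor unbinding are not modelled.  The cargo relaxes much faster
than the motor kinetics, so between events it sits at the equilibrium
`x_eq(Z)` of the tether forces against the constant load, optionally
blurred by a truncated-Gaussian thermal distribution (±3σ) around
`x_eq`.  When the last motor detaches the cargo is lost; this absorbing
event terminates a run.

Tethers are slack below their rest length `l0` and Hookean (stiffness
`k_el`) beyond; the total tether force is therefore piecewise linear
and monotone in the cargo position, and the force balance is solved
*exactly* by scanning the breakpoints `a_k ± l0` and inverting the
active linear piece — no iterative root finder, no tolerance.  When the
balance holds on an interval (possible only when the required net
tether force is exactly zero, i.e. `F_load = 0` with all tethers
slack), the interval midpoint is returned and flagged
(`flat_interval`).  Attachment events are defined to carry zero cargo
displacement: admissible sites lie within `l0` of `x_eq`, so the new
tether is slack and the force balance is unchanged; the midpoint
convention is a representative choice and is not allowed to generate
spurious attachment displacements.

### Single-motor kinetics

With `F` the load on a motor (positive when opposing motion) and
`k_BT` the thermal energy:

| quantity | form |
|---|---|
| binding efficiency | `eps(F) = 1 (F≤0); (1−F/F_s)² (0<F<F_s); 0 (F≥F_s)` |
| hydrolysis back-rate | `k_off(F) = k0_off · exp(F·d_l/k_BT)` |
| stepping rate | `P_step(F) = k_cat[ATP]/([ATP]+(k_cat+k_off(F))/k_on) · eps(F)` |
| processivity | `L(F) = d_s[ATP]A e^{−Fδ_l/k_BT} / ([ATP]+B(1+A)e^{−Fδ_l/k_BT})` |
| detachment | `P_detach(F) = P_step(F)·d_s/L(F)` below stall, `P_back` at/above |

With thermal noise the configuration-level rate of each event is the
average of the force-dependent rate over the truncated-Gaussian cargo
position, times the site occupancy `z_k`.

### Finite relative chain

Translation invariance makes the projection onto occupancy *patterns*
(counts from the rearguard site; string notation with `|` separating
adjacent lattice sites, so `MM` is one doubly occupied site and `M|M`
two adjacent singles) Markov again: the projected rate
`λ_rel(σ′,σ)` is the sum of the elementary rates from any fixed
representative of σ into the class of σ′, and the associated mean
cargo displacement `d_av` is their rate-weighted average.  Events that
do not change the pattern (e.g. the lone motor stepping) are *self
transitions*: they cancel in the generator but carry displacement and
are retained in the transition table, which the velocity, run-length
and step-size observables consume in full.

The generator uses the column convention `dP/dt = A·P` with
`A[i,i] = −Σ_{j≠i} λ_rel(σ_j,σ_i)` (every column sums to zero; the
lost-cargo column is zero).  `Q` is the restriction to non-empty
states; its column sums are ≤ 0 and strictly negative wherever there
is flux into the absorbing state.

### Extent bound and verified closure

Stalling bounds the rearguard–vanguard extent: `max_extent` implements
the a priori bound
`n = max(⌈(m_bar·F_s − F_load)/(k_el·d_s)⌉+1, ⌈F_load/(k_el·d_s)+2l0/d_s+6σ/d_s⌉)`.
Taking the *maximum* of the force-stretch and slack terms is, however,
not always closed: a pattern can combine tether slack (up to `2·l0`)
*and* force stretch, so a state at the bound may still step outward.
The model builder therefore verifies closure constructively — it
enumerates the space at the a priori `n`, probes every state's
extent-increasing events (vanguard step, attachment outside the
current span), and enlarges `n` until no transition leaves the space.
The stall condition guarantees termination; the Gillespie extent
invariant (no simulated configuration ever exceeds the final bound,
checked across 1e5 events) confirms it empirically.  With the
reference parameters and `m_bar = 2` the closed extent is 36 sites (38
states); `m_bar = 3` gives 40 sites (862 states).  A user cap `n_cap`
truncates instead; out-of-space events are then dropped *identically*
in the exact solver and the simulator, and counted in the manifest.

### Numerical choices

- **Quadrature.** The thermally averaged rates integrate a
  piecewise-smooth integrand: the force law kinks at `a_k ± l0` and the
  detachment rate *jumps* at the stall position
  `a_k − l0 − F_s/k_el`.  The integration interval is split at these
  breakpoints and a fixed-order Gauss–Legendre rule (order 21,
  configurable) is applied per smooth piece — deterministic and, per
  the test suite, within 1e-8 relative of adaptive quadrature
  (in practice machine precision).
- **Propagation.** `exp(A t)·P` uses `scipy`'s matrix-exponential
  action; for long horizons at moderate dimension (≤1500 states,
  `‖A‖t ≳ 200`) the dense scaling-and-squaring exponential is used
  instead, whose cost is logarithmic rather than linear in `‖A‖t`.
- **Quasi-stationary distribution.** Dominant eigenvector of `Q`
  restricted to the states reachable from `M` (graph search on the
  rate pattern): dense `eig` up to 3000 states, sparse shift-invert
  (σ=0) beyond.  Unreachable states carry exactly zero.  The result is
  cross-checked in tests against long-horizon conditional propagation
  (total variation ≤ 1e-6) and against the survival decay rate.
- **Run length.** `∫v(t)dt` is evaluated in closed form as
  `Σ d_av·λ_rel·τ` with `τ = −Q⁻¹P0` the expected occupancy times
  (sparse LU), and cross-checked against time quadrature of `v(t)`.
- **Step-size support.** Displacements are grouped at 1e-6 nm;
  displacements below 5e-7 nm (attachments, slack-motor steps —
  provably exact zeros, snapped at 1e-9 nm) are excluded from the
  support.  The signed distribution is kept; headline modes are
  reported over positive lengths.
- **Determinism.** State order is graded (motor count, then span, then
  lexicographic occupancy; absorbing state last), so generators are
  bit-reproducible; the simulator uses `numpy`'s PCG64 with explicit
  seeds throughout.

## Parameters

Units repo-wide: nm, nN, s, M, K.  The measured kinesin-1 set (defaults):
`k_cat=105/s`, `k_on=2e6/(M·s)`, `k0_off=55/s`, `[ATP]=2e-3 M`,
`F_s=0.006 nN`, `d_s=8 nm`, `d_l=1.6 nm`, `δ_l=1.3 nm`, `A=107`,
`B=2.9e-8 M`, `T=300 K`, `k_el=0.32e-3 nN/nm`, `P_att=5/s`,
`P_back=2/s`; `F_load` defaults to 0 and `m_bar` to 2.
`A` is dimensionless 107 — this gives the physiological zero-force
processivity `L(0) ≈ 855 nm`; reading it as 1e7 would give ~0.5 mm.

Two mechanical parameters are not part of the measured set and are
package choices:

- `l0 = 110 nm` — a typical kinesin tether rest length (as used in
  Monte-Carlo studies of this system); configurable.
- `sigma_th = sqrt(k_BT/k_el) ≈ 3.60 nm` — equipartition of the cargo
  in a single-tether harmonic well; `sigma_th = 0` selects the
  noiseless model variant.  Both enter the extent bound and the rates.

`P_att` is interpreted as a total rate per unattached motor, split
uniformly over admissible sites (a per-site interpretation is
available via `att_per_site`).

## Parameter sensitivity of headline features

The step-size distribution's mode structure depends on `F_load` and
`l0`.  At `F_load = 0` the two-motor distribution has its modes at
4 nm and 8 nm and rare >8 nm steps at 12, 16, … nm.  Under load the
shared-load (4 nm) steps require spans beyond `2·l0 + F_load/k_el`,
which the chain visits rarely; already at 1 pN the secondary modes sit
at `F_load/(2k_el)` and `d_s − F_load/(2k_el)` (1.56 / 6.44 nm)
instead.  Computed second-mode locations: 4.0 nm (0 pN), 0.31 nm
(0.2 pN), 0.78 nm (0.5 pN), 1.56 nm (1 pN).  Similarly, the claim that
a lone motor outruns a larger ensemble holds at the zero-load limit
(807.7 > 804.5 > 800.6 > 796.1 nm/s for `m_bar = 1..4`, noiseless) but
inverts at finite load for `m_bar ≥ 3`, where load sharing speeds the
front motor up while slack rear tethers (with `l0 = 110 nm`) never
drag.  These are statements about this parameterization, not artifacts
of the solver.

## The stochastic oracle, and what the tests do and do not show

The Gillespie simulator samples the *absolute* chain with exactly the
same mechanics and kinetics code as the exact solver (one rate
implementation, two solution paths), memoizing event tables per
relative configuration — legitimate because the rates are translation
invariant, a property tested independently.  Agreement between the two
paths (distribution TV ≤ 0.02 at 20k trajectories, run lengths within
3 SE, step histogram TV ≤ 0.03) therefore isolates projection/solver
defects; it cannot validate the *physical* modelling assumptions.  In
particular: cargo inertia and explicit Brownian dynamics are replaced
by the instantaneous-equilibrium + truncated-Gaussian approximation;
backward stepping and motor-cargo unbinding are absent; all motors are
mapped to one cargo attachment point (multiple motors may share a
site).  Conclusions transfer to real cargo transport only insofar as
those assumptions do.

## Problem sizes used

Exact computations use the full closed state spaces (38 states for
`m_bar = 2`, 862 for `m_bar = 3`, ~13k for `m_bar = 4` noiseless).
Oracle comparisons use 20,000 trajectories (distribution and
run-length checks), 4,000 trajectories for the conditional-velocity
drift, and 20,000 events for the step histogram; fine-grid load sweeps
use a 0.2 pN grid over 5–7 pN.  These sizes make every stochastic
check conclusive at its stated tolerance while keeping the default
suite fast.

## Known limitations

- The architecture allows `m_bar > 4`, but spaces grow combinatorially
  with the extent; beyond `m_bar ≈ 5` at full extent the dense
  eigen/exponential paths should be replaced by their sparse variants
  throughout.
- Near-stall loads make the chain stiff (detachment rates approach
  zero): run lengths grow by orders of magnitude and the fundamental-
  matrix solve, while exact, amplifies the model's own sensitivity to
  the detachment law there — the fine-grid peak is a feature of the
  model, not necessarily of real kinesin.
- Multiple motor species are not supported (single parameter set per
  model).
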