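# Methods

## Body model

The body is a planar double inverted pendulum: link 1 (legs) hinged at
the ankle, link 2 (HAT: head-arms-trunk) at the hip. Default
anthropometrics describe a young adult male of 84.14 kg / 1.78 m:

| quantity | value | meaning |
|---|---|---|
| m₁, m₂ | 28.047, 56.093 kg | leg / HAT mass (⅓ and ⅔ of body mass) |
| L₁, L₂ | 0.90, 0.88 m | segment lengths |
| r₁, r₂ | 0.576, 0.318 m | CoM offsets from ankle / hip |
| I₁, I₂ | m·r² | segment inertias about their own CoM |
| g | 9.81 m/s² | gravity |

Inertias are recomputed as `I = m r²` so that invariant holds exactly
(the rounded printed-table values differ by ~0.2%). The equations of
motion use the standard inertia constants `A = I₁+I₂+m₁r₁²+m₂(L₁²+r₂²)`,
`B = m₂L₁r₂`, `D = I₂+m₂r₂²`. The Coriolis matrix is derived from the
kinetic energy and satisfies the skew-symmetry of `Ṁ − 2C` (the tests
check this against a finite-difference `Ṁ`).

**Gravity sign convention.** `gravity_torque` returns the *destabilizing*
generalized torque `−∂U/∂q`, which enters the forward dynamics with a
plus sign, `M q̈ = τ − C q̇ + G`. This makes the upright reference an
exact equilibrium of the uncontrolled system and any tilt diverge, which
is the physically required behavior (an under-critically-stiff ankle must
fall without active control — a test verifies this against the
eigenvalues of the linearization). The bias torque is `−G(q_ref)`, so a
tilted reference is still an exact equilibrium of the controlled system.

**Critical stiffness.** Linearizing gravity at the reference gives the
Jacobian `g·[[m₁r₁+m₂L₁+m₂r₂, m₂r₂],[m₂r₂, m₂r₂]]`. The critical hip
stiffness is `g·m₂·r₂ ≈ 175 Nm/rad`. For the ankle, the value derived
from these segment parameters is `g·m_tot·L_com ≈ 829 Nm/rad`, while the
conventional reference figure for this parameter set is 654 Nm/rad; the
package exposes both (`critical_ankle_stiffness`, a configurable constant
defaulting to 654, and `critical_ankle_stiffness_derived`) and sets the
default ankle stiffness directly to the operating value 523 Nm/rad rather
than deriving it from either critical value.

## Controller

Four torque components sum at each step.

* **Stiffness/damping** (defaults): K_a = 523, B_a = 30, K_h = 350
  (= 2 × critical, μ_h = 2), B_h = 44 (Nm/rad, Nms/rad).
* **Intermittent PD.** The feedback variable is the VIP angle
  `q_com = atan2(z_com, y_com)` of the ankle-to-CoM line, reconstructed
  each step from the joint angles; its velocity is the backward
  difference of consecutive samples (first sample: zero). The controller
  reads the state δ = 0.2 s in the past and forms errors
  `Δq = π/2 − q_com(t−δ)`, `Δq̇ = −q̇_com(t−δ)`.
  The switching rule is `Δq·(Δq̇ + Φ·Δq) > 0` with Φ = 0.4: the
  first/third quadrants of the error phase plane *plus* a slice of slope
  −Φ cut from the second/fourth quadrants. The quadrants are the unsafe
  regions of the gravitational saddle, where the state diverges without
  intervention; near the stable manifold (steep negative slope) the
  controller stays off and lets the intrinsic dynamics pull the state
  back. Note the sign: a rule with `−Φ` inside the bracket would *shrink*
  the active set below the unstable manifold's slope and demonstrably
  destabilizes the model; only the widening orientation reproduces the
  reference sway indicators, so that is what is implemented. The boundary
  (strict inequality, including Δq = 0) maps to "off".
  When active, the ankle and hip channels output `P_a Δq + D_a Δq̇` and
  `P_h Δq + D_h Δq̇` (defaults 875/125 and 0/0: pure ankle strategy;
  the canonical pure hip strategy uses 1120/305).
* **Soft clipping** (optional, ankle channel only, modeling limited
  torque transmission to the ground): `AS − AS³/(3σ²)` inside ±σ,
  constant ±2σ/3 outside — odd, continuous, non-decreasing.
* **Noise.** Two independent channels of Gaussian white noise passed
  causally (sample-by-sample recursion, zero initial filter state)
  through a 4th-order low-pass Butterworth at 10 Hz. The white input is
  pre-scaled by the filter's noise power gain `√(Σh²)` (computed once
  from the impulse response) so each channel's long-run standard
  deviation equals the target 2.844 Nm without per-run renormalization,
  leaving realization statistics unbiased. Channel sub-streams are
  spawned from the master seed, so the two channels are independent and
  a run is bit-reproducible from its seed.

## Simulation

Forward Euler at dt = 1 ms (the scheme used to generate all reference
indicators; a test verifies first-order convergence under dt-halving and
work-energy consistency on noiseless runs). Default duration 240 s,
transient discard 30 s. The sensory delay is realized by indexing the
stored VIP series exactly `delay/dt` samples behind the write position;
during the first δ seconds the delayed state is the initial state
(pre-filled buffer), so a run started at rest has no spurious torque
transient. Initial conditions default to the exact reference at rest,
letting the noise excite sway — this matches the stationary character of
the target behavior and avoids an arbitrary perturbation.

A run terminates early, flagged *fell*, when |q_com − 90°| exceeds 30°.
A run is classified **unstable** if it fell or its post-transient VIP
excursion exceeds 10°. Stable sway is well below 1°, and unstable runs
diverge far beyond 10°, so the classification is insensitive to either
cut over a wide band; both thresholds are configurable.

## Analyses

* **Sway summary**: standard deviations of q_com, q₁, q₂ (degrees) and of
  each torque component per channel (Nm) over the post-transient record.
* **Off-time fraction**: fraction of post-transient samples with the
  switch off. It is defined by the error trajectory alone, so it is
  meaningful even at zero gains.
* **Intermittent power**: per joint, the time average of τ_I·q̇. The
  headline value is the *magnitude* average `mean(|τ_I·q̇|)`; the signed
  net average is also reported but is an order of magnitude smaller for
  the ankle strategy because concentric and eccentric phases nearly
  cancel. (The magnitude average is the variant that matches the
  reference indicator values.)
* **Anti-phase regression**: OLS slopes between the two joint angular
  accelerations in both orientations plus the Pearson correlation; the
  headline slope is the orientation with |slope| > 1 (the two slopes
  multiply to r², so at most one can). Accelerations are the values
  computed inside the dynamics step, not re-differentiated.
* **RoV scan**: per-axis stability interval of one intermittent gain,
  holding the others at base values; a grid point is stable when a
  majority of seeds yields a stable run, and the interval is the
  contiguous stable block containing the base point. Refining the grid
  cannot move the reported endpoints by more than one coarse cell.
* **μ_h sweep** (`K_h = μ_h · g·m₂·r₂`, other parameters fixed) and the
  **saturation experiment** (σ list, ankle strategy) report majority
  stability plus the relevant summary statistic per condition.

## Problem sizes used

Statistics are computed from 240-s runs (210 s post-transient, 210 000
samples) averaged over 5 seeds; experiment protocols (RoV scans, μ_h
sweep, borderline mixed strategies) use majority votes over 3 seeds per
condition. The per-step loop is JIT-compiled (numba), so a full 240-s
run takes tens of milliseconds after the one-off compilation.

## Known behavior and limitations

* With the default ankle strategy the model reproduces the canonical
  indicator set (sway stds ≈ 0.18/0.15/0.31°, off-time ≈ 43.7%,
  intermittent-torque std ≈ 2.4–2.5 Nm, |power| ≈ 0.013 W, acceleration
  slope ≈ −3.7), the hip-strategy set, the borderline mixed-strategy
  stabilizations (including robustness to doubling the added component),
  the soft-clipping cliff between σ = 9 (stable) and σ = 8 (unstable),
  and gain ranges of variation close to P_a ∈ [408, 2562] and
  P_h ∈ [980, 1260].
* The μ_h sensitivity of the ankle strategy is qualitatively reproduced
  (std(q_com) grows monotonically as μ_h decreases from 2) but the
  instability onset sits at μ_h ≈ 1.0 in this implementation, lower than
  the reference figure of 1.2, and the low-μ_h sway amplitudes are
  roughly half the reference values; the onset and amplitudes in this
  marginal regime are sensitive to modeling details not fully pinned
  down by the published constants. The hip strategy's stable μ_h band is
  a narrow neighborhood of 2, strictly contained in the ankle strategy's
  band, as expected.
* The model is sagittal-plane only: no medio-lateral sway, no foot/CoP
  contact geometry (the clipping threshold is a proxy), no muscle-level
  (Hill-type) actuation, no state estimation beyond the fixed delay.
* The synthetic noise emulates the *band* and *power* of the physiological
  disturbance, not its detailed spectrum; passing tests show the
  controller's behavior under this stationary band-limited drive, not
  under real non-stationary physiological noise.
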