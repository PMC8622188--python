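# Methods

## Model

The duplex is two chains of rigid pendulums (the nitrogenous bases) on
elastic threads (the sugar-phosphate backbones), with elastic hydrogen-bond
links between complementary bases. The state is the pair of angle arrays
φ₁, φ₂ (rad, counterclockwise, never wrapped modulo 2π — the angles enter
the forces only through sines, and the observables track cumulative
deviations) and their time derivatives. Forces per site are:

* **backbone torsion** K·(discrete second difference) in the interior,
  single-neighbour coupling K·(φ_neighbour − φ_site) at the two chain
  ends. The per-site K multiplies the whole difference stencil (not
  symmetrized into half-site averages), so exact energy bookkeeping holds
  only for homogeneous chains;
* **pair restoring and cross terms** derived from the hydrogen-bond
  stiffness k₁₂ and the lever arms R of the two pair members;
* **external influence** F = −λβ·φ̇ + M(t): viscous dissipation
  (coefficient β per base type, globally scaled by the dimensionless
  viscosity factor λ) plus an applied torque, by default the same M(t) on
  every pendulum of both strands (the target set is configurable because
  the source model leaves it open).

The model deliberately excludes hydrogen-bond breaking (no open-state
formation), stacking/helicoidal terms, bending, supercoiling, and thermal
(Langevin) forcing; dissipation is purely deterministic.

### The strand-2 sign structure

The published equations give strand 2 a pair-restoring term of opposite
sign to strand 1 (`+k₁₂R₂(R₁+R₂) sin φ₂`). We implement this verbatim as
the default. Its consequence, derived and verified numerically here: the
all-zero equilibrium is a **saddle**. For an isolated A·T pair the
linearized acceleration matrix has eigenvalues −8.01×10²³ and
+3.68×10²³ s⁻², i.e. one oscillatory mode (ω ≈ 8.95×10¹¹ rad/s) and one
exponentially growing mode (rate ≈ 6.06×10¹¹ s⁻¹). Under any forcing,
strand 2 therefore leaves the zero state and relaxes onto a flipped
equilibrium near φ₂ ≈ π, after which oscillations about that state damp at
a λ-controlled rate. The qualitative viscosity phenomenology (fast
settling at high λ, persistent oscillation at low λ) is unaffected, but
the *linear static profile is not the long-time limit* of the nonlinear
dynamics: `linearized_steady_state` warns when the stiffness operator is
indefinite, and the steady-state consistency check in the acceptance suite
fails by design under the default convention. A `sign_convention="symmetrized"`
switch (strand 2 mirrored to match strand 1) is provided as a clearly
non-default diagnostic; under it the zero state is stable and damped
integration converges to the linear static solve to better than 0.1%
(covered by a passing test).

## Parameters

Per-base constants (SI): inertia I (kg·m²), lever R (m), backbone
stiffness K (J), pair stiffness k₁₂ (N/m, equal within a Watson–Crick
pair), dissipation β (J·s). The published table values (originally in
10⁻⁴⁴ kg·m², Å, 10⁻¹⁸ J, 10⁻² N/m, 10⁻³⁴ J·s) are stored as SI decimal
literals so the mapping is bit-exact. λ defaults to 1 and spans the
studied range 0.1–4; the torque amplitude defaults to 10⁻²² N·m, at which
constant and slow-cosine (ω ≤ 10⁹ s⁻¹) forcing drive nearly identical
dynamics. A YAML override table supports sensitivity studies; only
A/C/G/T are accepted (ambiguity codes are rejected, not coerced, since no
coefficients exist for them).

## Numerics

* **Integrator**: fixed-step classical 4th-order Runge–Kutta on the 4n
  first-order system; transparent and bit-wise deterministic. Default
  dt = 10⁻¹⁴ s: the fastest linearized mode, ω ≈ √(4K/I) ≈ 1.4×10¹³ 1/s
  (period ≈ 4.5×10⁻¹³ s), is resolved ~45-fold. Steps with
  dt·ω_max > 0.6 are rejected up front. An adaptive RK45 backend
  (scipy.integrate.solve_ivp) is available for cross-checking.
* **Verification** is two-route: the vectorized right-hand side and
  integrator are compared against an independently coded scalar-loop
  tiny-step (dt = 10⁻¹⁶ s) integrator (agreement ≲ 10⁻⁹ rad over 10 ps on
  a 10-bp duplex, against a 10⁻⁸ rad gate), against term-by-term hand
  evaluations of interior and boundary equations, and against the
  closed-form 2×2 pair eigensystem (frequency agreement ~10⁻⁷ relative,
  gate 10⁻³).
* **Mode extraction** for the frequency check uses linear-prediction
  (Prony-type least squares on the autoregressive recurrence, then
  polynomial roots) rather than an FFT: the saddle's growing
  non-oscillatory mode dominates the spectrum on any window short enough
  to stay in the linear regime, while linear prediction separates all four
  complex rates cleanly.
* **Output decimation**: ~1000 stored snapshots per run by default
  (first/last steps always kept; full resolution on request) keeps
  trajectory files bounded.
* **Envelope/damping fits**: the steady offset is the mean over the final
  quarter of the window (constant torque induces a nonzero, slowly
  drifting mean); peaks of |deviation| are detected with a minimum
  separation of a quarter of the dominant period (zero-crossing estimate;
  |·|-rectified signals peak twice per period), and the decay rate is the
  least-squares slope of log peak amplitude vs. time, with R² reported as
  fit quality. Peaks below 10⁻⁹ of the largest are excluded as numerical
  noise. Recovery is within 5% for synthetic damped cosines with decay
  rates 10⁷–10¹⁰ 1/s. Degenerate inputs (all-zero series, too few
  extrema) are flagged, not silently fitted.

## Synthetic data

The studied gene sequences (interferon alpha 17, n = 980; a 5000-bp
Drosophila fragment) are not public in the source material, so experiments
run on seeded random surrogates of matching length at 50% GC
(`interferon_like`, `drosophila_like`), generated with numpy's PCG64 (the
algorithm identifier is recorded on the `SequenceSpec`). The generator draws
strong/weak pair type per site from the GC fraction, then a uniform member
of the pair, so both strands are unbiased. What this does *not* emulate:
real genes' local GC structure, repeats, and correlations — conclusions
from passing tests are about the model's response to sequence
heterogeneity in general, not about those specific genes.

## Experiment sizes

Tests and the acceptance script use scaled-down configurations chosen so
the full pipeline still exhibits the phenomenology: unit tests run 10–50 bp
duplexes over 10⁻¹²–10⁻⁹ s; the sweep checks use n = 100 over 2 ns
(five λ values); the acceptance script runs the interferon-length n = 980
sweep over 2 ns. The long-window comparison (published at 6 ns) is
exercised at proportionally reduced spans with windows at the first and
last sixth of the span. Full gene-scale presets (n = 980 over 6 ns,
n = 5000) are one function call away but not part of the default suite.

## Known limitations

* The printed strand-2 sign structure makes the zero state a saddle (see
  above); whether that is the intended geometric convention is an open
  question of the source model. All stability statements here are
  conditional on the convention chosen.
* Exact discrete energy conservation is not guaranteed for heterogeneous
  sequences (verbatim per-site K stencil).
* No open states: angles may grow arbitrarily large without any change in
  the hydrogen-bond term; large-|φ| behaviour signals instability but has
  no bond-breaking interpretation.
* The envelope decay-rate fit assumes a roughly exponential settling; at
  very low λ (little decay within the window) the fitted rate has low R²
  and should be read together with the amplitude ratio.
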