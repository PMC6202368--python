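# Methods

## Circuit model

The skin under a dry measuring electrode is modelled as two conduction
branches in parallel, both seeing the effective voltage
`v_eff = v + e_dc` (the applied stimulus plus a constant series EMF standing
in for endogenous skin and half-cell potentials):

* **Sweat-duct memristor.** Memductance `G_D(x) = g_min + (g_max - g_min) x`
  with a dimensionless duct-filling state `x` clipped to [0, 1]. The state is
  driven by the effective voltage (electro-osmosis is field-driven), with
  separate fill and drain gains and first-order relaxation to a baseline
  filling:

      dx/dt = a(v_eff) v_eff - (x - x0)/tau_x,
      a = a_plus if v_eff > 0 else a_minus.

  This is the minimal state equation that reproduces all the observed loop
  morphologies: symmetric gains give odd-symmetric transversal loops,
  unequal gains give the asymmetric class (large first-quadrant lobe, small
  third-quadrant lobe), and the relaxation term makes the loop shape
  stabilize over the first two periods. Driving the state with current
  instead of voltage is a switch away (the drive enters only through the
  derivative function) but voltage drive is the default, as electro-osmotic
  flow follows the field.

* **Stratum-corneum branch.** An NTC-thermistor conductance
  `G_S(T) = g_ref exp(-B (1/T - 1/T_ref))` (Arrhenius form, non-decreasing
  in T) heated by its own Joule power through a first-order lumped thermal
  circuit,

      dT/dt = (G_S(T) v_eff^2 - (T - T_amb)/R_th)/C_th,

  in parallel with a capacitance `C_S`. Because the heating follows
  `v_eff^2`, the temperature (and hence the conductance) peaks twice per
  stimulus period; the resulting loop touches its pinch *tangentially*.
  The electro-thermal loop gain `R_th G_S v^2 B / T^2` must stay below 1;
  the packaged parameter ranges keep it near 0.2–0.4, and the integrator
  flags any non-finite or physically absurd (> 10^4 K) temperature as a
  numerical failure naming the regime.

The measured current is
`i = (G_D(x) + G_S(T)) v_eff + C_S dv/dt + noise`, with the capacitive term
evaluated from the analytic stimulus derivative and additive i.i.d. Gaussian
current noise (default sd 50 nA, an order of magnitude under the smallest
noise-exclusion threshold). The small-signal admittance about an equilibrium
state is `Y = G_D(x_Q) + G_S(T_Q) + j*2*pi*f*C_S`.

### Integration

Fixed-step classical RK4 on the stimulus sample grid with 10 internal
substeps per sample (configurable). At 500 samples/period this resolves the
fastest state dynamics (thermal time constants of order seconds, duct
relaxation of order 10 s) by 3–5 orders of magnitude; halving the step or
oversampling 20x changes NL by well under 0.5% (tested). The duct state is
clipped to [0, 1] after each full step. Stiff parameter regimes are out of
scope; they raise rather than silently degrade.

## Stimulus protocol

Five stimulus types — sinusoids at 0.4 / 0.8 / 1.2 V, a triangular wave and
a decaying ("non-periodic") sinusoid at 1.2 V — crossed with six
frequencies, 3 periods each, 500 samples per period. Only the frequency
endpoints (0.05 and 2.5 Hz) are fixed by the protocol; the packaged sweep
{0.05, 0.1, 0.25, 0.5, 1, 2.5} Hz fills the interior with a 1–2.5–5 ladder
and is exposed as configuration. The decaying-sine envelope is linear from 1
to 0 over the three periods (an exponential variant pinned to the same
endpoints is available); the protocol's sign/order randomization is
reproduced as an optional seeded shuffle and affects no statistic.

## Synthetic population

Subjects are drawn from a five-class phenotype mixture with default weights
6 : 10 : 8 : 1 : 3 (over 28), matching the observed forehead morphology
counts: symmetric large-lobe, small-lobe, asymmetric, offset-shifted pinch,
and thermistor-dominated two-pinch loops (no duct contact,
`g_min = g_max = 0`). Per-class parameters are drawn log-normally (normally
for the DC offset) around medians chosen from physical reasoning, not fitted
to any subject data: duct conductances of a few to tens of µS so that peak
currents stay under 100 µA at 1.2 V, two-pinch currents of 2–10 µA,
sub-to-few-kelvin temperature swings, and a stable electro-thermal loop.
The class defaults are packaged as a versioned table
(`PHENOTYPE_CONFIG_VERSION`).

What the generator emulates: the loop-morphology classes, the amplitude and
frequency dependence of lobe area and NL, the pinch drift away from the
origin with frequency (via `C_S`), DC offsets, current noise, and the
after-effect of a non-linear measurement on subsequent ones (state
carry-over mode). What it does not: electrode electrochemistry, sweat-gland
physiology, inter-subject correlations between parameters, drift within a
session, or the extended-memristor regime `i = G(x, v) v` (the simulator is
a generic memristor by construction). Passing tests therefore validate the
analysis pipeline and the qualitative circuit mechanisms, not quantitative
agreement with any human cohort.

## Loop statistics — numerical choices

* **NL.** `v_max` is the stimulus amplitude; `i(0.5 v_max)` and
  `i(0.75 v_max)` are linearly interpolated on the ascending-voltage branch
  restricted to the first quadrant (the loop's other branch would give
  different values); `i_max` is the global current maximum of the period,
  earliest sample on ties. Negative-sign stimuli are folded to the positive
  half-cycle by multiplying v and i by the stimulus sign. NL is exactly
  invariant to current DC offsets. It is *not* invariant to a sign flip of
  the stimulus on a memristive subject: the flip swaps which duct phase
  (filling vs draining) coincides with the ascending branch. Denominators
  below 1e-12 A raise a degenerate-loop error.
* **Lobe area.** The closed V-I curve is split at its two voltage extrema
  into an ascending and a descending branch; both are resampled onto a
  common uniform voltage grid (500 steps, mirroring the sampling density)
  and the per-step absolute trapezoid-area differences are summed, split by
  the sign of the mid-step voltage (A1: v >= 0, A2: v < 0). If a branch is
  not monotone in voltage the method falls back, with a warning, to
  recursive self-intersection splitting plus shoelace areas. On noiseless
  simulated loops the grid method agrees with an independent polygonization
  oracle to ~0.05%; measurement noise perturbs both estimates at the
  percent level for small lobes, so the standing oracle comparison is run
  on noiseless loops.
* **Pinch detection.** Brute-force O(n^2) segment-pair intersection of the
  closed polyline, performed in range-normalized coordinates so the
  geometric epsilons are scale-free. The admissible intersection range is
  widened by 1e-9 so that crossings located exactly on a sample vertex — a
  loop through the origin at a voltage zero crossing — are found.
  Intersections within 1% of the per-axis data range merge into one pinch.
  Branch slopes come from a +/-5-sample local linear fit; a pinch is
  tangential when the slope angles agree within 15 degrees of arc. The
  thresholds are configurable; exact intersection of noisy polylines is
  ill-posed, and near-degenerate loops (high frequency, NL -> 2) have
  branch-slope gaps below the classifier tolerance even for the duct
  mechanism, so mechanism classification is meaningful only on
  well-developed loops. Pinch counting on noisy tangential loops may report
  spurious crossings; the two-pinch mechanism check is run noiseless.
* **Lock-in.** In-phase/quadrature demodulation over whole periods
  (truncating with a warning otherwise): `g = 2<i sin>/A`, `b = 2<i cos>/A`,
  `c = b/(2 pi f)`; consistent with the closed-form phase shift to < 0.1
  degree on linear RC traces.

## Cohort statistics

Rows with `i_max` strictly below the amplitude-specific threshold
(2.1 / 1.4 / 0.7 µA at 1.2 / 0.8 / 0.4 V) are excluded; equality retains
(the exclusion targets currents *below* threshold). Unknown amplitude
levels fall back to 1.75 µA/V with a warning. Percentiles use linear
interpolation between order statistics. The mixed model
`NL ~ 1 + |amplitude| + log2(frequency)` with a per-subject random intercept
is fitted by REML (statsmodels MixedLM); 95% CIs are Wald intervals on the
fixed effects — the same flavour a standard mixed-model coefficient table
reports — rather than profiled intervals, and no denominator-df correction
is applied (CIs, not p-values, are reported). The frequency coefficient is
per doubling; the conventional quote "NL increase per bisection" is its
negation. The boundary map takes, per frequency, the smallest tested
amplitude whose group statistic strictly exceeds the threshold (default
2.05): the `median` rule marks where the typical subject is non-linear, the
`p5-whisker` rule where more than 95% of subjects are.

## Known limitations

* All quantitative simulator parameters are package choices; cohort-level
  regression coefficients from the synthetic population need not match any
  measured cohort.
* Pinch detection is exact-geometry based; smoothing or averaging should
  precede it on noisy real recordings.
* The extended-memristor regime (conductance depending directly on the
  instantaneous voltage) is not modelled; at 1.2 V / 2.5 Hz real skin can
  leave the generic-memristor domain.
* The recording-format converter for externally deposited data is a
  template: the deposit layout is not standardized, so field mapping is left
  to the user.
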