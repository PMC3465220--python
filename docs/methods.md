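# Methods

This note records the modeling assumptions, parameter choices, numerical
methods, and known limits behind `neoglyc`.  It is the companion to the
README's overview; nothing here is needed to *use* the package, but all of
it matters when interpreting its output.

## 1. Metabolic model

States: plasma glucose `G` (mmol/L), plasma insulin `I` (mU/L),
interstitial insulin `Q` (mU/L).

```
dG/dt = −pG·G − SI·G·Q/(1 + alphaG·Q) + (P(t) + EGPnet) / (180.16·Vg)
dI/dt = −nI·I/(1 + alphaI·I) + (u_ex(t)·1000/60 + uEn) / Vi
dQ/dt = kIQ·(I − Q)
```

Defaults (per kg of body weight where volumes appear):

| parameter | value | units | meaning |
|---|---|---|---|
| `pG` | 0.003 | 1/min | insulin-independent glucose clearance |
| `alphaG` | 0 | L/mU | saturation of insulin-mediated disposal |
| `SI` | identified | L/(mU·min) | insulin sensitivity (time-varying) |
| `nI` | 0.16 | 1/min | plasma insulin clearance |
| `alphaI` | 1.7e-3 | L/mU | saturation of insulin clearance |
| `kIQ` | 0.0542 | 1/min | plasma→interstitial transport |
| `Vg` | 0.6 | L/kg | glucose distribution volume |
| `Vi` | 0.045 | L/kg | insulin distribution volume |
| `EGPnet` | 2.8 | mg/kg/min | net endogenous glucose production |
| `uEn` | 0 | mU/min | endogenous insulin secretion |

`P(t)` (mg/kg/min) sums three charted sources: dextrose infusion
(`conc% × 10 mg/mL/% × mL/hr ÷ weight ÷ 60`), expressed breast milk at
72 mg carbohydrate per mL (charted in mL/kg/day, ÷ 1440), and carrier/flush
fluids treated like dextrose.  The 180.16 g/mol glucose molar mass converts
mg to mmol.

**Regime note.** Under these defaults the insulin limb is potent: at
SI ≈ 1.5e-3 a steady 0.01 U/kg/hr infusion roughly quadruples glucose
clearance.  Closed-loop operating rates therefore sit near
0.005–0.05 U/kg/hr, well below the 0.5 U/kg/hr cap, and the cap binds only
for near-zero sensitivity.  All safety properties are enforced at the
controller level and do not depend on this regime.

## 2. Insulin-sensitivity identification

SI is fitted per inter-measurement interval by an integral method.
Integrating the G equation over an interval `[t0, t1]` with measured
endpoints `G0, G1` gives one linear equation in SI:

```
SI = ( −(G1 − G0) − pG·∫G dt + ∫κ(t) dt ) / ∫ G·Q/(1 + alphaG·Q) dt
```

where `κ(t) = (P(t) + EGPnet)/(180.16·Vg)`.  `Q(t)` is computed exactly
(RK4, dt = 0.5 min) from the charted insulin schedule — the insulin cascade
does not depend on G or SI.  `G(t)` inside the integrals is approximated by
the chord (linear interpolation) between the endpoint measurements.

- **Clamping:** estimates are clamped to `[0, 0.1]` L/(mU·min) and flagged.
- **Identifiability:** when the insulin-effect integral
  `∫ G·Q/(1+alphaG·Q) dt` is below 50 (mmol·mU·min/L²), SI is unidentifiable
  on that interval; the previous value is carried forward and flagged.  A
  standalone `identifiability_diagnostic` exposes the integral.
- **Residuals:** each interval is forward-checked by re-simulating with the
  fitted SI; the signed endpoint error is reported per interval.
- **Bias:** the chord is exact when G is quasi-steady across the interval
  and biased on fast transients (the glucose time constant is ~20–50 min
  against 1–4 h sampling).  Recovery on synthetic data: constant SI < 1 %
  error; hourly random-walk SI, median |relative error| ≈ 1.5 % noise-free
  and ≈ 2.4 % at 2 % multiplicative BG noise (200-patient suites in the
  tests).

## 3. Stochastic SI transition model

Hour-to-hour SI evolution is modeled by a kernel-density estimate of the
conditional distribution of the next-hour value given the current one,
fitted to pooled `(SI_n, SI_{n+1})` transition pairs (≥ 50 required).

**Parametrization.** Kernels are product Gaussians on
`(ln SI_n, ln(SI_{n+1}/SI_n))` — level × log-ratio — with Silverman
bandwidths on each marginal.  The level/ratio parametrization is essential:
between-patient level spread (ln-sd ≈ 0.56 in the default cohort) is nearly
five times the hour-to-hour conditional spread (ln-sd ≈ 0.12), so Gaussian
kernels with marginal Silverman bandwidths in the raw `(SI_n, SI_{n+1})`
plane would leak the identity trend into the conditional variance and
inflate nominal 90 % bands to ~95–98 % empirical coverage.  With the
level × ratio parametrization, held-out coverage of the nominal 90 % band
measures 0.91 (transition pairs from the same process) and 0.89 (default
cohort traces), inside the 0.90 ± 0.02 acceptance window.

**Tables.** Conditional CDFs are precomputed on a 120-point log-level grid ×
an adaptive log-ratio grid (spacing ≤ 0.5 × ratio bandwidth, capped at 2000
points) and renormalized; rows are linearly interpolated in log-level.
Conditioning outside the fitted support raises a `RuntimeWarning` and clamps
to the nearest edge.  One-hour percentiles are read directly from the CDF;
multi-hour forecasts iterate the hourly transition by seeded Monte-Carlo
(default 1000 paths; `n_paths` is exposed so tests can run 1e5-path
oracles).  Models persist to JSON (pairs + settings; tables rebuilt on
load).

## 4. BG forecast bands

The BG percentile band at a candidate rate uses monotone coupling: BG is a
monotone-decreasing function of SI along the model flow, so the BG q-th
percentile is computed by simulating with the SI (100−q)-th percentile held
constant over the horizon.  At the one-hour horizon (a single transition,
SI constant over the hour) this is exact up to Monte-Carlo noise.  At 2–4 h
it is **conservative**: holding SI at its horizon percentile for the whole
path widens the band, placing the computed p5 0.2–0.9 mmol/L *below* a full
path-sampled Monte-Carlo p5 in the tested scenarios — the safe direction
for the dosing safety rule.  Tests pin the 1-h band to a 1e4-path MC within
0.05 mmol/L and bound the 4-h conservatism by 1 mmol/L.

## 5. Dosing controller

After each measurement, with fitted `SI_now`, reconstructed `(I, Q)` from
the charted insulin history, and the charted nutrition profile:

1. **Horizon**: time to the next planned measurement, rounded to whole
   hours, clamped to 1–4 h.
2. **Candidates**: rates `{0, 0.005, …, 0.5}` U/kg/hr (step configurable).
3. **Selection**: the candidate whose median forecast is closest to the
   5.5 mmol/L setpoint; ties break toward the lower rate.
4. **Safety**: the selection is reduced to the largest candidate whose
   forecast 5th percentile exceeds 4.0 mmol/L; if none qualifies the rate
   is 0 (`safety_reduced`).  A current BG below 4.0 mmol/L stops insulin
   outright (`below_band_stop`).  The 0.5 U/kg/hr cap is structural
   (`cap_applied` flags when it binds).
5. **Zero fitted SI**: identification clamps SI at 0 on insulin-resistant
   intervals; the log-domain stochastic model cannot condition there, so
   the controller conditions at the lower edge of the model's fitted
   support — the most-resistant sensitivity it has evidence for.  This is
   conservative: forecasts stay high, dosing is still capped, and with true
   SI near zero insulin has little BG effect.
6. **Pump arithmetic**: `[5 × weight] U` insulin in 20 mL gives
   0.25 U/kg/mL for every weight; flow (mL/hr) = rate / 0.25.

The sliding-scale comparator reproduces the threshold table: BG > 20 →
0.1 U/kg/hr; 15–20 → 0.075; 10–15 → 0.05; 5–10 → hold; < 5 → stop; starting
rate 0.05.

The SI percentile draw is shared across all candidates of one decision, so
a recommendation is bitwise deterministic given the rng seed.

## 6. Virtual cohort generator

Defaults describe a stable VLBW population on parenteral + advancing enteral
nutrition over 72 h:

- weight lognormal (median 0.760 kg, ln-sd 0.32);
- initial SI lognormal (median 1.73e-3, ln-sd 0.557); hourly geometric
  random walk, step ln-sd 0.12, plus a per-patient constant drift with
  ln-sd 0.015/hr, clipped to [1e-5, 5e-2];
- initial BG lognormal (median 11.4, ln-sd 0.263), rejection-sampled
  ≥ 10 mmol/L (an enrolment criterion);
- dextrose GIR lognormal (median 7.9 mg/kg/min, ln-sd 0.313) at 10 % or
  12.5 % concentration; EBM ramping to a lognormal target (median
  15.8 mL/kg/day) clipped to [0, 60]; a 5 % carrier at 0.5 mL/hr;
- measurements every 2–4 h (uniform; 1–3 h, ≤ 12/day in the short-term
  preset) plus a Poisson blood-gas overlay (0.5/day), merged with a 15-min
  minimum gap; multiplicative BG noise, CV 2 % arterial / 5 % capillary
  (arterial fraction 0.27); the first measurement reports the true initial
  state.

**Calibration.** The per-patient drift term exists to satisfy a single
distributional constraint: the 95th/5th-percentile ratio of per-patient
median SI must be ≥ 10-fold.  The level + walk process alone gave 8.7–15.5
across seeds; with drift the spread is 15–30 while stochastic-model
coverage on cohort transitions stays at 0.89.  This calibration was fixed
before the test seeds were frozen.

**Limits.** The generator is a calibrated stand-in, not an estimate of a
clinical population: SI volatility, nutrition practice, and measurement
scheduling are plausible but not fitted to real data, so absolute outcome
numbers (time-in-band, hypoglycemia rates) from virtual trials characterize
the *controller*, not any real unit.  Closed-loop hygiene is enforced: the
controller sees only noisy observations and the charted schedules; the true
SI trajectory and true BG are hidden and used only for truth-side
simulation and analysis.

## 7. Analysis definitions

- **Hourly resampling**: linear interpolation of measurements at integer
  hours `h` with `t_first < h ≤ t_last`; no extrapolation.
- **Bands**: `[4.0, 7.0]` and `[4.0, 8.0]` closed on both ends;
  `> 10`, `< 4`, `< 3`, `< 2.7` strict.  Nesting invariants are enforced at
  construction.
- **Pooling**: whole-cohort percentages pool hourly values across patients
  (duration-weighted); per-patient rows are reported alongside.
- **SI spread**: 95th/5th-percentile ratio of per-patient median SI.
- **Comparisons**: Mann–Whitney U (with rank-biserial effect size) on
  pooled hourly BG, Fisher's exact test on hypoglycemia counts, chi-squared
  on 4–8 band counts; p-values cross-checked against R in the tests.

## 8. Numerical choices

- **Reference integration** (`simulate`): scipy `solve_ivp` LSODA,
  rtol 1e-6 / atol 1e-8, segmented at every discontinuity of the
  piecewise-constant inputs so the integrator never steps across a jump;
  breakpoints closer than 1e-9 min are merged (float-coincident event times
  otherwise create zero-length segments LSODA rejects).  Negative
  undershoots beyond −1e-7 warn; states are clamped at 0.
- **Controller fast path** (`forecast_glucose`): `(I, Q)` by vectorized RK4
  (dt = 0.5 min) per candidate rate, then an exponential integrating-factor
  scheme for G — `G_{k+1} = e^{−dA}(G_k + h/2·κ_k) + h/2·κ_{k+1}` with
  `dA = h/2·(a_k + a_{k+1})`, `a = pG + SI·Q/(1+alphaG·Q)` — which is
  positivity-preserving and overflow-safe; it matches `simulate` to
  max(5e-4, 1.5 %) on extreme overdose scenarios and much tighter in the
  operating range.
- **Identification quadrature**: trapezoid on a 0.5-min grid; the
  diagnostic equals brute-force trapezoid quadrature to 1e-8.
- **Oracles in the tests**: fixed-step Euler (dt = 0.01 min) agrees with
  the reference at equilibrium and at transient endpoints to 1e-6 mmol/L;
  whole transient trajectories are instead pinned to a fixed-step RK4
  oracle at 1e-6, because Euler's own first-order bias on a transient is
  1e-3–1e-2 mmol/L and no accurate integrator can match it to 1e-6.
- **Determinism**: every stochastic component takes an explicit seed or
  `numpy` Generator; virtual-trial patients draw independent child seeds
  via `SeedSequence.spawn`, so per-patient results are reproducible and
  order-independent.

## 9. Known limitations

- Chord interpolation biases SI estimates on fast transients (Section 2);
  with 1–4 h sampling this is the method's intended operating envelope.
- Multi-hour forecast bands are conservative (Section 4); dosing decisions
  based on them under-dose slightly rather than over-dose.
- The default parameter set puts the system in a strong-insulin regime
  (Section 1); rate *selection* behavior at other parameterizations is
  covered by config-driven tests, but default virtual-trial dose magnitudes
  should not be read as clinical guidance.
- The synthetic cohort is a calibrated generator, not a fitted population
  model (Section 6).
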