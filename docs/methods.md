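# Methods

This note records the models the package implements, the defaults it
ships, and the numerical and design choices made where the underlying
physics or the published analysis conventions leave room. Units throughout:
forces in pN, lengths in nm, energies in pN·nm, time in s, concentrations
in molar.

## Thermal energy

All assays modelled here run at 25 °C, so `kBT = 4.114 pN·nm` is the
package-wide constant (`a2mech.KBT_25C`). Every fitting function accepts an
explicit `kBT` for other temperatures; parameter containers carry their own
`kBT` and refuse to be combined across mismatched values (a crossover force
computed from two kinetics at different temperatures is meaningless).

## Worm-like chain

The Marko–Siggia interpolation is used as *the* WLC force law:

    F(x) = (kBT/Lp)·[¼(1 − x/Lc)⁻² − ¼ + x/Lc],  0 ≤ x < Lc.

It is exact in both the Hookean (`F ≈ 3kBT·x/(2·Lp·Lc)`) and the
divergence limits and is the standard choice for protein unfolding data in
the 1–50 pN range. Extensible-WLC and FJC variants are out of scope.

**Inversion.** The dimensionless form is strictly monotone on `[0, 1)`, so
the inverse (fractional extension at force) is computed by 80 steps of
vectorized bisection — deterministic, branch-free, and converged to double
precision; `wlc_extension(wlc_force(x))` round-trips to better than
`1e-9·Lc`, and zero force maps to exactly zero extension.

**Fitting.** `fit_wlc` runs least squares with `kBT` fixed and offers two
residual directions:

* `objective="force"` (default): residuals in force, the conventional
  presentation. Free-parameter starting point `Lc = 1.05·max(x)`,
  `Lp = 0.4 nm`; `Lc` is bounded just above the largest observed extension
  so the model stays defined over the whole search.
* `objective="extension"`: residuals in extension against
  `x = Lc·ξ(F; Lp)`. This is the consistent regression direction when the
  dominant noise is on the extension channel — exactly the situation for
  rupture extension gains, which are measured at matched force. With noisy
  narrow-range data the force-direction joint fit can drift into the
  degenerate Hookean valley (`Lc → ∞`, `Lp → 0`, only the product
  identified); the extension direction does not.

`fix_Lp` holds the persistence length at a known value; combined with the
extension objective the contour length then has a closed-form solution
(regression through the origin in `ξ`), used for per-step contour lengths
where only `Lc` is sought. On noise-free data every route recovers the
generating parameters exactly (asserted in the test suite at 1e-6
relative). Uncertainties are asymptotic standard errors from the Jacobian.

## Bell–Evans kinetics

`k(F) = k0·exp(γF/kBT)`. Under a constant loading rate `r` the
Evans–Ritchie most-probable force is `F* = (kBT/γ)·ln(γr/(k0·kBT))`;
for `r ≤ k0·kBT/γ` the expression is negative and `evans_ritchie_force`
clamps to zero with a warning (the rupture-force density then peaks at
zero force; a negative mode is unphysical).

`fit_bell_evans` fits `(k0, γ)` by nonlinear least squares on the
Evans–Ritchie relation, seeded by the exact back-transformation of the
linear regression of `F*` on `ln r` (`γ = kBT/slope`,
`k0 = γ·e^(−intercept/slope)/kBT`). The linear route is also exposed
(`method="linear"`); the two agree exactly on clean data, which the suite
asserts. Note `k0` enters through a logarithm: small errors in the
intercept amplify exponentially, so `k0` recoveries are intrinsically an
order of magnitude looser than `γ` recoveries.

**Stability crossover.** Two kinetic states cross at
`F× = kBT·ln(k0_a/k0_b)/(γ_b − γ_a)`, returned signed (negative =
unphysical crossing); equal `γ` raises a degenerate-parameters error. The
rate ratio `k_bound(F)/k_free(F)` (`stability_profile`) passes through 1
exactly at `F×`.

## Pulling simulator

The simulator emulates a constant-loading-rate pull of a construct with
one or more *sequential* unfolding transitions, each with its own
Bell–Evans kinetics and contour-length increment.

**Exact event sampling.** Along a ramp the cumulative hazard of a
transition has closed form, so transition forces are sampled by inverting
it against Exp(1) waiting thresholds — equivalent in distribution to the
analytic first-rupture density

    p(F) = [k(F)/r]·exp[−(k0·kBT)/(γr)·(e^(γF/kBT) − 1)]

with *zero* time-discretization bias (no `k·Δt` sub-stepping is needed;
the sampled trace is just an exact event schedule rendered onto a sampling
grid). Stand-alone rupture forces (`simulate_rupture_forces`) use the
closed-form inverse CDF directly. Both routes are KS-tested against the
analytic CDF in the suite, and the trace-level and force-level samplers
are tested to agree in distribution.

**Mechanics.** The folded construct (DNA handle + folded domain) is a
stiff WLC baseline (defaults `Lc = 20 nm`, `Lp = 10 nm`); the unfolded
polypeptide is a WLC with `Lp = 0.28 nm` whose contour length grows by the
step increment at each transition. At a rupture at force `F_r` the
extension jumps by `ΔLc·ξ(F_r)` and the force drops instantaneously by
`effective_stiffness · jump` (default 0.25 pN/nm) before the ramp resumes
at the nominal rate. The effective stiffness is a phenomenological series
stiffness that produces the sawtooth force signature detection relies on;
bead/trap hydrodynamics are deliberately not modelled. Protocols may be
specified by loading rate directly (what the downstream fits consume) or
by pulling speed × effective stiffness.

**Noise.** Gaussian, uncorrelated, per channel: 0.3 pN on force and 2 nm
on extension by default — a typical tweezer noise floor at the default
500 Hz sampling (`sampling_interval = 0.002 s`). All randomness flows from
explicit seeds; experiments spawn independent child seeds per trace, and
identical seeds give byte-identical traces.

**Default pathways.** `UnfoldingPathway.single_step()` is the A2-alone
condition: one 55.3 nm contour gain with `k0 = 0.15 s⁻¹`, `γ = 0.71 nm`.
`UnfoldingPathway.two_step()` emulates the low-CFH-concentration regime in
which the single long unfolding splits into two shorter sequential steps:
increments 27.0 + 28.3 nm (each within the observed 25–30 nm per-step
range, summing to the one-step 55.3 nm), a faster first step
(`k0 = 0.3 s⁻¹`, `γ = 0.71 nm`) that ruptures at lower force, and a
control-like second step (`k0 = 0.15 s⁻¹`, `γ = 0.71 nm`).

## Event detection

Detection looks for the co-occurrence of a force drop and an extension
gain. Moving means over `window = 3` samples on both channels suppress the
noise floor (a 1 pN drop threshold is ≈ 5σ of the smoothed force
difference at default noise); candidate runs closer than 2 samples merge,
and each run is localized at its largest single-step drop. The rupture
force is the pre-drop local maximum. The extension gain is measured where
the ramp first *recovers* the rupture force, so on noise-free data the
measured gain equals the WLC jump `ΔLc·ξ(F_r)` exactly (the naive
immediate jump would mix in the compliance recoil of the force drop);
when the trace ends first, the immediate jump is used as a fallback.
Defaults: `min_force_drop = 1 pN`, `min_extension_gain = 5 nm`.

The 5 nm gain floor implies a detection floor in force (a 55.3 nm gain
needs `F ≳ 2 pN`, a 27 nm step `F ≳ 4.5 pN`): rupture modes must sit above
it for unbiased histograms, which drives the default loading-rate ladder
below.

**Summaries.** The most probable force is the center of the tallest bin of
a uniform histogram (default 1 pN bins anchored at force 0), with half the
bin width as its uncertainty; ties break toward the lower-force bin.
Extension gains are summarized by a maximum-likelihood Gaussian (sample
mean and σ, identical to the histogram Gaussian fit for this family),
reported as mean ± HWHM with `HWHM = σ·√(2 ln 2)`. Per-event loading
rates are the least-squares slope of force on time over the final 20% of
the pre-rupture ramp, falling back to the nominal rate (with a warning)
when fewer than 5 samples are available.

## Pipeline defaults

`RunConfig` defaults to five loading rates (3, 7, 15, 40, 100 pN/s) × 66
traces = 330 traces per condition — the scale of a real campaign. The
ladder starts at 3 pN/s because at 1 pN/s the A2-alone rupture mode
(~0.8 pN) sits below the detection floor and the censored histogram
corrupts the Evans–Ritchie fit. Per-rate spectrum points use the median
per-event loading-rate estimate (measured, not nominal). The event-cloud
WLC fit uses the extension objective (noise on gains). With two or more
conditions the report adds the crossover force of each condition against
the first, computed from the *fitted* kinetics: across seeds this
recovers ≈ 8 pN in the median, with a few-pN spread driven by the 1 pN
histogram quantization acting on the log-sensitive `k0` (documented
rather than hidden: the closed-form crossover from known parameters is
exact; the pipeline value is an estimator).

Reports are canonical JSON (sorted keys) with seed, config hash and
package version as provenance and no timestamps: identical configurations
produce byte-identical reports, verified in the suite.

## Binding titrations

The dilution schedule is `steps + 1` concentrations at `top/factor^i`
(default 15 two-fold steps, i.e. 16 points down to `top/32768`; default
top 500 nM). The Hill fit frees EC50, `n` (bounded 0.3–4), amplitude and
baseline, starting from the geometric-mean concentration and the observed
signal range. `no_binding` is declared when `|amplitude| < 3·residual SD`
— an invented but stated criterion mirroring how flat series are reported;
it never triggers on clean data with nonzero amplitude. The fitted EC50 is
exposed as a Kd-equivalent only when `n` is within 25% of 1. Simulated
titrations default to 2% Gaussian noise on a unit-amplitude normalized
signal.

## Enzyme kinetics

Progress curves are modelled as a single-exponential approach to plateau,
`RFU(t) = plateau·(1 − e^(−kt))`, the simplest shape with a linear early
phase (slope `plateau·k`) and substrate depletion at long times — an
invented but stated stand-in; no Michaelis–Menten estimation is attempted.
Default sampling is 2-minute intervals for 60 minutes. The initial rate is
the least-squares slope over the first 10 minutes (6 points): long enough
to average noise, early enough that curvature bias stays within a few
percent for realistic depletion; the window is configurable and the same
window must be used for calibration and assay so the bias cancels in
relative activities. The standard curve is a straight line through the
calibration points; relative activity is the enzyme-equivalent
concentration as a percentage of the 12.5 nM reference assay
concentration, clamped at 0% (with a warning) for rates below the
intercept. Enhancement profiles require an explicit zero-concentration
reference and report fold = activity(c)/activity(0) with its maximum.

## What the simulators do and do not emulate

The generators reproduce the statistical structure the analyses assume:
Bell–Evans rupture statistics under ideal force ramps, WLC extension
jumps, i.i.d. Gaussian channel noise, Hill isotherms, exponential progress
curves. They do not emulate instrument drift, low-frequency (1/f) noise,
bead rotation or linkage artifacts, refolding/rebinding, multiple tethers,
thermophoresis physics, or pipetting errors in dilution series. Passing
recovery tests therefore demonstrates that the analysis chain is
*internally consistent and unbiased under its own assumptions* — not that
those assumptions hold for any particular instrument; on real data the
detection thresholds, bin width and rate windows are the knobs to revisit.

## Degenerate inputs and tie-breaks

* extension ≥ Lc, negative forces/extensions/concentrations: domain errors.
* fewer than 4 WLC points, < 2 distinct loading rates, < 6 titration
  points or ≤ 2 decades of span, < 3 events for a Gaussian summary, < 3
  progress-curve points in window: input errors.
* identical extension gains (zero variance): degenerate-fit error.
* equal barrier positions in a crossover: degenerate-parameters error.
* equally tall histogram bins: lower-force bin wins.
* `k0 = 0` pathways: no-event error from the force sampler; in a trace
  context the transition simply never fires and the trace is flagged
  truncated.
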