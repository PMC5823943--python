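# Methods

## Model

`stochzyme` treats a single enzyme as a semi-Markov (renewal) process on the
coarse-grained states {E, ES, EI, ESI, E+P}. Dwell times in each state come
from arbitrary distributions — collapsing many microscopic conformations
into one coarse state generally destroys exponentiality — while the future
depends only on the current state: every clock is redrawn on state entry.
Because the single enzyme is embedded in a sea of substrate and inhibitor
molecules, binding events are exponential with pseudo-first-order rates
`k_on [S]`, `k_on_EI [I]` and `k_on_ESI [I]`; the catalysis time `T_cat`,
substrate unbinding time `T_off` and the inhibitor dwell times `T_off_EI`,
`T_off_ESI` are unrestricted positive random variables.

The central observable is the turnover rate `k_turn = 1/⟨T_turn⟩`, the
reciprocal mean time between product formations. Renewal analysis gives:

* **Competitive** (inhibitor binds E only):
  `1/k_turn = K_m (1 + [I]/K_EI) / (v_max [S]) + 1/v_max`, with the
  generalized constants
  `v_max = Pr(T_cat < T_off)/⟨W_ES⁰⟩`, `K_m = (k_on ⟨W_ES⁰⟩)⁻¹`,
  `K_EI = (⟨T_off_EI⟩ k_on_EI)⁻¹`, and `W_ES⁰ = min(T_cat, T_off)` the
  uninhibited ES lifetime. The functional form is identical to the classical
  bulk law: microscopic detail enters only through the constants.

* **Uncompetitive** (inhibitor binds ES only):
  `1/k_turn = K_m A([I]) / (v_max [S]) + (1 + [I]/K_ESI) B([I]) / v_max`,
  with `K_ESI = (⟨T_off_ESI⟩ k_on_ESI)⁻¹` and two modulation factors built
  from the transforms
  `f̃_M(s) = ∫ e^{-st} F̄_cat F̄_off dt / ⟨W_ES⁰⟩` and
  `f̃_P(s) = ∫ e^{-st} f_cat F̄_off dt / Pr(T_cat < T_off)`
  evaluated at `s = k_on_ESI [I]`:
  `A = (1 − s ⟨W_ES⁰⟩ f̃_M(s)) / f̃_P(s)`, `B = f̃_M(s)/f̃_P(s)`.
  `A(0) = B(0) = 1` always; for exponential catalysis `A = B = 1` at every
  concentration and the classical law is recovered. Equivalently, `A` and
  `B` can be written probabilistically through the inhibited ES lifetime
  `W_ES = min(T_cat, T_off, T_on_ESI)` and the three-way catalysis
  probability; the package computes both representations and checks they
  agree to 1e-8.

* **Mixed** combines both factors:
  `1/k_turn = K_m (1 + [I]/K_EI) A([I]) / (v_max [S]) + (1 + [I]/K_ESI) B([I]) / v_max`.

## Inhibitor–activator duality

An uncompetitive inhibitor interrupts the ES complex at a random inspection
epoch. Length-biased sampling (the inspection paradox) means the
interrupted visit has mean remaining time `⟨W⟩/2 + σ²(W)/(2⟨W⟩)`, which
exceeds the fresh-visit mean whenever the lifetime is over-dispersed
(CV > 1). Unbinding then resets the ES clock, so a molecule that blocks
catalysis outright can *raise* the mean turnover rate. Activation at
`[I] → 0⁺` (`dk_turn/d[I] > 0`) holds iff

```
⟨T_off_ESI⟩/⟨W_ES⁰⟩ < (CV²−1)/2 + [1 − ⟨W_ES⁰|ES→E+P⟩/⟨W_ES⁰⟩] / ([S]/(K_m+[S]))
```

and, when substrate unbinding is exponential with rate `k_off`, the
equivalent simplified form

```
⟨T_off_ESI⟩ < (CV²−1)/2 · (1/v_max) · (1 + k_off/(k_on [S]))
```

Since the left side is positive, CV ≤ 1 excludes activation at any
substrate level; the right side grows as `[S]` falls, so the set of
substrate concentrations with activation is always a down-set; and if
`⟨T_off_ESI⟩ v_max < (CV²−1)/2` activation occurs at every `[S]`.
Both criteria are implemented; the simplified one refuses non-exponential
`T_off` and directs the caller to the general form. For mixed schemes no
printed closed-form criterion is exposed; duality is assessed through the
numerical derivative of the mixed rate law only.

The `{[I], 1/[S]}` plane is classified by comparing `k_turn(S, I)` with
`k_turn(S, 0)` and by the sign of `dk_turn/d[I]`: **activation** (above
baseline, rising), **transition** (above baseline, falling), **inhibition**
(below baseline, falling). Boundaries are refined per substrate level by
bisection to 1e-6 relative in I; turnover peaks on the
activation/transition border and re-crosses its uninhibited value on the
transition/inhibition border.

## Numerical choices

* **Units** are fixed throughout: time in ms, rates in ms⁻¹, concentrations
  in μM, binding constants in (μM ms)⁻¹, matching the scales where
  published kinetic constants live (`K_m` 1e-2–1e6 μM, `v_max`
  1e-2–1e5 s⁻¹). Column names embed units to prevent drift.
* **Quadrature.** All semi-infinite integrals share one policy
  (`quadrature.integrate_tail`): adaptive Gauss–Kronrod split at a
  characteristic cutoff (the 1−1e-12 survival quantile), relative tolerance
  1e-11, with the error estimate re-checked against the returned value.
  When `T_off` is exponential the ES integrals collapse onto the
  catalysis-time Laplace transform, which is closed-form for the
  exponential, two-state (hyperexponential) and gamma families — this path
  is exact and is what makes the Markovian-reduction identities hold to
  1e-10 and better.
* **Numeric Laplace transforms** (Weibull, lognormal) integrate by parts,
  `f̃(s) = 1 − s∫e^{-st}F̄(t)dt`, avoiding pdf evaluation (singular at 0
  when shape < 1); for `s·mean > 1` the substitution `x = st` keeps the
  mass at x ≈ 1 regardless of stiffness.
* **Moment matching** solves (mean, CV) → parameters in closed form for
  gamma and lognormal and by bracketed 1-D root finding on the Weibull
  shape (CV is monotone in shape); recovered moments are exact to 1e-8
  relative.
* **Dose–response derivative at zero.** The modulation factors extend
  analytically to slightly negative transform arguments, so
  `dk_turn/d[I]|₀` uses a central difference with step
  `h = 1e-4/(k_on_ESI ⟨W_ES⁰⟩)` and one Richardson extrapolation.
* **Degenerate inputs.** Absent binding channels (or a binding constant of
  0) are treated as the exact algebraic limit `K → ∞`, never a large-number
  surrogate. Points within 1e-9 relative of a phase boundary are assigned
  deterministically to the more-inhibited label and logged.
* **Simulator.** Event-driven, with fresh clocks on every state entry (the
  semi-Markov contract — persisting clocks across an ESI excursion would
  erase exactly the switching mechanism under study). Ties, a
  probability-zero event, break by the fixed priority catalysis >
  unbinding > inhibitor binding. Cycles end at product formation and are
  regeneration points, so cycle times are i.i.d.; `se(k_turn)` comes from
  the delta method on the reciprocal mean. A single integer seed drives a
  `numpy` Generator per run.

## What the fixtures emulate

The bundled scenarios (`stochzyme.FIXTURES`) carry the published constants
of the two-state catalysis model: `fig5a` (p = 0.1, k₁ = 50, k₂ = 0.5,
k_off = 2.3 ms⁻¹, k_on = 0.1, k_on_ESI = 3 (μM ms)⁻¹), the three
dose-response variants `fig5c_i/ii/iii` (k₁/k₂ = 0.1/0.1, 10/0.5, 10/0.1),
and the phase-diagram set `fig6` (k₁ = 50, k₂ = 0.5, k_on = 0.2,
k_on_ESI = 30, k_off_ESI = 50 ms⁻¹). Constants the published captions do
not print (the ESI dwell rate for the `fig5a`/`fig5c` family, the
`fig5c` substrate/binding constants, `fig6`'s per-panel k_off, and the
moments of the `fig5d` moment-matched family) are package-chosen defaults —
k_off_ESI = 10 ms⁻¹, k_off = 0.5 ms⁻¹, S = 10 μM, k_off = 2.3 ms⁻¹ and
(mean 1.5 ms, CV 1.8) respectively — selected once as kinetically typical
values that place the `fig5c_iii`/`fig5d` schemes inside the activation
regime, and flagged in each fixture's `notes`.

The synthetic scenarios exercise the theory's full parameter space but are
idealized in ways real single-molecule data are not: perfectly known
waiting-time families, no measurement dead time or photobleaching, no
substrate depletion, no enzyme–enzyme coupling, and strictly semi-Markov
dynamics (no memory of previous states). Passing tests therefore validate
the mathematics and the implementation, not the applicability of any
particular distribution family to a given enzyme.

## Problem sizes

Unit tests run the simulator at 2e3–4e4 cycles per point and Monte Carlo
oracles at 2e5–1e6 draws; the analytic-vs-simulator validation runs nine
scheme/mode combinations at 1e5 cycles each, the scale at which the 3-SE
band is a few parts in a thousand. Phase diagrams default to log-spaced
grids (16×16 in tests, 64×64 via the CLI).

## Known limitations

* Heavy-tailed waiting times without finite variance are rejected (the
  residual-lifetime formula and the duality criteria need two moments).
* The re-entry-free ordering activation → transition → inhibition along
  increasing [I] is asserted on the computed fixtures; it is not proven
  here for arbitrary distributions.
* Bulk (many-enzyme) kinetics, pre-steady-state transients and
  experimental dwell-time fitting are out of scope.
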