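# stochzyme

Single-enzyme theory of enzymatic inhibition, built on semi-Markov renewal
processes: analytic turnover rates for competitive, uncompetitive and mixed
inhibition with **arbitrarily distributed** catalysis and unbinding times,
the inhibitor–activator duality criteria, phase diagrams in the
{[I], 1/[S]} plane, and a stochastic single-enzyme simulator that
independently validates every analytic quantity.

It is intended for single-molecule enzymology and chemical-kinetics
modelling: anyone asking how an inhibitor reshapes the turnover statistics
of one enzyme whose internal conformational dynamics make its dwell times
non-exponential.

## The model in brief

A single enzyme walks the coarse states {E, ES, EI, ESI, E+P}. Binding is
exponential with pseudo-first-order rates `k_on[S]`, `k_on_EI[I]`,
`k_on_ESI[I]`; catalysis (`T_cat`), substrate unbinding (`T_off`) and
inhibitor dwell times (`T_off_EI`, `T_off_ESI`) come from arbitrary
distributions, with all clocks redrawn on every state entry. The mean
turnover rate obeys (uncompetitive case; the others are analogous)

```
1/k_turn = K_m A([I]) / (v_max [S]) + (1 + [I]/K_ESI) B([I]) / v_max
```

with generalized constants `v_max = Pr(T_cat<T_off)/⟨W_ES⁰⟩`,
`K_m = (k_on⟨W_ES⁰⟩)⁻¹`, `K_ESI = (⟨T_off_ESI⟩k_on_ESI)⁻¹`, where
`W_ES⁰ = min(T_cat, T_off)` is the ES lifetime, and two modulation factors
`A([I])`, `B([I])` — ratios of Laplace-transform functionals of the
catalysis and unbinding times at `s = k_on_ESI[I]`. For exponential
catalysis `A = B = 1` and the classical Michaelis–Menten-type law is
recovered; for over-dispersed catalysis (`CV(W_ES⁰) > 1`) an
"inhibitor" can *activate*: `dk_turn/d[I] > 0` at `[I] = 0` whenever

```
⟨T_off_ESI⟩ < (CV² − 1)/2 · (1/v_max) · (1 + k_off/(k_on[S]))
```

(exponential unbinding form; the general criterion is also implemented).
See `docs/methods.md` for the full account.

## Worked example

Two-state catalysis — a mixture of a fast (10 ms⁻¹) and a slow (0.1 ms⁻¹)
catalytic pathway taken with probabilities 0.1/0.9 — with an uncompetitive
inhibitor:

```python
import stochzyme as sz

scheme = sz.get_fixture("fig5c_iii").scheme   # two-state catalysis, ESI channel
ec = sz.effective_constants(scheme)
print(f"K_m = {ec.K_m:.3f} uM   v_max = {ec.v_max:.4f} ms^-1   K_ESI = {ec.K_ESI:.3f} uM")
rep = sz.duality_criterion_markovian_binding(scheme, S=10.0)
print(f"CV(W_ES0) = {rep.cv_WES0:.4f}   lhs = {rep.lhs:.4f} ms   "
      f"rhs = {rep.rhs:.4f} ms   activates: {rep.holds}")
k0 = sz.turnover(scheme, 10.0, 0.0)
for I in (0.0, 0.5, 2.0, 10.0, 50.0):
    k = sz.turnover(scheme, 10.0, I)
    print(f"[I] = {I:5.1f} uM   k_turn = {k:.5f} ms^-1   k/k0 = {k/k0:.3f}")
est = sz.simulate(scheme, 10.0, 2.0, 50_000, seed=7)
print(f"simulated k_turn = {est.k_turn:.5f} +/- {est.se_k_turn:.5f} ms^-1 "
      f"(analytic {sz.turnover(scheme, 10.0, 2.0):.5f})")
```

prints

```
K_m = 6.625 uM   v_max = 0.1625 ms^-1   K_ESI = 3.333 uM
CV(W_ES0) = 1.0932   lhs = 0.1000 ms   rhs = 0.9005 ms   activates: True
[I] =   0.0 uM   k_turn = 0.09772 ms^-1   k/k0 = 1.000
[I] =   0.5 uM   k_turn = 0.14897 ms^-1   k/k0 = 1.524
[I] =   2.0 uM   k_turn = 0.19886 ms^-1   k/k0 = 2.035
[I] =  10.0 uM   k_turn = 0.16150 ms^-1   k/k0 = 1.653
[I] =  50.0 uM   k_turn = 0.05901 ms^-1   k/k0 = 0.604
simulated k_turn = 0.19889 +/- 0.00079 ms^-1 (analytic 0.19886)
```

The ES lifetime is over-dispersed (CV = 1.09 > 1) and the activation
criterion holds at [S] = 10 μM, so moderate inhibitor doubles the turnover
rate before ordinary inhibition takes over at high [I] — a non-monotonic
dose response the classical theory cannot produce. The Monte Carlo
estimate (50 000 cycles) agrees with the analytic rate well within one
standard error.

The same computations are available from the shell:

```
stochzyme rates --fixture fig5a --I 0:10:50 --out rates.csv
stochzyme duality --fixture fig5c_iii --S 10
stochzyme phase-diagram --fixture fig6 --out phase.csv --boundary-out bounds.csv
stochzyme simulate --fixture fig5a --S 10 --I 2 --cycles 100000 --seed 7
stochzyme validate --fixture fig5a --S 10 --I 1 --cycles 50000
stochzyme fixtures --name fig5a --dump
```

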