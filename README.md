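# a2mech

Quantitative analysis of how complement factor H (CFH) modulates the
mechanics of the von Willebrand factor A2 domain — the domain whose
force-induced unfolding exposes the Tyr1605–Met1606 bond cleaved by the
plasma protease ADAMTS-13. The package is aimed at single-molecule and
hemostasis labs who want a tested, scriptable version of the standard
analysis chain for this system: optical-tweezer pulling experiments,
binding titrations, and fluorogenic protease activity assays, each paired
with a seeded simulator that generates the same data type with known
ground truth.

## Models

**Worm-like chain (Marko–Siggia).** The force–extension relation of an
unfolded polypeptide of contour length `Lc` and persistence length `Lp`:

    F(x) = (kBT/Lp) · [ 1/4·(1 − x/Lc)⁻² − 1/4 + x/Lc ]

`fit_wlc` estimates `Lc` and `Lp` from force–extension data (residuals in
either the force or the extension direction; the persistence length can be
held fixed).

**Bell–Evans kinetics and the Evans–Ritchie relation.** Unfolding under
force is a thermally activated barrier crossing whose rate grows
exponentially with force, `k(F) = k0·exp(γF/kBT)`, with `k0` the unstressed
unfolding rate and `γ` the distance to the transition state. Under a force
ramp at loading rate `r` the most probable rupture force is

    F* = (kBT/γ) · ln( γ·r / (k0·kBT) )

which is affine in `ln r` with slope `kBT/γ`; `fit_bell_evans` inverts this
from (loading rate, most-probable-force) data. Two kinetic states — e.g.
A2 alone versus A2 with CFH bound — cross at

    F× = kBT · ln(k0_a/k0_b) / (γ_b − γ_a)

(`crossover_force`): below `F×` the bound state unfolds more slowly
(mechanically stabilized), above it more quickly.

**Hill dose–response.** Binding titrations follow
`S(c) = baseline + amplitude·cⁿ/(EC50ⁿ + cⁿ)`; `fit_hill` reports the
EC50 (Kd-equivalent for `n ≈ 1`), flags flat series as "no binding", and
`fold_affinity_change` computes the wild-type/mutant affinity ratio.

**Enzyme activity.** `initial_rate` extracts early-phase slopes from
fluorogenic progress curves, `relative_activity` calibrates them to a
linear standard curve of known protease concentrations, and
`enhancement_profile` summarizes ligand concentration–response series as
fold enhancement over the no-ligand control.

All simulators (`simulate_rupture_forces`, `simulate_trace`,
`simulate_experiment`, `simulate_titration`, `simulate_progress_curve`)
are exact-in-distribution and fully reproducible from a seed; see
`docs/methods.md` for the model details and numerical choices.

## Worked example

```python
import numpy as np
import a2mech as m

# kinetics of the A2 domain alone vs bound to wild-type CFH
solo = m.BellEvansParams(k0=0.15, gamma=0.71)
bound = m.BellEvansParams(k0=0.017, gamma=1.88)
print(f"stability crossover: {m.crossover_force(solo, bound):.2f} pN")
print(f"rate ratio at 0 pN:  {m.stability_profile([0.0], solo, bound)[0]:.3f}")
print(f"rate ratio at 15 pN: {m.stability_profile([15.0], solo, bound)[0]:.3f}")

# simulate a pulling campaign at the A2-alone truth and re-fit it
pathway = m.UnfoldingPathway.single_step()  # 55.3 nm gain, k0=0.15/s, gamma=0.71 nm
result = m.simulate_experiment(pathway, [3, 7, 15, 40, 100], 66, seed=1)
events, rates, modes = [], [], []
for rate in result.loading_rates:
    group = [e for t in result.traces_at(rate) for e in m.detect_unfolding_events(t)]
    events += group
    rates.append(np.median([e.loading_rate for e in group]))
    modes.append(m.most_probable_force(group, bin_width=1.0)[0])
be = m.fit_bell_evans(rates, modes)
wlc = m.fit_wlc([e.rupture_force for e in events],
                [e.extension_gain for e in events], objective="extension")
print(f"fitted k0 = {be.params.k0:.3f} 1/s   (truth 0.15)")
print(f"fitted gamma = {be.params.gamma:.2f} nm  (truth 0.71)")
print(f"fitted Lc = {wlc.params.contour_length:.1f} nm  (truth 55.3)")

# binding titration at the A2 fragment's affinity
hill = m.fit_hill(m.simulate_titration(6.1e-9, noise_sd=0.02, seed=3))
print(f"fitted EC50 = {hill.ec50*1e9:.2f} nM  (truth 6.1 nM)")
print(f"affinity fold (A2, WT vs mutant): {m.fold_affinity_change(6.1e-9, 2.3e-9)}")
```

prints

```
stability crossover: 7.66 pN
rate ratio at 0 pN:  0.113
rate ratio at 15 pN: 8.073
fitted k0 = 0.160 1/s   (truth 0.15)
fitted gamma = 0.86 nm  (truth 0.71)
fitted Lc = 56.3 nm  (truth 55.3)
fitted EC50 = 6.44 nM  (truth 6.1 nM)
affinity fold (A2, WT vs mutant): 2.7
```

The crossover says CFH binding stabilizes A2 nine-fold against unfolding
at zero force but makes it eight-fold *easier* to unfold at 15 pN — the
force regime where ADAMTS-13 cleavage becomes possible. The re-fitted
kinetic and elastic parameters recover the simulation truth to within the
sampling error of a ~330-trace campaign (the histogram-mode reduction of
rupture forces carries a bin-width floor; `k0` is exponentially sensitive
to it).

## Command line

`a2mech` exposes the same chain as subcommands:

```sh
a2mech simulate-pulling --rates 3,7,15,40,100 --n 66 --seed 7 --out run/
a2mech analyze-traces run/traces.tsv --bin 1.0 --out run/
a2mech crossover --k0-a 0.15 --gamma-a 0.71 --k0-b 0.017 --gamma-b 1.88
a2mech simulate-mst --ec50 6.1e-9 --seed 3 --out titration.csv
a2mech fit-hill titration.csv
a2mech run-all config.toml        # full multi-condition pipeline + report
```

`run-all` consumes a TOML configuration (see `a2mech.config.RunConfig`)
with a mandatory seed and writes a JSON report whose every number is
traceable to that seed.

## Layout

```
src/a2mech/
  force_models.py      WLC + Bell-Evans forward models, fits, crossover
  pulling_simulator.py kinetic Monte-Carlo force-ramp simulator
  trace_analysis.py    event detection, histograms, rupture statistics
  binding_titration.py serial dilutions, Hill fits, affinity folds
  enzyme_kinetics.py   progress curves, standard curves, enhancement
  io.py / config.py    delimited-text formats, TOML run configuration
  pipeline.py / cli.py end-to-end pipeline and the click CLI
docs/methods.md        model assumptions, defaults, numerical choices
tests/                 pytest suite (unit, property, acceptance)
```
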