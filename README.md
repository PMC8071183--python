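# girkfit

Estimation of agonist binding kinetics at G-protein-coupled receptors
from GIRK-channel current recordings — with a full ODE simulator of the
receptor → G protein → channel cascade for validating every step by
parameter recovery.

## The problem

For many drugs the *rates* of target engagement matter as much as the
equilibrium affinity: the association rate constant k_on (M⁻¹s⁻¹) sets
how quickly occupancy builds, and the dissociation rate constant k_off
(s⁻¹) sets the residence time 1/k_off.  At the dopamine D2 receptor
these rates can be read out functionally: in *Xenopus* oocytes
co-expressing the receptor, GIRK1/4 channels and RGS4, the GIRK current
tracks receptor occupancy in close to real time, so the current's
activation and deactivation time courses under controlled perfusion
carry the binding kinetics of the applied agonist.

`girkfit` implements that analysis for anyone running (or simulating)
such experiments:

* **k_off** from monoexponential fits of the post-washout current decay:
  k_off = 1/τ_deact;
* **k_on** from the observed activation rate k_obs = 1/τ_act measured at
  several concentrations, via k_obs = [A]·k_on + k_off, as the slope
  over the automatically selected linear concentration range;
* **kinetic affinity** K_d = k_off/k_on (pK_d = −log₁₀ K_d) with
  propagated uncertainties;
* **functional potency and efficacy** from fixed-slope logistic
  concentration–response fits, Y = Top/(1 + 10^(logEC50 − X));
* **cross-ligand statistics**: Spearman correlation of pEC50 vs pK_d
  with an exact permutation p-value (full n! enumeration for n ≤ 9),
  summary-statistics two-way ANOVA, Sidak adjustment, and ordinal
  arrow tables of wild-type → mutant shifts.

Because raw recordings from the original experiments are not deposited
anywhere, the package also contains a first-class synthetic-data module:
a stiff-capable ODE model of agonist binding, G-protein cycling, channel
gating, finite solution exchange and recording noise that generates
voltage-clamp traces with the kinetic structure the analysis assumes.
Every estimator is tested by recovering the parameters that generated
the traces.

## Worked example

Simulate a washout experiment for dopamine at the wild-type receptor
(k_on = 9.70×10⁷ M⁻¹s⁻¹, k_off = 0.197 s⁻¹), then estimate the
dissociation rate from the decay:

```python
from girkfit import (LigandKinetics, fast_reporter_params, make_protocol,
                     simulate_trace, subtract_basal, fit_deactivation)

da = LigandKinetics("dopamine", k_on=9.70e7, k_off=0.197, efficacy=1.0)
protocol = make_protocol("washout", "dopamine", [10e-9], tail_s=58.0)  # 13-s 10 nM pulse
trace = simulate_trace(da, fast_reporter_params(), protocol, seed=1)
trace = subtract_basal(trace, (1.0, 9.0))
fit = fit_deactivation(trace, washout_start=23.0, window_s=42.0)
print(f"tau = {fit.tau:.2f} s  ->  k_off = {fit.rate:.3f} /s")
```

prints

```
tau = 5.21 s  ->  k_off = 0.192 /s
```

i.e. the fitted residence time (5.21 s) returns the generating
dissociation rate within ~2%.  The whole eight-condition study — four
agonists at wild-type and S193A mutant receptors, each with
concentration–response, washout and activation experiments — runs from
the command line:

```bash
girkfit run --seed 7 --out out/ --fast
```

```
       ligand receptor    pEC50  ...    k_off         k_on      pKd
           DA       WT 8.719466  ... 0.191819 9.757730e+07 8.706457
(S)-5-OH-DPAT       WT 8.985504  ... 0.027393 2.941568e+07 9.030943
...
[run] Spearman rho=0.9762 p=0.0004 (exact_permutation, n=8)
```

Each row recovers the rate constants that generated the data (compare
k_off = 0.1918 vs the 0.197 truth for DA/WT), the kinetic pK_d matches
the functional pEC50 because the simulated assay has no receptor
reserve, and the cross-ligand correlation between potency and kinetic
affinity is computed with an exact permutation test.  `girkfit
reproduce` separately re-derives all deterministic arithmetic of the
bundled reference table (pK_ds, SEMs, EC50s, fold changes, arrow grid)
and reports each check.

Other subcommands: `girkfit simulate` (one trace from a YAML experiment
description), `girkfit fit-trace` (exponential fits of stored traces),
`girkfit fit-cr` (concentration–response fits from a TSV).

## Layout

| path | contents |
|---|---|
| `src/girkfit/simulate.py`, `protocol.py`, `params.py` | cascade ODE model, perfusion protocols, solution-exchange kinetics |
| `src/girkfit/models.py` | sklearn-style estimators: `MonoExponential`, `ConcentrationResponse`, `KobsLinear` |
| `src/girkfit/traces.py` | baseline subtraction, amplitudes, activation/deactivation fits, QC |
| `src/girkfit/dose_response.py`, `kinetics.py` | potency/efficacy fits, rate-constant and affinity arithmetic |
| `src/girkfit/stats.py` | exact-permutation Spearman, summary ANOVA, Sidak, report tables |
| `src/girkfit/pipeline.py`, `cli.py`, `io.py` | end-to-end studies, CLI, plain-text serialization |
| `docs/methods.md` | model assumptions, parameter rationale, numerical choices, limitations |
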