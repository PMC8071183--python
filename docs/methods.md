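# Methods

`girkfit` estimates agonist binding kinetics at a Gi/o-coupled receptor
(the dopamine D2 receptor) from the time course of GIRK channel currents
recorded in voltage-clamped *Xenopus* oocytes, and ships an ODE
simulator of the full receptor → G protein → channel cascade so that
every estimator can be validated by parameter recovery at known truths.

## The estimation model

Binding is treated as a single-step bimolecular reaction,
R + A ⇌ RA with rate constants k_on (M⁻¹s⁻¹) and k_off (s⁻¹).  Three
classical identities drive the whole analysis:

* **Dissociation.**  After agonist washout the response decays with the
  receptor's residence time; a monoexponential fit of the decay gives
  τ_deact and **k_off = 1/τ_deact**.
* **Association.**  At constant agonist concentration [A] the occupancy
  relaxes monoexponentially with observed rate
  **k_obs = k_on·[A] + k_off**.  k_obs is measured as 1/τ_act from a
  monoexponential fit of the current rise; k_on is the slope of k_obs
  against [A] over the concentration range where that relation is
  linear.  The intercept of the line is kept only as a cross-check of
  k_off (k_off itself always comes from washout decays, which are less
  exposed to cascade saturation).
* **Kinetic affinity.**  **K_d = k_off / k_on**, reported as
  pK_d = −log₁₀ K_d.  With no receptor reserve, pK_d should match the
  functional potency pEC50.

Functional potency comes from the fixed-slope logistic

    Y = Top / (1 + 10^(logEC50 − X)),    X = log₁₀([A]/M),

with bottom fixed at 0 and Hill slope at 1 (the model has neither as a
free parameter).  Responses are normalized to a maximally effective
dopamine response in the same cell, so the fitted Top is a relative
efficacy and dopamine's Top ≈ 1.

The pK_d uncertainty propagates the relative standard errors of the two
rates, `sqrt((se_off/k_off)² + (se_on/k_on)²)`, reported directly as the
pK_d SEM.  (Including the conventional 1/ln10 factor would shrink it
~2.3-fold; the undivided convention is what the bundled reference SEMs
follow, and it reproduces 7 of the 8 of them at two decimals.)

## The cascade simulator

State variables: agonist occupancy RL, competitive-antagonist occupancy
RA, active-G fraction Ga.

    dRL/dt = k_on·c_a(t)·(1 − RL − RA) − k_off·RL
    dRA/dt = b_on·c_b(t)·(1 − RL − RA) − b_off·RA
    dGa/dt = g_act·ε·RL·(1 − Ga) − g_deact·Ga
    |I|(t) = i_basal + i_max · Ga^h / (Ga^h + girk_half^h)

ε ∈ [0,1] is the ligand's intrinsic efficacy.  The bath concentrations
c_a, c_b follow the commanded perfusion steps through a first-order
solution-exchange filter `dc/dt = (c_applied − c)/exchange_tau`, solved
exactly per protocol segment; the chamber starts agonist-free.  The
stored current is inward-negative (cell clamped at −80 mV in 25 mM K⁺)
with additive white Gaussian noise and optional exponential rundown of
the evoked component.  Integration is segment-wise LSODA (stiff-capable,
rtol 1e−8) resampled onto the 156 Hz acquisition grid; identical seeds
give bit-identical traces.

### Default parameters and why

| parameter | default | rationale |
|---|---|---|
| `g_act_rate` | 1.5 s⁻¹ | G activation per occupied receptor; kept low so amplification never saturates the readout |
| `g_deact_rate` | 50 s⁻¹ | RGS-accelerated GTP hydrolysis, upper end of reported GAP-stimulated rates; makes Ga a quasi-instantaneous report of occupancy |
| `girk_half` | 0.9 | channel gate operated deep in its linear range (Ga ≤ 0.03 in practice) |
| `girk_hill` | 1 | minimal gating model |
| `i_max` | 50 µA | whole-pool capacity; with the ~3.1% maximal gate this yields a ~1.6 µA maximal dopamine response, the scale of real recordings |
| `i_basal` | 0.2 µA | below the 0.5 µA holding-current QC bound |
| `exchange_tau` | 0.45 s | slowest exchange consistent with the measured rate bound > 2 s⁻¹ |
| `noise_sd` | 5 nA | white recording noise at 156 Hz |
| `rundown_rate` | 0 (off) | rundown is a nuisance, modeled only on demand |

The first three are a deliberate design point.  For the washout decay to
carry k_off, the map from occupancy to current must be close to linear
along the whole decay trajectory.  Writing u = g_act·ε·RL, the
instantaneous log-slope of the current is attenuated by the two factors
g_deact/(u + g_deact) and girk_half/(Ga + girk_half); a
high-amplification cascade (large g_act, small g_deact, small girk_half)
drives both far below 1 at realistic occupancies and makes the fitted
washout rate underestimate k_off severely.  The defaults keep
u ≤ 0.03·g_deact and Ga ≪ girk_half, which bounds the fitted-k_off bias
below ~4% across all eight bundled conditions at their stated washout
concentrations (measured noise-free; the target was < 5% for
k_off ≤ 0.2 s⁻¹).  The same linearity is what makes the simulated assay
reserve-free, so simulated EC50 ≈ K_d — the premise under which
functional potency is comparable to binding affinity.

Two parameter regimes are used deliberately:

* **default** (`CascadeParams()`): `exchange_tau = 0.45 s`, emulating
  the real perfusion system;
* **fast-reporter** (`fast_reporter_params()`): identical but with
  `exchange_tau = 0.05 s` (≥ 100× shorter than every bundled residence
  time), used for parameter-recovery validation so that trace kinetics
  are binding-limited.

## Trace analysis choices

* Basal current is removed by subtracting the mean over an explicit
  buffer-only window; windows overlapping an application are rejected.
* Steady-state amplitude of a staircase step is the mean evoked
  magnitude over the final 1 s of the 60-s application.
* Monoexponential fits use Levenberg–Marquardt (lmfit) with scale-free
  initial guesses (amplitude = first − last, offset = last,
  τ = window/3) and τ bounded to [sample interval, 10 × window]; hitting
  a bound flags the fit as non-converged.  The offset is free by default
  (a flag anchors it at zero).
* The activation fit window covers 80% of the current increase.  The
  plateau is the mean over the final 10% of the application; the start
  level is the mean over the second preceding application; the
  80%-crossing is located on a 0.5-s boxcar-smoothed copy of the trace
  (the exponential itself is fitted to raw samples).  A fit is refused
  if the final plateau window still rises by more than 5% of the
  increase (or the noise floor of the window means) relative to the
  preceding window — the practical meaning of "plateau not reached".
* Linear-range selection for k_on: points are sorted by concentration
  and the largest prefix (≥ 3 points) is kept for which (a) a quadratic
  term does not significantly improve the straight-line fit (partial
  F-test, α = 0.05, on a standardized regressor to avoid losing the
  curvature column to conditioning at molar scales) and (b) the highest
  included point deviates from the line by < 15%.  Both thresholds are
  configurable; they are this package's operationalization of "the range
  where the relation was linear".

## Statistics

* **Spearman correlation** of pEC50 vs pK_d uses the rank-difference
  formula; for tie-free n ≤ 9 the two-sided p-value enumerates all n!
  rank pairings with integer arithmetic on Σd² (n = 8 → 40 320
  permutations, instantaneous).  Ties or larger n fall back to the t
  approximation with a warning.
* **Two-way ANOVA from summary statistics** (mean, SEM, n per cell) uses
  the unweighted-means solution with the harmonic-mean cell size — the
  appropriate choice when per-cell n is only approximately known — and
  pools cell variances for the error term.  It reduces exactly to the
  pooled t² for a two-level single factor and matches raw-data ANOVA on
  balanced designs.  Because published group sizes are ranges, published
  F statistics are not reproduction targets.
* **Sidak adjustment**: p_adj = 1 − (1 − p)^m, clipped to 1.
* WT → mutant changes are classified into ordinal arrows by
  |log₁₀ fold|: < 0.15 no change ("−"), < 0.7 one arrow, 0.7–2 two,
  > 2 three; potency folds are inverted so "↑" always means gain of
  function.  These thresholds are this package's calibration; they
  reproduce all 16 reference arrows.

## The simulated study

`default_study_config()` mirrors the real experimental program for the
eight ligand × receptor conditions at the bundled rate-constant truths:
concentration–response staircases (60-s stabilization, then 60-s
applications of 5 increasing concentrations spanning EC50/9 to 9·EC50;
one agonist per simulated oocyte, normalized to a 1 µM (WT) or 300 µM
(S193A) dopamine reference in the same cell), 13-s washout applications
at the per-condition reference concentrations with the per-condition fit
windows (42/104 s at WT, 24 s at the mutant), and activation series at
five concentrations chosen to keep k_obs within
[k_off + 0.2·Δ, k_off + Δ], Δ = min(4·k_off, 0.35 s⁻¹) — inside the
linear range and below the solution-exchange rate, as in the real
design.  Activation lasts max(60 s, 4.6/k_obs) so the plateau is
reached.  All child seeds derive deterministically from the study seed;
re-running a config byte-identically reproduces the output bundle, which
embeds the seed and a config hash.

Default problem sizes (2 oocytes per concentration–response curve, 2
kinetic replicates; recovery validation uses 20 independent seeds per
condition) were chosen as the smallest sets at which the recovery checks
are comfortably stable.

## What the generator does and does not emulate

Emulated: concentration-dependent GIRK activation through a saturable
G-protein cycle, finite solution exchange, per-ligand intrinsic
efficacy, basal current, white recording noise, optional rundown, the
four protocol shapes, and the systematic washout-rate underestimation
that appears when 1/k_off approaches the exchange time constant (the
real assay's main caveat, reproduced as a property: fitted rate ≤ true
k_off across k_off = 0.03–1 s⁻¹ at exchange_tau = 0.45 s).

Not emulated: oocyte-to-oocyte variability in expression (i_max/i_basal
are parameters, not a population distribution), receptor desensitization
and G-protein depletion, correlated (1/f) noise and slow drift,
voltage-dependence and K⁺ driving-force changes, direct channel block by
antagonists, and two-step/induced-fit binding.  Consequently, passing
recovery tests show the *estimators* are faithful given the assumed
reaction scheme; they cannot certify robustness to drift, desensitization
or multi-step binding in real recordings.  One visible consequence: the
simulated assay is reserve-free and exchange-unlimited in the
fast-reporter regime, so its pEC50 matches pK_d almost exactly, whereas
real measured EC50s ran ~10× higher than the kinetic K_d — the
overestimation of affinity by kinetic K_d that the original study itself
flags.

## Known limitations

* The linear-range rule degenerates to the 3 lowest concentrations on
  noise-free saturating data (the F-test becomes infinitely sensitive);
  with realistic noise it keeps 4–5 points.
* The exact permutation test is limited to n ≤ 9 (n! enumeration) and
  tie-free data.
* The summary-statistics ANOVA is an unweighted-means approximation for
  unbalanced designs, not the regression (Type III) solution.
* k_off values approaching the exchange rate (≳ 0.4 s⁻¹ at the default
  perfusion) are structurally underestimated; the package reports them
  anyway, as the real assay does, and the bias property test documents
  the direction.
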