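# Methods

## Scope and model

The package scripts the desk analysis of a small crossover-style PK study:
eight koalas dosed orally with paracetamol at 15 mg/kg (two also
subcutaneously), serial plasma sampling at 0.25/0.5/1/2/4/8/12/24 h, trough
samples before the 24/48/72 h doses of a twice-daily regimen and a final
78 h draw, assay LLOQ 0.625 μg/mL. The in-vivo model underlying both the
synthetic generator and the multiple-dose reasoning is the one-compartment
first-order-absorption (Bateman) curve

    C(t) = S · ka/(ka − ke) · (e^(−ke t) − e^(−ka t)),   S = F·D/V,

with analytic AUC0–∞ = S/ke and peak time ln(ka/ke)/(ka − ke). The NCA
itself is model-free; the Bateman curve is used only to generate data and as
a closed-form oracle in the tests. ka = ke is rejected as degenerate rather
than switching to the t·e^(−kt) limit — the parameter sets of interest are
nowhere near it and silently changing model family would hide input errors.

## Non-compartmental analysis

- **Terminal fit.** All contiguous tails of ≥ 3 quantifiable points strictly
  after Tmax are fitted by OLS on (t, ln C); the tail with the highest
  adjusted r² is selected, ties going to the longer tail. If fewer than
  three quantifiable points lie strictly after the peak, the Tmax point is
  admitted with a warning (otherwise profiles whose observed peak is the
  first usable sample — common with fast s.c. absorption — cannot be fitted
  at all). Tails with non-negative slope are discarded; if none declines the
  profile is rejected.
- **AUC dialects.** Default is linear-up/log-down: linear trapezoid when
  C(i+1) ≥ C(i) or either endpoint is ≤ 0, logarithmic rule otherwise. A
  pure-log dialect is available (`method="log"`); on exactly exponential
  segments the log rule reproduces the analytic integral to machine
  precision. AUMC always uses the linear trapezoid on t·C(t): the log rule
  is ill-defined where the moment curve starts at zero.
- **BLQ rule.** Leading below-LLOQ samples integrate as zero (pre-dose
  baseline); embedded and trailing BLQ samples are excluded, so integration
  and Clast stop at the last quantifiable observation, and the requested
  t_end is truncated there (recorded in the result's notes).
- **Method of residuals.** Residuals exp(intercept − ke t) − C(t) at the
  quantifiable pre-peak times must all be positive; their log-linear slope
  gives −ka, and ka ≤ ke is reported as an unreliable-absorption error.
  Two residual points are accepted (with a warning) because fast-absorbing
  s.c. profiles rarely leave more than two pre-peak samples; in `run_nca`
  an infeasible ka becomes NaN with a note instead of aborting the run.
- **Units.** Dose in mg/kg over AUC in μg·h/mL yields Cl/F directly in
  L/(kg·h) (1 mg per 1 μg/mL is 1 L), hence Vz/F in L/kg. Reports round
  half-up to 3 decimals for rate constants, half-lives and volumes, 2 for
  areas and concentrations; full precision is kept internally.

### Known bias of short terminal windows

With the study's median oral parameters (ka = 0.22, ke = 0.125 /h — a ratio
of only 1.76) absorption is far from complete at 24 h: the noise-free curve
still peaks at the 8 h sample and the 8/12/24 h tail has log-slope
−0.0945 /h, 24% shallower than the true ke. Washout samples that would
resolve this (48 h onward) fall below the LLOQ at a 17 μg/mL Cmax. Two
consequences, both reproduced by the validation suite:

- AUC0–∞ is nearly unbiased anyway (within ~0.4% of S/ke at the default
  parameters): the biased-low ke inflates the extrapolated tail by almost
  exactly the amount the truncated trapezoid misses.
- Half-life recovered from simulated 8-subject studies is ~30% high
  (median ≈ 7.4 h against the nominal 5.55 h), and the AUC0–24/AUC0–∞
  ratio sits near 0.86 rather than above 0.90. Recovered medians should
  therefore be read as estimates *conditional on the design*, exactly as
  printed per-animal indices from any 24 h extravascular study must be.
  When absorption is fast (s.c.-like ka of several per hour) the terminal
  fit recovers ke essentially exactly.

## Multiple dosing and therapeutic window

Accumulation factor (1 − e^(−n ke τ))/(1 − e^(−ke τ)), reported at one
decimal; with the median oral ke and τ = 12 h it is 1.22 at the second dose
and 1.29 at steady state. Time to steady state is the five-half-lives rule.
Superposition sums Bateman curves shifted to the dose times (doses at
0, 24, 36, 48, 60, 72 h for the study regimen); it is exactly linear in the
dose scale. Note that at the fitted median parameters linear superposition
predicts a 72 h trough near 17 μg/mL, well above the observed 5–11 μg/mL
troughs — the fitted single-dose parameters and linear accumulation are not
jointly consistent with the observed multidose data, one more echo of the
terminal-window bias above. Time-in-window treats the 4–20 μg/mL bounds as
a closed interval and locates crossings by linear interpolation on the
concentration scale (the window spans rising and falling limbs); an
exponential-interpolation option exists for falling limbs.

## Binding and in-vitro depletion

Percent bound per ultrafiltration replicate, mean ± SD (n−1 denominator,
SD marked unavailable for single replicates) per nominal concentration;
buffer-matrix rows are summarised separately as non-specific binding and
flagged when below 5%. No non-specific-binding correction is applied to the
plasma values — the two quantities are reported side by side, as is
conventional for these assays.

Depletion assays regress ln(% remaining) on minutes (substrate at t = 0
defined as 100%; raw concentrations are converted by dividing by the t = 0
value). The 0.693 constant, not ln 2 to full precision, is used in
t1/2 = −0.693/k and Clint = (0.693/t1/2)·(V/m) to match how these assays
are conventionally reported; `exact_ln2=True` switches to ln 2. By
construction Clint·t1/2 = 0.693·V/m identically. "No depletion" is a
distinct result state, declared when the slope is ≥ 0 or not significantly
below zero at the one-sided 5% level; with only three time points this
t-test has a single degree of freedom and is deliberately conservative, so
shallow true depletion can be reported as no depletion. Species summaries
average per-replicate t1/2 and Clint (mean of ratios, not a pooled slope).

## Paired statistics

Exact signed-rank test: zero differences dropped, mid-ranks on tied
absolute differences, W+ = sum of positive-difference ranks, two-sided
p = min(1, 2·min tail) over the exact null distribution of the realized
rank vector. The distribution is built by convolution over the (doubled)
ranks — arithmetically identical to enumerating all 2^n sign vectors, and
checked against a literal recursive enumeration in the tests. For n > 25 a
tie-corrected normal approximation with continuity correction takes over.
Six unanimous-direction pairs give p = 2/64 = 0.03125, the smallest
two-sided p attainable at n = 6. No multiplicity correction is applied —
analyte panels are tested one at a time at α = 0.05, and users screening
many analytes should treat marginal p-values accordingly.

## Synthetic data generator

Defaults are the study conditions: ka = 0.22 /h, ke = 0.125 /h, residual
CV 10% (multiplicative lognormal, σ = √ln(1+cv²) so the CV is exact),
between-subject CV 20% (median-1 lognormal on ka, ke and scale, consistent
with the spread of the published per-animal indices), schedule
0.25…24 h plus 48/72/78 h, LLOQ 0.625 μg/mL, and scale S set so the
analytic single-dose peak is 17 μg/mL (the sampled noise-free Cmax is then
16.2 μg/mL at the 8 h grid point). Subject streams are spawned from the
study seed (`SeedSequence.spawn`), so extending a cohort never changes
earlier subjects. Depletion curves use k = 0.00315 /min-scale rates with
2% noise and the t = 0 anchor forced to 100%; paired panels default to a
+4 U/L shift on a 25 ± 5 baseline with unit noise, making unanimous-sign
panels overwhelmingly likely.

What the generator does *not* emulate: metabolite kinetics, enterohepatic
recirculation, assay runs/batch effects, correlated random effects, or any
departure from one-compartment linearity. Passing recovery tests therefore
demonstrate the correctness of the estimators under the stated model and
design — including its honest failure modes (the terminal-window bias) —
not the physiological accuracy of the model for koalas.

## Numerical choices

- OLS via `numpy.polyfit` / `scipy.stats.linregress`; ranks via
  `scipy.stats.rankdata`; adjusted r² tie tolerance 1e-9 (ties → more
  points).
- Cmax ties resolve to the earliest time (argmax on sorted times).
- Reporting rounds half-up (ties away from zero), matching how the study's
  tables round; Python's banker's rounding would drop 16.925 to 16.92.
- `run_nca` truncation, interpolation of a partial terminal interval, and
  report serialisation (sorted keys, fixed decimals, no timestamps) are all
  deterministic, so identical inputs give byte-identical reports.

## Limitations

- No compartmental or population (mixed-effects) fitting, no
  bioavailability estimation (requires intravenous data), no urine or
  metabolite NCA.
- Exact per-animal reproduction of the published table from raw plasma
  concentrations is impossible without the unpublished supplementary data;
  the package instead reproduces every printed-value identity and summary,
  and validates the full pipeline on synthetic data.
- The unbound-fraction comparison across species (≈40% unbound in koala
  plasma vs ≈80% in humans) is a documentation-level interpretation; no
  per-animal unbound data exist to compute it here.
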