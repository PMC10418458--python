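# Methods

## The estimation problem

A ground-nutmeg sample may contain an undeclared mass fraction *f* of
ground nutmeg shell. Given an FT-NIR absorbance spectrum on the fixed
instrument grid (11,550–3950 cm⁻¹ at 4 cm⁻¹, 1901 channels), the package
estimates the shell content in percent and characterizes the reliability
of that estimate through the distribution of predictions on *blanks* —
pure nutmeg samples whose true shell content is zero.

## Synthetic measurement campaign

Real campaign spectra are not shipped; the simulator generates data with
the statistical structure the analysis relies on. What it emulates:

- **Two endmember populations.** Each pure sample's noise-free spectrum is
  a non-negative baseline (offset plus a ramp toward low wavenumbers) plus
  Gaussian bands at the lipid-associated wavenumbers (8260, 5780, 5665,
  4330, 4250 cm⁻¹; amplitudes larger for nutmeg) and the
  carbohydrate-associated ones (6890, 4400, 4000 cm⁻¹; larger for shell),
  plus three broad background bands shared by both. Band amplitudes get
  independent per-sample log-normal multipliers `exp(population_sd · z)`;
  the defaults are `population_sd = 0.010` for nutmeg and `0.030` for
  shell, keeping shell three times as variable as nutmeg — shell is the
  botanically and geographically messier material. These two numbers set
  the difficulty of the whole problem: they control the blank σ, the
  ensemble R²/RMSEP and the PC1 variance share simultaneously, and were
  fixed once so that the default campaign operates at the performance
  level the method is designed for (R² ≈ 0.95–0.98, blank σ ≈ 0.5%).
- **Gravimetric mixing.** A mixture's true spectrum is the convex
  combination `(1 − f)·x_nutmeg + f·x_shell` of its *specific* constituent
  samples, never of population means — constituent identity is exactly
  what the cross-validation has to respect.
- **The design.** 36 nutmeg and 10 shell samples measured pure; every
  nutmeg sample mixed at 3% and 7%; 15–23 mixtures at each of 1, 2, 4, 5,
  6, 8, 9, 10% and 20, 30, 40, 50%; totals 307 mixtures, 230 of them at
  1–10%. Partners are drawn by balanced random assignment so per-sample
  minimum-use constraints hold whenever arithmetically feasible. With 307
  mixtures over 10 shell samples the guaranteed per-shell minimum is
  ⌊307/10⌋ = 30, which is the default constraint; the generator raises an
  explicit infeasibility error naming the violated constraint otherwise.
- **Replicate scatter.** Each of 5 technical replicates is
  `b·x + a + ε` with `b = exp(N(0, σ_b²))`, `σ_b = 0.08`,
  `a ~ N(0, 0.02²)` absorbance offset and per-channel noise
  `ε ~ N(0, 0.0005²)`. Scatter is drawn per replicate, not per sample,
  because vial repacking between scans re-randomizes the physical packing.

What it does **not** emulate: real NIR band shapes (Voigt-like, heavily
overlapped), wavelength-dependent scatter, instrument drift, moisture and
temperature effects, correlated compositional variation (a sample with
more lipid has less of something else), or reflectance-to-absorbance
non-linearity. Spectra are treated as absorbance-like intensities
throughout; the linear mixing law is exact here but only approximate for
real diffuse-reflectance data. Passing tests therefore demonstrate the
correctness and leak-freedom of the *procedure*, not field performance on
real material.

## Preprocessing

Order is fixed: replicate averaging → scatter correction → model.

- **MSC** fits each spectrum on a reference by OLS over all 1901 channels
  and returns `(x − a)/b`; `|b|` below 1e−12 or a zero-variance reference
  raises a degenerate-fit error. The reference is the mean of all pure
  samples for exploratory work, but inside cross-validation it is the mean
  of the *training* samples only, applied unchanged to the test spectra —
  the one place preprocessing could leak test information.
- **SNV** standardizes each spectrum (n−1 denominator, a documented
  convention choice). **Detrend+SNV** then removes the least-squares
  2nd-degree polynomial in wavenumber (implemented as projection on an
  orthonormalized quadratic basis).
- **MSC + derivative** smooths with a centered moving average of length
  101 channels (truncated, shrinking windows at the edges — the simplest
  well-defined contract) and differentiates by central differences over
  the signed −4 cm⁻¹ step, one-sided at the two ends. This is a plain
  post-smoothing difference, not a gap-segment derivative.

Plain MSC is the default pipeline; the variants give closely similar
results on the default campaign and are exposed for comparison.

## PCA

Fitted by SVD on the averaged, MSC-corrected pure samples only, centered,
unscaled, all components kept; mixtures are only ever projected with the
frozen transformation. Component signs are fixed (largest-magnitude
loading element positive) for reproducibility. On the default campaign
PC1 carries ≈ 99.5% of pure-sample variance and separates the two groups
with no overlap.

## Cross-validated regression

Per repeat, nutmeg samples are split into random halves of 18/18 and
shell samples 5/5 (odd counts: ⌊n/2⌋/⌈n/2⌉ with the larger half
randomized). A mixture joins a fold's training set iff both constituents
are in that fold's half; mixtures with split constituents sit out the
repeat. Folds swap halves, so each pure sample is tested exactly once per
repeat; an eligible mixture (≤ 10% shell) is tested in ~half the repeats
and lands in a given fold's training set with probability ~1/4. A leakage
audit (no test mixture shares a constituent with any training sample or
mixture) runs on every fold of every run and raises on violation.

The regressor is ε-SVR with a linear kernel, C = 1, ε = 0.1 (the
conventional defaults of the libsvm family), on features standardized
with training-set statistics; the target is shell content in percent.
Pure shell samples enter training as 100% targets by default (switchable)
but are excluded from the 0–10% evaluation ranges. PLS with 10 latent
variables is available as the alternative model; 10 is a configurable
convention, since "default" component counts are data-dependent in other
implementations. Predictions are recorded exactly as returned — no
clipping — so blank predictions can and should go slightly negative.
100 repeats are ensembled by per-sample arithmetic means.

## Evaluation

- R² is 1 − SS_res/SS_tot of predicted vs. true (squared Pearson
  correlation available behind a flag — the two differ when predictions
  are biased). Range filters apply to the *true* value: single-prediction
  metrics over 1–10%, ensemble metrics over 0–10% (including blanks).
- Blank statistics use the sample SD (n−1); both the pooled
  single-prediction and the ensemble variants are reported.
- Tail probabilities model blanks as N(0, σ²) — centered at the known
  true value 0, not the empirical blank mean — and report z = t/σ,
  Φ(z) and 1 − Φ(z) at full precision.
- LOD = 3σ and LOQ = 9σ of the ensemble blank distribution, the
  blank-measurement convention of analytical method validation,
  transferred to model predictions as estimated (not formal) limits.
- The flow table bins ensemble predictions: "pure" below 0.5%, else the
  nearest integer level (edges at k ± 0.5); out-of-range predictions are
  clamped to the boundary bin and counted.

## Determinism and problem sizes

One master seed derives per-stage seeds by fixed offsets (design +0,
spectra +1, CV +2, mod 2³¹); per-repeat seeds spawn from the CV seed via
`SeedSequence`. Identical seeds give byte-identical report JSON. The full
default campaign (1765 simulated spectra × 1901 channels, 200 SVR fits)
runs in under a minute on one core; the test suite uses a coarse 191- or
101-channel grid and 4 + 2 samples for unit-level work and one full
default campaign for the protocol-level checks.

## Known limitations

- The simulator's band-amplitude variability is independent across bands;
  real compositional variation is correlated and would make MSC less
  clean.
- The SVR ε-tube (0.1%) bounds how exactly noise-free data can be
  memorized; parameter-recovery checks hold at R² > 0.999, not machine
  precision.
- With ~50 ensemble members per mixture the Binomial(100, ½) spread means
  per-mixture precision varies run to run; bookkeeping checks use a ±2
  tolerance on the mean count.
- No hyperparameter tuning is implemented anywhere, by design: the
  method's claim is specifically that defaults suffice for this problem.
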