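# respwave

Detection of **low-functional respiration** in chest-displacement signals by
complex Morlet wavelet spectra and correlation of fixed-duration spectrum
segments.

## The problem

Postoperative and infectious-disease patients need frequent respiratory
checks, but oximetry can miss episodes of labored, low-functional breathing.
A stretch sensor spanning the 6th–8th ribs gives a direct one-dimensional
displacement proxy for lung volume, sampled at 10 Hz. Normal breathing is a
stable quasi-periodic oscillation near 0.2–0.25 Hz; low-functional breathing
has a time-varying spectrum that drifts toward higher frequencies and shows
only weak slow repetition (tens of seconds). `respwave` turns that contrast
into a per-segment score and a threshold detector.

## The method

1. **Complex Morlet CWT.** The signal x(t) is correlated with scaled,
   shifted copies of ψ(η) = e^(−η²/2) e^(iω₀η) (ω₀ = 6 by default):

       W(f; t) = (1/√s) Σ_ζ x(ζ) ψ*((ζ−t)/s) Δ,   s = f_c / (f Δ),

   with f_c = ω₀/2π, over a log-spaced grid spanning 0.01–5 Hz. The complex
   coefficients make the downstream score insensitive to breath-to-breath
   phase shifts. An inverse (single-integral) transform is provided for
   signal reconstruction from a spectrogram.

2. **Segmentation and NCC.** The scalogram |W| is cut into consecutive
   blocks of duration t_d (1, 3, 5, 10, 20, 30, 60, 90 s by default), the
   blocks of one labeled condition period are averaged elementwise, and each
   block S is scored against the average S̄ by the normalized correlation
   coefficient

       NCC(S, S̄) = ⟨S̃ | S̄̃⟩,

   where ~ denotes mean removal and scaling to unit norm over the flattened
   (frequency × time) matrix. Stable breathing gives NCC ≈ 1; time-varying
   breathing pulls it down.

3. **Detection.** A segment is called low-functional when its NCC falls
   below a threshold; sweeping the threshold from 0.8 to 1.0 in 0.001 steps
   traces the ROC curve. Welch's unequal-variance t-test compares the NCC
   populations of the two conditions, and per-frequency mean/std of |W|
   summarize spectral stability per condition.

Because no patient recordings are publicly available, the package includes a
seeded generator of labeled synthetic cohorts (`respwave.simulate`) that
reproduces the qualitative structure above; see `docs/methods.md` for the
model and its limits.

## Worked example

```python
from respwave import (SimulationConfig, simulate_cohort, cwt, make_frequency_grid,
                      score_series, roc_sweep, welch_test, NCCSeries, NORMAL, LOW_FUNCTIONAL)

cohort = simulate_cohort(SimulationConfig(seed=1))   # 10 subjects, labeled periods
grid = make_frequency_grid()                         # 0.01-5 Hz, 12 voices/octave
entries = []
for sig in cohort:
    entries.extend(score_series(cwt(sig, grid), td=90.0).entries)
series = NCCSeries(entries=sorted(entries), duration=90.0)

nor, lf = series.values(NORMAL), series.values(LOW_FUNCTIONAL)
print(f"mean NCC, normal periods         {nor.mean():.4f}  (n={nor.size})")
print(f"mean NCC, low-functional periods {lf.mean():.4f}  (n={lf.size})")
print(f"Welch t-test p-value             {welch_test(nor, lf).p_value:.2e}")
print(f"ROC AUC (thresholds 0.8-1.0)     {roc_sweep(series).auc:.4f}")
```

prints

```
mean NCC, normal periods         0.9924  (n=200)
mean NCC, low-functional periods 0.8776  (n=200)
Welch t-test p-value             1.10e-55
ROC AUC (thresholds 0.8-1.0)     0.9999
```

Normal segments correlate almost perfectly with their period average while
low-functional segments decorrelate, the difference is overwhelmingly
significant, and a simple NCC threshold separates the two conditions almost
perfectly on this synthetic cohort.

The same pipeline is available from the shell:

```sh
respwave simulate --seed 1 --out cohort          # write signal + label CSVs
respwave run --seed 1 --out results              # full pipeline + manifest
respwave score cohort/subject00_signal.csv --td 90 --out ncc.csv
respwave roc ncc.csv --out roc.csv
```

Signal files are plain CSV (`time_s,displacement`), labels are
`start_s,end_s,label` with labels `normal` / `low_functional`.

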