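# speechtrf

Objective speech audiometry from EEG: estimate temporal response
functions (TRFs) between the speech envelope and EEG recorded at several
signal-to-noise ratios around a listener's speech reception threshold,
extract evoked-potential-like morphology features from the TRFs, and
predict the individual 50% speech reception threshold (SRT₅₀) without
any behavioral response.

Intended users: auditory-neuroscience and audiology researchers working
on EEG-based measures of speech-in-noise intelligibility.

## The method

Speech-evoked EEG is modelled as a linear convolution of the stimulus
envelope *s* with an impulse response, the TRF:

```
r̂(t) = Σ_τ TRF(τ) · s(t − τ),         τ = −200 … 500 ms
TRF  = (SᵀS + λI)⁻¹ Sᵀ r,             λ = 2¹⁵
```

where the columns of *S* are time-lagged copies of the 1–10 Hz band-passed,
power-law-compressed (exponent 0.6) envelope at 120 Hz. A TRF behaves
like a slow auditory evoked potential: it shows an N1 deflection
(~100 ms) and a P2 deflection (~200 ms) whose amplitudes shrink and
latencies grow as noise increases. Five features are extracted per TRF
(N1 amplitude/latency, P2 amplitude/latency, windowed RMS); the RMS
values of electrodes C3, CP3 and CPz — inside per-electrode latency
windows optimized for rank correlation with ΔSNR — are summed into
`RMS_sum`. Intelligibility is linked to the EEG feature by

```
Intelligibility = 100 · (1 − e^(−b·RMS_sum)) %,    RMS₅₀ = ln 2 / b
```

and a subject's SRT₅₀ is predicted leave-one-out as the first ΔSNR
condition at which their `RMS_sum` crosses the RMS₅₀ fitted on everyone
else.

A synthetic cohort generator (OLSa-style sentence envelopes, ground-truth
N1/P2 kernels convolved into 32-channel EEG with 1/f noise, binomial
word scores from a logistic psychometric function) makes the entire
pipeline runnable and testable without any recordings.

## Worked example

```python
from speechtrf import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(), out_dir="report")
p = report.summary
print(f"mean SRT50          {p['mean_srt50_db']:.2f} dB")
print(f"psychometric slope  {p['psychometric']['slope_s_db']:.3f} dB")
print(f"RMS_sum mean rho    {p['rms_sum_mean_rho']:.2f}")
print(f"exponential b       {p['exponential']['b']:.3f}  "
      f"RMS50 {p['exponential']['rms50']:.3f}")
pred = p["prediction"]
print(f"mean |deviation|    {pred['mean_abs_deviation_db']:.2f} dB, "
      f"{pred['n_within_2db']}/{pred['n_subjects']} within ±2 dB")
```

With the default configuration (18 synthetic subjects × 6 ΔSNR
conditions × 32 channels, 9 min of stimulus per condition, seed 0) this
prints:

```
mean SRT50          -6.92 dB
psychometric slope  1.376 dB
RMS_sum mean rho    1.00
exponential b       1.900  RMS50 0.365
mean |deviation|    0.83 dB, 18/18 within ±2 dB
```

i.e. the simulated cohort's mean threshold sits at −6.9 dB SNR, the
behavioral fit recovers a slope close to the generating 1.462 dB, the
EEG composite `RMS_sum` is perfectly rank-correlated with ΔSNR at this
noise level, and the leave-one-out EEG-based prediction places every
subject's threshold within ±2 dB of the behavioral one (mean absolute
error 0.83 dB). The `report/` directory receives the full bundle:
`trf.csv`, `rms_windows.csv`, `features.csv`, `rms_sum.csv`, `stats.csv`,
`posthoc.csv`, `behavior.csv`, `predictions.csv`, `summary.json`.

The same pipeline is available from the shell:

```sh
speechtrf run --out report --seed 0          # full pipeline
speechtrf simulate --out dataset --seed 0    # just the synthetic cohort
speechtrf trf --data dataset --out trf.csv   # TRFs from a dataset on disk
```

Exit codes: 0 success, 2 config error, 3 data error, 4 fit failure.

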