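# cpet-entropy

Sample-entropy analysis of breath-by-breath cardiopulmonary exercise
testing (CPET).  A progressive ramp test yields short (~100–250 breath),
trending, nonstationary series of gas exchange (V̇O2, V̇CO2, V̇E),
respiratory rate, tidal volume, and instantaneous heart rate.  This package
turns those series into statistically defensible entropy comparisons across
work intensity (before vs after the first ventilatory threshold, VT1),
biological sex, and pubertal status — the kind of question asked in
pediatric exercise physiology, where signal regularity carries information
about maturing autonomic and respiratory control.

The pipeline (each stage is an importable module):

1. **`io_cpet`** — read/validate breath tables, peak-effort QC (windowed
   RER > 1.0 and/or HR > 185), peak V̇O2 (highest 20-s rolling average in
   the final minute).
2. **`vt1`** — automated VT1 detection: the breath index k minimizing the
   two-segment log-variance objective
   `(k−1)·log V(x[1..k]) + (N−k+1)·log V(x[k+1..N])`, applied to the
   V-slope and excess-CO2 (V̇CO2²/V̇O2 − V̇CO2) series and averaged.
3. **`preprocess`** — slice at VT1, first-difference, standardize; verify
   weak stationarity by the augmented Dickey-Fuller test with per-record
   Holm-Sidak correction.
4. **`sampen`** — sample entropy `SampEn(x, m, r) = −log(A/B)` with exact
   Chebyshev template matching, explicit undefined/infinite statuses, and
   a short-signal (m, r) selection heuristic.
5. **`bayes`** — hierarchical Student-t model over
   metric × pubertal × sex × VT1-side cells
   (`μ ~ N(2,1)`, `σ ~ U(0.05,0.5)`, shared `ν ~ logN(1,1)`), sampled by an
   in-package No-U-Turn sampler with analytic gradients; posterior
   contrasts Δμ, sex/pubertal percent differences, HR vs minimum
   gas-exchange entropy, each summarized by `P(contrast ≥ 0 | y)`.
6. **`synthetic`** — ramp-CPET cohort generator with known VT1 index and
   controllable entropy structure (MIX-process noise), used by every test.

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example

Generate a cohort, inspect one record, and run the full analysis:

```sh
cpet-entropy simulate --out scratch/demo --participants-per-cell 10 --seed 42
cpet-entropy qc scratch/demo/me000.csv
cpet-entropy vt1 scratch/demo/me000.csv
```

```
me000: rer_peak=1.100 hr_peak=197.1 valid=True
me000: k_vslope=97 k_exco2=110 k_mean=104 (t=222s)
```

The detected threshold (breath 104, the generator's truth is 110) splits
each channel for the entropy stage.  The numbered drivers run the cohort
analysis end to end:

```sh
cd analysis
python 01_simulate_cohort.py && python 02_detect_vt1.py \
  && python 03_stationarity.py && python 04_entropy.py \
  && python 05_fit_contrasts.py
```

selected output:

```
VT1 recovery over 40 records:
  median |error| 5.0 breaths, within ±8: 92%
480 segments tested (0 degenerate, excluded)
adjusted-stationary at α=0.05: 100.0%

mean SampEn by metric and side:
side    after  before
hr      0.228   0.977
rr      2.222   1.685
vco2    1.747   1.971
vo2     1.756   2.009

P(Δμ ≥ 0 | y) by metric (min–max over the four groups):
    hr: 0.000–0.000
    rr: 0.983–1.000
  vco2: 0.010–0.231
   vo2: 0.002–0.398

median HR SampEn change after VT1: -76.9%
```

Reading this: every gas-exchange channel and HR lose entropy beyond VT1
(P(Δμ ≥ 0) far below 0.5; for HR not a single posterior draw is
non-negative), respiratory rate gains entropy, and the HR drop is by far
the most extreme — the directional pattern the cohort was built to carry,
recovered through detection, preprocessing, entropy estimation, and
posterior inference.

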