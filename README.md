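# isomob

Oxygen- and carbon-isotope palaeomobility analysis for tooth-enamel
carbonate. `isomob` is for bioarchaeologists who have per-individual enamel
carbonate measurements (δ¹⁸Oca, δ¹³Cca, both ‰ V-PDB) from one or more
prehistoric funerary communities and want a reproducible answer to the
question: *which individuals are unlikely to have grown up locally?*

## What it computes

**Scale conversions.** Measured carbonate values are mapped between reference
scales and to estimated drinking water with two fixed affine transfer
functions:

```
δ¹⁸Oca(V-SMOW) = 1.03091 · δ¹⁸Oca(V-PDB) + 30.91
δ¹⁸Odw         = 1.59 · δ¹⁸Oca(V-SMOW) − 48.634
```

**Per-community statistics.** For each site: min/max/mean/sd (n−1), median,
quartiles (R type-7 interpolation by default, type 2 optional), and the
robust spread set MAD_raw, MAD_norm = 1.4826·MAD_raw, MAD_Q3 (the 75th
percentile of absolute deviations from the median) and IQR. Shapiro–Wilk
tests normality at α = 0.05; neighbouring contemporaneous sites can be pooled
into one population after a location test (Student's t for two groups,
Kruskal–Wallis for three or more) finds no shift.

**The locality screen.** A community's "locality window" — the δ¹⁸O interval
compatible with local origin — is built from its own sample under four
criteria: mean ± 2σ; median ± 3·MAD (MADnorm for normal sites, MADQ3
otherwise, chosen by the Shapiro–Wilk result); Tukey's fences
[q1 − 1.5·IQR, q3 + 1.5·IQR]; and a fixed mean ± 2.0‰ band. An individual
strictly outside **every** applied window is a *consensus outlier* — the
operational definition of a probable newcomer. The screen only runs on
communities with n ≥ 9; windows include the candidates themselves (single
pass, no leave-one-out). The screen is an sklearn-compatible outlier detector
(`LocalityScreen`, with `fit` / `predict` / `decision_function`).

**Provenance checks.** Site drinking-water estimates (mean ± 1 sd) are
compared against modern local water ranges; deciduous teeth are screened for
the systematic 0.5–2‰ pre-weaning ¹⁸O enrichment; and a two-endmember mixing
check quantifies whether carbonate values fall on a line toward a
secondary-carbonate endmember (e.g. a cave speleothem), the signature of
diagenetic δ¹³C alteration.

**Synthetic data.** A seeded generator produces cemetery datasets with known
ground truth — per-site normal δ¹⁸O distributions, planted migrants at chosen
offsets, deciduous enrichment, diagenetic mixing — so detection power and
false-positive rates are measured, not assumed.

## Worked example

Generate the bundled ten-community scenario with one migrant planted 2.1‰
below the coastal-Tuscany community (SS) mean, and screen it:

```python
from isomob import generate_study_like, run_pipeline, round_report

samples, truth, registry = generate_study_like(2, migrants={"SS": [(1, -2.1)]})
result = run_pipeline(samples, registry)

rep = result.outliers["SS"]
print("applied criteria:", rep.methods)
for m, win in rep.windows.items():
    print(f"  {m:15s} [{round_report(win.lower)}, {round_report(win.upper)}] ‰ V-SMOW")
for r in rep.consensus_outliers():
    print(f"consensus outlier: {r.sample_id} at {round_report(r.value)} ‰ V-SMOW "
          f"(flagged by {r.consensus_count}/4 criteria)")
```

prints

```
applied criteria: ['two_sd', 'three_mad_q3', 'tukey_iqr', 'two_permil']
  two_sd          [25.4, 28.2] ‰ V-SMOW
  three_mad_q3    [24.8, 29.1] ‰ V-SMOW
  tukey_iqr       [25.3, 28.4] ‰ V-SMOW
  two_permil      [24.8, 28.8] ‰ V-SMOW
consensus outlier: SS_027 at 24.4 ‰ V-SMOW (flagged by 4/4 criteria)
```

`SS_027` is exactly the planted migrant (`truth` confirms it), flagged by all
four criteria: under these community parameters (n = 50, σ = 0.6) a −2.1‰
newcomer is usually, though not always, recoverable. The MADQ3 variant was
selected because this draw of the site failed the normality check. The same
run reports the community's drinking-water estimate (−6.0 ± 1.1‰, consistent
with the −6…−5‰ modern reference range for the area), skips the two
communities below the n ≥ 9 gate (CE, GN), and pools the four Rome-area sites
after a Kruskal–Wallis test (p = 0.25) finds no location shift.

The same analysis from a shell:

```
isomob synth --scenario study_like --seed 2 --out synth/
isomob run --data synth/samples.csv --out results/ --figures
```

writes `site_stats.tsv`, `spread.tsv`, `outliers.json`, `water_verdicts.tsv`,
`run_log.json` and the violin/bivariate figures.

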