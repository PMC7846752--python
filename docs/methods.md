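# Methods

## Model and assumptions

Tooth enamel mineralises in childhood and is isotopically inert afterwards,
so the carbonate fraction of enamel bioapatite records the oxygen isotope
composition of the water (and the carbon isotope composition of the diet)
ingested during early life. If most members of a funerary community grew up
locally, the community's δ¹⁸Oca sample estimates the local signature, and an
individual far outside that distribution probably mineralised their enamel
elsewhere. The package operationalises this with per-community locality
windows; it deliberately does **not** attempt to assign flagged individuals
to a geographic origin, which single-element isotope data cannot support.

Working assumptions:

* each community's δ¹⁸Oca values are approximately normal with most members
  local (the screen's windows are computed from the full sample, migrants
  included — heavy contamination by non-locals would widen every window and
  reduce power);
* drinking water was local and unmodified (brewing, stewing, or imported
  water shift δ¹⁸O upward of the meteoric signal);
* modern reference water ranges approximate mid-Holocene ones (climate
  fluctuations since then are acknowledged but not modelled).

## Scale conversions

V-PDB → V-SMOW uses the fixed affine map with slope 1.03091 and intercept
30.91‰; carbonate V-SMOW → drinking water uses slope 1.59 and intercept
−48.634‰. The constants live in one module (`conversions`), are echoed into
every run log, and are not silently overridable; a user preferring another
transfer function can apply it explicitly. Reported `mean ± sd` pairs
propagate exactly: means through the map, sds scaled by |slope|. Conversion
of drinking-water estimates carries an inherent calibration error of order
1–2‰, which is why reference-range verdicts use a ±1 sd overlap rule rather
than a point comparison.

Note on rounding paths: converting a mean that was first rounded to one
decimal can differ by 0.1‰ from rounding the conversion of the full-precision
mean. All internal computation is at full precision; one-decimal
round-half-away-from-zero is applied only in reporting columns.

## Statistics

* sd is the n−1 sample standard deviation (undefined at n = 1, reported NaN).
* Quantiles use linear interpolation of order statistics with
  h = (n−1)p + 1 — R's type 7, the default of the statistical environment
  this style of analysis is usually run in — with type 2 available by option.
  The choice matters at these sample sizes: IQRs from types 2 and 7 can
  differ by a few tenths of a per mil at n < 20.
* MAD_raw = median |x − median(x)|; MAD_norm = 1.4826 × MAD_raw (exact, an
  identity property-tested on every input); MAD_Q3 = 75th percentile of the
  absolute deviations, using the same quantile rule. MAD_Q3 ≥ MAD_raw always,
  making the MADQ3 window the more permissive of the two variants — a
  deliberately conservative choice for skewed sites.
* Shapiro–Wilk (scipy implementation) decides normality at α = 0.05, with
  p ≤ α treated as non-normal (boundary inclusive).
* Poolability: two groups → two-sided Student's t with pooled variance
  (Welch by flag); three or more → Kruskal–Wallis. Sites merge only when the
  test accepts (p > α) or the user forces with an explicit, logged override.
  No multiple-testing correction is applied anywhere, matching standard
  practice for this screen.

## The locality screen

Window definitions: mean ± 2σ; median ± 3·MADnorm or ± 3·MADQ3 (variant
selected by normality, forcible by option); [q1 − 1.5·IQR, q3 + 1.5·IQR];
mean ± 2.0‰. Width identities (4σ, 6·MAD, 4·IQR, 4.0‰) are exact and tested.

Conventions, each genuinely open and decided here:

* **Closed windows, strict flagging.** A value exactly on a bound is local.
  Values within 0.05‰ (half the reporting-rounding unit) of a bound are
  annotated `boundary` so reports can discuss them separately, as analysts
  conventionally do for individuals "sitting at the boundary".
* **Consensus over the applied set.** Default criteria: 2σ, the selected MAD
  variant, Tukey 1.5·IQR, ±2‰. A consensus outlier is flagged by all of them.
  Both MAD variants can be forced simultaneously for sensitivity analysis,
  in which case consensus is over five windows.
* **Single pass.** No iterative re-screening after removal of outliers.
* **Centers.** Mean-based rules (2σ, 2‰) center on the mean; MAD rules on
  the median; Tukey's fences hang off the quartiles directly.
* **Gate.** Communities with n < 9 get descriptive statistics, drinking-water
  estimates and plots but no outlier screen; the literature suggests n ≈ 25
  as genuinely sufficient, so even gated-in screens at n ≈ 9–20 deserve
  caution.
* **Scale invariance.** The 2σ/3MAD/1.5IQR criteria flag identical
  individuals whether computed on V-PDB or V-SMOW (affine equivariance,
  property-tested). The ±2‰ band is the exception: its half-width is an
  absolute per-mil quantity and does not rescale with the 1.03091 slope, so
  a value within ~3% of that band's edge can flip between scales. The
  package computes windows on V-SMOW throughout.

A documented inconsistency in the source analysis this screen follows: for
the coastal-Tuscany community the ±2‰ band centered on the mean (26.8‰)
cannot exclude values at 25.4/25.5‰, yet the original discussion names them
as outside it. The ±2.0‰-from-the-mean reading is implemented as stated in
the method definition; the discrepancy is noted rather than guessed around.

## Provenance checks

* **Reference water:** verdict `consistent` iff [mean − sd, mean + sd]
  overlaps the (normalized) reference interval, closed at the endpoints;
  otherwise `below`/`above` by the side the mean falls on; `no_reference`
  when a site has no published range. The bundled registry carries ranges
  only for the sites with published bounds (SS −6…−5‰; GN and the Rome-area
  sites −7…−6‰).
* **Breastfeeding:** `systematic_enrichment` requires the deciduous −
  permanent mean offset to fall in [0.5, 2.0]‰ *and* every deciduous value
  to exceed the permanent median. A single high deciduous tooth does not
  qualify; absence of deciduous teeth yields an empty report, not an error.
* **Mixing:** the mixing fraction is solved on the δ¹³C axis only
  (f = (δ¹³C − δ¹³C_B)/(δ¹³C_A − δ¹³C_B)), because carbonate δ¹³C is the
  axis diagenesis moves most while δ¹⁸O typically stays within biogenic
  range. The off-line distance is perpendicular distance to the endmember
  segment after standardizing each axis by the segment's span, which makes
  it invariant to affine rescaling of δ¹⁸O. The check is diagnostic only; it
  never excludes samples, because carbonate alteration cannot be confirmed
  from these two axes alone.

## Synthetic generator

`generate_site` draws n values from Normal(μ, σ) on the V-SMOW scale and
stores them as V-PDB through the exact inverse conversion, mimicking a
laboratory table. Migrants replace randomly chosen locals with draws at
μ + offset (same σ); deciduous teeth get a fixed offset added; diagenetic
mixing replaces δ¹³C with (1−f)·biogenic + f·endmember, f uniform in a given
range. The bundled `study_like` scenario uses the ten communities' published
sizes and mean/sd pairs verbatim (126 individuals in all), with per-site
seeds spawned from one integer.

What the generator does *not* emulate: measurement error as a separate term
(it is folded into σ), age-structured weaning variation, intra-tooth
sampling position effects, correlated δ¹³C–δ¹⁸O structure, and non-normal
site distributions. Passing tests therefore demonstrate the pipeline's
arithmetic and its power under idealised normal communities, not performance
on real, messier collections.

Sequence stability of the pseudo-random generator across numpy versions is
not promised; tests assert statistical properties and seeded determinism
within an environment, not exact draws.

## Simulation conditions and observed behaviour

Power and type-I behaviour are measured at n = 30, σ = 0.5 per community —
a mid-sized community at typical analytical spread: 500 seeded replicates
with one migrant at ±3‰ for power; 1000 migrant-free replicates for
false-positive rates. Under these conditions consensus recovery of a 3‰
migrant runs at ~95–97% and the 2σ criterion flags ~3.9% of locals (its
nominal Gaussian rate is 4.55%; the shortfall is the usual small-sample
effect of estimating mean and σ from the same 30 values being tested).
These are the sizes `scripts/acceptance.py` uses; they complete in seconds.

## Known limitations

* δ¹⁸O alone cannot separate "non-local" from "local with modified water
  habits"; consensus outliers are candidates, not verdicts.
* Windows computed from samples that include migrants are slightly inflated;
  with several same-direction migrants in a small community, masking is
  possible. The robust (MAD/IQR) criteria mitigate but do not eliminate this.
* The n ≥ 9 gate admits communities where all five windows are noisy; treat
  single-criterion flags at small n as exploratory.
* Reference-water verdicts inherit both the transfer-function calibration
  error (1–2‰) and the modern-vs-Holocene water question.
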