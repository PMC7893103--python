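# Methods

This note documents the modeling substance behind `circlight`: the equations
it evaluates, the spectral data it bundles, the numerical conventions it
adopts, and the places where the design was genuinely open and a choice had
to be made.

## The phototransduction model

The package evaluates a retinal-circuit model of human circadian
phototransduction in two generations.  Both share the same architecture: a
melanopsin (ipRGC) signal, a blue-versus-yellow (b−y) spectral opponent
signal contributed by S-ON bipolar input, and a rod signal that sets a
light-level-dependent threshold.  The opponent signal is two-state by
design: when b−y > 0 ("cool" spectra) the opponent pathway contributes;
when b−y ≤ 0 ("warm" spectra) it cannot, and only the melanopsin (plus, in
the revised model, rod/cone) terms remain.  The model is explicitly
discontinuous across the b−y = 0 boundary — no smoothing is applied, and
the boundary itself belongs to the warm branch.

Model constants (all dimensionless unless noted):

| constant | 2005 | revised (2.0) | role |
|---|---|---|---|
| k | 0.2616 | 0.2616 | opponent balance point |
| a_b−y | 0.7 | 0.21 | opponent gain |
| a_rod (/1, /2) | 3.3 | 2.30, 1.60 | rod gains (melanopsin / opponent pathway) |
| g1, g2 | — | 1.00, 0.16 | S-cone weight in the rod-ratio denominators |
| RodSat | 6.5 W·m⁻² | 6.5 W·m⁻² | rod saturation constant (on ∫V′E) |
| norm | 1548 | 1548 | calibration: CL_A = 1000 at 1000 lx Illuminant A |

The circadian stimulus is a fixed logistic of circadian light with
asymptote 0.7 (fractional suppression), half-saturation constant 355.7 and
exponent 1.1026; only the half-saturation constant is ever allowed to vary,
and exposure duration t (hours, 0.5–3) and retinal distribution factor
f ∈ {2.0, 1.0, 0.5} act by replacing CL_A with t·f·CL_A — equivalently,
half-saturation 355.7·t⁻¹.  The response therefore depends on the product
t·f·CL_A only, which the code preserves bit-exactly and the tests assert.

The normalization 1548 is hard-coded for both generations.  Under the
revised equation the Illuminant-A anchor drifts (the rod terms subtract
roughly a fifth of the response for an incandescent source at 1000 lx);
`circlight calibrate` reports both values and their deviation from 1000
rather than silently recalibrating, because reproducing the printed
equations takes precedence over preserving the anchor.

A deliberately ambiguous point in the revised equation's typography is the
grouping of the rod/cone interaction term.  The adopted reading is

    a_rod · [ ∫V′E / (∫Vc E + g ∫Sc E) ] · (1 − e^(−∫V′E/RodSat)),

i.e. the denominator of the ratio is the g-weighted cone sum — the only
grouping in which the ratio is dimensionless.

### Conventions for degenerate inputs

* A dark stimulus gives CL_A = 0 in both generations; the rod ratio terms
  are defined as 0 when ∫V′E = 0 or the cone denominator is 0 (no rod
  signal, no suppression — removes the 0/0).
* Negative intermediate results are floored at CL_A = 0 before the
  logistic: circadian light is a stimulus magnitude, and for dim
  short-wavelength stimuli the rod subtraction can exceed the opsin terms.
* Exposure contexts outside the modeled ranges (t outside 0.5–3 h,
  f outside {2, 1, 0.5}) are accepted with a warning, since the three f
  levels are an acknowledged low-precision first approximation.

## Spectral weighting functions

All curves live on a uniform wavelength grid, default 380–780 nm at 1 nm.
Spectral integrals are trapezoidal — identical to the rectangle rule at
interior samples, with half-weighted endpoints so that integrands that do
not vanish at the grid edges (e.g. macular transmittance) do not acquire a
closed-interval bias; refining from a 5-nm to a 1-nm grid changes any model
integral by well under 1%.

* **V(λ), V′(λ)** — the standard 1924 photopic and 1951 scotopic luminous
  efficiency tabulations, bundled from their published 5-nm values and
  monotone-cubic interpolated to 1 nm (the scotopic table includes its
  507-nm unit maximum).  Illuminance uses the standard maximum efficacies,
  683 lm·W⁻¹ photopic and 1700 lm·W⁻¹ scotopic.
* **S-cone fundamental** — the exact tabulation behind the original model
  is not recoverable, so the package bundles a *synthetic stand-in* with
  the standard 2° corneal S-cone shape (peak 440 nm; file
  `scone_fundamental_synthetic.tsv`).  Because the model equations multiply
  S by macular transmittance, the in-code S is the bundled corneal curve
  *divided* by macular transmittance and renormalized ("macular-free"), so
  the product S·mp appearing in the equations reconstitutes the corneal
  fundamental's shape rather than double-counting macular screening.
* **Macular pigment** — synthetic stand-in: optical density with the
  standard two-lobe shape (main lobe 458 nm, shoulder 485 nm), 2° peak
  density 0.35; transmittance 10^(−OD).
* **Crystalline lens** — synthetic stand-in for a young-adult lens:
  two-component optical density tabulation (strong cutoff below 450 nm),
  transmittance 10^(−OD).
* **Melanopsin (in vivo)** — built analytically as a vitamin-A1 pigment
  nomogram filtered by lens transmittance.  The published constraint on
  this curve consists of two scalars per variant — peak 485 nm / FWHM 89 nm
  (the template used by the model's authors) and peak 490 nm / FWHM 84 nm
  (the alternative CIE-style template) — so two knobs are tuned once to
  meet them: the nomogram peak λmax and a multiplier on the lens optical
  density.  One knob (λmax alone) cannot satisfy both scalars
  simultaneously.  The frozen solutions are λmax = 480.34 nm with lens
  scale 0.651 (rea variant) and λmax = 479.39 nm with lens scale 1.509
  (cie variant); `tune_melanopsin_template()` reproduces them.

Only the *shapes* of the stand-ins matter downstream: the revised model
renormalizes its S and V weightings, the 2005 opponent term enters through
the calibrated constants, and the acceptance checks are anchored on
quantities (calibration, template scalars, sensitivity peak) with stated
tolerances that absorb tabulation differences.

Peak wavelengths are reported at the grid sample of maximum value, ties
broken toward the shorter wavelength; FWHM is measured between the two
half-maximum crossings with linear interpolation between samples, and a
missing crossing raises an error naming the truncated side.

## Constant-criterion spectral sensitivity

The classical action-spectrum procedure: for each narrowband stimulus
(Gaussian, 10-nm FWHM by default), find the irradiance at which the
predicted response reaches a fixed criterion (0.35, half the asymptote —
i.e. circadian light equal to the half-saturation constant), then define
relative sensitivity as the reciprocal criterion irradiance normalized to
the most sensitive wavelength.  The criterion irradiance is solved by
bracketed root finding on log irradiance to 1e-12.

One modeling decision required analysis.  If the rod saturation factor is
evaluated self-consistently at each test stimulus's own level, the revised
equation's rod ratios — whose denominators hold only cone signals — become
large precisely where V′ is large relative to Vc + g·Sc.  For dim
narrowband stimuli both the opsin terms and the saturation factor are
linear in irradiance, so this cancellation is level-independent and carves
a deep artificial trough into the derived sensitivity between roughly 470
and 510 nm, pushing the apparent peak to ~435–440 nm.  That behavior is an
artifact of probing an adaptation-dependent threshold mechanism with the
test stimulus itself.  The derivation therefore anchors the rod saturation
factor at a stated reference operating point — 300 scotopic lx by default,
the overall retinal flux at which the model's published sensitivity curves
are defined, and close to the criterion stimuli's own levels — while
everything else (opsin terms, opponent sign, rod ratios) follows the test
stimulus.  With this anchoring the derived curve peaks at 450 nm on the
default tables, in the blue region where the empirical suppression action
spectra peak.  Passing `reference_scotopic_lux=None` restores the fully
self-consistent evaluation for anyone who wants to study the trough.

## Fitting procedures

* **Half-saturation fit** — the logistic's asymptote and exponent stay
  fixed; the half-saturation constant alone is estimated by least squares
  on suppression (levels in CL_A units, each row weighted equally), using a
  log-spaced scan over 10⁻² – 10⁷ followed by bounded scalar refinement to
  1e-10 in log10.  Residual SSE and r² (about the response mean) are
  reported.  Datasets with fewer than three distinct levels, or identical
  responses everywhere, are rejected as degenerate.
* **Log-abscissa alignment** — the lateral shift on the log-level axis that
  minimizes the mean squared response difference between two dose-response
  curves, found by a 0.02-decade scan over ±5 decades with bounded
  refinement; responses are compared by interpolation over the overlapping
  range.  A least-squares objective stands in for the original "empirical
  alignment to a mid-point", whose exact objective is unstated.
* **Duration exponent** — ordinary least squares in log10–log10 space on
  (t, half-saturation) pairs; with the coefficient fixed, the intercept is
  pinned at log10(355.7) and only the slope is estimated.  Noiseless pairs
  generated from the t⁻¹ law recover exponent −1 with r² = 1 to machine
  precision.

## Synthetic suppression data

The generator emulates the *structure* of the melatonin-suppression
literature, not any particular dataset: each row is one stimulus condition
(an SPD at a level, an exposure duration t and distribution f), whose
recorded suppression is the model prediction plus additive Gaussian noise,
clipped to [−0.2, 1] (observed suppressions can be slightly negative
through assay noise).  Rows carry an `n` column: in real studies a
condition's datum is the mean over a panel of subjects, so the dose-response
simulator treats its noise parameter as per-subject assay noise and scales
the row noise by 1/√n, with a default panel of 8 subjects per level — the
typical size in the narrowband suppression studies — and levels placed
across the response's dynamic range (±0.6 decades around half-saturation),
as dose-response designs do.  The protocol-level generator
(`generate_synthetic_dataset`) defaults to n = 1, i.e. raw per-row noise.

What the generator does *not* emulate, and what recovery tests therefore do
not demonstrate about real data: between-subject sensitivity differences
and prior-light-history effects (the noise is i.i.d.), assay
heteroscedasticity near 0% and 100% suppression, pupil-size variation,
intermittent or flickering exposures, and habituation beyond 3 h.  Passing
the seeded recovery suites shows that the estimators are consistent and
correctly implemented under the model's own noise assumptions — not that
the model fits any particular laboratory dataset.

## Problem sizes and determinism

The default grid has 401 samples; sensitivity derivations use 51 narrowband
stimuli (400–650 nm in 5-nm steps); recovery suites use 100 seeded
replicates of 8-level studies.  Everything outside the synthetic-noise
generators is deterministic; all randomness flows through
`numpy.random.default_rng(seed)`.

## Known limitations

* CL_A and CS are instantaneous photometric quantities: no prediction of
  phase shift, sleep, alertness or cortisol, no intermittent-exposure
  dynamics or hysteresis, no habituation beyond 3 h of continuous exposure.
* The retinal distribution factor has three discrete levels only; no
  finer spatial anisotropy is modeled.
* SPDs are corneal spectral irradiance with an assumed cosine-corrected
  detector; pupil area and age-dependent lens transmittance are not
  modeled (the bundled lens curve is a young-adult standard).
* The S-cone, macular and lens tables are documented synthetic stand-ins;
  users with authoritative tabulations can swap the data files, whose
  format is two-column text with '#' headers.
* The revised model's published fit qualities to the original pooled
  suppression datasets cannot be reproduced here because those datasets
  are not redistributable; the property and recovery suites take their
  place.
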