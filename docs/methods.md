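# Methods

## Scope and model

`hexapure` implements trichromatic colorimetry for bee-pollinator vision —
the colour hexagon and the receptor-noise-limited (RNL) model — together
with the two "saturation" statistics used in the pollination literature
(hexagon spectral purity and model-independent chroma), a synthetic
reflectance-spectrum generator, and a rank-correlation pipeline for testing
how entangled these metrics are. All computation happens on a common
wavelength grid, by default 300–700 nm at 1-nm steps (401 points). The
endpoints are conventional, not physical, and are configurable; their
influence on purity (through the closure of the monochromatic line) is one
of the things the package is designed to expose.

Assumptions inherited from the hexagon model: three receptor classes,
complete von Kries adaptation to a uniform background, hyperbolic
transduction E = P/(P+1), no brightness/lightness channel. The RNL model
further assumes discrimination is limited by channel noise e_i and uses the
standard trichromatic closed form on log receptor contrasts; it measures
chromatic contrast only and deliberately has no purity/saturation analogue.

## Photoreceptors and visual systems

Receptor sensitivities are Govardovskii A1 nomogram templates: the
closed-form alpha band plus, by default, the ultraviolet beta band
(amplitude 0.26, centre 189 + 0.315·λmax nm, width −40.5 + 0.195·λmax nm),
peak-normalised. Bundled peak wavelengths (nm):

| system | UV | B | G | note |
|---|---|---|---|---|
| honeybee | 344 | 436 | 544 | conventional measured peaks |
| bumblebee | 328 | 428 | 536 | |
| stingless_bee | 344 | 436 | 544 | honeybee values reused under its own label |

These are parameters, not constants: published colour spaces for the same
species differ visibly, so λmax, the beta flag and the template itself are
exposed. Templates are an idealisation of measured sensitivity curves; the
main consequence (see *Limitations*) is that the secondary ultraviolet peaks
of the B and G receptors sit exactly at the Govardovskii beta centres
(326 and 360 nm for the honeybee), which fixes *where* on the wavelength
axis the ultraviolet artefacts of the monochromatic line appear.

Default illuminant: `flat_quantum` (constant quantum flux; a `d65_approx`
daylight-shaped curve is available). Default adapting background: a
parametric green leaf, R(λ) = 0.6·exp(−1.5·[g(λ;450,40) + g(λ;680,20)])
with g(λ;μ,w) = exp(−((λ−μ)/w)²) — chlorophyll absorption bands at 450 and
680 nm on a flat scattering baseline, giving the characteristic reflectance
peak near 550 nm. Throughout the package this Gaussian convention (unit
height, w the 1/e half-width) is used.

## Monochromatic line and spectral purity

The hexagon locus of a single-wavelength light depends on its intensity,
because excitations saturate; the literature does not agree on a
convention, and published lines for the same species differ up to two-fold
in places. The construction is therefore explicit:

- **intensity rule `max_distance`** (default): per wavelength, the quantum
  flux q is optimised to put the locus at its maximum distance from the
  achromatic centre (distance → 0 both as q → 0 and as q → ∞, so the
  maximum is interior; 120-point log-spaced scan refined by bounded
  golden-section search, tolerance 1e-6 in log q). Deterministic and
  well-defined, at a price: at the optimum the dominant receptor is deep in
  saturation, which compresses hue angles (a 440-nm light plots at ~37°
  rather than near the blue corner) and lets ordinary reflective stimuli
  exceed the boundary in some sectors (reported as purity > 1 with a
  warning, never an error).
- **intensity rule `fixed_multiple(k)`**: q is k times the background's
  total quantum flux. Emulates published fixed-intensity lines, including
  their own artefact — the loci spiral into the achromatic centre at both
  spectral ends where absolute sensitivity vanishes.

The non-spectral gap between the 700- and 300-nm loci is closed by
`closure_steps` (default 100) stepwise mixtures α·light(700) +
(1−α)·light(300) under the same intensity rule, stored in descending α so
the closed polygon follows the boundary continuously. This closure is a
convention of the field with no physical counterpart.

Spectral purity of a stimulus at distance a from the centre is a/(a+b),
with b measured along the ray from the centre through the stimulus to the
boundary polygon. Geometric decisions: a stimulus within 1e-9 of the centre
has undefined hue and purity NaN; a stimulus within 1e-9 of the boundary
polygon is its own boundary point (purity exactly 1 — checked directly
because ray–segment intersection is ill-conditioned where the boundary
runs along the ray); otherwise the boundary point is the **first ray
crossing at or beyond the stimulus**. Where the beta band folds the
boundary so that one hue angle crosses it several times, this rule — rather
than "nearest crossing to the centre" — is what keeps every boundary locus
at purity 1 and every interior stimulus at purity ≤ 1. A stimulus beyond
every crossing gets purity > 1 against the outermost crossing, with a
warning. Degenerate ray-collinear segments resolve to their nearest
endpoint on the ray.

## RNL model

Log receptor contrasts Δf_i = ln(q_i/q_i^ref) use *un-adapted* catches and
require strictly positive catches. Default noise: ω = 0.12, receptor
abundances η = (1, 0.471, 4.412) (conventional hymenopteran values), giving
e_i = ω/√η_i. ΔS scales inversely with the noise, so these defaults are
explicit and overridable; correlation results involving ΔS should be read
with that scale-dependence in mind (rank correlations are unaffected by the
overall scale, but not by the η ratios).

## Model-independent chroma

(R_max − R_min)/R_mean over grid points in a stated range (default
300–700 nm, endpoints inclusive; unweighted mean, which equals the integral
mean on the uniform grid). Scale-invariant, observer-independent, and
range-dependent by construction — widening the range can only extend the
extrema.

## Synthetic flora

The generator emulates flower reflectance with a Beer–Lambert model
R(λ) = S·exp(−c·A(λ)): scattering level S sets brightness, pigment amount c
sets colourfulness, and the absorbance profile A sets hue. Four classes:

| class | A(λ) | emulates |
|---|---|---|
| `white_sigmoid` | 0.5·logistic((380−λ)/25) | white petals with a weak UV-absorbing edge |
| `yellow_uv_absorbing` | logistic((500−λ)/20) | carotenoid-type absorption below ~500 nm |
| `band_purple_blue` | exp(−((λ−540)/60)²) | anthocyanin-type mid-wavelength band |
| `uv_red` | logistic((λ−390)/15)·logistic((610−λ)/15) | UV-reflecting red (poppy-type) |

Defaults (the study conditions for every seeded run): 200 flowers, equal
class proportions, pigment amount uniform on [0.3, 6] (near-achromatic
through saturated), scatter uniform on [0.3, 0.9], additive Gaussian noise
of sd 0.005 per grid point clipped to [0, 1]. Within each class, pigment
amount monotonically increases chroma, and increases hexagon contrast up to
the saturation point of the colour (tested properties). What the generator
does **not** emulate: within-species correlation structure, spatial
patterning (bullseyes), thin-film/multilayer optics, realistic community
hue distributions (real floras are biased towards the white/yellow sector;
the default equal mix is deliberately agnostic). Passing tests on this
flora therefore demonstrate properties of the metrics and geometry, not
community-level statistics of any real flora.

## Correlation study

Per stimulus and visual system: hexagon contrast, green contrast, spectral
purity (against the system's monochromatic line, or any supplied boundary,
including a constant-radius circle for the limiting case), chroma, and
optionally RNL contrast. Spearman's rank correlation on every requested
metric pair: tie-averaged ranks, Pearson on ranks; two-sided p exact by
full permutation enumeration for n ≤ 9 and via the t approximation with
n−2 df above (|rho| = 1 maps to p = 0, never a division by zero).
NaN-purity stimuli (achromatic, at the centre) are dropped pairwise —
the only choice that keeps rank tests defined — with the retained count
reported as `n_used`. Benjamini–Hochberg step-up adjustment (via
statsmodels) pools all tests in the run into one family by default;
per-system families are available. Stimulus sets under 15 spectra are
refused: rank correlations on smaller sets are uninformative and such
datasets are excluded from this kind of analysis.

Problem sizes used by the bundled tests, examples and the acceptance
script: 200-flower floras, 401-point grids, 100 closure steps, five seeds
for stability checks — small enough to run in seconds, large enough that
the rank correlations are stable to ±0.1 across seeds.

## Known limitations

- The purity–contrast entanglement on the *pooled* default flora is weaker
  (rho ≈ 0.3, still highly significant) than within single colour classes
  (rho 0.95–1.0), because the beta band contracts the boundary ~4-fold in
  the ultraviolet-blue sector where two of the four classes sit, making the
  purity denominator class-dependent. This is the denominator argument in
  both directions: purity tracks contrast exactly insofar as the boundary
  distance is constant over the stimuli analysed. The constant-radius
  limiting case (rho = 1 exactly) is part of the test suite.
- With Govardovskii templates the least-chromatic ultraviolet wavelength is
  the G-receptor beta centre (~360 nm for the honeybee), so the
  ultraviolet "hook" of the line bottoms out near 360 nm rather than below
  310 nm as drawn in some published colour spaces based on measured
  sensitivity curves; two acceptance tests assert those published-geometry
  expectations and fail, documenting the discrepancy rather than hiding it.
- No brightness channel, no tetrachromatic spaces, no behavioural response
  modelling: the package quantifies metric entanglement, not pollinator
  behaviour.
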