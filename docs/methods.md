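# Methods

`conegain` estimates the Shannon information that noisy cone photoreceptor
responses carry about the radiance spectra of colored surfaces in a scene,
for observers with normal, dichromatic, anomalous-trichromatic, or
monochromatic color vision, and relates the losses in red-green color
deficiency to the colorimetric structure of scenes. This note documents the
model, the estimators, the synthetic-data generator, and the numerical
choices, in enough detail to reproduce or audit any number the package
prints.

## The receptor-level information model

A scene is a hyperspectral radiance image L(u, v; λ). At each sampled pixel
the cone excitations are

    q_c = ∫ L(λ) S_c(λ) dλ,   c ∈ {L, M, S},

with S_c the corneal spectral sensitivity of cone class c, and integration
by the trapezoid rule over the scene's wavelength grid (400–720 nm at 10 nm
by default, 33 bands). Phototransduction noise is modeled as Gaussian with
standard deviation proportional to the local excitation: y_c = q_c + ε_c,
ε_c ~ N(0, (w_c q_c)²). The Weber fraction for L cones, `weber_l`, is the
headline noise parameter (default 0.02, a practical minimum; 0.01 and 0.05
are the conventional sweep); M and S fractions are scaled by the ratios of
the increment-threshold Weber fractions 0.018 : 0.019 : 0.087, so at
`weber_l = 0.02` the S-cone relative SD is ≈ 0.097.

With X the radiance vector (33- or 31-dimensional) and Y the noisy
excitation vector (3, 2, or 1 dimensional depending on the observer), the
quantity of interest is the mutual information I(X; Y) in bits; the loss of
a deficient observer is ΔI = I − I′ against the normal trichromat on the
same pixels and the same noise stream (paired design). N = 2^I is the
effective number of distinguishable surfaces; a loss ΔI reduces it by
100·(1 − 2^(−ΔI)) percent. I(X; Y) is a receptor-level quantity: by the
data-processing inequality no later neural stage can increase it, which is
also the invariant the test suite checks (a deficiency never *gains*
information beyond estimator noise).

Observers: normal = pigments peaking at 559/530/426 nm; protanope = {M, S};
deuteranope = {L, S}; protanomal = {M(530), hybrid 536, S}; deuteranomal =
{L(559), hybrid 549, S}; M- and L-cone monochromats. The S pigment is
always unaltered and optical density is held constant.

### Cone fundamentals and hybrid pigments

The shipped fundamental tables are **synthetic**: Govardovskii A1 pigment
templates multiplied by a smooth lens/macular-like short-wave attenuation,
with the pigment peak solved (Brent's method) so the corneal peak lands
exactly at 559, 530, or 426 nm. They are stand-ins with realistic shape and
exact peak placement, not measured human data; any conclusions that depend
on fine spectral detail of real fundamentals should re-run with a measured
table (`load_fundamentals(path)` accepts any CSV covering 400–720 nm).

Hybrid (anomalous) pigments are built by smoothing a fundamental with a
local-quadratic (loess) fit of sensitivity against log wavelength — tricube
weights, bandwidth chosen by exact leave-one-out cross-validation over
spans {0.03, 0.05, 0.08, 0.12, 0.2} of the log-λ range — and translating
the smoothed curve along the log-wavelength axis, which preserves its shape
on that axis. A fixed-point adjustment puts the realized peak within 0.3 nm
of the target (536 nm protanomal, 549 nm deuteranomal). A zero shift
returns the untranslated smoothed template; the smoother itself may move
the peak by up to ~1 nm relative to the raw argmax, within the ±1 nm peak
contract. Shifts beyond 35 nm are refused.

## Mutual-information estimation

The core estimator is the Kozachenko–Leonenko kth-nearest-neighbor
differential entropy estimate (Euclidean metric, k = 3 by default, exposed
in every API), combined as Î = ĥ(X) + ĥ(Y) − ĥ(X, Y).

**Offset (bias) correction.** The raw 3-entropy combination carries a
small-sample bias that depends strongly on dimension and on how close the
data sit to a low-dimensional manifold; comparisons between observers whose
Y have different dimension (3 vs 2 vs 1) would inherit that differential
bias. The offset correction evaluates the *same* estimator on a Gaussian
surrogate drawn with the data's joint covariance — whose mutual information
is known in closed form, ½ log₂ (det Σ_X det Σ_Y / det Σ_XY) — and
subtracts the surrogate's estimation error:

    Î_offset = Î_KL(data) − mean_r Î_KL(surrogate_r) + I_gauss(Σ̂).

The surrogate correction is averaged over 3 replicates to keep its own
sampling noise small. The reported standard error is half the absolute
difference between the offset estimates on the two halves of a random split
of the sample. Against closed-form Gaussian oracles (independent pairs,
bivariate Gaussians ρ ∈ {0.3, 0.6, 0.9}, Gaussian channels SNR ∈
{1, 3, 10}) the worst error at n = 10⁴ is below 0.07 bits for k ∈ {1, 3, 5}.

**Coordinate scaling.** X is standardized to unit variance per band. Y is
scaled so every cone channel has the same *noise* standard deviation
(dividing channel c by w_c·mean(q_c)), then by one common factor; both are
information-preserving diagonal maps. Equalizing noise thickness matters
because the S-cone Weber fraction is ~5× the L-cone one, and a 5× scale
imbalance in the joint space destabilizes the cancellation between ĥ(X)
and ĥ(X, Y).

**Sampling.** Scene estimates draw n pixels uniformly *without* replacement
(n = 10⁴ by default; palettes and thinned subsets are used in full).
Duplicate points break log-distance terms; exact ties that remain (e.g.
user-supplied data) are perturbed by additive jitter at 10⁻⁶ of the
coordinate scale, far below any data structure but above the numerical
floor of the BLAS distance computation. Degenerate (constant) inputs return
0 bits with a warning. `stability_check` reruns an estimate across
resamples and subset sizes and flags instability.

## Uniformization by thinning

To compare natural frequency-of-occurrence conditions with approximately
uniform ones, spectra are thinned in the sup metric d(l_r, l_s) =
sup_λ |l_r(λ) − l_s(λ)|: visiting spectra in a seeded random order, a
spectrum is retained iff it is at least d away from every already retained
spectrum. The greedy order is randomized because the criterion does not
define a unique survivor set; order-sensitive results should be
seed-averaged. `adaptive_thin` increases d along a grid until successive
information estimates change by less than `stability_tol` (default 0.05
bits) while at least `count_floor` (default 500) spectra remain — the floor
keeps the kNN estimator meaningful. The union condition concatenates the
per-scene thinned sets and thins once more, maximizing the gamut. The
pipeline's default d grid is {1, 2, 4, 8, 16}% of the 95th percentile of
the radiance values.

## Colorimetry

Radiance spectra are mapped to CIE XYZ with analytic piecewise-Gaussian
fits of the CIE 1931 2° color-matching functions (Wyman, Sloan & Shirley
2013; errors below ~1% of peak), then through CIECAM02 to CAM02-UCS
(J′, a′M, b′M). Viewing conditions default to a 6500 K daylight white,
adapting luminance 64 cd/m², background luminance factor 20, average
surround, and *full* chromatic adaptation (D = 1, appropriate for
well-adapted outdoor viewing; the CIECAM02 D formula is available via
`full_adaptation=False` and is used when reproducing the published CIE
worked example). Scenes carry no absolute luminance calibration, so the
99th-percentile luminance pixel is mapped to the adapting white's
luminance.

The daylight illuminant is constructed as a Planckian radiator at the
requested correlated color temperature times a smooth quadratic correction
solved exactly (a 2×2 linear system) so the chromaticity lies on the CIE
daylight locus, normalized to 100 at 560 nm; valid for 4000–25000 K.

Scene descriptors: the variance partition var J′ : var a′M : var b′M
normalized to 1; the mean (or median) chroma-to-lightness ratio
√(a′M² + b′M²)/J′; and the major chromatic axis φ ∈ [0°, 180°), the leading
eigenvector of the 2×2 chromatic covariance (an error, not a guess, when
the covariance is isotropic). Confusion-locus directions at the origin are
obtained by mapping the line through the white toward the copunctal point —
protan (0.747, 0.253), deutan (1.400, −0.400), tritan (0.171, 0.000) in
CIE 1931 (x, y) — into CAM02-UCS at fixed luminance and taking the central
difference tangent (default half-step 10⁻³ in chromaticity; stable within
±0.5° over two orders of magnitude of the step). These land at ≈ 11.7°
(protan), 177.6° (deutan), 113.4° (tritan).

Colorimetric quantities are descriptive only: `conegain.information` has no
import path to `conegain.colorimetry`, and a test enforces the firewall.

## Synthetic scenes

The generator is a statistical surrogate for hyperspectral image sets of
outdoor scenes — not a photorealistic renderer, and no claim is made that
it reproduces any real set's absolute information values. It emulates the
features the analysis depends on:

* **Dominant lightness variance.** A per-pixel log-normal shading field
  (log-SD 0.35, spatially smoothed with a 4-px Gaussian) multiplies the
  radiance, standing in for illumination and surface-geometry variation.
* **Small, directional chromatic variance.** Each of `n_materials`
  (default 64) materials is a smooth reflectance: a gray level plus
  chromatic perturbations along two spectra that move the appearance by
  unit a′M and unit b′M (obtained by differentiating the
  reflectance→CAM02-UCS map around mid-gray over a 6-function Gaussian
  reflectance basis). Material chromatic coordinates are drawn from a
  covariance aligned with `chromatic_axis_deg`.
* **Uneven surface frequencies with colorful outliers.** Material
  frequencies follow a Zipf law with exponent `frequency_skew` (entropy of
  realized frequencies decreases monotonically in the exponent), and rarer
  materials receive proportionally larger chromatic spread
  (`rarity_chroma`, default 0.5): common surfaces cluster near neutral,
  rare ones carry the gamut. This coupling is what makes uniformization
  (thinning) raise both the available information and the deficiency
  losses, as observed on real scene sets.
* **Within-material spectral texture.** Each pixel adds a small random
  draw on the reflectance basis (`texture_sd`, default 0.012). Real
  surfaces are not spectrally uniform; without this the radiance
  distribution collapses onto a near-1-D manifold per material, for which
  differential entropy is undefined and every kNN estimator fails.
  Chromatic texture is suppressed for purely achromatic targets so
  grayscale scenes stay exactly gray.
* **Bounded gamut.** Reflectances are clipped to [0.001, 1].

**Calibration.** Requested variance shares are realized by an internal
solve, not assumed: the generator measures the realized CAM02-UCS shares on
a pixel subsample and updates the 2×2 chromatic mixing matrix using (i) the
regression-estimated linear transfer from material coordinates to realized
(a′M, b′M), (ii) the measured residual chromatic covariance (gray-level and
shading dependence) which also counts toward the shares, and (iii) the
pixel-weighted covariance of the unit draws (uneven frequencies inflate
it). Updates are damped 50% and capped by `gamut_scale`; convergence
requires the total chromatic share within 0.02, the rg/yb split within
0.03, and the realized axis within 2° (when anisotropy ≥ 1.3). Unreachable
targets raise rather than clamp. All randomness is drawn before the loop,
so output is bit-identical for a given `SceneSpec`. Across seeds, realized
shares sit within ±0.02 of targets and axes within ~3°. An optional
`chroma_lightness` target shifts the mean chromatic coordinate until the
median chroma/lightness ratio matches (e.g. 0.25, the natural-scene
median). `SceneSpec.with_axis` derives a consistent rg/yb split for an
arbitrary axis direction, since not every (axis, split) pair is
geometrically possible.

Under the defaults (2% cone noise, shares 0.77/0.08/0.15) the synthetic
trichromat information comes out at ≈ 5.5–6.5 bits per scene — the regime
reported for real natural-scene sets — and the loss ordering is
deuteranomaly < protanomaly < deuteranopia < protanopia, with monochromat
losses a further ~2× above dichromat losses and thinning/union conditions
increasing all losses.

**What the generator does not emulate:** spatial texture statistics beyond
single-pixel draws, specular highlights, sky regions (scenes are all
"ground"), inter-reflections, sensor noise models, and the full
dimensionality of natural reflectance spectra (6-function basis). Passing
tests on the synthetic suite therefore validate the machinery and the
qualitative structure, not the absolute bit values of any real image set.

Palettes (`generate_palette`) are jittered lattices in (lightness, a′M,
b′M) mapped back to smooth reflectances: approximately uniform in
CAM02-UCS (nearest-neighbor distance CV < 0.5), with chromatic variance
share ≈ 0.45 — the regime of the matt Munsell set under daylight —
against ≈ 0.23 for natural-like scenes. `gamut_scale=0` degenerates to an
achromatic lightness series.

## Statistics

Confidence intervals use Efron's percentile bootstrap in nonparametric
mode, resampling cases (scenes), 1000 replications by default; simulated
coverage for a Gaussian mean at n = 50 falls in [0.92, 0.97]. Variance
proportions are linearized with the logit before linear regression; the
transform refuses boundary values (callers clamp explicitly — no silent
data edits). Regressions of losses on the major chromatic axis double the
axial angle onto the circle, regress on (cos 2φ, sin 2φ), and fold the
fitted extremum directions back to [0°, 180°); R² is the ordinary
coefficient of determination of the two-regressor model, and the circular
mean direction of the angles is reported alongside. Rotating all angles
rotates the extrema identically; adding 180° changes nothing.

## Pipeline and problem sizes

`run_analysis` orchestrates: per scene — descriptors, pixel draw, paired
I and ΔI for each observer and noise level, thinned-subset repeat — then
one union condition per collection; summaries are group means with
bootstrap CIs; the regression suite fits ΔI against logit rg share
(gradient + CI + R²) and against φ (circular fit). Per-scene failures are
logged and excluded; a run fails if more than 10% of scenes do. Reruns with
the same config are bit-identical.

Default problem sizes in the shipped test and acceptance suites: 20
synthetic scenes of 128×128 px, 3000 sampled spectra per scene, k = 3 —
sizes at which the estimator's half-sample spread is ≈ 0.1 bits, small
against the effects being ranked (0.2–1.6 bits). The estimator cost is
dominated by the joint-space neighbor search (d = 34–36), implemented as a
chunked BLAS distance matrix below n ≈ 6000 and a KD-tree above (and for
d ≤ 10).

## Known limitations

* Information is evaluated at the receptor level only; no spatial,
  postreceptoral, or task-level processing.
* The fundamentals are synthetic templates (exact peaks, approximate
  shape); hybrid-shift fidelity is therefore at the template level.
* kNN MI estimation near log₂(n) bits saturates; estimates above ~10 bits
  at n = 3000 would not be trustworthy. The synthetic defaults keep the
  true values well below that ceiling.
* The thinning survivor set depends on the seeded visiting order; only
  seed-averaged statements are stable.
* CIECAM02 is used outside its calibrated photopic mid-luminance range for
  very dark pixels; descriptor statistics are dominated by mid-range pixels
  so the effect is minor.
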