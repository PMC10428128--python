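# conegain

How much information about the colored surfaces in a scene do the eye's
cone photoreceptors deliver — and how much of it is lost in red-green color
vision deficiency?

`conegain` answers this computationally. It models cone excitations from
hyperspectral radiance images, adds Weber-scaled phototransduction noise,
and estimates the Shannon mutual information I(**X**; **Y**) between scene
radiance spectra **X** (one ~33-dimensional spectrum per sampled pixel) and
noisy cone responses **Y** (3 channels for a normal trichromat, 2 for a
dichromat, 1 for a cone monochromat). The loss of a deficient observer is

ΔI = I − I′,

the paired difference against the normal trichromat on the same pixels and
noise stream, and N = 2^I is the effective number of distinguishable
surfaces (a loss ΔI removes 100·(1 − 2^(−ΔI)) percent of them). Mutual
information is estimated with an offset Kozachenko–Leonenko
kth-nearest-neighbor estimator whose small-sample bias is canceled against
a Gaussian surrogate with the data's joint covariance.

Around that core, the package provides:

* **Observers** — normal (pigment peaks 559/530/426 nm), protanopia,
  deuteranopia, protanomaly (hybrid 536 nm) and deuteranomaly (hybrid
  549 nm) built by loess-based spectral shifts on the log-wavelength axis,
  and M-/L-cone monochromats.
* **Synthetic hyperspectral scenes** with the color statistics of outdoor
  environments — dominant lightness variance, small directional chromatic
  variance, bounded gamut, Zipf-skewed surface frequencies with colorful
  rare materials — calibrated so requested CAM02-UCS variance shares are
  realized within ±0.05. Every analysis is testable without downloading
  image sets; readers for HDF5 / ENVI / MAT v7.3 cubes cover real data.
* **Uniformization** by sup-metric thinning and gamut-maximizing unions
  across scenes, for comparing natural frequencies of occurrence with
  approximately uniform ones.
* **Colorimetry** — CIECAM02 / CAM02-UCS (validated against the published
  worked example), scene descriptors (variance partition across J′, a′M,
  b′M; chroma/lightness ratio; major chromatic axis), and dichromatic
  confusion-locus directions at the achromatic point.
* **Statistics** — percentile bootstrap CIs, logit-linearized regressions
  of losses on redness-greenness variance, and circular-linear regressions
  of losses on the major chromatic axis (axial data, doubled).

The headline empirical pattern this machinery reproduces on its synthetic
suite: losses are smallest in deuteranomaly, intermediate in protanomaly
and deuteranopia, largest in protanopia; removing chromatic information
entirely (monochromacy) costs severalfold more; and making surface
frequencies more uniform — or maximizing the gamut — increases both the
information available and the losses.

## Worked example

```python
import numpy as np
from conegain import synthetic, colorimetry, information
from conegain.cones import NoiseModel, load_fundamentals, make_observer
from conegain.spectral_io import sample_spectra

# A 128x128 synthetic scene in the natural regime: 77% of CAM02-UCS
# variance in lightness, 8% redness-greenness, 15% yellowness-blueness.
scene = synthetic.generate_scene(synthetic.SceneSpec(seed=7))

vc = colorimetry.ViewingConditions.from_cct(6500)
ucs = colorimetry.set_to_ucs(scene.flatten(), vc)
shares = colorimetry.variance_partition(ucs)
axis = colorimetry.major_chromatic_axis(ucs)
print(f"variance shares  J'={shares.lightness:.2f}  "
      f"a'M={shares.rg:.2f}  b'M={shares.yb:.2f}")
print(f"major chromatic axis  phi = {axis.phi:.1f} deg")

fundamentals = load_fundamentals()
normal = make_observer("normal", fundamentals)
deficient = [make_observer(n, fundamentals) for n in
             ("protanope", "deuteranope", "protanomal", "deuteranomal")]
spectra = sample_spectra(scene, 3000, seed=1, replace=False)
losses = information.information_losses(spectra, deficient, normal,
                                        NoiseModel(weber_l=0.02),
                                        n=3000, seed=1)
print(f"normal trichromat I = {losses[0].reference_bits:.2f} bits")
for d in losses:
    print(f"{d.observer:13s} deltaI = {d.bits:.2f} bits "
          f"({d.percent_surface_reduction:.0f}% fewer surfaces)")
```

prints

```
variance shares  J'=0.79  a'M=0.07  b'M=0.14
major chromatic axis  phi = 90.4 deg
normal trichromat I = 5.56 bits
protanope     deltaI = 1.06 bits (52% fewer surfaces)
deuteranope   deltaI = 0.88 bits (46% fewer surfaces)
protanomal    deltaI = 0.44 bits (26% fewer surfaces)
deuteranomal  deltaI = 0.22 bits (14% fewer surfaces)
```

Read: the scene's color variation is dominated by lightness (79%), its
chromatic variation lies essentially along the yellowness-blueness axis
(φ ≈ 90°), and a normal trichromat can effectively distinguish
2^5.56 ≈ 47 surfaces in it at 2% cone noise. The deficiency losses are a
fraction of a bit to one bit — ordered protanopia > deuteranopia >
protanomaly > deuteranomaly — but translate into substantially larger
percentage reductions in distinguishable surfaces, because N scales
exponentially with I.

The same analysis runs over whole collections with
`conegain.pipeline.run_analysis`, which adds thinned-subset and
union-of-scenes conditions, bootstrap summaries, and the regressions of ΔI
on the logit redness-greenness share and on the major chromatic axis. A
thin CLI wraps the library:

```sh
conegain synth --n-scenes 10 --out scenes/ --seed 1
conegain info --scene scenes/scene_000.h5 --observer deuteranope --weber 0.02
conegain colors --scene scenes/scene_000.h5
conegain run --scenes scenes/ --out results/
conegain confusion-axes
```

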