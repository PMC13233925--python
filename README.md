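# midgetmosaic

Synthesis and simulation of ON-center midget retinal ganglion cell (mRGC)
mosaics of the human retina, as image-computable linear spatio-chromatic
receptive fields.

Midget RGCs are the dominant primate ganglion cell class; their small
center-surround receptive fields carry most of the spatial and red-green
chromatic information that leaves the eye. This package builds complete
mRGC mosaics from first principles — eccentricity-dependent cell densities,
position lattices relaxed to match them, anatomically constrained
cone-to-center wiring, and cone-to-surround wiring optimized by forward
simulation of physiology — and then runs the standard experiments on the
result: spatial transfer functions through (or without) the eye's optics,
white-noise receptive-field mapping, and a template-matching computational
observer for contrast sensitivity. It is intended for computational visual
neuroscientists who want a transparent, fully scripted counterpart to
physiological and psychophysical measurements of the midget pathway.

## The model

Synthesis proceeds in three stages.

1. **Lattices.** Target densities (cells/deg^2) for cones and ON-mRGC RF
   centers are built from four meridian functions (the ON mosaic is half of
   the total midget density) and interpolated in polar form. A hexagonal
   seed warped to the density map is relaxed by density-weighted centroidal
   iteration, giving smoothly graded, hexagonal-like lattices whose counts
   equal the density integral.
2. **Centers.** Every L/M cone joins exactly one RF center (S cones are
   never pooled); a single parameter phi trades spatial compactness against
   spectral purity of the centers; then exclusivity is relaxed with a
   supra-Gaussian weight profile exp[-0.5 (r/sigma_k)^alpha] whose exponent
   falls from 10 (flat-top, non-overlapping) centrally to 2 (Gaussian,
   overlapping) beyond 15 deg.
3. **Surrounds.** Each surround is a double exponential
   W_s(r) = K_w exp(-r/R_w) + K_n exp(-r/R_n) (the H1 horizontal-cell form),
   optimized within H1-like bounds so that the cell's simulated spatial
   transfer function is well fit by a Difference of Gaussians
   DoG(w) = Kc Rc^2 exp(-(pi Rc w)^2) - Ks Rs^2 exp(-(pi Rs w)^2)
   with shape ratios Rs/Rc and (Ks/Kc)(Rs/Rc)^2 held in a narrow band
   around population targets. Optimized pooling functions are derived on a
   sparse grid, interpolated to every cell, and given a seeded per-cell
   variance in the integrated ratio.

Responses are instantaneous and linear on cone contrast,
R(k,t) = [sum_i Pc(i,k) C(i,t) - sum_j Ps(j,k) C(j,t)] / sum_i Pc(i,k),
with C = (E_stim - E_bkgnd)/E_bkgnd per cone. See `docs/methods.md` for the
full account, including the simplified optics (Airy diffraction, reduced-eye
chromatic aberration, eccentricity-dependent elongated blur).

## Worked example

```python
import numpy as np
from midgetmosaic import synthesize_mosaic
from midgetmosaic.frontend.optics import OpticsModel
from midgetmosaic.response import measure_vstf
from midgetmosaic.wiring.surround import fit_dog

# a parafoveal mosaic at 3 deg temporal, synthesized through stage 3
mosaic = synthesize_mosaic((2.9, 3.3, -0.2, 0.2), seed=2, stage="3", n_xy=1)
print(f"{mosaic.n_cells} mRGCs pooling {len(mosaic.cone_mosaic)} cones")

rho = (np.asarray(mosaic.P_surround.sum(axis=0)).ravel()
       / np.asarray(mosaic.P_center.sum(axis=0)).ravel())
print(f"integrated surround/center ratio: mean {rho.mean():.2f}")

optics = OpticsModel("simplified_physiological", eccentricity_deg=(3.1, 0.0))
sf = np.concatenate([[0.0], np.geomspace(0.2, 30.0, 9)])
amp = measure_vstf(mosaic.cone_mosaic, mosaic.P_center, mosaic.P_surround,
                   optics, sf)
dog, rms = fit_dog(sf, amp[10])
print(f"cell 10: Rs/Rc = {dog.radius_ratio:.2f}, "
      f"integrated ratio = {dog.integrated_ratio:.2f}")
```

Output from this script:

```
167 mRGCs pooling 475 cones
integrated surround/center ratio: mean 0.52
cell 10: Rs/Rc = 5.37, integrated ratio = 0.35
```

167 cells over a 0.4 x 0.4 deg patch at 3 deg matches the encoded ON-midget
density there (about 1,000 cells/deg^2), with roughly 2.6 L/M cones per RF
center; the integrated surround/center weight ratio near 0.5 and the fitted
DoG shape (surround five to seven times wider than the center) are the
signature center-surround balance of parvocellular cells measured in vivo.

A command-line interface mirrors the library:

```
midgetmosaic synthesize --region 2.9 3.3 -0.2 0.2 --seed 2 --stage 2C --out mosaic.npz
midgetmosaic vstf mosaic.npz --out vstf.csv
midgetmosaic csf mosaic.npz --direction L_minus_M --out csf.csv
```

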