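{
  "version": 1,
  "comment": "Eccentricity-dependent density models for the human retina. The midget-RGC receptive-field block encodes the Watson (2014) formula: density(r) = peak * (1 + r/rm)^-1 * [a*(1 + r/r2)^-2 + (1-a)*exp(-r/re)], with r in visual degrees and density in cells/deg^2; the ON-center mosaic is taken as half of the total midget density. The cone block uses the same parametric basis expressed against linear eccentricity in retinal mm, with coefficients chosen to approximate the Curcio et al. (1990) human cone density profiles; the foveal peak of 288,000 cones/mm^2 is near the high end of the reported human range. Meridian names refer to the visual field of a right eye (x > 0 temporal).",
  "on_mrgc_fraction": 0.5,
  "mrgc_rf": {
    "form": "watson_midget_deg",
    "peak_density_deg2": 29609.2,
    "rm_deg": 41.03,
    "meridians": {
      "temporal": {"a": 0.9851, "r2": 1.058, "re": 22.14},
      "superior": {"a": 0.9935, "r2": 1.035, "re": 16.35},
      "nasal":    {"a": 0.9729, "r2": 1.084, "re": 7.633},
      "inferior": {"a": 0.9960, "r2": 0.9932, "re": 12.13}
    }
  },
  "cone": {
    "form": "basis_mm",
    "peak_density_mm2": 288000.0,
    "meridians": {
      "temporal": {"a": 0.980, "r2": 0.45, "re": 25.0},
      "superior": {"a": 0.980, "r2": 0.45, "re": 21.0},
      "nasal":    {"a": 0.980, "r2": 0.45, "re": 18.0},
      "inferior": {"a": 0.980, "r2": 0.45, "re": 20.0}
    }
  },
  "deg_to_mm_human": {
    "comment": "Cubic polynomial in degrees (Drasdo & Fowler schematic eye as parameterized by Watson 2014): mm = c1*r + c2*r^2 + c3*r^3",
    "c1": 0.268,
    "c2": 3.427e-4,
    "c3": -8.3309e-6
  },
  "macaque_mm_per_deg": 0.221
}
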