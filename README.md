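# translocq

Quantification of fluorescent lipid-biosensor translocation experiments:
multi-scale wavelet membrane masks, ratiometric confocal and TIRF traces,
replicate-aware ("SuperPlot") statistics, and liposome binding-curve
fitting — all validated against a synthetic-microscopy generator with
analytic ground truth.

## The problem

A lipid biosensor is a fluorescently tagged lipid-binding domain that
relocates from the cytosol to a membrane when its target lipid (here,
phosphatidic acid) appears there. Live-cell experiments report this
relocation as time series:

* **Confocal**: the mean biosensor intensity inside a membrane mask built
  from a marker channel, divided by the mean in a cytosolic (or
  whole-cell) ROI, background-subtracted — the **PM/Cyto ratio**

  r(t) = (I_mask(t) − b(t)) / (I_cyto(t) − b(t))

* **TIRF**: footprint fluorescence at each time normalized to the mean
  over the pre-stimulus frames — **F_t / F_pre**.

Per-cell responses are summarized as the trapezoidal **AUC** of the
baseline-subtracted trace (ratio·min), and inference runs on the *mean AUC
of each experimental replicate*, not on pooled cells, because cells within
one dish/day are not independent.

The membrane mask is an à-trous-style **wavelet product**: the marker
image is Gaussian-blurred at 1×, 2×, 3×, 4× the Airy disk radius
(1.22λ/2NA; 1–2× for ER, 1–3× for Rab5 endosomes), adjacent scales are
subtracted to form band images, the bands are multiplied, the product is
thresholded at 0.5× the SD of the original image, and the mask is dilated
by 1–2 px.

The in vitro arm quantifies liposome cosedimentation
(% bound = 100·P/(P+S), baseline-subtracted) and fits the one-site
binding hyperbola with background

  Y(X) = BG + (Bmax − BG)·X / (K_d + X)

with BG fixed at the minimum observed Y, Bmax ≤ 100%, and a 95%
profile-likelihood confidence interval on K_d. Coflotation fractions
(with the 6× middle-band dilution correction) and CD molar-ellipticity
conversion (m°·10⁶ / (path(mm)·conc(µM)·n_bonds)) round out the assays.

Because published imaging datasets of this kind are not numerically
available at desk scale, the package ships a first-class synthetic-scene
generator: disc cells with nucleus, cytosol and membrane ring (or
organelle blobs), a conserved probe pool with first-order on/off
translocation kinetics φ(t), and scaled-Poisson + Gaussian camera noise —
so every quantifier can be checked against a closed-form oracle.

## Worked example

```python
import translocq as tq

# simulate one cell (phi0 = 0.1, delta_phi = 0.4, tau_on = 60 s, stimulus at 2 min)
scene = tq.SceneSpec(seed=1)
stack, truth = tq.render_confocal_timelapse(scene)

# segment the marker channel and quantify the biosensor channel
optics = tq.OpticalConfig(wavelength=640, numerical_aperture=1.45,
                          pixel_size=scene.pixel_size)
masks, _ = tq.per_frame_masks(stack, optics, tq.MaskRecipe.for_preset("pm"))
rois = tq.RoiSet(cell=truth.cell_mask, cytosol=truth.cytosol_mask,
                 background=truth.background_mask)
trace = tq.ratio_trace(stack, masks, rois)
print(f"basal PM/Cyto = {trace.values[:8].mean():.3f}, peak = {trace.values.max():.3f}")
print(f"AUC = {tq.auc(trace):.2f} ratio*min")

# constrained one-site binding fit on synthetic cosedimentation data
d = tq.synth_binding_data(422, 95, 9.504, [0, 25, 100, 400, 1600, 6400],
                          noise_sd=3, seed=2)
fit = tq.fit_binding(d.x_uM, d.y_pct, bg_mode="fixed-min")
print(f"Kd = {fit.kd:.0f} uM (95% CI {fit.ci_low:.0f}-{fit.ci_high:.0f}), "
      f"R2 = {fit.r_squared:.3f}")
```

prints

```
basal PM/Cyto = 1.562, peak = 6.081
AUC = 37.87 ratio*min
Kd = 545 uM (95% CI 370-741), R2 = 0.992
```

The basal ratio exceeds 1 because 10% of the probe starts membrane-bound;
the peak reflects the 0.4 amplitude of the simulated response. The binding
fit recovers the generating K_d (422 µM) within its asymmetric profile
CI — note the upper arm is longer than the lower, as expected for a
hyperbolic design.

A full pipeline run (two groups × three replicates, simulate → segment →
quantify → AUC → replicate-mean ANOVA) is driven by a YAML config:

```bash
translocq run --config examples/demo_config.yaml --outdir results/demo
```

Other subcommands: `simulate`, `segment`, `quantify`, `stats`,
`fit-binding` (see `translocq --help`).

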