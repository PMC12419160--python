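# Methods

## Rendering model and its assumptions

A synthetic cell is a disc of radius `cell_radius` containing a nuclear
disc and, depending on `organelle`, either a plasma-membrane ring of width
`pm_thickness` or a set of non-overlapping organelle blobs placed in the
cytosol. A conserved biosensor pool of total signal `total_probe`
partitions between the target compartment (fraction φ(t)) and the
cytosolic space. The cytosolic concentration is

    c(t) = total_probe · (1 − φ(t)) / A_eff,
    A_eff = A_cytosol + ν·A_nucleus + A_compartment,

where ν (`nuclear_ratio`, default 1) scales nuclear relative to cytosolic
intensity. Compartment pixels additionally carry the membrane pool spread
uniformly over the compartment area:

    p(t) = c(t) + total_probe · φ(t) / A_compartment.

Including nucleus and compartment pixels in A_eff reflects that, in a
confocal section, a membrane or nuclear pixel still contains cytosol above
and below it; it is also what makes total signal exactly conserved across
frames, which the tests assert to 0.1%. The implied analytic ratio oracle
is r(t) = p/c = 1 + φ/(1−φ) · A_eff/A_compartment, strictly increasing in
φ and divergent at φ = 1 (empty cytosol — raised as a degenerate-ratio
error).

φ(t) follows the simplest kinetics consistent with observed translocation
curves: constant `phi0` before the stimulus, single-exponential rise of
amplitude `delta_phi` with time constant `tau_on` after it, and an
optional single-exponential reversal toward `phi0` (time constant
`tau_off` from `t_rev`), continuous at both breakpoints. This is
phenomenological ground truth, not a mechanistic binding model.

Camera noise is the standard sCMOS approximation: `Poisson(poisson_scale ·
I)/poisson_scale` plus additive `N(0, read_sigma)`. An optional Gaussian
`blur_sigma_px` emulates partial-volume blur of the noiseless frames.

### Default scene parameters

| parameter | default | rationale |
|---|---|---|
| image | 128×128 px at 160 nm/px | ~20 µm field holding one cell |
| cell / nucleus radius | 50 / 15 px | ~16 µm cell, ~5 µm nucleus |
| pm ring width | 3 px | diffraction-scale membrane thickness |
| frames / interval | 48 × 15 s | 12 min movie, within typical 15–30 s sampling |
| kinetics | φ₀ 0.1, Δφ 0.4, τ_on 60 s, stimulus 120 s | 2 min baseline, minute-scale agonist response |
| total_probe | 1.2·10⁶ a.u. | peak membrane pixel ≈ 10³ photons at poisson_scale 1 |
| background offset | 50 a.u. | non-zero camera offset so subtraction is exercised |
| noise | poisson_scale 1, read σ 2 | shot-noise-limited with a few counts of read noise |

Acquisition bit depth and detector gain are not modeled beyond the 16-bit
quantization applied when stacks are written to TIFF (with a recorded
scale factor, so integer-grid data round-trip exactly).

### What the generator does not emulate

No photobleaching, cell motion beyond optional uniform drift, 3-D
structure, organelle dynamics, autofluorescence gradients, or
cell-to-cell geometric variability. Passing tests therefore demonstrate
the *quantification machinery* is correct and calibrated on data obeying
the stated model; they do not certify robustness to the full messiness of
real microscopy (motion, bleaching, segmentation of irregular cells).

## Segmentation

"Airy disk size" is taken as the Rayleigh radius 1.22λ/(2NA) converted to
pixels; the Gaussian at scale multiplier m uses σ = m × that radius
(σ versus FWHM being a free convention, σ is chosen and exposed).
Wavelet bands are differences of adjacent scales; negative band values
are clipped to zero before multiplication by default, preventing two
negative bands from multiplying into a spurious positive (exposed as
`clip_negative_wavelets` for ablation). The threshold applies to the band
*product* and uses the SD of the original unfiltered image, computed over
the whole frame by default (`sd_within_roi` restricts it to a ROI).
Dilation is 8-connected, default 1 cycle (1–2 conventional). A perfectly
flat image has SD 0 and an all-zero product, yielding an empty mask rather
than an error.

Exact gain invariance of the mask holds for two-scale recipes (product and
threshold both scale linearly). For the four-scale recipe the product
scales as k³ against the threshold's k, so invariance is only empirical:
on the ring fixture masks are bit-identical over a 4× gain range and agree
to Jaccard ≥ 0.98 (with unchanged ring recall) over three decades.

## Quantification

Background is the per-frame mean of the background ROI, subtracted from
numerator and denominator before division; the membrane mask is
intersected with the cell ROI so marker signal from neighboring cells
cannot leak in. Ratio denominators use the arithmetic mean (median is a
plausible alternative the source procedure leaves unstated). Frames with
an empty mask or non-positive denominator are flagged and filled by linear
interpolation so the time grid stays uniform; flags travel with the trace.
F_pre defaults to all frames before the stimulus. AUC uses the trapezoidal
rule on the Δ-trace (value minus baseline-window mean) with time in
minutes — computing AUC on Δ rather than raw ratios makes a non-responding
cell integrate to zero. Kinetic recovery inverts the ratio to φ via the
known area ratio (available for synthetic scenes) and fits the
single-exponential model with the stimulus time held fixed.

## Statistics

The unit of inference is the replicate mean; SEM is the SD of replicate
means over √n_reps. Many-to-one comparisons use the one-way ANOVA's pooled
within-group variance and df with Šídák adjustment over the
n_groups − 1 comparisons — a deliberate, slightly conservative stand-in
for Dunnett's exact many-to-one distribution (raw p-values are also
reported so users can apply any correction). Two-way ANOVA is restricted
to balanced designs, where the sums-of-squares decomposition is
orthogonal; unbalanced tables raise. The Wilcoxon signed-rank test uses
the exact null for n ≤ 25 without ties. Null calibration of the
replicate-mean ANOVA is checked by vectorized Monte-Carlo simulation
(10,000 two-level null datasets; rejection 5.0% ± 0.7%).

## Binding fit

K_d is fitted on a log scale (trf bounded least squares) with Bmax
constrained to (BG, 100] and a boundary hit flagged; BG is fixed at
min(y) by default, at a supplied value, or free. The 95% CI on K_d is a
profile likelihood: K_d values whose profiled SSR stays below
SSR_min·(1 + F₀.₉₅(1, dof)/dof) are retained, with bounds located by
log-scale bisection. Profile rather than Wald because near-saturating
hyperbolic designs give strongly asymmetric K_d uncertainty that a
symmetric interval cannot express. A perfect (SSR = 0) fit collapses the
interval onto the estimate. Monte-Carlo calibration (500 five-point
datasets, 5% noise, BG fixed at min(y)) puts coverage at ~92–94%, the mild
undercoverage coming from fixing BG at a noisy order statistic.

## Problem sizes

The test suite and acceptance script run on 128×128 scenes (48 frames),
50-cell recovery sweeps, 500-dataset CI calibrations and 10,000-simulation
null sweeps — sizes chosen so the whole validation executes in a few
minutes on one CPU while leaving Monte-Carlo margins (binomial SE ≈ 0.2%
at 10,000 sims) well inside the asserted bands.

## Known limitations

- The wavelet mask is validated on synthetic rings/blobs with uniform
  marker; heavily textured or dim markers may need threshold retuning.
- Kinetic inversion to φ requires the compartment/cytosol area ratio,
  which real experiments only know approximately.
- The profile CI assumes Gaussian residuals; percent-bound clipping at
  0/100 mildly violates this at extreme noise.
- No mixed-effects models: replicate means weight replicates equally
  regardless of cell count.
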