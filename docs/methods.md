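# Methods

This note records the models, defaults and numerical choices behind
`tgtquant`, and what the synthetic-data tests do and do not demonstrate.

## Sensor model

Each tension gauge tether is a 21-bp duplex of the ligand strand
(`CAC AGC ACG GAG GCA CGA CAC`, NP hapten on the 3′ amine) and the anchor
strand (`GTG TCG TGC CTC CGT GCT GTG`, biotin at one of eight positions).
The biotin position sets the mean rupture force through a fixed one-to-one
map (positions 1, 2, 4, 7, 11, 15, 18, 21 → 12, 16, 23, 33, 43, 50, 54,
56 pN). No mechanics are derived from sequence; the map is taken as
measured input.

Rupture thresholds are modeled as Gaussian with the sensor's mean and a
full width at half maximum of 5 pN (unzipping mode) or 15 pN (shearing
mode), truncated at 0 pN (`σ = FWHM / 2√(2 ln 2)`). A Gaussian is the
minimal two-parameter family consistent with a (mean, FWHM) description;
whether the true distribution is symmetric is unknown, and the family is a
recorded assumption. Which intermediate biotin positions behave as
unzipping versus shearing is likewise not specified by the assay design;
the default assigns positions 1–2 to unzipping and 4–21 to shearing, and a
per-sensor override exists. Forces are treated as static thresholds
(constant-force, fixed time-under-load regime); loading-rate dependence is
out of scope.

`survival_probability(sensor, F)` is the upper tail of the truncated
Gaussian. Note a consequence of the two-width model: monotonicity of
survival in the sensor's mean force holds *within* a rupture mode, but a
wide shearing sensor (e.g. 23 pN, FWHM 15) carries more sub-10-pN mass
than a narrow unzipping one (16 pN, FWHM 5), so cross-mode comparisons at
low applied force can invert. The tests assert monotonicity per mode.

### FWHM estimation

The empirical FWHM of sampled forces is estimated from a 0.05-pN-bin
histogram: boxcar smoothing at 0.3× a first-pass width estimate, linear
interpolation of the half-maximum crossings, and quadrature removal of the
boxcar's broadening (variance `w²/12`). At 10⁵ draws the estimator's SD is
≈ 0.03 pN for the 5-pN mode and ≈ 0.09 pN for the 15-pN mode, with
negligible bias.

## Synthetic TIRFM data

The generator emulates three kinds of data, all seeded and reproducible
bit-for-bit.

**Optics/camera defaults.** 512×512 frames (tests use smaller frames for
speed; the per-pixel model is scale-free), pixel size 0.16 µm — chosen so
the 136×136-pixel counting ROI covers ≈ 473.6 µm², matching the assay's
≈ 473.1 µm² counting area — PSF σ 0.15 µm (diffraction-limited 1.49 NA
objective), 800 expected counts per molecule, camera offset 100, Gaussian
read noise SD 2, unit gain. Spots are rendered by integrating the Gaussian
PSF over each pixel (error-function differences), so photons are conserved;
shot noise is Poisson on the signal, before offset and read noise.

**Single-molecule fields.** Molecule positions follow a homogeneous
spatial Poisson process at the requested density. The
incubation-concentration → surface-density curve is a monotone PCHIP
interpolation through the measured anchors (2, 5, 10, 50 nM → 0.3, 4.0,
19.0, 29.0 molecules/µm²), zero at zero, saturating above 50 nM.

**Calibration series.** The antibody-stain reporter channel uses a
per-molecule brightness of `473.1 / (2.42 · 0.16²) ≈ 7637` counts, so that
a stained surface's background-subtracted mean intensity converts to
molecules per counting area with the assay's published slope of 2.42 —
i.e. the generated series embodies the measured calibration relation and
the regression's job is to recover it. Fields are rendered with an
8-pixel guard band around the counting ROI (as on a real, much larger
frame) and a matched blank frame supplies the background estimate.

**Synapse frames and time-lapses.** Per-cell accumulation follows
saturating growth `A(t) = A_plateau (1 − e^{−t/τ})` with τ = 120 s. The
plateau is drawn from the response level implied by (isotype, sensor
force): for force-gated isotypes (IgM, and the GGM tail swap) forces 12–16,
23–43 and 50–56 pN map to low/medium/high levels with means 1 : 2 : 3.5
(arbitrary units, CV 25 %, truncated at 0); for force-independent isotypes
(IgG, IgE, MMG) every force maps to high. The no-hapten control (NC) draws
a baseline plateau of 0.15. Contact area, microcluster count and diffuse
membrane signal all scale linearly with A(t) (18 µm², 8 clusters and 12
counts/pixel per accumulation unit; clusters are Gamma-distributed around
4000 integrated counts with σ 0.25 µm). These absolute levels are
configuration, not claims — the real assay's units are arbitrary. The
link between tether survival probability and accumulation level is not
modeled quantitatively; the step response *is* the model, and
`survival_probability` is available separately.

**What the generator does not emulate:** receptor diffusion and
nanocluster biophysics, photobleaching, stage drift, cell-to-cell optical
variation, uneven illumination. Parameter-recovery results on this data
therefore validate the estimators' correctness under the stated noise
model, not their robustness to every real-microscope artifact.

## Spot and cluster quantification

Detection: difference-of-Gaussians band-pass (σ 0.7 / 6 px), candidate
threshold 4× the robust (MAD-based) noise SD of the band-passed image,
non-maximum suppression at 2 px keeping the brighter of merged maxima.
Detection is offset-invariant by construction. Fitting: symmetric
2D Gaussian + constant background (5 parameters) by bounded
Levenberg–Marquardt with analytic Jacobian in a 9×9 window; fits whose
window leaves the frame are flagged and excluded. On noiseless
single-Gaussian input the fit is exact to solver tolerance. Quality
filters for counting: convergence, σ within [0.5, 3]× the PSF σ,
amplitude > 3× noise SD. An elliptical fit is intentionally not the
default — the spots are round by design — and overlapping-emitter
deconvolution is out of scope.

**Counting efficiency.** Even well below optical saturation some molecule
pairs fall within the detector's resolvability distance and register as
one candidate. The fraction of molecules surviving detection and filtering
is described by `r(λ) = exp(c₀ + c₁λ + c₂λ²)` (λ in molecules/pixel²),
whose constants were calibrated once against generator ground truth for
the default settings at diffraction-limited optics; `count_spots` inverts
it by fixed point to report density. With the correction, mean |error| is
≈ 3 % over 0.3–1 molecules/µm² (validated on seeds disjoint from the
calibration); without it, losses reach ~10 % at 0.3 and ~35 % at
1 molecule/µm². The curve is valid to ≈ 1 molecule/µm²; denser surfaces
must use the MFI calibration pathway, which is exactly the assay's own
division of labor (counting at sparse coating, antibody MFI at dense
coating).

## MFI → density calibration

Through-origin least squares, `slope = Σxy/Σx²`, because zero molecules
produce zero background-subtracted signal — the model has no intercept by
construction. R² is computed against the through-origin model with the
total sum of squares about zero (conventions differ for no-intercept
models; this one is documented and used consistently). Background for MFI
is, in order of preference: an explicit value, the median of a
user-designated empty region, or the image-wide 10th percentile.
`mfi_to_density` divides the per-counting-area prediction by the 473.1 µm²
counting area to give molecules/µm².

## Synapse segmentation and traces

Synapse frames contain three intensity classes — camera background,
diffuse membrane footprint, bright microclusters — so single bimodal
thresholds (Otsu, Li, multi-Otsu were all evaluated) latch onto the
cluster class and recover as little as a tenth of the true footprint.
The implemented segmentation is two-stage: a rough mask at
median + 3×robust SD of the σ=1-px-smoothed frame, morphologically closed
(9×9) and hole-filled into a solid footprint; then a final threshold at
the midpoint of the median intensities inside and outside that footprint,
which places the boundary halfway up the edge profile and keeps the area
estimate unbiased (0.3 % error on a clean disk at SNR 10; 5–15 % on
cluster-dominated low-signal frames). A fixed-threshold override is
available. Frames with a rough foreground below 50 px are declared empty
(no cell) rather than segmented noise.

Per-frame metrics: background = median of a frame-border annulus (width
5 % of the frame) outside the mask; MFI = mean in-mask intensity minus
background, clamped at 0; total FI = MFI × masked pixel count; area =
pixel count × pixel size². Segmentation is per-frame independent — cells
are stationary in this assay geometry, so no tracking is needed. Total FI
is additive over disjoint mask partitions up to the (shared) background
estimate.

## Statistics

Pairwise comparisons default to Welch's unequal-variance two-tailed t-test
(Welch–Satterthwaite degrees of freedom); it reduces to Student's test
when variances match, and a pooled-variance option exists. Raw p-values
are primary; Holm-adjusted values are reported alongside in
cross-comparison matrices for transparency.

**Threshold grouping.** Walking the panel in ascending force order, each
sensor is tested against the pooled sample of the current group and starts
a new group on a significant difference. With k sensors the sweep performs
k−1 boundary tests, so each runs at α/(k−1) (Bonferroni): the procedure's
`alpha` (default 0.05) bounds the *family-wise* probability of declaring
any spurious split on a flat panel. This choice is what makes the
procedure's operating characteristics coherent: on the three-level
generator at n = 40 cells/sensor it recovers exactly three groups with
boundaries 16|23 and 43|50 pN in ≈ 95 % of runs, and on a flat panel
P(more than one group) ≈ α. Running the same sweep with uncorrected
per-boundary α = 0.05 would spuriously split a flat 8-sensor panel ≈ 23 %
of the time (1 − 0.95⁵) and find the correct three-group structure in only
≈ 77 % of runs. The sweep-and-merge rule itself is one formalization of
"statistically distinct contiguous levels"; it is not claimed to be the
only one.

## Problem sizes and tolerances

Unit and property tests run on reduced frames (48–152 px) and moderate
replicate counts (6–200 fields or noise realisations, 400–1000 null
replicates for error-rate checks), chosen to keep the full suite under a
minute while leaving Monte-Carlo margins of ≥ 3 standard errors.
Rupture-distribution checks use 10⁵ draws. Degenerate inputs follow the
contracts: empty images and zero-area ROIs are errors; blank frames
segment to empty masks (not errors); non-converged or border-clipped fits
are flagged and excluded rather than raised.

## Known limitations

- The counting-efficiency constants are specific to the default detection
  parameters and optics; changing either requires re-calibration against
  the generator.
- Cluster quantification reports merged close pairs as single clusters by
  design (no multi-emitter deconvolution).
- The response-level means/CVs are plausible placeholders for an assay
  whose published units are arbitrary; grouping *accuracy* claims are
  therefore conditional on those effect sizes, though the family-wise
  error control is not.
- Segmentation assumes one dominant cell per frame (largest connected
  component) and no drift.
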