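# tgtquant

Quantitative analysis and simulation toolkit for DNA **tension-gauge-tether
(TGT)** B-cell mechanosensing assays imaged by TIRF microscopy.

## The problem

A TGT is a short DNA duplex that anchors an antigen to a coverslip and
ruptures when the cell pulls harder than a tunable threshold. Moving a
biotin anchor along one 21-nt strand switches the rupture geometry from
*unzipping* (base pairs peeled in series, low threshold) to *shearing* (all
base pairs loaded in parallel, high threshold), giving a panel of eight
sensors with mean rupture forces of 12, 16, 23, 33, 43, 50, 54 and 56 pN.
Plating B cells on surfaces coated with NP-hapten-conjugated TGTs and
measuring how much B-cell receptor (BCR) accumulates into the immunological
synapse at each force probes whether receptor triggering is
mechanical-force gated. IgM-class receptors show a **multi-threshold**
response — weak at 12–16 pN, intermediate at 23–43 pN, strong at 50–56 pN —
while IgG/IgE-class receptors respond fully at every force in the panel.

`tgtquant` implements the full quantitative machinery of such an assay as a
tested, reusable pipeline:

- **`tgtquant.sensors`** — the sensor panel (strand sequences,
  biotin-position → force map), rupture-force distributions
  (Gaussian with FWHM 5 pN for unzipping, 15 pN for shearing, truncated at
  0), tether survival probabilities.
- **`tgtquant.simulate`** — ground-truthed synthetic TIRFM data: sparse
  single-molecule fields (spatial Poisson positions, pixel-integrated
  Gaussian PSFs, shot + read noise), the incubation-concentration →
  surface-density coating curve, and synapse end-point frames and
  time-lapses driven by the isotype-specific force response.
- **`tgtquant.spots`** — detection and 2D-Gaussian fitting of
  single molecules and microclusters
  (`I = b + A·exp(−((x−x0)² + (y−y0)²)/2σ²)`; integrated intensity
  `2πAσ²` is the cluster volume proxy), plus density counting with a
  calibrated resolvability correction.
- **`tgtquant.calibration`** — the dense-surface pathway: through-origin
  regression `molecules per counting area = k · MFI` (closed form
  `k = Σxy/Σx²`), with the counting area fixed at 473.1 µm².
- **`tgtquant.synapse`** — contact-footprint segmentation and per-frame
  MFI / total-FI / area traces.
- **`tgtquant.stats`** — Welch two-tailed comparisons, pairwise
  cross-comparison matrices (with Holm-adjusted p alongside raw p), and the
  agglomerative force-threshold grouping that classifies the 8-sensor panel
  into statistically distinct response levels.

## Worked example

```python
import numpy as np
from tgtquant import calibration, sensors, simulate, stats

# The sensor panel
panel = sensors.build_sensor_panel()
print(panel[0].id, panel[0].rupture_mode, panel[0].fwhm)
# TGT-12pN unzipping 5.0

# MFI -> density calibration on a simulated stained-surface series
cal = calibration.fit_calibration(
    calibration.synthetic_calibration_series([0.3, 4.0, 19.0, 29.0], seed=0))
print(f"slope = {cal.slope:.3f} per {cal.counting_area:g} µm², R² = {cal.r_squared:.4f}")
# slope = 2.417 per 473.1 µm², R² = 0.9999

mfi = calibration.measure_field_mfi(4.0, seed=1)
print(f"MFI {mfi:.1f} -> {calibration.mfi_to_density(mfi, cal):.2f} molecules/µm²")
# MFI 776.3 -> 3.97 molecules/µm²

# Force-threshold grouping of a simulated IgM condition panel (40 cells/sensor)
manifest, _ = simulate.simulate_condition_panel(
    simulate.default_response("IgM"), panel, 40, seed=2, render=False)
samples = {float(f): g["true_accumulation"].to_numpy()
           for f, g in manifest.groupby("force_pN")}
grouping = stats.group_force_levels(samples)
print(grouping.n_groups, grouping.boundaries)
# 3 ((16.0, 23.0), (43.0, 50.0))
```

The grouping output reads: the eight forces fall into three statistically
distinct activation levels, split between 16 and 23 pN and between 43 and
50 pN — the multi-threshold signature. Running the same code with
`default_response("IgG")` returns a single group (force-independent
activation).

A thin CLI mirrors the library:

```bash
tgtquant panel build --control --out panel.json
tgtquant simulate field --density 0.4 --seed 5 --out field.tif
tgtquant quantify spots --in field.tif --roi 8,8,136,136 --out spots.json
tgtquant stats thresholds --in panel.csv --value true_accumulation --out groups.json
```

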