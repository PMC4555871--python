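"""Ground-truthed synthetic TIRFM data.

Three generators, all seeded and bit-reproducible:

* sparse single-molecule fields at a controlled surface density (spatial
  Poisson positions, diffraction-limited Gaussian spots, shot noise +
  read noise + camera offset) — for counting and calibration;
* B-cell synapse end-point frames and time-lapses whose microcluster
  content and contact area follow the isotype-specific force response: a
  three-level step over the 12–56 pN sensor panel for IgM-class receptors,
  a flat (force-independent) response for IgG/IgE-class receptors;
* mean-fluorescence-intensity calibration series linking images of stained
  surfaces to known molecular densities.

Every generator returns the rendered pixels together with the ground truth
(molecule positions, photon budgets, per-frame true contact area and
accumulation), so downstream estimators can be validated by parameter
recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.special import erf

from .sensors import TGTSensor

__all__ = [
    "OpticsModel",
    "ImageFrame",
    "ImageStack",
    "GroundTruth",
    "ResponseModel",
    "default_response",
    "reporter_optics",
    "simulate_molecule_field",
    "coating_density",
    "simulate_cell_timelapse",
    "simulate_condition_panel",
    "COUNTING_AREA_UM2",
    "COUNTING_ROI_PIXELS",
    "MFI_TO_DENSITY_SLOPE",
]

#: Side of the square single-molecule counting ROI, pixels.
COUNTING_ROI_PIXELS = 136

#: Nominal counting-ROI area, µm² (136 px × 0.16 µm/px squared ≈ 473.6;
#: the conventional constant used throughout density bookkeeping).
COUNTING_AREA_UM2 = 473.1

#: Molecules per counting area per MFI unit for the emulated FITC-antibody
#: stain; the brightness of the reporter optics is set so that surfaces
#: imaged with them obey this conversion.
MFI_TO_DENSITY_SLOPE = 2.42


@dataclass(frozen=True)
class OpticsModel:
    """Camera + objective model for rendering and for pixel/µm bookkeeping.

    pixel_size        µm per pixel in the sample plane (100x objective + EMCCD)
    psf_sigma         Gaussian PSF standard deviation, µm (diffraction limited)
    frame_shape       (rows, cols) of a frame
    photons_per_molecule  expected integrated counts of one fluorophore-labelled
                      molecule per exposure
    background_offset camera baseline added to every pixel, counts
    read_noise_sd     Gaussian read-noise SD per pixel, counts
    """

    pixel_size: float = 0.16
    psf_sigma: float = 0.15
    frame_shape: tuple[int, int] = (512, 512)
    photons_per_molecule: float = 800.0
    background_offset: float = 100.0
    read_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if min(self.pixel_size, self.psf_sigma, self.photons_per_molecule) <= 0:
            raise ValueError("optics parameters must be positive")
        if min(self.frame_shape) <= 0 or self.background_offset < 0 or self.read_noise_sd < 0:
            raise ValueError("invalid optics parameters")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma / self.pixel_size

    @property
    def field_area_um2(self) -> float:
        h, w = self.frame_shape
        return h * w * self.pixel_size**2


def reporter_optics(**overrides) -> OpticsModel:
    """Optics of the antibody-stain density reporter channel.

    The per-molecule brightness is chosen so that the background-subtracted
    mean intensity of a stained surface converts to molecules per counting
    area with slope :data:`MFI_TO_DENSITY_SLOPE` — i.e. the generated
    calibration series embodies the assay's published conversion.
    """
    base = OpticsModel()
    photons = COUNTING_AREA_UM2 / (MFI_TO_DENSITY_SLOPE * base.pixel_size**2)
    params = dict(photons_per_molecule=photons)
    params.update(overrides)
    return replace(base, **params)


@dataclass
class ImageFrame:
    """A single 2D frame with its pixel size (µm/pixel)."""

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("frame must be 2D")


@dataclass
class ImageStack:
    """A (T, Y, X) time-lapse with pixel size (µm) and frame interval (s)."""

    data: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack must be 3D (T, Y, X)")

    def __len__(self) -> int:
        return self.data.shape[0]

    def frame(self, i: int) -> ImageFrame:
        return ImageFrame(self.data[i], self.pixel_size)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.frame_interval


@dataclass
class GroundTruth:
    """What the generator actually put into the pixels."""

    molecule_positions: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    photons: np.ndarray = field(default_factory=lambda: np.empty(0))
    contact_area: np.ndarray | float | None = None  # µm², per frame for stacks
    accumulation: np.ndarray | float | None = None  # arbitrary units
    clusters: list | None = None  # per-frame list of (positions µm, photons)


# ---------------------------------------------------------------------------
# rendering

_SQRT2 = math.sqrt(2.0)


def _render_spots(
    shape: tuple[int, int],
    x_px: np.ndarray,
    y_px: np.ndarray,
    photons: np.ndarray,
    sigma_px: float,
) -> np.ndarray:
    """Add pixel-integrated Gaussian spots to a blank frame.

    Each spot's photons are spread with the error-function integral of the
    PSF over each pixel, so total counts are conserved for interior spots.
    """
    img = np.zeros(shape, dtype=float)
    h, w = shape
    half = int(math.ceil(5.0 * sigma_px))
    denom = _SQRT2 * sigma_px
    for x, y, p in zip(x_px, y_px, photons):
        ix, iy = int(round(x)), int(round(y))
        x0, x1 = max(0, ix - half), min(w, ix + half + 1)
        y0, y1 = max(0, iy - half), min(h, iy + half + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)
        fx = 0.5 * (erf((xs + 0.5 - x) / denom) - erf((xs - 0.5 - x) / denom))
        fy = 0.5 * (erf((ys + 0.5 - y) / denom) - erf((ys - 0.5 - y) / denom))
        img[y0:y1, x0:x1] += p * np.outer(fy, fx)
    return img


def _apply_camera(signal: np.ndarray, optics: OpticsModel, rng: np.random.Generator) -> np.ndarray:
    noisy = rng.poisson(np.clip(signal, 0, None)).astype(float)
    noisy += optics.background_offset
    if optics.read_noise_sd > 0:
        noisy += rng.normal(0.0, optics.read_noise_sd, size=signal.shape)
    return np.clip(noisy, 0.0, None)


def simulate_molecule_field(
    density: float,
    optics: OpticsModel | None = None,
    seed: int | np.random.Generator = 0,
    add_noise: bool = True,
) -> tuple[ImageFrame, GroundTruth]:
    """A sparse single-molecule field at the given surface density.

    Molecule positions follow a homogeneous spatial Poisson process at
    ``density`` molecules/µm² over the frame; each molecule is rendered as a
    diffraction-limited Gaussian spot of ``photons_per_molecule`` expected
    counts.  Camera model: Poisson shot noise on the signal, plus a constant
    offset and Gaussian read noise (EMCCD surrogate with unit gain).
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    optics = optics or OpticsModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = optics.frame_shape
    n = rng.poisson(density * optics.field_area_um2)
    # positions in µm; x along columns, y along rows
    xy = rng.uniform([0, 0], [w * optics.pixel_size, h * optics.pixel_size], size=(n, 2))
    photons = np.full(n, optics.photons_per_molecule)
    signal = _render_spots(
        (h, w),
        xy[:, 0] / optics.pixel_size,
        xy[:, 1] / optics.pixel_size,
        photons,
        optics.psf_sigma_px,
    )
    if add_noise:
        data = _apply_camera(signal, optics, rng)
    else:
        data = signal + optics.background_offset
    return ImageFrame(data, optics.pixel_size), GroundTruth(molecule_positions=xy, photons=photons)


# ---------------------------------------------------------------------------
# coating density vs incubation concentration

_CONC_NM = np.array([0.0, 2.0, 5.0, 10.0, 50.0])
_DENSITY = np.array([0.0, 0.3, 4.0, 19.0, 29.0])
_coating_interp = PchipInterpolator(_CONC_NM, _DENSITY)


def coating_density(concentration: float | np.ndarray) -> float | np.ndarray:
    """Surface density (molecules/µm²) after incubating at ``concentration`` nM.

    Monotone (PCHIP) interpolation through the measured anchor points
    (2, 5, 10, 50 nM -> 0.3, 4.0, 19.0, 29.0 molecules/µm²), zero at zero and
    saturating at the 50 nM value above the calibrated range.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = np.where(c >= _CONC_NM[-1], _DENSITY[-1], _coating_interp(np.clip(c, 0, _CONC_NM[-1])))
    return float(out) if np.isscalar(concentration) or np.ndim(concentration) == 0 else out


# ---------------------------------------------------------------------------
# isotype force response

_LEVELS = ("low", "medium", "high")

#: Force bands for receptors whose activation is mechanical-force gated
#: (IgM-class, including the GGM tail swap): weak below ~23 pN, intermediate
#: at 23–43 pN, strong at 50 pN and above.
_BANDED = {12.0: "low", 16.0: "low", 23.0: "medium", 33.0: "medium", 43.0: "medium",
           50.0: "high", 54.0: "high", 56.0: "high"}
#: Force-independent receptors (IgG/IgE-class, including the MMG tail swap)
#: respond fully at every panel force.
_FLAT = {f: "high" for f in _BANDED}

_BANDED_ISOTYPES = ("IgM", "GGM")
_FLAT_ISOTYPES = ("IgG", "IgE", "MMG")


@dataclass(frozen=True)
class ResponseModel:
    """Isotype-specific mapping from sensor force to accumulation level.

    ``level_means`` are the expected synapse-accumulation plateaus (arbitrary
    units) of the three response levels; per-cell plateaus are drawn from a
    truncated Normal with coefficient of variation ``level_cv``.  ``baseline``
    is the residual plateau for the no-antigen (NC) control.
    """

    isotype: str
    level_means: dict = field(
        default_factory=lambda: {"low": 1.0, "medium": 2.0, "high": 3.5}
    )
    level_cv: float = 0.25
    baseline: float = 0.15
    force_bands: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.force_bands:
            bands = _BANDED if self.isotype in _BANDED_ISOTYPES else _FLAT
            object.__setattr__(self, "force_bands", dict(bands))
        lm = self.level_means
        if not (lm["low"] < lm["medium"] < lm["high"]):
            raise ValueError("level means must be ordered low < medium < high")

    def level_of(self, sensor: TGTSensor) -> str | None:
        """Response level for a sensor; None for the NC control."""
        if not sensor.np_conjugated:
            return None
        return self.force_bands[sensor.mean_rupture_force]

    def plateau_mean(self, sensor: TGTSensor) -> float:
        level = self.level_of(sensor)
        return self.baseline if level is None else self.level_means[level]

    def sample_plateau(self, sensor: TGTSensor, rng: np.random.Generator) -> float:
        mu = self.plateau_mean(sensor)
        draw = rng.normal(mu, self.level_cv * mu)
        while draw <= 0:  # truncate at 0; vanishing mass at default CV
            draw = rng.normal(mu, self.level_cv * mu)
        return draw


def default_response(isotype: str) -> ResponseModel:
    if isotype not in _BANDED_ISOTYPES + _FLAT_ISOTYPES:
        raise ValueError(f"unknown isotype {isotype!r}")
    return ResponseModel(isotype=isotype)


# ---------------------------------------------------------------------------
# synapse rendering

#: Synapse geometry/brightness defaults: contact area and cluster count grow
#: in proportion to accumulation.
_AREA_PER_UNIT_UM2 = 18.0     # contact area per accumulation unit
_CLUSTERS_PER_UNIT = 8.0      # microclusters per accumulation unit
_CLUSTER_PHOTONS = 4000.0     # integrated counts per microcluster
_CLUSTER_SIGMA_UM = 0.25      # microclusters slightly above the PSF size
_DIFFUSE_PER_UNIT = 12.0      # diffuse membrane signal (counts/px per unit)
_DEFAULT_TAU_S = 120.0        # accumulation time constant


def _render_synapse_frame(
    accumulation: float,
    area_um2: float,
    optics: OpticsModel,
    rng: np.random.Generator,
    add_noise: bool = True,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Render one synapse frame: diffuse disk + microclusters at the centre."""
    h, w = optics.frame_shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r_px = math.sqrt(max(area_um2, 0.0) / math.pi) / optics.pixel_size
    yy, xx = np.ogrid[:h, :w]
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    signal = disk * (_DIFFUSE_PER_UNIT * accumulation)

    n_clusters = rng.poisson(_CLUSTERS_PER_UNIT * accumulation)
    if n_clusters > 0 and r_px > 1:
        rr = r_px * np.sqrt(rng.uniform(0, 1, n_clusters))
        th = rng.uniform(0, 2 * math.pi, n_clusters)
        cxs = cx + rr * np.cos(th)
        cys = cy + rr * np.sin(th)
        photons = rng.gamma(4.0, _CLUSTER_PHOTONS / 4.0, n_clusters)
        signal = signal + _render_spots(
            (h, w), cxs, cys, photons, _CLUSTER_SIGMA_UM / optics.pixel_size
        )
        cluster_xy = np.column_stack([cxs, cys]) * optics.pixel_size
    else:
        cluster_xy = np.empty((0, 2))
        photons = np.empty(0)
    if add_noise:
        data = _apply_camera(signal, optics, rng)
    else:
        data = signal + optics.background_offset
    return data, (cluster_xy, photons)


def simulate_cell_timelapse(
    response: ResponseModel,
    sensor: TGTSensor,
    duration: float,
    interval: float,
    optics: OpticsModel | None = None,
    seed: int | np.random.Generator = 0,
    tau: float = _DEFAULT_TAU_S,
    add_noise: bool = True,
) -> tuple[ImageStack, GroundTruth]:
    """One cell landing on a sensor-coated surface, imaged at fixed interval.

    The per-cell accumulation follows saturating growth
    ``A(t) = A_plateau * (1 - exp(-t/tau))`` with the plateau drawn from the
    response level implied by (isotype, sensor force); contact area and
    microcluster count grow in proportion.  NC (unconjugated) sensors give
    baseline-only traces.  Frames are taken at t = 0, interval, ...,
    giving ``floor(duration/interval) + 1`` frames.
    """
    if duration <= 0 or interval <= 0 or duration < interval:
        raise ValueError("need duration >= interval > 0")
    optics = optics or OpticsModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_frames = int(math.floor(duration / interval)) + 1
    times = np.arange(n_frames) * interval

    plateau = response.sample_plateau(sensor, rng)
    acc = plateau * (1.0 - np.exp(-times / tau))
    areas = _AREA_PER_UNIT_UM2 * acc

    frames = np.empty((n_frames, *optics.frame_shape))
    clusters = []
    for i in range(n_frames):
        frames[i], inventory = _render_synapse_frame(acc[i], areas[i], optics, rng, add_noise)
        clusters.append(inventory)
    stack = ImageStack(frames, optics.pixel_size, interval)
    truth = GroundTruth(contact_area=areas, accumulation=acc, clusters=clusters)
    return stack, truth


def simulate_condition_panel(
    response: ResponseModel,
    panel: Sequence[TGTSensor],
    n_cells: int,
    optics: OpticsModel | None = None,
    seed: int | np.random.Generator = 0,
    render: bool = True,
) -> tuple[pd.DataFrame, list[ImageFrame | None]]:
    """End-point synapse frames for every (sensor, cell) combination.

    Returns a tidy manifest (cell, sensor id, force, level, true accumulation
    and contact area) and, when ``render`` is on, the matching frames.  With
    ``render=False`` only the ground-truth table is produced, which is what
    statistical power studies need.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not panel:
        raise ValueError("panel must be non-empty")
    optics = optics or OpticsModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rows = []
    frames: list[ImageFrame | None] = []
    for sensor in panel:
        for cell in range(n_cells):
            plateau = response.sample_plateau(sensor, rng)
            area = _AREA_PER_UNIT_UM2 * plateau
            rows.append(
                {
                    "cell": f"{sensor.id}-c{cell:03d}",
                    "sensor_id": sensor.id,
                    "force_pN": sensor.mean_rupture_force,
                    "np_conjugated": sensor.np_conjugated,
                    "level": response.level_of(sensor),
                    "true_accumulation": plateau,
                    "true_contact_area_um2": area,
                }
            )
            if render:
                data, _ = _render_synapse_frame(plateau, area, optics, rng)
                frames.append(ImageFrame(data, optics.pixel_size))
            else:
                frames.append(None)
    return pd.DataFrame(rows), frames
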