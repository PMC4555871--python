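"""MFI -> surface-density calibration.

Single-molecule counting saturates once spots start to overlap (a few
molecules/µm² at diffraction-limited optics), so dense surfaces are
quantified indirectly: the background-subtracted mean fluorescence
intensity (MFI) of a stained region is converted to molecules per counting
area through a through-origin linear calibration,

    molecules per counting area = slope * MFI,

fitted on sparse fields whose density can still be counted directly.  The
regression has no intercept by construction (zero molecules produce zero
background-subtracted signal); its slope is the closed form
sum(x*y) / sum(x^2) and R^2 is computed about the through-origin model with
the total sum of squares taken about zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simulate import (
    COUNTING_AREA_UM2,
    COUNTING_ROI_PIXELS,
    ImageFrame,
    OpticsModel,
    reporter_optics,
    simulate_molecule_field,
)

__all__ = [
    "DensityCalibration",
    "compute_mfi",
    "fit_calibration",
    "mfi_to_density",
    "synthetic_calibration_series",
]


@dataclass(frozen=True)
class DensityCalibration:
    """A fitted through-origin MFI->density conversion.

    slope          molecules per counting area per MFI unit
    counting_area  µm² of the counting area the slope refers to
    r_squared      coefficient of determination about the through-origin model
    n_points       calibration points used
    """

    slope: float
    counting_area: float = COUNTING_AREA_UM2
    r_squared: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.slope <= 0 or self.counting_area <= 0:
            raise ValueError("slope and counting area must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "slope": self.slope,
                    "counting_area_um2": self.counting_area,
                    "r_squared": self.r_squared,
                    "n_points": self.n_points,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "DensityCalibration":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            slope=d["slope"],
            counting_area=d["counting_area_um2"],
            r_squared=d["r_squared"],
            n_points=d["n_points"],
        )


def compute_mfi(
    image: ImageFrame,
    roi: tuple[int, int, int, int] | None = None,
    background_region: tuple[int, int, int, int] | None = None,
    background_value: float | None = None,
) -> float:
    """Background-subtracted mean intensity of ``roi`` (whole frame if None).

    Background priority: explicit ``background_value``, else the median of a
    user-designated empty ``background_region``, else the image-wide 10th
    percentile.  The result is clamped at 0.
    """
    data = np.asarray(image.data, dtype=float)
    if roi is None:
        roi = (0, 0, data.shape[0], data.shape[1])
    r0, c0, rh, cw = roi
    if rh <= 0 or cw <= 0:
        raise ValueError("roi must have positive area")
    if r0 < 0 or c0 < 0 or r0 + rh > data.shape[0] or c0 + cw > data.shape[1]:
        raise ValueError("roi outside image")
    region = data[r0 : r0 + rh, c0 : c0 + cw]
    if background_value is not None:
        bg = float(background_value)
    elif background_region is not None:
        br0, bc0, brh, bcw = background_region
        bg = float(np.median(data[br0 : br0 + brh, bc0 : bc0 + bcw]))
    else:
        bg = float(np.percentile(data, 10))
    return max(float(region.mean()) - bg, 0.0)


def fit_calibration(
    points: Sequence[tuple[float, float]],
    counting_area: float = COUNTING_AREA_UM2,
) -> DensityCalibration:
    """Through-origin least squares on (MFI, molecules per counting area).

    slope = sum(x*y) / sum(x^2); R^2 = 1 - SS_res / sum(y^2), the total sum
    of squares being taken about zero as is proper for a no-intercept model.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 calibration points")
    x, y = pts[:, 0], pts[:, 1]
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("degenerate fit: all MFI values are zero")
    slope = float(np.sum(x * y)) / sxx
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum(y * y))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return DensityCalibration(
        slope=slope, counting_area=counting_area, r_squared=r2, n_points=len(x)
    )


def mfi_to_density(mfi: float, cal: DensityCalibration) -> float:
    """Convert an MFI reading to molecules/µm² through the calibration."""
    if mfi < 0:
        raise ValueError("MFI must be >= 0")
    return cal.slope * mfi / cal.counting_area


#: Pixels of guard band around the counting ROI when simulating calibration
#: fields, so spots just outside the ROI still deposit their tail photons in
#: it (as on a real, much larger frame).
_ROI_MARGIN_PX = 8


def measure_field_mfi(
    density: float,
    optics: OpticsModel | None = None,
    seed: int | np.random.Generator = 0,
) -> float:
    """Simulate a stained surface and read its counting-ROI MFI.

    The field is rendered with a guard margin around the counting ROI and a
    matched blank frame supplies the background estimate, as an empty
    coverslip region would in the real assay.
    """
    roi_px = COUNTING_ROI_PIXELS
    side = roi_px + 2 * _ROI_MARGIN_PX
    optics = optics or reporter_optics(frame_shape=(side, side))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frame, _ = simulate_molecule_field(density, optics, rng)
    blank, _ = simulate_molecule_field(0.0, optics, rng)
    m = _ROI_MARGIN_PX
    roi = (m, m, roi_px, roi_px)
    return compute_mfi(frame, roi, background_value=float(blank.data.mean()))


def synthetic_calibration_series(
    densities: Sequence[float],
    optics: OpticsModel | None = None,
    seed: int | np.random.Generator = 0,
) -> list[tuple[float, float]]:
    """Generate (MFI, molecules per counting area) calibration points.

    One simulated stained field per target density, measured with
    :func:`measure_field_mfi`; the ground-truth y value is the target
    density times the nominal counting area.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [
        (measure_field_mfi(d, optics, rng), d * COUNTING_AREA_UM2) for d in densities
    ]
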