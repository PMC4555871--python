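"""NP-TGT force-sensor panel: strand chemistry, force mapping, rupture statistics.

A tension gauge tether (TGT) is a short DNA duplex anchoring a ligand to a
surface.  One strand carries the NP hapten (the antigen seen by the B1-8
receptor), the other a biotin anchor.  Moving the biotin along the anchor
strand switches the rupture geometry between *unzipping* (force applied
across the helix, peeling base pairs one at a time — low threshold) and
*shearing* (force loaded along the helix onto all base pairs in parallel —
high threshold).  The eight anchoring positions used here define an
ascending panel of mean rupture forces from 12 to 56 pN.

Rupture thresholds of nominally identical tethers are not a single number
but a distribution; the panel is characterised by the full width at half
maximum (FWHM) of that distribution: 5 pN for unzipping-mode tethers and
15 pN for shearing-mode tethers.  We model each sensor's threshold as a
Gaussian with the stated mean and FWHM, truncated at zero force.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq
from scipy.stats import truncnorm

__all__ = [
    "LIGAND_STRAND_BASES",
    "ANCHOR_STRAND_BASES",
    "POSITION_FORCE_PN",
    "FWHM_UNZIPPING_PN",
    "FWHM_SHEARING_PN",
    "StrandSequence",
    "TGTSensor",
    "DuplexReport",
    "build_sensor_panel",
    "check_duplex",
    "sample_rupture_forces",
    "survival_probability",
    "empirical_fwhm",
    "panel_to_json",
    "panel_from_json",
    "panel_to_fasta",
]

#: Ligand strand, 5'->3'; the 3' amine carries the NP hapten conjugate.
LIGAND_STRAND_BASES = "CACAGCACGGAGGCACGACAC"

#: Anchor strand, 5'->3'; biotin is placed at one of eight base positions.
ANCHOR_STRAND_BASES = "GTGTCGTGCCTCCGTGCTGTG"

#: Biotin position (1-based from the 5' end of the anchor strand) -> mean
#: rupture force in pN.  A bijection; the panel is read in ascending force.
POSITION_FORCE_PN: dict[int, float] = {
    1: 12.0,
    2: 16.0,
    4: 23.0,
    7: 33.0,
    11: 43.0,
    15: 50.0,
    18: 54.0,
    21: 56.0,
}

FWHM_UNZIPPING_PN = 5.0
FWHM_SHEARING_PN = 15.0

#: Biotin positions whose pulling geometry peels the duplex (unzipping).
#: Positions at or near the 5' anchor end load the terminal base pairs in
#: series; all deeper positions are treated as shearing.  The split between
#: the two modes for intermediate positions is a modeling default and can be
#: overridden per sensor.
UNZIPPING_POSITIONS = frozenset({1, 2})

#: FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian.
_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

_ALPHABET = frozenset("ACGT")
_MODIFICATIONS = ("none", "NP_3prime", "biotin")


@dataclass(frozen=True)
class StrandSequence:
    """A DNA strand read 5'->3' with an optional terminal/internal label.

    ``modification`` is ``"none"``, ``"NP_3prime"`` (hapten on the 3' amine)
    or ``"biotin"`` with ``biotin_position`` giving the 1-based base index of
    the biotin counted from the 5' end.  Modifications are metadata only and
    never alter base-pairing.
    """

    bases: str
    modification: str = "none"
    biotin_position: int | None = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("strand must be non-empty")
        bad = set(self.bases) - _ALPHABET
        if bad:
            raise ValueError(f"invalid bases {sorted(bad)}; alphabet is ACGT")
        if self.modification not in _MODIFICATIONS:
            raise ValueError(f"unknown modification {self.modification!r}")
        if self.modification == "biotin":
            k = self.biotin_position
            if k is None or not (1 <= k <= len(self.bases)):
                raise ValueError(
                    f"biotin position {k} outside [1, {len(self.bases)}]"
                )
        elif self.biotin_position is not None:
            raise ValueError("biotin_position given without biotin modification")

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "StrandSequence":
        return StrandSequence(str(Seq(self.bases).reverse_complement()))


@dataclass(frozen=True)
class DuplexReport:
    """Outcome of annealing two strands end-to-end."""

    is_fully_complementary: bool
    duplex_length: int
    mismatch_positions: tuple[int, ...]


@dataclass(frozen=True)
class TGTSensor:
    """One tether of the panel: strands, anchor position, rupture statistics."""

    id: str
    ligand_strand: StrandSequence
    anchor_strand: StrandSequence
    biotin_position: int
    mean_rupture_force: float  # pN
    rupture_mode: str  # "unzipping" | "shearing"
    fwhm: float  # pN
    np_conjugated: bool = True

    def __post_init__(self) -> None:
        if self.biotin_position not in POSITION_FORCE_PN:
            raise ValueError(f"biotin position {self.biotin_position} not in panel")
        expected = POSITION_FORCE_PN[self.biotin_position]
        if self.mean_rupture_force != expected:
            raise ValueError(
                f"position {self.biotin_position} maps to {expected} pN, "
                f"got {self.mean_rupture_force}"
            )
        if self.rupture_mode not in ("unzipping", "shearing"):
            raise ValueError(f"unknown rupture mode {self.rupture_mode!r}")
        expected_fwhm = (
            FWHM_UNZIPPING_PN if self.rupture_mode == "unzipping" else FWHM_SHEARING_PN
        )
        if self.fwhm != expected_fwhm:
            raise ValueError(
                f"{self.rupture_mode} mode implies FWHM {expected_fwhm} pN, got {self.fwhm}"
            )

    @property
    def sigma(self) -> float:
        """Gaussian SD of the rupture-force distribution, pN."""
        return self.fwhm / _FWHM_PER_SIGMA


def _make_sensor(position: int, np_conjugated: bool = True, label: str | None = None) -> TGTSensor:
    force = POSITION_FORCE_PN[position]
    mode = "unzipping" if position in UNZIPPING_POSITIONS else "shearing"
    fwhm = FWHM_UNZIPPING_PN if mode == "unzipping" else FWHM_SHEARING_PN
    return TGTSensor(
        id=label or f"TGT-{force:g}pN",
        ligand_strand=StrandSequence(LIGAND_STRAND_BASES, "NP_3prime")
        if np_conjugated
        else StrandSequence(LIGAND_STRAND_BASES),
        anchor_strand=StrandSequence(ANCHOR_STRAND_BASES, "biotin", position),
        biotin_position=position,
        mean_rupture_force=force,
        rupture_mode=mode,
        fwhm=fwhm,
        np_conjugated=np_conjugated,
    )


def build_sensor_panel(include_control: bool = False) -> list[TGTSensor]:
    """The eight NP-conjugated sensors in ascending force order.

    With ``include_control`` a ninth entry is appended: the 56 pN tether
    without the NP hapten ("NC"), which presents no antigen and serves as the
    negative control.
    """
    panel = [_make_sensor(p) for p in sorted(POSITION_FORCE_PN, key=POSITION_FORCE_PN.get)]
    if include_control:
        panel.append(_make_sensor(21, np_conjugated=False, label="NC"))
    return panel


def check_duplex(a: StrandSequence, b: StrandSequence) -> DuplexReport:
    """Compare strand ``a`` against the reverse complement of ``b``.

    The strands are aligned end-to-end; the duplex length is the shorter
    strand length and mismatches are reported as 1-based positions along the
    aligned duplex (counted from the 5' end of ``a``).
    """
    rc = b.reverse_complement().bases
    n = min(len(a.bases), len(rc))
    mismatches = tuple(i + 1 for i in range(n) if a.bases[i] != rc[i])
    return DuplexReport(
        is_fully_complementary=not mismatches,
        duplex_length=n,
        mismatch_positions=mismatches,
    )


def sample_rupture_forces(
    sensor: TGTSensor, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` rupture thresholds (pN) from the sensor's distribution.

    The distribution is Gaussian(mean_rupture_force, FWHM/2.3548) truncated
    at 0 pN.  Reproducible given the seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mu, sigma = sensor.mean_rupture_force, sensor.sigma
    a = (0.0 - mu) / sigma
    return truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng)


def survival_probability(sensor: TGTSensor, applied_force: float) -> float:
    """P(rupture threshold > applied_force): the chance the tether survives.

    Non-increasing in applied force; a tether pulled at exactly its mean
    threshold survives with probability ~1/2 (exactly 1/2 for the
    untruncated Gaussian; truncation at 0 pN adds a negligible correction
    for all panel forces).
    """
    if applied_force < 0:
        raise ValueError("applied force must be >= 0")
    mu, sigma = sensor.mean_rupture_force, sensor.sigma
    a = (0.0 - mu) / sigma
    return float(truncnorm.sf(applied_force, a, np.inf, loc=mu, scale=sigma))


def empirical_fwhm(
    samples: np.ndarray, bin_width: float = 0.05, smooth_fraction: float = 0.3
) -> float:
    """Full width at half maximum estimated from a fine histogram.

    Counts are binned at ``bin_width``, boxcar-smoothed, and the
    half-maximum crossings located by linear interpolation.  Smoothing is
    two-pass: a first narrow pass yields a rough width, the second uses a
    boxcar of ``smooth_fraction`` times that width so the estimator noise
    scales with the distribution width.  The broadening a boxcar of width
    ``w`` adds to a peak (variance ``w**2 / 12``) is removed by quadrature
    deconvolution of the measured width.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 100:
        raise ValueError("need >= 100 samples for a histogram FWHM estimate")

    def _fwhm_once(smooth_bins: int) -> float:
        lo, hi = samples.min() - bin_width, samples.max() + bin_width
        edges = np.arange(lo, hi + bin_width, bin_width)
        counts, edges = np.histogram(samples, bins=edges)
        if smooth_bins > 1:
            kernel = np.ones(smooth_bins) / smooth_bins
            counts = np.convolve(counts.astype(float), kernel, mode="same")
        centers = 0.5 * (edges[:-1] + edges[1:])
        peak = counts.max()
        half = peak / 2.0
        above = np.flatnonzero(counts >= half)
        i0, i1 = above[0], above[-1]
        # interpolate the crossings on either flank
        if i0 > 0:
            c0, c1 = counts[i0 - 1], counts[i0]
            left = centers[i0 - 1] + (half - c0) / (c1 - c0) * bin_width
        else:
            left = centers[i0]
        if i1 < counts.size - 1:
            c0, c1 = counts[i1], counts[i1 + 1]
            right = centers[i1] + (half - c0) / (c1 - c0) * bin_width
        else:
            right = centers[i1]
        width = right - left
        # remove the boxcar's quadrature broadening (FWHM of the kernel's
        # variance contribution is _FWHM_PER_SIGMA * w / sqrt(12))
        w = smooth_bins * bin_width
        broaden_sq = (_FWHM_PER_SIGMA**2 / 12.0) * w**2
        return math.sqrt(max(width**2 - broaden_sq, 0.0))

    rough = _fwhm_once(5)
    smooth_bins = max(1, int(round(smooth_fraction * rough / bin_width)))
    return _fwhm_once(smooth_bins)


# ---------------------------------------------------------------------------
# serialisation

def _sensor_record(s: TGTSensor) -> dict:
    return {
        "id": s.id,
        "ligand_bases": s.ligand_strand.bases,
        "anchor_bases": s.anchor_strand.bases,
        "biotin_position": s.biotin_position,
        "mean_rupture_force_pN": s.mean_rupture_force,
        "rupture_mode": s.rupture_mode,
        "fwhm_pN": s.fwhm,
        "np_conjugated": s.np_conjugated,
    }


def panel_to_json(panel: Sequence[TGTSensor], path) -> None:
    with open(path, "w") as fh:
        json.dump([_sensor_record(s) for s in panel], fh, indent=1)


def panel_from_json(path) -> list[TGTSensor]:
    with open(path) as fh:
        records = json.load(fh)
    panel = []
    for r in records:
        panel.append(
            TGTSensor(
                id=r["id"],
                ligand_strand=StrandSequence(
                    r["ligand_bases"], "NP_3prime" if r["np_conjugated"] else "none"
                ),
                anchor_strand=StrandSequence(
                    r["anchor_bases"], "biotin", r["biotin_position"]
                ),
                biotin_position=r["biotin_position"],
                mean_rupture_force=r["mean_rupture_force_pN"],
                rupture_mode=r["rupture_mode"],
                fwhm=r["fwhm_pN"],
                np_conjugated=r["np_conjugated"],
            )
        )
    return panel


def panel_to_fasta(panel: Sequence[TGTSensor], path) -> None:
    """Two records per sensor; modifications encoded in the description."""
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = []
    for s in panel:
        lig_desc = "ligand 5'->3'" + (" NP@3'-NH2" if s.np_conjugated else " unconjugated")
        records.append(
            SeqRecord(Seq(s.ligand_strand.bases), id=f"{s.id}|ligand", description=lig_desc)
        )
        records.append(
            SeqRecord(
                Seq(s.anchor_strand.bases),
                id=f"{s.id}|anchor",
                description=f"anchor 5'->3' biotin@{s.biotin_position}",
            )
        )
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
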