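"""Core measurement containers.

Units are fixed package-wide: heights and displacements in nanometres, lateral
positions and pixel sizes in micrometres, forces in nanonewtons, stresses in
megapascals, strains as dimensionless fractions, wavenumbers in cm^-1 and
transmittance in percent.  The force sign convention is positive = repulsive;
attractive excursions are negative and reported magnitudes are positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import DataFormatError, InvalidParameterError

__all__ = [
    "TopographyImage",
    "LineProfile",
    "StepEvent",
    "RoughnessResult",
    "ForceDistanceCurve",
    "FDFeatures",
    "TensileCurve",
    "TensileFeatures",
    "Spectrum",
    "BandDefinition",
    "BandQuantification",
    "GroupSummary",
    "ComparisonResult",
]


@dataclass
class TopographyImage:
    """Height grid with physical pixel size.

    heights : 2-D array (rows, cols) of heights in nm, row-major, origin
        top-left, 0-based indices; physical positions refer to pixel centers.
    pixel_size : (row, col) pixel pitch in um.
    """

    heights: np.ndarray
    pixel_size: tuple[float, float]
    source_id: str = ""

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or min(self.heights.shape) < 1:
            raise DataFormatError("heights must be a non-empty 2-D grid")
        if not np.all(np.isfinite(self.heights)):
            raise DataFormatError("heights must be finite")
        if np.isscalar(self.pixel_size):
            self.pixel_size = (float(self.pixel_size), float(self.pixel_size))
        else:
            self.pixel_size = (float(self.pixel_size[0]), float(self.pixel_size[1]))
        if min(self.pixel_size) <= 0:
            raise InvalidParameterError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def extent(self) -> tuple[float, float]:
        """Physical (rows, cols) extent in um."""
        return (
            self.shape[0] * self.pixel_size[0],
            self.shape[1] * self.pixel_size[1],
        )


@dataclass
class LineProfile:
    """1-D height profile: positions in um (strictly increasing), heights in nm."""

    positions: np.ndarray
    heights: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.positions.shape != self.heights.shape or self.positions.ndim != 1:
            raise DataFormatError("positions and heights must be matching 1-D arrays")
        if len(self.positions) >= 2 and not np.all(np.diff(self.positions) > 0):
            raise DataFormatError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class StepEvent:
    """One cuticle step: boundary position (um), height magnitude (nm), direction."""

    position: float
    height: float
    direction: Literal["rise", "fall"]

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise InvalidParameterError("step height must be a positive magnitude")
        if self.direction not in ("rise", "fall"):
            raise InvalidParameterError("direction must be 'rise' or 'fall'")


@dataclass
class RoughnessResult:
    """Areal roughness over the sampled area after flattening.

    Sa: mean absolute deviation from the mean plane (nm).
    Sz: maximum peak-to-valley height (nm), areal convention (global max - min).
    """

    Sa: float
    Sz: float
    area: tuple[float, float]
    flatten_order: int


@dataclass
class ForceDistanceCurve:
    """Approach/retract force-vs-piezo-displacement branches.

    Each branch is an (n, 2) array of (displacement nm, force nN); displacement
    increases toward the sample and is strictly monotone within a branch
    (approach in increasing order, retract stored in time order, decreasing).
    """

    approach: np.ndarray
    retract: np.ndarray
    spring_constant: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.approach = np.asarray(self.approach, dtype=float)
        self.retract = np.asarray(self.retract, dtype=float)
        for name, branch in (("approach", self.approach), ("retract", self.retract)):
            if branch.ndim != 2 or branch.shape[1] != 2:
                raise DataFormatError(f"{name} branch must be an (n, 2) array")
            if branch.shape[0] < 20:
                raise DataFormatError(f"{name} branch must have at least 20 points")
            d = np.diff(branch[:, 0])
            if not (np.all(d > 0) or np.all(d < 0)):
                raise DataFormatError(f"{name} displacement must be strictly monotone")
        if not self.spring_constant > 0:
            raise InvalidParameterError("spring_constant must be positive")


@dataclass
class FDFeatures:
    """Features extracted from one force-distance curve.

    stiffness is the raw force-vs-displacement slope of the contact region
    (bounded above by the cantilever spring constant); sample_stiffness is the
    series-spring-corrected sample value k*m/(k-m), inf at the rigid limit.
    adhesion and attraction are dip magnitudes (nN, >= 0).
    """

    stiffness: float
    adhesion: float
    attraction: float
    contact_point: float
    fit_quality: float
    sample_stiffness: float = float("nan")
    attraction_detected: bool = True
    adhesion_detected: bool = True
    low_fit_quality: bool = False
    source_id: str = ""


@dataclass
class TensileCurve:
    """Stress-strain record of a single fiber pulled to fracture.

    strain: dimensionless fraction, non-decreasing from ~0; stress: MPa;
    diameter: um (circular cross-section assumed); gauge_force: mN pre-tension.
    """

    strain: np.ndarray
    stress: np.ndarray
    diameter: float
    gauge_force: float = 0.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.ndim != 1:
            raise DataFormatError("strain and stress must be matching 1-D arrays")
        if np.any(np.diff(self.strain) < 0):
            raise DataFormatError("strain must be non-decreasing")
        if not np.all(np.isfinite(self.stress)):
            raise DataFormatError("stress must be finite")
        if not self.diameter > 0:
            raise InvalidParameterError("diameter must be positive")


@dataclass
class TensileFeatures:
    """Features of a three-region (pre-yield / yield / post-yield) tensile curve."""

    elastic_modulus: float
    yield_stress: float
    yield_bounds: tuple[float, float]
    fracture_stress: float
    fracture_strain: float
    fit_r_squared: float
    degenerate: bool = False
    segmentation_ok: bool = True
    source_id: str = ""


@dataclass
class Spectrum:
    """FT-IR spectrum: wavenumbers (cm^-1, strictly increasing), transmittance (%)."""

    wavenumbers: np.ndarray
    transmittance: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.transmittance = np.asarray(self.transmittance, dtype=float)
        if self.wavenumbers.shape != self.transmittance.shape or self.wavenumbers.ndim != 1:
            raise DataFormatError("wavenumbers and transmittance must be matching 1-D arrays")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise DataFormatError("wavenumbers must be strictly increasing")
        if np.any(self.transmittance < 0) or np.any(self.transmittance > 110):
            raise DataFormatError("transmittance must lie in [0, 110] %")

    def __len__(self) -> int:
        return len(self.wavenumbers)


@dataclass(frozen=True)
class BandDefinition:
    """Named wavenumber window for band quantification."""

    name: str
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.window[0] < self.window[1]:
            raise InvalidParameterError(f"band {self.name!r}: window low must be < high")


@dataclass
class BandQuantification:
    """One band's measurement: center of maximum depth, depth below local baseline."""

    name: str
    center: float
    depth: float
    present: bool
    window: tuple[float, float]


@dataclass
class GroupSummary:
    """Per-dye-cycle group mean +/- SEM (fiber is the experimental unit)."""

    group: int
    n: int
    mean: float
    sem: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidParameterError("group summary requires n >= 2 (SEM defined)")
        if self.sem < 0:
            raise InvalidParameterError("sem must be non-negative")


@dataclass
class ComparisonResult:
    """Two-sample comparison: t statistic, two-tailed p, significance stars."""

    t: float
    p: float
    stars: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise InvalidParameterError("p must lie in [0, 1]")
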