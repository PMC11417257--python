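"""Tensile stress-strain analysis of single fibers.

Converts force-elongation records to engineering stress (sigma = F/A with a
circular cross-section A = pi*(d/2)^2), segments the curve into the three
regions characteristic of keratin fibers — pre-yield (Hookean), yield
(near-flat plateau) and post-yield (re-stiffening up to fracture) — and
extracts the elastic modulus, yield stress, and fracture stress/strain.

Segmentation fits a continuous three-piece linear model (free slopes, shared
breakpoints) by exhaustive coarse search over a breakpoint grid followed by
deterministic local grid refinement; there is no random initialization, so
repeated runs are identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datatypes import TensileCurve, TensileFeatures
from .errors import AnalysisError, InvalidParameterError

__all__ = [
    "compute_stress",
    "cross_section_area_um2",
    "segment_regions",
    "extract_features",
    "GF_TO_MN",
    "SegmentationResult",
]

GF_TO_MN = 9.80665  # 1 gram-force in millinewtons


def cross_section_area_um2(diameter_um: float) -> float:
    if not diameter_um > 0:
        raise InvalidParameterError("diameter must be positive")
    return math.pi * (diameter_um / 2.0) ** 2


def compute_stress(
    force_mN: np.ndarray,
    diameter_um: float,
    gauge_force_mN: float = 0.0,
    subtract_gauge: bool = False,
) -> np.ndarray:
    """Engineering stress in MPa from force in mN and fiber diameter in um.

    sigma = F/A with A = pi*(d/2)^2.  Instruments quoting the pre-tension in
    gram-force convert at 1 gf = 9.80665 mN; when ``subtract_gauge`` is set
    the gauge pre-tension is removed from the force before dividing (off by
    default: whether the pre-tension enters sigma is instrument convention).
    """
    force = np.asarray(force_mN, dtype=float)
    if subtract_gauge:
        force = force - gauge_force_mN
    area_um2 = cross_section_area_um2(diameter_um)
    # MPa = N/mm^2; F[mN]*1e-3 / (A[um^2]*1e-6 mm^2) = F/A * 1e3
    return force / area_um2 * 1e3


@dataclass
class SegmentationResult:
    yield_bounds: tuple[float, float]
    slopes: tuple[float, float, float]
    r_squared: float
    degenerate: bool
    middle_slope_smallest: bool


def _three_piece_sse(
    strain: np.ndarray, stress: np.ndarray, b1: float, b2: float
) -> tuple[float, np.ndarray]:
    """SSE of the continuous three-piece linear fit with breakpoints (b1, b2).

    Basis: 1, e, (e-b1)+, (e-b2)+ — continuous by construction.
    """
    design = np.column_stack(
        [
            np.ones_like(strain),
            strain,
            np.clip(strain - b1, 0.0, None),
            np.clip(strain - b2, 0.0, None),
        ]
    )
    coef, *_ = np.linalg.lstsq(design, stress, rcond=None)
    resid = stress - design @ coef
    return float(resid @ resid), coef


def segment_regions(curve: TensileCurve) -> SegmentationResult:
    """Find the two break strains of the three-region model.

    A coarse grid over (b1, b2) is refined locally three times (factor-5
    shrink each round).  The fit is degenerate — whole curve treated as
    pre-yield — when three pieces do not improve materially on a single line;
    a segmentation-failure flag is set when the fitted middle slope is not the
    smallest of the three.
    """
    strain, stress = curve.strain, curve.stress
    e_max = float(strain[-1])
    if e_max < 0.1 or len(strain) < 100:
        raise InvalidParameterError("curve must span strain >= 0.1 with >= 100 points")

    # single-line reference
    one = np.column_stack([np.ones_like(strain), strain])
    coef1, *_ = np.linalg.lstsq(one, stress, rcond=None)
    resid1 = stress - one @ coef1
    sse1 = float(resid1 @ resid1)

    b1_grid = np.linspace(0.01 * e_max, 0.30 * e_max, 24)
    b2_grid = np.linspace(0.20 * e_max, 0.90 * e_max, 29)
    min_gap = 0.05 * e_max

    def search(b1s: np.ndarray, b2s: np.ndarray) -> tuple[float, float, float]:
        best = (np.inf, b1s[0], b2s[-1])
        for b1 in b1s:
            for b2 in b2s:
                if b2 - b1 < min_gap:
                    continue
                sse, _ = _three_piece_sse(strain, stress, b1, b2)
                if sse < best[0]:
                    best = (sse, float(b1), float(b2))
        return best

    sse3, b1, b2 = search(b1_grid, b2_grid)
    db1 = b1_grid[1] - b1_grid[0]
    db2 = b2_grid[1] - b2_grid[0]
    for _ in range(3):
        b1s = np.linspace(b1 - db1, b1 + db1, 11)
        b2s = np.linspace(b2 - db2, b2 + db2, 11)
        b1s = b1s[b1s > 0]
        b2s = b2s[b2s < e_max]
        sse3, b1, b2 = search(b1s, b2s)
        db1 /= 5.0
        db2 /= 5.0

    if not np.isfinite(sse3):
        raise AnalysisError("three-piece fit did not converge on this curve")

    sse, coef = _three_piece_sse(strain, stress, b1, b2)
    slopes = (float(coef[1]), float(coef[1] + coef[2]), float(coef[1] + coef[2] + coef[3]))
    ss_tot = float(np.sum((stress - stress.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 1.0

    degenerate = sse1 <= 1e-12 * ss_tot or (sse1 - sse) < 0.2 * sse1
    middle_smallest = slopes[1] < slopes[0] and slopes[1] < slopes[2]
    return SegmentationResult(
        yield_bounds=(b1, b2),
        slopes=slopes,
        r_squared=r2,
        degenerate=degenerate,
        middle_slope_smallest=middle_smallest,
    )


def extract_features(curve: TensileCurve) -> TensileFeatures:
    """Modulus, yield and fracture features of a segmented tensile curve.

    elastic_modulus: least-squares slope over the pre-yield segment;
    yield_stress: maximum stress within pre-yield; the fracture point is the
    last recorded sample (the instrument stops at break).  On a degenerate
    (single-region) curve the whole record is treated as pre-yield.
    """
    seg = segment_regions(curve)
    strain, stress = curve.strain, curve.stress

    if seg.degenerate:
        pre = np.ones_like(strain, dtype=bool)
        bounds = (float(strain[-1]), float(strain[-1]))
    else:
        pre = strain <= seg.yield_bounds[0]
        bounds = seg.yield_bounds
    if pre.sum() < 2:
        raise AnalysisError("pre-yield segment too short to fit a modulus")
    coef = np.polyfit(strain[pre], stress[pre], 1)
    pred = np.polyval(coef, strain[pre])
    ss_res = float(np.sum((stress[pre] - pred) ** 2))
    ss_tot = float(np.sum((stress[pre] - stress[pre].mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    return TensileFeatures(
        elastic_modulus=float(coef[0]),
        yield_stress=float(stress[pre].max()),
        yield_bounds=bounds,
        fracture_stress=float(stress[-1]),
        fracture_strain=float(strain[-1]),
        fit_r_squared=r2,
        degenerate=seg.degenerate,
        segmentation_ok=seg.degenerate or seg.middle_slope_smallest,
        source_id=curve.source_id,
    )
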