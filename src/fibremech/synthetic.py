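"""Synthetic per-fiber measurements with known ground truth.

Emulates the four modalities measured on control and repeatedly-dyed hair
fibers: stepped cuticle topography with tunable roughness, force-distance
curves with snap-in / contact / pull-off structure, three-region tensile
curves, and keratin transmittance spectra as Gaussian dips on a ~100 %T
baseline.  Every generator is a pure function of (truth, geometry, seed), so
analysis stages can be tested by parameter recovery against the manifest.

Default group truths follow the measured dose-response trends on human hair
dyed 0/1/3/5/7/10 times: control cuticle step height 430.2 nm dropping ~20 %
after one dye then partially recovering; fine-scale roughness rising
monotonically with dye count; contact stiffness 0.163 nN/nm (cantilever
0.2 nN/nm) rising a few percent at 7-10 dyes; tip-sample attraction falling
~38-51 %; elastic modulus rising up to ~190 %; fracture strain 47 % control
vs >50 % dyed; amide/water band dips shrinking and a new 1575 cm^-1 NH2 band
appearing on dyed fibers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import io as fio
from .datatypes import ForceDistanceCurve, Spectrum, TensileCurve, TopographyImage
from .errors import InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "TopoTruth",
    "FDTruth",
    "TensileTruth",
    "SpectrumTruth",
    "GroupTruth",
    "CohortConfig",
    "gen_topography",
    "gen_fd_curve",
    "gen_tensile_curve",
    "gen_spectrum",
    "gen_cohort",
    "paper_trend_cohort",
    "MODALITIES",
]

MODALITIES = ("topo", "fd", "tensile", "ftir")


# ------------------------------------------------------------------- truths

@dataclass(frozen=True)
class TopoTruth:
    """Cuticle staircase + roughness ground truth (lengths nm, lateral um)."""

    step_height_mean: float = 430.2
    step_height_sd: float = 52.7
    terrace_length: float = 4.5
    roughness_sd: float = 5.0
    roughness_correlation_length: float = 0.3
    tilt: float = 5.0  # nm per um along the column (fiber) axis
    debris_density: float = 0.0  # bumps per um^2
    debris_height: float = 0.0  # nm

    def __post_init__(self) -> None:
        if not self.step_height_mean > 0:
            raise InvalidParameterError("step_height_mean must be > 0")
        if self.roughness_sd < 0:
            raise InvalidParameterError("roughness_sd must be >= 0")
        if not self.terrace_length > 0:
            raise InvalidParameterError("terrace_length must be > 0")


@dataclass(frozen=True)
class FDTruth:
    """Force-distance ground truth (forces nN, stiffnesses nN/nm).

    ``sample_stiffness=math.inf`` is the rigid-surface flag: the contact slope
    then equals the cantilever spring constant.
    """

    sample_stiffness: float = 0.8811  # gives slope k*s/(k+s) ~ 0.163 with k=0.2
    spring_constant: float = 0.2
    attraction_depth: float = 0.591
    adhesion_depth: float = 1.2
    setpoint: float = 9.0
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if not self.spring_constant > 0:
            raise InvalidParameterError("spring_constant must be > 0")
        if not self.sample_stiffness > 0:
            raise InvalidParameterError("sample_stiffness must be > 0")
        if self.attraction_depth < 0 or self.adhesion_depth < 0:
            raise InvalidParameterError("dip depths must be >= 0")
        if not 0 < self.setpoint <= 10:
            raise InvalidParameterError("setpoint must be in (0, 10] nN")

    @property
    def contact_slope(self) -> float:
        """Series-spring contact slope k*s/(k+s) in nN/nm."""
        if math.isinf(self.sample_stiffness):
            return self.spring_constant
        k, s = self.spring_constant, self.sample_stiffness
        return k * s / (k + s)


@dataclass(frozen=True)
class TensileTruth:
    """Three-region stress-strain ground truth (stresses MPa, strains fractions).

    The yield plateau is generated with slope 2 % of the elastic modulus:
    the plateau shows minimal, not zero, stress change, so segmentation has to
    handle a near-flat rather than degenerate middle region.
    """

    elastic_modulus: float = 3000.0
    yield_strain: float = 0.03
    post_yield_onset_strain: float = 0.25
    post_yield_modulus: float = 350.0
    fracture_strain: float = 0.47
    diameter: float = 78.0  # um
    noise_sd: float = 2.0  # MPa

    PLATEAU_SLOPE_FRACTION = 0.02

    def __post_init__(self) -> None:
        if not (0 < self.yield_strain < self.post_yield_onset_strain < self.fracture_strain):
            raise InvalidParameterError(
                "require 0 < yield_strain < post_yield_onset_strain < fracture_strain"
            )
        if self.elastic_modulus <= 0 or self.post_yield_modulus <= 0:
            raise InvalidParameterError("moduli must be > 0")
        if not self.diameter > 0:
            raise InvalidParameterError("diameter must be > 0")

    def stress_at(self, strain: np.ndarray) -> np.ndarray:
        """Noiseless piecewise-linear stress (MPa) at the given strains."""
        e = np.asarray(strain, dtype=float)
        ey, ep = self.yield_strain, self.post_yield_onset_strain
        e_mod = self.elastic_modulus
        plateau = self.PLATEAU_SLOPE_FRACTION * e_mod
        sy = e_mod * ey
        sp = sy + plateau * (ep - ey)
        out = np.where(
            e <= ey,
            e_mod * e,
            np.where(e <= ep, sy + plateau * (e - ey), sp + self.post_yield_modulus * (e - ep)),
        )
        return out


@dataclass(frozen=True)
class SpectrumTruth:
    """Transmittance spectrum truth: Gaussian dips on a sloped ~100 %T baseline.

    bands: (center cm^-1, depth %T, width cm^-1) with width the Gaussian sigma.
    """

    bands: tuple[tuple[float, float, float], ...] = ()
    baseline_slope: float = 0.0  # %T per cm^-1, relative to the low-wavenumber end
    noise_sd: float = 0.3  # %T

    def __post_init__(self) -> None:
        for center, depth, width in self.bands:
            if not 0 <= depth <= 100:
                raise InvalidParameterError(f"band at {center}: depth must be in [0, 100]")
            if not width > 0:
                raise InvalidParameterError(f"band at {center}: width must be > 0")


# --------------------------------------------------------------- generators

def _rng(seed: int | np.random.SeedSequence) -> np.random.Generator:
    return np.random.default_rng(seed)


def gen_topography(
    truth: TopoTruth,
    size: tuple[int, int] = (128, 128),
    pixel_size: float = 15.0 / 128.0,
    seed: int = 0,
) -> TopographyImage:
    """Generate a stepped cuticle height image.

    The staircase runs along the column axis (height rises with column index,
    emulating cuticle scales overlapping along the fiber axis): terraces of
    ``terrace_length`` separated by rises drawn from
    Normal(step_height_mean, step_height_sd^2), the first terrace starting at
    column position 0.  A tilt plane, a correlated Gaussian roughness field
    (point sd ``roughness_sd``, smoothed to the stated correlation length) and
    optional debris bumps are added.
    """
    rows, cols = size
    if rows < 16 or cols < 16:
        raise InvalidParameterError("image must be at least 16 x 16 pixels")
    if not pixel_size > 0:
        raise InvalidParameterError("pixel_size must be > 0")
    rng = _rng(seed)

    x = (np.arange(cols) + 0.5) * pixel_size  # um, pixel centers
    terrace_index = np.floor(x / truth.terrace_length).astype(int)
    n_boundaries = int(terrace_index.max())
    rises = (
        rng.normal(truth.step_height_mean, truth.step_height_sd, size=n_boundaries)
        if n_boundaries > 0
        else np.empty(0)
    )
    levels = np.concatenate([[0.0], np.cumsum(rises)])
    staircase = levels[terrace_index]

    heights = np.tile(staircase + truth.tilt * x, (rows, 1))

    if truth.roughness_sd > 0:
        noise = rng.standard_normal((rows, cols))
        sigma_px = truth.roughness_correlation_length / pixel_size
        if sigma_px > 0:
            noise = ndimage.gaussian_filter(noise, sigma_px, mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise *= truth.roughness_sd / sd
        heights += noise

    if truth.debris_density > 0 and truth.debris_height > 0:
        area = rows * cols * pixel_size**2
        n_debris = rng.poisson(truth.debris_density * area)
        radius_px = max(1.0, 0.2 / pixel_size)  # ~0.2 um footprint
        rr, cc = np.mgrid[0:rows, 0:cols]
        for _ in range(n_debris):
            r0 = rng.uniform(0, rows)
            c0 = rng.uniform(0, cols)
            d2 = (rr - r0) ** 2 + (cc - c0) ** 2
            heights += truth.debris_height * np.exp(-d2 / (2 * radius_px**2))

    return TopographyImage(heights, (pixel_size, pixel_size))


def gen_fd_curve(
    truth: FDTruth, n_points: int = 500, seed: int = 0
) -> ForceDistanceCurve:
    """Generate one approach/retract force-distance curve.

    Displacement is piezo travel in nm increasing toward the sample; force is
    positive-repulsive.  Approach: zero-force baseline, a sharp attractive
    ramp to -attraction_depth at the contact point, then a linear contact rise
    with the series-spring slope up to the setpoint.  Retract: the same
    contact line continued down to -adhesion_depth, then pull-off back to the
    baseline.  Gaussian force noise is added to both branches.
    """
    if n_points < 50:
        raise InvalidParameterError("n_points must be >= 50")
    if not truth.setpoint > 0:
        raise InvalidParameterError("setpoint must be > 0")
    rng = _rng(seed)

    slope = truth.contact_slope
    contact_len = (truth.setpoint + truth.attraction_depth) / slope
    z_max = 2.0 * contact_len  # ~50 % of the range is non-contact baseline
    z = np.linspace(0.0, z_max, n_points)
    i_c = (n_points - 1) // 2  # contact point lands exactly on the grid
    z_c = z[i_c]
    dz = z_max / (n_points - 1)
    dip_width = 3.0 * dz

    approach = np.zeros(n_points)
    pre = (z >= z_c - dip_width) & (z < z_c)
    approach[pre] = -truth.attraction_depth * (z[pre] - (z_c - dip_width)) / dip_width
    contact = z >= z_c
    approach[contact] = -truth.attraction_depth + slope * (z[contact] - z_c)

    # retract follows the contact line down to -adhesion_depth, touches it at
    # the pull-off sample, then returns to the zero-force baseline
    retract_line = -truth.attraction_depth + slope * (z - z_c)
    on_line = retract_line >= -truth.adhesion_depth
    retract = np.where(on_line, retract_line, 0.0)
    below = np.nonzero(~on_line)[0]
    if below.size:
        retract[below[-1]] = -truth.adhesion_depth  # pull-off point, exact depth

    if truth.noise_sd > 0:
        approach = approach + rng.normal(0.0, truth.noise_sd, n_points)
        retract = retract + rng.normal(0.0, truth.noise_sd, n_points)

    return ForceDistanceCurve(
        np.column_stack([z, approach]),
        np.column_stack([z[::-1], retract[::-1]]),  # retract stored in time order
        truth.spring_constant,
    )


def gen_tensile_curve(
    truth: TensileTruth, n_points: int = 800, seed: int = 0
) -> TensileCurve:
    """Generate a three-region stress-strain record ending at fracture."""
    if n_points < 100:
        raise InvalidParameterError("n_points must be >= 100")
    rng = _rng(seed)
    strain = np.linspace(0.0, truth.fracture_strain, n_points)
    stress = truth.stress_at(strain)
    if truth.noise_sd > 0:
        stress = stress + rng.normal(0.0, truth.noise_sd, n_points)
    return TensileCurve(strain, stress, truth.diameter)


def gen_spectrum(
    truth: SpectrumTruth,
    wavenumber_range: tuple[float, float] = (400.0, 4000.0),
    resolution: float = 4.0,
    seed: int = 0,
) -> Spectrum:
    """Generate a transmittance spectrum: 100 %T baseline + slope - Gaussian dips."""
    lo, hi = wavenumber_range
    if not lo < hi:
        raise InvalidParameterError("wavenumber range: min must be < max")
    if not resolution > 0:
        raise InvalidParameterError("resolution must be > 0")
    rng = _rng(seed)
    nu = np.arange(lo, hi + 0.5 * resolution, resolution)
    t = 100.0 + truth.baseline_slope * (nu - lo)
    for center, depth, width in truth.bands:
        if not (lo <= center <= hi):
            logger.warning("band at %.1f cm^-1 outside range (%.1f, %.1f); skipped", center, lo, hi)
            continue
        t = t - depth * np.exp(-((nu - center) ** 2) / (2.0 * width**2))
    if truth.noise_sd > 0:
        t = t + rng.normal(0.0, truth.noise_sd, nu.size)
    t = np.clip(t, 0.0, None)
    return Spectrum(nu, t)


# ------------------------------------------------------------------- cohort

@dataclass(frozen=True)
class GroupTruth:
    """All four modality truths for one dye-cycle group."""

    dye_count: int
    n_fibers: int
    topo: TopoTruth
    fd: FDTruth
    tensile: TensileTruth
    spectrum: SpectrumTruth

    def __post_init__(self) -> None:
        if self.dye_count < 0:
            raise InvalidParameterError("dye_count must be >= 0")
        if self.n_fibers < 2:
            raise InvalidParameterError("n_fibers must be >= 2 (SEM defined)")


@dataclass(frozen=True)
class CohortConfig:
    groups: tuple[GroupTruth, ...]
    seed: int = 0
    topo_size: tuple[int, int] = (128, 128)
    topo_pixel_size: float = 15.0 / 128.0
    fd_points: int = 500
    tensile_points: int = 800
    spectrum_range: tuple[float, float] = (400.0, 4000.0)
    spectrum_resolution: float = 4.0

    def __post_init__(self) -> None:
        counts = [g.dye_count for g in self.groups]
        if len(set(counts)) != len(counts):
            raise InvalidParameterError("dye_count values must be unique")


# Key bands tracked in hair keratin spectra: (center cm^-1, sigma cm^-1).
KERATIN_BAND_SHAPES = {
    "amide_I": (1650.0, 15.0),
    "amide_II": (1540.0, 13.0),
    "amide_III": (1265.0, 14.0),
    "amide_B": (3066.0, 12.0),
    "lipid": (3135.0, 10.0),
    "water": (3277.0, 30.0),
    "cysteic_acid": (1036.0, 7.0),
    "nh2_1575": (1575.0, 6.0),
}


def _spectrum_truth(depths: dict[str, float], noise_sd: float = 0.3) -> SpectrumTruth:
    bands = tuple(
        (KERATIN_BAND_SHAPES[name][0], depth, KERATIN_BAND_SHAPES[name][1])
        for name, depth in depths.items()
        if depth > 0
    )
    return SpectrumTruth(bands=bands, baseline_slope=5e-4, noise_sd=noise_sd)


def paper_trend_cohort(n_fibers: int = 25, seed: int = 0) -> CohortConfig:
    """Default six-group cohort (0/1/3/5/7/10 dye cycles) following the
    measured dose-response trends; 25 fibers per group (20-30 were measured)."""
    dye_counts = [0, 1, 3, 5, 7, 10]
    step_mean = [430.2, 343.3, 360.0, 380.0, 400.0, 410.0]
    rough_sd = [5.0, 6.0, 8.0, 10.0, 12.0, 14.0]
    debris_density = [0.0, 0.005, 0.01, 0.02, 0.03, 0.04]
    debris_height = [0.0, 30.0, 40.0, 50.0, 60.0, 80.0]
    # contact slopes: ~constant to 3 dyes, dip at 5, +4 % at 7, +10 % at 10
    slope_target = [0.163, 0.163, 0.163, 0.155, 0.16952, 0.1793]
    attraction = [0.591, 0.367, 0.345, 0.337, 0.296, 0.290]
    adhesion = [1.20, 1.22, 1.25, 1.50, 1.55, 1.60]
    e_mod = [3000.0, 3900.0, 4800.0, 6000.0, 5400.0, 8700.0]
    yield_strain = [0.030, 0.0323, 0.0281, 0.0240, 0.0258, 0.0176]
    post_mod = [350.0, 415.0, 400.0, 405.0, 395.0, 350.0]
    fracture = [0.47, 0.52, 0.52, 0.53, 0.53, 0.54]
    band_depths = {
        #        ctrl   1x    3x    5x    7x    10x
        "amide_I": [20.0, 16.4, 16.0, 13.5, 13.0, 12.4],
        "amide_II": [15.0, 12.6, 12.3, 10.0, 9.8, 9.5],
        "amide_III": [8.0, 7.0, 6.8, 5.8, 5.6, 5.4],
        "amide_B": [6.0, 5.5, 5.2, 4.5, 4.2, 3.8],
        "lipid": [4.0, 3.7, 3.5, 3.1, 2.9, 2.7],
        "water": [12.0, 7.2, 6.5, 5.76, 5.76, 5.76],  # ~52 % of control at >=5 dyes
        "cysteic_acid": [3.0, 2.6, 2.0, 1.9, 1.9, 1.9],
        "nh2_1575": [0.0, 5.0, 5.0, 5.0, 5.0, 5.0],  # absent in control
    }
    k = 0.2
    groups = []
    for i, dye in enumerate(dye_counts):
        m = slope_target[i]
        sample_stiffness = k * m / (k - m)
        groups.append(
            GroupTruth(
                dye_count=dye,
                n_fibers=n_fibers,
                topo=TopoTruth(
                    step_height_mean=step_mean[i],
                    step_height_sd=52.7,
                    terrace_length=4.5,
                    roughness_sd=rough_sd[i],
                    roughness_correlation_length=0.3,
                    tilt=5.0,
                    debris_density=debris_density[i],
                    debris_height=debris_height[i],
                ),
                fd=FDTruth(
                    sample_stiffness=sample_stiffness,
                    spring_constant=k,
                    attraction_depth=attraction[i],
                    adhesion_depth=adhesion[i],
                ),
                tensile=TensileTruth(
                    elastic_modulus=e_mod[i],
                    yield_strain=yield_strain[i],
                    post_yield_modulus=post_mod[i],
                    fracture_strain=fracture[i],
                ),
                spectrum=_spectrum_truth({b: band_depths[b][i] for b in band_depths}),
            )
        )
    return CohortConfig(groups=tuple(groups), seed=seed)


def _truth_columns(group: GroupTruth) -> dict[str, object]:
    cols: dict[str, object] = {}
    for prefix, truth in (
        ("topo", group.topo),
        ("fd", group.fd),
        ("tensile", group.tensile),
    ):
        for key, value in asdict(truth).items():
            cols[f"{prefix}_{key}"] = value
    cols["fd_expected_slope"] = group.fd.contact_slope
    import json

    cols["ftir_bands_json"] = json.dumps(list(group.spectrum.bands))
    cols["ftir_baseline_slope"] = group.spectrum.baseline_slope
    cols["ftir_noise_sd"] = group.spectrum.noise_sd
    for name, (center, _w) in KERATIN_BAND_SHAPES.items():
        depth = 0.0
        for c, d, _ in group.spectrum.bands:
            if abs(c - center) < 1e-9:
                depth = d
        cols[f"ftir_{name}_depth"] = depth
    return cols


def gen_cohort(config: CohortConfig, root: str | Path) -> pd.DataFrame:
    """Write per-fiber files for all four modalities and return the manifest.

    Layout: ``<root>/<dye_count>/<fiber_id>.<modality>.txt`` with the manifest
    at ``<root>/manifest.csv``.  Fully reproducible from ``config.seed``:
    per-fiber, per-modality seeds are spawned from a SeedSequence so the same
    config always produces byte-identical datasets.
    """
    root = Path(root)
    try:
        root.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output root {root}: {exc}") from exc

    ss = np.random.SeedSequence(config.seed)
    rows = []
    for group in config.groups:
        gdir = root / str(group.dye_count)
        gdir.mkdir(exist_ok=True)
        for j in range(group.n_fibers):
            fiber_id = f"d{group.dye_count:02d}_f{j:02d}"
            seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]
            paths = {m: gdir / f"{fiber_id}.{m}.txt" for m in MODALITIES}

            topo = gen_topography(
                group.topo, config.topo_size, config.topo_pixel_size, seed=seeds[0]
            )
            fio.write_topography_txt(topo, paths["topo"])

            fd = gen_fd_curve(group.fd, config.fd_points, seed=seeds[1])
            fio.write_fd_txt(fd, paths["fd"])

            tens = gen_tensile_curve(group.tensile, config.tensile_points, seed=seeds[2])
            area_um2 = math.pi * (group.tensile.diameter / 2.0) ** 2
            force_mN = tens.stress * area_um2 * 1e-3  # MPa * um^2 -> mN
            fio.write_tensile_txt(tens, force_mN, paths["tensile"])

            spec = gen_spectrum(
                group.spectrum, config.spectrum_range, config.spectrum_resolution,
                seed=seeds[3],
            )
            fio.write_spectrum_txt(spec, paths["ftir"])

            row: dict[str, object] = {
                "fiber_id": fiber_id,
                "dye_count": group.dye_count,
            }
            for m in MODALITIES:
                row[f"{m}_path"] = str(paths[m].relative_to(root))
            row.update(_truth_columns(group))
            rows.append(row)

    manifest = pd.DataFrame(rows)
    fio.write_manifest(manifest, root / "manifest.csv")
    return manifest
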