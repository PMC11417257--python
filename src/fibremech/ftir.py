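"""FT-IR band quantification for keratin fibers.

Band intensity is measured as the transmittance dip depth below a *local
linear baseline* — the straight line through the transmittance at the band
window's endpoints.  A deeper dip means stronger absorption; the band center
is the wavenumber of maximum depth within the window.  Operating on depth
below a local baseline makes the measure reproducible regardless of the
instrument's global baseline or normalization, and no absorbance (-log T) or
ATR penetration-depth correction is applied: everything stays in %T.

The default eight-band table covers the amide I/II/III and amide B backbone
bands, the lipid and water bands near 3135 / 3277 cm^-1, the cysteic acid
S=O band at ~1036 cm^-1 (disulfide oxidation marker) and the 1575 cm^-1 NH2
scissoring band that appears only after dyeing as peptide bonds break.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import BandDefinition, BandQuantification, Spectrum
from .errors import InvalidParameterError
from .stats import percent_change, summarize, t_test

__all__ = [
    "DEFAULT_BANDS",
    "local_baseline",
    "quantify_band",
    "quantify_all",
    "band_trend",
    "spectrum_noise_estimate",
]

DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("amide_I", (1600.0, 1690.0)),
    BandDefinition("amide_II", (1480.0, 1575.0)),
    BandDefinition("amide_III", (1229.0, 1301.0)),
    BandDefinition("amide_B", (3030.0, 3102.0)),
    BandDefinition("lipid", (3104.0, 3170.0)),
    BandDefinition("water", (3200.0, 3350.0)),
    BandDefinition("cysteic_acid", (1020.0, 1060.0)),
    BandDefinition("nh2_1575", (1560.0, 1592.0)),
)


def _window_slice(spectrum: Spectrum, window: tuple[float, float]) -> slice:
    lo, hi = window
    if lo < spectrum.wavenumbers[0] or hi > spectrum.wavenumbers[-1]:
        raise InvalidParameterError(
            f"window {window} outside spectrum range "
            f"({spectrum.wavenumbers[0]}, {spectrum.wavenumbers[-1]})"
        )
    i0 = int(np.searchsorted(spectrum.wavenumbers, lo, side="left"))
    i1 = int(np.searchsorted(spectrum.wavenumbers, hi, side="right"))
    return slice(i0, i1)


def spectrum_noise_estimate(spectrum: Spectrum) -> float:
    """Robust noise sd (%T) from the median absolute first difference."""
    d = np.diff(spectrum.transmittance)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def _smooth(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return y
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(y, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[: len(y)]


def local_baseline(
    spectrum: Spectrum, window: tuple[float, float], smooth_width: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Local linear baseline over a band window.

    Returns (wavenumbers, baseline values): the straight line through the
    (optionally lightly smoothed) transmittance at the window endpoints.  The
    baseline is the 0-depth reference for the band.
    """
    sl = _window_slice(spectrum, window)
    nu = spectrum.wavenumbers[sl]
    if nu.size < 3:
        raise InvalidParameterError(f"window {window} spans fewer than 3 samples")
    t = _smooth(spectrum.transmittance, smooth_width)[sl]
    y0, y1 = t[0], t[-1]
    baseline = y0 + (y1 - y0) * (nu - nu[0]) / (nu[-1] - nu[0])
    return nu, baseline


def quantify_band(
    spectrum: Spectrum,
    band: BandDefinition,
    min_depth: float | None = None,
    smooth_width: int = 1,
) -> BandQuantification:
    """Quantify one band: center = wavenumber of maximum depth
    (baseline - transmittance) within the window; present when the depth
    reaches ``min_depth``.

    The default threshold is 3x the noise sd of a *depth reading*: a depth
    subtracts the chord through two noisy endpoints from a noisy point, so
    its sd is ~sqrt(2) times the spectrum noise estimate.

    A band counts as present only when at least one immediate neighbour of
    the deepest point also dips (>= min_depth/2): real vibrational bands are
    wider than one grid sample, single-point noise spikes are not, and a
    one-sided test tolerates bands sitting on a neighbouring band's shoulder.

    An absent band is a valid result (depth as measured, present=False).
    For two non-overlapping dips within one window the reported depth is the
    larger dip's depth (max rule).
    """
    if min_depth is None:
        min_depth = 3.0 * np.sqrt(2.0) * spectrum_noise_estimate(spectrum)
    sl = _window_slice(spectrum, band.window)
    nu, baseline = local_baseline(spectrum, band.window, smooth_width)
    t = _smooth(spectrum.transmittance, smooth_width)[sl]
    depth_curve = baseline - t
    i_max = int(np.argmax(depth_curve))
    depth = float(depth_curve[i_max])
    neighbours = depth_curve[max(i_max - 1, 0) : i_max + 2]
    neighbour_ok = bool(np.sum(neighbours >= 0.5 * min_depth) >= 2)  # peak + one side
    present = depth >= min_depth and neighbour_ok
    return BandQuantification(
        name=band.name,
        center=float(nu[i_max]),
        depth=max(depth, 0.0),
        present=present,
        window=band.window,
    )


def quantify_all(
    spectrum: Spectrum,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    min_depth: float | None = None,
    smooth_width: int = 1,
) -> list[BandQuantification]:
    """Quantify every band in the table, one result per band in stable order.

    Overlapping windows are allowed; duplicate names are not.
    """
    if not bands:
        raise InvalidParameterError("band table must be non-empty")
    names = [b.name for b in bands]
    if len(set(names)) != len(names):
        raise InvalidParameterError("duplicate band names in table")
    if min_depth is None:
        min_depth = 3.0 * np.sqrt(2.0) * spectrum_noise_estimate(spectrum)
    return [quantify_band(spectrum, b, min_depth, smooth_width) for b in bands]


def band_trend(
    depths: pd.DataFrame,
    control_group: int = 0,
) -> pd.DataFrame:
    """Dose-response trend table for band depths.

    ``depths`` has one row per fiber with columns ``dye_count`` and one column
    per band (depth in %T).  Returns, per band and dye count: n, mean +/- SEM,
    percent change vs control, Student's t and p vs control, and significance
    stars.  Requires at least two groups.
    """
    groups = sorted(depths["dye_count"].unique())
    if len(groups) < 2:
        raise InvalidParameterError("band_trend requires >= 2 groups")
    if control_group not in groups:
        raise InvalidParameterError(f"control group {control_group} missing")
    band_cols = [c for c in depths.columns if c != "dye_count"]
    rows = []
    for band in band_cols:
        control_vals = depths.loc[depths["dye_count"] == control_group, band].to_numpy()
        for g in groups:
            vals = depths.loc[depths["dye_count"] == g, band].to_numpy()
            summary = summarize(vals, group=g)
            if g == control_group:
                pct, comp = 0.0, None
            else:
                pct = percent_change(float(control_vals.mean()), float(vals.mean()))
                comp = t_test(control_vals, vals)
            rows.append(
                {
                    "band": band,
                    "dye_count": g,
                    "n": summary.n,
                    "mean_depth": summary.mean,
                    "sem": summary.sem,
                    "pct_change_vs_control": pct,
                    "p": comp.p if comp else np.nan,
                    "stars": comp.stars if comp else "",
                }
            )
    return pd.DataFrame(rows)
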