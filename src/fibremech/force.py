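"""Force-distance curve analysis: stiffness, adhesion and attraction.

A measurement cycle has five phases: approach at zero force, snap-in (the tip
jumps to contact under the attractive tip-sample force), contact loading up to
the setpoint, retraction with the tip held by adhesion, and pull-off.  The
attraction force is the snap-in dip depth on the approach branch; the adhesion
force is the pull-off dip depth on the retract branch; the stiffness is the
slope of force vs piezo displacement in the repulsive contact region.

The stiffness reported is the RAW force-vs-displacement slope, not corrected
for cantilever compliance: the slope of a cantilever (spring constant k) in
series with a sample of stiffness S is k*S/(k+S), which is bounded above by k.
A corrected sample stiffness (the series-spring inversion S = k*m/(k-m)) is
reported as a secondary field.
"""

from __future__ import annotations

import numpy as np

from .datatypes import FDFeatures, ForceDistanceCurve
from .errors import AnalysisError, InvalidParameterError

__all__ = [
    "baseline_correct",
    "detect_snap_in",
    "detect_pull_off",
    "fit_stiffness",
    "extract_features",
    "noise_estimate",
]

FAR_FRACTION = 0.25  # leading fraction of the approach treated as non-contact


def _ascending(branch: np.ndarray) -> np.ndarray:
    """Branch sorted by increasing displacement (toward the sample)."""
    if branch[0, 0] > branch[-1, 0]:
        return branch[::-1]
    return branch


def noise_estimate(branch: np.ndarray, fraction: float = FAR_FRACTION) -> float:
    """Robust (MAD-based) force-noise sd of the far-from-surface segment."""
    asc = _ascending(branch)
    n_far = max(5, int(len(asc) * fraction))
    far = asc[:n_far, 1]
    resid = far - np.polyval(np.polyfit(asc[:n_far, 0], far, 1), asc[:n_far, 0])
    mad = np.median(np.abs(resid - np.median(resid)))
    return float(1.4826 * mad)


def baseline_correct(curve: ForceDistanceCurve) -> ForceDistanceCurve:
    """Remove the zero-force reference: each branch has a linear fit of its
    own far-from-surface segment subtracted, so the far-segment mean force is
    zero afterward.  Fitting per branch keeps attraction a function of the
    approach only and adhesion of the retract only.

    Raises AnalysisError when no non-contact region can be identified (the
    far segment rises as steeply as the contact end, i.e. the whole curve is
    in contact).
    """
    asc = _ascending(curve.approach)
    n = len(asc)
    n_far = max(5, int(n * FAR_FRACTION))
    far = asc[:n_far]
    far_slope = np.polyfit(far[:, 0], far[:, 1], 1)[0]

    n_contact = max(5, int(n * 0.25))
    tail = asc[-n_contact:]
    contact_slope = np.polyfit(tail[:, 0], tail[:, 1], 1)[0]
    force_span = float(asc[:, 1].max() - asc[:, 1].min())
    if force_span > 0 and abs(far_slope) > 0.5 * abs(contact_slope) and abs(
        far_slope
    ) * (asc[-1, 0] - asc[0, 0]) > 0.1 * force_span:
        raise AnalysisError("cannot identify a non-contact region: curve appears fully in contact")

    def _corrected(branch: np.ndarray) -> np.ndarray:
        branch_asc = _ascending(branch)
        m = max(5, int(len(branch_asc) * FAR_FRACTION))
        coef = np.polyfit(branch_asc[:m, 0], branch_asc[:m, 1], 1)
        out = branch.copy()
        out[:, 1] = branch[:, 1] - np.polyval(coef, branch[:, 0])
        return out

    return ForceDistanceCurve(
        _corrected(curve.approach),
        _corrected(curve.retract),
        curve.spring_constant,
        source_id=curve.source_id,
    )


def detect_snap_in(approach: np.ndarray, noise_sd: float | None = None) -> tuple[float, bool]:
    """Attraction force from the snap-in dip of a baselined approach branch.

    Returns (attraction nN, detected).  The attraction is the magnitude of the
    minimum force on the branch (the contact region is repulsive, so the
    minimum lies in the pre-contact/snap-in portion); it is reported as 0 with
    ``detected=False`` when no excursion falls below -3x the noise sd.
    """
    forces = np.asarray(approach)[:, 1]
    if noise_sd is None:
        noise_sd = noise_estimate(np.asarray(approach))
    fmin = float(forces.min())
    if fmin < -3.0 * noise_sd:
        return -fmin, True
    return 0.0, False


def detect_pull_off(retract: np.ndarray, noise_sd: float | None = None) -> tuple[float, bool]:
    """Adhesion force from the pull-off dip of a baselined retract branch.

    Returns (adhesion nN, detected); 0 with ``detected=False`` when no dip
    exceeds 3x the noise sd.  Attraction and adhesion are independent: no
    ordering between them is imposed.
    """
    forces = np.asarray(retract)[:, 1]
    if noise_sd is None:
        noise_sd = noise_estimate(np.asarray(retract))
    fmin = float(forces.min())
    if fmin < -3.0 * noise_sd:
        return -fmin, True
    return 0.0, False


def fit_stiffness(
    approach: np.ndarray,
    fit_fraction: float = 0.7,
    noise_sd: float | None = None,
) -> tuple[float, float, float]:
    """Least-squares contact slope of a baselined approach branch.

    The contact point is the displacement at which the force first crosses
    +3x the noise sd after the snap-in minimum (a deterministic threshold
    rule); the stiffness is the slope of force vs displacement over the top
    ``fit_fraction`` of the contact region.  Returns (stiffness nN/nm,
    contact_point nm, R^2).
    """
    if not 0 < fit_fraction <= 1:
        raise InvalidParameterError("fit_fraction must be in (0, 1]")
    asc = _ascending(np.asarray(approach))
    z, f = asc[:, 0], asc[:, 1]
    if noise_sd is None:
        noise_sd = noise_estimate(asc)
    i_min = int(np.argmin(f))
    threshold = 3.0 * noise_sd
    after = np.nonzero(f[i_min:] > threshold)[0]
    if after.size == 0:
        raise AnalysisError("no contact region: force never exceeds the noise threshold")
    i_contact = i_min + int(after[0])
    contact_point = float(z[i_contact])
    zc, fc = z[i_contact:], f[i_contact:]
    if len(zc) < 10:
        raise AnalysisError(f"contact region too short ({len(zc)} points; need >= 10)")
    n_fit = max(5, int(round(len(zc) * fit_fraction)))
    zf, ff = zc[-n_fit:], fc[-n_fit:]
    coef = np.polyfit(zf, ff, 1)
    pred = np.polyval(coef, zf)
    ss_res = float(np.sum((ff - pred) ** 2))
    ss_tot = float(np.sum((ff - ff.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(coef[0]), contact_point, r2


def extract_features(
    curve: ForceDistanceCurve,
    fit_fraction: float = 0.7,
    use_retract_for_stiffness: bool = False,
) -> FDFeatures:
    """Full per-curve feature extraction: baseline correction, then snap-in,
    pull-off and contact-slope fitting.

    The extracted stiffness respects the series-spring bound (slope <= k); a
    noisy fit marginally above k is clipped to k.  The corrected sample
    stiffness k*m/(k-m) is reported alongside (inf at the rigid limit).
    """
    try:
        corrected = baseline_correct(curve)
    except AnalysisError as exc:
        raise AnalysisError(f"curve {curve.source_id!r}: {exc}") from exc

    sigma_app = noise_estimate(corrected.approach)
    sigma_ret = noise_estimate(corrected.retract)
    attraction, att_detected = detect_snap_in(corrected.approach, sigma_app)
    adhesion, adh_detected = detect_pull_off(corrected.retract, sigma_ret)
    branch = corrected.retract if use_retract_for_stiffness else corrected.approach
    try:
        slope, contact_point, r2 = fit_stiffness(branch, fit_fraction, sigma_app)
    except AnalysisError as exc:
        raise AnalysisError(f"curve {curve.source_id!r}: {exc}") from exc
    if slope <= 0:
        raise AnalysisError(f"curve {curve.source_id!r}: non-positive contact slope")

    k = curve.spring_constant
    stiffness = min(slope, k)
    sample = float("inf") if stiffness >= k else k * stiffness / (k - stiffness)
    return FDFeatures(
        stiffness=stiffness,
        adhesion=adhesion,
        attraction=attraction,
        contact_point=contact_point,
        fit_quality=r2,
        sample_stiffness=sample,
        attraction_detected=att_detected,
        adhesion_detected=adh_detected,
        low_fit_quality=r2 < 0.9,
        source_id=curve.source_id,
    )
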