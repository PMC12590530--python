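"""Force-curve calibration, contact-point detection, Sneddon fitting, map QC.

The per-curve model is a rigid cone indenting an incompressible elastic
half-space: F = (2/pi) tan(theta) E / (1 - nu^2) * delta^2, with the
indentation delta = (z - z0) - (d - d0) correcting piezo travel for cantilever
bending.  The fit is linearized (F regressed on delta^2 through the origin),
which is convex, deterministic and easy to cross-check by brute force.  Only
the approach segment is analyzed; samples above the force cap (default
1.8 nN, the maximum applied load) are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .synth import CantileverModel, ForceCurve, ForceMap, sneddon_coefficient

__all__ = [
    "ContactPoint",
    "SneddonFit",
    "ElasticityMap",
    "QCConfig",
    "REJECT_CODES",
    "calibrate",
    "detect_contact_point",
    "fit_sneddon",
    "analyze_map",
]

# rejection reason codes stored per masked-out pixel
REJECT_CODES = {
    0: "ok",
    1: "non_contact",
    2: "not_converged",
    3: "nonpositive_modulus",
    4: "low_r_squared",
}


@dataclass(frozen=True)
class ContactPoint:
    """Piecewise-model contact point: linear baseline before, cone after."""

    z0: float
    d0: float
    index: int
    baseline_slope: float
    baseline_intercept: float
    is_contact: bool
    improvement: float  # fractional SSR reduction vs all-baseline model


@dataclass(frozen=True)
class SneddonFit:
    e_kpa: float
    contact_point_z0: float
    contact_deflection_d0: float
    nu: float
    theta: float
    r_squared: float
    max_indentation: float
    n_fit: int
    converged: bool
    reject_code: int = 0

    @property
    def e_pa(self) -> float:
        return self.e_kpa * 1000.0


@dataclass
class QCConfig:
    """Map-level quality control thresholds (conservative, configurable)."""

    r_squared_min: float = 0.80
    min_post_contact: int = 10
    max_reject_fraction: float = 0.5


@dataclass
class ElasticityMap:
    """QC-masked grid of fitted Young's moduli (kPa)."""

    e_kpa: np.ndarray
    qc_mask: np.ndarray
    reject_codes: np.ndarray
    pixel_size: float
    specimen_id: str = ""
    map_index: int = 0
    r_squared: np.ndarray | None = None
    flagged_unusable: bool = False

    @property
    def n_pass(self) -> int:
        return int(self.qc_mask.sum())

    @property
    def n_reject(self) -> int:
        return int((~self.qc_mask).sum())

    def passing_values(self) -> np.ndarray:
        return self.e_kpa[self.qc_mask]

    def rejection_stats(self) -> dict[str, int]:
        return {
            name: int((self.reject_codes == code).sum())
            for code, name in REJECT_CODES.items()
            if code != 0
        }


def calibrate(curve: ForceCurve, sensitivity: float | None = None,
              spring_constant: float | None = None) -> ForceCurve:
    """Convert a raw (volt) curve to nm deflection and attach the force channel.

    deflection_nm = V * sensitivity [nm/V]; force_nN = k [N/m] * deflection_nm.
    Idempotent on already-calibrated curves.  Calibration constants must be
    supplied either explicitly or on the curve's cantilever — never defaulted
    silently.
    """
    if curve.is_calibrated:
        return curve
    sens = sensitivity if sensitivity is not None else curve.cantilever.deflection_sensitivity
    k = spring_constant if spring_constant is not None else curve.cantilever.spring_constant
    if sens is None or sens <= 0 or k is None or k <= 0:
        raise ValueError("calibration requires positive sensitivity and spring constant")
    from dataclasses import replace as dc_replace

    cant = dc_replace(curve.cantilever, deflection_sensitivity=sens, spring_constant=k)
    return ForceCurve(
        z=curve.z,
        deflection=np.asarray(curve.deflection_v, dtype=float) * sens,
        cantilever=cant,
        map_index=curve.map_index,
        grid_position=curve.grid_position,
        truth=curve.truth,
    )


def _baseline_fit(z: np.ndarray, d: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line d = a*z + b; returns (a, b, ssr)."""
    n = z.size
    zm = z.mean()
    dm = d.mean()
    zc = z - zm
    denom = float(zc @ zc)
    a = float(zc @ (d - dm)) / denom if denom > 0 else 0.0
    b = dm - a * zm
    resid = d - (a * z + b)
    return a, b, float(resid @ resid)


def _piecewise_ssr(z: np.ndarray, d: np.ndarray, j: int) -> float:
    """Total SSR of {linear baseline on [0, j)} + {cone on [j, n)}.

    The cone segment fits baseline-corrected deflection dc = amp * delta^2
    with delta = (z - z0) - dc, amplitude constrained non-negative.
    """
    a, b, ssr_pre = _baseline_fit(z[:j], d[:j])
    z0 = z[j]
    dc = d[j:] - (a * z[j:] + b)
    delta = np.clip((z[j:] - z0) - dc, 0.0, None)
    d2 = delta * delta
    denom = float(d2 @ d2)
    amp = max(float(d2 @ dc) / denom, 0.0) if denom > 0 else 0.0
    resid = dc - amp * d2
    return ssr_pre + float(resid @ resid)


def detect_contact_point(curve: ForceCurve, min_pre: int = 20,
                         min_post: int = 10,
                         improvement_threshold: float = 0.05) -> ContactPoint:
    """Locate the tip-sample contact point by a piecewise residual scan.

    Every candidate split index j is scored by the total squared residual of a
    linear baseline before j plus a Sneddon quadratic after j; the scan is
    coarse-to-fine.  If the best split barely improves on the all-baseline
    model the curve is flagged non-contact.
    """
    if not curve.is_calibrated:
        raise ValueError("curve must be calibrated before contact detection")
    z = curve.z if curve.z[0] < curve.z[-1] else curve.z[::-1]
    d = curve.deflection if curve.z[0] < curve.z[-1] else curve.deflection[::-1]
    n = z.size
    if n < min_pre + min_post:
        raise ValueError("curve too short for contact detection")

    lo, hi = min_pre, n - min_post
    step = max(1, (hi - lo) // 64)
    coarse = list(range(lo, hi, step))
    ssrs = [_piecewise_ssr(z, d, j) for j in coarse]
    j_best = coarse[int(np.argmin(ssrs))]

    fine_lo = max(lo, j_best - step)
    fine_hi = min(hi, j_best + step + 1)
    fine = range(fine_lo, fine_hi)
    fine_ssrs = [_piecewise_ssr(z, d, j) for j in fine]
    j_star = fine_lo + int(np.argmin(fine_ssrs))
    best_ssr = min(fine_ssrs)

    a_all, b_all, ssr_all = _baseline_fit(z, d)
    scale = float(np.mean(np.square(d - d.mean()))) * n + 1e-30
    if ssr_all <= 1e-12 * scale:
        # the whole record is a perfect line: nothing was touched
        is_contact = False
        improvement = 0.0
    else:
        improvement = (ssr_all - best_ssr) / ssr_all
        is_contact = improvement > improvement_threshold

    a, b, _ = _baseline_fit(z[:j_star], d[:j_star])
    z0 = float(z[j_star])
    d0 = float(a * z0 + b)
    return ContactPoint(
        z0=z0,
        d0=d0,
        index=j_star,
        baseline_slope=a,
        baseline_intercept=b,
        is_contact=is_contact,
        improvement=float(improvement),
    )


def fit_sneddon(
    curve: ForceCurve,
    theta: float | None = None,
    nu: float = 0.5,
    force_cap: float = 1.8,
    contact: ContactPoint | None = None,
    min_post: int = 10,
) -> SneddonFit:
    """Fit the conical-indenter model to one calibrated approach curve.

    E (kPa) is the slope of the through-origin regression of force (nN) on
    squared indentation (nm^2), divided by the geometry factor; r_squared is
    reported on that same F-vs-delta^2 fit.  Only post-contact samples with
    positive indentation and force at or below ``force_cap`` enter the fit.
    """
    if not curve.is_calibrated:
        raise ValueError("curve must be calibrated before fitting")
    theta = theta if theta is not None else curve.cantilever.half_open_angle_theta
    if contact is None:
        contact = detect_contact_point(curve, min_post=min_post)
    if not contact.is_contact:
        return SneddonFit(
            e_kpa=float("nan"), contact_point_z0=contact.z0,
            contact_deflection_d0=contact.d0, nu=nu, theta=theta,
            r_squared=0.0, max_indentation=0.0, n_fit=0,
            converged=False, reject_code=1,
        )

    z = curve.z
    d = curve.deflection
    k = curve.cantilever.spring_constant
    dc = d - (contact.baseline_slope * z + contact.baseline_intercept)
    post = slice(contact.index, None)
    delta = (z[post] - contact.z0) - dc[post]
    force = k * dc[post]
    sel = (delta > 0) & (force <= force_cap)
    delta = delta[sel]
    force = force[sel]
    if delta.size < min_post:
        return SneddonFit(
            e_kpa=float("nan"), contact_point_z0=contact.z0,
            contact_deflection_d0=contact.d0, nu=nu, theta=theta,
            r_squared=0.0, max_indentation=0.0, n_fit=int(delta.size),
            converged=False, reject_code=2,
        )

    d2 = delta * delta
    slope = float(d2 @ force) / float(d2 @ d2)
    e_kpa = slope / (sneddon_coefficient(theta, nu) * 1e-6)
    resid = force - slope * d2
    sst = float(np.sum(np.square(force - force.mean())))
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 1.0
    r2 = float(min(max(r2, 0.0), 1.0))
    converged = bool(np.isfinite(e_kpa) and e_kpa > 0)
    return SneddonFit(
        e_kpa=float(e_kpa),
        contact_point_z0=contact.z0,
        contact_deflection_d0=contact.d0,
        nu=nu,
        theta=theta,
        r_squared=r2,
        max_indentation=float(delta.max()),
        n_fit=int(delta.size),
        converged=converged,
        reject_code=0 if converged else 3,
    )


def analyze_map(
    force_map: ForceMap,
    qc: QCConfig | None = None,
    theta: float | None = None,
    nu: float = 0.5,
    force_cap: float = 1.8,
    specimen_id: str = "",
) -> ElasticityMap:
    """Fit every curve of a force map and assemble the QC-masked modulus grid.

    Pixels failing the fit (non-contact, non-converged, E <= 0, low r^2) are
    masked with a reason code; a map rejecting more than half its pixels is
    flagged unusable but retained.
    """
    qc = qc or QCConfig()
    g = force_map.grid_points
    e = np.full((g, g), np.nan)
    r2 = np.zeros((g, g))
    codes = np.zeros((g, g), dtype=int)
    for curve in force_map.curves:
        if not curve.is_calibrated:
            raise ValueError("all curves must be calibrated before map analysis")
        i, j = curve.grid_position
        fit = fit_sneddon(curve, theta=theta, nu=nu, force_cap=force_cap,
                          min_post=qc.min_post_contact)
        r2[i, j] = fit.r_squared
        if not fit.converged:
            codes[i, j] = fit.reject_code
            continue
        if fit.r_squared < qc.r_squared_min:
            codes[i, j] = 4
            continue
        e[i, j] = fit.e_kpa
    mask = codes == 0
    reject_fraction = 1.0 - mask.mean()
    return ElasticityMap(
        e_kpa=e,
        qc_mask=mask,
        reject_codes=codes,
        pixel_size=force_map.pixel_size,
        specimen_id=specimen_id,
        map_index=force_map.map_index,
        r_squared=r2,
        flagged_unusable=bool(reject_fraction > qc.max_reject_fraction),
    )
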