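"""TG-43U1 line-source dose calculation for HDR Ir-192 afterloading plans.

Implements the standard AAPM TG-43 (updated) factorization of the dose rate
around a cylindrically symmetric source,

    D-rate(r, theta) = S_k * Lambda * G_L(r, theta) / G_L(1 cm, 90 deg)
                       * g(r) * F(r, theta),

where ``S_k`` is the air-kerma strength (U = cGy cm^2 h^-1), ``Lambda`` the
dose-rate constant (cGy h^-1 U^-1), ``G_L`` the line-source geometry function,
``g`` the radial dose function and ``F`` the 2D anisotropy function.  The
radial and anisotropy data live in swappable :class:`SourceDescription`
tables so that different source-model data files (mHDR-v2 style variants)
can be exchanged without touching the dose code.

Coordinates are millimetres internally; radii are converted to centimetres
for the table lookups; total doses are returned in Gy.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Sequence

import numba
import numpy as np

__all__ = [
    "SourceDescription",
    "DwellPosition",
    "Plan",
    "SingularGeometryError",
    "geometry_function_line",
    "interpolate_radial",
    "interpolate_anisotropy",
    "decayed_strength",
    "dose_rate_at_point",
    "total_dose",
]

MM_PER_CM = 10.0
#: cGy/h -> Gy/s conversion: 1 cGy = 0.01 Gy, 1 h = 3600 s.
CGY_PER_H_TO_GY_PER_S = 0.01 / 3600.0
#: Points closer than this to the active source segment are flagged (mm).
NEAR_SOURCE_MM = 0.5


class SingularGeometryError(ValueError):
    """Evaluation point lies on the active source segment."""


class ConfigurationError(ValueError):
    """Source-description table is malformed."""


@dataclass(frozen=True)
class SourceDescription:
    """TG-43 dosimetric description of one HDR source model.

    Parameters
    ----------
    model_id:
        Label such as ``"mHDR-v2"``.
    active_length_mm:
        Length of the active source core, mm.
    dose_rate_constant:
        Lambda, cGy h^-1 U^-1.
    radial_r_cm, radial_g:
        Radial dose function table g(r), r strictly increasing, g(1 cm) = 1.
    aniso_r_cm, aniso_theta_deg, aniso_f:
        2D anisotropy function F(r, theta) on a rectangular grid;
        ``aniso_f`` has shape (len(aniso_r_cm), len(aniso_theta_deg)) and
        F(r, 90 deg) = 1.
    half_life_days:
        Radionuclide half-life (Ir-192: 73.83 d).
    """

    model_id: str
    active_length_mm: float
    dose_rate_constant: float
    radial_r_cm: np.ndarray
    radial_g: np.ndarray
    aniso_r_cm: np.ndarray
    aniso_theta_deg: np.ndarray
    aniso_f: np.ndarray
    half_life_days: float = 73.83

    def __post_init__(self) -> None:
        r = np.asarray(self.radial_r_cm, dtype=float)
        g = np.asarray(self.radial_g, dtype=float)
        if r.size == 0:
            raise ConfigurationError("empty radial table")
        if np.any(np.diff(r) <= 0):
            raise ConfigurationError("radial table r values must be strictly increasing")
        ar = np.asarray(self.aniso_r_cm, dtype=float)
        at = np.asarray(self.aniso_theta_deg, dtype=float)
        af = np.asarray(self.aniso_f, dtype=float)
        if af.shape != (ar.size, at.size):
            raise ConfigurationError("anisotropy grid is not rectangular")
        if self.half_life_days <= 0:
            raise ConfigurationError("half_life_days must be positive")
        object.__setattr__(self, "radial_r_cm", r)
        object.__setattr__(self, "radial_g", g)
        object.__setattr__(self, "aniso_r_cm", ar)
        object.__setattr__(self, "aniso_theta_deg", at)
        object.__setattr__(self, "aniso_f", af)

    @property
    def active_length_cm(self) -> float:
        return self.active_length_mm / MM_PER_CM


@dataclass(frozen=True)
class DwellPosition:
    """One source stopping point: location, catheter tangent and dwell time."""

    position_mm: np.ndarray  # shape (3,)
    axis_direction: np.ndarray  # unit vector, shape (3,)
    dwell_time_s: float
    catheter_id: str = "0"

    def __post_init__(self) -> None:
        p = np.asarray(self.position_mm, dtype=float)
        a = np.asarray(self.axis_direction, dtype=float)
        n = np.linalg.norm(a)
        if not np.isfinite(n) or n == 0:
            raise ValueError("axis_direction must be a nonzero vector")
        if self.dwell_time_s < 0:
            raise ValueError("dwell_time_s must be >= 0")
        object.__setattr__(self, "position_mm", p)
        object.__setattr__(self, "axis_direction", a / n)


@dataclass
class Plan:
    """A multi-dwell treatment plan with source-strength calibration."""

    dwells: list[DwellPosition]
    air_kerma_strength_U: float
    calibration_date: date
    treatment_date: date

    def __post_init__(self) -> None:
        if not any(d.dwell_time_s > 0 for d in self.dwells):
            raise ValueError("plan needs at least one dwell with positive time")
        if self.treatment_date < self.calibration_date:
            raise ValueError("treatment_date must be on or after calibration_date")

    def positions(self) -> np.ndarray:
        return np.array([d.position_mm for d in self.dwells])

    def axes(self) -> np.ndarray:
        return np.array([d.axis_direction for d in self.dwells])

    def times(self) -> np.ndarray:
        return np.array([d.dwell_time_s for d in self.dwells])

    def scaled(self, factor: float) -> "Plan":
        """Return a copy with every dwell time multiplied by ``factor``."""
        dwells = [
            DwellPosition(d.position_mm, d.axis_direction, d.dwell_time_s * factor, d.catheter_id)
            for d in self.dwells
        ]
        return Plan(dwells, self.air_kerma_strength_U, self.calibration_date, self.treatment_date)


def geometry_function_line(r_cm, theta_deg, active_length_cm: float):
    """Line-source geometry function G_L(r, theta), cm^-2.

    ``G_L = beta / (L r sin(theta))`` with ``beta`` the angle subtended at the
    point by the active line of length ``L``; on the source long axis
    (sin(theta) = 0) the limit ``1 / (r^2 - L^2/4)`` is used.  ``L -> 0``
    recovers the point-source kernel ``1/r^2``.

    Accepts scalars or arrays (broadcast together).  Scalar input raises
    :class:`SingularGeometryError` for points on the active segment itself.
    """
    r = np.asarray(r_cm, dtype=float)
    theta = np.asarray(theta_deg, dtype=float)
    scalar = r.ndim == 0 and theta.ndim == 0
    r, theta = np.broadcast_arrays(np.atleast_1d(r), np.atleast_1d(theta))
    L = float(active_length_cm)
    if L <= 0:
        out = 1.0 / r**2
        return float(out[0]) if scalar else out

    th = np.radians(theta)
    half = L / 2.0
    # Components of the point relative to the source centre in the plane
    # spanned by the source axis (z') and the perpendicular direction.
    z = r * np.cos(th)
    rho = r * np.sin(th)
    # beta = angle between the vectors from the point to the two segment ends.
    beta = np.arctan2(rho, z - half) - np.arctan2(rho, z + half)
    with np.errstate(divide="ignore", invalid="ignore"):
        g_line = beta / (L * rho)
        g_axis = 1.0 / (r**2 - half**2)
    on_axis = rho < 1e-12 * np.maximum(r, 1.0)
    out = np.where(on_axis, g_axis, g_line)
    singular = on_axis & (r <= half)
    if scalar:
        if singular[0]:
            raise SingularGeometryError(
                f"point at r={float(r[0]):g} cm lies on the active segment (L={L:g} cm)"
            )
        return float(out[0])
    return out


def interpolate_radial(source: SourceDescription, r_cm):
    """g(r): linear interpolation in r, clamped to the table end values."""
    r = np.clip(np.asarray(r_cm, dtype=float), source.radial_r_cm[0], source.radial_r_cm[-1])
    out = np.interp(r, source.radial_r_cm, source.radial_g)
    return float(out) if np.ndim(r_cm) == 0 else out


def interpolate_anisotropy(source: SourceDescription, r_cm, theta_deg):
    """F(r, theta): bilinear interpolation on the grid, clamped at the edges."""
    ar, at, af = source.aniso_r_cm, source.aniso_theta_deg, source.aniso_f
    r = np.clip(np.asarray(r_cm, dtype=float), ar[0], ar[-1])
    t = np.clip(np.asarray(theta_deg, dtype=float), at[0], at[-1])
    r, t = np.broadcast_arrays(r, t)
    ir = np.clip(np.searchsorted(ar, r, side="right"), 1, ar.size - 1)
    it = np.clip(np.searchsorted(at, t, side="right"), 1, at.size - 1)
    wr = (r - ar[ir - 1]) / (ar[ir] - ar[ir - 1])
    wt = (t - at[it - 1]) / (at[it] - at[it - 1])
    out = (
        (1 - wr) * (1 - wt) * af[ir - 1, it - 1]
        + (1 - wr) * wt * af[ir - 1, it]
        + wr * (1 - wt) * af[ir, it - 1]
        + wr * wt * af[ir, it]
    )
    scalar = np.ndim(r_cm) == 0 and np.ndim(theta_deg) == 0
    return float(out.ravel()[0]) if scalar else out


def decayed_strength(plan: Plan, source: SourceDescription) -> float:
    """Air-kerma strength at treatment: S_k(0) * 2^(-dt / half_life)."""
    dt_days = (plan.treatment_date - plan.calibration_date).days
    return plan.air_kerma_strength_U * 2.0 ** (-dt_days / source.half_life_days)


def _polar_coords(points_mm: np.ndarray, dwell_pos_mm: np.ndarray, axis: np.ndarray):
    """(r in cm, theta in deg, distance to active segment in mm)."""
    vec = points_mm - dwell_pos_mm  # (n, 3)
    dist_mm = np.linalg.norm(vec, axis=-1)
    r_cm = dist_mm / MM_PER_CM
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = (vec @ axis) / np.where(dist_mm > 0, dist_mm, np.nan)
    theta = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
    return r_cm, theta, dist_mm


def _segment_distance_mm(points_mm, dwell_pos_mm, axis, half_len_mm):
    """Distance from points to the active source segment, mm."""
    vec = points_mm - dwell_pos_mm
    z = vec @ axis
    z_clamped = np.clip(z, -half_len_mm, half_len_mm)
    closest = dwell_pos_mm + np.outer(z_clamped, axis)
    return np.linalg.norm(points_mm - closest, axis=-1)


def dose_rate_at_point(
    dwell: DwellPosition,
    point_mm: Sequence[float],
    source: SourceDescription,
    strength_U: float,
) -> tuple[float, bool]:
    """Dose rate (cGy/h) at one point from one dwell, plus a near-source flag.

    The flag is True when the point lies within 0.5 mm of the active source
    segment; the value is still computed (the kernel is finite off the
    segment) and the caller decides whether to exclude such points.
    """
    p = np.asarray(point_mm, dtype=float)[None, :]
    L_cm = source.active_length_cm
    r, theta, _ = _polar_coords(p, dwell.position_mm, dwell.axis_direction)
    if r[0] == 0:
        raise SingularGeometryError("point coincides with the dwell position")
    g_l = geometry_function_line(r, theta, L_cm)
    g0 = geometry_function_line(1.0, 90.0, L_cm)
    rate = (
        strength_U
        * source.dose_rate_constant
        * (g_l / g0)
        * interpolate_radial(source, r)
        * interpolate_anisotropy(source, r, theta)
    )
    seg = _segment_distance_mm(p, dwell.position_mm, dwell.axis_direction, source.active_length_mm / 2)
    return float(rate[0]), bool(seg[0] < NEAR_SOURCE_MM)


@numba.njit(cache=False, fastmath=True)
def _dose_kernel(pts, pos, axs, times, L_cm, g0, r_tab, g_tab, ar, at, af, near_mm2):
    """Sum of dwell-time-weighted TG-43 kernels per point (unit strength,
    unit dose-rate constant); also flags points near any active segment."""
    n = pts.shape[0]
    m = pos.shape[0]
    out = np.zeros(n)
    near = np.zeros(n, dtype=numba.boolean)
    half = L_cm / 2.0
    half_mm = half * 10.0
    nr, nt = ar.size, at.size
    for i in range(n):
        acc = 0.0
        for j in range(m):
            t = times[j]
            if t == 0.0:
                continue
            dx = (pts[i, 0] - pos[j, 0]) * 0.1
            dy = (pts[i, 1] - pos[j, 1]) * 0.1
            dz = (pts[i, 2] - pos[j, 2]) * 0.1
            r2 = dx * dx + dy * dy + dz * dz
            r = np.sqrt(r2)
            zc = dx * axs[j, 0] + dy * axs[j, 1] + dz * axs[j, 2]
            rho2 = r2 - zc * zc
            rho = np.sqrt(rho2) if rho2 > 0.0 else 0.0
            # geometry function G_L
            if rho < 1e-12 * (r if r > 1.0 else 1.0):
                gl = 1.0 / (r2 - half * half)
            else:
                beta = np.arctan2(rho, zc - half) - np.arctan2(rho, zc + half)
                gl = beta / (L_cm * rho)
            # distance to the active segment (near-source flag), mm
            zc_mm = zc * 10.0
            zcl = min(max(zc_mm, -half_mm), half_mm)
            seg2 = r2 * 100.0 - 2.0 * zc_mm * zcl + zcl * zcl
            if seg2 < near_mm2:
                near[i] = True
            # radial dose function, clamped linear interpolation
            rc = min(max(r, r_tab[0]), r_tab[-1])
            k = 1
            while k < r_tab.size - 1 and r_tab[k] < rc:
                k += 1
            g = g_tab[k - 1] + (g_tab[k] - g_tab[k - 1]) * (rc - r_tab[k - 1]) / (
                r_tab[k] - r_tab[k - 1]
            )
            # anisotropy, clamped bilinear interpolation
            ct = zc / r if r > 0.0 else 1.0
            if ct > 1.0:
                ct = 1.0
            elif ct < -1.0:
                ct = -1.0
            theta = np.degrees(np.arccos(ct))
            rc2 = min(max(r, ar[0]), ar[-1])
            tc = min(max(theta, at[0]), at[-1])
            p = 1
            while p < nr - 1 and ar[p] < rc2:
                p += 1
            q = 1
            while q < nt - 1 and at[q] < tc:
                q += 1
            wr = (rc2 - ar[p - 1]) / (ar[p] - ar[p - 1])
            wt = (tc - at[q - 1]) / (at[q] - at[q - 1])
            f = (
                (1 - wr) * (1 - wt) * af[p - 1, q - 1]
                + (1 - wr) * wt * af[p - 1, q]
                + wr * (1 - wt) * af[p, q - 1]
                + wr * wt * af[p, q]
            )
            acc += t * (gl / g0) * g * f
        out[i] = acc
    return out, near


def total_dose(
    plan: Plan,
    source: SourceDescription,
    points_mm: np.ndarray,
    return_near_source: bool = False,
):
    """Total absorbed dose (Gy) at each point from all dwells of a plan.

    Superposes the TG-43 line-source dose rate over every dwell, applying the
    source decay from calibration to treatment date, and converts
    cGy/h x s to Gy.  Linear in dwell times and in source strength.

    Parameters
    ----------
    points_mm : (n, 3) array
    return_near_source : also return a boolean mask of points within 0.5 mm
        of any active source segment (the validation-exclusion criterion;
        by default such points are kept and evaluated).
    """
    pts = np.ascontiguousarray(np.atleast_2d(np.asarray(points_mm, dtype=float)))
    strength = decayed_strength(plan, source)
    L_cm = source.active_length_cm
    g0 = geometry_function_line(1.0, 90.0, L_cm)
    acc, near = _dose_kernel(
        pts,
        np.ascontiguousarray(plan.positions()),
        np.ascontiguousarray(plan.axes()),
        np.ascontiguousarray(plan.times()),
        L_cm,
        g0,
        source.radial_r_cm,
        source.radial_g,
        source.aniso_r_cm,
        source.aniso_theta_deg,
        source.aniso_f,
        NEAR_SOURCE_MM**2,
    )
    dose = acc * (strength * source.dose_rate_constant * CGY_PER_H_TO_GY_PER_S)
    if return_near_source:
        return dose, near
    return dose
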