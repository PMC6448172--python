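"""Synthetic HDR prostate brachytherapy patients.

Generates reproducible phantom cohorts — structure sets plus dwell plans —
with the geometric and dosimetric structure the sensitivity analysis
assumes:

* organ volumes inside the clinical ranges (prostate ~16-71 cm³, bladder
  ~45-265 cm³, rectum ~23-109 cm³, urethra ~0.5-3.8 cm³, vesicles
  ~0.5-11.8 cm³), delineated at a 3.3 mm slice thickness;
* a urethra tube overlapping the prostate on shared slices and extending
  into the bladder (it is delineated as the urinary catheter);
* seminal vesicles with only a few (2-4) delineated contours — only the
  base is delineated clinically;
* a bladder sitting on the prostate base whose most irradiated 1-2 cm³
  lies at its most caudal contour;
* 14-20 near-parallel catheters with activated dwell positions in the
  250-668 range, dwell times set by an urethra-sparing heuristic and
  globally scaled so that D90% prostate matches the 13 Gy planning aim.

Organs are randomized superellipsoids: anatomical fidelity is not the goal,
only the volume, adjacency and contour-count structure that the computation
settings act on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
from scipy.special import gamma as _gamma

from .geometry import Contour, RoiSettings, StructureSet, build_roi_model
from .indices import dose_index_relative
from .sampling import SamplingConfig, sample_points
from .tg43 import DwellPosition, Plan, SourceDescription, total_dose

__all__ = [
    "PhantomConfig",
    "SyntheticPatient",
    "GenerationFailure",
    "generate_patient",
    "generate_cohort",
    "place_catheters_and_dwells",
    "thin_plan",
]

TWO_PI = 2.0 * np.pi


class GenerationFailure(RuntimeError):
    """The phantom generator could not satisfy its constraints."""


@dataclass(frozen=True)
class PhantomConfig:
    """Cohort-level generation parameters (volumes in cm³, lengths in mm)."""

    seed: int = 1
    n_patients: int = 26
    prostate_volume_range: tuple[float, float] = (20.0, 60.0)
    bladder_volume_range: tuple[float, float] = (60.0, 180.0)
    rectum_volume_range: tuple[float, float] = (35.0, 80.0)
    vesicle_volume_range: tuple[float, float] = (1.5, 6.0)
    urethra_radius_mm: float = 3.25
    slice_thickness_mm: float = 3.3
    catheter_range: tuple[int, int] = (14, 20)
    dwell_spacing_mm: float = 2.0
    dwell_margin_mm: float = 3.0
    caudal_bladder_hotspot: bool = True
    few_slice_vesicles: bool = True
    prescription_gy: float = 13.0
    #: air-kerma strength at calibration and decay interval to treatment
    strength_U: float = 20_000.0
    decay_days: int = 14
    #: points used when scaling dwell times to the planning aim
    scaling_points: int = 32_000


@dataclass
class SyntheticPatient:
    """One phantom: contours, plan and the provenance that reproduces it."""

    patient_id: str
    structure_set: StructureSet
    plan: Plan
    config: PhantomConfig
    patient_seed: int


def _patient_rng(config: PhantomConfig, index: int) -> np.random.Generator:
    return np.random.Generator(np.random.MT19937(np.random.SeedSequence([config.seed, index])))


def _superellipse_ring(a: float, b: float, exponent: float, n: int = 64) -> np.ndarray:
    """Vertices of |x/a|^e + |y/b|^e = 1, counter-clockwise."""
    phi = np.linspace(0.0, TWO_PI, n, endpoint=False)
    c, s = np.cos(phi), np.sin(phi)
    x = a * np.sign(c) * np.abs(c) ** (2.0 / exponent)
    y = b * np.sign(s) * np.abs(s) ** (2.0 / exponent)
    return np.column_stack([x, y])


def _superellipsoid_volume_unit(exponent: float, c: float) -> float:
    """Volume of the superellipsoid with a = b = 1 and half-height c."""
    # cross-section area at height z: A(z) = A0 * (1 - |z/c|^e)^(2/e),
    # A0 = area of the unit superellipse with exponent e.
    a0 = 4.0 * _gamma(1 + 1 / exponent) ** 2 / _gamma(1 + 2 / exponent)
    zs = np.linspace(-c, c, 2001)
    prof = (1.0 - np.abs(zs / c) ** exponent) ** (2.0 / exponent)
    return a0 * float(np.trapezoid(prof, zs))


def _perturbed(ring: np.ndarray, rng: np.random.Generator, amp: float = 0.05) -> np.ndarray:
    """Smooth low-harmonic radial perturbation of a star-shaped ring."""
    phi = np.arctan2(ring[:, 1], ring[:, 0])
    factor = np.ones(len(ring))
    for k in (2, 3, 4):
        factor += amp / k * rng.uniform(-1, 1) * np.cos(k * phi + rng.uniform(0, TWO_PI))
    return ring * factor[:, None]


def _slice_grid(z_min: float, z_max: float, dz: float, offset: float) -> np.ndarray:
    """Slice heights offset + k*dz falling inside [z_min, z_max]."""
    k0 = int(np.ceil((z_min - offset) / dz))
    k1 = int(np.floor((z_max - offset) / dz))
    return offset + dz * np.arange(k0, k1 + 1)


def _prostate_contours(rng, config: PhantomConfig):
    """Prostate stack; returns (contours, half_height c, mid-gland scale s)."""
    target = rng.uniform(*config.prostate_volume_range) * 1000.0  # mm^3
    e = 2.5
    c = 0.95 * (3.0 * target / (4.0 * np.pi)) ** (1.0 / 3.0)
    s = float(np.sqrt(target / _superellipsoid_volume_unit(e, c)))
    offset = rng.uniform(-config.slice_thickness_mm / 2, config.slice_thickness_mm / 2)
    contours = []
    for z in _slice_grid(-c + 1.0, c - 1.0, config.slice_thickness_mm, offset):
        scale = s * (1.0 - np.abs(z / c) ** e) ** (1.0 / e)
        ring = _superellipse_ring(scale, scale * rng.uniform(0.92, 1.0), e)
        contours.append(Contour(float(z), _perturbed(ring, rng)))
    if len(contours) < 3:
        raise GenerationFailure("prostate spans fewer than 3 slices")
    return contours, c, s


def _bladder_contours(rng, config: PhantomConfig, z_base: float):
    """Dome-shaped bladder starting at its most caudal contour plane."""
    target = rng.uniform(*config.bladder_volume_range) * 1000.0
    height = rng.uniform(38.0, 55.0)
    if config.caudal_bladder_hotspot:
        # ellipsoidal dome truncated at the base: the most caudal contour is
        # large and closest to the implant -> the hottest 1-2 cm³ sits there.
        radius = float(np.sqrt(3.0 * target / (2.0 * np.pi * height)))
        zs = np.arange(z_base, z_base + height - 1.0, config.slice_thickness_mm)
        contours = []
        for z in zs:
            frac = (z - z_base) / height
            scale = radius * np.sqrt(max(1.0 - frac**2, 1e-4))
            ring = _superellipse_ring(scale, scale * rng.uniform(0.9, 1.0), 2.0)
            contours.append(Contour(float(z), _perturbed(ring, rng, 0.04)))
    else:
        # full ellipsoid: the caudal contour is a small cap, no base hotspot
        radius = float(np.sqrt(3.0 * target / (4.0 * np.pi * (height / 2.0))))
        z_mid = z_base + height / 2.0
        zs = np.arange(z_base + 1.0, z_base + height - 1.0, config.slice_thickness_mm)
        contours = []
        for z in zs:
            frac = (z - z_mid) / (height / 2.0)
            scale = radius * np.sqrt(max(1.0 - frac**2, 1e-4))
            ring = _superellipse_ring(scale, scale * rng.uniform(0.9, 1.0), 2.0)
            contours.append(Contour(float(z), _perturbed(ring, rng, 0.04)))
    return contours


def _rectum_contours(rng, config: PhantomConfig, y_center: float, z_lo: float, z_hi: float):
    target = rng.uniform(*config.rectum_volume_range) * 1000.0
    length = z_hi - z_lo
    radius = float(np.sqrt(target / (np.pi * length)))
    contours = []
    for z in np.arange(z_lo, z_hi, config.slice_thickness_mm):
        ring = _superellipse_ring(radius, radius * rng.uniform(0.85, 1.0), 2.0)
        center = np.array([rng.uniform(-2, 2), y_center + rng.uniform(-2, 2)])
        contours.append(Contour(float(z), _perturbed(ring, rng, 0.04) + center))
    return contours


def _urethra_contours(config: PhantomConfig, axis_xy: np.ndarray, z_values: np.ndarray):
    ring = _superellipse_ring(config.urethra_radius_mm, config.urethra_radius_mm, 2.0, 32)
    return [Contour(float(z), ring + axis_xy) for z in z_values]


def _vesicle_contours(rng, config: PhantomConfig, y_center: float, z_start: float):
    n_sl = int(rng.integers(2, 5)) if config.few_slice_vesicles else int(rng.integers(5, 7))
    target = rng.uniform(*config.vesicle_volume_range) * 1000.0
    area = target / (n_sl * config.slice_thickness_mm)
    # near-constant cross-section: only the base is delineated, so the stack
    # does not taper to a point
    aspect = 2.0
    b_ax = float(np.sqrt(area / (np.pi * aspect)))
    contours = []
    for i in range(n_sl):
        shrink = 1.0 - 0.08 * i
        ring = _superellipse_ring(aspect * b_ax * shrink, b_ax * shrink, 2.0, 48)
        center = np.array([0.0, y_center])
        contours.append(
            Contour(float(z_start + i * config.slice_thickness_mm), _perturbed(ring, rng, 0.03) + center)
        )
    return contours


def place_catheters_and_dwells(
    structure_set: StructureSet,
    rng: np.random.Generator,
    config: PhantomConfig,
    prostate_half_height: float,
    prostate_scale: float,
    urethra_xy: np.ndarray,
) -> list[DwellPosition]:
    """Near-parallel cranio-caudal catheters with unit-time dwells.

    Catheters are placed on two rings of the mid-gland cross-section (a
    template-like pattern), keeping >= 6 mm clearance from the urethra axis;
    dwells run at fixed spacing over the prostate z-extent plus a small
    margin.  Times carry an urethra-sparing factor; the global time scale is
    applied later against the planning aim.
    """
    n_cath = int(rng.integers(config.catheter_range[0], config.catheter_range[1] + 1))
    n_outer = int(np.ceil(2 * n_cath / 3))
    placements = []
    for ring_radius, count in ((0.75 * prostate_scale, n_outer), (0.42 * prostate_scale, n_cath - n_outer)):
        angles = np.linspace(0, TWO_PI, count, endpoint=False) + rng.uniform(0, TWO_PI)
        for ang in angles:
            xy = ring_radius * np.array([np.cos(ang), np.sin(ang)]) + rng.uniform(-1.5, 1.5, 2)
            if np.linalg.norm(xy - urethra_xy) < 9.0:
                xy = urethra_xy + (xy - urethra_xy) * 9.5 / max(np.linalg.norm(xy - urethra_xy), 1e-6)
            placements.append(xy)

    dwells = []
    z_lo = -prostate_half_height - config.dwell_margin_mm
    z_hi = prostate_half_height + config.dwell_margin_mm
    for cath_id, xy in enumerate(placements):
        tilt = rng.normal(0.0, 0.03, 2)
        axis = np.array([tilt[0], tilt[1], 1.0])
        axis /= np.linalg.norm(axis)
        for z in np.arange(z_lo, z_hi + 1e-9, config.dwell_spacing_mm):
            pos = np.array([xy[0] + tilt[0] * z, xy[1] + tilt[1] * z, z])
            d_ure = np.linalg.norm(pos[:2] - urethra_xy)
            # urethra sparing: dwell times taper towards the urethra axis so
            # the urethral dose sits below the prostate dose on average
            sparing = float(np.clip((d_ure - 6.0) / 13.0, 0.15, 1.0))
            dwells.append(DwellPosition(pos, axis, sparing, str(cath_id)))
    return dwells


def _scale_to_aim(
    patient: SyntheticPatient, source: SourceDescription, config: PhantomConfig
) -> None:
    """Globally scale dwell times so baseline D90% prostate hits the aim."""
    settings = RoiSettings(interpolate=True, outer_slab="partial", intersection_policy={})
    roi = build_roi_model(patient.structure_set, "prostate", settings)
    pts = sample_points(roi, SamplingConfig("per_roi", config.scaling_points, seed=patient.patient_seed))
    doses = total_dose(patient.plan, source, pts)
    d90 = dose_index_relative(doses, 90.0)
    if not np.isfinite(d90) or d90 <= 0:
        raise GenerationFailure("dwell-time scaling diverged (zero D90)")
    patient.plan = patient.plan.scaled(config.prescription_gy / d90)


def generate_patient(
    config: PhantomConfig, index: int, source: SourceDescription
) -> SyntheticPatient:
    """Generate one phantom patient (deterministic in (config.seed, index))."""
    rng = _patient_rng(config, index)
    prostate, c, s = _prostate_contours(rng, config)
    z_top_slice = prostate[-1].z_mm
    bladder_base = c + 5.0
    bladder = _bladder_contours(rng, config, bladder_base)
    rectum = _rectum_contours(rng, config, -(s + 18.0), -c - 12.0, c + 15.0)
    urethra_xy = np.array([rng.uniform(-1.0, 1.0), rng.uniform(0.0, 2.0)])
    urethra_z = _slice_grid(
        prostate[0].z_mm, bladder_base + 1.5 * config.slice_thickness_mm,
        config.slice_thickness_mm, prostate[0].z_mm,
    )
    urethra = _urethra_contours(config, urethra_xy, urethra_z)
    # vesicle base overlaps the cranial prostate slices; the stack then runs
    # out of the high-dose region, which is what makes its V80% sensitive to
    # the outer-slab mode
    vesicles = _vesicle_contours(rng, config, -0.45 * s, z_top_slice - config.slice_thickness_mm)

    structure_set = StructureSet(
        {
            "prostate": prostate,
            "vesicles": vesicles,
            "bladder": bladder,
            "rectum": rectum,
            "urethra": urethra,
        },
        config.slice_thickness_mm,
    )
    dwells = place_catheters_and_dwells(structure_set, rng, config, c, s, urethra_xy)
    treatment = date(2017, 1, 1) + timedelta(days=index)
    plan = Plan(
        dwells,
        config.strength_U,
        treatment - timedelta(days=config.decay_days),
        treatment,
    )
    patient_seed = int(np.random.SeedSequence([config.seed, index]).generate_state(1)[0] % (2**31))
    patient = SyntheticPatient(f"P{index:03d}", structure_set, plan, config, patient_seed)
    _scale_to_aim(patient, source, config)
    return patient


def generate_cohort(config: PhantomConfig, source: SourceDescription) -> list[SyntheticPatient]:
    """Generate the full cohort (default 26 patients), deterministic in seed."""
    return [generate_patient(config, i, source) for i in range(config.n_patients)]


def thin_plan(
    patient: SyntheticPatient, source: SourceDescription, n_dwells: int = 50
) -> Plan:
    """Reduced plan with ~``n_dwells`` dwells, rescaled to the planning aim.

    Keeps every k-th dwell of the full plan and reapplies the global D90
    scaling; used for desk-scale replicate studies where the dose field only
    needs to be plausible, not clinical.
    """
    step = max(1, round(len(patient.plan.dwells) / n_dwells))
    kept = patient.plan.dwells[::step]
    plan = Plan(
        kept,
        patient.plan.air_kerma_strength_U,
        patient.plan.calibration_date,
        patient.plan.treatment_date,
    )
    settings = RoiSettings(interpolate=True, outer_slab="partial", intersection_policy={})
    roi = build_roi_model(patient.structure_set, "prostate", settings)
    pts = sample_points(
        roi, SamplingConfig("per_roi", patient.config.scaling_points, seed=patient.patient_seed)
    )
    d90 = dose_index_relative(total_dose(plan, source, pts), 90.0)
    return plan.scaled(patient.config.prescription_gy / d90)
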