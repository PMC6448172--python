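"""Plain-text readers and writers for source, plan and structure-set files.

All formats are UTF-8 text with '#' comments, '.' decimal separators and LF
endings; coordinates are mm, doses Gy, z increases cranially.

Source file::

    [meta]
    model_id mHDR-v2
    active_length_mm 3.5
    lambda_cGy_per_hU 1.109
    half_life_days 73.83
    [radial]
    0.25 0.990            # r_cm  g
    ...
    [anisotropy]
    r\\theta 0 10 ... 180  # first row: theta grid (deg)
    0.25 0.680 ...         # first column: r grid (cm); body: F(r, theta)

Plan file::

    strength_U 20000
    calibration_date 2016-12-18
    treatment_date 2017-01-01
    # catheter_id x_mm y_mm z_mm tx ty tz time_s
    0 -12.1 3.0 -18.0 0.0 0.0 1.0 0.421

Structure-set file::

    slice_thickness 3.3
    roi prostate
    contour z=-13.2
    -20.133,1.352          # x_mm,y_mm vertex lines
    ...

A DICOM-RT STRUCT converter is documented as a stub only
(:func:`from_dicom_rt`); full DICOM parsing is out of scope here.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field as dc_field
from datetime import date, datetime, timezone
from importlib import resources
from pathlib import Path

import numpy as np

from .geometry import Contour, StructureSet
from .tg43 import DwellPosition, Plan, SourceDescription

__all__ = [
    "ParseError",
    "read_source",
    "load_packaged_source",
    "packaged_source_models",
    "read_plan",
    "write_plan",
    "read_structure_set",
    "write_structure_set",
    "write_points_csv",
    "RunManifest",
    "from_dicom_rt",
]

PACKAGED_MODELS = ("mHDR-v2", "mHDR-v2r", "mHDR-v2c")


class ParseError(ValueError):
    """Malformed input file; message carries the line number."""


def _clean_lines(text: str):
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            yield lineno, line


def _parse_source(text: str, origin: str = "<string>") -> SourceDescription:
    section = None
    meta: dict[str, str] = {}
    radial: list[tuple[float, float]] = []
    theta_grid: list[float] | None = None
    aniso_r: list[float] = []
    aniso_rows: list[list[float]] = []
    for lineno, line in _clean_lines(text):
        if line.startswith("["):
            section = line.strip("[]").lower()
            continue
        try:
            if section == "meta":
                key, value = line.split(maxsplit=1)
                meta[key] = value
            elif section == "radial":
                r, g = (float(tok) for tok in line.split())
                radial.append((r, g))
            elif section == "anisotropy":
                toks = line.split()
                if theta_grid is None:
                    theta_grid = [float(t) for t in toks[1:]]
                else:
                    aniso_r.append(float(toks[0]))
                    aniso_rows.append([float(t) for t in toks[1:]])
            else:
                raise ValueError("content outside any [section]")
        except ValueError as exc:
            raise ParseError(f"{origin}:{lineno}: {exc}") from exc
    if theta_grid is None or not radial or not meta:
        raise ParseError(f"{origin}: missing [meta], [radial] or [anisotropy] section")
    radial_arr = np.array(radial)
    return SourceDescription(
        model_id=meta["model_id"],
        active_length_mm=float(meta["active_length_mm"]),
        dose_rate_constant=float(meta["lambda_cGy_per_hU"]),
        radial_r_cm=radial_arr[:, 0],
        radial_g=radial_arr[:, 1],
        aniso_r_cm=np.array(aniso_r),
        aniso_theta_deg=np.array(theta_grid),
        aniso_f=np.array(aniso_rows),
        half_life_days=float(meta.get("half_life_days", 73.83)),
    )


def read_source(path: str | Path) -> SourceDescription:
    """Read a TG-43 source-description text file."""
    path = Path(path)
    return _parse_source(path.read_text(), str(path))


def packaged_source_models() -> tuple[str, ...]:
    """Model ids of the schematic source tables shipped with the package."""
    return PACKAGED_MODELS


def load_packaged_source(model_id: str = "mHDR-v2") -> SourceDescription:
    """Load one of the packaged schematic source descriptions by model id."""
    if model_id not in PACKAGED_MODELS:
        raise KeyError(f"unknown packaged model {model_id!r}; have {PACKAGED_MODELS}")
    text = resources.files("brachydv.data").joinpath(f"{model_id}.txt").read_text()
    return _parse_source(text, f"packaged:{model_id}")


def read_plan(path: str | Path) -> Plan:
    path = Path(path)
    headers: dict[str, str] = {}
    dwells: list[DwellPosition] = []
    for lineno, line in _clean_lines(path.read_text()):
        toks = line.split()
        if toks[0] in ("strength_U", "calibration_date", "treatment_date"):
            headers[toks[0]] = toks[1]
            continue
        if len(toks) != 8:
            raise ParseError(f"{path}:{lineno}: expected 8 dwell fields, got {len(toks)}")
        try:
            cath = toks[0]
            x, y, z, tx, ty, tz, t = (float(v) for v in toks[1:])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        dwells.append(DwellPosition(np.array([x, y, z]), np.array([tx, ty, tz]), t, cath))
    try:
        return Plan(
            dwells,
            float(headers["strength_U"]),
            date.fromisoformat(headers["calibration_date"]),
            date.fromisoformat(headers["treatment_date"]),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing header line {exc}") from exc


def write_plan(plan: Plan, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"strength_U {plan.air_kerma_strength_U:.6g}",
        f"calibration_date {plan.calibration_date.isoformat()}",
        f"treatment_date {plan.treatment_date.isoformat()}",
        "# catheter_id x_mm y_mm z_mm tx ty tz time_s",
    ]
    for d in plan.dwells:
        p, a = d.position_mm, d.axis_direction
        lines.append(
            f"{d.catheter_id} {p[0]:.4f} {p[1]:.4f} {p[2]:.4f} "
            f"{a[0]:.6f} {a[1]:.6f} {a[2]:.6f} {d.dwell_time_s:.6f}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_structure_set(path: str | Path) -> StructureSet:
    path = Path(path)
    rois: dict[str, list[Contour]] = {}
    slice_thickness = 3.3
    roi_name: str | None = None
    z: float | None = None
    verts: list[list[float]] = []

    def flush():
        nonlocal verts, z
        if z is not None and verts:
            rois.setdefault(roi_name, []).append(Contour(z, np.array(verts)))
        verts, z = [], None

    for lineno, line in _clean_lines(path.read_text()):
        if line.startswith("slice_thickness"):
            slice_thickness = float(line.split()[1])
        elif line.startswith("roi "):
            flush()
            roi_name = line[4:].strip()
        elif line.startswith("contour "):
            flush()
            try:
                z = float(line.split("z=", 1)[1])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: bad contour header {line!r}") from exc
        else:
            try:
                x, y = (float(v) for v in line.split(","))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad vertex line {line!r}") from exc
            verts.append([x, y])
    flush()
    return StructureSet(rois, slice_thickness)


def write_structure_set(structure_set: StructureSet, path: str | Path) -> None:
    path = Path(path)
    lines = [f"slice_thickness {structure_set.slice_thickness_mm:g}"]
    for name, contours in structure_set.rois.items():
        lines.append(f"roi {name}")
        for c in contours:
            lines.append(f"contour z={c.z_mm:.4f}")
            lines.extend(f"{x:.4f},{y:.4f}" for x, y in c.vertices)
    path.write_text("\n".join(lines) + "\n")


def write_points_csv(path: str | Path, roi: str, points_mm: np.ndarray, doses_gy: np.ndarray) -> None:
    """Export sampled points and their doses: roi, x_mm, y_mm, z_mm, dose_Gy."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("roi,x_mm,y_mm,z_mm,dose_Gy\n")
        for p, d in zip(np.atleast_2d(points_mm), np.atleast_1d(doses_gy)):
            fh.write(f"{roi},{p[0]:.4f},{p[1]:.4f},{p[2]:.4f},{d:.6f}\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-run a computation bit- or statistically identically."""

    tool_version: str
    settings: dict
    seeds: list[int]
    inputs: dict[str, str] = dc_field(default_factory=dict)  # path -> sha256
    outputs: list[str] = dc_field(default_factory=list)
    timestamp: str = dc_field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )
    platform: str = dc_field(default_factory=platform.platform)

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.inputs[str(p)] = _sha256(p)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")


def from_dicom_rt(path: str | Path) -> StructureSet:  # pragma: no cover - stub
    """Converter stub for DICOM-RT STRUCT files (not implemented).

    Mapping: each item of ``ROIContourSequence`` becomes one named ROI; each
    ``ContourSequence`` item's ``ContourData`` triplets (x, y, z in mm,
    patient coordinates) become a :class:`~brachydv.geometry.Contour` at the
    shared z of the planar contour; ``SliceThickness`` of the referenced
    image series supplies ``slice_thickness_mm``.  Use pydicom to read the
    dataset and feed the vertices to :class:`StructureSet`.
    """
    raise NotImplementedError("DICOM-RT STRUCT conversion is a documented stub")
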