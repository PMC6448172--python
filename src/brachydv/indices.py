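"""Dose-volume indices computed directly from sampled point doses.

No dose-volume histogram is ever binned.  A volume index Vx% is the fraction
of dose-calculation points at or above the threshold dose; a dose index
Dxcm³ is read off the descending dose sort at the rank corresponding to the
requested absolute volume, ``rank = ceil(n * x / V)`` (1-based).  With
1,000 points in a 2.01 cm³ urethra, D0.1cm³ is therefore the dose of point
50 in the sorted list.

The nine study indices and their clinical criteria:

====================  =====================
prostate              V100% > 95%, D90% > 100%, V150% < 50%, V200% < 20%
seminal vesicles      V80% > 95%
bladder               D1cm³ < 86%, D2cm³ < 74%
rectum                D1cm³ < 78%, D2cm³ < 74%
urethra               D0.1cm³ < 110%
====================  =====================

V criteria are in % of the organ volume; D criteria in % of the
planning-aim dose (D90% prostate > 13 Gy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UndefinedIndexError",
    "PlanningAim",
    "STUDY_INDICES",
    "volume_index",
    "dose_index",
    "dose_index_relative",
    "evaluate_plan",
    "criteria_table",
]


class UndefinedIndexError(ValueError):
    """The requested index is not defined for the given sample/volume."""


@dataclass(frozen=True)
class PlanningAim:
    """Prescription level and the clinical DV criteria evaluated against it."""

    prescription_gy: float = 13.0
    #: (organ, index id, comparator, threshold); thresholds are % of organ
    #: volume for V indices and % of the planning-aim dose for D indices.
    criteria: tuple = (
        ("prostate", "V100%", ">", 95.0),
        ("prostate", "D90%", ">", 100.0),
        ("prostate", "V150%", "<", 50.0),
        ("prostate", "V200%", "<", 20.0),
        ("vesicles", "V80%", ">", 95.0),
        ("bladder", "D1cm3", "<", 86.0),
        ("bladder", "D2cm3", "<", 74.0),
        ("rectum", "D1cm3", "<", 78.0),
        ("rectum", "D2cm3", "<", 74.0),
        ("urethra", "D0.1cm3", "<", 110.0),
    )

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be positive")


#: (organ, index id) -> ("V", percent-of-aim threshold) or ("D", x cm³) or
#: ("Drel", percent of organ volume) for the relative dose index D90%.
STUDY_INDICES: dict[tuple[str, str], tuple[str, float]] = {
    ("prostate", "V100%"): ("V", 100.0),
    ("prostate", "D90%"): ("Drel", 90.0),
    ("prostate", "V150%"): ("V", 150.0),
    ("prostate", "V200%"): ("V", 200.0),
    ("vesicles", "V80%"): ("V", 80.0),
    ("bladder", "D1cm3"): ("D", 1.0),
    ("bladder", "D2cm3"): ("D", 2.0),
    ("rectum", "D1cm3"): ("D", 1.0),
    ("rectum", "D2cm3"): ("D", 2.0),
    ("urethra", "D0.1cm3"): ("D", 0.1),
}


def volume_index(doses_gy: np.ndarray, threshold_gy: float, direction: str = "at_least") -> float:
    """Percent of ROI volume receiving at least (or at most) a dose.

    Counts the dose-calculation points beyond the threshold and divides by
    the total; points exactly at the threshold count towards "at least".
    """
    d = np.asarray(doses_gy, dtype=float)
    if d.size == 0:
        raise UndefinedIndexError("volume index of an empty dose sample")
    if direction == "at_least":
        k = int(np.count_nonzero(d >= threshold_gy))
    elif direction == "at_most":
        k = int(np.count_nonzero(d <= threshold_gy))
    else:
        raise ValueError("direction must be 'at_least' or 'at_most'")
    return 100.0 * k / d.size


def dose_index(doses_gy: np.ndarray, x_cm3: float, roi_volume_cm3: float) -> float:
    """Lowest dose (Gy) to the most irradiated ``x`` cm³ of the ROI.

    Sorts the point doses from highest to lowest and returns the dose at
    1-based rank ``ceil(n * x / V)``.
    """
    d = np.asarray(doses_gy, dtype=float)
    if d.size == 0:
        raise UndefinedIndexError("dose index of an empty dose sample")
    if not 0 < x_cm3 <= roi_volume_cm3:
        raise UndefinedIndexError(
            f"D{x_cm3}cm3 undefined for ROI volume {roi_volume_cm3:.3f} cm3"
        )
    rank = math.ceil(d.size * x_cm3 / roi_volume_cm3)
    rank = min(rank, d.size)
    # rank-th largest, 1-based
    return float(np.partition(d, d.size - rank)[d.size - rank])


def dose_index_relative(doses_gy: np.ndarray, percent_volume: float) -> float:
    """Lowest dose (Gy) to the most irradiated ``percent_volume`` % of the ROI."""
    d = np.asarray(doses_gy, dtype=float)
    if d.size == 0:
        raise UndefinedIndexError("dose index of an empty dose sample")
    if not 0 < percent_volume <= 100:
        raise UndefinedIndexError("percent_volume must be in (0, 100]")
    rank = min(math.ceil(d.size * percent_volume / 100.0), d.size)
    return float(np.partition(d, d.size - rank)[d.size - rank])


def evaluate_plan(
    doses_by_organ: dict[str, np.ndarray],
    volumes_cm3: dict[str, float],
    aim: PlanningAim,
    setting_label: str = "baseline",
) -> pd.DataFrame:
    """Evaluate the nine study indices and their clinical criteria.

    Returns a tidy table with one row per criterion: the index value (V in %
    of organ volume; D both in Gy and in % of planning-aim dose), the
    criterion and its pass flag.  Missing organs are reported as
    not-evaluable rather than raising.
    """
    rows = []
    for organ, index_id, comparator, limit in aim.criteria:
        kind, param = STUDY_INDICES[(organ, index_id)]
        row = {
            "setting": setting_label,
            "organ": organ,
            "index": index_id,
            "criterion": f"{index_id} {comparator} {limit:g}",
            "evaluable": True,
        }
        doses = doses_by_organ.get(organ)
        if doses is None or len(doses) == 0:
            row.update(value=np.nan, unit="", value_gy=np.nan, passed=None, evaluable=False)
            rows.append(row)
            continue
        try:
            if kind == "V":
                value = volume_index(doses, param / 100.0 * aim.prescription_gy)
                row.update(value=value, unit="% of ROI volume", value_gy=np.nan)
            else:
                if kind == "Drel":
                    gy = dose_index_relative(doses, param)
                else:
                    gy = dose_index(doses, param, volumes_cm3[organ])
                value = 100.0 * gy / aim.prescription_gy
                row.update(value=value, unit="% of planning-aim dose", value_gy=gy)
            row["passed"] = bool(value > limit) if comparator == ">" else bool(value < limit)
        except UndefinedIndexError:
            row.update(value=np.nan, unit="", value_gy=np.nan, passed=None, evaluable=False)
        rows.append(row)
    return pd.DataFrame(rows)


def criteria_table(
    values: dict[tuple[str, str], float], aim: PlanningAim, setting_label: str = "baseline"
) -> pd.DataFrame:
    """Criteria table from already-computed index values.

    ``values`` maps (organ, index id) to the index value in study units
    (% of ROI volume for V, % of planning-aim dose for D); indices absent
    from the mapping or NaN are reported as not-evaluable.
    """
    rows = []
    for organ, index_id, comparator, limit in aim.criteria:
        value = values.get((organ, index_id), np.nan)
        kind, _ = STUDY_INDICES[(organ, index_id)]
        evaluable = bool(np.isfinite(value))
        rows.append(
            {
                "setting": setting_label,
                "organ": organ,
                "index": index_id,
                "value": value,
                "unit": "% of ROI volume" if kind == "V" else "% of planning-aim dose",
                "value_gy": np.nan if kind == "V" or not evaluable
                else value / 100.0 * aim.prescription_gy,
                "criterion": f"{index_id} {comparator} {limit:g}",
                "passed": (bool(value > limit) if comparator == ">" else bool(value < limit))
                if evaluable
                else None,
                "evaluable": evaluable,
            }
        )
    return pd.DataFrame(rows)
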