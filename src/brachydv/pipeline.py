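"""Sensitivity analysis of DV indices to computation settings.

Orchestrates the study design: a baseline setting that mirrors a clinical
TPS default (mHDR-v2 dosimetry, contour interpolation on, urethra counted
as part of prostate and bladder, partial outer slice thickness), a
convergence study of the sampling uncertainty over doubling point counts, a
2x2x2 factor grid over (interpolation, intersection policy, outer slab)
plus two source-model swaps, per-patient deltas against baseline, and the
paired t / sign tests with a 0.01 significance threshold.

All values are carried in the units the study reports: volume indices in %
of ROI volume, dose indices in % of the planning-aim dose.  Replicate
uncertainty is summarized as the width of the normal 95% confidence
interval, 2 x 1.96 x (SD over seeds).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import RoiModel, RoiSettings, StructureSet, build_roi_model
from .indices import (
    PlanningAim,
    STUDY_INDICES,
    dose_index,
    dose_index_relative,
    volume_index,
)
from .sampling import SamplingConfig, sample_points
from .tg43 import Plan, SourceDescription, total_dose

__all__ = [
    "TARGET_ORGANS",
    "OAR_ORGANS",
    "ComputationSetting",
    "baseline_setting",
    "factor_grid",
    "build_models",
    "compute_dv_values",
    "replicate_study",
    "convergence_study",
    "run_sensitivity",
    "summarize_deltas",
    "TestResult",
    "paired_t_test",
    "paired_sign_test",
    "distribution_diagnostics",
]

TARGET_ORGANS = ("prostate", "vesicles")
OAR_ORGANS = ("bladder", "rectum", "urethra")
#: urethra is subtracted from the organs it intersects when excluded
EXCLUSION_POLICY = {"prostate": ("urethra",), "bladder": ("urethra",)}
CI_FACTOR = 2.0 * 1.96


class DegenerateTestError(RuntimeError):
    """Paired test input has no usable variation."""


@dataclass(frozen=True)
class ComputationSetting:
    """One point of the factor grid under study."""

    source_model: str = "mHDR-v2"
    interpolate: bool = True
    intersection: str = "include"  # "include" | "exclude"
    outer_slab: str = "partial"  # "full" | "partial"
    target_points: int = 256_000
    oar_density_per_cm3: float = 2_560.0

    def __post_init__(self) -> None:
        if self.intersection not in ("include", "exclude"):
            raise ValueError("intersection must be 'include' or 'exclude'")

    @property
    def label(self) -> str:
        return (
            f"{self.source_model}/interp={'on' if self.interpolate else 'off'}/"
            f"{self.intersection}/{self.outer_slab}"
        )

    def roi_settings(self, grid_spacing_mm: float = 0.82) -> RoiSettings:
        policy = EXCLUSION_POLICY if self.intersection == "exclude" else {}
        return RoiSettings(
            interpolate=self.interpolate,
            outer_slab=self.outer_slab,
            intersection_policy=policy,
            grid_spacing_mm=grid_spacing_mm,
        )

    def sampling_for(self, organ: str, seed: int) -> SamplingConfig:
        if organ in TARGET_ORGANS:
            return SamplingConfig("per_roi", self.target_points, seed=seed)
        return SamplingConfig("per_cm3", None, self.oar_density_per_cm3, seed=seed)


def baseline_setting(**overrides) -> ComputationSetting:
    """The study baseline: mHDR-v2, interpolation on, include, partial."""
    return replace(ComputationSetting(), **overrides)


def factor_grid(baseline: ComputationSetting) -> list[ComputationSetting]:
    """The 2x2x2 grid over (interpolate, intersection, outer slab) at the
    baseline source model, plus the two source-model swap settings at
    baseline geometry; deterministic order, baseline appears exactly once."""
    grid = [
        replace(baseline, interpolate=interp, intersection=inter, outer_slab=slab)
        for interp in (True, False)
        for inter in ("include", "exclude")
        for slab in ("partial", "full")
    ]
    swaps = [replace(baseline, source_model=m) for m in ("mHDR-v2r", "mHDR-v2c")]
    return grid + swaps


def build_models(
    structure_set: StructureSet, roi_settings: RoiSettings, organs: Sequence[str] | None = None
) -> dict[str, tuple[RoiModel, float]]:
    """ROI models and volumes for the study organs under one setting."""
    organs = organs or (*TARGET_ORGANS, *OAR_ORGANS)
    out = {}
    for organ in organs:
        model = build_roi_model(structure_set, organ, roi_settings)
        out[organ] = (model, model.volume_cm3())
    return out


def _eval_index(kind: str, param: float, doses: np.ndarray, volume: float, aim: PlanningAim) -> float:
    if kind == "V":
        return volume_index(doses, param / 100.0 * aim.prescription_gy)
    if kind == "Drel":
        return 100.0 * dose_index_relative(doses, param) / aim.prescription_gy
    return 100.0 * dose_index(doses, param, volume) / aim.prescription_gy


def compute_dv_values(
    models: Mapping[str, tuple[RoiModel, float]],
    plan: Plan,
    source: SourceDescription,
    setting: ComputationSetting,
    seed: int,
    aim: PlanningAim,
) -> dict[tuple[str, str], float]:
    """The nine study indices for one patient, setting and sampling seed.

    Indices whose absolute volume exceeds the ROI volume (e.g. D2cm³ of a
    degenerate organ) come back as NaN rather than raising.
    """
    values: dict[tuple[str, str], float] = {}
    for organ, (model, volume) in models.items():
        specs = [(idx, kp) for (org, idx), kp in STUDY_INDICES.items() if org == organ]
        if not specs:
            continue
        if volume <= 0:
            values.update({(organ, idx): np.nan for idx, _ in specs})
            continue
        pts = sample_points(model, setting.sampling_for(organ, seed), volume_cm3=volume)
        doses = total_dose(plan, source, pts)
        for idx, (kind, param) in specs:
            if kind == "D" and param > volume:
                values[(organ, idx)] = np.nan
            else:
                values[(organ, idx)] = _eval_index(kind, param, doses, volume, aim)
    return values


def replicate_study(
    model: RoiModel,
    volume: float,
    plan: Plan,
    source: SourceDescription,
    index_specs: Sequence[tuple[str, str, float]],
    sampling: SamplingConfig,
    seeds: Iterable[int],
    aim: PlanningAim,
) -> pd.DataFrame:
    """Per-seed index values and their replicate summary for one ROI.

    ``index_specs`` is a list of (index id, kind, parameter); returns one
    row per index with mean, SD and ci_width = 2 x 1.96 x SD over seeds.
    """
    seeds = list(seeds)
    per_index: dict[str, list[float]] = {idx: [] for idx, _, _ in index_specs}
    for seed in seeds:
        pts = sample_points(model, sampling.with_seed(seed), volume_cm3=volume)
        doses = total_dose(plan, source, pts)
        n_pts = len(doses)
        for idx, kind, param in index_specs:
            per_index[idx].append(_eval_index(kind, param, doses, volume, aim))
    rows = []
    for idx, kind, param in index_specs:
        vals = np.array(per_index[idx])
        rows.append(
            {
                "index": idx,
                "n_points": n_pts,
                "n_seeds": len(seeds),
                "mean": vals.mean(),
                "sd": vals.std(ddof=1),
                "ci_width": CI_FACTOR * vals.std(ddof=1),
                "values": vals,
            }
        )
    return pd.DataFrame(rows)


def _organ_index_specs(organ: str) -> list[tuple[str, str, float]]:
    return [(idx, kind, param) for (org, idx), (kind, param) in STUDY_INDICES.items() if org == organ]


def convergence_study(
    patients: Sequence,
    source: SourceDescription,
    n_values: Sequence[int] = (1000, 2000, 4000, 8000, 16000, 32000, 64000, 128000, 256000),
    density_values: Sequence[float] = (10, 20, 40, 80, 160, 320, 640, 1280, 2560),
    seeds: Iterable[int] = range(1, 101),
    aim: PlanningAim = PlanningAim(),
) -> pd.DataFrame:
    """Replicate CI width of every index over doubling point counts.

    Two series are produced: a fixed count per ROI (all organs) and a fixed
    count per cm³ (OARs only); CI widths are arithmetic means over patients.
    Default spans and the 100-seed replication follow the study design;
    scaled-down values can be passed for desk-size runs.
    """
    seeds = list(seeds)
    settings = baseline_setting().roi_settings()
    rows = []
    for patient in patients:
        models = build_models(patient.structure_set, settings)
        for organ, (model, volume) in models.items():
            specs = _organ_index_specs(organ)
            for n in n_values:
                rep = replicate_study(
                    model, volume, patient.plan, source, specs,
                    SamplingConfig("per_roi", int(n)), seeds, aim,
                )
                for _, row in rep.iterrows():
                    rows.append(
                        dict(patient=patient.patient_id, series="per_roi", amount=n,
                             organ=organ, index=row["index"], mean=row["mean"],
                             sd=row["sd"], ci_width=row["ci_width"])
                    )
            if organ in OAR_ORGANS:
                for dens in density_values:
                    rep = replicate_study(
                        model, volume, patient.plan, source, specs,
                        SamplingConfig("per_cm3", None, float(dens)), seeds, aim,
                    )
                    for _, row in rep.iterrows():
                        rows.append(
                            dict(patient=patient.patient_id, series="per_cm3", amount=dens,
                                 organ=organ, index=row["index"], mean=row["mean"],
                                 sd=row["sd"], ci_width=row["ci_width"])
                        )
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["series", "amount", "organ", "index"], as_index=False)
        .agg(mean=("mean", "mean"), ci_width=("ci_width", "mean"))
        .assign(n_patients=len(patients))
    )
    return summary


def run_sensitivity(
    patients: Sequence,
    sources: Mapping[str, SourceDescription],
    grid: Sequence[ComputationSetting],
    aim: PlanningAim = PlanningAim(),
    seed: int = 1,
) -> pd.DataFrame:
    """Per-patient, per-setting deltas of every index against baseline.

    One sampling seed is used throughout (the clinical fixed-seed mode); the
    baseline rows carry delta 0 by construction.  Not-evaluable indices
    propagate as NaN.
    """
    base = baseline_setting(
        target_points=grid[0].target_points, oar_density_per_cm3=grid[0].oar_density_per_cm3
    )
    rows = []
    for patient in patients:
        models_cache: dict[tuple, dict] = {}

        def values_for(setting: ComputationSetting):
            key = (setting.interpolate, setting.intersection, setting.outer_slab)
            if key not in models_cache:
                models_cache[key] = build_models(patient.structure_set, setting.roi_settings())
            return compute_dv_values(
                models_cache[key], patient.plan, sources[setting.source_model], setting, seed, aim
            )

        base_vals = values_for(base)
        for setting in grid:
            vals = base_vals if setting == base else values_for(setting)
            for (organ, idx), value in vals.items():
                rows.append(
                    dict(
                        patient=patient.patient_id,
                        setting=setting.label,
                        organ=organ,
                        index=idx,
                        value=value,
                        baseline=base_vals[(organ, idx)],
                        delta=value - base_vals[(organ, idx)],
                    )
                )
    return pd.DataFrame(rows)


def summarize_deltas(deltas: pd.DataFrame) -> pd.DataFrame:
    """Boxplot statistics of the per-patient deltas (median, quartiles,
    whiskers at min/max), with NaN deltas excluded and counted."""
    def _summary(g: pd.Series) -> pd.Series:
        vals = g.dropna()
        return pd.Series(
            {
                "median": vals.median(),
                "q25": vals.quantile(0.25),
                "q75": vals.quantile(0.75),
                "min": vals.min(),
                "max": vals.max(),
                "n": len(vals),
                "n_missing": g.isna().sum(),
            }
        )

    return (
        deltas.groupby(["setting", "organ", "index"])["delta"].apply(_summary).unstack().reset_index()
    )


@dataclass(frozen=True)
class TestResult:
    """Outcome of a paired test at the 0.01 significance threshold."""

    estimate: float  # mean (t test) or median (sign test) difference
    p_value: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    significant: bool = False
    degenerate: bool = False
    n: int = 0


def paired_t_test(differences: np.ndarray, alpha: float = 0.01) -> TestResult:
    """Classical paired-samples t test on per-patient differences.

    Two-sided p and 95% CI of the mean difference; zero-variance input is a
    degenerate-test signal (CI collapses onto the constant difference).
    """
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    if d.size < 3:
        raise DegenerateTestError("paired t test needs >= 3 differences")
    if np.allclose(d, d[0]):
        c = float(d[0])
        return TestResult(c, 1.0 if c == 0 else 0.0, c, c, c != 0, degenerate=True, n=d.size)
    res = stats.ttest_1samp(d, 0.0)
    ci = res.confidence_interval(0.95)
    return TestResult(
        float(d.mean()), float(res.pvalue), float(ci.low), float(ci.high),
        bool(res.pvalue < alpha), n=d.size,
    )


def paired_sign_test(differences: np.ndarray, alpha: float = 0.01) -> TestResult:
    """Exact two-sided binomial sign test; ties are dropped."""
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return TestResult(0.0, 1.0, significant=False, degenerate=True, n=0)
    if nonzero.size < 5:
        raise DegenerateTestError("sign test needs >= 5 non-zero differences")
    k = int(np.sum(nonzero > 0))
    res = stats.binomtest(k, nonzero.size, 0.5, alternative="two-sided")
    return TestResult(
        float(np.median(d)), float(res.pvalue), significant=bool(res.pvalue < alpha), n=nonzero.size
    )


def distribution_diagnostics(values: np.ndarray) -> dict:
    """Q-Q pairs against the normal, five-number summary and a skewness
    advisory (|skew| > 1) — the plot data behind the normality/symmetry
    checks; the accept/reject judgement stays with the analyst."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 3:
        raise ValueError("need >= 3 values")
    probs = (np.arange(1, v.size + 1) - 0.5) / v.size
    theoretical = stats.norm.ppf(probs, loc=v.mean(), scale=v.std(ddof=1))
    skew = float(stats.skew(v, bias=False))
    return {
        "qq_theoretical": theoretical,
        "qq_empirical": v,
        "five_number": (
            float(v[0]),
            float(np.quantile(v, 0.25)),
            float(np.median(v)),
            float(np.quantile(v, 0.75)),
            float(v[-1]),
        ),
        "skewness": skew,
        "advisory_nonnormal": bool(abs(skew) > 1.0),
    }
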