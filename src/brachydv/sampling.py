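"""Uniform rejection sampling of dose-calculation points inside an ROI.

Points are drawn uniformly in the ROI's bounding box and kept when they are
members of the ROI under the active computation settings, until the desired
count is reached.  The generator is the Mersenne Twister 19937; a fixed seed
makes the point placement, and hence every dose-volume index computed from
it, deterministic.  Each ROI draws from an independently seeded substream
(seed combined with a hash of the ROI name) so adding or removing an organ
does not perturb another organ's points.

The accepted-point count inside any sub-volume of fraction ``p`` is
binomial: mean ``np`` and variance ``np(1-p)``, which yields the normal
95% confidence-interval width ``2 * 1.96 * sqrt(p(1-p)/n)`` used throughout
the convergence analysis.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .geometry import RoiModel

__all__ = [
    "SamplingConfig",
    "SamplingStatistics",
    "SamplingFailure",
    "roi_rng",
    "sample_points",
    "binomial_ci_width",
]

#: hard cap on raw draws before rejection sampling gives up
MAX_DRAWS = 10**9


class SamplingFailure(RuntimeError):
    """Rejection sampling could not reach the requested count."""


@dataclass(frozen=True)
class SamplingConfig:
    """Point-placement mode: fixed count per ROI or fixed count per cm³."""

    mode: str = "per_roi"  # "per_roi" | "per_cm3"
    n: int | None = 10_000
    density_per_cm3: float | None = None
    seed: int = 0
    generator: str = "MT19937"

    def __post_init__(self) -> None:
        if self.mode not in ("per_roi", "per_cm3"):
            raise ValueError("mode must be 'per_roi' or 'per_cm3'")
        if self.mode == "per_roi" and (self.n is None or self.n < 1):
            raise ValueError("per_roi mode needs n >= 1")
        if self.mode == "per_cm3" and (self.density_per_cm3 is None or self.density_per_cm3 <= 0):
            raise ValueError("per_cm3 mode needs density_per_cm3 > 0")

    def count_for(self, volume_cm3: float) -> int:
        if self.mode == "per_roi":
            return int(self.n)
        return max(1, round(self.density_per_cm3 * volume_cm3))

    def with_seed(self, seed: int) -> "SamplingConfig":
        return SamplingConfig(self.mode, self.n, self.density_per_cm3, seed, self.generator)


@dataclass(frozen=True)
class SamplingStatistics:
    """Binomial statistics of the point count inside a volume fraction p."""

    p: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def mean(self) -> float:
        return self.n * self.p

    @property
    def variance(self) -> float:
        return self.n * self.p * (1.0 - self.p)


def roi_rng(seed: int, roi_name: str) -> np.random.Generator:
    """Mersenne Twister stream for one ROI, independent across ROI names."""
    name_hash = zlib.crc32(roi_name.encode("utf-8"))
    ss = np.random.SeedSequence([int(seed), name_hash])
    return np.random.Generator(np.random.MT19937(ss))


def sample_points(
    roi: RoiModel,
    config: SamplingConfig,
    volume_cm3: float | None = None,
    batch: int = 65_536,
) -> np.ndarray:
    """Rejection-sample exactly ``n`` points uniformly inside an ROI.

    In per-cm³ mode the target count is ``max(1, round(density * volume))``
    with the ROI volume computed under the active settings (or passed in to
    avoid recomputation).  Raises :class:`SamplingFailure` after 10^9 raw
    draws (degenerate ROI).
    """
    if config.mode == "per_cm3" and volume_cm3 is None:
        volume_cm3 = roi.volume_cm3()
    n_target = config.count_for(volume_cm3 if volume_cm3 is not None else 0.0)
    box = roi.bounding_box()
    lo, hi = box[0], box[1]
    rng = roi_rng(config.seed, roi.organ)

    accepted: list[np.ndarray] = []
    n_acc = 0
    n_drawn = 0
    while n_acc < n_target:
        if n_drawn >= MAX_DRAWS:
            raise SamplingFailure(
                f"{roi.organ}: {n_acc}/{n_target} points after {n_drawn} draws"
            )
        m = min(batch, MAX_DRAWS - n_drawn)
        pts = rng.uniform(lo, hi, size=(m, 3))
        n_drawn += m
        keep = roi.contains(pts)
        if keep.any():
            accepted.append(pts[keep])
            n_acc += int(keep.sum())
    return np.vstack(accepted)[:n_target]


def binomial_ci_width(stat: SamplingStatistics) -> float:
    """Width of the normal-approximation 95% CI of the volume fraction, in %.

    ``width = 2 * 1.96 * sqrt(p(1-p)/n) * 100``; maximal at p = 0.5 and
    zero at p in {0, 1}.
    """
    return 2.0 * 1.96 * float(np.sqrt(stat.p * (1.0 - stat.p) / stat.n)) * 100.0
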