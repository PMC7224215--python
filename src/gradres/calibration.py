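"""Calibrating division probabilities from observed colony sizes.

The lattice model needs the tolerant (initial) and resistant (maximal)
division probabilities, but experiments only report colony sizes.  A
mutation-free simulation maps each division probability to an expected
final colony size over the clonogenic growth window; inverting that
monotone map converts observed sizes back into probabilities:

* ``p_init`` comes from the *median* tolerant colony size (tolerant
  cells are assumed to have little rate variability);
* each simulated colony's ``p_max`` is drawn by resampling one observed
  resistant colony size (with replacement) and inverting it, so the
  in-silico cohort inherits the empirical spread of resistant growth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .abm import as_rng

__all__ = ["RateSizeMap", "EmpiricalRateSampler", "CohortCalibration", "calibrate_cohort"]


@dataclass
class RateSizeMap:
    """Monotone map between division probability and expected colony size.

    Built from mutation-free lattice simulations of fixed duration and
    regularised by isotonic regression so inversion is well defined.
    """

    p_grid: np.ndarray
    expected_size: np.ndarray
    reps_per_point: int
    duration_updates: int

    def __post_init__(self):
        self.p_grid = np.asarray(self.p_grid, dtype=float)
        self.expected_size = np.asarray(self.expected_size, dtype=float)
        if np.any(np.diff(self.p_grid) <= 0):
            raise ValueError("p_grid must be strictly increasing")
        if np.any(np.diff(self.expected_size) < -1e-9):
            raise ValueError("expected_size must be non-decreasing")

    @classmethod
    def build(
        cls,
        duration_updates: int,
        p_grid=None,
        reps: int = 200,
        seed=None,
        updates_per_day: int = 2,
    ) -> "RateSizeMap":
        """Simulate mu = 0 colonies at each p and store isotonic mean sizes."""
        rng = as_rng(seed)
        if p_grid is None:
            p_grid = np.linspace(0.0, 1.0, 21)
        p_grid = np.asarray(p_grid, dtype=float)
        if np.any((p_grid < 0) | (p_grid > 1)) or np.any(np.diff(p_grid) <= 0):
            raise ValueError("p_grid must be sorted within [0, 1]")
        from .abm import MAX_SEED, _cohort_sizes, _safe_side

        means = np.empty(len(p_grid))
        for i, p in enumerate(p_grid):
            if p == 0.0:
                means[i] = 1.0  # no division ever: colony stays the founder
                continue
            seeds = rng.integers(0, MAX_SEED, size=reps).astype(np.int64)
            side = _safe_side(duration_updates)
            out, _, status = _cohort_sizes(
                side, duration_updates,
                np.zeros(reps, dtype=np.int64),
                np.full(reps, p, dtype=np.float64),
                seeds,
                1, p, 0.0, 0.0, False, 0.0, True,
            )
            means[i] = out.mean()
        iso = IsotonicRegression(increasing=True)
        smoothed = iso.fit_transform(p_grid, means)
        smoothed = np.maximum(smoothed, 1.0)
        return cls(p_grid, smoothed, reps, duration_updates)

    # -- interpolation ----------------------------------------------------
    def size_for_rate(self, p) -> np.ndarray:
        return np.interp(np.asarray(p, dtype=float), self.p_grid, self.expected_size)

    def rate_for_size(self, target_size) -> np.ndarray:
        """Invert the map by linear interpolation on its increasing envelope.

        Sizes above the map's maximum clamp to the largest grid p (with a
        warning); sizes below 1 are invalid.
        """
        s = np.asarray(target_size, dtype=float)
        if np.any(s < 1):
            raise ValueError("target colony size must be >= 1")
        if np.any(s > self.expected_size[-1]):
            warnings.warn(
                "target size above calibrated range; clamping to the largest p",
                stacklevel=2,
            )
        # keep the first grid point of any flat stretch so xp is usable
        keep = np.concatenate(([True], np.diff(self.expected_size) > 0))
        xp = self.expected_size[keep]
        fp = self.p_grid[keep]
        return np.interp(s, xp, fp)

    # -- persistence ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"p": self.p_grid, "expected_size": self.expected_size})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, reps: int = 0, duration_updates: int = 0):
        return cls(df["p"].to_numpy(), df["expected_size"].to_numpy(), reps, duration_updates)


class EmpiricalRateSampler:
    """Per-colony p_max sampler: invert a resampled resistant colony size."""

    def __init__(self, resistant_sizes, rate_map: RateSizeMap, p_floor: float = 0.0):
        self.sizes = np.asarray(resistant_sizes)
        if len(self.sizes) == 0:
            raise ValueError("resistant size sample is empty")
        self.map = rate_map
        self.p_floor = p_floor
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rates = rate_map.rate_for_size(self.sizes)
        if np.any(rates < p_floor):
            warnings.warn(
                "some resistant colonies invert below p_init; clamping their "
                "p_max up to p_init",
                stacklevel=2,
            )
        self.rates = np.clip(rates, p_floor, 1.0)

    def __call__(self, rng) -> float:
        return float(rng.choice(self.rates))


@dataclass
class CohortCalibration:
    """Calibrated initial probability plus the per-colony p_max sampler."""

    p_init: float
    p_max_sampler: EmpiricalRateSampler
    rate_map: RateSizeMap

    @property
    def p_max_median(self) -> float:
        return float(np.median(self.p_max_sampler.rates))


def calibrate_cohort(
    tolerant_sizes, resistant_sizes, rate_map: RateSizeMap
) -> CohortCalibration:
    """Derive (p_init, p_max sampler) from tolerant/resistant colony sizes."""
    tolerant_sizes = np.asarray(tolerant_sizes)
    resistant_sizes = np.asarray(resistant_sizes)
    if len(tolerant_sizes) == 0 or len(resistant_sizes) == 0:
        raise ValueError("both colony-size samples must be non-empty")
    p_init = float(rate_map.rate_for_size(np.median(tolerant_sizes)))
    sampler = EmpiricalRateSampler(resistant_sizes, rate_map, p_floor=p_init)
    return CohortCalibration(p_init=p_init, p_max_sampler=sampler, rate_map=rate_map)
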