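"""Limiting-dilution estimation of resistance-initiating cell frequency.

Cells are plated at a series of two-fold dilutions, many wells per dose,
and each well is scored negative when it contains no colony at or above
a size threshold.  Under single-hit kinetics a well seeded with ``d``
cells is negative with probability ``(1 - f)^d``, so

    ln(fraction negative) = d * ln(1 - f)

is linear through the origin in the seeding dose.  The fitted slope
``s`` gives the number of cells per resistance-initiating cell (RIC)

    cells_per_ric = 1 / (1 - e^s)

with delta-method standard error ``se_s * e^s / (1 - e^s)^2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LimitingDilutionPlate",
    "LimitingDilutionModel",
    "LimitingDilutionResults",
    "RICEstimate",
    "score_wells",
    "fit_limiting_dilution",
    "ric_frequency",
    "EstimationError",
]

DEFAULT_SCORING_THRESHOLD = 50  # cells: wells with no colony >= this are negative


class EstimationError(RuntimeError):
    """The plate carries no usable information for the single-hit fit."""


@dataclass
class LimitingDilutionPlate:
    """Per-dose summary of a limiting-dilution experiment."""

    doses: np.ndarray          # cells seeded per well, per dilution level
    wells_total: np.ndarray
    wells_negative: np.ndarray

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.wells_total = np.asarray(self.wells_total, dtype=np.int64)
        self.wells_negative = np.asarray(self.wells_negative, dtype=np.int64)
        if not (len(self.doses) == len(self.wells_total) == len(self.wells_negative)):
            raise ValueError("dose, total and negative arrays must align")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be > 0")
        if np.any(self.wells_negative < 0) or np.any(
            self.wells_negative > self.wells_total
        ):
            raise ValueError("need 0 <= wells_negative <= wells_total")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose_cells_per_well": self.doses,
                "wells_total": self.wells_total,
                "wells_negative": self.wells_negative,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LimitingDilutionPlate":
        required = {"dose_cells_per_well", "wells_total", "wells_negative"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"plate table missing columns: {sorted(missing)}")
        return cls(
            df["dose_cells_per_well"].to_numpy(),
            df["wells_total"].to_numpy(),
            df["wells_negative"].to_numpy(),
        )


def score_wells(
    per_well_sizes: pd.DataFrame, threshold: int = DEFAULT_SCORING_THRESHOLD
) -> LimitingDilutionPlate:
    """Score a long-form per-well colony table into a plate summary.

    ``per_well_sizes`` needs columns ``dose_cells_per_well``, ``well``
    and ``colony_size_cells``; every well must be listed, with empty
    wells carrying size 0 (or NaN).  A well is negative when its largest
    colony is strictly below ``threshold`` (a colony of exactly
    ``threshold`` cells makes the well positive).
    """
    required = {"dose_cells_per_well", "well", "colony_size_cells"}
    missing = required - set(per_well_sizes.columns)
    if missing:
        raise ValueError(f"per-well table missing columns: {sorted(missing)}")
    df = per_well_sizes.copy()
    df["colony_size_cells"] = df["colony_size_cells"].fillna(0)
    per_well = df.groupby(["dose_cells_per_well", "well"])["colony_size_cells"].max()
    negative = (per_well < threshold).groupby("dose_cells_per_well").sum()
    total = per_well.groupby("dose_cells_per_well").size()
    doses = np.sort(total.index.to_numpy())[::-1]
    return LimitingDilutionPlate(
        doses=doses,
        wells_total=total.loc[doses].to_numpy(),
        wells_negative=negative.loc[doses].to_numpy(),
    )


@dataclass
class RICEstimate:
    """Resistance-initiating cell frequency derived from a fitted slope."""

    slope: float
    slope_se: float
    cells_per_ric: float
    cells_per_ric_error: float
    per_cell_frequency: float


def ric_frequency(slope: float, slope_se: float = 0.0) -> RICEstimate:
    """Convert the fitted log-linear slope into a RIC frequency estimate.

    ``cells_per_ric = 1 / (1 - e^slope)`` and its delta-method error is
    ``slope_se * e^slope / (1 - e^slope)^2``; requires ``slope < 0``.
    """
    if not slope < 0:
        raise EstimationError(f"slope must be negative for a valid estimate, got {slope}")
    es = np.exp(slope)
    cells = 1.0 / (1.0 - es)
    err = slope_se * es / (1.0 - es) ** 2
    return RICEstimate(
        slope=float(slope),
        slope_se=float(slope_se),
        cells_per_ric=float(cells),
        cells_per_ric_error=float(err),
        per_cell_frequency=float(1.0 - es),
    )


def fit_limiting_dilution(
    plate: LimitingDilutionPlate,
    intercept: str = "zero",
    zero_negative: str = "drop",
    se_method: str = "binomial",
):
    """OLS fit of ln(fraction negative) against seeding dose.

    Dose levels with zero negative wells have an undefined log fraction;
    they are dropped with a warning (``zero_negative="drop"``, default)
    or continuity-corrected with +0.5 negatives (``"correct"``).  With
    ``intercept="zero"`` (default, the single-hit model) the line is
    forced through the origin; ``"free"`` adds an intercept.  Returns
    ``(slope, slope_se)``.

    The slope's standard error is, by default (``se_method="binomial"``),
    the sandwich form propagating the per-level binomial variance of
    ln(wells_negative / wells_total): the log fraction is strongly
    heteroscedastic across dilution levels, and the residual-based OLS
    error understates the sampling spread of the slope roughly two-fold
    on realistic plates.  ``se_method="residual"`` gives the classical
    homoscedastic OLS error instead (exactly 0 on noiseless data).
    """
    frac = np.full(len(plate.doses), np.nan)
    nz = plate.wells_negative > 0
    frac[nz] = plate.wells_negative[nz] / plate.wells_total[nz]
    if zero_negative == "correct":
        z = ~nz
        frac[z] = (plate.wells_negative[z] + 0.5) / (plate.wells_total[z] + 0.5)
        usable = np.ones(len(frac), dtype=bool)
    elif zero_negative == "drop":
        usable = nz
        if (~nz).any():
            warnings.warn(
                f"dropping {int((~nz).sum())} dose level(s) with zero negative wells "
                "(log fraction undefined)",
                stacklevel=2,
            )
    else:
        raise ValueError("zero_negative must be 'drop' or 'correct'")
    # a level where every well is negative carries no slope information loss;
    # it is kept (log fraction = 0 at the top of the line only when dose -> 0)
    d = plate.doses[usable]
    y = np.log(frac[usable])
    if len(d) < 2:
        raise EstimationError("fewer than 2 usable dilution levels")
    X = d[:, None] if intercept == "zero" else sm.add_constant(d)
    res = sm.OLS(y, X).fit()
    slope = res.params[-1]
    if se_method == "residual":
        slope_se = res.bse[-1]
        if np.isnan(slope_se):  # perfect fit with zero residual df: se is 0
            slope_se = 0.0
    elif se_method == "binomial":
        # delta-method variance of ln(n/N) per level, guarded at n = N
        n = plate.wells_negative[usable].astype(float)
        N = plate.wells_total[usable].astype(float)
        p = np.where(n == N, (n - 0.5) / N, n / N)
        sigma = (1.0 - p) / (N * p)
        xtx_inv = np.linalg.inv(X.T @ X)
        cov = xtx_inv @ (X.T * sigma) @ X @ xtx_inv
        slope_se = float(np.sqrt(cov[-1, -1]))
    else:
        raise ValueError("se_method must be 'binomial' or 'residual'")
    if not slope < 0:
        raise EstimationError(
            f"fitted slope {slope:.4g} is not negative; frequency inestimable"
        )
    return float(slope), float(slope_se)


class LimitingDilutionModel:
    """Single-hit frequency model for one limiting-dilution plate.

    Examples
    --------
    >>> plate = LimitingDilutionPlate([400, 200, 100], [10, 10, 10], [4, 7, 8])
    >>> res = LimitingDilutionModel(plate).fit()
    >>> round(res.estimate.cells_per_ric)  # doctest: +SKIP
    """

    def __init__(self, plate: LimitingDilutionPlate):
        self.plate = plate

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LimitingDilutionModel":
        return cls(LimitingDilutionPlate.from_frame(df))

    def fit(
        self,
        intercept: str = "zero",
        zero_negative: str = "drop",
        se_method: str = "binomial",
    ) -> "LimitingDilutionResults":
        slope, se = fit_limiting_dilution(self.plate, intercept, zero_negative, se_method)
        est = ric_frequency(slope, se)
        # flag when the free- and zero-intercept fits disagree materially
        alt_est = None
        try:
            other = "free" if intercept == "zero" else "zero"
            s2, se2 = fit_limiting_dilution(self.plate, other, zero_negative, se_method)
            alt_est = ric_frequency(s2, se2)
            rel = abs(alt_est.cells_per_ric - est.cells_per_ric) / est.cells_per_ric
            if rel > 0.10:
                warnings.warn(
                    f"zero- and free-intercept fits disagree by {rel:.0%} "
                    f"({est.cells_per_ric:.0f} vs {alt_est.cells_per_ric:.0f} cells/RIC)",
                    stacklevel=2,
                )
        except EstimationError:
            pass
        return LimitingDilutionResults(self, est, intercept, alt_est)


@dataclass
class LimitingDilutionResults:
    """Fitted RIC frequency with uncertainty."""

    model: LimitingDilutionModel
    estimate: RICEstimate
    intercept: str
    alternative_estimate: RICEstimate | None = None

    @property
    def cells_per_ric(self) -> float:
        return self.estimate.cells_per_ric

    @property
    def per_cell_frequency(self) -> float:
        return self.estimate.per_cell_frequency

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "Limiting-dilution single-hit fit",
            "================================",
            f"dilution levels used : {len(self.model.plate.doses)}",
            f"intercept            : {self.intercept}",
            f"slope (per cell)     : {e.slope:.6g} +/- {e.slope_se:.3g}",
            f"per-cell frequency   : {e.per_cell_frequency:.6g}",
            f"cells per RIC        : {e.cells_per_ric:.4g} +/- {e.cells_per_ric_error:.3g}",
        ]
        return "\n".join(lines)
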