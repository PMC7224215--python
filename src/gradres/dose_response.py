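"""Viability normalisation and four-parameter sigmoidal dose-response fits.

Raw luminescence is background-corrected against empty wells and scaled
so the DMSO (vehicle) wells average 100%, then the curve

    y = b + (100 - b) / (1 + (x / IC50)^k)

is fitted on the linear concentration axis by nonlinear least squares,
giving the bottom plateau ``b`` (% viability as x -> infinity), the hill
slope ``k`` and the half-maximal inhibitory concentration ``IC50``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "normalize_viability",
    "DoseResponseModel",
    "DoseResponseResults",
    "fit_dose_response",
    "PlateError",
]


class PlateError(ValueError):
    """The plate cannot be normalised (e.g. DMSO signal below background)."""


def _curve(x, b, k, ic50):
    return b + (100.0 - b) / (1.0 + (x / ic50) ** k)


def normalize_viability(plate: pd.DataFrame) -> pd.DataFrame:
    """Convert raw signal to % viability.

    Expects the long-form schema of
    :func:`gradres.synthetic.generate_dose_response_plate` (columns
    ``concentration``, ``replicate``, ``signal``, ``well_type``).
    Viability is ``100 * (signal - mean empty) / (mean DMSO - mean
    empty)``, so DMSO wells average exactly 100 by construction.
    Returns the treated and DMSO rows with a ``viability`` column.
    """
    for col in ("concentration", "signal", "well_type"):
        if col not in plate.columns:
            raise ValueError(f"plate table missing column {col!r}")
    empty = plate.loc[plate["well_type"] == "empty", "signal"]
    dmso = plate.loc[plate["well_type"] == "dmso", "signal"]
    if len(empty) == 0 or len(dmso) == 0:
        raise PlateError("plate needs at least one empty and one DMSO well")
    bg = empty.mean()
    ref = dmso.mean()
    if ref <= bg:
        raise PlateError(
            f"mean DMSO signal ({ref:.3g}) not above mean empty-well signal ({bg:.3g})"
        )
    out = plate.loc[plate["well_type"].isin(["treated", "dmso"])].copy()
    out["viability"] = 100.0 * (out["signal"] - bg) / (ref - bg)
    return out


@dataclass
class DoseResponseResults:
    """Fitted dose-response parameters with uncertainties."""

    b: float
    k: float
    ic50: float
    b_se: float
    k_se: float
    ic50_se: float
    residual_sse: float
    converged: bool
    n_obs: int

    def predict(self, x):
        return _curve(np.asarray(x, dtype=float), self.b, self.k, self.ic50)

    def summary(self) -> str:
        lines = [
            "Dose-response fit: y = b + (100 - b) / (1 + (x/IC50)^k)",
            "=======================================================",
            f"n observations : {self.n_obs}",
            f"converged      : {self.converged}",
            f"IC50           : {self.ic50:.6g} +/- {self.ic50_se:.3g}",
            f"hill slope k   : {self.k:.4g} +/- {self.k_se:.3g}",
            f"bottom b (%)   : {self.b:.4g} +/- {self.b_se:.3g}",
            f"residual SSE   : {self.residual_sse:.4g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Quick-look plot of the fitted curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lo = self.ic50 / 1e3
        xs = np.geomspace(lo, self.ic50 * 1e3, 200)
        ax.plot(xs, self.predict(xs))
        ax.set_xscale("log")
        ax.set_xlabel("concentration")
        ax.set_ylabel("viability (%)")
        return ax


class DoseResponseModel:
    """Nonlinear least-squares model for one drug's viability curve.

    Parameters
    ----------
    conc, viability : array-like
        Paired concentrations (>= 0; include the zero-dose anchor) and
        normalised viabilities (%).
    """

    #: deterministic initialisation: b0 = min viability, k0 = 1, ic50_0 =
    #: the positive concentration whose viability is closest to the
    #: half-way point (100 + b0) / 2.
    MAX_K = 10.0

    def __init__(self, conc, viability):
        self.conc = np.asarray(conc, dtype=float)
        self.viability = np.asarray(viability, dtype=float)
        if self.conc.shape != self.viability.shape:
            raise ValueError("conc and viability must align")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be >= 0")
        if not np.all(np.isfinite(self.viability)):
            raise ValueError("viability values must be finite")
        if len(np.unique(self.conc[self.conc > 0])) < 4:
            raise ValueError("need at least 4 distinct positive concentrations")

    @classmethod
    def from_plate(cls, plate: pd.DataFrame) -> "DoseResponseModel":
        """Build from a raw luminescence plate (normalises internally)."""
        v = normalize_viability(plate)
        return cls(v["concentration"].to_numpy(), v["viability"].to_numpy())

    def fit(self) -> DoseResponseResults:
        x = self.conc
        y = self.viability
        b0 = float(np.clip(y.min(), 0.0, 100.0))
        pos = x > 0
        half = (100.0 + b0) / 2.0
        ic50_0 = float(x[pos][np.argmin(np.abs(y[pos] - half))])
        if ic50_0 <= 0:
            ic50_0 = float(np.median(x[pos]))
        p0 = [b0, 1.0, ic50_0]
        ic50_hi = 1e4 * float(x.max())
        bounds = ([0.0, 1e-6, 1e-12], [100.0, self.MAX_K, ic50_hi])
        converged = True
        try:
            popt, pcov = curve_fit(
                _curve, x, y, p0=p0, bounds=bounds, maxfev=20000
            )
        except RuntimeError:
            popt, pcov = np.array(p0), np.full((3, 3), np.nan)
            converged = False
        resid = y - _curve(x, *popt)
        sse = float(resid @ resid)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(pcov))
        # an IC50 pinned at its bound, or a collapsed dynamic range
        # (b -> 100, e.g. flat data), leaves the midpoint unidentified:
        # flag rather than fail silently
        if (
            popt[2] >= 0.999 * ic50_hi
            or 100.0 - popt[0] < 1e-3
            or not np.all(np.isfinite(se))
        ):
            converged = False
        return DoseResponseResults(
            b=float(popt[0]),
            k=float(popt[1]),
            ic50=float(popt[2]),
            b_se=float(se[0]),
            k_se=float(se[1]),
            ic50_se=float(se[2]),
            residual_sse=sse,
            converged=converged,
            n_obs=len(x),
        )


def fit_dose_response(conc, viability) -> DoseResponseResults:
    """Functional wrapper around :class:`DoseResponseModel`."""
    return DoseResponseModel(conc, viability).fit()
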