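"""Synthetic-data generators for every input the analysis pipeline consumes.

No raw per-colony, per-well or per-barcode tables are publicly available
for the experiments these analyses were designed around, so each
generator emulates the statistical structure the corresponding analysis
assumes:

* colony-size samples: lognormal or lognormal-mixture distributions of
  per-colony cell counts (bimodal for a single-hit world, gradually
  shifting for multi-step adaptation);
* limiting-dilution plates: single-hit kinetics, i.e. a well seeded with
  ``d`` cells stays colony-free with probability ``(1 - f)^d``;
* barcode experiments: a clone pool in which a fixed set of clones per
  condition is expanded in every replicate (pre-existing, heritable
  advantage), with multinomial sequencing noise;
* viability plates: four-parameter sigmoidal dose-response with plate
  background and multiplicative measurement noise.

All generators draw from a single seeded :class:`numpy.random.Generator`
per call and are byte-reproducible given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abm import as_rng
from .limiting_dilution import LimitingDilutionPlate

__all__ = [
    "Lognormal",
    "ColonyPopulationSpec",
    "BarcodeSimSpec",
    "DoseResponseTruth",
    "generate_colony_sizes",
    "generate_limiting_dilution_plates",
    "generate_barcode_experiment",
    "generate_dose_response_plate",
    "sigmoid_viability",
]


@dataclass(frozen=True)
class Lognormal:
    """Lognormal distribution parametrised on the log scale."""

    meanlog: float
    sdlog: float

    def __post_init__(self):
        if self.sdlog < 0:
            raise ValueError("sdlog must be >= 0")

    @property
    def mean(self) -> float:
        return float(np.exp(self.meanlog + self.sdlog**2 / 2))

    def sample(self, n: int, rng) -> np.ndarray:
        return rng.lognormal(self.meanlog, self.sdlog, size=n)


@dataclass(frozen=True)
class ColonyPopulationSpec:
    """A population of colonies with a lognormal or mixture size law.

    ``components`` is a list of ``(weight, Lognormal)`` pairs; a single
    pair with weight 1 describes a plain lognormal.  Sizes are cell
    counts, so draws are rounded half-up and clipped at ``min_size``.
    """

    name: str
    components: tuple
    min_size: int = 1

    def __post_init__(self):
        if not self.components:
            raise ValueError("at least one mixture component required")
        w = sum(c[0] for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {w}")
        for wt, comp in self.components:
            if wt < 0:
                raise ValueError("mixture weights must be >= 0")
            if not isinstance(comp, Lognormal):
                raise TypeError("components must be (weight, Lognormal) pairs")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")

    @classmethod
    def lognormal(cls, name: str, meanlog: float, sdlog: float, min_size: int = 1):
        return cls(name, ((1.0, Lognormal(meanlog, sdlog)),), min_size)

    @classmethod
    def mixture(cls, name: str, components, min_size: int = 1):
        return cls(name, tuple((w, c) for w, c in components), min_size)


def generate_colony_sizes(spec: ColonyPopulationSpec, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` integer colony sizes (cells) from the spec's distribution."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = as_rng(seed)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    weights = np.array([w for w, _ in spec.components])
    which = rng.choice(len(spec.components), size=n, p=weights / weights.sum())
    raw = np.empty(n)
    for i, (_, comp) in enumerate(spec.components):
        m = which == i
        raw[m] = comp.sample(int(m.sum()), rng)
    sizes = np.floor(raw + 0.5).astype(np.int64)  # round half-up
    return np.maximum(sizes, spec.min_size)


def generate_limiting_dilution_plates(
    per_cell_freq: float,
    top_densities,
    n_twofold_dilutions: int = 5,
    wells_per_density: int = 10,
    seed=None,
) -> LimitingDilutionPlate:
    """Simulate negative-well counts under single-hit kinetics.

    For each top density the dose series is the density followed by
    ``n_twofold_dilutions`` successive two-fold dilutions; at dose ``d``
    the number of colony-free wells is ``Binomial(wells, (1 - f)^d)``.
    """
    if not (0 < per_cell_freq < 1):
        raise ValueError("per_cell_freq must lie strictly in (0, 1)")
    rng = as_rng(seed)
    doses: list[float] = []
    for top in np.atleast_1d(np.asarray(top_densities, dtype=float)):
        doses.extend(top / 2.0**j for j in range(n_twofold_dilutions + 1))
    doses = sorted(set(doses), reverse=True)
    doses_arr = np.array(doses)
    p_neg = (1.0 - per_cell_freq) ** doses_arr
    negative = rng.binomial(wells_per_density, p_neg)
    return LimitingDilutionPlate(
        doses=doses_arr,
        wells_total=np.full(len(doses), wells_per_density, dtype=np.int64),
        wells_negative=negative.astype(np.int64),
    )


@dataclass(frozen=True)
class BarcodeSimSpec:
    """Generative spec for a clone-tracing experiment.

    A fixed ``expanded_fraction`` of barcodes per condition carries a
    heritable growth advantage: the same barcode set is amplified in all
    replicates of that condition (clone identity is decided before the
    cultures are split), while the realised growth factor of each clone
    is re-drawn per replicate.  ``selection_overlap`` is the proportion
    of each condition's expanded set shared across all conditions.
    """

    n_barcodes: int = 1000
    baseline_abundance: Lognormal = field(default_factory=lambda: Lognormal(0.0, 0.5))
    n_conditions: int = 3
    n_replicates_per_condition: int = 4
    expanded_fraction: float = 0.01
    selection_overlap: float = 0.0
    growth_factor: Lognormal = field(default_factory=lambda: Lognormal(3.0, 0.5))
    sequencing_depth: int = 1_000_000
    n_baseline_samples: int = 2

    def __post_init__(self):
        if self.n_barcodes < 1:
            raise ValueError("n_barcodes must be >= 1")
        if not (0.0 <= self.expanded_fraction <= 1.0):
            raise ValueError("expanded_fraction must lie in [0, 1]")
        if not (0.0 <= self.selection_overlap <= 1.0):
            raise ValueError("selection_overlap must lie in [0, 1]")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be > 0")


def generate_barcode_experiment(spec: BarcodeSimSpec, seed=None):
    """Simulate a barcode count table plus the planted ground truth.

    Returns ``(table, truth)`` where ``table`` is a
    :class:`gradres.barcode.BarcodeTable` holding read counts for
    ``n_baseline_samples`` baseline samples and every condition x
    replicate sample, and ``truth`` maps condition name -> array of
    expanded (planted) barcode ids.
    """
    from .barcode import BarcodeTable  # deferred: avoids import cycle

    rng = as_rng(seed)
    nb = spec.n_barcodes
    barcode_ids = np.array([f"bc{i:05d}" for i in range(nb)])
    base_weights = spec.baseline_abundance.sample(nb, rng)
    base_freq = base_weights / base_weights.sum()

    n_exp = int(round(spec.expanded_fraction * nb))
    n_shared = int(round(spec.selection_overlap * n_exp))
    pool = rng.permutation(nb)
    shared = pool[:n_shared]
    cursor = n_shared
    conditions = [f"cond{c + 1}" for c in range(spec.n_conditions)]
    truth: dict[str, np.ndarray] = {}
    for cond in conditions:
        own = pool[cursor : cursor + (n_exp - n_shared)]
        cursor += n_exp - n_shared
        truth[cond] = np.sort(np.concatenate([shared, own]))

    counts = {}
    roles = {}
    for b in range(spec.n_baseline_samples):
        name = f"baseline_{b + 1}"
        counts[name] = rng.multinomial(spec.sequencing_depth, base_freq)
        roles[name] = "baseline"
    for cond in conditions:
        for r in range(spec.n_replicates_per_condition):
            w = base_weights.copy()
            gf = spec.growth_factor.sample(len(truth[cond]), rng)
            w[truth[cond]] *= gf
            name = f"{cond}_rep{r + 1}"
            counts[name] = rng.multinomial(spec.sequencing_depth, w / w.sum())
            roles[name] = cond
    table = pd.DataFrame(counts, index=barcode_ids)
    return BarcodeTable(table, roles), {c: barcode_ids[idx] for c, idx in truth.items()}


@dataclass(frozen=True)
class DoseResponseTruth:
    """Ground-truth parameters of a simulated viability plate.

    ``b`` is the bottom plateau (% viability as dose -> infinity), ``k``
    the hill slope, ``ic50`` the half-maximal concentration (same units
    as the doses), ``noise_cv`` the coefficient of variation of the
    multiplicative measurement noise and ``background`` the raw signal
    of an empty well.
    """

    b: float
    k: float
    ic50: float
    noise_cv: float = 0.0
    background: float = 500.0
    scale: float = 1_000_000.0

    def __post_init__(self):
        if self.ic50 <= 0:
            raise ValueError("ic50 must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not (0.0 <= self.b <= 100.0):
            raise ValueError("b must lie in [0, 100]")


def sigmoid_viability(x, b: float, k: float, ic50: float):
    """Four-parameter viability curve y = b + (100 - b) / (1 + (x/IC50)^k)."""
    x = np.asarray(x, dtype=float)
    return b + (100.0 - b) / (1.0 + (x / ic50) ** k)


def generate_dose_response_plate(
    truth: DoseResponseTruth,
    concentrations,
    n_replicates: int = 3,
    seed=None,
) -> pd.DataFrame:
    """Simulate a luminescence plate table.

    Returns a long-form frame with columns ``concentration``,
    ``replicate``, ``signal`` and ``well_type`` in {treated, dmso,
    empty}; DMSO (zero-dose) wells and empty wells are always included.
    Signal is ``background + scale * y(x)/100 * (1 + eps)`` with
    ``eps ~ Normal(0, noise_cv)``; empty wells carry background only.
    """
    rng = as_rng(seed)
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    conc = conc[conc > 0]  # zero dose is represented by the DMSO wells
    rows = []

    def noise():
        return 1.0 + rng.normal(0.0, truth.noise_cv) if truth.noise_cv > 0 else 1.0

    for r in range(1, n_replicates + 1):
        rows.append((0.0, r, truth.background + truth.scale * noise(), "dmso"))
        rows.append((np.nan, r, truth.background * noise(), "empty"))
        for x in conc:
            y = float(sigmoid_viability(x, truth.b, truth.k, truth.ic50))
            rows.append((x, r, truth.background + truth.scale * y / 100.0 * noise(), "treated"))
    return pd.DataFrame(rows, columns=["concentration", "replicate", "signal", "well_type"])
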