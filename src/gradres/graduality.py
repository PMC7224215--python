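"""Single-hit versus gradual resistance: KL grid scan and KS mixture test.

Two complementary analyses of colony-size distributions:

``GradualityScan``
    Simulates clonogenic cohorts across a grid of (mutation probability
    mu, number of (epi)mutational steps n) and scores each parameter
    pair by the Kullback-Leibler divergence D(observed || simulated)
    between histograms of colony sizes, averaged over pre-incubation
    timepoints.  A single-hit world corresponds to n = 1; a gradual one
    to n >> 1.  The best-fit region is the set of grid cells whose
    divergence is within a relative tolerance of the minimum.

``MixtureNullModel``
    Tests whether an observed colony-size sample can be explained as a
    weighted mixture of the tolerant and fully-resistant reference
    distributions (the single-hit expectation at an intermediate
    timepoint).  The mixing weight alpha is fitted by minimising the
    Kolmogorov-Smirnov distance over a fine grid, and significance comes
    from a parametric bootstrap under the fitted mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abm import SimulationParams, as_rng, run_colony_cohort

__all__ = [
    "SizeHistogram",
    "size_histogram",
    "shared_log2_edges",
    "kl_divergence",
    "kl_between_samples",
    "GradualityScan",
    "GradualityResults",
    "MixtureNullModel",
    "MixtureTestResult",
    "ks_mixture_test",
    "clonogenic_fraction",
]


# ---------------------------------------------------------------------------
# histograms and KL divergence
# ---------------------------------------------------------------------------

@dataclass
class SizeHistogram:
    """Normalised colony-size histogram with pseudocounts.

    ``probs`` sums to 1 and every bin is strictly positive (a Laplace
    pseudocount is added before normalisation), so KL divergences are
    always finite.
    """

    bin_edges: np.ndarray
    probs: np.ndarray
    pseudocount: float = 1.0

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.probs) != len(self.bin_edges) - 1:
            raise ValueError("probs/edges length mismatch")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probs must sum to 1")
        if np.any(self.probs <= 0):
            raise ValueError("all probs must be > 0 after pseudocount")


def shared_log2_edges(*samples) -> np.ndarray:
    """log2-spaced bin edges (powers of two) spanning all given samples."""
    lo = 0
    hi = 1
    for s in samples:
        s = np.asarray(s)
        if len(s) == 0:
            raise ValueError("cannot bin an empty sample")
        if np.any(s < 1):
            raise ValueError("colony sizes must be >= 1")
        hi = max(hi, int(np.ceil(np.log2(s.max() + 1))))
    return 2.0 ** np.arange(lo, hi + 1)


def size_histogram(sizes, bin_edges=None, pseudocount: float = 1.0) -> SizeHistogram:
    """Histogram of colony sizes on log2 bins, pseudocounted and normalised."""
    sizes = np.asarray(sizes)
    if len(sizes) == 0:
        raise ValueError("cannot histogram an empty colony-size sample")
    if bin_edges is None:
        bin_edges = shared_log2_edges(sizes)
    bin_edges = np.asarray(bin_edges, dtype=float)
    counts, _ = np.histogram(sizes, bins=bin_edges)
    counts = counts.astype(float) + pseudocount
    return SizeHistogram(bin_edges, counts / counts.sum(), pseudocount)


def kl_divergence(P: SizeHistogram, Q: SizeHistogram) -> float:
    """D(P || Q) = sum_i P_i ln(P_i / Q_i), in nats.

    The direction is fixed as D(observed || simulated): a simulated
    model is penalised for assigning low probability where data exist.
    """
    if len(P.bin_edges) != len(Q.bin_edges) or not np.allclose(P.bin_edges, Q.bin_edges):
        raise ValueError("histograms must share identical bin edges")
    d = float(np.sum(P.probs * np.log(P.probs / Q.probs)))
    if d < 0:  # only reachable through rounding; KL is non-negative
        if d < -1e-12:
            raise AssertionError(f"negative KL divergence {d}")
        d = 0.0
    return d


def kl_between_samples(observed, simulated, pseudocount: float = 1.0) -> float:
    """KL divergence between two size samples on shared log2 bins."""
    edges = shared_log2_edges(observed, simulated)
    P = size_histogram(observed, edges, pseudocount)
    Q = size_histogram(simulated, edges, pseudocount)
    return kl_divergence(P, Q)


# ---------------------------------------------------------------------------
# KL grid scan over (mu, n)
# ---------------------------------------------------------------------------

@dataclass
class GradualityResults:
    """KL divergence surface over the (mu, n_steps) grid."""

    mu_values: np.ndarray
    n_values: np.ndarray
    divergence: np.ndarray  # shape (len(mu), len(n)), nats
    reps: int

    def __post_init__(self):
        if self.divergence.shape != (len(self.mu_values), len(self.n_values)):
            raise ValueError("divergence matrix does not match the grids")
        if np.any(self.divergence < 0):
            raise AssertionError("negative KL in grid")

    @property
    def argmin(self) -> tuple[float, int]:
        i, j = np.unravel_index(np.argmin(self.divergence), self.divergence.shape)
        return float(self.mu_values[i]), int(self.n_values[j])

    def best_fit_region(self, tolerance: float = 0.0):
        """All (mu, n) cells with divergence <= (1 + tolerance) * minimum."""
        dmin = self.divergence.min()
        cells = []
        for i, mu in enumerate(self.mu_values):
            for j, n in enumerate(self.n_values):
                if self.divergence[i, j] <= (1.0 + tolerance) * dmin:
                    cells.append((float(mu), int(n)))
        return cells

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (mu, n, self.divergence[i, j])
            for i, mu in enumerate(self.mu_values)
            for j, n in enumerate(self.n_values)
        ]
        return pd.DataFrame(rows, columns=["mu", "n", "kl_nats"])

    def summary(self) -> str:
        mu, n = self.argmin
        lines = [
            "KL model selection over (mu, n_steps)",
            "=====================================",
            f"grid            : {len(self.mu_values)} mu x {len(self.n_values)} n "
            f"({self.reps} colonies per cell)",
            f"minimum KL      : {self.divergence.min():.4f} nats at mu={mu:g}, n={n}",
            f"KL at n=1 (min over mu) : "
            + (
                f"{self.divergence[:, list(self.n_values).index(1)].min():.4f} nats"
                if 1 in self.n_values
                else "n=1 not in grid"
            ),
        ]
        return "\n".join(lines)

    def plot_heatmap(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.divergence, aspect="auto", origin="lower")
        ax.set_xticks(range(len(self.n_values)), [str(n) for n in self.n_values])
        ax.set_yticks(range(len(self.mu_values)), [f"{m:g}" for m in self.mu_values])
        ax.set_xlabel("(epi)mutational steps n")
        ax.set_ylabel("mutation probability mu")
        plt.colorbar(im, ax=ax, label="KL divergence (nats)")
        return ax


class GradualityScan:
    """Grid scan of the lattice model against observed colony sizes.

    Parameters
    ----------
    observed : mapping
        ``{preincubation_weeks: colony-size array}`` — the experimental
        colony sizes per timepoint.
    p_init : float
        Calibrated tolerant division probability.
    p_max_sampler
        Per-colony maximal division probability: scalar, callable(rng),
        or an array resampled with replacement (see
        :func:`gradres.abm.run_colony_cohort`).
    """

    def __init__(
        self,
        observed: dict,
        p_init: float,
        p_max_sampler,
        clonogenic_days: int = 7,
        updates_per_day: int = 2,
        death_prob: float = 0.0,
        bidirectional: bool = False,
        effect_sd: float = 0.0,
        pseudocount: float = 1.0,
    ):
        if not observed:
            raise ValueError("need at least one observed timepoint")
        self.observed = {int(w): np.asarray(s) for w, s in observed.items()}
        for w, s in self.observed.items():
            if len(s) == 0:
                raise ValueError(f"observed sample at week {w} is empty")
        self.p_init = p_init
        self.p_max_sampler = p_max_sampler
        self.clonogenic_days = clonogenic_days
        self.updates_per_day = updates_per_day
        self.death_prob = death_prob
        self.bidirectional = bidirectional
        self.effect_sd = effect_sd
        self.pseudocount = pseudocount

    def _params(self, mu: float, n: int) -> SimulationParams:
        # bulk pre-incubation uses the sampler's central p_max
        sampler = self.p_max_sampler
        if np.isscalar(sampler):
            p_max_bulk = float(sampler)
        elif callable(sampler):
            rates = getattr(sampler, "rates", None)
            p_max_bulk = float(np.median(rates)) if rates is not None else None
            if p_max_bulk is None:
                probe = np.random.default_rng(0)
                p_max_bulk = float(np.median([sampler(probe) for _ in range(199)]))
        else:
            p_max_bulk = float(np.median(np.asarray(sampler)))
        return SimulationParams(
            p_init=self.p_init,
            p_max=max(p_max_bulk, self.p_init),
            n_steps=n,
            mu=mu,
            death_prob=self.death_prob,
            bidirectional=self.bidirectional,
            effect_sd=self.effect_sd,
            updates_per_day=self.updates_per_day,
        )

    def simulate_cohorts(self, mu: float, n: int, reps: int, rng) -> dict:
        """One simulated cohort per observed timepoint at grid cell (mu, n)."""
        params = self._params(mu, n)
        return {
            w: run_colony_cohort(
                params,
                preincubation_weeks=w,
                n_colonies=reps,
                p_max_sampler=self.p_max_sampler,
                clonogenic_days=self.clonogenic_days,
                rng=rng,
            )
            for w in self.observed
        }

    def fit(self, mu_values, n_values, reps: int = 2000, seed=None) -> GradualityResults:
        """Populate the KL grid: mean D(observed || simulated) over timepoints."""
        rng = as_rng(seed)
        mu_values = np.asarray(mu_values, dtype=float)
        n_values = np.asarray(n_values, dtype=int)
        D = np.empty((len(mu_values), len(n_values)))
        for i, mu in enumerate(mu_values):
            for j, n in enumerate(n_values):
                cohorts = self.simulate_cohorts(float(mu), int(n), reps, rng)
                kls = [
                    kl_between_samples(self.observed[w], cohorts[w], self.pseudocount)
                    for w in self.observed
                ]
                D[i, j] = float(np.mean(kls))
        return GradualityResults(mu_values, n_values, D, reps)


# ---------------------------------------------------------------------------
# KS mixture test
# ---------------------------------------------------------------------------

def _ecdf_at(sorted_sample: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.searchsorted(sorted_sample, grid, side="right") / len(sorted_sample)


def _fit_mixture_alpha(obs, tol_sorted, res_sorted, alphas):
    """Minimise KS distance between obs and alpha*F_tol + (1-alpha)*F_res.

    Both CDFs are step functions, so the supremum is attained at a jump
    point of the pooled sample; evaluating right-limits there is exact.
    """
    obs_sorted = np.sort(obs)
    grid = np.unique(np.concatenate([obs_sorted, tol_sorted, res_sorted]))
    Fo = _ecdf_at(obs_sorted, grid)
    Ft = _ecdf_at(tol_sorted, grid)
    Fr = _ecdf_at(res_sorted, grid)
    u = Fo - Fr
    v = Ft - Fr
    D = np.abs(u[None, :] - alphas[:, None] * v[None, :]).max(axis=1)
    i = int(np.argmin(D))
    return float(alphas[i]), float(D[i])


@dataclass
class MixtureTestResult:
    """Outcome of the tolerant/resistant mixture KS test."""

    alpha_hat: float
    ks_stat: float
    p_value: float
    n_boot: int

    def __post_init__(self):
        if not (0.0 <= self.alpha_hat <= 1.0):
            raise AssertionError("alpha_hat outside [0, 1]")
        if not (0.0 <= self.ks_stat <= 1.0):
            raise AssertionError("ks_stat outside [0, 1]")
        if not (0.0 <= self.p_value <= 1.0):
            raise AssertionError("p_value outside [0, 1]")

    def summary(self) -> str:
        return (
            "KS mixture test (observed vs alpha*tolerant + (1-alpha)*resistant)\n"
            "==================================================================\n"
            f"fitted tolerant fraction alpha : {self.alpha_hat:.2f}\n"
            f"KS distance at alpha-hat       : {self.ks_stat:.4f}\n"
            f"bootstrap p-value              : {self.p_value:.4g} "
            f"({self.n_boot} parametric bootstrap draws)"
        )


class MixtureNullModel:
    """Can the observed sizes be a mixture of the two reference samples?

    The null hypothesis is single-hit: every colony is founded either by
    a tolerant cell or a fully resistant one, so the observed size
    distribution must be a two-component mixture of the reference
    distributions.  Rejection indicates sizes (e.g. a unimodal
    intermediate distribution) incompatible with any mixing weight.
    """

    def __init__(self, observed, tolerant_ref, resistant_ref, alpha_step: float = 0.01):
        self.observed = np.asarray(observed, dtype=float)
        self.tolerant = np.sort(np.asarray(tolerant_ref, dtype=float))
        self.resistant = np.sort(np.asarray(resistant_ref, dtype=float))
        for name, s in (
            ("observed", self.observed),
            ("tolerant_ref", self.tolerant),
            ("resistant_ref", self.resistant),
        ):
            if len(s) == 0:
                raise ValueError(f"{name} sample is empty")
        refs = np.concatenate([self.tolerant, self.resistant])
        if np.all(refs == refs[0]):
            raise ValueError(
                "both reference samples are a single identical value; "
                "the mixture null is degenerate"
            )
        self.alphas = np.arange(0.0, 1.0 + alpha_step / 2, alpha_step)

    def fit(self, n_boot: int = 1000, seed=None) -> MixtureTestResult:
        if n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        rng = as_rng(seed)
        alpha_hat, ks = _fit_mixture_alpha(
            self.observed, self.tolerant, self.resistant, self.alphas
        )
        n = len(self.observed)
        # parametric bootstrap from the fitted empirical mixture, refitting
        # alpha on every replicate (the null has an estimated parameter)
        exceed = 0
        for _ in range(n_boot):
            from_tol = rng.random(n) < alpha_hat
            k = int(from_tol.sum())
            boot = np.empty(n)
            boot[:k] = rng.choice(self.tolerant, size=k, replace=True)
            boot[k:] = rng.choice(self.resistant, size=n - k, replace=True)
            _, d = _fit_mixture_alpha(boot, self.tolerant, self.resistant, self.alphas)
            if d >= ks:
                exceed += 1
        return MixtureTestResult(alpha_hat, ks, exceed / n_boot, n_boot)


def ks_mixture_test(
    observed, tolerant_ref, resistant_ref, n_boot: int = 1000, seed=None
) -> MixtureTestResult:
    """Functional wrapper around :class:`MixtureNullModel`."""
    return MixtureNullModel(observed, tolerant_ref, resistant_ref).fit(n_boot, seed)


# ---------------------------------------------------------------------------
# clonogenic fraction
# ---------------------------------------------------------------------------

def clonogenic_fraction(
    treated_sizes,
    seeded_treated: int,
    dmso_sizes,
    seeded_dmso: int,
    min_size: int = 5,
) -> float:
    """Vehicle-normalised clonogenic survival.

    Colonies of at least ``min_size`` cells count (default 5, the
    macroscopic-colony threshold); the treated plating efficiency is
    divided by the DMSO (vehicle) plating efficiency.
    """
    if seeded_treated <= 0 or seeded_dmso <= 0:
        raise ValueError("seeded cell counts must be > 0")
    treated = np.asarray(treated_sizes)
    dmso = np.asarray(dmso_sizes)
    n_dmso = int((dmso >= min_size).sum())
    if n_dmso == 0:
        raise ValueError("no DMSO colonies above threshold: normalisation undefined")
    n_treated = int((treated >= min_size).sum())
    return (n_treated / seeded_treated) / (n_dmso / seeded_dmso)
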