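"""Agent-based model of colony growth on a 2D lattice.

Cells occupy sites of a square lattice (the surface of a culture dish).
Each update round, every live cell — visited in a freshly randomised
order — may die, and otherwise attempts to divide with a probability that
depends on how many heritable (epi)mutational steps it has accumulated:

    p(k) = p_init + k * (p_max - p_init) / n_steps,   k = 0 .. n_steps

Division requires space: an empty site among the cell's neighbours, or an
empty site separated from it by exactly one occupied neighbour, in which
case the intervening cell is pushed outward into that empty site and the
daughter takes its place.  At each division, each of the two daughter
cells independently gains one step with probability ``mu`` (optionally
bidirectional, optionally with variable per-step fitness increments).

The hot loop is compiled with numba; :mod:`gradres.reference` holds an
independently written pure-Python simulator used only for cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

__all__ = [
    "SimulationParams",
    "LatticeState",
    "ColonySimResult",
    "LatticeBoundaryError",
    "step_lattice",
    "simulate_colony",
    "simulate_preincubation",
    "run_colony_cohort",
    "as_rng",
]

_STATUS_OK = 0
_STATUS_BOUNDARY = 1

MAX_SEED = 2**31 - 1


def as_rng(seed) -> np.random.Generator:
    """Return a numpy Generator from a seed, Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class LatticeBoundaryError(RuntimeError):
    """A colony touched the lattice boundary: the lattice is too small."""


@dataclass(frozen=True)
class SimulationParams:
    """Parameter bundle for the lattice agent-based model.

    Parameters
    ----------
    p_init : float
        Division probability per update of an unmutated (step-0) cell,
        i.e. the drug-tolerant state.
    p_max : float
        Division probability per update of a fully adapted (step-n) cell,
        i.e. the fully resistant state.
    n_steps : int
        Number of (epi)mutational steps separating the tolerant from the
        fully resistant state; each step confers a fractional increment
        ``(p_max - p_init) / n_steps``.
    mu : float
        Probability, per daughter cell per division, of gaining one step.
    death_prob : float
        Probability per update of cell death (default 0, no death).
    bidirectional : bool
        If True a (epi)mutation event moves the step index +1 or -1 with
        equal odds (floored at 0, capped at ``n_steps``).
    effect_sd : float
        Relative spread of per-step fitness increments.  0 (default)
        means every step adds exactly the mean increment; otherwise each
        gained increment is drawn from
        ``Normal(mean_inc, effect_sd * mean_inc)`` truncated at 0.
    updates_per_day : int
        Lattice update rounds per day of wall-clock experiment time; the
        default 2 makes ``p = 1`` approximate a ~12 h minimum cell cycle.
    neighborhood : str
        ``"moore"`` (8 neighbours, default) or ``"von_neumann"`` (4).
    lattice_size : int
        Default side of the square lattice for standalone colony runs.
    """

    p_init: float
    p_max: float
    n_steps: int = 1
    mu: float = 0.0
    death_prob: float = 0.0
    bidirectional: bool = False
    effect_sd: float = 0.0
    updates_per_day: int = 2
    neighborhood: str = "moore"
    lattice_size: int = 401

    def __post_init__(self):
        if not (0.0 <= self.p_init <= self.p_max <= 1.0):
            raise ValueError(
                f"need 0 <= p_init <= p_max <= 1, got {self.p_init}, {self.p_max}"
            )
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must lie in [0, 1]")
        if not (0.0 <= self.death_prob < 1.0):
            raise ValueError("death_prob must lie in [0, 1)")
        if self.effect_sd < 0:
            raise ValueError("effect_sd must be >= 0")
        if self.updates_per_day < 1:
            raise ValueError("updates_per_day must be >= 1")
        if self.neighborhood not in ("moore", "von_neumann"):
            raise ValueError("neighborhood must be 'moore' or 'von_neumann'")

    def division_prob(self, k):
        """p(k): linear interpolation from p_init (k=0) to p_max (k=n_steps)."""
        k = np.asarray(k)
        if np.any((k < 0) | (k > self.n_steps)):
            raise ValueError("step index outside [0, n_steps]")
        return self.p_init + k * (self.p_max - self.p_init) / self.n_steps

    def with_(self, **kw) -> "SimulationParams":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _run_rounds(
    grid, xs, ys, ks, ps, alive, n_cells, n_rounds,
    n_steps, p_init, p_max, mu, death_prob, bidirectional, effect_sd,
    moore, error_on_boundary, seed, traj,
):  # pragma: no cover - exercised via wrappers
    """Advance the lattice ``n_rounds`` update rounds in place.

    grid[y, x] holds the cell index occupying the site, -1 if empty.
    Returns (n_cells, n_alive, status).
    """
    np.random.seed(seed)
    h, w = grid.shape
    dp = (p_max - p_init) / n_steps
    if moore:
        n_off = 8
        offx = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)
        offy = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)
    else:
        n_off = 4
        offx = np.array([0, -1, 1, 0], dtype=np.int64)
        offy = np.array([-1, 0, 0, 1], dtype=np.int64)

    cand_x = np.empty(8, dtype=np.int64)
    cand_y = np.empty(8, dtype=np.int64)
    cand_push = np.empty(8, dtype=np.uint8)
    emp_x = np.empty(8, dtype=np.int64)
    emp_y = np.empty(8, dtype=np.int64)

    n_alive = 0
    for i in range(n_cells):
        if alive[i]:
            n_alive += 1
    if traj.shape[0] > 0:
        traj[0] = n_alive

    order = np.empty(grid.size, dtype=np.int64)
    status = _STATUS_OK

    for r in range(n_rounds):
        n0 = n_cells
        m = 0
        for i in range(n0):
            if alive[i]:
                order[m] = i
                m += 1
        # Fisher-Yates shuffle of this round's processing order
        for i in range(m - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmp = order[i]
            order[i] = order[j]
            order[j] = tmp

        for t in range(m):
            i = order[t]
            if not alive[i]:
                continue
            if death_prob > 0.0 and np.random.random() < death_prob:
                alive[i] = False
                grid[ys[i], xs[i]] = -1
                n_alive -= 1
                continue
            if np.random.random() >= ps[i]:
                continue
            x = xs[i]
            y = ys[i]
            nc = 0
            for o in range(n_off):
                nx = x + offx[o]
                ny = y + offy[o]
                if nx < 0 or nx >= w or ny < 0 or ny >= h:
                    continue
                if grid[ny, nx] < 0:
                    cand_x[nc] = nx
                    cand_y[nc] = ny
                    cand_push[nc] = 0
                    nc += 1
                else:
                    # occupied neighbour is pushable iff it has an empty neighbour
                    ok = False
                    for o2 in range(n_off):
                        mx = nx + offx[o2]
                        my = ny + offy[o2]
                        if mx < 0 or mx >= w or my < 0 or my >= h:
                            continue
                        if grid[my, mx] < 0:
                            ok = True
                            break
                    if ok:
                        cand_x[nc] = nx
                        cand_y[nc] = ny
                        cand_push[nc] = 1
                        nc += 1
            if nc == 0:
                continue  # contact-inhibited: no reachable empty site
            c = np.random.randint(0, nc)
            tx = cand_x[c]
            ty = cand_y[c]
            if cand_push[c] == 1:
                ne = 0
                for o2 in range(n_off):
                    ex = tx + offx[o2]
                    ey = ty + offy[o2]
                    if ex < 0 or ex >= w or ey < 0 or ey >= h:
                        continue
                    if grid[ey, ex] < 0:
                        emp_x[ne] = ex
                        emp_y[ne] = ey
                        ne += 1
                e = np.random.randint(0, ne)
                ex = emp_x[e]
                ey = emp_y[e]
                if error_on_boundary and (
                    ex == 0 or ex == w - 1 or ey == 0 or ey == h - 1
                ):
                    return n_cells, n_alive, _STATUS_BOUNDARY
                di = grid[ty, tx]
                grid[ey, ex] = di
                xs[di] = ex
                ys[di] = ey
                grid[ty, tx] = -1
            if error_on_boundary and (
                tx == 0 or tx == w - 1 or ty == 0 or ty == h - 1
            ):
                return n_cells, n_alive, _STATUS_BOUNDARY
            # place daughter
            ni = n_cells
            xs[ni] = tx
            ys[ni] = ty
            ks[ni] = ks[i]
            ps[ni] = ps[i]
            alive[ni] = True
            grid[ty, tx] = ni
            n_cells += 1
            n_alive += 1
            # each daughter cell independently acquires an (epi)mutation
            for d in range(2):
                ci = i if d == 0 else ni
                if np.random.random() >= mu:
                    continue
                k = ks[ci]
                if bidirectional:
                    delta = 1 if np.random.random() < 0.5 else -1
                else:
                    delta = 1
                k2 = k + delta
                if k2 < 0:
                    k2 = 0
                if k2 > n_steps:
                    k2 = n_steps
                if k2 == k:
                    continue
                ks[ci] = k2
                if effect_sd == 0.0:
                    ps[ci] = p_init + k2 * dp  # exact endpoints by construction
                else:
                    inc = np.random.normal(dp, effect_sd * dp)
                    if inc < 0.0:
                        inc = 0.0
                    p2 = ps[ci] + inc * delta
                    if p2 < p_init:
                        p2 = p_init
                    if p2 > 1.0:
                        p2 = 1.0
                    ps[ci] = p2
        if traj.shape[0] > r + 1:
            traj[r + 1] = n_alive
    return n_cells, n_alive, status


@njit(cache=True)
def _cohort_sizes(
    side, n_rounds, founder_steps, p_maxes, seeds,
    n_steps, p_init, mu, death_prob, bidirectional, effect_sd, moore,
):  # pragma: no cover - exercised via wrappers
    """Grow one colony per (founder step, p_max, seed) triple; return sizes.

    Shared buffers are reused across colonies and wiped between runs.
    Returns (sizes, max_bbox_side, status).
    """
    n_col = founder_steps.shape[0]
    cap = side * side
    grid = np.full((side, side), -1, dtype=np.int64)
    xs = np.empty(cap, dtype=np.int64)
    ys = np.empty(cap, dtype=np.int64)
    ks = np.empty(cap, dtype=np.int64)
    ps = np.empty(cap, dtype=np.float64)
    alive = np.zeros(cap, dtype=np.bool_)
    traj = np.empty(0, dtype=np.int64)
    sizes = np.empty(n_col, dtype=np.int64)
    c0 = side // 2
    max_bbox = 1
    for j in range(n_col):
        k0 = founder_steps[j]
        p_max = p_maxes[j]
        dp = (p_max - p_init) / n_steps
        xs[0] = c0
        ys[0] = c0
        ks[0] = k0
        ps[0] = p_init + k0 * dp
        alive[0] = True
        grid[c0, c0] = 0
        n_cells, n_alive, status = _run_rounds(
            grid, xs, ys, ks, ps, alive, 1, n_rounds,
            n_steps, p_init, p_max, mu, death_prob, bidirectional, effect_sd,
            moore, True, seeds[j], traj,
        )
        if status != _STATUS_OK:
            return sizes, max_bbox, status
        sizes[j] = n_alive
        # bounding box of occupied sites, then wipe the buffers
        minx = side
        maxx = -1
        miny = side
        maxy = -1
        for i in range(n_cells):
            if alive[i]:
                if xs[i] < minx:
                    minx = xs[i]
                if xs[i] > maxx:
                    maxx = xs[i]
                if ys[i] < miny:
                    miny = ys[i]
                if ys[i] > maxy:
                    maxy = ys[i]
            grid[ys[i], xs[i]] = -1
            alive[i] = False
        if n_alive > 0:
            bb = max(maxx - minx + 1, maxy - miny + 1)
            if bb > max_bbox:
                max_bbox = bb
    return sizes, max_bbox, _STATUS_OK


# ---------------------------------------------------------------------------
# python-facing state and operations
# ---------------------------------------------------------------------------

@dataclass
class LatticeState:
    """Mutable lattice state: site occupancy plus per-cell attributes.

    ``grid[y, x]`` stores the index of the occupying cell, -1 if empty.
    Cell arrays are preallocated to full lattice capacity; ``n_cells``
    counts allocated slots (dead cells keep their slot, flagged in
    ``alive``).
    """

    grid: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    step_index: np.ndarray
    div_prob: np.ndarray
    alive: np.ndarray
    n_cells: int

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def n_alive(self) -> int:
        return int(self.alive[: self.n_cells].sum())

    @property
    def live_step_indices(self) -> np.ndarray:
        m = self.alive[: self.n_cells]
        return self.step_index[: self.n_cells][m]

    @classmethod
    def empty(cls, width: int, height: int) -> "LatticeState":
        cap = width * height
        return cls(
            grid=np.full((height, width), -1, dtype=np.int64),
            xs=np.empty(cap, dtype=np.int64),
            ys=np.empty(cap, dtype=np.int64),
            step_index=np.empty(cap, dtype=np.int64),
            div_prob=np.empty(cap, dtype=np.float64),
            alive=np.zeros(cap, dtype=np.bool_),
            n_cells=0,
        )

    def add_cell(self, x: int, y: int, step: int, params: SimulationParams) -> int:
        if self.grid[y, x] >= 0:
            raise ValueError(f"site ({x}, {y}) already occupied")
        i = self.n_cells
        self.xs[i] = x
        self.ys[i] = y
        self.step_index[i] = step
        self.div_prob[i] = float(params.division_prob(step))
        self.alive[i] = True
        self.grid[y, x] = i
        self.n_cells += 1
        return i

    @classmethod
    def single_founder(
        cls, params: SimulationParams, founder_step: int = 0, side: int | None = None
    ) -> "LatticeState":
        side = side or params.lattice_size
        st = cls.empty(side, side)
        st.add_cell(side // 2, side // 2, founder_step, params)
        return st

    @classmethod
    def fully_occupied(
        cls, params: SimulationParams, side: int, step: int = 0
    ) -> "LatticeState":
        st = cls.empty(side, side)
        for y in range(side):
            for x in range(side):
                st.add_cell(x, y, step, params)
        return st


def step_lattice(
    state: LatticeState,
    params: SimulationParams,
    rng=None,
    n_rounds: int = 1,
    error_on_boundary: bool = False,
) -> LatticeState:
    """Advance ``state`` by ``n_rounds`` update rounds (in place).

    Each round every live cell, in a freshly randomised order, first
    faces death with ``death_prob`` and otherwise attempts one division
    with its step-dependent probability; see the module docstring for
    the space rule.
    """
    rng = as_rng(rng)
    seed = int(rng.integers(0, MAX_SEED))
    traj = np.empty(0, dtype=np.int64)
    n_cells, _, status = _run_rounds(
        state.grid, state.xs, state.ys, state.step_index, state.div_prob,
        state.alive, state.n_cells, n_rounds,
        params.n_steps, params.p_init, params.p_max, params.mu,
        params.death_prob, params.bidirectional, params.effect_sd,
        params.neighborhood == "moore", error_on_boundary, seed, traj,
    )
    state.n_cells = n_cells
    if status == _STATUS_BOUNDARY:
        raise LatticeBoundaryError(
            f"colony reached the boundary of the {state.width}x{state.height} lattice"
        )
    return state


@dataclass
class ColonySimResult:
    """Outcome of a single simulated colony."""

    final_size: int
    size_trajectory: np.ndarray  # live-cell count after each update (index 0 = start)
    step_index_histogram: np.ndarray  # counts per step index at the end
    bbox_side: int

    def __post_init__(self):
        t = len(self.size_trajectory) - 1
        if self.bbox_side > 1 + 4 * t:
            raise AssertionError(
                f"geometric bound violated: bbox side {self.bbox_side} > 1 + 4*{t}"
            )


def _safe_side(n_updates: int) -> int:
    # bounding-box side after t updates is at most 1 + 4t; pad by 2 so the
    # boundary ring is never reachable
    return 4 * n_updates + 7


def simulate_colony(
    params: SimulationParams,
    n_updates: int,
    founder_step: int = 0,
    seed=None,
    lattice_size: int | None = None,
) -> ColonySimResult:
    """Grow one colony from a central founder for ``n_updates`` rounds.

    The lattice must be large enough that the colony cannot touch the
    boundary; contact raises :class:`LatticeBoundaryError`.
    """
    if n_updates < 0:
        raise ValueError("n_updates must be >= 0")
    if not (0 <= founder_step <= params.n_steps):
        raise ValueError("founder_step outside [0, n_steps]")
    rng = as_rng(seed)
    side = lattice_size or min(params.lattice_size, _safe_side(n_updates))
    state = LatticeState.single_founder(params, founder_step, side=side)
    traj = np.zeros(n_updates + 1, dtype=np.int64)
    kernel_seed = int(rng.integers(0, MAX_SEED))
    n_cells, n_alive, status = _run_rounds(
        state.grid, state.xs, state.ys, state.step_index, state.div_prob,
        state.alive, state.n_cells, n_updates,
        params.n_steps, params.p_init, params.p_max, params.mu,
        params.death_prob, params.bidirectional, params.effect_sd,
        params.neighborhood == "moore", True, kernel_seed, traj,
    )
    state.n_cells = n_cells
    if status == _STATUS_BOUNDARY:
        raise LatticeBoundaryError(
            f"colony reached the boundary of the {side}x{side} lattice "
            f"after <= {n_updates} updates; increase lattice_size"
        )
    steps = state.live_step_indices
    hist = np.bincount(steps, minlength=params.n_steps + 1)
    if n_alive > 0:
        m = state.alive[:n_cells]
        bx = state.xs[:n_cells][m]
        by = state.ys[:n_cells][m]
        bbox = int(max(bx.max() - bx.min(), by.max() - by.min()) + 1)
    else:
        bbox = 1
    return ColonySimResult(
        final_size=int(n_alive),
        size_trajectory=traj,
        step_index_histogram=hist,
        bbox_side=bbox,
    )


def simulate_preincubation(
    params: SimulationParams,
    duration_days: int,
    n_cells: int = 100_000,
    ceiling: int = 1_000_000,
    rng=None,
) -> np.ndarray:
    """Step-index distribution after ``duration_days`` of bulk growth.

    The pre-incubation culture is modelled well-mixed: every cell divides
    with its step-dependent probability irrespective of space, daughters
    mutate as on the lattice, and whenever the population exceeds
    ``ceiling`` it is randomly down-sampled to ``n_cells`` (mimicking
    re-plating).  Returns the normalised distribution over step indices
    ``0 .. n_steps``; day 0 puts all mass on step 0.
    """
    if duration_days < 0:
        raise ValueError("duration_days must be >= 0")
    rng = as_rng(rng)
    n = params.n_steps
    counts = np.zeros(n + 1, dtype=np.int64)
    counts[0] = n_cells
    pk = np.asarray(params.division_prob(np.arange(n + 1)), dtype=np.float64)
    rounds = duration_days * params.updates_per_day
    for _ in range(rounds):
        if params.death_prob > 0:
            counts = counts - rng.binomial(counts, params.death_prob)
        div = rng.binomial(counts, pk)
        daughters = 2 * div
        mut = rng.binomial(daughters, params.mu)
        new = counts - div + (daughters - mut)
        if params.bidirectional:
            up = rng.binomial(mut, 0.5)
            down = mut - up
            new[1:] += up[:-1]
            new[n] += up[n]        # capped at the top
            new[:-1] += down[1:]
            new[0] += down[0]      # floored at the bottom
        else:
            new[1:] += mut[:-1]
            new[n] += mut[n]
        counts = new
        total = int(counts.sum())
        if total == 0:
            return counts.astype(float)  # extinct culture: all-zero vector
        if total > ceiling:
            counts = rng.multivariate_hypergeometric(counts, n_cells)
    total = counts.sum()
    if total == 0:
        return counts.astype(float)
    return counts / total


def _as_sampler(p_max_sampler, params: SimulationParams):
    """Normalise the per-colony p_max specification into callable(rng, size)."""
    if p_max_sampler is None:
        return lambda rng, size: np.full(size, params.p_max)
    if np.isscalar(p_max_sampler):
        v = float(p_max_sampler)
        return lambda rng, size: np.full(size, v)
    if callable(p_max_sampler):
        def call(rng, size):
            return np.array([float(p_max_sampler(rng)) for _ in range(size)])
        return call
    arr = np.asarray(p_max_sampler, dtype=float)
    return lambda rng, size: rng.choice(arr, size=size, replace=True)


def run_colony_cohort(
    params: SimulationParams,
    preincubation_weeks: int,
    n_colonies: int,
    p_max_sampler=None,
    clonogenic_days: int = 7,
    rng=None,
    preincubation_cells: int = 100_000,
) -> np.ndarray:
    """Simulate a cohort of clonogenic colonies; return per-colony final sizes.

    Each colony's founder draws its step index from the step distribution
    after ``preincubation_weeks`` of bulk growth (using ``params.p_max``),
    then grows on the lattice for ``clonogenic_days`` with its own maximal
    division probability drawn from ``p_max_sampler`` (None: ``params.p_max``;
    scalar; callable(rng) -> float; or an array resampled with replacement).
    Sampled p_max values below ``p_init`` are clamped up to ``p_init``.
    """
    if n_colonies < 0:
        raise ValueError("n_colonies must be >= 0")
    rng = as_rng(rng)
    if n_colonies == 0:
        return np.empty(0, dtype=np.int64)
    dist = simulate_preincubation(
        params, 7 * preincubation_weeks, n_cells=preincubation_cells, rng=rng
    )
    if dist.sum() == 0:
        raise RuntimeError("pre-incubation culture went extinct; no founders")
    founder_steps = rng.choice(params.n_steps + 1, size=n_colonies, p=dist)
    sampler = _as_sampler(p_max_sampler, params)
    p_maxes = np.clip(sampler(rng, n_colonies), params.p_init, 1.0)
    seeds = rng.integers(0, MAX_SEED, size=n_colonies)
    n_rounds = clonogenic_days * params.updates_per_day
    side = _safe_side(n_rounds)
    sizes, max_bbox, status = _cohort_sizes(
        side, n_rounds,
        founder_steps.astype(np.int64), p_maxes.astype(np.float64),
        seeds.astype(np.int64),
        params.n_steps, params.p_init, params.mu, params.death_prob,
        params.bidirectional, params.effect_sd, params.neighborhood == "moore",
    )
    if status == _STATUS_BOUNDARY:
        raise LatticeBoundaryError("cohort colony reached the lattice boundary")
    if max_bbox > 1 + 4 * n_rounds:
        raise AssertionError(
            f"geometric bound violated: bbox {max_bbox} > 1 + 4*{n_rounds}"
        )
    return sizes
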