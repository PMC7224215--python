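"""Minimal pure-Python colony simulator used as an independent oracle.

This is a deliberately plain re-implementation of the lattice growth
rules — dictionaries of occupied sites on an unbounded plane instead of
preallocated arrays, no compilation — written separately from
:mod:`gradres.abm` so the two can be compared distributionally in tests.
It is far too slow for production cohorts; that is the point.
"""

from __future__ import annotations

import numpy as np

_MOORE = [(-1, -1), (0, -1), (1, -1), (-1, 0), (1, 0), (-1, 1), (0, 1), (1, 1)]
_VON_NEUMANN = [(0, -1), (-1, 0), (1, 0), (0, 1)]


def grow_colony_reference(
    p_init: float,
    p_max: float,
    n_steps: int = 1,
    mu: float = 0.0,
    n_updates: int = 10,
    founder_step: int = 0,
    death_prob: float = 0.0,
    bidirectional: bool = False,
    neighborhood: str = "moore",
    rng=None,
) -> int:
    """Grow one colony with the same rules as the main simulator.

    Returns the final number of live cells.  Cells are tracked by id so a
    cell displaced mid-round keeps its place in the update order, exactly
    as in the array-based implementation.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    offsets = _MOORE if neighborhood == "moore" else _VON_NEUMANN
    dp = (p_max - p_init) / n_steps

    site_of = {0: (0, 0)}            # cell id -> site
    cell_at = {(0, 0): 0}            # site -> cell id
    steps = {0: founder_step}        # cell id -> step index
    next_id = 1

    for _ in range(n_updates):
        ids = list(site_of.keys())
        rng.shuffle(ids)
        for cid in ids:
            if cid not in site_of:
                continue  # died earlier this round
            if death_prob > 0.0 and rng.random() < death_prob:
                del cell_at[site_of.pop(cid)]
                del steps[cid]
                continue
            p = p_init + steps[cid] * dp
            if rng.random() >= p:
                continue
            x, y = site_of[cid]
            candidates = []
            for dx, dy in offsets:
                s = (x + dx, y + dy)
                if s not in cell_at:
                    candidates.append((s, False))
                else:
                    sx, sy = s
                    if any(
                        (sx + ex, sy + ey) not in cell_at for ex, ey in offsets
                    ):
                        candidates.append((s, True))
            if not candidates:
                continue
            target, push = candidates[rng.integers(len(candidates))]
            if push:
                tx, ty = target
                empties = [
                    (tx + ex, ty + ey)
                    for ex, ey in offsets
                    if (tx + ex, ty + ey) not in cell_at
                ]
                dest = empties[rng.integers(len(empties))]
                moved = cell_at.pop(target)
                cell_at[dest] = moved
                site_of[moved] = dest
            did = next_id
            next_id += 1
            site_of[did] = target
            cell_at[target] = did
            steps[did] = steps[cid]
            for who in (cid, did):
                if rng.random() >= mu:
                    continue
                if bidirectional:
                    delta = 1 if rng.random() < 0.5 else -1
                else:
                    delta = 1
                steps[who] = min(max(steps[who] + delta, 0), n_steps)
    return len(site_of)


def reference_cohort(
    p: float, n_updates: int, n_colonies: int, rng=None, **kw
) -> np.ndarray:
    """Final sizes of ``n_colonies`` mutation-free colonies at division prob p."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return np.array(
        [
            grow_colony_reference(p, p, n_steps=1, mu=0.0, n_updates=n_updates, rng=rng, **kw)
            for _ in range(n_colonies)
        ],
        dtype=np.int64,
    )
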