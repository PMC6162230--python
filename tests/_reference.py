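"""Naive pure-Python reference engines used as independent oracles.

These deliberately avoid the package's array kernels: utilities live in a
dict keyed by coordinates, edges are enumerated explicitly, and the
imitation rule is applied by collecting the argmax set.  They share only the
package's *documented* randomness contract (sites row-major; East edge then
South edge; focal endpoint's abstention draw before the neighbour's), which
is what makes exact trajectory comparison possible.
"""

from __future__ import annotations

import numpy as np

from pdpa.game_core import payoff_pair

TOL = 1e-9


def _edge_order(side):
    for r in range(side):
        for c in range(side):
            for dr, dc in ((0, 1), (1, 0)):  # East edge, then South edge
                yield (r, c), ((r + dr) % side, (c + dc) % side)


def _von_neumann(r, c, side):
    return [
        ((r - 1) % side, c),
        ((r + 1) % side, c),
        (r, (c - 1) % side),
        (r, (c + 1) % side),
    ]


def reference_sync_utilities(world, params, rng) -> dict:
    """Accrue per-agent utilities by explicit undirected-edge enumeration."""
    side = world.side
    lv = world.grid.levels
    s = world.s
    ai = world.alpha_idx
    util = {(r, c): 0.0 for r in range(side) for c in range(side)}
    for (x, y) in _edge_order(side):
        ax = rng.random() < lv[ai[x]]
        ay = rng.random() < lv[ai[y]]
        px, py = payoff_pair(int(s[x]), int(s[y]), ax, ay, params)
        util[x] += px
        util[y] += py
    return util


def reference_imitate(world, util) -> tuple[np.ndarray, np.ndarray]:
    """Simultaneous best-neighbour imitation, argmax-set formulation.

    An agent changes only when a *unique* maximal neighbour strictly
    outperforms it; any tie at the maximum (including duplicated neighbours
    on degenerate tori) freezes the agent.
    """
    side = world.side
    s, ai = world.s, world.alpha_idx
    new_s, new_ai = s.copy(), ai.copy()
    for r in range(side):
        for c in range(side):
            nb = _von_neumann(r, c, side)
            umax = max(util[p] for p in nb)
            top = [p for p in nb if abs(util[p] - umax) <= TOL]
            if len(top) == 1 and umax > util[(r, c)] + TOL:
                p = top[0]
                new_s[r, c] = s[p]
                new_ai[r, c] = ai[p]
    return new_s, new_ai


def reference_sync_step(world, params, rng) -> tuple[np.ndarray, np.ndarray]:
    """One synchronous MC step, computed naively.  Returns (s, alpha_idx)."""
    util = reference_sync_utilities(world, params, rng)
    return reference_imitate(world, util)


def reference_pd_sync_step(world, params, rng) -> tuple[np.ndarray, np.ndarray]:
    """A PD-only engine: no abstention code path at all.

    Payoffs come from the strategy matrix alone.  The two per-edge uniforms
    of the randomness contract are still consumed (and discarded), which is
    what "the same seed discipline" means for an abstention-free game.
    """
    side = world.side
    s = world.s
    util = {(r, c): 0.0 for r in range(side) for c in range(side)}
    for (x, y) in _edge_order(side):
        rng.random()
        rng.random()
        px, py = payoff_pair(int(s[x]), int(s[y]), False, False, params)
        util[x] += px
        util[y] += py
    return reference_imitate(world, util)
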