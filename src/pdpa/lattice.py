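"""Toroidal square-lattice world with von Neumann adjacency.

Agents sit on an ``side x side`` square grid with periodic boundary
conditions (a torus), fully populated, each interacting with its four
orthogonal neighbours (degree kappa = 4).  Coordinates are 0-based
(row, column); the neighbour order is fixed as North, South, West, East so
that seeded runs are bit-reproducible.

``side = 2`` is a degenerate torus in which wrap-around makes the North and
South (and West and East) neighbours coincide: adjacency then carries
multiplicity, every agent still has exactly 4 neighbour *slots*, and a
duplicated neighbour counts twice in payoff accrual and ties in imitation.
It is permitted only outside strict mode, for hand-checkable oracles.

State is stored as two flat-indexable integer arrays (strategy bits and
abstention-grid indices) rather than per-agent objects, which is what lets
the update kernels vectorise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .game_core import AlphaGrid

__all__ = [
    "LatticeWorld",
    "DegenerateLatticeError",
    "build_lattice",
    "neighbors",
    "neighbor_array",
    "save_snapshot",
    "load_snapshot",
]

#: Fixed neighbour offsets in (row, col), order North, South, West, East.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = ((-1, 0), (1, 0), (0, -1), (0, 1))


class DegenerateLatticeError(ValueError):
    """Raised for lattices too small to carry the von Neumann neighbourhood."""


@dataclass
class LatticeWorld:
    """A toroidal grid of agents.

    Attributes
    ----------
    side : int
        Lattice side length; the population size is ``N = side ** 2``.
    grid : AlphaGrid
        The discrete abstention-probability levels shared by all agents.
    s : numpy.ndarray
        ``(side, side)`` int8 array of strategy bits (0 = C, 1 = D).
    alpha_idx : numpy.ndarray
        ``(side, side)`` int8 array of indices into ``grid.levels``.
    """

    side: int
    grid: AlphaGrid
    s: np.ndarray = field(repr=False)
    alpha_idx: np.ndarray = field(repr=False)

    @property
    def n_agents(self) -> int:
        return self.side * self.side

    @property
    def alpha(self) -> np.ndarray:
        """Per-agent abstention probabilities as floats, shape (side, side)."""
        return self.grid.levels[self.alpha_idx]

    def copy(self) -> "LatticeWorld":
        return LatticeWorld(
            side=self.side,
            grid=self.grid,
            s=self.s.copy(),
            alpha_idx=self.alpha_idx.copy(),
        )

    def state_equal(self, other: "LatticeWorld") -> bool:
        return (
            self.side == other.side
            and np.array_equal(self.s, other.s)
            and np.array_equal(self.alpha_idx, other.alpha_idx)
        )


def build_lattice(side: int, grid: AlphaGrid | None = None, strict: bool = False) -> LatticeWorld:
    """Build an (as yet uninitialised) toroidal world of ``side ** 2`` agents.

    All agents start as cooperators with abstention level 0; population
    initialisers overwrite this.  ``side < 2`` raises
    :class:`DegenerateLatticeError`; ``side == 2`` (a multigraph torus) is
    rejected in strict mode.
    """
    if side < 2:
        raise DegenerateLatticeError(
            f"side={side} cannot host a von Neumann neighbourhood; need side >= 2"
        )
    if strict and side == 2:
        raise DegenerateLatticeError(
            "side=2 duplicates neighbours through wrap-around; allowed only in non-strict mode"
        )
    if grid is None:
        grid = AlphaGrid(kappa=4)
    return LatticeWorld(
        side=side,
        grid=grid,
        s=np.zeros((side, side), dtype=np.int8),
        alpha_idx=np.zeros((side, side), dtype=np.int8),
    )


def neighbors(world: LatticeWorld, site: tuple[int, int]) -> list[tuple[int, int]]:
    """The four von Neumann neighbours of ``site`` in (N, S, W, E) order.

    Wraps around all edges; raises IndexError for out-of-bounds sites.
    """
    r, c = site
    n = world.side
    if not (0 <= r < n and 0 <= c < n):
        raise IndexError(f"site {site} outside a {n}x{n} lattice")
    return [((r + dr) % n, (c + dc) % n) for dr, dc in NEIGHBOR_OFFSETS]


def neighbor_array(side: int) -> np.ndarray:
    """Flat-index neighbour table of shape (N, 4), columns in (N, S, W, E) order.

    Row ``r * side + c`` lists the flat indices of the neighbours of (r, c).
    """
    idx = np.arange(side * side).reshape(side, side)
    return np.stack(
        [np.roll(idx, (-dr, -dc), axis=(0, 1)).ravel() for dr, dc in NEIGHBOR_OFFSETS],
        axis=1,
    )


# ---------------------------------------------------------------------------
# Plain-text snapshot format: a header line, then one line per lattice row of
# "s:alpha_index" tokens.  Human-diffable and safe to commit.
# ---------------------------------------------------------------------------

def save_snapshot(world: LatticeWorld, path) -> None:
    """Write the world state as a plain-text matrix of ``s:alpha_index`` tokens."""
    with open(path, "w") as fh:
        fh.write(f"# pdpa snapshot side={world.side} kappa={world.grid.kappa}\n")
        for r in range(world.side):
            fh.write(
                " ".join(
                    f"{int(world.s[r, c])}:{int(world.alpha_idx[r, c])}"
                    for c in range(world.side)
                )
                + "\n"
            )


def load_snapshot(path) -> LatticeWorld:
    """Read a world written by :func:`save_snapshot`."""
    with open(path) as fh:
        header = fh.readline().strip()
        fields = dict(tok.split("=") for tok in header.split() if "=" in tok)
        side = int(fields["side"])
        kappa = int(fields.get("kappa", 4))
        world = build_lattice(side, AlphaGrid(kappa=kappa))
        for r in range(side):
            tokens = fh.readline().split()
            if len(tokens) != side:
                raise ValueError(f"snapshot row {r} has {len(tokens)} tokens, expected {side}")
            for c, tok in enumerate(tokens):
                s_str, a_str = tok.split(":")
                world.s[r, c] = int(s_str)
                world.alpha_idx[r, c] = int(a_str)
    if world.alpha_idx.max(initial=0) >= world.grid.n_levels or world.alpha_idx.min(initial=0) < 0:
        raise ValueError("snapshot contains alpha indices outside the grid")
    if not np.isin(world.s, (0, 1)).all():
        raise ValueError("snapshot contains strategies outside {0, 1}")
    return world
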