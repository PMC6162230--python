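"""Evolutionary update engines and the Monte Carlo driver.

Two update schemes evolve the lattice population:

**Synchronous** — each Monte Carlo (MC) step, every undirected lattice edge is
realised exactly once (one abstention draw per endpoint, then payoffs to
both), giving each agent a utility summed over its 4 incident edges.  All
agents then update simultaneously: an agent copies the strategy *and* the
abstention level of its strictly best-performing neighbour; any tie for the
neighbourhood maximum — among neighbours, or between the best neighbour and
the agent itself — leaves the agent unchanged.

**Asynchronous** — each MC step performs N elementary moves (uniform site
selection with replacement).  A move picks a focal agent x, realises fresh
interactions with all 4 of its neighbours to obtain u_x, picks one neighbour
y uniformly and realises y's 4 interactions likewise (the shared x-y edge is
drawn independently in the two utilities), and, if u_y > u_x, x adopts y's
(s, alpha) with the Fermi probability

    W = 1 / (1 + exp((u_x - u_y) / (kappa * K))),

applied immediately.  K is the noise amplitude (0.1 by default).

Randomness contract
-------------------
One seeded numpy ``Generator`` (PCG64) drives a whole run.  The hot loops are
numba kernels that consume *pre-drawn* uniform arrays in a fixed, documented
order, so a run is a pure function of its seed and any independent
implementation that honours the same order reproduces it bit-for-bit:

* initialisation: N uniform ints for strategies, then (opd/pdpa) N uniform
  ints for abstention levels;
* sync accrual: sites in row-major order; for each site its East edge then
  its South edge; per edge, the abstention draw of the row-major site first,
  its neighbour second (4N uniforms per step);
* async move: 19 uniforms per move — [0] focal-site pick, [1:9] the focal
  agent's four interactions in N,S,W,E order (focal draw before neighbour
  draw), [9] neighbour pick, [10:18] the neighbour's four interactions
  (its own draw first), [18] the Fermi coin, drawn every move but consulted
  only when u_y > u_x.

Utilities are compared with absolute tolerance 1e-9 in the synchronous tie
rule; payoffs are short sums drawn from {0, L, 1, T}, so true ties are
exactly representable and the tolerance only guards against accumulation
order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .game_core import AlphaGrid, GameParams, validate_params
from .lattice import LatticeWorld, build_lattice, neighbor_array
from .metrics import StateMetrics, measure_state

__all__ = [
    "SimulationConfig",
    "PayoffLedger",
    "RunResult",
    "UPDATE_SCHEMES",
    "INIT_MODES",
    "TIE_TOLERANCE",
    "init_population",
    "accrue_payoffs_sync",
    "imitation_update_sync",
    "sync_step",
    "fermi_probability",
    "async_elementary_move",
    "async_step",
    "run_simulation",
]

UPDATE_SCHEMES = ("synchronous", "asynchronous")
INIT_MODES = ("pd", "opd", "pdpa")

#: Absolute tolerance for utility comparisons in the synchronous tie rule.
TIE_TOLERANCE = 1e-9

#: Uniforms consumed per asynchronous elementary move.
_DRAWS_PER_MOVE = 19


# ---------------------------------------------------------------------------
# Configuration and result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one run bit-for-bit."""

    params: GameParams = GameParams()
    side: int = 102
    update_scheme: str = "synchronous"
    init_mode: str = "pdpa"
    mc_steps: int = 100_000
    seed: int = 0
    record_every: int = 100
    kappa: int = 4
    strict: bool = False
    early_stop: bool = False

    def validate(self) -> "SimulationConfig":
        if self.update_scheme not in UPDATE_SCHEMES:
            raise ValueError(
                f"update_scheme must be one of {UPDATE_SCHEMES}, got {self.update_scheme!r}"
            )
        if self.init_mode not in INIT_MODES:
            raise ValueError(f"init_mode must be one of {INIT_MODES}, got {self.init_mode!r}")
        if self.mc_steps < 1:
            raise ValueError(f"mc_steps must be >= 1, got {self.mc_steps}")
        if self.record_every < 1:
            raise ValueError(f"record_every must be >= 1, got {self.record_every}")
        if self.side < 2:
            raise ValueError(f"side must be >= 2, got {self.side}")
        validate_params(self.params, strict=self.strict)
        return self


@dataclass(frozen=True)
class PayoffLedger:
    """Per-agent utilities for the current step (flat array of length N).

    Each utility is the sum of exactly kappa per-interaction payoffs, each
    drawn from {P, S, L, R, T}.
    """

    utilities: np.ndarray


@dataclass
class RunResult:
    """Time series of population metrics plus the final state of one run."""

    config: SimulationConfig
    metrics: list[StateMetrics]
    final_world: LatticeWorld
    steps_run: int

    def to_frame(self):
        from .metrics import timeseries_frame

        return timeseries_frame(self)


# ---------------------------------------------------------------------------
# Numba kernels (pure functions of state + uniform block)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _pair_payoff(sx, sy, abx, aby, R, P, S, T, L):
    if abx or aby:
        return L, L
    if sx == 0 and sy == 0:
        return R, R
    if sx == 0:
        return S, T
    if sy == 0:
        return T, S
    return P, P


@njit(cache=True)
def _accrue_sync_kernel(s, ai, levels, nbr, R, P, S, T, L, u01):
    n = s.shape[0]
    util = np.zeros(n)
    k = 0
    for x in range(n):
        ax_prob = levels[ai[x]]
        for col in (3, 1):  # East edge, then South edge
            y = nbr[x, col]
            abx = u01[k] < ax_prob
            aby = u01[k + 1] < levels[ai[y]]
            k += 2
            px, py = _pair_payoff(s[x], s[y], abx, aby, R, P, S, T, L)
            util[x] += px
            util[y] += py
    return util


@njit(cache=True)
def _imitate_sync_kernel(s, ai, util, nbr, tol):
    n = s.shape[0]
    ns = s.copy()
    na = ai.copy()
    for x in range(n):
        best = nbr[x, 0]
        bu = util[best]
        tie = False
        for j in range(1, 4):
            y = nbr[x, j]
            uy = util[y]
            if uy > bu + tol:
                best = y
                bu = uy
                tie = False
            elif uy > bu - tol:
                tie = True
        if (not tie) and bu > util[x] + tol:
            ns[x] = s[best]
            na[x] = ai[best]
    return ns, na


@njit(cache=True)
def _site_utility(s, ai, levels, nbr, x, R, P, S, T, L, u01, k):
    ux = 0.0
    ax_prob = levels[ai[x]]
    for j in range(4):
        y = nbr[x, j]
        abx = u01[k] < ax_prob
        aby = u01[k + 1] < levels[ai[y]]
        k += 2
        px, _ = _pair_payoff(s[x], s[y], abx, aby, R, P, S, T, L)
        ux += px
    return ux


@njit(cache=True)
def _async_moves_kernel(s, ai, levels, nbr, R, P, S, T, L, kappa, K, u01, nmoves):
    n = s.shape[0]
    adoptions = 0
    k = 0
    for _ in range(nmoves):
        x = int(u01[k] * n)
        if x >= n:
            x = n - 1
        ux = _site_utility(s, ai, levels, nbr, x, R, P, S, T, L, u01, k + 1)
        j = int(u01[k + 9] * 4)
        if j >= 4:
            j = 3
        y = nbr[x, j]
        uy = _site_utility(s, ai, levels, nbr, y, R, P, S, T, L, u01, k + 10)
        if uy > ux:
            w = 1.0 / (1.0 + np.exp((ux - uy) / (kappa * K)))
            if u01[k + 18] < w:
                s[x] = s[y]
                ai[x] = ai[y]
                adoptions += 1
        k += _DRAWS_PER_MOVE
    return adoptions


# ---------------------------------------------------------------------------
# Population initialisers
# ---------------------------------------------------------------------------

def init_population(
    world: LatticeWorld, mode: str, rng: np.random.Generator
) -> LatticeWorld:
    """Populate a world in place: strategies 50/50, abstention levels per mode.

    * ``pd``   — all agents at level 0 (never abstain): the classic PD limit.
    * ``opd``  — level 0 or level 1.0 with equal probability: the optional
      PD limit with pure loners.
    * ``pdpa`` — level drawn uniformly over the whole grid.

    Strategy draws consume the stream before abstention draws.
    """
    if mode not in INIT_MODES:
        raise ValueError(f"unknown init mode {mode!r}; expected one of {INIT_MODES}")
    shape = world.s.shape
    world.s[...] = rng.integers(0, 2, size=shape, dtype=np.int8)
    top = world.grid.n_levels - 1
    if mode == "pd":
        world.alpha_idx[...] = 0
    elif mode == "opd":
        world.alpha_idx[...] = rng.integers(0, 2, size=shape, dtype=np.int8) * top
    else:
        world.alpha_idx[...] = rng.integers(0, top + 1, size=shape, dtype=np.int8)
    return world


# ---------------------------------------------------------------------------
# Synchronous engine
# ---------------------------------------------------------------------------

def accrue_payoffs_sync(
    world: LatticeWorld,
    params: GameParams,
    rng: np.random.Generator,
    _nbr: Optional[np.ndarray] = None,
) -> PayoffLedger:
    """Realise every undirected edge once and sum payoffs into utilities."""
    nbr = neighbor_array(world.side) if _nbr is None else _nbr
    n = world.n_agents
    u01 = rng.random(4 * n)
    util = _accrue_sync_kernel(
        world.s.ravel(),
        world.alpha_idx.ravel(),
        world.grid.levels,
        nbr,
        params.R,
        params.P,
        params.S,
        params.T,
        params.L,
        u01,
    )
    return PayoffLedger(utilities=util)


def imitation_update_sync(
    world: LatticeWorld,
    ledger: PayoffLedger,
    _nbr: Optional[np.ndarray] = None,
) -> LatticeWorld:
    """Simultaneous best-neighbour imitation from a common payoff ledger.

    Deterministic: consumes no randomness.  Returns a new world; the input is
    untouched.
    """
    nbr = neighbor_array(world.side) if _nbr is None else _nbr
    ns, na = _imitate_sync_kernel(
        world.s.ravel(), world.alpha_idx.ravel(), ledger.utilities, nbr, TIE_TOLERANCE
    )
    return LatticeWorld(
        side=world.side,
        grid=world.grid,
        s=ns.reshape(world.s.shape),
        alpha_idx=na.reshape(world.alpha_idx.shape),
    )


def sync_step(
    world: LatticeWorld,
    params: GameParams,
    rng: np.random.Generator,
    _nbr: Optional[np.ndarray] = None,
) -> LatticeWorld:
    """One synchronous MC step: accrue payoffs, then imitate simultaneously."""
    nbr = neighbor_array(world.side) if _nbr is None else _nbr
    ledger = accrue_payoffs_sync(world, params, rng, _nbr=nbr)
    return imitation_update_sync(world, ledger, _nbr=nbr)


# ---------------------------------------------------------------------------
# Asynchronous engine
# ---------------------------------------------------------------------------

def fermi_probability(ux: float, uy: float, kappa: int = 4, K: float = 0.1) -> float:
    """Probability that x adopts from y: W = 1 / (1 + exp((u_x - u_y)/(kappa K))).

    Numerically stable for any utility gap (evaluated as a logistic sigmoid).
    """
    if K <= 0:
        raise ValueError(f"noise amplitude K must be positive, got {K}")
    if kappa < 1:
        raise ValueError(f"degree kappa must be >= 1, got {kappa}")
    from scipy.special import expit

    return float(expit((uy - ux) / (kappa * K)))


def async_elementary_move(
    world: LatticeWorld,
    params: GameParams,
    rng: np.random.Generator,
    _nbr: Optional[np.ndarray] = None,
) -> LatticeWorld:
    """One asynchronous elementary move; mutates the world at most at one site."""
    nbr = neighbor_array(world.side) if _nbr is None else _nbr
    u01 = rng.random(_DRAWS_PER_MOVE)
    s = world.s.ravel()
    ai = world.alpha_idx.ravel()
    _async_moves_kernel(
        s,
        ai,
        world.grid.levels,
        nbr,
        params.R,
        params.P,
        params.S,
        params.T,
        params.L,
        float(world.grid.kappa),
        params.K,
        u01,
        1,
    )
    return world


def async_step(
    world: LatticeWorld,
    params: GameParams,
    rng: np.random.Generator,
    _nbr: Optional[np.ndarray] = None,
) -> LatticeWorld:
    """One asynchronous MC step: N elementary moves, selection with replacement.

    Returns a new world; the input is untouched.
    """
    nbr = neighbor_array(world.side) if _nbr is None else _nbr
    out = world.copy()
    n = out.n_agents
    u01 = rng.random(_DRAWS_PER_MOVE * n)
    _async_moves_kernel(
        out.s.reshape(-1),
        out.alpha_idx.reshape(-1),
        out.grid.levels,
        nbr,
        params.R,
        params.P,
        params.S,
        params.T,
        params.L,
        float(out.grid.kappa),
        params.K,
        u01,
        n,
    )
    return out


# ---------------------------------------------------------------------------
# Monte Carlo driver
# ---------------------------------------------------------------------------

def _is_absorbing(world: LatticeWorld, scheme: str) -> bool:
    s = world.s
    ai = world.alpha_idx
    if scheme == "synchronous":
        return bool((s == s.flat[0]).all() and (ai == ai.flat[0]).all())
    top = world.grid.n_levels - 1
    return bool((s == 1).all() or (ai == top).all())


def run_simulation(config: SimulationConfig) -> RunResult:
    """Run one seeded simulation and record population metrics over time.

    Metrics are recorded at step 0 (post-initialisation), every
    ``record_every`` steps, and always at the final step.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = AlphaGrid(kappa=config.kappa)
    world = build_lattice(config.side, grid, strict=config.strict)
    init_population(world, config.init_mode, rng)

    nbr = neighbor_array(config.side)
    step_op = sync_step if config.update_scheme == "synchronous" else async_step

    series = [measure_state(world, 0)]
    steps_run = 0
    for t in range(1, config.mc_steps + 1):
        world = step_op(world, config.params, rng, _nbr=nbr)
        steps_run = t
        if t % config.record_every == 0 or t == config.mc_steps:
            series.append(measure_state(world, t))
        if config.early_stop and _is_absorbing(world, config.update_scheme):
            if series[-1].step != t:
                series.append(measure_state(world, t))
            break
    return RunResult(config=config, metrics=series, final_world=world, steps_run=steps_run)
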