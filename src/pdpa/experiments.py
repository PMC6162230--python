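"""Experiment designs: presets, ensembles, parameter sweeps and fixtures.

Three study designs are provided at configurable scale:

* a temptation (T) sweep at fixed loner's payoff L, comparing the PD, OPD
  and PDPA initialisations under either update scheme;
* time courses of the mean effective cooperation and mean abstention
  probability (available from any ensemble's recorded series);
* a T x L plane scan of the stationary means.

Two scales ship as presets.  ``paper`` is the full protocol (102 x 102
lattice, 1e5 MC steps, 100 runs); ``desk`` is a reduced protocol
(60 x 60, 2e4 steps, 20 runs) sized so that the whole property suite runs
in minutes while leaving the stationary phenomenology intact.

Seeds for sweep cells are derived with ``numpy.random.SeedSequence`` from
(base seed, cell indices, run index), so results are invariant to the order
in which cells execute.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .dynamics import RunResult, SimulationConfig, run_simulation
from .game_core import GameParams
from .lattice import LatticeWorld, build_lattice
from .metrics import ensemble_average

__all__ = [
    "Preset",
    "SweepSpec",
    "FixtureCatalogError",
    "preset_config",
    "run_ensemble",
    "run_T_sweep",
    "run_TL_heatmap",
    "make_fixture",
    "FIXTURE_NAMES",
    "write_manifest",
]

logger = logging.getLogger("pdpa")

_SCALES = {
    # side, mc_steps, runs, record_every
    "paper": (102, 100_000, 100, 100),
    "desk": (60, 20_000, 20, 10),
}


@dataclass(frozen=True)
class Preset:
    """A run configuration plus the ensemble size that goes with it."""

    config: SimulationConfig
    runs: int


def preset_config(game: str = "pdpa", scheme: str = "synchronous", scale: str = "desk") -> Preset:
    """Standard configurations for the three games at two scales.

    ``paper`` scale: side=102, 1e5 MC steps, 100 runs.  ``desk`` scale:
    side=60, 2e4 MC steps, 20 runs.  Both use T=1.4, L=0.4, R=1, P=S=0,
    K=0.1 unless overridden afterwards with :func:`dataclasses.replace`.
    """
    if scale not in _SCALES:
        raise ValueError(f"unknown scale {scale!r}; expected one of {tuple(_SCALES)}")
    side, steps, runs, record_every = _SCALES[scale]
    config = SimulationConfig(
        params=GameParams(T=1.4, L=0.4),
        side=side,
        update_scheme=scheme,
        init_mode=game,
        mc_steps=steps,
        seed=0,
        record_every=record_every,
    ).validate()
    return Preset(config=config, runs=runs)


def run_ensemble(
    config: SimulationConfig, runs: int, base_seed: int | None = None
) -> list[RunResult]:
    """Run ``runs`` independent replicates; replicate i uses seed base + i."""
    if runs < 1:
        raise ValueError(f"runs must be >= 1, got {runs}")
    base = config.seed if base_seed is None else base_seed
    out = []
    for i in range(runs):
        out.append(run_simulation(replace(config, seed=base + i)))
        logger.debug("run %d/%d done (seed=%d)", i + 1, runs, base + i)
    return out


@dataclass(frozen=True)
class SweepSpec:
    """A grid of (T, L) cells sharing one base protocol.

    All cells use the base config's lattice, step count and scheme; only the
    payoffs, the initialisation game and the seeds vary.  ``games`` and
    ``schemes`` default to the base config's values.
    """

    base: SimulationConfig
    T_values: tuple = (1.1, 1.4, 1.9)
    L_values: tuple = (0.4,)
    runs: int = 20
    games: tuple = ()
    schemes: tuple = ()
    base_seed: int = 0

    def games_(self) -> tuple:
        return self.games or (self.base.init_mode,)

    def schemes_(self) -> tuple:
        return self.schemes or (self.base.update_scheme,)


def _cell_seed(base_seed: int, game: str, scheme: str, T: float, run: int) -> int:
    """Deterministic per-cell seed: a pure function of the cell's values.

    Depends on the game, the scheme, the bit pattern of T and the run index —
    not on grid positions, so sweep outputs are invariant to cell execution
    order; and not on L, so cells along the L axis share random numbers
    (which makes PD-mode rows exactly constant across L, as they must be
    when the loner's payoff is never awarded).
    """
    from .dynamics import INIT_MODES, UPDATE_SCHEMES

    key = (
        INIT_MODES.index(game),
        UPDATE_SCHEMES.index(scheme),
        int(np.float64(T).view(np.uint64)),
        run,
    )
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=key)
    return int(ss.generate_state(1)[0] % (2**31))


def _run_cells(spec: SweepSpec, L_values) -> pd.DataFrame:
    rows = []
    for game in spec.games_():
        for scheme in spec.schemes_():
            for T in spec.T_values:
                for L in L_values:
                    cfg = replace(
                        spec.base,
                        params=replace(spec.base.params, T=T, L=L),
                        update_scheme=scheme,
                        init_mode=game,
                    )
                    results = [
                        run_simulation(
                            replace(cfg, seed=_cell_seed(spec.base_seed, game, scheme, T, r))
                        )
                        for r in range(spec.runs)
                    ]
                    stat = ensemble_average(results).stationary
                    rows.append(
                        {
                            "game": game,
                            "scheme": scheme,
                            "T": T,
                            "L": L,
                            "mean_eps": stat["mean_eps"],
                            "sem_mean_eps": stat["sem_mean_eps"],
                            "mean_alpha": stat["mean_alpha"],
                            "sem_mean_alpha": stat["sem_mean_alpha"],
                            "frac_coop": stat["frac_coop"],
                            "runs": spec.runs,
                        }
                    )
                    logger.info(
                        "cell game=%s scheme=%s T=%.3g L=%.3g: eps=%.4f alpha=%.4f",
                        game, scheme, T, L, stat["mean_eps"], stat["mean_alpha"],
                    )
    return pd.DataFrame(rows)


def run_T_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Stationary ensemble means versus T at a single loner's payoff L."""
    if not spec.T_values:
        raise ValueError("T sweep needs at least one T value")
    if len(spec.L_values) != 1:
        raise ValueError(f"T sweep expects a single L value, got {spec.L_values}")
    return _run_cells(spec, spec.L_values)


def run_TL_heatmap(spec: SweepSpec) -> pd.DataFrame:
    """Stationary ensemble means over the full T x L grid (one row per cell)."""
    if not spec.T_values or not spec.L_values:
        raise ValueError("T-L scan needs non-empty T and L grids")
    return _run_cells(spec, spec.L_values)


# ---------------------------------------------------------------------------
# Fixture catalogue: tiny deterministic worlds for tests and documentation
# ---------------------------------------------------------------------------

class FixtureCatalogError(KeyError):
    """Raised for fixture names outside the documented catalogue."""


def _single_c_3x3() -> LatticeWorld:
    w = build_lattice(3)
    w.s[...] = 1
    w.s[1, 1] = 0  # a lone cooperator surrounded by defectors, all alpha = 0
    return w


def _all_loners_5x5() -> LatticeWorld:
    w = build_lattice(5)
    w.s[...] = np.indices((5, 5)).sum(axis=0) % 2  # arbitrary strategies
    w.alpha_idx[...] = w.grid.n_levels - 1  # everyone always abstains
    return w


def _checkerboard_4x4() -> LatticeWorld:
    w = build_lattice(4)
    w.s[...] = np.indices((4, 4)).sum(axis=0) % 2  # alternating C/D, alpha = 0
    return w


def _two_level_split_6x6() -> LatticeWorld:
    w = build_lattice(6)
    w.s[...] = np.indices((6, 6)).sum(axis=0) % 2
    w.alpha_idx[:3, :] = 2  # top half at alpha = 0.25
    w.alpha_idx[3:, :] = 6  # bottom half at alpha = 0.75
    return w


_FIXTURES = {
    "single_c_3x3": _single_c_3x3,
    "all_loners_5x5": _all_loners_5x5,
    "checkerboard_4x4": _checkerboard_4x4,
    "two_level_split_6x6": _two_level_split_6x6,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def make_fixture(name: str) -> LatticeWorld:
    """Deterministic hand-constructed small worlds used by the test suite."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise FixtureCatalogError(
            f"unknown fixture {name!r}; catalogue: {FIXTURE_NAMES}"
        ) from None
    return builder()


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def write_manifest(path, config: SimulationConfig, **extra) -> dict:
    """Write a JSON manifest sufficient to reproduce a run bit-for-bit."""
    from . import __version__

    manifest = {
        "package": "pdpa",
        "version": __version__,
        "config": asdict(config),
        **extra,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
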