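"""Payoff structure and abstention mechanics for the PDPA game.

The prisoner's dilemma with probabilistic abstention (PDPA) is a hybrid of the
classic prisoner's dilemma (PD) and the optional prisoner's dilemma (OPD).
Each agent carries two heritable attributes:

* a strategy ``s`` — 0 for cooperate (C), 1 for defect (D);
* an abstention probability ``alpha`` in [0, 1] — the chance that the agent
  sits out any single pairwise interaction.

When both parties actually play, payoffs follow the standard PD matrix
(R for mutual cooperation, P for mutual defection, T to a defector meeting a
cooperator, S to that cooperator).  If either party abstains, both receive the
loner's payoff L instead.  The dilemma regime uses R = 1, P = S = 0 with
1 < T < 2 and 0 < L < 1 (so T > R > L > P = S).

Abstention probabilities live on a discrete grid of 2*kappa + 1 equally spaced
levels on [0, 1], where kappa is the agent's degree (4 on the von Neumann
lattice).  Storing the grid *index* rather than a float makes imitation copies
bit-exact and keeps the level set closed under the dynamics.

The observable that summarises both attributes at once is the effective
cooperation rate ``eps = (1 - s) * (1 - alpha)``: the probability that an
agent is a cooperator *and* actually shows up to play.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GameParams",
    "AlphaGrid",
    "AgentState",
    "InteractionOutcome",
    "InvalidDilemmaError",
    "validate_params",
    "payoff_pair",
    "draw_abstention",
    "play_interaction",
    "effective_cooperation",
]


class InvalidDilemmaError(ValueError):
    """Raised in strict mode when (T, L) leave the PDPA dilemma regime."""


@dataclass(frozen=True)
class GameParams:
    """Payoff constants and imitation noise for one PDPA game.

    Parameters
    ----------
    T : float
        Temptation to defect.  The dilemma requires 1 < T < 2.
    L : float
        Loner's payoff, paid to both parties when either abstains.
        The dilemma requires 0 < L < 1.
    R, P, S : float
        Reward for mutual cooperation, punishment for mutual defection and
        sucker's payoff.  Fixed at 1, 0, 0 in the standard parameterisation;
        overridable for experiments.
    K : float
        Noise amplitude of the Fermi imitation rule (asynchronous updating).
        Must be positive.
    """

    T: float = 1.4
    L: float = 0.4
    R: float = 1.0
    P: float = 0.0
    S: float = 0.0
    K: float = 0.1

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError(f"noise amplitude K must be positive, got K={self.K}")


def validate_params(params: GameParams, strict: bool = False) -> GameParams:
    """Check that (T, L) define a proper PDPA dilemma: 1 < T < 2, 0 < L < 1.

    In strict mode an out-of-range value raises :class:`InvalidDilemmaError`
    naming the violated bound; otherwise a warning is emitted and the params
    are returned unchanged, so limiting cases (e.g. T = 1 exactly) stay
    runnable.
    """
    violations = []
    if not (1.0 < params.T < 2.0):
        violations.append(f"temptation T={params.T} outside the dilemma bound 1 < T < 2")
    if not (0.0 < params.L < 1.0):
        violations.append(f"loner's payoff L={params.L} outside the dilemma bound 0 < L < 1")
    if violations:
        msg = "; ".join(violations)
        if strict:
            raise InvalidDilemmaError(msg)
        warnings.warn(msg, stacklevel=2)
    return params


def _levels_for_degree(kappa: int) -> np.ndarray:
    return np.linspace(0.0, 1.0, 2 * kappa + 1)


@dataclass(frozen=True)
class AlphaGrid:
    """Discrete set of admissible abstention probabilities.

    The grid has ``2 * kappa + 1`` equally spaced levels spanning [0, 1],
    where kappa is the agent degree.  For the von Neumann lattice (kappa = 4)
    that is {0, 0.125, 0.25, ..., 0.875, 1.0}.
    """

    kappa: int = 4
    levels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kappa < 1:
            raise ValueError(f"degree kappa must be >= 1, got {self.kappa}")
        lv = _levels_for_degree(self.kappa)
        lv.setflags(write=False)
        object.__setattr__(self, "levels", lv)

    @property
    def n_levels(self) -> int:
        return 2 * self.kappa + 1

    def __len__(self) -> int:
        return self.n_levels


@dataclass(frozen=True)
class AgentState:
    """One agent's heritable state: strategy bit and abstention-grid index."""

    s: int
    alpha_index: int

    def __post_init__(self) -> None:
        if self.s not in (0, 1):
            raise ValueError(f"strategy s must be 0 (C) or 1 (D), got {self.s}")
        if self.alpha_index < 0:
            raise ValueError(f"alpha_index must be non-negative, got {self.alpha_index}")

    def alpha(self, grid: AlphaGrid) -> float:
        return float(grid.levels[self.alpha_index])


@dataclass(frozen=True)
class InteractionOutcome:
    """Result of one realised pairwise interaction."""

    abstained: bool
    payoff_x: float
    payoff_y: float


def payoff_pair(
    sx: int,
    sy: int,
    abstain_x: bool,
    abstain_y: bool,
    params: GameParams,
) -> tuple[float, float]:
    """Payoffs to (x, y) for one realised interaction.

    If either party abstains, both receive the loner's payoff L.  Otherwise
    the classic matrix applies: (C,C) -> (R,R); (C,D) -> (S,T); (D,C) ->
    (T,S); (D,D) -> (P,P).
    """
    if sx not in (0, 1) or sy not in (0, 1):
        raise ValueError(f"strategies must be 0 or 1, got sx={sx}, sy={sy}")
    if abstain_x or abstain_y:
        return params.L, params.L
    if sx == 0 and sy == 0:
        return params.R, params.R
    if sx == 0:
        return params.S, params.T
    if sy == 0:
        return params.T, params.S
    return params.P, params.P


def draw_abstention(alpha: float, rng: np.random.Generator) -> bool:
    """Draw whether an agent with abstention probability ``alpha`` sits out.

    Consumes exactly one uniform from ``rng``; returns True with probability
    ``alpha``, independently per call.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return bool(rng.random() < alpha)


def play_interaction(
    sx: int,
    sy: int,
    alpha_x: float,
    alpha_y: float,
    params: GameParams,
    rng: np.random.Generator,
) -> InteractionOutcome:
    """Realise one interaction: one abstention draw per endpoint, then payoffs.

    The focal endpoint's abstention draw is consumed first.
    """
    ax = draw_abstention(alpha_x, rng)
    ay = draw_abstention(alpha_y, rng)
    px, py = payoff_pair(sx, sy, ax, ay, params)
    return InteractionOutcome(abstained=ax or ay, payoff_x=px, payoff_y=py)


def effective_cooperation(s, alpha):
    """Effective cooperation rate eps = (1 - s) * (1 - alpha).

    Accepts scalars or numpy arrays.  Defectors (s = 1) score 0 regardless of
    alpha; a cooperator scores the probability that it actually plays.
    """
    if isinstance(s, np.ndarray) or isinstance(alpha, np.ndarray):
        return (1 - np.asarray(s)) * (1 - np.asarray(alpha))
    if s not in (0, 1):
        raise ValueError(f"strategy s must be 0 or 1, got {s}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return (1 - s) * (1 - alpha)
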