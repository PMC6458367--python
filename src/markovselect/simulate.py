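"""Synthetic data: random multistep networks and free-throw seasons.

Two generators drive the evaluation studies.

*Random networks* are ``M``-state order-``h_true`` chains whose
transition vectors are drawn independently from Dirichlet(1), with a
designated start state (trajectories begin with a history of start-state
padding) and a designated absorbing state (entering it ends the
trajectory, so trajectory length is the stochastic first-passage time).
Absorption and start-revisit probabilities are random like every other
entry.

*Free-throw seasons* emulate a season of basketball games: each game is
one trajectory of makes (``+``) and misses (``-``), its number of
attempts drawn from a zero-truncated Poisson (every counted game has at
least one attempt), and outcomes produced by one of three processes —
independent Bernoulli shots, a one-step Markov chain (distinct make
probabilities after a make, after a miss, and on the game's first
attempt), or an "error correction" variable-length process where only
the shot immediately after a miss has a different make probability.
"""

from __future__ import annotations

import itertools
import json
import string
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.optimize import brentq

from .trajectories import Alphabet, Context, TrajectorySet

__all__ = [
    "RandomNetwork",
    "IIDProcess",
    "Markov1Process",
    "ErrorCorrectionProcess",
    "FreeThrowConfig",
    "generate_network",
    "sample_trajectory",
    "sample_trajectories",
    "simulate_season",
    "truncated_poisson_rate",
]

#: Alphabet used by simulated free-throw strings, ordered [miss, make].
FREE_THROW_ALPHABET = Alphabet(("-", "+"))


def network_symbols(M: int) -> tuple[str, ...]:
    """State labels of an M-state network: A, B, ...; first = start, last = absorbing."""
    if M <= 26:
        return tuple(string.ascii_uppercase[:M])
    return tuple(chr(0x41 + i) for i in range(M))


@dataclass
class RandomNetwork:
    """True transition law of an M-state, order-``h_true`` chain."""

    alphabet: Alphabet
    h_true: int
    start: str
    absorbing: str
    transitions: dict[Context, np.ndarray]
    _cumulative: dict[Context, np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for ctx, vec in self.transitions.items():
            if len(ctx) != self.h_true:
                raise ValueError(f"context {ctx} has length != h_true")
            if abs(vec.sum() - 1.0) > 1e-9 or np.any(vec < 0):
                raise ValueError(f"transition vector for {ctx} is not a distribution")

    def cumulative(self, ctx: Context) -> np.ndarray:
        if self._cumulative is None:
            self._cumulative = {c: np.cumsum(v) for c, v in self.transitions.items()}
        return self._cumulative[ctx]

    def to_json(self) -> str:
        return json.dumps(
            {
                "symbols": list(self.alphabet.symbols),
                "h_true": self.h_true,
                "start": self.start,
                "absorbing": self.absorbing,
                "transitions": {
                    "".join(c): v.tolist() for c, v in self.transitions.items()
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RandomNetwork":
        obj = json.loads(text)
        return cls(
            Alphabet(tuple(obj["symbols"])),
            obj["h_true"],
            obj["start"],
            obj["absorbing"],
            {tuple(k): np.asarray(v, dtype=float) for k, v in obj["transitions"].items()},
        )


def generate_network(M: int, h_true: int, seed) -> RandomNetwork:
    """Draw a random network: one Dirichlet(1) vector per order-``h_true`` context.

    The first state label is the start state, the last the absorbing
    state; both participate in transitions like any other state (so the
    absorption probability out of each context is itself random).
    ``h_true = 0`` gives a memory-free system (a single shared vector).
    Deterministic given ``seed``.
    """
    if M < 3:
        raise ValueError("need M >= 3 (start, absorbing, and at least one other state)")
    if h_true < 0:
        raise ValueError("h_true must be nonnegative")
    symbols = network_symbols(M)
    alphabet = Alphabet(symbols)
    rng = np.random.default_rng(seed)
    transitions = {
        ctx: rng.dirichlet(np.ones(M))
        for ctx in itertools.product(symbols, repeat=h_true)
    }
    return RandomNetwork(alphabet, h_true, symbols[0], symbols[-1], transitions)


def sample_trajectory(net: RandomNetwork, max_len: int = 10**6, rng=None) -> tuple[str, ...]:
    """Sample one trajectory to absorption.

    The history starts as ``h_true`` copies of the start state; the
    absorbing state is included as the final symbol.  ``rng`` may be a
    seed or a ``numpy.random.Generator``.  Raises if ``max_len`` steps
    pass without absorption.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    symbols = net.alphabet.symbols
    hist: Context = (net.start,) * net.h_true
    out: list[str] = []
    for _ in range(max_len):
        cum = net.cumulative(hist)
        m = int(np.searchsorted(cum, rng.random(), side="right"))
        m = min(m, len(symbols) - 1)  # guard against cum[-1] < 1 by rounding
        s = symbols[m]
        out.append(s)
        if s == net.absorbing:
            return tuple(out)
        if net.h_true:
            hist = hist[1:] + (s,)
    raise RuntimeError(
        f"trajectory did not reach the absorbing state within {max_len} steps"
    )


def sample_trajectories(net: RandomNetwork, J: int, rng=None, max_len: int = 10**6) -> TrajectorySet:
    """Sample ``J`` independent trajectories from one network."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return TrajectorySet(
        net.alphabet, [sample_trajectory(net, max_len, rng) for _ in range(J)]
    )


# ---------------------------------------------------------------------------
# free-throw seasons

@dataclass(frozen=True)
class IIDProcess:
    """Independent shots with make probability ``p``."""

    p: float

    def __post_init__(self):
        _check_prob("p", self.p)


@dataclass(frozen=True)
class Markov1Process:
    """One-step Markov outcomes with a separate first-shot probability."""

    p_first: float
    p_after_make: float
    p_after_miss: float

    def __post_init__(self):
        for name in ("p_first", "p_after_make", "p_after_miss"):
            _check_prob(name, getattr(self, name))


@dataclass(frozen=True)
class ErrorCorrectionProcess:
    """Shots independent except immediately after a miss.

    ``p_after_miss`` applies to the shot following a miss;
    ``p_otherwise`` applies everywhere else, including the first shot.
    """

    p_after_miss: float
    p_otherwise: float

    def __post_init__(self):
        _check_prob("p_after_miss", self.p_after_miss)
        _check_prob("p_otherwise", self.p_otherwise)


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


Process = Union[IIDProcess, Markov1Process, ErrorCorrectionProcess]


@dataclass(frozen=True)
class FreeThrowConfig:
    """A season: ``games`` trajectories with zero-truncated Poisson lengths."""

    games: int = 91
    mean_attempts: float = 7.6
    process: Process = IIDProcess(0.68)
    seed: int | None = None

    def __post_init__(self):
        if self.games < 1:
            raise ValueError("games must be >= 1")
        if self.mean_attempts <= 1.0:
            raise ValueError("mean_attempts must exceed 1 (every game has >= 1 attempt)")


def truncated_poisson_rate(mean: float) -> float:
    """Poisson rate whose zero-truncated mean equals ``mean`` (> 1)."""
    if mean <= 1.0:
        raise ValueError("zero-truncated Poisson mean must exceed 1")
    f = lambda lam: lam / (1.0 - np.exp(-lam)) - mean
    return brentq(f, 1e-10, mean)


def _truncated_poisson(rng: np.random.Generator, lam: float, n: int) -> np.ndarray:
    draws = rng.poisson(lam, n)
    while True:
        zeros = draws == 0
        if not zeros.any():
            return draws
        draws[zeros] = rng.poisson(lam, int(zeros.sum()))


def simulate_season(cfg: FreeThrowConfig, rng=None) -> TrajectorySet:
    """Simulate one season of free-throw strings over the ``-``/``+`` alphabet.

    Deterministic given ``cfg.seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lam = truncated_poisson_rate(cfg.mean_attempts)
    lengths = _truncated_poisson(rng, lam, cfg.games)
    proc = cfg.process
    games: list[tuple[str, ...]] = []
    for L in lengths:
        u = rng.random(int(L))
        if isinstance(proc, IIDProcess):
            outcome = u < proc.p
        elif isinstance(proc, Markov1Process):
            outcome = np.empty(int(L), dtype=bool)
            outcome[0] = u[0] < proc.p_first
            for i in range(1, int(L)):
                p = proc.p_after_make if outcome[i - 1] else proc.p_after_miss
                outcome[i] = u[i] < p
        else:
            outcome = np.empty(int(L), dtype=bool)
            outcome[0] = u[0] < proc.p_otherwise
            for i in range(1, int(L)):
                p = proc.p_otherwise if outcome[i - 1] else proc.p_after_miss
                outcome[i] = u[i] < p
        games.append(tuple("+" if hit else "-" for hit in outcome))
    return TrajectorySet(FREE_THROW_ALPHABET, games)
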