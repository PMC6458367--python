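"""Discrete-state trajectories and their transition sufficient statistics.

A trajectory is a finite string over a small alphabet of single-character
state labels (e.g. ``"+"``/``"-"`` for made/missed free throws, or
nucleotide letters).  For an order-``h`` Markov model the sufficient
statistics of the likelihood are the transition counts
``N[x, m]`` — how often symbol ``m`` follows the history (context) ``x``
of the previous ``h`` symbols.  Histories at the start of a trajectory
are left-padded with a reserved boundary marker, so the outcome of the
first step is itself modelled (a context of all boundary markers), the
second step conditions on one real symbol, and so on.

Counts are kept both pooled over trajectories and per trajectory: the
per-trajectory decomposition is what the pointwise predictive criteria
(LPPD, WAIC, LOO, LHO) operate on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Alphabet",
    "TrajectorySet",
    "Context",
    "CountTable",
    "parse_trajectories",
    "read_fasta",
    "count_transitions",
    "count_all_orders",
    "reduce_order",
    "shuffle_within_trajectories",
    "split_half",
]

#: A context (history) is a tuple of symbols, oldest first.  Boundary
#: markers may appear only as a leading prefix.
Context = tuple[str, ...]


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of ``M >= 2`` distinct single-character state labels.

    ``boundary`` is a reserved sentinel used to pad histories at the start
    of a trajectory; it must not collide with a state label.
    """

    symbols: tuple[str, ...]
    boundary: str = "."

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", tuple(self.symbols))
        if len(self.symbols) < 2:
            raise ValueError("alphabet needs at least 2 states")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be distinct")
        for s in self.symbols:
            if not (isinstance(s, str) and len(s) == 1):
                raise ValueError(f"state labels must be single characters, got {s!r}")
        if not (isinstance(self.boundary, str) and len(self.boundary) == 1):
            raise ValueError("boundary marker must be a single character")
        if self.boundary in self.symbols:
            raise ValueError("boundary marker must not be a state label")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    @property
    def lookup(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.symbols)}


@dataclass
class TrajectorySet:
    """An ordered collection of trajectories over a shared alphabet.

    Order is significant: leave-half-out cross-validation splits on the
    position of a trajectory in the collection.
    """

    alphabet: Alphabet
    trajectories: list[tuple[str, ...]]

    def __post_init__(self) -> None:
        if len(self.trajectories) < 1:
            raise ValueError("need at least one trajectory")
        valid = set(self.alphabet.symbols)
        self.trajectories = [tuple(t) for t in self.trajectories]
        for j, traj in enumerate(self.trajectories):
            if len(traj) < 1:
                raise ValueError(f"trajectory {j + 1} is empty")
            bad = set(traj) - valid
            if bad:
                raise ValueError(
                    f"trajectory {j + 1} contains symbols outside the alphabet: {sorted(bad)}"
                )

    @property
    def n_trajectories(self) -> int:
        return len(self.trajectories)

    @property
    def lengths(self) -> list[int]:
        return [len(t) for t in self.trajectories]

    def serialize(self) -> str:
        """One trajectory per line; inverse of :func:`parse_trajectories`."""
        return "\n".join("".join(t) for t in self.trajectories) + "\n"


def parse_trajectories(text: str, alphabet: Alphabet) -> TrajectorySet:
    """Parse one trajectory per non-blank line.

    Raises ``ValueError`` naming the offending line and character position
    when a symbol outside the alphabet is encountered, and when no
    non-blank lines are present.
    """
    valid = set(alphabet.symbols)
    trajectories: list[tuple[str, ...]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        for pos, ch in enumerate(line, start=1):
            if ch not in valid:
                raise ValueError(
                    f"unknown symbol {ch!r} at line {lineno}, char {pos}"
                )
        trajectories.append(tuple(line))
    if not trajectories:
        raise ValueError("no trajectories found (all lines blank)")
    return TrajectorySet(alphabet, trajectories)


def read_fasta(path, alphabet: Alphabet | None = None) -> TrajectorySet:
    """Read each FASTA record's sequence as one trajectory.

    If ``alphabet`` is omitted it is inferred from the distinct characters
    present (sorted order).
    """
    from Bio import SeqIO

    seqs = [str(rec.seq) for rec in SeqIO.parse(path, "fasta")]
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    if alphabet is None:
        chars = sorted(set("".join(seqs)))
        boundary = "." if "." not in chars else "\x00"
        alphabet = Alphabet(tuple(chars), boundary=boundary)
    return TrajectorySet(alphabet, [tuple(s) for s in seqs])


@dataclass
class CountTable:
    """Transition counts for a memory specification.

    ``pooled`` maps each observed context to an integer vector of length M
    (destination counts); ``per_traj[j]`` holds the same decomposed by
    trajectory.  Only observed contexts are materialised — unobserved ones
    have implicit zero counts.  ``merged`` marks a table whose keys are
    blocks of contexts (variable-length models) rather than plain
    fixed-order contexts.
    """

    h: int
    alphabet: Alphabet
    pooled: dict[Context, np.ndarray]
    per_traj: list[dict[Context, np.ndarray]]
    merged: bool = False

    @property
    def n_trajectories(self) -> int:
        return len(self.per_traj)

    @property
    def total_transitions(self) -> int:
        return int(sum(int(v.sum()) for v in self.pooled.values()))

    @property
    def n_contexts(self) -> int:
        """Observed contexts (or blocks) with nonzero total count."""
        return sum(1 for v in self.pooled.values() if v.sum() > 0)


def _pool(per_traj: list[dict[Context, np.ndarray]], M: int) -> dict[Context, np.ndarray]:
    pooled: dict[Context, np.ndarray] = {}
    for d in per_traj:
        for ctx, vec in d.items():
            acc = pooled.get(ctx)
            if acc is None:
                pooled[ctx] = vec.copy()
            else:
                acc += vec
    return pooled


def count_transitions(trajs: TrajectorySet, h: int, pad: str | None = None) -> CountTable:
    """Count order-``h`` transitions, left-padding initial histories.

    Every observed symbol is counted exactly once: position ``l`` of a
    trajectory increments the cell (context of the ``h`` previous symbols,
    left-padded with ``pad``) → (symbol at ``l``).  ``h = 0`` yields a
    single empty context.

    ``pad`` defaults to the alphabet's boundary marker, which gives the
    first symbols their own boundary contexts.  Passing a state label
    instead (e.g. a designated start state of a simulated system, known
    to precede every trajectory) folds the initial transitions into
    ordinary contexts.
    """
    if h < 0:
        raise ValueError("h must be nonnegative")
    ab = trajs.alphabet
    M = ab.size
    lookup = ab.lookup
    if pad is None:
        pad = ab.boundary
    elif pad != ab.boundary and pad not in ab.symbols:
        raise ValueError(f"pad symbol {pad!r} is neither a state nor the boundary marker")
    per_traj: list[dict[Context, np.ndarray]] = []
    for traj in trajs.trajectories:
        d: dict[Context, np.ndarray] = {}
        hist: Context = (pad,) * h
        for s in traj:
            vec = d.get(hist)
            if vec is None:
                vec = d[hist] = np.zeros(M, dtype=np.int64)
            vec[lookup[s]] += 1
            if h:
                hist = hist[1:] + (s,)
        per_traj.append(d)
    return CountTable(h, ab, _pool(per_traj, M), per_traj)


def reduce_order(counts: CountTable) -> CountTable:
    """Marginalise the oldest context position: order ``h`` → ``h - 1``.

    Summing an order-``h`` table over the first (oldest) context symbol
    reproduces the order-``h-1`` table exactly, because dropping the
    oldest of the ``h`` padded history symbols leaves the ``h-1`` padded
    history.
    """
    if counts.merged:
        raise ValueError("cannot reduce a merged (variable-length) count table")
    if counts.h < 1:
        raise ValueError("order is already 0")
    per_traj: list[dict[Context, np.ndarray]] = []
    for d in counts.per_traj:
        nd: dict[Context, np.ndarray] = {}
        for ctx, vec in d.items():
            key = ctx[1:]
            acc = nd.get(key)
            if acc is None:
                nd[key] = vec.copy()
            else:
                acc += vec
        per_traj.append(nd)
    return CountTable(
        counts.h - 1, counts.alphabet, _pool(per_traj, counts.alphabet.size), per_traj
    )


def count_all_orders(
    trajs: TrajectorySet, h_max: int, pad: str | None = None
) -> dict[int, CountTable]:
    """Count once at ``h_max`` and derive all lower orders by marginalisation."""
    tables = {h_max: count_transitions(trajs, h_max, pad)}
    for h in range(h_max, 0, -1):
        tables[h - 1] = reduce_order(tables[h])
    return tables


def shuffle_within_trajectories(trajs: TrajectorySet, seed) -> TrajectorySet:
    """Permute each trajectory's symbols independently and uniformly.

    Destroys any sequential correlation while preserving each
    trajectory's symbol multiset (so all order-0 statistics are
    invariant).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    shuffled = []
    for traj in trajs.trajectories:
        perm = rng.permutation(len(traj))
        shuffled.append(tuple(traj[i] for i in perm))
    return TrajectorySet(trajs.alphabet, shuffled)


def split_half(counts: CountTable) -> tuple[CountTable, CountTable]:
    """Split into the first ``ceil(J/2)`` trajectories and the remainder.

    The two blocks' pooled counts sum to the full pooled counts.  Used by
    leave-half-out cross-validation.
    """
    J = counts.n_trajectories
    if J < 2:
        raise ValueError("LHO undefined: need at least 2 trajectories to split")
    cut = (J + 1) // 2
    M = counts.alphabet.size

    def _block(per: list[dict[Context, np.ndarray]]) -> CountTable:
        per = [{k: v.copy() for k, v in d.items()} for d in per]
        return CountTable(counts.h, counts.alphabet, _pool(per, M), per, counts.merged)

    return _block(counts.per_traj[:cut]), _block(counts.per_traj[cut:])
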