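"""Dirichlet-multinomial model over Markov contexts.

Each context ``x`` carries its own transition-probability vector ``p_x``
on the M-simplex with a shared conjugate prior ``p_x ~ Dirichlet(alpha)``;
given multinomial counts ``N_x`` the posterior is
``Dirichlet(alpha + N_x)``.  The default ``alpha = 1`` (uniform) assigns
unobserved transitions a posterior-mean probability of
``alpha_m / (sum(alpha) + N_x)`` instead of the maximum-likelihood zero.

Variable-length (context-merging) models are expressed as a partition of
the fixed-order context set into blocks that share one parameter vector;
merging the count table over a block keeps the likelihood a product of
Dirichlet-multinomial terms, so every closed-form criterion applies
unchanged to merged tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .trajectories import Context, CountTable

__all__ = [
    "DirichletPrior",
    "MemorySpec",
    "ProbabilityTable",
    "merge_contexts",
    "mle",
    "posterior_params",
    "posterior_mean",
    "log_likelihood",
]


@dataclass(frozen=True)
class DirichletPrior:
    """A Dirichlet concentration vector shared by all contexts."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        if a.ndim != 1 or a.size < 2:
            raise ValueError("alpha must be a vector of length M >= 2")
        if not np.all(a > 0):
            raise ValueError("all components of alpha must be positive")
        object.__setattr__(self, "alpha", a)

    @classmethod
    def uniform(cls, M: int) -> "DirichletPrior":
        """alpha = 1: the flat prior on every simplex."""
        return cls(np.ones(M))

    @classmethod
    def jeffreys(cls, M: int) -> "DirichletPrior":
        """alpha = 1/2: Jeffreys' prior for the multinomial."""
        return cls(np.full(M, 0.5))

    @classmethod
    def symmetric(cls, M: int, a: float) -> "DirichletPrior":
        return cls(np.full(M, float(a)))


@dataclass(frozen=True)
class MemorySpec:
    """Either a fixed memory order ``h`` or a partition of contexts.

    A partition is a tuple of disjoint blocks; each block is a tuple of
    fixed-order contexts (all of one base order) whose transition counts
    are pooled into a single shared parameter vector.  The two-parameter
    "error correction" free-throw model, for instance, keeps the
    after-miss context in its own block and pools everything else.
    """

    order: int | None = None
    partition: tuple[tuple[Context, ...], ...] | None = None

    def __post_init__(self) -> None:
        if (self.order is None) == (self.partition is None):
            raise ValueError("specify exactly one of order or partition")
        if self.order is not None:
            if self.order < 0:
                raise ValueError("order must be nonnegative")
        else:
            blocks = tuple(
                tuple(tuple(c) for c in block) for block in self.partition
            )
            object.__setattr__(self, "partition", blocks)
            seen: set[Context] = set()
            lengths = set()
            for block in blocks:
                if not block:
                    raise ValueError("empty partition block")
                for ctx in block:
                    if ctx in seen:
                        raise ValueError(f"context {ctx} appears in two blocks")
                    seen.add(ctx)
                    lengths.add(len(ctx))
            if len(lengths) != 1:
                raise ValueError("all partition contexts must share one base order")

    @property
    def is_fixed_order(self) -> bool:
        return self.order is not None

    @property
    def base_order(self) -> int:
        """The context length the spec operates on."""
        if self.order is not None:
            return self.order
        return len(self.partition[0][0])

    def label(self) -> str:
        if self.order is not None:
            return f"h={self.order}"
        blocks = "|".join(
            ",".join("".join(c) for c in block) for block in self.partition
        )
        return f"partition[{blocks}]"

    def to_json(self) -> str:
        if self.order is not None:
            return json.dumps({"order": self.order})
        return json.dumps(
            {"partition": [["".join(c) for c in block] for block in self.partition]}
        )

    @classmethod
    def from_json(cls, text: str) -> "MemorySpec":
        obj = json.loads(text)
        if "order" in obj:
            return cls(order=int(obj["order"]))
        blocks = tuple(
            tuple(tuple(ctx) for ctx in block) for block in obj["partition"]
        )
        return cls(partition=blocks)


class ProbabilityTable(dict):
    """Map from context (or context block) to a probability vector.

    An optional ``default`` vector is returned for unobserved contexts —
    e.g. the prior mean when built from a posterior with no data.
    """

    def __init__(self, mapping=None, default: np.ndarray | None = None):
        super().__init__(mapping or {})
        self.default = default

    def __missing__(self, key):
        if self.default is not None:
            return self.default.copy()
        raise KeyError(key)


class _ParamTable(dict):
    """Posterior Dirichlet parameters; unobserved contexts fall back to alpha."""

    def __init__(self, mapping, alpha: np.ndarray):
        super().__init__(mapping)
        self.alpha = alpha

    def __missing__(self, key):
        return self.alpha.copy()


def merge_contexts(counts: CountTable, spec: MemorySpec) -> CountTable:
    """Pool counts within each partition block of a variable-length spec.

    The block (tuple of its contexts, sorted) becomes the new context
    key.  Total counts are conserved.  Every context with nonzero count
    must be covered by some block.
    """
    if spec.is_fixed_order:
        if spec.order != counts.h:
            raise ValueError(
                f"fixed-order spec h={spec.order} does not match counts of order {counts.h}"
            )
        return counts
    if spec.base_order != counts.h:
        raise ValueError(
            f"partition base order {spec.base_order} does not match counts of order {counts.h}"
        )
    block_of: dict[Context, tuple[Context, ...]] = {}
    for block in spec.partition:
        key = tuple(sorted(block))
        for ctx in block:
            block_of[ctx] = key
    for ctx, vec in counts.pooled.items():
        if vec.sum() > 0 and ctx not in block_of:
            raise ValueError(f"context {''.join(ctx)!r} not covered by any partition block")

    M = counts.alphabet.size
    per_traj = []
    for d in counts.per_traj:
        nd: dict = {}
        for ctx, vec in d.items():
            key = block_of.get(ctx)
            if key is None:  # zero-count context outside the partition
                continue
            acc = nd.get(key)
            if acc is None:
                nd[key] = vec.copy()
            else:
                acc += vec
        per_traj.append(nd)
    pooled: dict = {}
    for d in per_traj:
        for key, vec in d.items():
            acc = pooled.get(key)
            if acc is None:
                pooled[key] = vec.copy()
            else:
                acc += vec
    return CountTable(counts.h, counts.alphabet, pooled, per_traj, merged=True)


def mle(counts: CountTable) -> ProbabilityTable:
    """Maximum-likelihood transition probabilities ``N_x / N_x·``.

    Contexts with zero total count are omitted (their MLE is undefined).
    Note the MLE assigns probability zero to unobserved transitions.
    """
    out = ProbabilityTable()
    for ctx, vec in counts.pooled.items():
        tot = vec.sum()
        if tot > 0:
            out[ctx] = vec / tot
    return out


def posterior_params(counts: CountTable, prior: DirichletPrior) -> dict:
    """Posterior Dirichlet parameters ``alpha + N_x`` per context.

    Querying an unobserved context returns the prior ``alpha`` itself.
    """
    a = prior.alpha
    if a.size != counts.alphabet.size:
        raise ValueError("prior dimension does not match alphabet size")
    return _ParamTable({ctx: a + vec for ctx, vec in counts.pooled.items()}, a)


def posterior_mean(counts: CountTable, prior: DirichletPrior) -> ProbabilityTable:
    """Posterior mean ``(alpha_m + N_x,m) / (sum(alpha) + N_x·)`` per context."""
    a = prior.alpha
    if a.size != counts.alphabet.size:
        raise ValueError("prior dimension does not match alphabet size")
    table = ProbabilityTable(default=a / a.sum())
    for ctx, vec in counts.pooled.items():
        post = a + vec
        table[ctx] = post / post.sum()
    return table


def log_likelihood(counts: CountTable, probs: ProbabilityTable) -> float:
    """Pooled log-likelihood ``sum_x sum_m N_x,m log p_x,m``.

    Uses the convention ``0 * log 0 = 0``.  A zero probability facing a
    positive count yields ``-inf`` with a warning.
    """
    total = 0.0
    for ctx, vec in counts.pooled.items():
        if vec.sum() == 0:
            continue
        try:
            p = np.asarray(probs[ctx], dtype=float)
        except KeyError:
            raise ValueError(f"no probability vector for context {ctx} with nonzero counts")
        mask = vec > 0
        if np.any(p[mask] == 0):
            warnings.warn(
                f"zero probability for an observed transition in context {ctx}; "
                "log-likelihood is -inf",
                RuntimeWarning,
                stacklevel=2,
            )
            return float("-inf")
        total += float(np.sum(vec[mask] * np.log(p[mask])))
    return total
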