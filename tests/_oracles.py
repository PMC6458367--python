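"""Independent oracles for the closed-form criteria.

Everything here is deliberately written without using the package's
counting or criteria code: contexts are plain string keys, counts are
plain lists, and predictive probabilities come from sequential Polya-urn
updates.  Under Dirichlet-multinomial conjugacy the log predictive
probability of a block of data given base counts C is
``log B(C + N_block + alpha) - log B(C + alpha)``, and the urn computes
the same quantity one symbol at a time:
``Pr(next = m) = (alpha_m + C_m) / (sum(alpha) + sum(C))``.
"""

from __future__ import annotations

import math


def naive_counts(traj, h, boundary="."):
    """Per-context destination-symbol tallies as {context str: {symbol: n}}."""
    counts = {}
    hist = boundary * h
    for s in traj:
        d = counts.setdefault(hist, {})
        d[s] = d.get(s, 0) + 1
        if h:
            hist = (hist + s)[1:]
    return counts


def _merge(into, other):
    for ctx, d in other.items():
        t = into.setdefault(ctx, {})
        for s, n in d.items():
            t[s] = t.get(s, 0) + n


def _subtract(base, other):
    out = {ctx: dict(d) for ctx, d in base.items()}
    for ctx, d in other.items():
        for s, n in d.items():
            out[ctx][s] -= n
    return out


def urn_log_predictive(traj, h, symbols, alpha, base=None, boundary="."):
    """Sequential-predictive log probability of one trajectory.

    ``base`` holds prior counts (same nested-dict shape as
    :func:`naive_counts`); they are not modified.  Within the trajectory
    the urn updates after each symbol.
    """
    running = {ctx: dict(d) for ctx, d in (base or {}).items()}
    a = {s: alpha[i] for i, s in enumerate(symbols)}
    a_tot = sum(alpha)
    lp = 0.0
    hist = boundary * h
    for s in traj:
        d = running.setdefault(hist, {})
        tot = sum(d.values())
        lp += math.log((a[s] + d.get(s, 0)) / (a_tot + tot))
        d[s] = d.get(s, 0) + 1
        if h:
            hist = (hist + s)[1:]
    return lp


def lml_urn(trajs, h, symbols, alpha):
    """Log marginal likelihood: urn fed all trajectories sequentially."""
    counts = {}
    lp = 0.0
    for traj in trajs:
        lp += urn_log_predictive(traj, h, symbols, alpha, counts)
        _merge(counts, naive_counts(traj, h))
    return lp


def lppd_urn(trajs, h, symbols, alpha):
    """Pointwise predictive density: each trajectory scored from the full counts."""
    full = {}
    for traj in trajs:
        _merge(full, naive_counts(traj, h))
    return sum(urn_log_predictive(t, h, symbols, alpha, full) for t in trajs)


def loo_urn(trajs, h, symbols, alpha):
    """Leave-one-out: each trajectory scored from everyone else's counts."""
    full = {}
    for traj in trajs:
        _merge(full, naive_counts(traj, h))
    total = 0.0
    for traj in trajs:
        base = _subtract(full, naive_counts(traj, h))
        total += urn_log_predictive(traj, h, symbols, alpha, base)
    return total


def lho_urn(trajs, h, symbols, alpha):
    """Leave-half-out: each trajectory scored from the other half's counts."""
    cut = (len(trajs) + 1) // 2
    halves = (trajs[:cut], trajs[cut:])
    total = 0.0
    for block, other in (halves, halves[::-1]):
        base = {}
        for traj in other:
            _merge(base, naive_counts(traj, h))
        for traj in block:
            total += urn_log_predictive(traj, h, symbols, alpha, base)
    return total
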