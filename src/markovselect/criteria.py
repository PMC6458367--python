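"""Closed-form predictive model-selection criteria for Markov chains.

Because the Dirichlet prior is conjugate to the per-context multinomial
likelihood, every criterion in the Bayesian predictive-accuracy family —
the log marginal likelihood (Bayes-factor term), the expected log
(pointwise) predictive density, both WAIC variants, both DIC variants,
and exact leave-one-out / leave-half-out cross-validation — reduces to
sums of log multivariate beta functions and digamma/trigamma terms over
the observed transition counts.  No sampling or refitting is needed; the
whole candidate ladder can be scored directly from one pass over the
counts.

All criteria are reported on the deviance scale (−2 × log predictive
quantity), so lower is better and values are directly comparable with
AIC/BIC.  The raw (un-negated) LML/LPD/LPPD are exposed alongside.

Conventions: ``0 * log 0 = 0`` in all plug-in deviances; unobserved
contexts contribute nothing (their prior-over-prior beta ratios cancel);
leave-half-out splits the trajectory list into its first ``ceil(J/2)``
members versus the rest, each half scored per-trajectory against the
posterior trained on the other half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, polygamma, psi

from .dirichlet import DirichletPrior, MemorySpec, merge_contexts
from .trajectories import CountTable, TrajectorySet, count_all_orders

__all__ = [
    "CRITERIA",
    "CriteriaReport",
    "log_multivariate_beta",
    "stirling_log_beta",
    "aic_bic",
    "marginal_criteria",
    "waic",
    "dic",
    "loo",
    "lho",
    "criteria_values",
    "evaluate_all",
    "select_model",
]

#: Canonical column order of the deviance-scale criteria.
CRITERIA = (
    "AIC", "BIC", "nLML", "nLPD", "nLPPD",
    "WAIC1", "WAIC2", "DIC1", "DIC2", "LOO", "LHO",
)


def log_multivariate_beta(x) -> float | np.ndarray:
    """``log B(x) = sum_m logGamma(x_m) - logGamma(sum_m x_m)``.

    Accepts a vector or an array of vectors (reduction over the last
    axis).  All components must be positive.
    """
    x = np.asarray(x, dtype=float)
    if x.size and not np.all(x > 0):
        raise ValueError("log_multivariate_beta requires positive components")
    return _lb(x)


def _lb(x: np.ndarray) -> float | np.ndarray:
    out = gammaln(x).sum(axis=-1) - gammaln(x.sum(axis=-1))
    return float(out) if np.ndim(out) == 0 else out


def stirling_log_beta(x) -> float:
    """Stirling expansion of ``log B(x)`` through the ``1/(12 x)`` terms.

    Accurate to O((sum x)^-3) when every component is large; it is *not*
    guarded against small inputs, where it is simply inaccurate.
    """
    x = np.asarray(x, dtype=float)
    s = x.sum(axis=-1)
    term = (
        (x * np.log(x / s[..., None])).sum(axis=-1)
        - 0.5 * (np.log(x / (2.0 * np.pi)).sum(axis=-1) - np.log(s / (2.0 * np.pi)))
        + (1.0 / 12.0) * ((1.0 / x).sum(axis=-1) - 1.0 / s)
    )
    return float(term) if np.ndim(term) == 0 else term


# ---------------------------------------------------------------------------
# stacked array view of a CountTable

@dataclass
class _Stacked:
    """Dense views of a sparse CountTable for vectorised criterion sums."""

    P: np.ndarray          # (C, M) pooled counts
    rows: np.ndarray       # (R, M) per-trajectory counts, one row per (j, ctx)
    row_ctx: np.ndarray    # (R,) index into P
    row_traj: np.ndarray   # (R,) trajectory index
    J: int
    M: int


def _stack(counts: CountTable) -> _Stacked:
    M = counts.alphabet.size
    ctxs = list(counts.pooled.keys())
    index = {c: i for i, c in enumerate(ctxs)}
    if ctxs:
        P = np.stack([counts.pooled[c] for c in ctxs]).astype(float)
    else:
        P = np.zeros((0, M))
    rows, row_ctx, row_traj = [], [], []
    for j, d in enumerate(counts.per_traj):
        for c, v in d.items():
            rows.append(v)
            row_ctx.append(index[c])
            row_traj.append(j)
    if rows:
        R = np.stack(rows).astype(float)
        rc = np.asarray(row_ctx, dtype=np.intp)
        rt = np.asarray(row_traj, dtype=np.intp)
    else:
        R = np.zeros((0, M))
        rc = np.zeros(0, dtype=np.intp)
        rt = np.zeros(0, dtype=np.intp)
    return _Stacked(P, R, rc, rt, counts.n_trajectories, M)


def _check_prior(counts: CountTable, prior: DirichletPrior | None) -> np.ndarray:
    if prior is None:
        return np.ones(counts.alphabet.size)
    a = np.asarray(prior.alpha, dtype=float)
    if a.size != counts.alphabet.size:
        raise ValueError("prior dimension does not match alphabet size")
    return a


# ---------------------------------------------------------------------------
# individual criteria

def _deviance_mle(P: np.ndarray) -> float:
    """-2 sum_x sum_m N log(N / N·) with 0 log 0 = 0."""
    if P.size == 0:
        return 0.0
    tot = P.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(P > 0, P / np.where(tot > 0, tot, 1.0), 1.0)
        ll = np.where(P > 0, P * np.log(ratio), 0.0)
    return float(-2.0 * ll.sum())


def _k_param(counts: CountTable, k_mode: str) -> float:
    M = counts.alphabet.size
    if k_mode == "literal":
        if counts.merged:
            raise ValueError("literal parameter counting requires a fixed-order model")
        return float(M ** counts.h * (M - 1))
    if k_mode == "contexts":
        return float(counts.n_contexts * (M - 1))
    raise ValueError(f"unknown k_mode {k_mode!r}")


def aic_bic(counts: CountTable, k_mode: str = "literal") -> tuple[float, float, float]:
    """AIC and BIC with either parameter-counting convention.

    ``literal`` uses ``k = M^h (M - 1)`` (the full fixed-order parameter
    space, boundary contexts excluded); ``contexts`` counts only
    observed contexts (or blocks) times ``M - 1``.  The BIC sample size
    is the total number of observed transitions.
    """
    st = _stack(counts)
    dev = _deviance_mle(st.P)
    k = _k_param(counts, k_mode)
    n = st.P.sum()
    bic_pen = float(np.log(n) * k) if n > 0 else 0.0
    return dev + 2.0 * k, dev + bic_pen, k


def marginal_criteria(
    counts: CountTable, prior: DirichletPrior | None = None
) -> tuple[float, float, float]:
    """Deviance-scale marginal likelihood, LPD and LPPD (nLML, nLPD, nLPPD)."""
    a = _check_prior(counts, prior)
    st = _stack(counts)
    return (
        -2.0 * _raw_lml(st, a),
        -2.0 * _raw_lpd(st, a),
        -2.0 * _raw_lppd(st, a),
    )


def _raw_lml(st: _Stacked, a: np.ndarray) -> float:
    if st.P.shape[0] == 0:
        return 0.0
    return float(np.sum(_lb(st.P + a)) - st.P.shape[0] * _lb(a))


def _raw_lpd(st: _Stacked, a: np.ndarray) -> float:
    if st.P.shape[0] == 0:
        return 0.0
    return float(np.sum(_lb(2.0 * st.P + a) - _lb(st.P + a)))


def _raw_lppd(st: _Stacked, a: np.ndarray) -> float:
    if st.rows.shape[0] == 0:
        return 0.0
    base = st.P[st.row_ctx]
    return float(np.sum(_lb(base + st.rows + a) - _lb(base + a)))


def waic(
    counts: CountTable, prior: DirichletPrior | None = None, variant: int = 1
) -> tuple[float, float]:
    """WAIC (deviance scale) and its effective parameter count.

    Variant 1 penalises by twice the gap between the LPPD and the
    posterior expectation of the log-likelihood (digamma form); variant 2
    uses the pointwise posterior variance (trigamma form).
    """
    a = _check_prior(counts, prior)
    st = _stack(counts)
    lppd = _raw_lppd(st, a)
    k = _k_waic1(st, a, lppd) if variant == 1 else _k_waic2(st, a)
    return -2.0 * lppd + 2.0 * k, k


def _expected_loglik(st: _Stacked, a: np.ndarray) -> float:
    """E_post[log Pr(N | p)] = sum N_x,m [psi(N_x,m + a_m) - psi(N_x + sum a)]."""
    if st.P.shape[0] == 0:
        return 0.0
    inner = psi(st.P + a) - psi(st.P.sum(axis=1) + a.sum())[:, None]
    return float(np.sum(st.P * inner))


def _k_waic1(st: _Stacked, a: np.ndarray, lppd: float) -> float:
    return 2.0 * lppd - 2.0 * _expected_loglik(st, a)


def _k_waic2(st: _Stacked, a: np.ndarray) -> float:
    if st.rows.shape[0] == 0:
        return 0.0
    base = st.P[st.row_ctx]
    tri = polygamma(1, base + a)
    tri_tot = polygamma(1, base.sum(axis=1) + a.sum())
    term = (st.rows**2 * tri).sum(axis=1) - st.rows.sum(axis=1) ** 2 * tri_tot
    return float(term.sum())


def dic(
    counts: CountTable, prior: DirichletPrior | None = None, variant: int = 1
) -> tuple[float, float]:
    """DIC (plug-in deviance at the posterior mean + 2k) and its k.

    Variant 1 measures the gap between the plug-in log-likelihood and
    its posterior expectation; variant 2 is twice the posterior variance
    of the log-likelihood (trigamma form).
    """
    a = _check_prior(counts, prior)
    st = _stack(counts)
    plug = _plugin_loglik(st, a)
    if variant == 1:
        k = 2.0 * (plug - _expected_loglik(st, a))
    else:
        k = _k_dic2(st, a)
    return -2.0 * plug + 2.0 * k, k


def _plugin_loglik(st: _Stacked, a: np.ndarray) -> float:
    """sum N_x,m log((N_x,m + a_m) / (N_x + sum a)) — log-lik at the posterior mean."""
    if st.P.shape[0] == 0:
        return 0.0
    pmean = (st.P + a) / (st.P.sum(axis=1) + a.sum())[:, None]
    return float(np.sum(np.where(st.P > 0, st.P * np.log(pmean), 0.0)))


def _k_dic2(st: _Stacked, a: np.ndarray) -> float:
    if st.P.shape[0] == 0:
        return 0.0
    tri = polygamma(1, st.P + a)
    tri_tot = polygamma(1, st.P.sum(axis=1) + a.sum())
    term = (st.P**2 * tri).sum(axis=1) - st.P.sum(axis=1) ** 2 * tri_tot
    return float(2.0 * term.sum())


def loo(counts: CountTable, prior: DirichletPrior | None = None) -> float:
    """Exact leave-one-(trajectory)-out cross-validation, deviance scale.

    Each trajectory is scored by the posterior predictive trained on the
    other ``J - 1`` trajectories; conjugacy collapses the score to a
    ratio of multivariate beta functions, no refitting required.
    """
    a = _check_prior(counts, prior)
    st = _stack(counts)
    if st.rows.shape[0] == 0:
        return 0.0
    base = st.P[st.row_ctx]
    return float(-2.0 * np.sum(_lb(base + a) - _lb(base - st.rows + a)))


def lho(counts: CountTable, prior: DirichletPrior | None = None) -> float:
    """Exact twofold (leave-half-out) cross-validation, deviance scale.

    The first ``ceil(J/2)`` trajectories are each scored against the
    posterior from the remaining trajectories' counts, and vice versa.
    """
    a = _check_prior(counts, prior)
    if counts.n_trajectories < 2:
        raise ValueError("LHO undefined: need at least 2 trajectories")
    st = _stack(counts)
    return _lho_from_stack(st, a)


def _lho_from_stack(st: _Stacked, a: np.ndarray) -> float:
    cut = (st.J + 1) // 2
    in_first = st.row_traj < cut
    C = st.P.shape[0]
    pooled_first = np.zeros((C, st.M))
    pooled_second = np.zeros((C, st.M))
    np.add.at(pooled_first, st.row_ctx[in_first], st.rows[in_first])
    np.add.at(pooled_second, st.row_ctx[~in_first], st.rows[~in_first])
    total = 0.0
    for mask, other in ((in_first, pooled_second), (~in_first, pooled_first)):
        if not np.any(mask):
            continue
        base = other[st.row_ctx[mask]]
        total += float(np.sum(_lb(base + st.rows[mask] + a) - _lb(base + a)))
    return -2.0 * total


# ---------------------------------------------------------------------------
# batch evaluation

def criteria_values(
    counts: CountTable,
    prior: DirichletPrior | None = None,
    k_mode: str = "literal",
) -> dict[str, float]:
    """All eleven criteria (and effective sizes) from one pass over the counts.

    Returns a flat dict keyed by the names in :data:`CRITERIA`, plus
    ``k_param``, ``k_WAIC1/2``, ``k_DIC1/2``, the raw ``LML/LPD/LPPD``
    and the MLE ``deviance``.  ``LHO`` is ``nan`` when ``J = 1``.
    """
    a = _check_prior(counts, prior)
    st = _stack(counts)

    dev = _deviance_mle(st.P)
    k = _k_param(counts, k_mode)
    n = st.P.sum()
    bic_pen = float(np.log(n) * k) if n > 0 else 0.0

    lml = _raw_lml(st, a)
    lpd = _raw_lpd(st, a)
    lppd = _raw_lppd(st, a)
    exp_ll = _expected_loglik(st, a)
    plug = _plugin_loglik(st, a)
    k_w1 = 2.0 * lppd - 2.0 * exp_ll
    k_w2 = _k_waic2(st, a)
    k_d1 = 2.0 * (plug - exp_ll)
    k_d2 = _k_dic2(st, a)

    base = st.P[st.row_ctx] if st.rows.size else st.rows
    loo_val = (
        float(-2.0 * np.sum(_lb(base + a) - _lb(base - st.rows + a)))
        if st.rows.size
        else 0.0
    )
    lho_val = _lho_from_stack(st, a) if st.J >= 2 else float("nan")

    return {
        "AIC": dev + 2.0 * k,
        "BIC": dev + bic_pen,
        "nLML": -2.0 * lml,
        "nLPD": -2.0 * lpd,
        "nLPPD": -2.0 * lppd,
        "WAIC1": -2.0 * lppd + 2.0 * k_w1,
        "WAIC2": -2.0 * lppd + 2.0 * k_w2,
        "DIC1": -2.0 * plug + 2.0 * k_d1,
        "DIC2": -2.0 * plug + 2.0 * k_d2,
        "LOO": loo_val,
        "LHO": lho_val,
        "k_param": k,
        "k_WAIC1": k_w1,
        "k_WAIC2": k_w2,
        "k_DIC1": k_d1,
        "k_DIC2": k_d2,
        "LML": lml,
        "LPD": lpd,
        "LPPD": lppd,
        "deviance": dev,
    }


@dataclass
class CriteriaReport:
    """One row of criterion values per candidate memory specification."""

    table: pd.DataFrame
    specs: list[MemorySpec]
    alpha: np.ndarray
    n_trajectories: int
    total_transitions: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="model")

    def to_json(self) -> str:
        return self.table.to_json(orient="index")


def evaluate_all(
    trajs: TrajectorySet,
    specs: list[MemorySpec],
    prior: DirichletPrior | None = None,
    k_mode: str = "literal",
) -> CriteriaReport:
    """Score every candidate model on the same trajectory set.

    Fixed-order candidates share one counting pass (lower orders are
    marginalised from the highest).  Variable-length candidates are
    scored on merged count tables and always use observed-context
    parameter counting for AIC/BIC, whatever ``k_mode`` says.
    """
    if not specs:
        raise ValueError("no candidate models supplied")
    if prior is None:
        prior = DirichletPrior.uniform(trajs.alphabet.size)

    orders = sorted(
        {s.base_order for s in specs}
        | {s.base_order for s in specs if not s.is_fixed_order}
    )
    tables = count_all_orders(trajs, max(orders)) if orders else {}

    if trajs.n_trajectories < 2:
        warnings.warn("J = 1: LHO is undefined and omitted", UserWarning, stacklevel=2)

    rows = []
    for spec in specs:
        counts = tables[spec.base_order]
        if not spec.is_fixed_order:
            counts = merge_contexts(counts, spec)
        mode = k_mode if spec.is_fixed_order else "contexts"
        rows.append(criteria_values(counts, prior, mode))
    table = pd.DataFrame(rows, index=[s.label() for s in specs])
    total = tables[0].total_transitions if tables else 0
    return CriteriaReport(
        table, list(specs), prior.alpha, trajs.n_trajectories, total
    )


def select_model(report: CriteriaReport, criterion: str) -> MemorySpec:
    """The candidate with the smallest value of ``criterion``.

    Exact ties break toward the simplest model: fewest parameters, then
    lowest memory order.
    """
    if criterion not in report.table.columns:
        raise KeyError(f"criterion {criterion!r} not in report")
    col = report.table[criterion]
    if col.isna().all():
        raise ValueError(f"criterion {criterion!r} has no finite values (J = 1?)")
    best = None
    for spec, value, k in zip(report.specs, col.values, report.table["k_param"].values):
        if np.isnan(value):
            continue
        key = (value, k, spec.base_order)
        if best is None or key < best[0]:
            best = (key, spec)
    return best[1]
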