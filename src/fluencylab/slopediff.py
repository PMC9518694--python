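"""Slope-difference linkage: exponential output curve vs. empirical word rate.

Cumulative word production in a timed fluency task is well described by a
saturating exponential y = c(1 - exp(-m t)): retrieval slows as the task
proceeds.  Fitting (c, m) to a participant's own onset times yields a
personal expectation of output rate.  At the midpoint between two
consecutive valid words the empirical slope (one word per inter-word
interval, 1/IWI) is compared with the model slope c*m*exp(-m t*): a faster-
than-expected transition is *linked* to the previous word, a slower one is
a *switch*.  Runs of linked words are called *chains*; chains are defined
only through consecutive-word linkage and score exactly like clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .clustering import ClusterPartition
from .sessions import FluencySession

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpFit:
    """Fitted saturating exponential: asymptote ``c`` (words), rate ``m`` (1/s)."""

    c: float
    m: float
    sse: float

    def __post_init__(self) -> None:
        if self.c <= 0 or self.m <= 0:
            raise ValueError("c and m must be positive")

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.c * (1.0 - np.exp(-self.m * np.asarray(t, dtype=float)))

    def slope(self, t: np.ndarray | float) -> np.ndarray | float:
        """dy/dt = c*m*exp(-m t): positive and strictly decreasing in t."""
        return self.c * self.m * np.exp(-self.m * np.asarray(t, dtype=float))


def fit_exponential(onsets: np.ndarray, n_starts: int = 5, seed: int = 0) -> ExpFit:
    """Least-squares fit of i = c(1 - exp(-m t_i)) to cumulative word onsets.

    Observations are (t_i, i) for the i-th valid word (1-based).  The fit is
    bounded nonlinear least squares, c in (0, 5N], m in (0, 10], started
    from (N, ln 2 / t_half) plus ``n_starts - 1`` perturbed starts; the best
    attained sum of squared errors wins.  Tied onsets are perturbed by +1 ms
    with a warning.
    """
    t = np.asarray(onsets, dtype=float).copy()
    n = t.size
    if n < 3:
        raise ValueError("insufficient data for curve fit (need >= 3 valid words)")
    for i in range(1, n):
        if t[i] <= t[i - 1]:
            logger.warning("non-increasing onset at index %d; perturbing by +1 ms", i)
            t[i] = t[i - 1] + 1e-3
    y = np.arange(1, n + 1, dtype=float)

    def residuals(params):
        c, m = params
        return y - c * (1.0 - np.exp(-m * t))

    t_half = t[int(np.ceil(n / 2)) - 1]
    base = np.array([float(n), np.log(2.0) / max(t_half, 1e-6)])
    # generous asymptote bound: a near-linear early phase is fit by a large c
    lower, upper = np.array([1e-9, 1e-9]), np.array([20.0 * n, 10.0])
    rng = np.random.default_rng(seed)
    starts = [base]
    starts += [base * np.exp(rng.normal(0.0, 0.5, size=2)) for _ in range(n_starts - 1)]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lower * 1.01, upper * 0.99)
        sol = least_squares(residuals, x0, bounds=(lower, upper), xtol=1e-12, ftol=1e-10, gtol=1e-12)
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[1] - 1e-10:
            best = (sol.x, sse)
    (c, m), sse = best
    return ExpFit(float(c), float(m), sse)


def transition_table(
    session: FluencySession, fit: ExpFit, include_repetitions: bool = False
) -> list[dict]:
    """Per consecutive valid-word transition: midpoint, slopes, linked label.

    Exact slope equality labels a switch (conservative; measure-zero
    event for real timings).
    """
    toks = session.valid_tokens(include_repetitions)
    rows = []
    for i in range(len(toks) - 1):
        t0, t1 = toks[i].onset, toks[i + 1].onset
        t_mid = (t0 + t1) / 2.0
        iwi = t1 - t0
        empirical = np.inf if iwi <= 0 else 1.0 / iwi
        model = float(fit.slope(t_mid))
        rows.append(
            {
                "session_id": session.session_id,
                "index": i + 1,
                "t_mid": t_mid,
                "empirical_slope": empirical,
                "model_slope": model,
                "linked": bool(empirical > model),
            }
        )
    return rows


def classify_transitions(
    session: FluencySession, fit: ExpFit | None = None, include_repetitions: bool = False
) -> ClusterPartition:
    """Chain partition of a session from slope-difference linkage labels."""
    toks = session.valid_tokens(include_repetitions)
    if not toks:
        raise ValueError("nothing to partition")
    if len(toks) == 1:
        return ClusterPartition([[toks[0].canonical]], source="slope_difference",
                                session_id=session.session_id)
    if fit is None:
        fit = fit_exponential(session.valid_onsets(include_repetitions))
    rows = transition_table(session, fit, include_repetitions)
    runs: list[list[str]] = [[toks[0].canonical]]
    for tok, row in zip(toks[1:], rows):
        if row["linked"]:
            runs[-1].append(tok.canonical)
        else:
            runs.append([tok.canonical])
    return ClusterPartition(runs, source="slope_difference", session_id=session.session_id)
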