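"""Inter-word intervals, switch/edge speed scores, and Mayr C/S regression.

The inter-word interval (IWI) is the onset-to-onset time between
consecutive *valid* words; intervening repetitions or intrusions do not
split an interval.  Three timing summaries build on IWIs:

* **Speed scores** — under a given linkage, every transition is an *edge*
  (consecutive words linked) or a *switch*.  Within each transition type,
  intervals are normalized by a fourth root (the IWI distribution is
  positively skewed), min-max scaled over the normalization pool, and
  inverted, so the pool's fastest transition scores 1.0 and its slowest
  0.0; a participant's switch-speed and edge-speed scores are the sums of
  their inverted values.
* **Mayr C/S** — per-list OLS of IWI (seconds) on IWI index: the slope S
  indexes semantic search that grows harder as the task proceeds, the
  intercept C constant non-semantic factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .clustering import ClusterPartition
from .sessions import FluencySession

logger = logging.getLogger(__name__)


def compute_iwis(session: FluencySession, include_repetitions: bool = False) -> pd.DataFrame:
    """IWIs between consecutive valid words: columns ``index`` (1-based), ``interval``."""
    onsets = session.valid_onsets(include_repetitions)
    if onsets.size < 2:
        logger.warning("session %s has < 2 valid words; empty IWI series", session.session_id)
        return pd.DataFrame({"index": pd.Series(dtype=int), "interval": pd.Series(dtype=float)})
    intervals = np.diff(onsets)
    return pd.DataFrame({"index": np.arange(1, intervals.size + 1), "interval": intervals})


@dataclass(frozen=True)
class MayrScores:
    """Intercept C (seconds) and slope S (seconds per IWI index)."""

    C: float
    S: float


def mayr_scores(iwis: pd.DataFrame) -> MayrScores:
    """OLS of raw IWI seconds on IWI index; NaN scores when < 2 IWIs exist."""
    if len(iwis) < 2:
        return MayrScores(float("nan"), float("nan"))
    x = iwis["index"].to_numpy(dtype=float)
    y = iwis["interval"].to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        return MayrScores(float("nan"), float("nan"))
    fit = linregress(x, y)
    return MayrScores(float(fit.intercept), float(fit.slope))


def transitions_frame(
    pairs: Sequence[tuple[FluencySession, ClusterPartition]],
    include_repetitions: bool = False,
) -> pd.DataFrame:
    """Long table of labelled transitions across a cohort.

    Columns: session_id, task, index, interval, linked.  The partition must
    cover exactly the session's scored word sequence.
    """
    rows = []
    for session, partition in pairs:
        iwis = compute_iwis(session, include_repetitions)
        labels = partition.transition_linked()
        if len(labels) != len(iwis):
            raise ValueError(
                f"session {session.session_id}: {len(labels)} transition labels "
                f"for {len(iwis)} intervals"
            )
        for (_, row), linked in zip(iwis.iterrows(), labels):
            rows.append(
                {
                    "session_id": session.session_id,
                    "task": session.task,
                    "index": int(row["index"]),
                    "interval": float(row["interval"]),
                    "linked": bool(linked),
                }
            )
    return pd.DataFrame(rows, columns=["session_id", "task", "index", "interval", "linked"])


def _invert_minmax(values: np.ndarray) -> np.ndarray:
    """Fourth root, min-max onto [0, 1], then inversion (1 = fastest)."""
    roots = np.power(values, 0.25)
    lo, hi = roots.min(), roots.max()
    if hi == lo:
        logger.info("single-value normalization pool; midpoint score 0.5 assigned")
        return np.full_like(roots, 0.5)
    return 1.0 - (roots - lo) / (hi - lo)


def speed_scores(transitions: pd.DataFrame, scope: str = "cohort") -> pd.DataFrame:
    """Per-session switch- and edge-speed sums.

    ``scope="cohort"`` pools intervals across the whole dataset per task and
    transition type (cross-participant comparability: the pool's fastest
    transition scores exactly 1.0); ``scope="session"`` normalizes within
    each session instead.
    """
    if scope not in ("cohort", "session"):
        raise ValueError(f"unknown scope {scope!r}")
    df = transitions.copy()
    group_cols = ["task", "linked"] if scope == "cohort" else ["session_id", "task", "linked"]
    df["speed"] = np.nan
    for _, idx in df.groupby(group_cols).groups.items():
        df.loc[idx, "speed"] = _invert_minmax(df.loc[idx, "interval"].to_numpy(dtype=float))
    out = []
    for sid, sub in df.groupby("session_id", sort=False):
        out.append(
            {
                "session_id": sid,
                "switch_speed_sum": float(sub.loc[~sub["linked"], "speed"].sum()),
                "edge_speed_sum": float(sub.loc[sub["linked"], "speed"].sum()),
            }
        )
    return pd.DataFrame(out).set_index("session_id")
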