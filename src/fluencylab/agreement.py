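"""Inter-technique linkage agreement and raw-score-residualized correlations.

The three linkage techniques (rule-based, network, slope difference) can be
compared on the set of unordered word pairs that ever occur consecutively
in a corpus.  Rule-based and network labels are fixed properties of a pair;
the slope-difference label varies by list, so a pair counts as linked when
it was linked in at least half of its consecutive occurrences.  Agreement
between techniques is Cohen's kappa on these binary labels.

Because nearly every derived score correlates with the raw score, score
correlation matrices are computed after regressing raw score out of every
column (raw then has correlation 0 with everything by construction).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .clustering import ClusterPartition
from .linkage import LinkageRelation
from .sessions import FluencySession

logger = logging.getLogger(__name__)


def _pair(a: str, b: str) -> tuple[str, str]:
    a, b = a.lower(), b.lower()
    return (a, b) if a <= b else (b, a)


def linkage_labels(
    sessions: Sequence[FluencySession],
    troyer: LinkageRelation,
    network: LinkageRelation,
    slope_partitions: Mapping[str, ClusterPartition],
    include_repetitions: bool = False,
) -> pd.DataFrame:
    """Binary linkage label per technique over consecutively co-occurring pairs.

    Index: unordered (word1, word2) pairs occurring consecutively (among
    valid words) at least once in the corpus.  Columns ``troyer`` and
    ``network`` come straight from the relations; ``slope_difference`` is 1
    iff the pair was linked in at least half of its consecutive occurrences
    (exactly half counts).
    """
    occurrences: dict[tuple[str, str], int] = {}
    linked_counts: dict[tuple[str, str], int] = {}
    for session in sessions:
        words = session.valid_words(include_repetitions)
        part = slope_partitions[session.session_id]
        labels = part.transition_linked()
        if len(labels) != max(len(words) - 1, 0):
            raise ValueError(f"partition for {session.session_id} does not match its word sequence")
        for (a, b), linked in zip(zip(words, words[1:]), labels):
            key = _pair(a, b)
            occurrences[key] = occurrences.get(key, 0) + 1
            linked_counts[key] = linked_counts.get(key, 0) + int(linked)
    if not occurrences:
        raise ValueError("no consecutive word pairs in the corpus")
    rows = []
    for key in sorted(occurrences):
        a, b = key
        rows.append(
            {
                "word1": a,
                "word2": b,
                "troyer": int(troyer.related(a, b)),
                "network": int(network.related(a, b)),
                "slope_difference": int(linked_counts[key] * 2 >= occurrences[key]),
                "n_consecutive": occurrences[key],
            }
        )
    return pd.DataFrame(rows).set_index(["word1", "word2"])


def cohens_kappa(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Cohen's kappa for two binary label vectors.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the
    marginal proportions.  When both raters are constant and identical
    (p_e = 1) kappa is defined as 1.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    if a.size == 0:
        raise ValueError("empty label vectors")
    po = float(np.mean(a == b))
    pe = 0.0
    for value in (0, 1):
        pe += float(np.mean(a == value)) * float(np.mean(b == value))
    if pe >= 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def kappa_matrix(labels: pd.DataFrame, methods: Sequence[str] = ("network", "troyer", "slope_difference")) -> pd.DataFrame:
    """Pairwise Cohen's kappa among linkage techniques."""
    out = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    for i, m1 in enumerate(methods):
        for m2 in methods[i + 1:]:
            k = cohens_kappa(labels[m1], labels[m2])
            out.loc[m1, m2] = out.loc[m2, m1] = k
    return out


def residualize(score: Sequence[float], raw: Sequence[float]) -> np.ndarray:
    """Residuals of OLS of ``score`` on (intercept, ``raw``).

    A constant raw vector carries no variance to remove: the centered score
    is returned (logged).
    """
    y = np.asarray(score, dtype=float)
    x = np.asarray(raw, dtype=float)
    if y.shape != x.shape:
        raise ValueError("score and raw must be aligned")
    if np.allclose(x, x[0]):
        logger.info("constant raw vector; returning centered score")
        return y - y.mean()
    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def correlation_matrix(
    scores: pd.DataFrame, raw: Sequence[float] | None = None, reorder: bool = False
) -> pd.DataFrame:
    """Pearson correlations among scores, optionally raw-residualized first.

    With ``reorder`` the rows/columns are permuted by average-linkage
    clustering of 1 - r so similarly correlated scores sit adjacent (a
    display convenience only).
    """
    df = scores.copy()
    if raw is not None:
        for col in df.columns:
            df[col] = residualize(df[col].to_numpy(dtype=float), raw)
    corr = df.corr(method="pearson")
    if reorder and len(corr) > 2:
        dist = np.clip(1.0 - corr.to_numpy(), 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        order = leaves_list(scipy_linkage(squareform(dist, checks=False), method="average"))
        cols = [corr.columns[i] for i in order]
        corr = corr.loc[cols, cols]
    return corr
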