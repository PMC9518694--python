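"""Partition a word sequence into clusters under a linkage relation.

A consecutive run of words is a *cluster* when the corresponding vertices
form a complete subgraph of the relatedness structure.  Cluster size is one
less than the number of words in the run (a lone word is a cluster of size
0), and the switch count is one less than the number of clusters.

Overlapping complete subgraphs are resolved greedily left to right: the
current run is extended with the next word iff that word is related to
every word already in the run; otherwise a new run starts.  For shared-
subcategory linkage this is exactly "runs sharing a common subcategory"
(the running intersection of subcategory sets stays nonempty).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .linkage import LinkageRelation


@dataclass
class ClusterPartition:
    """Ordered runs over a session's scored word sequence."""

    runs: list[list[str]]
    source: str = "troyer"
    session_id: str | None = None

    def __post_init__(self) -> None:
        if any(len(r) == 0 for r in self.runs):
            raise ValueError("runs must be nonempty")

    @property
    def words(self) -> list[str]:
        return [w for run in self.runs for w in run]

    @property
    def cluster_sizes(self) -> list[int]:
        return [len(r) - 1 for r in self.runs]

    @property
    def switches(self) -> int:
        return len(self.runs) - 1

    @property
    def mean_cluster_size(self) -> float:
        sizes = self.cluster_sizes
        return sum(sizes) / len(sizes)

    def transition_linked(self) -> list[bool]:
        """Per consecutive-word transition: True within a run, False across runs."""
        labels: list[bool] = []
        for i, run in enumerate(self.runs):
            if i > 0:
                labels.append(False)
            labels.extend([True] * (len(run) - 1))
        return labels


def partition_clusters(
    words: Sequence[str],
    rel: LinkageRelation,
    source: str | None = None,
    session_id: str | None = None,
) -> ClusterPartition:
    """Greedy left-to-right maximal complete-subgraph partition."""
    if len(words) == 0:
        raise ValueError("nothing to partition")
    runs: list[list[str]] = [[words[0]]]
    for w in words[1:]:
        run = runs[-1]
        if all(rel.related(w, u) for u in run):
            run.append(w)
        else:
            runs.append([w])
    return ClusterPartition(runs, source=source or rel.method, session_id=session_id)


def cluster_scores(p: ClusterPartition) -> tuple[int, float]:
    """(switch count, mean cluster size) of a partition."""
    return p.switches, p.mean_cluster_size


def write_partitions(partitions: Sequence[ClusterPartition], path: str | Path, sep: str = "\t") -> None:
    """One row per run: session_id, run_index, words joined by '|', size."""
    with Path(path).open("w") as fh:
        fh.write(sep.join(("session_id", "run_index", "words", "size")) + "\n")
        for p in partitions:
            for i, run in enumerate(p.runs):
                fh.write(sep.join((str(p.session_id), str(i), "|".join(run), str(len(run) - 1))) + "\n")
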