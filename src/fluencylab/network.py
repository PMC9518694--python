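"""Data-driven lexical network construction and network statistics.

Two constructions are provided, both yielding an unweighted, undirected
word graph whose edges drive complete-subgraph cluster scoring:

* **Animal network** — pairs of words that co-occur within a short
  positional window of fluency lists more often than a binomial null
  predicts form a preliminary network; a generalized topological overlap
  measure (GTOM) turns it into a dissimilarity matrix; hierarchical
  clustering of that matrix yields modules which are completed into
  cliques; words the preliminary step excluded are attached to the module
  of their nearest word-embedding neighbour (cosine similarity).

* **Letter-F union network** — three weighted similarity layers over the
  vocabulary (semantic: embedding cosine; orthographic: negative
  Levenshtein distance; phonological: Needleman–Wunsch global alignment of
  ARPAbet pronunciations with a feature-based substitution score) are each
  z-transformed; a grid search over per-layer z-thresholds maximizes mean
  Cohen's kappa against human relatedness judgments; the final network is
  the union of the three thresholded layers.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from scipy.stats import binom

from .linkage import LinkageRelation
from .phonology import ARPABET, phoneme_similarity, strip_stress

logger = logging.getLogger(__name__)


@dataclass
class LexicalNetwork:
    """Unweighted undirected word graph, optionally module-labelled."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    modules: dict[str, int] | None = None

    @property
    def vertices(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def to_relation(self) -> LinkageRelation:
        return LinkageRelation.from_edges("network", self.graph.edges, self.graph.nodes)

    def write_edge_list(self, path: str | Path, sep: str = "\t") -> None:
        with Path(path).open("w") as fh:
            for a, b in sorted(tuple(sorted(e)) for e in self.graph.edges):
                fh.write(f"{a}{sep}{b}\n")

    def write_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        if self.modules:
            nx.set_node_attributes(g, self.modules, "module")
        nx.write_graphml(g, path)

    def write_module_table(self, path: str | Path, sep: str = "\t") -> None:
        if self.modules is None:
            raise ValueError("network has no modules")
        with Path(path).open("w") as fh:
            fh.write(f"word{sep}module_id\n")
            for w in sorted(self.modules):
                fh.write(f"{w}{sep}{self.modules[w]}\n")


# ---------------------------------------------------------------------------
# animal network: co-occurrence -> GTOM -> modules -> embedding attachment

def cooccurrence_edges(
    corpus: Sequence[Sequence[str]],
    window: int = 2,
    alpha: float = 0.001,
    null: str = "binomial",
    n_permutations: int = 1000,
    seed: int | None = None,
) -> LexicalNetwork:
    """Link word pairs that co-occur within ``window`` positions more often than chance.

    ``window`` is the maximum positional distance (2 = adjacent or one
    intervening word).  Under the default binomial null the number of
    window-slot pairs carrying an unordered pair (u, v) is Binomial(N, p)
    with N the total number of within-window position pairs in the corpus
    and p = 2 f_u f_v from the words' marginal relative frequencies; an edge
    requires a one-sided tail probability < ``alpha`` (no multiplicity
    correction: alpha is interpreted per pair).  ``null="permutation"``
    shuffles words within lists instead.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    lists = [[w.lower() for w in lst] for lst in corpus]
    freqs: dict[str, int] = {}
    for lst in lists:
        for w in lst:
            freqs[w] = freqs.get(w, 0) + 1
    total_tokens = sum(freqs.values())
    net = LexicalNetwork()
    net.graph.add_nodes_from(freqs)
    if len(freqs) < 2:
        return net

    def pair_counts(lsts):
        counts: dict[tuple[str, str], int] = {}
        for lst in lsts:
            for i in range(len(lst)):
                for j in range(i + 1, min(i + window + 1, len(lst))):
                    if lst[i] != lst[j]:
                        key = tuple(sorted((lst[i], lst[j])))
                        counts[key] = counts.get(key, 0) + 1
        return counts

    observed = pair_counts(lists)
    n_slots = sum(
        max(0, len(lst) - d) for lst in lists for d in range(1, window + 1)
    )
    if null == "binomial":
        for (u, v), k in observed.items():
            p = 2.0 * (freqs[u] / total_tokens) * (freqs[v] / total_tokens)
            if binom.sf(k - 1, n_slots, p) < alpha:
                net.graph.add_edge(u, v)
    elif null == "permutation":
        rng = np.random.default_rng(seed)
        exceed = {pair: 0 for pair in observed}
        for _ in range(n_permutations):
            perm = [list(rng.permutation(lst)) for lst in lists]
            null_counts = pair_counts(perm)
            for pair, k in observed.items():
                if null_counts.get(pair, 0) >= k:
                    exceed[pair] += 1
        for pair, x in exceed.items():
            if (x + 1) / (n_permutations + 1) < alpha:
                net.graph.add_edge(*pair)
    else:
        raise ValueError(f"unknown null {null!r}")
    return net


def gtom_dissimilarity(net: LexicalNetwork, gtom_order: int = 2) -> tuple[list[str], np.ndarray]:
    """Generalized topological overlap dissimilarity.

    Neighbourhoods are first expanded to radius ``gtom_order`` (vertices at
    most m steps apart become neighbours); then for each pair

        overlap(i, j) = (|N(i) & N(j)| + a_ij) / (min(|N(i)|, |N(j)|) + 1 - a_ij)

    on the expanded adjacency a, and dissimilarity = 1 - overlap with zero
    diagonal.  An isolated vertex has overlap 0 with every other vertex.
    """
    if gtom_order < 1:
        raise ValueError("gtom_order must be >= 1")
    words = sorted(net.graph.nodes)
    a = nx.to_numpy_array(net.graph, nodelist=words, dtype=bool)
    reach = a.copy()
    step = a.copy()
    for _ in range(gtom_order - 1):
        step = (step @ a) | reach
        reach = reach | step
    np.fill_diagonal(reach, False)
    r = reach.astype(float)
    shared = r @ r  # |N(i) & N(j)|
    deg = r.sum(axis=1)
    if np.any(deg == 0) and len(words) > 1:
        logger.info("%d isolated vertices: overlap defined as 0", int((deg == 0).sum()))
    denom = np.minimum.outer(deg, deg) + 1.0 - r
    overlap = (shared + r) / denom
    np.fill_diagonal(overlap, 1.0)
    dissim = 1.0 - overlap
    np.fill_diagonal(dissim, 0.0)
    return words, np.clip(dissim, 0.0, 1.0)


def module_detection(
    words: Sequence[str],
    dissim: np.ndarray,
    method: str = "average",
    n_modules: int | None = None,
) -> dict[str, int]:
    """Agglomerative clustering of a dissimilarity matrix into modules.

    With ``n_modules=None`` the dendrogram is cut at the largest gap between
    consecutive merge heights; otherwise it is cut to the requested count.
    """
    n = len(words)
    if dissim.shape != (n, n) or not np.allclose(dissim, dissim.T, atol=1e-12):
        raise ValueError("dissimilarity must be square and symmetric")
    if n_modules is not None and n_modules > n:
        raise ValueError(f"n_modules={n_modules} exceeds vertex count {n}")
    if n == 1:
        return {words[0]: 1}
    z = scipy_linkage(squareform(dissim, checks=False), method=method)
    if n_modules is not None:
        labels = fcluster(z, t=n_modules, criterion="maxclust")
    else:
        heights = z[:, 2]
        gaps = np.diff(heights)
        if len(gaps) == 0 or np.max(gaps) <= 0:
            labels = np.ones(n, dtype=int)
        else:
            cut = (heights[np.argmax(gaps)] + heights[np.argmax(gaps) + 1]) / 2.0
            labels = fcluster(z, t=cut, criterion="distance")
    return {w: int(lbl) for w, lbl in zip(words, labels)}


def complete_modules(net: LexicalNetwork, labels: Mapping[str, int]) -> LexicalNetwork:
    """Add edges between all pairs of words within each module (never removes edges)."""
    out = LexicalNetwork(net.graph.copy(), dict(labels))
    by_module: dict[int, list[str]] = {}
    for w, m in labels.items():
        by_module.setdefault(m, []).append(w)
    for members in by_module.values():
        out.graph.add_edges_from(itertools.combinations(sorted(members), 2))
    return out


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))


def attach_remaining_words(
    net: LexicalNetwork,
    excluded: Iterable[str],
    embeddings: Mapping[str, np.ndarray],
) -> LexicalNetwork:
    """Place each excluded word in the module of its nearest embedding neighbour.

    Words are processed in lexicographic order; ties in cosine similarity
    break toward the lexicographically smallest neighbour.  Each attached
    word gains edges to every member of its module; existing edges are
    untouched.  Excluded words without an embedding are skipped with a
    warning.
    """
    if net.modules is None:
        raise ValueError("network must have modules before attachment")
    out = LexicalNetwork(net.graph.copy(), dict(net.modules))
    for word in sorted({w.lower() for w in excluded} - set(out.modules)):
        if word not in embeddings:
            logger.warning("excluded word %r has no embedding; skipped", word)
            continue
        candidates = sorted(w for w in out.modules if w in embeddings)
        if not candidates:
            raise ValueError("no networked word has an embedding")
        sims = np.array([_cosine(embeddings[word], embeddings[c]) for c in candidates])
        neighbour = candidates[int(np.argmax(sims))]
        module = out.modules[neighbour]
        members = [w for w, m in out.modules.items() if m == module]
        out.modules[word] = module
        out.graph.add_node(word)
        out.graph.add_edges_from((word, m) for m in members)
    return out


def build_animal_network(
    corpus: Sequence[Sequence[str]],
    embeddings: Mapping[str, np.ndarray],
    window: int = 2,
    alpha: float = 0.001,
    gtom_order: int = 2,
    n_modules: int | None = None,
    linkage_method: str = "average",
) -> LexicalNetwork:
    """Full animal-network pipeline: co-occurrence, GTOM, modules, attachment."""
    prelim = cooccurrence_edges(corpus, window=window, alpha=alpha)
    core = [w for w in prelim.graph.nodes if prelim.graph.degree(w) > 0]
    core_net = LexicalNetwork(prelim.graph.subgraph(core).copy())
    words, dissim = gtom_dissimilarity(core_net, gtom_order)
    labels = module_detection(words, dissim, method=linkage_method, n_modules=n_modules)
    completed = complete_modules(core_net, labels)
    vocab = {w.lower() for lst in corpus for w in lst}
    return attach_remaining_words(completed, vocab - set(core), embeddings)


# ---------------------------------------------------------------------------
# letter-F union network: three z-scored similarity layers

@dataclass
class WeightedLayer:
    """A symmetric word-pair similarity layer and its z-standardized form."""

    name: str
    words: list[str]
    weights: np.ndarray
    zweights: np.ndarray = field(init=False)
    defined: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w, w.T, equal_nan=True):
            raise ValueError("layer weights must be symmetric")
        self.weights = w
        n = len(self.words)
        iu = np.triu_indices(n, k=1)
        vals = w[iu]
        finite = np.isfinite(vals)
        mu = vals[finite].mean()
        sd = vals[finite].std()
        z = np.full_like(w, np.nan)
        z[iu] = (vals - mu) / sd if sd > 0 else 0.0
        z = np.where(np.isnan(z) & ~np.isnan(z.T), z.T, z)
        floor = np.nanmin(z[iu]) if finite.any() else 0.0
        self.defined = np.isfinite(w)
        z[~np.isfinite(z)] = floor  # missing-resource pairs can never exceed a threshold above the floor
        np.fill_diagonal(z, floor)
        self.zweights = z

    def zpair(self, w1: str, w2: str) -> float:
        i, j = self.words.index(w1.lower()), self.words.index(w2.lower())
        return float(self.zweights[i, j])


def _phoneme_aligner(gap_penalty: float = -0.5,
                     substitution: Mapping[tuple[str, str], float] | None = None) -> Align.PairwiseAligner:
    phones = tuple(sorted(ARPABET))
    mat = substitution_matrices.Array(alphabet=phones, dims=2)
    for a in phones:
        for b in phones:
            if substitution is not None:
                mat[a, b] = substitution.get((a, b), substitution.get((b, a), phoneme_similarity(a, b)))
            else:
                mat[a, b] = phoneme_similarity(a, b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = gap_penalty
    aligner.extend_gap_score = gap_penalty
    return aligner


def needleman_wunsch_score(
    p1: Sequence[str], p2: Sequence[str],
    gap_penalty: float = -0.5,
    substitution: Mapping[tuple[str, str], float] | None = None,
) -> float:
    """Global-alignment similarity of two stress-stripped phoneme sequences."""
    aligner = _phoneme_aligner(gap_penalty, substitution)
    return float(aligner.score([strip_stress(p) for p in p1], [strip_stress(p) for p in p2]))


def build_letterf_layers(
    vocab: Iterable[str],
    embeddings: Mapping[str, np.ndarray],
    pronunciations: Mapping[str, list[tuple[str, ...]]],
    gap_penalty: float = -0.5,
    substitution: Mapping[tuple[str, str], float] | None = None,
) -> dict[str, WeightedLayer]:
    """Semantic (cosine), orthographic (-Levenshtein) and phonological (alignment) layers.

    Pairs involving a word missing from a resource receive that layer's
    minimum z-weight, so they can never be linked through that layer.
    The first dictionary pronunciation of each word is aligned.
    """
    words = sorted({w.lower() for w in vocab})
    n = len(words)
    sem = np.full((n, n), np.nan)
    orth = np.zeros((n, n))
    phon = np.full((n, n), np.nan)
    aligner = _phoneme_aligner(gap_penalty, substitution)
    prons = {}
    for w in words:
        if pronunciations.get(w):
            prons[w] = [strip_stress(p) for p in pronunciations[w][0]]
        else:
            logger.info("no pronunciation for %r; phonological layer undefined", w)
    missing_emb = [w for w in words if w not in embeddings]
    for w in missing_emb:
        logger.info("no embedding for %r; semantic layer undefined", w)
    for i, a in enumerate(words):
        for j in range(i, n):
            b = words[j]
            orth[i, j] = orth[j, i] = -float(edlib.align(a, b)["editDistance"])
            if a in embeddings and b in embeddings:
                sem[i, j] = sem[j, i] = _cosine(embeddings[a], embeddings[b])
            if a in prons and b in prons:
                phon[i, j] = phon[j, i] = float(aligner.score(prons[a], prons[b]))
    return {
        "semantic": WeightedLayer("semantic", words, sem),
        "orthographic": WeightedLayer("orthographic", words, orth),
        "phonological": WeightedLayer("phonological", words, phon),
    }


@dataclass(frozen=True)
class ThresholdTriple:
    """Per-layer z-thresholds selected by the kappa-maximizing grid search."""

    semantic_z: float
    phonological_z: float
    orthographic_z: float
    achieved_kappa: float
    per_rater_kappa: tuple[float, ...] = ()


def _kappa_from_counts(c1: np.ndarray, c0: np.ndarray, n1: int, n0: int) -> np.ndarray:
    """Vectorized Cohen's kappa from predicted-positive counts per class."""
    n = n1 + n0
    po = (c1 + (n0 - c0)) / n
    pred1 = c1 + c0
    pe = (pred1 * n1 + (n - pred1) * (n - n1)) / (n * n)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (po - pe) / (1.0 - pe)
    return np.where(pe >= 1.0, 1.0, kappa)


def load_judgments(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Rater relatedness judgments: columns word1, word2, rater, related."""
    df = pd.read_csv(path, sep=sep)
    df["word1"] = df["word1"].str.lower()
    df["word2"] = df["word2"].str.lower()
    df["related"] = df["related"].astype(int)
    return df


def threshold_grid_search(
    layers: Mapping[str, WeightedLayer],
    judgments: pd.DataFrame,
    step: float = 0.05,
    zrange: tuple[float, float] = (-1.0, 4.0),
) -> ThresholdTriple:
    """Exhaustive 3-D scan for the thresholds maximizing mean rater kappa.

    For every threshold triple the union network's adjacency restricted to
    the judged pairs is compared with each rater by Cohen's kappa; the
    triple with the best mean kappa wins, ties resolved toward the largest
    (sparsest) thresholds, lexicographically on (semantic, phonological,
    orthographic).
    """
    if len(judgments) == 0:
        raise ValueError("no judged pairs")
    sem, pho, ort = layers["semantic"], layers["phonological"], layers["orthographic"]
    pairs = judgments[["word1", "word2"]].drop_duplicates().reset_index(drop=True)
    zs = np.array([sem.zpair(a, b) for a, b in pairs.itertuples(index=False)])
    zp = np.array([pho.zpair(a, b) for a, b in pairs.itertuples(index=False)])
    zo = np.array([ort.zpair(a, b) for a, b in pairs.itertuples(index=False)])
    grid = np.round(np.arange(zrange[0], zrange[1] + step / 2, step), 10)
    t = len(grid)
    ps = zs[None, :] > grid[:, None]
    pp = zp[None, :] > grid[:, None]
    po = zo[None, :] > grid[:, None]

    pair_key = {tuple(r): i for i, r in enumerate(pairs.itertuples(index=False))}
    raters = sorted(judgments["rater"].unique())
    rater_y = []
    for r in raters:
        sub = judgments[judgments["rater"] == r]
        y = np.full(len(pairs), -1)
        for w1, w2, lbl in sub[["word1", "word2", "related"]].itertuples(index=False):
            y[pair_key[(w1, w2)]] = lbl
        rater_y.append(y)

    ksum = np.zeros((t, t, t))
    for y in rater_y:
        judged = y >= 0
        y1 = judged & (y == 1)
        y0 = judged & (y == 0)
        n1, n0 = int(y1.sum()), int(y0.sum())
        for i in range(t):
            s = ps[i]
            base1 = int((s & y1).sum())
            base0 = int((s & y0).sum())
            r1 = (~s) & y1
            r0 = (~s) & y0
            m1, o1 = pp[:, r1].astype(float), po[:, r1].astype(float)
            m0, o0 = pp[:, r0].astype(float), po[:, r0].astype(float)
            c1 = base1 + m1.sum(1)[:, None] + o1.sum(1)[None, :] - m1 @ o1.T
            c0 = base0 + m0.sum(1)[:, None] + o0.sum(1)[None, :] - m0 @ o0.T
            ksum[i] += _kappa_from_counts(c1, c0, n1, n0)
    kmean = ksum / len(rater_y)
    best = kmean.max()
    cand = np.argwhere(np.isclose(kmean, best, rtol=0, atol=1e-12))
    i, j, k = max(cand, key=lambda x: (x[0], x[1], x[2]))
    per_rater = []
    for y in rater_y:
        judged = y >= 0
        pred = (ps[i] | pp[j] | po[k]) & judged
        c1 = int((pred & (y == 1)).sum())
        c0 = int((pred & judged & (y == 0)).sum())
        per_rater.append(float(_kappa_from_counts(
            np.array(c1, dtype=float), np.array(c0, dtype=float),
            int((y == 1).sum()), int(judged.sum() - (y == 1).sum()))))
    return ThresholdTriple(
        semantic_z=float(grid[i]),
        phonological_z=float(grid[j]),
        orthographic_z=float(grid[k]),
        achieved_kappa=float(best),
        per_rater_kappa=tuple(per_rater),
    )


def finalize_letterf_network(
    layers: Mapping[str, WeightedLayer], thresholds: ThresholdTriple
) -> LexicalNetwork:
    """Union network: edge iff any layer's z-weight strictly exceeds its threshold."""
    words = layers["semantic"].words
    above = (
        (layers["semantic"].zweights > thresholds.semantic_z)
        | (layers["phonological"].zweights > thresholds.phonological_z)
        | (layers["orthographic"].zweights > thresholds.orthographic_z)
    )
    np.fill_diagonal(above, False)
    net = LexicalNetwork()
    net.graph.add_nodes_from(words)
    idx = np.argwhere(np.triu(above, k=1))
    net.graph.add_edges_from((words[i], words[j]) for i, j in idx)
    return net


# ---------------------------------------------------------------------------
# statistics

def network_stats(net: LexicalNetwork) -> dict[str, float]:
    """Vertex/edge counts, mean degree, density (%), clustering, path length.

    Local clustering of a vertex with degree < 2 counts as 0; the mean
    shortest path length is computed over the largest connected component.
    """
    g = net.graph
    v = g.number_of_nodes()
    if v == 0:
        raise ValueError("empty network")
    e = g.number_of_edges()
    stats = {
        "vertices": float(v),
        "edges": float(e),
        "mean_degree": 2.0 * e / v,
        "density_percent": 100.0 * e / (v * (v - 1) / 2.0) if v > 1 else 0.0,
        "mean_clustering": nx.average_clustering(g) if v > 0 else 0.0,
    }
    if e > 0:
        giant = g.subgraph(max(nx.connected_components(g), key=len))
        stats["mean_path_length"] = (
            nx.average_shortest_path_length(giant) if giant.number_of_nodes() > 1 else 0.0
        )
    else:
        stats["mean_path_length"] = float("nan")
    return stats


def stats_from_counts(vertices: int, edges: int) -> dict[str, float]:
    """Mean degree and edge density implied by vertex and edge counts alone."""
    return {
        "mean_degree": 2.0 * edges / vertices,
        "density_percent": 100.0 * edges / (vertices * (vertices - 1) / 2.0),
    }
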