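"""Rule-based word-relatedness predicates and materialized linkage relations.

The classic (Troyer-style) scoring rules define two words as *linked* when:

* animal task — the words share at least one animal subcategory
  (a word may belong to several: beaver is a rodent, a water creature,
  and used for fur);
* letter-F task — the words rhyme, share their first two letters, are
  homonyms, or differ by exactly one vowel sound, judged on ARPAbet
  pronunciations.

A :class:`LinkageRelation` materializes any symmetric binary relation over a
vocabulary (rule-based, network-edge-based, or arbitrary) so the cluster
partitioner can query it uniformly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .phonology import is_vowel, strip_stress

logger = logging.getLogger(__name__)

Pron = tuple[str, ...]


# ---------------------------------------------------------------------------
# animal task: shared subcategory

def animal_linked(w1: str, w2: str, table: Mapping[str, set[str]]) -> bool:
    """True iff the two words' subcategory sets intersect.

    Words absent from the table have an empty subcategory set and therefore
    link to nothing (except themselves, by the identical-word convention).
    """
    a, b = w1.lower(), w2.lower()
    if a == b:
        return True
    for w in (a, b):
        if w not in table:
            logger.debug("word %r absent from subcategory table", w)
    return bool(table.get(a, set()) & table.get(b, set()))


# ---------------------------------------------------------------------------
# letter-F task: four sound/spelling predicates

def _stressless(p: Pron) -> Pron:
    return tuple(strip_stress(x) for x in p)


def _rime(p: Pron) -> Pron | None:
    """Phoneme suffix from the last primary-stressed vowel onward.

    Falls back to the last vowel when no vowel carries primary stress.
    The rime always includes at least the anchor vowel, so monosyllabic
    identical-rime pairs count as rhymes.
    """
    anchor = None
    for i, ph in enumerate(p):
        if ph.endswith("1"):
            anchor = i
    if anchor is None:
        for i, ph in enumerate(p):
            if is_vowel(ph):
                anchor = i
    if anchor is None:
        return None
    return _stressless(p[anchor:])


def rhyme(p1: Pron, p2: Pron) -> bool:
    r1, r2 = _rime(p1), _rime(p2)
    return r1 is not None and r1 == r2


def homonym(w1: str, w2: str, p1: Pron, p2: Pron) -> bool:
    """Identical stress-stripped pronunciations with different spellings."""
    return w1.lower() != w2.lower() and _stressless(p1) == _stressless(p2)


def one_vowel_difference(p1: Pron, p2: Pron) -> bool:
    """Equal-length pronunciations differing at exactly one position, a vowel in both."""
    s1, s2 = _stressless(p1), _stressless(p2)
    if len(s1) != len(s2):
        return False
    diffs = [i for i, (a, b) in enumerate(zip(s1, s2)) if a != b]
    if len(diffs) != 1:
        return False
    i = diffs[0]
    return is_vowel(s1[i]) and is_vowel(s2[i])


def same_first_two_letters(w1: str, w2: str) -> bool:
    a, b = w1.lower(), w2.lower()
    return len(a) >= 2 and len(b) >= 2 and a[:2] == b[:2]


def letterf_linked(w1: str, w2: str, lex: Mapping[str, list[Pron]]) -> bool:
    """True iff any of the four letter-F predicates holds.

    With several dictionary pronunciations, a predicate holds if ANY pairing
    of pronunciations satisfies it (a rater would credit any valid reading).
    Words without pronunciations fall back to the orthographic predicate
    alone.
    """
    a, b = w1.lower(), w2.lower()
    if a == b:
        return True
    if same_first_two_letters(a, b):
        return True
    prons1 = lex.get(a, [])
    prons2 = lex.get(b, [])
    if not prons1 or not prons2:
        if len(a) < 2 or len(b) < 2:
            logger.warning("word pair (%r, %r) lacks both pronunciation and two letters", w1, w2)
        return False
    for p1 in prons1:
        for p2 in prons2:
            if rhyme(p1, p2) or homonym(a, b, p1, p2) or one_vowel_difference(p1, p2):
                return True
    return False


# ---------------------------------------------------------------------------
# materialized relation

def _key(w1: str, w2: str) -> tuple[str, str]:
    return (w1, w2) if w1 <= w2 else (w2, w1)


@dataclass
class LinkageRelation:
    """A symmetric boolean word-relatedness relation over a vocabulary.

    Stored irreflexively as an unordered edge set; identical words are
    defined linked by convention (reachable only under include-repetitions
    scoring).  ``method`` names the linkage technique that produced it.
    """

    method: str
    edges: set[tuple[str, str]] = field(default_factory=set)
    vocabulary: set[str] = field(default_factory=set)

    def related(self, w1: str, w2: str) -> bool:
        a, b = w1.lower(), w2.lower()
        if a == b:
            return True
        return _key(a, b) in self.edges

    __call__ = related

    def add(self, w1: str, w2: str) -> None:
        a, b = w1.lower(), w2.lower()
        self.vocabulary.update((a, b))
        if a != b:
            self.edges.add(_key(a, b))

    @classmethod
    def from_predicate(cls, method: str, vocab: Iterable[str], predicate) -> "LinkageRelation":
        """Materialize ``predicate(w1, w2)`` over all unordered pairs of ``vocab``."""
        words = sorted({w.lower() for w in vocab})
        rel = cls(method=method, vocabulary=set(words))
        for i, a in enumerate(words):
            for b in words[i + 1:]:
                if predicate(a, b):
                    rel.edges.add((a, b))
        return rel

    @classmethod
    def from_edges(cls, method: str, edges: Iterable[tuple[str, str]],
                   vocabulary: Iterable[str] = ()) -> "LinkageRelation":
        rel = cls(method=method, vocabulary={w.lower() for w in vocabulary})
        for a, b in edges:
            rel.add(a, b)
        return rel

    def to_edge_list(self, path: str | Path, sep: str = "\t") -> None:
        """Export as an undirected, lexicographically ordered edge list."""
        with Path(path).open("w") as fh:
            for a, b in sorted(self.edges):
                fh.write(f"{a}{sep}{b}\n")

    @classmethod
    def from_edge_list(cls, method: str, path: str | Path, sep: str = "\t") -> "LinkageRelation":
        edges = []
        with Path(path).open() as fh:
            for line in fh:
                if line.strip():
                    a, b = line.strip().split(sep)[:2]
                    edges.append((a, b))
        return cls.from_edges(method, edges)


def build_linkage_relation(
    vocab: Iterable[str],
    method: str,
    subcategories: Mapping[str, set[str]] | None = None,
    pronunciations: Mapping[str, list[Pron]] | None = None,
) -> LinkageRelation:
    """Materialize the Troyer-style relation for a task over a vocabulary.

    ``method`` is ``"animal"`` (needs ``subcategories``) or ``"letter_f"``
    (needs ``pronunciations``).
    """
    if method == "animal":
        if subcategories is None:
            raise ValueError("animal linkage requires a subcategory table")
        return LinkageRelation.from_predicate(
            "troyer", vocab, lambda a, b: animal_linked(a, b, subcategories)
        )
    if method == "letter_f":
        if pronunciations is None:
            raise ValueError("letter-F linkage requires a pronunciation lexicon")
        return LinkageRelation.from_predicate(
            "troyer", vocab, lambda a, b: letterf_linked(a, b, pronunciations)
        )
    raise ValueError(f"unknown method {method!r}")
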