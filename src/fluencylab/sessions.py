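"""Data model and I/O for time-stamped verbal fluency sessions.

A *fluency session* is one administration of a timed word-generation task
(semantic cue "animals" or letter cue "F", conventionally 60 s).  Each
utterance is a :class:`WordToken` carrying the surface form, a canonical
(unabbreviated, uninflected) form, the onset time in seconds from the task
cue, the speaker, and a validity status.  The *raw score* is the count of
valid words; utterances whose canonical form repeats an earlier participant
utterance are *repetitions*; words that do not satisfy the task cue
(non-animals; proper nouns or non-F-words) are *intrusions*.

Session files are plain text: either a delimited table with header
``session_id, task, word, canonical, onset_s, speaker, status`` or JSON
lines with the same keys.  Lexical resources use the field's standard
plain-text formats: a two-column (word, subcategory) table, a CMUdict-style
pronunciation file, and a word-vector table (word followed by floats).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

VALID = "valid"
REPETITION = "repetition"
INTRUSION = "intrusion"

TASKS = ("animal", "letter_f")
SPEAKERS = ("participant", "administrator")
STATUSES = (VALID, REPETITION, INTRUSION)

SESSION_COLUMNS = ("session_id", "task", "word", "canonical", "onset_s", "speaker", "status")


class SessionFormatError(ValueError):
    """Raised when a session file does not conform to the documented schema."""


@dataclass(frozen=True)
class WordToken:
    """One utterance in a fluency session.

    ``canonical`` defaults to the surface form when the transcript does not
    supply a separate canonical form (canonicalization is input data, not
    computed here).
    """

    surface: str
    onset: float
    canonical: str = ""
    speaker: str = "participant"
    status: str = VALID

    def __post_init__(self) -> None:
        if not self.canonical:
            object.__setattr__(self, "canonical", self.surface)
        if self.onset < 0:
            raise ValueError(f"token onset must be >= 0, got {self.onset}")
        if self.speaker not in SPEAKERS:
            raise ValueError(f"unknown speaker {self.speaker!r}")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


@dataclass
class FluencySession:
    """An ordered, time-stamped word list from one task administration."""

    session_id: str
    task: str
    tokens: list[WordToken] = field(default_factory=list)
    duration: float = 60.0
    group: str | None = None

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")
        onsets = [t.onset for t in self.tokens]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            self.tokens = sorted(self.tokens, key=lambda t: t.onset)

    @property
    def participant_tokens(self) -> list[WordToken]:
        return [t for t in self.tokens if t.speaker == "participant"]

    def valid_tokens(self, include_repetitions: bool = False) -> list[WordToken]:
        """Tokens entering cluster/timing scores: valid participant words.

        ``include_repetitions`` adds repeated words back for sensitivity
        analyses.
        """
        keep = {VALID, REPETITION} if include_repetitions else {VALID}
        return [t for t in self.participant_tokens if t.status in keep]

    def valid_words(self, include_repetitions: bool = False) -> list[str]:
        return [t.canonical for t in self.valid_tokens(include_repetitions)]

    def valid_onsets(self, include_repetitions: bool = False) -> np.ndarray:
        return np.asarray([t.onset for t in self.valid_tokens(include_repetitions)], dtype=float)


@dataclass(frozen=True)
class BasicScores:
    """Raw / repetition / intrusion counts for one session."""

    raw: int
    repetitions: int
    intrusions: int

    @property
    def total(self) -> int:
        return self.raw + self.repetitions + self.intrusions


def annotate_statuses(
    session: FluencySession,
    animal_lexicon: set[str] | None = None,
    proper_nouns: Iterable[str] = (),
) -> FluencySession:
    """Return a copy of ``session`` with statuses assigned by rule.

    Repetition assignment precedes intrusion assignment: an utterance whose
    canonical form recurs is a repetition regardless of its validity (the
    repetition label is defined purely by canonical-form recurrence).
    Administrator tokens are retained but never labelled.

    For the animal task an utterance is an intrusion when its canonical form
    is absent from ``animal_lexicon`` (no lexicon -> every non-repetition is
    valid).  For letter F, intrusions are proper nouns (an explicit list,
    case-insensitive; orthographic case in transcripts is unreliable) and
    words whose canonical form does not start with "f".
    """
    proper = {w.lower() for w in proper_nouns}
    seen: set[str] = set()
    out: list[WordToken] = []
    for tok in session.tokens:
        if tok.speaker != "participant":
            out.append(tok)
            continue
        canon = tok.canonical.lower()
        if canon in seen:
            status = REPETITION
        elif session.task == "animal":
            ok = animal_lexicon is None or canon in {w.lower() for w in animal_lexicon}
            status = VALID if ok else INTRUSION
        else:
            ok = canon.startswith("f") and canon not in proper
            status = VALID if ok else INTRUSION
        seen.add(canon)
        out.append(replace(tok, status=status))
    return FluencySession(session.session_id, session.task, out, session.duration, session.group)


def basic_scores(
    session: FluencySession,
    animal_lexicon: set[str] | None = None,
    proper_nouns: Iterable[str] = (),
    rescore: bool = True,
) -> BasicScores:
    """Raw, repetition, and intrusion counts.

    With ``rescore`` (default) statuses are re-derived by
    :func:`annotate_statuses`; otherwise the statuses carried by the tokens
    are trusted.  An empty session yields all-zero scores.
    """
    if rescore:
        session = annotate_statuses(session, animal_lexicon, proper_nouns)
    counts = {VALID: 0, REPETITION: 0, INTRUSION: 0}
    for tok in session.participant_tokens:
        counts[tok.status] += 1
    return BasicScores(counts[VALID], counts[REPETITION], counts[INTRUSION])


# ---------------------------------------------------------------------------
# session file I/O

def _token_row(session: FluencySession, tok: WordToken) -> dict:
    return {
        "session_id": session.session_id,
        "task": session.task,
        "word": tok.surface,
        "canonical": tok.canonical,
        "onset_s": tok.onset,
        "speaker": tok.speaker,
        "status": tok.status,
    }


def _sessions_from_rows(rows: list[dict]) -> list[FluencySession]:
    by_id: dict[str, FluencySession] = {}
    order: list[str] = []
    for row in rows:
        sid = str(row["session_id"])
        if sid not in by_id:
            by_id[sid] = FluencySession(sid, str(row["task"]))
            order.append(sid)
        by_id[sid].tokens.append(
            WordToken(
                surface=str(row["word"]),
                canonical=str(row["canonical"]),
                onset=float(row["onset_s"]),
                speaker=str(row["speaker"]),
                status=str(row["status"]),
            )
        )
    out = []
    for sid in order:
        s = by_id[sid]
        s.tokens.sort(key=lambda t: t.onset)
        out.append(s)
    return out


def parse_sessions(path: str | Path, format: str = "tabular", sep: str = "\t") -> list[FluencySession]:
    """Read fluency sessions from a tabular or JSON-lines file.

    Malformed rows raise :class:`SessionFormatError` naming the line number.
    """
    path = Path(path)
    rows: list[dict] = []
    if format == "tabular":
        with path.open() as fh:
            header_line = fh.readline()
            if not header_line:
                return []
            header = [h.strip() for h in header_line.rstrip("\n").split(sep)]
            missing = set(SESSION_COLUMNS) - set(header)
            if missing:
                raise SessionFormatError(f"missing required column(s): {sorted(missing)}")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split(sep)
                if len(parts) != len(header):
                    raise SessionFormatError(f"line {lineno}: expected {len(header)} fields, got {len(parts)}")
                row = dict(zip(header, parts))
                try:
                    float(row["onset_s"])
                except ValueError:
                    raise SessionFormatError(f"line {lineno}: non-numeric onset {row['onset_s']!r}") from None
                rows.append(row)
    elif format == "json-lines":
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise SessionFormatError(f"line {lineno}: invalid JSON ({exc})") from None
                missing = set(SESSION_COLUMNS) - set(row)
                if missing:
                    raise SessionFormatError(f"line {lineno}: missing key(s) {sorted(missing)}")
                rows.append(row)
    else:
        raise ValueError(f"unknown format {format!r}")
    return _sessions_from_rows(rows)


def write_sessions(
    sessions: Sequence[FluencySession], path: str | Path, format: str = "tabular", sep: str = "\t"
) -> None:
    """Write sessions in a form :func:`parse_sessions` reads back losslessly."""
    path = Path(path)
    with path.open("w") as fh:
        if format == "tabular":
            fh.write(sep.join(SESSION_COLUMNS) + "\n")
            for s in sessions:
                for tok in s.tokens:
                    row = _token_row(s, tok)
                    fh.write(sep.join(str(row[c]) for c in SESSION_COLUMNS) + "\n")
        elif format == "json-lines":
            for s in sessions:
                for tok in s.tokens:
                    fh.write(json.dumps(_token_row(s, tok)) + "\n")
        else:
            raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# lexical resources

def load_subcategories(path: str | Path, sep: str = "\t") -> dict[str, set[str]]:
    """Two-column (word, subcategory) table -> word -> set of subcategories.

    A word may appear on multiple rows (e.g. beaver as rodent, water
    creature, and used-for-fur).
    """
    table: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            word, subcat = line.split(sep)[:2]
            table.setdefault(word.lower(), set()).add(subcat)
    return table


def write_subcategories(table: Mapping[str, set[str]], path: str | Path, sep: str = "\t") -> None:
    with Path(path).open("w") as fh:
        for word in sorted(table):
            for subcat in sorted(table[word]):
                fh.write(f"{word}{sep}{subcat}\n")


def load_pronunciations(path: str | Path) -> dict[str, list[tuple[str, ...]]]:
    """CMUdict-format file -> word -> list of ARPAbet phone tuples.

    Lines look like ``FOR  F AO1 R``; alternative pronunciations are marked
    ``WORD(1)``; ``;;;`` introduces comments.
    """
    lex: dict[str, list[tuple[str, ...]]] = {}
    with Path(path).open(encoding="latin-1") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(";;;"):
                continue
            head, *phones = line.split()
            word = head.split("(")[0].lower()
            if phones:
                lex.setdefault(word, []).append(tuple(phones))
    return lex


def write_pronunciations(lex: Mapping[str, list[tuple[str, ...]]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for word in sorted(lex):
            for i, phones in enumerate(lex[word]):
                head = word.upper() if i == 0 else f"{word.upper()}({i})"
                fh.write(f"{head}  {' '.join(phones)}\n")


def load_embeddings(path: str | Path) -> dict[str, np.ndarray]:
    """Plain-text word-vector table (word then d floats per line)."""
    emb: dict[str, np.ndarray] = {}
    dim = None
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            vec = np.asarray([float(x) for x in parts[1:]], dtype=float)
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise SessionFormatError(f"line {lineno}: vector dimension {vec.size} != {dim}")
            if not np.any(vec):
                raise SessionFormatError(f"line {lineno}: zero vector for {parts[0]!r}")
            emb[parts[0].lower()] = vec
    return emb


def write_embeddings(emb: Mapping[str, np.ndarray], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for word in sorted(emb):
            fh.write(word + " " + " ".join(f"{x:.6g}" for x in emb[word]) + "\n")
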