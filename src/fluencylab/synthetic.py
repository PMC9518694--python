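"""Synthetic fluency data with the statistical structure the analyses assume.

The generator emulates 60-second fluency sessions: cumulative word count
follows a saturating exponential (word retrieval slows over the task),
inter-word intervals are short within a semantic module and long across
modules, occasional repetitions and intrusions occur, and case/control
outcomes follow a logistic model on demographics and scores.  A latent
impairment variable slows between-module (switch) transitions more than
within-module ones and reduces overall output, so timing-derived scores
carry signal beyond the raw score.

All randomness descends from a single master seed: every stream is opened
as ``np.random.default_rng([seed, stream_id, ...])``, so identical
configurations reproduce identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .network import LexicalNetwork
from .sessions import FluencySession, WordToken, annotate_statuses, basic_scores

# Posterior-mean effect sizes reported for a large case-control cohort of
# incident cognitive impairment serve as the default generating
# coefficients (logit scale, unstandardized covariates).
DEFAULT_OUTCOME_COEFS: dict[str, float] = {
    "const": 2.7,
    "age": -0.022,
    "male": 0.03,
    "hs": 0.084,
    "some_college": 0.229,
    "college_grad": 0.365,
    "white": 0.35,
    "belt": -0.131,
    "buckle": -0.12,
    "raw": -0.079,
    "repetitions": 0.073,
    "intrusions": 0.257,
    "latent": 0.5,
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic lexicon, walk, timing, and outcome model."""

    seed: int = 0
    # lexicon
    n_modules: int = 6
    words_per_module: int = 8
    embedding_dim: int = 50
    embedding_noise_sd: float = 0.1
    # timing: per-participant saturating-exponential parameters (lognormal)
    c_median: float = 16.0
    c_sigma: float = 0.25
    m_median: float = 0.05
    m_sigma: float = 0.3
    # walk
    p_stay: float = 0.75
    within_multiplier_median: float = 0.6
    between_multiplier_median: float = 1.8
    multiplier_sigma: float = 0.3
    repetition_rate: float = 0.05
    intrusion_rate: float = 0.02
    duration: float = 60.0
    task: str = "animal"
    # latent impairment coupling: impaired participants retrieve fewer words
    # and slow their switch transitions disproportionately
    impairment_c_effect: float = 0.15
    impairment_switch_effect: float = 0.25
    # cohort
    n_participants: int = 1280
    outcome_coefs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OUTCOME_COEFS))

    def __post_init__(self) -> None:
        for rate in (self.p_stay, self.repetition_rate, self.intrusion_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.c_median <= 0 or self.m_median <= 0:
            raise ValueError("c and m medians must be positive")
        if self.n_modules < 2:
            raise ValueError("need at least 2 modules")


# ---------------------------------------------------------------------------
# fixtures: lexical resources with planted structure

_PLANTED_F_PAIRS = {
    # relation -> (word, pron), (word, pron)
    "homonym": (("fohr", ("F", "AO1", "R")), ("fore", ("F", "AO1", "R"))),
    "rhyme": (("fane", ("F", "EY1", "N")), ("frane", ("F", "R", "EY1", "N"))),
    "one_vowel": (("fitt", ("F", "IH1", "T")), ("fatt", ("F", "AE1", "T"))),
    "first_two": (("flock", ("F", "L", "AA1", "K")), ("flonk", ("F", "L", "AA1", "NG", "K"))),
}

_F_CODAS = [("D",), ("G",), ("M",), ("N",), ("P",), ("S",), ("SH",), ("Z",),
            ("S", "T"), ("N", "D"), ("L",), ("K",)]
_F_NUCLEI = ["AA1", "AE1", "AH1", "EH1", "IH1", "IY1", "OW1", "UW1"]


def make_fixtures(config: SyntheticConfig) -> tuple[
    dict[str, set[str]], dict[str, list[tuple[str, ...]]], dict[str, np.ndarray], LexicalNetwork
]:
    """Toy lexical resources: subcategory table, F-pronunciations, embeddings, planted network.

    Animal words are organized into ``n_modules`` overlapping subcategories
    (every fourth word also belongs to the next subcategory).  The F-lexicon
    plants one pair for each letter-F predicate plus unrelated fillers.
    Embeddings place each word at its module centroid plus isotropic noise,
    unit-normalized; the planted network records the module ground truth as
    within-module cliques.
    """
    rng = np.random.default_rng([config.seed, 1])
    subcats: dict[str, set[str]] = {}
    modules: dict[str, int] = {}
    words_by_module: list[list[str]] = []
    for m in range(config.n_modules):
        members = [f"animal_m{m}w{j}" for j in range(config.words_per_module)]
        words_by_module.append(members)
        for j, w in enumerate(members):
            subcats.setdefault(w, set()).add(f"subcat{m}")
            modules[w] = m
            if j % 4 == 3:  # overlapping membership, like beaver the rodent/water creature
                subcats[w].add(f"subcat{(m + 1) % config.n_modules}")

    prons: dict[str, list[tuple[str, ...]]] = {}
    for (w1, p1), (w2, p2) in _PLANTED_F_PAIRS.values():
        prons.setdefault(w1, []).append(p1)
        prons.setdefault(w2, []).append(p2)
    fillers = []
    for i, (nuc, coda) in enumerate((n, c) for n in _F_NUCLEI for c in _F_CODAS):
        word = f"f{nuc[:-1].lower()}{''.join(coda).lower()}"
        if word not in prons:
            prons[word] = [("F", nuc, *coda)]
            fillers.append(word)

    dim = config.embedding_dim
    centroids = rng.standard_normal((config.n_modules, dim))
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    embeddings: dict[str, np.ndarray] = {}
    for m, members in enumerate(words_by_module):
        for w in members:
            v = centroids[m] + config.embedding_noise_sd * rng.standard_normal(dim)
            embeddings[w] = v / np.linalg.norm(v)
    for w in prons:
        v = rng.standard_normal(dim)
        embeddings[w] = v / np.linalg.norm(v)

    planted = LexicalNetwork(modules=dict(modules))
    planted.graph.add_nodes_from(modules)
    for members in words_by_module:
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                planted.graph.add_edge(a, b)
    return subcats, prons, embeddings, planted


# ---------------------------------------------------------------------------
# session simulation

def simulate_session(
    config: SyntheticConfig,
    planted: LexicalNetwork,
    session_id: str = "s0",
    c: float | None = None,
    m: float | None = None,
    impairment: float = 0.0,
    seed_stream: tuple[int, ...] = (2, 0),
) -> FluencySession:
    """One 60-s session from a modular random walk with rate-tracked timing.

    The k-th inter-word interval is ``baseline(t) * multiplier`` where
    ``baseline(t) = 1 / (c m e^{-mt})`` is the instantaneous inverse of the
    saturating-exponential retrieval rate and the multiplier is lognormal
    with median below 1 within a module and above 1 between modules (the
    between-module median grows with ``impairment``).  The walk ends at the
    task duration, or early if it exhausts the lexicon.
    """
    rng = np.random.default_rng([config.seed, *seed_stream])
    if c is None:
        c = config.c_median * float(np.exp(config.c_sigma * rng.standard_normal()))
    if m is None:
        m = config.m_median * float(np.exp(config.m_sigma * rng.standard_normal()))
    c = max(c * float(np.exp(-config.impairment_c_effect * impairment)), 3.0)
    between_median = config.between_multiplier_median * float(
        np.exp(config.impairment_switch_effect * impairment)
    )
    modules: dict[str, int] = dict(planted.modules or {})
    by_module: dict[int, list[str]] = {}
    for w, mod in modules.items():
        by_module.setdefault(mod, []).append(w)
    for members in by_module.values():
        members.sort()

    used: set[str] = set()
    tokens: list[WordToken] = []
    current_module = int(rng.choice(sorted(by_module)))
    word = str(rng.choice(by_module[current_module]))
    t = float(1.0 / (c * m) * np.exp(rng.normal(np.log(config.within_multiplier_median),
                                                config.multiplier_sigma)))
    n_extra = 0
    while t < config.duration:
        tokens.append(WordToken(surface=word, onset=round(t, 3)))
        used.add(word)
        # choose the next word
        u = rng.random()
        if u < config.repetition_rate and len(used) > 1:
            nxt = str(rng.choice(sorted(used)))
            within = True
        elif u < config.repetition_rate + config.intrusion_rate:
            n_extra += 1
            nxt = f"zzz{n_extra}" if config.task == "animal" else f"xq{n_extra}"
            within = True
        else:
            stay = rng.random() < config.p_stay
            pool = [w for w in by_module[current_module] if w not in used]
            if stay and pool:
                nxt = str(rng.choice(pool))
                within = True
            else:
                other = [mod for mod in by_module
                         if any(w not in used for w in by_module[mod]) and mod != current_module]
                if not other:
                    if pool:
                        nxt, within = str(rng.choice(pool)), True
                    else:
                        break  # lexicon exhausted: session ends early
                else:
                    current_module = int(rng.choice(other))
                    nxt = str(rng.choice([w for w in by_module[current_module] if w not in used]))
                    within = False
        median = config.within_multiplier_median if within else between_median
        rate = c * m * np.exp(-m * t)
        iwi = float(1.0 / rate * np.exp(rng.normal(np.log(median), config.multiplier_sigma)))
        t = t + max(iwi, 1e-3)
        word = nxt
    session = FluencySession(session_id, config.task, tokens, duration=config.duration)
    animal_lexicon = set(modules) if config.task == "animal" else None
    return annotate_statuses(session, animal_lexicon=animal_lexicon)


# ---------------------------------------------------------------------------
# cohort simulation

@dataclass
class Cohort:
    """Aligned sessions, demographic covariates, basic scores, and outcomes."""

    sessions: list[FluencySession]
    demographics: pd.DataFrame
    basic: pd.DataFrame
    outcome: np.ndarray
    latent: np.ndarray


def _sample_demographics(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Marginals patterned on a large US epidemiological cohort of older adults."""
    education = rng.choice(
        ["less_than_hs", "hs", "some_college", "college_grad"], size=n,
        p=[0.12, 0.30, 0.26, 0.32],
    )
    region = rng.choice(["nonbelt", "belt", "buckle"], size=n, p=[0.40, 0.38, 0.22])
    return pd.DataFrame(
        {
            "age": np.round(rng.normal(75.0, 8.6, size=n), 1),
            "sex": rng.choice(["male", "female"], size=n, p=[0.46, 0.54]),
            "education": education,
            "race": rng.choice(["white", "black"], size=n, p=[0.62, 0.38]),
            "region": region,
        }
    )


def simulate_cohort(config: SyntheticConfig, planted: LexicalNetwork | None = None) -> Cohort:
    """Simulate a case/control cohort with a logistic outcome model.

    Each participant receives demographics, a latent impairment score
    L ~ N(0, 1) that degrades timing, and a simulated session.  The outcome
    is Bernoulli with logit equal to the configured coefficients applied to
    the encoded demographics, the session's raw/repetition/intrusion
    counts, and L.
    """
    from .bayes import encode_demographics  # deferred: avoids a cycle at import time

    n = config.n_participants
    if n < 20:
        raise ValueError("cohort size < 20 gives unstable metrics")
    if planted is None:
        _, _, _, planted = make_fixtures(config)
    rng = np.random.default_rng([config.seed, 3])
    demo = _sample_demographics(n, rng)
    latent = rng.standard_normal(n)
    sessions = []
    basic_rows = []
    for i in range(n):
        session = simulate_session(
            config, planted, session_id=f"p{i:05d}", impairment=float(latent[i]),
            seed_stream=(2, i),
        )
        sessions.append(session)
        scores = basic_scores(session, rescore=False)
        basic_rows.append(
            {"raw": scores.raw, "repetitions": scores.repetitions, "intrusions": scores.intrusions}
        )
    basic = pd.DataFrame(basic_rows)
    X = encode_demographics(demo)
    for col in ("raw", "repetitions", "intrusions"):
        X[col] = basic[col].astype(float)
    X.insert(0, "const", 1.0)
    coefs = config.outcome_coefs
    logit = np.zeros(n)
    for col, beta in coefs.items():
        if col == "latent":
            logit += beta * latent
        elif col in X.columns:
            logit += beta * X[col].to_numpy()
        else:
            raise ValueError(f"outcome coefficient for unknown column {col!r}")
    prob = 1.0 / (1.0 + np.exp(-logit))
    outcome = (rng.random(n) < prob).astype(int)
    for session, y in zip(sessions, outcome):
        session.group = "case_progressive" if y else "control"
    return Cohort(sessions, demo, basic, outcome, latent)
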