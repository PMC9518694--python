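"""ARPAbet phoneme inventory and articulatory feature descriptions.

Vowel symbols in CMUdict carry a numeric stress marker (0 none, 1 primary,
2 secondary); :func:`strip_stress` removes it.  Each phoneme maps to a small
set of tagged binary articulatory features (consonants: place, manner,
voicing; vowels: height, backness, roundedness) used to score phoneme
substitutions in global alignment: similarity is the Jaccard overlap of the
feature sets mapped affinely onto [-1, +1], so e.g. G/K (velar stops
differing only in voicing) score higher than G/SH.
"""

from __future__ import annotations

ARPABET_VOWELS = frozenset(
    "AA AE AH AO AW AY EH ER EY IH IY OW OY UH UW".split()
)

_CONSONANT_FEATURES = {
    "B": ("bilabial", "stop", "voiced"),
    "CH": ("postalveolar", "affricate", "voiceless"),
    "D": ("alveolar", "stop", "voiced"),
    "DH": ("dental", "fricative", "voiced"),
    "F": ("labiodental", "fricative", "voiceless"),
    "G": ("velar", "stop", "voiced"),
    "HH": ("glottal", "fricative", "voiceless"),
    "JH": ("postalveolar", "affricate", "voiced"),
    "K": ("velar", "stop", "voiceless"),
    "L": ("alveolar", "liquid", "voiced"),
    "M": ("bilabial", "nasal", "voiced"),
    "N": ("alveolar", "nasal", "voiced"),
    "NG": ("velar", "nasal", "voiced"),
    "P": ("bilabial", "stop", "voiceless"),
    "R": ("alveolar", "liquid", "voiced"),
    "S": ("alveolar", "fricative", "voiceless"),
    "SH": ("postalveolar", "fricative", "voiceless"),
    "T": ("alveolar", "stop", "voiceless"),
    "TH": ("dental", "fricative", "voiceless"),
    "V": ("labiodental", "fricative", "voiced"),
    "W": ("bilabial", "glide", "voiced"),
    "Y": ("palatal", "glide", "voiced"),
    "Z": ("alveolar", "fricative", "voiced"),
    "ZH": ("postalveolar", "fricative", "voiced"),
}

_VOWEL_FEATURES = {
    "AA": ("low", "back", "unrounded"),
    "AE": ("low", "front", "unrounded"),
    "AH": ("mid", "central", "unrounded"),
    "AO": ("mid", "back", "rounded"),
    "AW": ("low", "back", "rounded"),
    "AY": ("low", "front", "unrounded"),
    "EH": ("mid", "front", "unrounded"),
    "ER": ("mid", "central", "rhotic"),
    "EY": ("mid", "front", "unrounded"),
    "IH": ("high", "front", "unrounded"),
    "IY": ("high", "front", "unrounded"),
    "OW": ("mid", "back", "rounded"),
    "OY": ("mid", "back", "rounded"),
    "UH": ("high", "back", "rounded"),
    "UW": ("high", "back", "rounded"),
}

ARPABET = frozenset(_CONSONANT_FEATURES) | ARPABET_VOWELS


def strip_stress(phone: str) -> str:
    """Remove the numeric stress digit from a vowel symbol (``AO1`` -> ``AO``)."""
    return phone.rstrip("012")


def is_vowel(phone: str) -> bool:
    return strip_stress(phone) in ARPABET_VOWELS


def feature_set(phone: str) -> frozenset[str]:
    """Tagged articulatory features; empty set for symbols outside ARPAbet."""
    base = strip_stress(phone)
    if base in ARPABET_VOWELS:
        height, backness, rounding = _VOWEL_FEATURES[base]
        return frozenset({"class:vowel", f"height:{height}", f"back:{backness}", f"round:{rounding}"})
    if base in _CONSONANT_FEATURES:
        place, manner, voicing = _CONSONANT_FEATURES[base]
        return frozenset({"class:cons", f"place:{place}", f"manner:{manner}", f"voice:{voicing}"})
    return frozenset()


def phoneme_similarity(a: str, b: str) -> float:
    """Feature-Jaccard substitution score on [-1, +1]; identical phones -> 1."""
    fa, fb = feature_set(a), feature_set(b)
    if not fa or not fb:
        return 1.0 if strip_stress(a) == strip_stress(b) else -1.0
    jaccard = len(fa & fb) / len(fa | fb)
    return 2.0 * jaccard - 1.0
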