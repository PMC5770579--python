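"""Flesch-Kincaid grade level under a small, documented heuristic.

grade = 0.39 * (words / sentences) + 11.8 * (syllables / words) - 15.59

Tokenization and syllable counting are deliberately simple and fully
specified here, so grades are reproducible:

* Sentences: maximal runs split on '.', '!', '?' (runs of terminators
  count once); if no terminator is present the text is one sentence.
* Words: maximal runs of letters, digits and apostrophes.
* Syllables per word: number of vowel groups (aeiouy), minus one for a
  silent final 'e' (not counted for words ending in consonant + 'le'),
  never below one.  All-digit tokens count one syllable.  A small
  exception table handles common irregulars.
"""

from __future__ import annotations

import re

from .errors import EmptyTextError

_WORD_RE = re.compile(r"[A-Za-z0-9']+")
_SENT_RE = re.compile(r"[.!?]+")
_VOWEL_GROUP_RE = re.compile(r"[aeiouy]+")

#: Words the vowel-group heuristic gets wrong.
SYLLABLE_EXCEPTIONS = {
    "people": 2,
    "area": 3,
    "idea": 3,
    "being": 2,
    "doing": 2,
    "going": 2,
    "quiet": 2,
    "science": 2,
    "create": 2,
}


def split_words(text: str) -> list[str]:
    return _WORD_RE.findall(text)


def count_sentences(text: str) -> int:
    terminators = len([m for m in _SENT_RE.finditer(text)])
    # Trailing text without a terminator still forms a sentence.
    tail = _SENT_RE.split(text)[-1]
    if split_words(tail):
        terminators += 1
    return max(terminators, 1)


def count_syllables(word: str) -> int:
    w = word.lower().strip("'")
    if not w:
        return 0
    if w in SYLLABLE_EXCEPTIONS:
        return SYLLABLE_EXCEPTIONS[w]
    if w.isdigit():
        return 1
    groups = len(_VOWEL_GROUP_RE.findall(w))
    if w.endswith("e") and not w.endswith("le") and groups > 1:
        groups -= 1
    return max(groups, 1)


def fk_grade(text: str) -> float:
    """Flesch-Kincaid grade of the text (may be negative for very easy text)."""
    words = split_words(text)
    if not words:
        raise EmptyTextError("cannot grade empty text")
    sentences = count_sentences(text)
    syllables = sum(count_syllables(w) for w in words)
    return (
        0.39 * (len(words) / sentences)
        + 11.8 * (syllables / len(words))
        - 15.59
    )
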