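"""Normalized Damerau-Levenshtein distances for spelling-error scoring.

Orthographic deviation of a typed response from its target is quantified as
the minimal number of character insertions, deletions, substitutions or
adjacent transpositions needed to turn one letter string into the other,
divided by the length of the longer string so the distance is bound at 1.
The same distance applied to IPA phone-symbol sequences yields a
phonological distance: 0 means the misspelling is homophonous with the
target (a phonologically plausible error).

The edit distance uses the optimal-string-alignment (restricted) recurrence:
a transposed pair costs 1 and cannot be edited further afterwards.
"""

from __future__ import annotations

from typing import Sequence

__all__ = [
    "damerau_levenshtein",
    "normalized_distance",
    "orthographic_distance",
    "phonological_distance",
    "MissingTranscriptionError",
]


class MissingTranscriptionError(ValueError):
    """A phonological distance was requested but a transcription is absent."""

    def __init__(self, side: str):
        self.side = side
        super().__init__(
            f"missing {side} transcription: provide an IPA transcription for the "
            f"{side}, either via a G2P adapter or a *_ipa column in the input table"
        )


def damerau_levenshtein(a: Sequence, b: Sequence) -> int:
    """Optimal-string-alignment Damerau-Levenshtein distance.

    Counts the minimal number of single-token insertions, deletions,
    substitutions and adjacent transpositions turning ``a`` into ``b``.
    Tokens may be characters of a string or items of any sequence
    comparable with ``==``.

    Symmetric, non-negative, and 0 iff the sequences are equal.
    """
    m, n = len(a), len(b)
    if m == 0:
        return n
    if n == 0:
        return m
    # two/three rolling rows of the DP table
    prev2: list[int] = []
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            best = min(
                prev[j] + 1,        # deletion
                cur[j - 1] + 1,     # insertion
                prev[j - 1] + cost, # substitution / match
            )
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                best = min(best, prev2[j - 2] + 1)  # adjacent transposition
            cur[j] = best
        prev2, prev = prev, cur
    return prev[n]


def normalized_distance(a: Sequence, b: Sequence) -> float:
    """Damerau-Levenshtein distance divided by the longer sequence length.

    Bounded in [0, 1]; 0 iff the sequences are equal.  Raises ``ValueError``
    when both sequences are empty (the normalization denominator would be 0).
    """
    denom = max(len(a), len(b))
    if denom == 0:
        raise ValueError("normalized distance is undefined for two empty sequences")
    return damerau_levenshtein(a, b) / denom


def orthographic_distance(target: str, response: str) -> float:
    """Normalized edit distance between a typed response and its target word.

    Both strings are whitespace-trimmed and case-folded first: typing case is
    not a spelling error.  An empty response has distance 1 from any target.
    """
    t = target.strip().casefold()
    r = response.strip().casefold()
    if not t:
        raise ValueError("target word must be non-empty")
    return normalized_distance(t, r)


def phonological_distance(
    target_ipa: Sequence | None, response_ipa: Sequence | None
) -> float:
    """Normalized edit distance between two phone-symbol sequences.

    Inputs are tokenized IPA transcriptions (see
    :func:`spelltract.spelling.ipa.tokenize_ipa`).  ``None`` or empty inputs
    raise :class:`MissingTranscriptionError` naming the missing side.
    """
    if target_ipa is None or len(target_ipa) == 0:
        raise MissingTranscriptionError("target")
    if response_ipa is None or len(response_ipa) == 0:
        raise MissingTranscriptionError("response")
    return normalized_distance(list(target_ipa), list(response_ipa))
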