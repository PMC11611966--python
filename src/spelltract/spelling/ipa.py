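"""Tokenization of IPA transcriptions into comparable phone symbols.

Phonological distances are computed over sequences of IPA symbols.  The
tokenizer:

* drops primary (U+02C8) and secondary (U+02CC) stress marks and whitespace
  — stress placement is not a spelling phenomenon;
* attaches combining diacritics (including the tie bar of affricates such
  as t͡ʃ, and the following base symbol) to their base phone, so an
  affricate is a single token;
* otherwise treats every IPA symbol as one token: diphthong components and
  the length mark ː count individually.

The symbol-level granularity is calibrated against the reference worked
example (dissuade vs DISSAUDE -> 0.43) and frozen; see docs/methods.md.
"""

from __future__ import annotations

import unicodedata

__all__ = ["tokenize_ipa", "STRESS_MARKS"]

STRESS_MARKS = {"ˈ", "ˌ", "'"}  # ˈ ˌ and ASCII apostrophe fallback

_TIE_BARS = {"͡", "͜"}  # combining double inverted breve / breve below


def tokenize_ipa(transcription: str) -> tuple[str, ...]:
    """Split an IPA string into phone-symbol tokens.

    >>> tokenize_ipa("dɪswˈeɪd")
    ('d', 'ɪ', 's', 'w', 'e', 'ɪ', 'd')
    >>> tokenize_ipa("t͡ʃɜːt͡ʃ")
    ('t͡ʃ', 'ɜ', 'ː', 't͡ʃ')
    """
    s = unicodedata.normalize("NFC", transcription.strip())
    tokens: list[str] = []
    pending_tie = False
    for ch in s:
        if ch.isspace() or ch in STRESS_MARKS:
            continue
        if ch in _TIE_BARS:
            if tokens:
                tokens[-1] += ch
                pending_tie = True
            continue
        if pending_tie:
            tokens[-1] += ch
            pending_tie = False
            continue
        if unicodedata.combining(ch) and tokens:
            tokens[-1] += ch
            continue
        tokens.append(ch)
    return tuple(tokens)
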