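"""Grapheme-to-phoneme adapters.

Phonological distances need IPA transcriptions of both the target word and
the (possibly misspelled) response.  Transcription is delegated to a
pluggable adapter so the scoring core stays dependency-free:

* :class:`EspeakProcessG2P` shells out to an ``espeak-ng``/``espeak``
  binary when one is on PATH (the engine used to produce the reference
  transcriptions).
* :class:`LexiconG2P` looks words up in a transcription table.  The package
  ships a frozen British-English reference table
  (``data/reference_transcriptions.tsv``) covering the built-in spelling
  test lexicon and its worked-example misspellings; it serves as the
  calibration fixture for the phonological-distance examples.

Pipelines may bypass adapters entirely by supplying ``target_ipa`` /
``response_ipa`` columns in the behavioral table.
"""

from __future__ import annotations

import csv
import shutil
import subprocess
from importlib import resources
from pathlib import Path

from .ipa import tokenize_ipa

__all__ = [
    "G2PUnavailableError",
    "EspeakProcessG2P",
    "LexiconG2P",
    "reference_g2p",
]


class G2PUnavailableError(RuntimeError):
    """No transcription backend can handle the request.

    Callers should either configure a different adapter or supply
    precomputed IPA transcriptions in the input table.
    """


class EspeakProcessG2P:
    """Transcribe via an external eSpeak NG process.

    Parameters
    ----------
    voice:
        eSpeak voice identifier; British English by default, matching the
        dialect of the reference transcriptions.
    """

    def __init__(self, voice: str = "en-gb", executable: str | None = None):
        self.voice = voice
        self.executable = executable or shutil.which("espeak-ng") or shutil.which("espeak")
        if self.executable is None:
            raise G2PUnavailableError(
                "no espeak-ng/espeak executable found on PATH; supply IPA "
                "transcriptions in the input table or use LexiconG2P"
            )
        self._cache: dict[str, tuple[str, ...]] = {}

    @property
    def name(self) -> str:
        return f"espeak:{self.voice}"

    def transcribe(self, word: str) -> tuple[str, ...]:
        """Return the phone-symbol tokens for *word* (deterministic per voice)."""
        if not word or not word.strip():
            raise ValueError("cannot transcribe an empty word")
        key = word.strip().casefold()
        if key not in self._cache:
            out = subprocess.run(
                [self.executable, "-q", "--ipa", "-v", self.voice, key],
                capture_output=True,
                text=True,
                check=True,
            )
            self._cache[key] = tokenize_ipa(out.stdout.strip())
        return self._cache[key]


class LexiconG2P:
    """Transcription by lookup in a word -> IPA table."""

    def __init__(self, table: dict[str, str], name: str = "lexicon"):
        self._table = {k.strip().casefold(): v for k, v in table.items()}
        self._name = name

    @property
    def name(self) -> str:
        return self._name

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "LexiconG2P":
        table = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                table[row["word"]] = row["ipa"]
        return cls(table, name=name or f"lexicon:{Path(path).name}")

    @classmethod
    def british_english_reference(cls) -> "LexiconG2P":
        """The packaged frozen British-English reference transcriptions."""
        ref = resources.files("spelltract.spelling") / "data" / "reference_transcriptions.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path, name="lexicon:british-english-reference")

    def words(self) -> tuple[str, ...]:
        return tuple(self._table)

    def raw(self, word: str) -> str:
        return self._table[word.strip().casefold()]

    def transcribe(self, word: str) -> tuple[str, ...]:
        if not word or not word.strip():
            raise ValueError("cannot transcribe an empty word")
        key = word.strip().casefold()
        if key not in self._table:
            raise G2PUnavailableError(
                f"word {word!r} is not in the transcription lexicon; supply its "
                "IPA transcription in the input table"
            )
        return tokenize_ipa(self._table[key])


def reference_g2p() -> LexiconG2P | EspeakProcessG2P:
    """Best available reference adapter: espeak-ng if installed, else the lexicon."""
    try:
        return EspeakProcessG2P()
    except G2PUnavailableError:
        return LexiconG2P.british_english_reference()
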