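"""Synthetic spelling responses with controllable error structure.

For each participant and test item, the response is correct with
probability equal to the participant's accuracy score.  Errors come in two
flavours mirroring the two spelling routes:

* *phonologically plausible* errors — the letters change but the
  pronunciation does not (homophonous respelling via grapheme
  substitutions), so ``phon_dist == 0`` while ``orth_dist > 0``;
* *orthographic* (implausible) errors — random letter edits that also
  perturb the pronunciation, so both distances are positive.

The per-group mixing proportion and the number of letter edits are tied to
the participant's group, planting a Group x ErrorType interaction: low
scorers produce errors that are further from the target orthographically,
more so than phonologically.  Response IPA for perturbed spellings is
constructed synthetically by applying a matched number of edits to the
target's phone sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..spelling.g2p import LexiconG2P

__all__ = ["ErrorModel", "simulate_responses", "plausible_respelling"]

# homophonous grapheme substitutions (British English); applied left to right
_HOMOPHONE_SWAPS = [
    ("ph", "f"),
    ("ss", "s"),
    ("rr", "r"),
    ("ll", "l"),
    ("mm", "m"),
    ("nn", "n"),
    ("tt", "t"),
    ("pp", "p"),
    ("cc", "c"),
    ("qu", "kw"),
    ("gh", "f"),
    ("ea", "ee"),
    ("ai", "ay"),
    ("c", "k"),
    ("y", "i"),
]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def plausible_respelling(word: str, rng: np.random.Generator) -> str:
    """A homophonous respelling of *word* (differs in letters, same sounds)."""
    order = rng.permutation(len(_HOMOPHONE_SWAPS))
    for pat, rep in (_HOMOPHONE_SWAPS[i] for i in order):
        if pat in word:
            out = word.replace(pat, rep, 1)
            if out != word:
                return out
    # fallback: double a consonant
    for i, ch in enumerate(word):
        if ch not in "aeiou":
            return word[: i + 1] + ch + word[i + 1 :]
    return word + word[-1]


def _letter_perturbation(word: str, n_edits: int, rng: np.random.Generator) -> str:
    chars = list(word)
    for _ in range(n_edits):
        op = rng.integers(4)
        i = int(rng.integers(len(chars)))
        if op == 0:  # substitution
            chars[i] = rng.choice([c for c in _LETTERS if c != chars[i]])
        elif op == 1:  # insertion
            chars.insert(i, rng.choice(list(_LETTERS)))
        elif op == 2 and len(chars) > 2:  # deletion
            del chars[i]
        elif len(chars) > 1:  # adjacent transposition
            i = min(i, len(chars) - 2)
            chars[i], chars[i + 1] = chars[i + 1], chars[i]
    out = "".join(chars)
    return out if out != word else out + rng.choice(list(_LETTERS))


def _perturb_ipa(ipa: str, n_edits: int, rng: np.random.Generator) -> str:
    """Synthetic pronunciation of a letter-perturbed spelling: edit the
    target's IPA string by a matched number of symbol edits."""
    vowels = "aeiouɪɛɔʊʌəɜɒ"
    chars = [c for c in ipa if c not in "ˈˌ"]
    for _ in range(max(1, n_edits)):
        op = rng.integers(3)
        i = int(rng.integers(len(chars)))
        if op == 0:
            chars[i] = rng.choice([c for c in vowels if c != chars[i]])
        elif op == 1:
            chars.insert(i, rng.choice(list(vowels)))
        elif len(chars) > 2:
            del chars[i]
    return "".join(chars)


@dataclass(frozen=True)
class ErrorModel:
    """Group-conditional error generator parameters.

    ``p_plausible``: probability that an error is phonologically plausible,
    per group.  ``n_edits``: letter-edit counts for implausible errors, per
    group.  Defaults plant the reference direction of effect: low scorers
    make fewer plausible and heavier orthographic errors.
    """

    p_plausible_high: float = 0.65
    p_plausible_low: float = 0.30
    n_edits_high: int = 1
    n_edits_low: int = 3


def simulate_responses(
    scores: pd.DataFrame,
    lexicon: LexiconG2P,
    error_model: ErrorModel = ErrorModel(),
    n_items: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a behavioral response table for a simulated cohort.

    ``scores`` is a cohort table from :func:`simulate_scores` (columns
    ``participant_id``, ``score``, ``component``).  Items are the lexicon's
    words.  Returns a long table with one row per participant x item and
    columns matching the scoring input schema (including IPA columns).
    """
    words = [w for w in lexicon.words()]
    if not words:
        raise ValueError("empty lexicon")
    rng = np.random.default_rng(seed)
    if n_items is None:
        n_items = min(40, len(words))
    items = words[:n_items]
    rows = []
    for rec in scores.itertuples(index=False):
        low_group = getattr(rec, "component", 2) == 1
        p_pl = (
            error_model.p_plausible_low if low_group else error_model.p_plausible_high
        )
        n_ed = error_model.n_edits_low if low_group else error_model.n_edits_high
        # realize exactly round(score * n_items) correct items so the
        # cohort's realized accuracy equals its mixture-drawn score: the
        # mixture parameters describe the analyzed accuracy distribution
        n_correct = int(round(rec.score * n_items))
        correct_idx = set(rng.choice(n_items, size=n_correct, replace=False))
        for j, word in enumerate(items):
            target_ipa = lexicon.raw(word)
            if j in correct_idx:
                response, response_ipa = word, target_ipa
            elif rng.random() < p_pl:
                response = plausible_respelling(word, rng)
                response_ipa = target_ipa  # homophone by construction
            else:
                response = _letter_perturbation(word, n_ed, rng)
                # pronunciation deviates by ~one phone regardless of how many
                # letters changed: groups diverge more orthographically than
                # phonologically, as in real misspellings
                response_ipa = _perturb_ipa(target_ipa, 1, rng)
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "item_id": f"item{j + 1:02d}",
                    "target": word,
                    "response": response,
                    "target_ipa": target_ipa,
                    "response_ipa": response_ipa,
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["error_model"] = error_model
    return df
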