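"""Per-response and per-participant spelling scores.

A response is correct only if it matches the target exactly after trimming
and case-folding (any inaccuracy counts as an error).  The participant
accuracy score is the proportion of correct items; mean orthographic and
phonological error distances are computed over error responses only, so a
perfect speller has no defined error-distance means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .distance import orthographic_distance, phonological_distance
from .g2p import G2PUnavailableError
from .ipa import tokenize_ipa

__all__ = [
    "SpellingRecord",
    "ParticipantSpellingSummary",
    "score_response",
    "score_participant",
    "score_table",
    "participant_summaries",
]


@dataclass(frozen=True)
class SpellingRecord:
    """One target/response pair with its derived scores."""

    participant_id: str
    item_id: str
    target: str
    response: str
    correct: bool
    orth_dist: float
    phon_dist: float | None = None
    target_ipa: tuple[str, ...] | None = None
    response_ipa: tuple[str, ...] | None = None

    def __post_init__(self):
        if not 0.0 <= self.orth_dist <= 1.0:
            raise ValueError("orth_dist must lie in [0, 1]")
        if self.phon_dist is not None and not 0.0 <= self.phon_dist <= 1.0:
            raise ValueError("phon_dist must lie in [0, 1]")
        if self.correct != (self.orth_dist == 0.0):
            raise ValueError("correct must hold exactly when orth_dist == 0")


@dataclass(frozen=True)
class ParticipantSpellingSummary:
    participant_id: str
    accuracy: float
    n_items: int
    mean_orth_dist_errors: float | None = None
    mean_phon_dist_errors: float | None = None


def _as_tokens(value) -> tuple[str, ...] | None:
    if value is None:
        return None
    if isinstance(value, str):
        if not value.strip():
            return None
        return tokenize_ipa(value)
    return tuple(value)


def score_response(
    participant_id: str,
    item_id: str,
    target: str,
    response: str,
    target_ipa=None,
    response_ipa=None,
    g2p=None,
) -> SpellingRecord:
    """Score a single target/response pair.

    IPA transcriptions may be given directly (strings or token sequences) or
    produced by a G2P adapter; if neither is possible the phonological
    distance is left undefined (``None``).
    """
    t_ipa = _as_tokens(target_ipa)
    r_ipa = _as_tokens(response_ipa)
    if g2p is not None:
        try:
            if t_ipa is None:
                t_ipa = g2p.transcribe(target)
            if r_ipa is None:
                r_ipa = g2p.transcribe(response) if response.strip() else None
        except G2PUnavailableError:
            pass
    orth = orthographic_distance(target, response)
    phon: float | None = None
    if t_ipa is not None and r_ipa is not None:
        phon = phonological_distance(t_ipa, r_ipa)
    return SpellingRecord(
        participant_id=str(participant_id),
        item_id=str(item_id),
        target=target,
        response=response,
        correct=orth == 0.0,
        orth_dist=orth,
        phon_dist=phon,
        target_ipa=t_ipa,
        response_ipa=r_ipa,
    )


def score_participant(records: Sequence[SpellingRecord]) -> ParticipantSpellingSummary:
    """Summarise one participant's records into accuracy and error-distance means."""
    if not records:
        raise ValueError("need at least one record")
    pids = {r.participant_id for r in records}
    if len(pids) != 1:
        raise ValueError(f"records mix participants: {sorted(pids)}")
    n = len(records)
    n_correct = sum(r.correct for r in records)
    errors = [r for r in records if not r.correct]
    mean_orth = (
        sum(r.orth_dist for r in errors) / len(errors) if errors else None
    )
    phon_errors = [r.phon_dist for r in errors if r.phon_dist is not None]
    mean_phon = sum(phon_errors) / len(phon_errors) if phon_errors else None
    return ParticipantSpellingSummary(
        participant_id=records[0].participant_id,
        accuracy=n_correct / n,
        n_items=n,
        mean_orth_dist_errors=mean_orth,
        mean_phon_dist_errors=mean_phon,
    )


def score_table(table: pd.DataFrame, g2p=None) -> pd.DataFrame:
    """Score a behavioral table of responses.

    Expects columns ``participant_id, item_id, target, response`` and
    optionally ``target_ipa, response_ipa``.  Returns the table with
    ``correct, orth_dist, phon_dist`` columns appended.
    """
    required = {"participant_id", "item_id", "target", "response"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"behavioral table is missing columns: {sorted(missing)}")
    rows = []
    for rec in table.itertuples(index=False):
        d = rec._asdict()
        record = score_response(
            d["participant_id"],
            d["item_id"],
            str(d["target"]),
            "" if (isinstance(d["response"], float) and math.isnan(d["response"])) else str(d["response"]),
            target_ipa=d.get("target_ipa"),
            response_ipa=d.get("response_ipa"),
            g2p=g2p,
        )
        out = dict(d)
        out["correct"] = record.correct
        out["orth_dist"] = record.orth_dist
        out["phon_dist"] = record.phon_dist
        rows.append(out)
    return pd.DataFrame(rows)


def participant_summaries(scored: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a scored table to one row per participant."""
    out = []
    for pid, grp in scored.groupby("participant_id", sort=True):
        errs = grp[~grp["correct"]]
        out.append(
            {
                "participant_id": pid,
                "accuracy": float(grp["correct"].mean()),
                "n_items": int(len(grp)),
                "mean_orth_dist_errors": float(errs["orth_dist"].mean()) if len(errs) else float("nan"),
                "mean_phon_dist_errors": float(errs["phon_dist"].mean()) if len(errs) and errs["phon_dist"].notna().any() else float("nan"),
            }
        )
    return pd.DataFrame(out)
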