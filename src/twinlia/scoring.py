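"""Four-level ordinal depression severity (IDSM) scoring.

The instrument assigns each respondent one of four ordinal severity
levels from a small set of yes/no questionnaire answers:

* 0 — never depressed, or depressed only following childbirth;
* 1 — mild: self-reported depression (the level is self-diagnostic);
* 2 — moderate: in addition, a GP or psychiatrist diagnosed depression;
* 3 — severe/recurrent: in addition, defined medication was prescribed
  and/or there was more than one treated episode.

Levels form a strict hierarchy: each level requires all the criteria of
the levels below it.  Missing answers are represented explicitly
(``None`` / ``NA``) and make a record unscoreable; such records are
excluded from cohort summaries and counted, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_LEVELS = 4

#: canonical CSV column order for questionnaire answers
ANSWER_COLUMNS = (
    "ever_depressed",
    "postnatal_only",
    "gp_diagnosed",
    "psychiatrist_diagnosed",
    "defined_medication",
    "multiple_treated_episodes",
)


class ScoringError(ValueError):
    """A response cannot be scored; ``field`` names the offending answer."""

    def __init__(self, field: str, message: Optional[str] = None):
        self.field = field
        super().__init__(message or f"missing answer for {field!r}: cannot score response")


@dataclass(frozen=True)
class QuestionnaireResponse:
    """One respondent's answers; ``None`` marks a missing answer."""

    ever_depressed: Optional[bool]
    postnatal_only: Optional[bool]
    gp_diagnosed: Optional[bool]
    psychiatrist_diagnosed: Optional[bool]
    defined_medication: Optional[bool]
    multiple_treated_episodes: Optional[bool]


@dataclass(frozen=True)
class CohortScores:
    """Scored cohort: per-row levels, category prevalences, exclusion count."""

    scores: tuple[int, ...]
    prevalences: np.ndarray  # length 4, sums to 1 over scored rows
    n_scored: int
    n_excluded: int


def score_response(r: QuestionnaireResponse) -> int:
    """Return the ordinal severity level (0-3) for one response.

    Raises :class:`ScoringError` naming the first missing field.  The
    postnatal-only exclusion overrides everything: depression reported
    only after childbirth scores 0 regardless of the other answers.
    """
    for f in fields(QuestionnaireResponse):
        if getattr(r, f.name) is None:
            raise ScoringError(f.name)
    if not r.ever_depressed or r.postnatal_only:
        return 0
    level = 1
    if r.gp_diagnosed or r.psychiatrist_diagnosed:
        level = 2
        if r.defined_medication or r.multiple_treated_episodes:
            level = 3
    return level


def score_cohort(rows: Iterable[QuestionnaireResponse]) -> CohortScores:
    """Score every scoreable row and summarise category prevalences.

    Rows with missing answers are excluded (and counted); prevalences
    are computed over scored rows only and sum to 1.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("cannot score an empty cohort")
    scores: list[int] = []
    n_excluded = 0
    for r in rows:
        try:
            scores.append(score_response(r))
        except ScoringError as err:
            n_excluded += 1
            logger.warning("excluded unscoreable response (%s)", err)
    if not scores:
        raise ValueError("no scoreable rows in cohort (all had missing answers)")
    counts = np.bincount(scores, minlength=N_LEVELS).astype(float)
    if n_excluded:
        logger.info("score_cohort: %d of %d rows excluded", n_excluded, len(rows))
    return CohortScores(
        scores=tuple(scores),
        prevalences=counts / counts.sum(),
        n_scored=len(scores),
        n_excluded=n_excluded,
    )


_TOKEN = {"yes": True, "no": False, "na": None, "true": True, "false": False, "": None}


def _parse_token(value) -> Optional[bool]:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    token = str(value).strip().lower()
    if token not in _TOKEN:
        raise ValueError(f"unrecognised answer token {value!r} (expected yes/no/NA)")
    return _TOKEN[token]


def read_responses(path) -> pd.DataFrame:
    """Read a respondent-level answers CSV, validating required columns."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ANSWER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"answers file {path} is missing columns {missing}")
    return df


def score_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add an ``idsm_level`` column to an answers table.

    Unscoreable rows get an empty level and are logged; all other
    columns pass through unchanged.
    """
    levels: list[object] = []
    n_excluded = 0
    for idx, row in df.iterrows():
        try:
            resp = QuestionnaireResponse(
                **{c: _parse_token(row[c]) for c in ANSWER_COLUMNS}
            )
            levels.append(score_response(resp))
        except (ScoringError, ValueError) as err:
            n_excluded += 1
            levels.append(pd.NA)
            logger.warning("row %s unscoreable: %s", idx, err)
    out = df.copy()
    out["idsm_level"] = levels
    if n_excluded:
        logger.info("score_table: %d of %d rows unscoreable", n_excluded, len(df))
    return out


def responses_for_level(level: int) -> QuestionnaireResponse:
    """A canonical answer pattern scoring exactly ``level`` (0-3)."""
    if level not in range(N_LEVELS):
        raise ValueError(f"level must be in 0..3, got {level}")
    return QuestionnaireResponse(
        ever_depressed=level >= 1,
        postnatal_only=False,
        gp_diagnosed=level >= 2,
        psychiatrist_diagnosed=False,
        defined_medication=level >= 3,
        multiple_treated_episodes=False,
    )
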