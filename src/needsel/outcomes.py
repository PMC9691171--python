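"""Outcome coding for the needs-selection model.

Two raw survey answers drive the model's outcomes.  The first question asks
whether the respondent ever failed to receive needed medical treatment or an
examination in the past 12 months (codes 1 = experienced at least once,
2 = did not experience, 3 = no care of any kind was needed); the second,
asked only of code-1 respondents, records the single main reason out of ten
listed ones.  From these we derive

* ``y1`` -- the dichotomous *needs* indicator (1 if the respondent
  experienced healthcare needs at all, i.e. answered 1 or 2; 0 for answer 3),
* ``y2`` -- the quadchotomous outcome among respondents with needs:
  1 = met needs, 2 = financial difficulty (reason 1), 3 = time constraint
  (reason 7), 4 = lack of caring and support (every other listed reason).

``y2`` is defined exactly when ``y1 = 1``.  Records with a missing first
answer, or a missing reason despite reporting an unmet need, cannot be coded
and are excluded listwise, mirroring the source survey's treatment of
observations without usable needs information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MET_NEEDS",
    "FINANCIAL",
    "TIME_CONSTRAINT",
    "LACK_OF_CARE",
    "BARRIER_LABELS",
    "CodingError",
    "ExclusionLog",
    "derive_outcomes",
]

MET_NEEDS = 1
FINANCIAL = 2
TIME_CONSTRAINT = 3
LACK_OF_CARE = 4

BARRIER_LABELS = {
    MET_NEEDS: "met needs",
    FINANCIAL: "financial difficulty",
    TIME_CONSTRAINT: "time constraint",
    LACK_OF_CARE: "lack of caring and support",
}

_VALID_Q1 = {1, 2, 3}
_VALID_Q2 = set(range(1, 11))
# reasons other than 1 (financial) and 7 (time) all map to lack of care
_LACK_REASONS = _VALID_Q2 - {1, 7}


class CodingError(ValueError):
    """Raised when a record carries an unknown q1/q2 answer code."""


@dataclass
class ExclusionLog:
    """Listwise exclusions accumulated while coding outcomes."""

    missing_q1: int = 0
    missing_q2_given_unmet: int = 0
    excluded_index: list = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return self.missing_q1 + self.missing_q2_given_unmet

    def to_text(self) -> str:
        lines = [
            "outcome-coding exclusion log",
            f"missing needs answer (q1): {self.missing_q1}",
            f"unmet need with missing reason (q2): {self.missing_q2_given_unmet}",
            f"total excluded records: {self.n_excluded}",
        ]
        return "\n".join(lines) + "\n"


def _as_float(series: pd.Series) -> np.ndarray:
    return pd.to_numeric(series, errors="raise").to_numpy(dtype=float)


def derive_outcomes(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Append ``y1``/``y2`` columns derived from the raw ``q1``/``q2`` codes.

    Parameters
    ----------
    records : DataFrame with at least ``q1`` and ``q2`` columns.  Missing
        answers are NaN (or empty fields upstream).  ``q2`` is only read for
        records with ``q1 = 1``.

    Returns
    -------
    coded : DataFrame
        Copy of the retained records with integer ``y1`` and float ``y2``
        columns (``y2`` is NaN where ``y1 = 0``, where it is undefined).
    log : ExclusionLog
        Counts and row labels of listwise-excluded records.

    Raises
    ------
    CodingError
        If a non-missing q1 or q2 value is outside the questionnaire's code
        lists; the message names the offending record.
    """
    q1 = _as_float(records["q1"])
    q2 = _as_float(records["q2"])

    known_q1 = np.isnan(q1) | np.isin(q1, sorted(_VALID_Q1))
    if not known_q1.all():
        bad = records.index[~known_q1][0]
        raise CodingError(f"unknown q1 code {q1[~known_q1][0]!r} at record {bad!r}")
    unmet = q1 == 1
    known_q2 = ~unmet | np.isnan(q2) | np.isin(q2, sorted(_VALID_Q2))
    if not known_q2.all():
        bad = records.index[~known_q2][0]
        raise CodingError(f"unknown q2 code {q2[~known_q2][0]!r} at record {bad!r}")

    drop_q1 = np.isnan(q1)
    drop_q2 = unmet & np.isnan(q2)
    keep = ~(drop_q1 | drop_q2)

    log = ExclusionLog(
        missing_q1=int(drop_q1.sum()),
        missing_q2_given_unmet=int(drop_q2.sum()),
        excluded_index=list(records.index[~keep]),
    )

    coded = records.loc[keep].copy()
    q1k, q2k = q1[keep], q2[keep]
    y1 = (q1k != 3).astype(int)
    y2 = np.full(len(coded), np.nan)
    y2[q1k == 2] = MET_NEEDS
    y2[(q1k == 1) & (q2k == 1)] = FINANCIAL
    y2[(q1k == 1) & (q2k == 7)] = TIME_CONSTRAINT
    y2[(q1k == 1) & np.isin(q2k, sorted(_LACK_REASONS))] = LACK_OF_CARE
    coded["y1"] = y1
    coded["y2"] = y2
    return coded, log
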