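"""Semiquantitative clinical phenotyping of labor status and group assignment.

Each delivery record is scored on five axes reflecting how far the pregnancy
had progressed toward spontaneous labor at the time of cesarean:

* gestational age, dichotomized term (1, delivery > 37 wk) vs preterm
  (0, < 34 wk); deliveries in the 34-37 wk band receive ``indeterminate``
  rather than a silent guess, as the dichotomy is partial there;
* uterine contractions on a 0-2 scale (0 absent; 1 irregular, not followed by
  cervical change, or receded after tocolysis; 2 regular and followed by
  cervical change);
* cervical dilation in cm (0-10, last exam before cesarean);
* membrane status (0 intact, 1 ruptured);
* intraamniotic infection/inflammation (Triple I; 0 absent, 1 suspected or
  confirmed; unknown propagates as ``missing`` and is excluded downstream).

Group assignment partitions records into the five clinical delivery groups
(term labor, term not-in-labor, spontaneous preterm labor with intact
membranes, PPROM, and provider-initiated preterm birth); records whose flags
contradict a group definition are left ``unclassified``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

INDETERMINATE = "indeterminate"
MISSING = "missing"

CONTRACTION_LEVELS = ("absent", "irregular_or_receded", "regular_with_cervical_change")
MEMBRANE_LEVELS = ("intact", "ruptured")
TRIPLE_I_LEVELS = ("absent", "suspected_or_confirmed", "unknown")

GROUPS = ("Gr1_TL", "Gr2_TNL", "Gr3_PTB_sPTL", "Gr4_PTB_PPROM", "Gr5_PTB_PI", "unclassified")

_CONTRACTION_SCORE = {"absent": 0, "irregular_or_receded": 1, "regular_with_cervical_change": 2}
_MEMBRANE_SCORE = {"intact": 0, "ruptured": 1}
_TRIPLE_I_SCORE = {"absent": 0, "suspected_or_confirmed": 1, "unknown": MISSING}


@dataclass(frozen=True)
class ClinicalRecord:
    """Raw clinical fields for one delivery."""

    ga_weeks: float
    contractions_raw: str
    dilation_cm: int
    membranes: str
    triple_i: str
    spontaneous_onset: bool
    provider_initiated: bool

    def __post_init__(self) -> None:
        if not 15 < self.ga_weeks < 45:
            raise ValueError(f"ga_weeks {self.ga_weeks} outside plausible range (15, 45)")
        if not 0 <= self.dilation_cm <= 10:
            raise ValueError(f"dilation_cm {self.dilation_cm} outside [0, 10]")
        if self.contractions_raw not in CONTRACTION_LEVELS:
            raise ValueError(f"contractions_raw must be one of {CONTRACTION_LEVELS}")
        if self.membranes not in MEMBRANE_LEVELS:
            raise ValueError(f"membranes must be one of {MEMBRANE_LEVELS}")
        if self.triple_i not in TRIPLE_I_LEVELS:
            raise ValueError(f"triple_i must be one of {TRIPLE_I_LEVELS}")


@dataclass(frozen=True)
class ScoreVector:
    """Semiquantitative scores for one delivery (heatmap row)."""

    ga_score: int | str
    contraction_score: int
    dilation_score: int
    membrane_score: int
    triple_i_score: int | str


def score_case(record: ClinicalRecord) -> ScoreVector:
    """Deterministic, total scoring of a valid clinical record."""
    ga = record.ga_weeks
    if ga > 37:
        ga_score: int | str = 1
    elif ga < 34:
        ga_score = 0
    else:
        ga_score = INDETERMINATE
    return ScoreVector(
        ga_score=ga_score,
        contraction_score=_CONTRACTION_SCORE[record.contractions_raw],
        dilation_score=int(record.dilation_cm),
        membrane_score=_MEMBRANE_SCORE[record.membranes],
        triple_i_score=_TRIPLE_I_SCORE[record.triple_i],
    )


def assign_group(record: ClinicalRecord) -> str:
    """Assign one of the five clinical delivery groups (or ``unclassified``).

    Term + spontaneous labor onset -> Gr1_TL; term + no labor -> Gr2_TNL;
    preterm + spontaneous + intact membranes -> Gr3_PTB_sPTL; preterm +
    membrane rupture -> Gr4_PTB_PPROM; preterm + provider-initiated in the
    absence of active labor contractions, cervical dilation, or membrane
    rupture -> Gr5_PTB_PI. Contradictory flags yield ``unclassified``.
    """
    scores = score_case(record)
    active_labor = record.contractions_raw == "regular_with_cervical_change"
    if record.spontaneous_onset and record.provider_initiated:
        return "unclassified"
    if scores.ga_score == 1:  # term
        if record.spontaneous_onset:
            return "Gr1_TL"
        if not active_labor:
            return "Gr2_TNL"
        return "unclassified"
    if scores.ga_score == 0:  # preterm
        if record.provider_initiated:
            if (not active_labor and record.dilation_cm == 0
                    and record.membranes == "intact"):
                return "Gr5_PTB_PI"
            return "unclassified"
        if record.spontaneous_onset:
            if record.membranes == "ruptured":
                return "Gr4_PTB_PPROM"
            return "Gr3_PTB_sPTL"
        return "unclassified"
    return "unclassified"  # indeterminate gestational-age band


def score_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Score every row of a sample table carrying the raw clinical columns.

    Returns a DataFrame with sample_id, the five score columns, and the
    assigned clinical group.
    """
    rows = []
    for _, row in samples.iterrows():
        rec = ClinicalRecord(
            ga_weeks=float(row["ga_weeks"]),
            contractions_raw=row["contractions_raw"],
            dilation_cm=int(row["dilation_cm"]),
            membranes=row["membranes"],
            triple_i=row["triple_i"],
            spontaneous_onset=_as_bool(row["spontaneous_onset"]),
            provider_initiated=_as_bool(row["provider_initiated"]),
        )
        sv = score_case(rec)
        rows.append({
            "sample_id": row["sample_id"],
            "ga_score": sv.ga_score,
            "contraction_score": sv.contraction_score,
            "dilation_score": sv.dilation_score,
            "membrane_score": sv.membrane_score,
            "triple_i_score": sv.triple_i_score,
            "clinical_group": assign_group(rec),
        })
    return pd.DataFrame(rows)


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"true", "1", "yes"}
    return bool(value)
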