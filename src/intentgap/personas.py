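"""TPB persona segmentation.

Dichotomising attitude (positive/negative), subjective norm (high/low) and
perceived behavioral control (high/low) yields 8 persona segments:

====== ======== ========================= ============================
index  attitude social pressure awareness perceived behavioral control
====== ======== ========================= ============================
1      Positive High                      High
2      Positive Low                       High
3      Positive High                      Low
4      Positive Low                       Low
5      Negative High                      High
6      Negative Low                       High
7      Negative High                      Low
8      Negative Low                       Low
====== ======== ========================= ============================

A score of exactly 0 classifies as negative/low by default (strict ``> 0`` for
positive/high); item-mean Likert scores hit 0 often enough that the choice is
exposed as the ``zero_as_positive`` switch and recorded in the segment table.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .scoring import _topic_cols
from .survey_io import TOPICS

__all__ = [
    "Persona",
    "PERSONAS",
    "LOW_PBC_PERSONAS",
    "SegmentTable",
    "assign_persona",
    "assign_personas",
    "segment_tables",
    "low_pbc_proportion",
]


@dataclasses.dataclass(frozen=True)
class Persona:
    index: int
    attitude_positive: bool
    sn_high: bool
    pbc_high: bool

    def __post_init__(self):
        expected = _index(self.attitude_positive, self.sn_high, self.pbc_high)
        if self.index != expected:
            raise ValueError(
                f"persona index {self.index} inconsistent with attributes (expected {expected})"
            )


def _index(attitude_positive: bool, sn_high: bool, pbc_high: bool) -> int:
    return 1 + (0 if attitude_positive else 4) + (0 if sn_high else 1) + (0 if pbc_high else 2)


#: The 8 personas keyed by index.
PERSONAS: dict[int, Persona] = {
    _index(a, s, p): Persona(_index(a, s, p), a, s, p)
    for a in (True, False)
    for s in (True, False)
    for p in (True, False)
}

#: Segments with low perceived behavioral control.
LOW_PBC_PERSONAS = (3, 4, 7, 8)


def assign_persona(a: float, sn: float, pbc: float, *, zero_as_positive: bool = False) -> Persona:
    """Assign one participant's (A, SN, PBC) to a persona.

    Raises ``ValueError`` on undefined (NaN) input; callers exclude such
    participants from the tables.
    """
    if any(pd.isna(v) for v in (a, sn, pbc)):
        raise ValueError("persona undefined: A, SN and PBC must all be defined")
    pos = (lambda v: v >= 0) if zero_as_positive else (lambda v: v > 0)
    return PERSONAS[_index(pos(a), pos(sn), pos(pbc))]


def assign_personas(
    scores: pd.DataFrame, topic: str, *, zero_as_positive: bool = False
) -> pd.Series:
    """Vectorised persona index per participant (NA where undefined)."""
    block = scores[_topic_cols(topic, ("A", "SN", "PBC"))]
    arr = block.to_numpy()
    pos = arr >= 0 if zero_as_positive else arr > 0
    idx = 1 + np.where(pos[:, 0], 0, 4) + np.where(pos[:, 1], 0, 1) + np.where(pos[:, 2], 0, 2)
    out = pd.Series(idx, index=scores.index, dtype="Int64", name=f"persona_{topic}")
    return out.where(block.notna().all(axis=1))


@dataclasses.dataclass
class SegmentTable:
    """Marginal and joint persona distributions.

    ``counts``/``proportions`` have one row per persona 1..8 and one column per
    topic (pairwise inclusion: a participant undefined on one topic still
    counts toward the other).  ``joint`` is the 8x8 cross-tabulation
    (health rows, sustainability columns) over participants defined on both.
    """

    counts: pd.DataFrame
    proportions: pd.DataFrame
    joint: pd.DataFrame
    n_by_topic: dict[str, int]
    zero_as_positive: bool


def segment_tables(scores: pd.DataFrame, *, zero_as_positive: bool = False) -> SegmentTable:
    idx = pd.Index(range(1, 9), name="persona")
    counts = pd.DataFrame(0, index=idx, columns=list(TOPICS))
    assignments = {}
    for topic in TOPICS:
        personas = assign_personas(scores, topic, zero_as_positive=zero_as_positive)
        assignments[topic] = personas
        vc = personas.dropna().astype(int).value_counts()
        counts[topic] = vc.reindex(idx, fill_value=0)
    n_by_topic = {t: int(counts[t].sum()) for t in TOPICS}
    proportions = counts / pd.Series(n_by_topic).replace(0, np.nan)
    proportions = proportions.fillna(0.0)

    both = pd.DataFrame(assignments).dropna().astype(int)
    joint = pd.crosstab(both["health"], both["sustainability"]).reindex(
        index=idx, columns=idx, fill_value=0
    )
    joint.index.name = "health_persona"
    joint.columns.name = "sustainability_persona"
    return SegmentTable(
        counts=counts,
        proportions=proportions,
        joint=joint,
        n_by_topic=n_by_topic,
        zero_as_positive=zero_as_positive,
    )


def low_pbc_proportion(table: SegmentTable, topic: str) -> float:
    """Share of participants in the low-PBC segments (3, 4, 7, 8)."""
    return float(table.proportions.loc[list(LOW_PBC_PERSONAS), topic].sum())
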