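"""Survey data model and I/O.

The questionnaire measures, for each of two shopping topics (*health* and
*sustainability*), the three Theory-of-Planned-Behavior constructs — attitude
(A), subjective norm (SN) and perceived behavioral control (PBC) — the four
Self-Determination-Theory regulation styles (external, introjected, identified,
intrinsic), and two single-item self reports: intention (I) and perceived
behavior (B).  Every item is a 5-point Likert response coded on the centred
scale -2..+2 (0 = neutral).

Two response sentinels are distinguished:

* :data:`MISSING` — the participant skipped the item; any construct touching a
  missing item is undefined, and a record with any missing item is incomplete.
* :data:`DONT_KNOW` — an explicit "Don't know" answer, admissible only on items
  that offer it (the behavior items by default).  DK counts as *answered* for
  completeness purposes but makes the behavior score undefined, so DK
  responders are excluded only from behavior analyses, not from the study.

A :class:`Cohort` stores responses as a float DataFrame (NaN where no usable
value exists) plus a boolean "Don't know" mask of the same shape, keeping the
two sentinels distinguishable while staying pandas-native.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

TOPICS = ("health", "sustainability")
TOPIC_SUFFIX = {"health": "H", "sustainability": "S"}
SUFFIX_TOPIC = {v: k for k, v in TOPIC_SUFFIX.items()}

TPB_CONSTRUCTS = ("A", "SN", "PBC")
SDT_CONSTRUCTS = ("R_Ext", "R_Intro", "R_Id", "R_Int")
MULTI_ITEM_CONSTRUCTS = TPB_CONSTRUCTS + SDT_CONSTRUCTS
SINGLE_ITEM_CONSTRUCTS = ("I", "B")
CONSTRUCTS = MULTI_ITEM_CONSTRUCTS + SINGLE_ITEM_CONSTRUCTS

ID_COLUMN = "participant_id"
DK_CODE = "DK"

LIKERT_MIN, LIKERT_MAX = -2, 2


class Sentinel(enum.Enum):
    """Non-numeric Likert responses."""

    MISSING = "missing"
    DONT_KNOW = "dont_know"

    def __repr__(self) -> str:  # keeps error messages short
        return self.name


MISSING = Sentinel.MISSING
DONT_KNOW = Sentinel.DONT_KNOW


class CohortValidationError(ValueError):
    """Raised when a cohort file violates the layout or coding rules.

    ``problems`` lists every offending (row, item, message) triple so a bad
    file is reported in full rather than failing on the first cell.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        preview = "\n  ".join(self.problems[:20])
        more = "" if len(self.problems) <= 20 else f"\n  ... {len(self.problems) - 20} more"
        super().__init__(f"{len(self.problems)} validation problem(s):\n  {preview}{more}")


def score_name(construct: str, topic: str) -> str:
    """Canonical score column, e.g. ``score_name('A', 'health') == 'A_H'``."""
    return f"{construct}_{TOPIC_SUFFIX[topic]}"


#: Canonical order of the 18 measured scores (14 constructs + 4 self reports).
SCORE_NAMES: tuple[str, ...] = tuple(
    score_name(c, t) for t in TOPICS for c in CONSTRUCTS
)


def recode_raw(raw_value, *, missing_codes: Iterable = ("",), dk_code=DK_CODE):
    """Recode a raw 1..5 Likert response to the centred -2..+2 scale.

    Declared missing codes map to :data:`MISSING` and the "Don't know" code to
    :data:`DONT_KNOW`.  Values outside 1..5 raise ``ValueError``.
    """
    if raw_value in missing_codes:
        return MISSING
    if raw_value == dk_code:
        return DONT_KNOW
    value = int(raw_value)
    if not 1 <= value <= 5:
        raise ValueError(f"raw Likert value {raw_value!r} outside 1..5")
    return value - 3


@dataclasses.dataclass(frozen=True)
class SurveyLayout:
    """Registry mapping item identifiers to (topic, construct) pairs.

    The exact item counts per construct are configurable; the default uses
    3 items per multi-item construct and a single item for I and B per topic.
    """

    items: Mapping[str, tuple[str, str]]
    dont_know_allowed: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "items", dict(self.items))
        object.__setattr__(self, "dont_know_allowed", frozenset(self.dont_know_allowed))
        self.validate()

    def validate(self) -> None:
        seen: dict[tuple[str, str], list[str]] = {}
        for item, (topic, construct) in self.items.items():
            if topic not in TOPICS:
                raise ValueError(f"item {item!r}: unknown topic {topic!r}")
            if construct not in CONSTRUCTS:
                raise ValueError(f"item {item!r}: unknown construct {construct!r}")
            seen.setdefault((topic, construct), []).append(item)
        for topic in TOPICS:
            for construct in CONSTRUCTS:
                n = len(seen.get((topic, construct), []))
                if n == 0:
                    raise ValueError(f"layout has no items for {construct}/{topic}")
                if construct in SINGLE_ITEM_CONSTRUCTS and n != 1:
                    raise ValueError(
                        f"{construct}/{topic} must map to exactly one item, got {n}"
                    )
        unknown_dk = self.dont_know_allowed - set(self.items)
        if unknown_dk:
            raise ValueError(f"dont_know_allowed references unknown items: {sorted(unknown_dk)}")

    @property
    def item_names(self) -> list[str]:
        return list(self.items)

    def items_for(self, topic: str, construct: str) -> list[str]:
        return [
            item
            for item, (t, c) in self.items.items()
            if t == topic and c == construct
        ]

    @classmethod
    def default(cls, items_per_construct: int | Mapping[str, int] = 3) -> "SurveyLayout":
        """Default layout: k items per TPB/SDT construct, 1 per I and B.

        ``items_per_construct`` may be a single integer or a per-construct map.
        "Don't know" is offered on the two behavior items.
        """
        if isinstance(items_per_construct, int):
            k = {c: items_per_construct for c in MULTI_ITEM_CONSTRUCTS}
        else:
            k = {c: int(items_per_construct.get(c, 3)) for c in MULTI_ITEM_CONSTRUCTS}
        items: dict[str, tuple[str, str]] = {}
        for topic in TOPICS:
            suf = TOPIC_SUFFIX[topic]
            for construct in CONSTRUCTS:
                if construct in SINGLE_ITEM_CONSTRUCTS:
                    items[f"{construct}_{suf}"] = (topic, construct)
                else:
                    for i in range(1, k[construct] + 1):
                        items[f"{construct}_{suf}_{i}"] = (topic, construct)
        dk = frozenset(f"B_{TOPIC_SUFFIX[t]}" for t in TOPICS)
        return cls(items=items, dont_know_allowed=dk)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "items": {item: {"topic": t, "construct": c} for item, (t, c) in self.items.items()},
            "dont_know_allowed": sorted(self.dont_know_allowed),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SurveyLayout":
        payload = yaml.safe_load(Path(path).read_text())
        items = {
            item: (spec["topic"], spec["construct"])
            for item, spec in payload["items"].items()
        }
        return cls(items=items, dont_know_allowed=frozenset(payload.get("dont_know_allowed", ())))


@dataclasses.dataclass
class Cohort:
    """Participant-level response table bound to a :class:`SurveyLayout`.

    ``values`` holds the centred Likert responses as floats with NaN where no
    numeric value exists (missing *or* "Don't know"); ``dont_know`` marks the
    DK cells so the two cases stay distinguishable.
    """

    values: pd.DataFrame
    dont_know: pd.DataFrame
    layout: SurveyLayout

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise CohortValidationError([f"duplicate participant_id: {d!r}" for d in dupes])
        unknown = [c for c in self.values.columns if c not in self.layout.items]
        if unknown:
            raise CohortValidationError([f"column {c!r} not in layout" for c in unknown])
        absent = [c for c in self.layout.item_names if c not in self.values.columns]
        if absent:
            raise CohortValidationError([f"layout item {c!r} absent from table" for c in absent])
        # canonical column order
        self.values = self.values[self.layout.item_names].astype(float)
        self.dont_know = self.dont_know.reindex(
            index=self.values.index, columns=self.values.columns, fill_value=False
        ).astype(bool)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def participant_ids(self) -> list:
        return list(self.values.index)

    @property
    def answered(self) -> pd.DataFrame:
        """True where the item has an answer (numeric or "Don't know")."""
        return self.values.notna() | self.dont_know

    @property
    def complete(self) -> pd.Series:
        """True for records with every layout item answered."""
        return self.answered.all(axis=1)

    def iter_records(self):
        """Yield ``(participant_id, {item: value-or-Sentinel})`` pairs."""
        for pid in self.values.index:
            row = {}
            for item in self.values.columns:
                if self.dont_know.at[pid, item]:
                    row[item] = DONT_KNOW
                elif pd.isna(self.values.at[pid, item]):
                    row[item] = MISSING
                else:
                    row[item] = int(self.values.at[pid, item])
            yield pid, row


def read_cohort(
    path: str | Path,
    layout: SurveyLayout,
    *,
    coding: str = "centered",
    delimiter: str = ",",
    dk_code: str = DK_CODE,
) -> Cohort:
    """Read a delimited participant table into a :class:`Cohort`.

    ``coding`` selects the on-disk scale: ``"centered"`` (-2..+2, the default)
    or ``"raw"`` (1..5, recoded on read).  Empty cells are MISSING; the
    ``dk_code`` literal is "Don't know".  Every malformed cell is collected and
    reported in one :class:`CohortValidationError`; nothing is silently
    dropped.
    """
    if coding not in ("centered", "raw"):
        raise ValueError(f"unknown coding {coding!r}")
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    problems: list[str] = []
    if ID_COLUMN not in frame.columns:
        problems.append(f"missing required column {ID_COLUMN!r}")
    absent = [c for c in layout.item_names if c not in frame.columns]
    problems.extend(f"missing item column {c!r}" for c in absent)
    if problems:
        raise CohortValidationError(problems)

    frame = frame.set_index(ID_COLUMN)
    if frame.index.has_duplicates:
        for d in frame.index[frame.index.duplicated()].unique():
            problems.append(f"duplicate participant_id {d!r}")

    lo, hi = (1, 5) if coding == "raw" else (LIKERT_MIN, LIKERT_MAX)
    values = pd.DataFrame(np.nan, index=frame.index, columns=layout.item_names)
    dk = pd.DataFrame(False, index=frame.index, columns=layout.item_names)
    for item in layout.item_names:
        col = frame[item].str.strip()
        for pid, cell in col.items():
            if cell == "":
                continue
            if cell == dk_code:
                if item not in layout.dont_know_allowed:
                    problems.append(
                        f"row {pid!r}, item {item!r}: 'Don't know' not offered on this item"
                    )
                else:
                    dk.at[pid, item] = True
                continue
            try:
                v = int(cell)
            except ValueError:
                problems.append(f"row {pid!r}, item {item!r}: unparseable cell {cell!r}")
                continue
            if not lo <= v <= hi:
                problems.append(
                    f"row {pid!r}, item {item!r}: value {v} outside {lo}..{hi} ({coding} coding)"
                )
                continue
            values.at[pid, item] = v - 3 if coding == "raw" else v
    if problems:
        raise CohortValidationError(problems)
    return Cohort(values=values, dont_know=dk, layout=layout)


def write_cohort(cohort: Cohort, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a cohort on the centred scale; round-trips bit-identically."""
    out = pd.DataFrame(index=cohort.values.index, columns=cohort.values.columns, dtype=object)
    vals = cohort.values
    for item in vals.columns:
        col = vals[item]
        rendered = col.map(lambda v: "" if pd.isna(v) else str(int(v)))
        rendered[cohort.dont_know[item]] = DK_CODE
        out[item] = rendered
    out.index.name = ID_COLUMN
    out.to_csv(path, sep=delimiter)


def filter_complete(cohort: Cohort) -> Cohort:
    """Retain exactly the complete records (all layout items answered)."""
    mask = cohort.complete
    kept, dropped = int(mask.sum()), int((~mask).sum())
    logger.info("filter_complete: retained %d, dropped %d incomplete record(s)", kept, dropped)
    if kept == 0:
        logger.warning("filter_complete: no complete records remain")
    return Cohort(
        values=cohort.values.loc[mask],
        dont_know=cohort.dont_know.loc[mask],
        layout=cohort.layout,
    )
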