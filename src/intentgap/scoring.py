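"""Construct scores and the two motivational composites.

Construct scores are plain item means on the centred -2..+2 scale.  From them
two composites are built:

* the TPB **Behavioral Intention** ``BI = w_A*A + w_SN*SN + w_PBC*PBC`` with
  non-negative weights.  Because Pearson correlation is invariant to positive
  rescaling, only the weight *direction* is identified by the calibration;
  weights form a scale class and the grid search reports one representative.
* the SDT **Relative Autonomy Index**
  ``RAI = 2*R_Int + R_Id - R_Intro - 2*R_Ext`` with fixed theory-given
  weights, ranging over [-12, +12] for scores in [-2, +2].

``calibrate_weights`` reproduces the data-driven weight choice: an exhaustive
grid search maximising the Pearson correlation between BI and the self-reported
intention I, with one-decimal grid granularity so results are exactly
reproducible.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .survey_io import (
    CONSTRUCTS,
    SCORE_NAMES,
    Cohort,
    TOPICS,
    score_name,
)

__all__ = [
    "TPBWeights",
    "RAI_WEIGHTS",
    "CalibrationError",
    "CalibrationResult",
    "construct_scores",
    "behavioral_intention",
    "relative_autonomy_index",
    "calibrate_weights",
]

#: Fixed SDT regulation weights defining the Relative Autonomy Index.
RAI_WEIGHTS: dict[str, float] = {"R_Int": 2.0, "R_Id": 1.0, "R_Intro": -1.0, "R_Ext": -2.0}


@dataclasses.dataclass(frozen=True)
class TPBWeights:
    """Non-negative weight triple (w_A, w_SN, w_PBC), not all zero."""

    w_a: float
    w_sn: float
    w_pbc: float

    def __post_init__(self):
        arr = self.as_array()
        if np.any(arr < 0):
            raise ValueError(f"weights must be non-negative, got {tuple(arr)}")
        if np.all(arr == 0):
            raise ValueError("weights must not all be zero")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_a, self.w_sn, self.w_pbc], dtype=float)

    @property
    def total(self) -> float:
        return float(self.as_array().sum())

    def normalized(self) -> "TPBWeights":
        """Representative with unit weight sum (the identified direction)."""
        arr = self.as_array() / self.total
        return TPBWeights(*arr)


class CalibrationError(ValueError):
    """Weight calibration is impossible (constant intention or composites)."""


@dataclasses.dataclass(frozen=True)
class CalibrationResult:
    weights: TPBWeights
    achieved_r: float
    n_used: int


def construct_scores(cohort: Cohort) -> pd.DataFrame:
    """Per-participant scores for the 18 measured variables.

    Each construct score is the mean of its items; any sentinel item (missing
    or "Don't know") makes that construct undefined (NaN) for the participant,
    so in particular B is undefined exactly when the behavior item was DK or
    missing.
    """
    out = pd.DataFrame(index=cohort.values.index, columns=list(SCORE_NAMES), dtype=float)
    for topic in TOPICS:
        for construct in CONSTRUCTS:
            items = cohort.layout.items_for(topic, construct)
            block = cohort.values[items]
            defined = block.notna().all(axis=1)
            out[score_name(construct, topic)] = block.mean(axis=1).where(defined)
    return out


def _topic_cols(topic: str, constructs) -> list[str]:
    return [score_name(c, topic) for c in constructs]


def behavioral_intention(scores: pd.DataFrame, weights: TPBWeights, topic: str) -> pd.Series:
    """BI = w_A*A + w_SN*SN + w_PBC*PBC; undefined where any construct is."""
    block = scores[_topic_cols(topic, ("A", "SN", "PBC"))]
    bi = block.to_numpy() @ weights.as_array()
    out = pd.Series(bi, index=scores.index, name=score_name("BI", topic))
    return out.where(block.notna().all(axis=1))


def relative_autonomy_index(scores: pd.DataFrame, topic: str) -> pd.Series:
    """RAI = 2*R_Int + R_Id - R_Intro - 2*R_Ext; undefined where any regulation is."""
    regs = list(RAI_WEIGHTS)
    block = scores[_topic_cols(topic, regs)]
    w = np.array([RAI_WEIGHTS[r] for r in regs])
    rai = block.to_numpy() @ w
    out = pd.Series(rai, index=scores.index, name=score_name("RAI", topic))
    return out.where(block.notna().all(axis=1))


def calibrate_weights(
    scores: pd.DataFrame,
    topic: str,
    *,
    grid_step: float = 0.1,
    weight_bound: float = 2.0,
) -> CalibrationResult:
    """Grid-search the BI weights maximising corr(BI, I) for ``topic``.

    The grid is ``{0, grid_step, ..., weight_bound}^3`` minus the origin.
    Participants with any of A, SN, PBC, I undefined are excluded pairwise.
    Ties (up to a 1e-9 relative correlation tolerance, which also collapses
    positively proportional triples) break toward the smallest weight sum and
    then lexicographic order on (w_A, w_SN, w_PBC).
    """
    cols = _topic_cols(topic, ("A", "SN", "PBC", "I"))
    data = scores[cols].dropna()
    n = len(data)
    if n < 3:
        raise CalibrationError(f"need >=3 complete participants, got {n}")
    x = data[cols[:3]].to_numpy()
    i = data[cols[3]].to_numpy()
    if np.ptp(i) == 0:
        raise CalibrationError("self-reported intention is constant; correlation undefined")

    n_steps = int(round(weight_bound / grid_step))
    axis = np.round(np.arange(n_steps + 1) * grid_step, 10)
    grid = np.array(list(itertools.product(axis, axis, axis)))[1:]  # drop origin

    cov = np.cov(np.column_stack([x, i]), rowvar=False, ddof=1)
    sxx, sxi, sii = cov[:3, :3], cov[:3, 3], cov[3, 3]
    num = grid @ sxi
    den = np.sqrt(np.einsum("ij,jk,ik->i", grid, sxx, grid) * sii)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / den, -np.inf)
    if not np.isfinite(r).any():
        raise CalibrationError("every candidate composite is constant")

    best = r.max()
    tied = np.flatnonzero(r >= best - 1e-9 * max(1.0, abs(best)))
    order = np.lexsort(
        (grid[tied, 2], grid[tied, 1], grid[tied, 0], grid[tied].sum(axis=1))
    )
    w = TPBWeights(*grid[tied[order[0]]])
    bi = x @ w.as_array()
    achieved = float(np.corrcoef(bi, i)[0, 1])
    return CalibrationResult(weights=w, achieved_r=achieved, n_used=n)
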