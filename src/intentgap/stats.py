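"""Statistical battery: paired t, Pearson r, Wilcoxon signed-rank, BH step-up.

All tests use pairwise deletion (a participant is excluded only from analyses
whose variables are undefined for them) and two-sided p-values.

Three paired effect-size variants are reported side by side because no single
standard formula reproduces every published Cohen's d in this literature:

* ``d_z``      — mean(d) / sd(d) on the paired differences,
* ``d_pooled`` — (mean(x) - mean(y)) / sqrt((sd(x)^2 + sd(y)^2) / 2),
* ``d_from_t`` — t / sqrt(n).

The Benjamini–Hochberg family reports per-rank critical thresholds
``alpha_i = i*q/m`` (rounded to 3 decimals for display, unrounded for the
step-up decision) alongside the rejection flags.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "BHEntry",
    "BHFamily",
    "cohens_d_from_t",
    "paired_t",
    "pearson_corr",
    "wilcoxon_signed_rank",
    "bh_family",
    "bh_thresholds",
]


def cohens_d_from_t(t: float, n: int) -> float:
    """Paired-design effect size recovered from the test statistic: t/sqrt(n)."""
    return float(t / np.sqrt(n))

_EXACT_WILCOXON_MAX_N = 12


@dataclasses.dataclass(frozen=True)
class TestResult:
    """A single test: statistic, df (where defined), n used, two-sided p."""

    name: str
    statistic_name: str  # "t", "r" or "W"
    statistic: float
    df: int | None
    n_used: int
    p: float
    effect_sizes: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(pd.Series(x), dtype=float)
    y = np.asarray(pd.Series(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    return x[mask], y[mask]


def paired_t(x, y, *, name: str = "paired_t", zero_variance: str = "error") -> TestResult:
    """Two-sided paired t-test on pairwise-complete (x, y).

    ``zero_variance`` controls the degenerate all-differences-equal-with-zero-
    spread case: ``"error"`` (default) raises, ``"zero"`` returns t = 0, p = 1.
    """
    xs, ys = _paired(x, y)
    n = len(xs)
    if n < 2:
        raise ValueError(f"paired t-test needs >=2 complete pairs, got {n}")
    d = xs - ys
    sd = d.std(ddof=1)
    if sd == 0:
        if zero_variance == "zero":
            t = 0.0
            p = 1.0
        else:
            raise ValueError("paired differences have zero variance")
    else:
        t = float(d.mean() / (sd / np.sqrt(n)))
        p = float(2 * sps.t.sf(abs(t), n - 1))
    sx, sy = xs.std(ddof=1), ys.std(ddof=1)
    pooled = np.sqrt((sx**2 + sy**2) / 2)
    effects = {
        "d_z": float(d.mean() / sd) if sd > 0 else 0.0,
        "d_pooled": float((xs.mean() - ys.mean()) / pooled) if pooled > 0 else 0.0,
        "d_from_t": cohens_d_from_t(t, n),
    }
    return TestResult(name, "t", t, n - 1, n, p, effects)


def pearson_corr(x, y, *, name: str = "pearson") -> TestResult:
    """Pearson correlation with df = n - 2 and t-based two-sided p."""
    xs, ys = _paired(x, y)
    n = len(xs)
    if n < 3:
        raise ValueError(f"Pearson correlation needs >=3 complete pairs, got {n}")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    r, p = sps.pearsonr(xs, ys)
    return TestResult(name, "r", float(r), n - 2, n, float(p))


def _signed_rank_setup(d: np.ndarray, zero_policy: str):
    """Ranks of |d| and the retained nonzero entries under the zero policy."""
    if zero_policy not in ("discard", "pratt"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    if zero_policy == "discard":
        d = d[d != 0]
        ranks = sps.rankdata(np.abs(d))
        return d, ranks
    # Pratt: rank zeros with everything else, then drop them from both sums.
    ranks = sps.rankdata(np.abs(d))
    keep = d != 0
    return d[keep], ranks[keep]


def _exact_signed_rank_p(ranks: np.ndarray, w: float) -> float:
    """Exact two-sided p for W+ = w by enumerating the 2^n sign null.

    Uses the distribution of sum(r_i * s_i), s_i iid Bernoulli(1/2), built by
    convolution over the doubled-rank integer grid (doubling makes tied
    average ranks integral).
    """
    r2 = np.rint(2 * ranks).astype(int)
    pmf = np.array([1.0])
    for r in r2:
        nxt = np.zeros(len(pmf) + r)
        nxt[: len(pmf)] += 0.5 * pmf
        nxt[r:] += 0.5 * pmf
        pmf = nxt
    w2 = int(round(2 * w))
    lower = pmf[: w2 + 1].sum()
    upper = pmf[w2:].sum()
    return float(min(1.0, 2 * min(lower, upper)))


def wilcoxon_signed_rank(
    x, y, *, zero_policy: str = "discard", name: str = "wilcoxon"
) -> TestResult:
    """Wilcoxon signed-rank test on pairwise-complete (x, y).

    The statistic is W+ (sum of ranks of positive differences), with average
    ranks for ties.  Zero differences are discarded by default or handled per
    Pratt (ranked, then excluded from both sums).  The p-value is exact (full
    sign enumeration) for <=12 retained nonzero differences, otherwise a
    normal approximation whose moments are computed from the actual retained
    ranks — which makes the tie and Pratt corrections automatic.
    """
    xs, ys = _paired(x, y)
    d = xs - ys
    nz, ranks = _signed_rank_setup(d, zero_policy)
    n = len(nz)
    if n == 0:
        raise ValueError("all paired differences are zero")
    w = float(ranks[nz > 0].sum())
    if n <= _EXACT_WILCOXON_MAX_N:
        p = _exact_signed_rank_p(ranks, w)
    else:
        mean = ranks.sum() / 2
        var = (ranks**2).sum() / 4
        z = (w - mean) / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
    return TestResult(name, "W", w, None, len(xs), p)


@dataclasses.dataclass(frozen=True)
class BHEntry:
    result: TestResult
    rank: int
    alpha: float  # unrounded i*q/m, used for the decision
    reject: bool

    @property
    def alpha_3dp(self) -> float:
        return round(self.alpha, 3)


@dataclasses.dataclass
class BHFamily:
    """Benjamini–Hochberg step-up family over an ordered list of tests.

    ``entries`` preserves the input order; ranks are by ascending p with ties
    broken by input order.  The rejection set is the step-up set: every test
    whose rank is <= max{i : p_(i) <= i*q/m}.
    """

    entries: list[BHEntry]
    q: float

    @property
    def m(self) -> int:
        return len(self.entries)

    def thresholds(self, *, rounded: bool = True) -> list[float]:
        by_rank = sorted(self.entries, key=lambda e: e.rank)
        return [e.alpha_3dp if rounded else e.alpha for e in by_rank]

    @property
    def n_rejected(self) -> int:
        return sum(e.reject for e in self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            t = e.result
            rows.append(
                {
                    "name": t.name,
                    "statistic_name": t.statistic_name,
                    "statistic": t.statistic,
                    "df": t.df,
                    "n": t.n_used,
                    "p": t.p,
                    **{k: t.effect_sizes.get(k) for k in ("d_z", "d_pooled", "d_from_t")},
                    "rank": e.rank,
                    "alpha_bh": e.alpha_3dp,
                    "reject": e.reject,
                }
            )
        return pd.DataFrame(rows)


def bh_thresholds(m: int, q: float = 0.05) -> np.ndarray:
    """Per-rank critical thresholds i*q/m for i = 1..m (unrounded)."""
    if m < 1:
        raise ValueError("family must contain at least one test")
    return np.arange(1, m + 1) * q / m


def bh_family(results: Sequence[TestResult], q: float = 0.05) -> BHFamily:
    """Apply the BH step-up procedure at level ``q`` to a family of tests."""
    if len(results) == 0:
        raise ValueError("empty test family")
    if not 0 < q < 1:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    m = len(results)
    p = np.array([r.p for r in results])
    order = np.argsort(p, kind="stable")
    alphas = bh_thresholds(m, q)
    sorted_p = p[order]
    passing = np.flatnonzero(sorted_p <= alphas)
    cutoff = passing.max() + 1 if len(passing) else 0  # max rank rejected
    rank_of = np.empty(m, dtype=int)
    rank_of[order] = np.arange(1, m + 1)
    entries = [
        BHEntry(result=r, rank=int(rank_of[i]), alpha=float(alphas[rank_of[i] - 1]),
                reject=bool(rank_of[i] <= cutoff))
        for i, r in enumerate(results)
    ]
    return BHFamily(entries=entries, q=q)
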