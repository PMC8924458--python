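"""Synthetic survey cohorts with prescribed score moments and correlations.

The generator emulates the reference survey so every downstream stage is
testable without the deposited dataset: 144 completers out of 176 starters,
construct scores on the centred -2..+2 scale with the published means/SDs, the
ten published inter-score Pearson correlations, and 6 "Don't know" answers on
the sustainability behavior item.

Model
-----
Participants are rows of a multivariate normal over the 18 *latent* scores
(14 constructs + 4 self reports).  Items are emitted as
``round(clip(latent, -2, 2) + noise)`` clipped to the Likert range; intention
and behavior are single discretized items.  The published moments constrain
composites (BI, RAI), not individual constructs, so the default calibration
derives construct-level targets from the composite ones by linear-composite
algebra under documented exchangeability assumptions (see
:func:`default_calibration`).

Discretization both shifts moments (saturation at the scale ends) and
attenuates correlations.  When ``calibrate_discretization`` is on (the
default), the generator solves — deterministically, via closed forms for
single items and Gauss–Hermite quadrature for multi-item constructs — for the
latent mean/SD whose *discretized* score reproduces the target moments, and
inflates each specified latent correlation by the classical attenuation factor
``1/(lambda_x * lambda_y)`` where ``lambda`` is the latent/observed
correlation of each variable.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import least_squares
from statsmodels.stats.correlation_tools import corr_clipped

from .scoring import RAI_WEIGHTS
from .survey_io import (
    Cohort,
    MULTI_ITEM_CONSTRUCTS,
    SCORE_NAMES,
    SurveyLayout,
    TOPICS,
    TOPIC_SUFFIX,
    score_name,
)
from . import study

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "default_calibration",
    "complete_correlation_matrix",
    "generate_scores",
    "generate_cohort",
]

# Derivation constants for construct-level targets (documented design
# choices: within-block exchangeable correlations and a mild positive
# baseline agreement on the regulation items).
RHO_TPB = 0.3
RHO_REG = 0.2
REG_BASELINE_MEAN = 0.5
#: Unreported cross-topic intention/behavior correlations (I_H~B_S, I_S~B_H).
#: A zero default contradicts the four published correlations in that quartet
#: (the implied matrix is indefinite); 0.30 sits between the published
#: within-topic gaps and cross-topic links and keeps the quartet consistent.
RHO_IB_CROSS = 0.30

_CUTS = np.array([-1.5, -0.5, 0.5, 1.5])
_LEVELS = np.arange(-2, 3, dtype=float)
_GH_X, _GH_W = np.polynomial.hermite.hermgauss(64)
_GH_WN = _GH_W / np.sqrt(np.pi)


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclasses.dataclass
class GeneratorConfig:
    """Targets, layout and missingness scheme for the cohort simulator."""

    n_participants: int = study.N_COMPLETERS
    n_starters: int = study.N_STARTERS
    target_means: dict = dataclasses.field(default_factory=dict)
    target_sds: dict = dataclasses.field(default_factory=dict)
    target_correlations: dict = dataclasses.field(default_factory=dict)
    items_per_construct: int = 3
    item_noise_sd: float = 0.4
    dk_count_behavior: int = study.DK_COUNT_BEHAVIOR
    dk_item: str = "B_S"
    #: items still answered by questionnaire starters who dropped out
    #: (drop-out happens toward the end, after the first self-report section)
    dropout_items: tuple = ("I_H", "B_H")
    calibrate_discretization: bool = True
    pd_floor: float = 1e-6
    corr_tol: float = 0.02
    seed: int | None = None
    _model_cache: object = dataclasses.field(default=None, repr=False, compare=False)

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_starters < self.n_participants:
            raise ValueError("need n_starters >= n_participants >= 1")
        for name in SCORE_NAMES:
            if name not in self.target_means or name not in self.target_sds:
                raise ValueError(f"missing target moments for score {name!r}")
            if not -2 <= self.target_means[name] <= 2:
                raise ValueError(f"target mean for {name!r} outside [-2, 2]")
            if self.target_sds[name] <= 0:
                raise ValueError(f"target SD for {name!r} must be > 0")
        for (a, b), r in self.target_correlations.items():
            if abs(r) > 1:
                raise ValueError(f"target correlation {a}~{b} = {r} outside [-1, 1]")
        if not 0 <= self.dk_count_behavior <= self.n_participants:
            raise ValueError("dk_count_behavior outside 0..n_participants")
        if self.item_noise_sd < 0:
            raise ValueError("item_noise_sd must be non-negative")

    def layout(self) -> SurveyLayout:
        return SurveyLayout.default(self.items_per_construct)

    # -- latent model (cached; see module docstring) ----------------------

    def latent_model(self):
        if self._model_cache is None:
            self.validate()
            self._model_cache = _build_latent_model(self)
        return self._model_cache


def default_calibration(**overrides) -> GeneratorConfig:
    """Generator configuration reproducing the published survey structure.

    Self-report (I, B) moments and the ten published correlations are taken
    directly from the study constants.  Construct-level targets, which the
    study reports only through composites, are derived as follows:

    * TPB constructs share a common mean ``BI_mean / sum(w)`` and common SD
      chosen so the weighted composite variance matches the BI SD under an
      exchangeable within-topic correlation ``RHO_TPB = 0.3``.
    * Regulations share a common SD matched to the RAI SD under
      ``RHO_REG = 0.2``; means sit at ``REG_BASELINE_MEAN`` shifted by
      ``sign(v_j) * RAI_mean / sum(|v|)`` so the composite mean matches.
    * Published correlations involving composites are translated into uniform
      construct-level correlations via the composite algebra (for RAI-linked
      pairs, proportional to the regulation weight so the signed sum does not
      cancel; for cross-topic RAI, same-regulation pairs only).
    """
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    corr: dict[tuple[str, str], float] = {}

    for name in ("I_H", "B_H", "I_S", "B_S"):
        means[name], sds[name] = study.SCORE_MOMENTS[name]
    for (a, b), r in study.SCORE_CORRELATIONS.items():
        if not (a.startswith(("BI", "RAI")) or b.startswith(("BI", "RAI"))):
            corr[_pair(a, b)] = r
    corr[_pair("I_H", "B_S")] = RHO_IB_CROSS
    corr[_pair("I_S", "B_H")] = RHO_IB_CROSS

    regs = list(RAI_WEIGHTS)
    v = np.array([RAI_WEIGHTS[r] for r in regs])
    sigma_c: dict[str, float] = {}
    sigma_r: dict[str, float] = {}
    for topic in TOPICS:
        suf = TOPIC_SUFFIX[topic]
        w = study.PUBLISHED_WEIGHTS[topic].as_array()
        bi_mean, bi_sd = study.SCORE_MOMENTS[f"BI_{suf}"]
        cross_w = sum(
            w[i] * w[j] for i in range(3) for j in range(i + 1, 3)
        )
        sigma_c[suf] = bi_sd / np.sqrt((w**2).sum() + 2 * RHO_TPB * cross_w)
        tpb = [score_name(c, topic) for c in ("A", "SN", "PBC")]
        for name in tpb:
            means[name] = bi_mean / w.sum()
            sds[name] = sigma_c[suf]
        for i in range(3):
            for j in range(i + 1, 3):
                corr[_pair(tpb[i], tpb[j])] = RHO_TPB

        rai_mean, rai_sd = study.SCORE_MOMENTS[f"RAI_{suf}"]
        cross_v = sum(
            v[i] * v[j] for i in range(4) for j in range(i + 1, 4)
        )
        sigma_r[suf] = rai_sd / np.sqrt((v**2).sum() + 2 * RHO_REG * cross_v)
        reg_names = [score_name(r, topic) for r in regs]
        for j, name in enumerate(reg_names):
            means[name] = REG_BASELINE_MEAN + np.sign(v[j]) * rai_mean / np.abs(v).sum()
            sds[name] = sigma_r[suf]
        for i in range(4):
            for j in range(i + 1, 4):
                corr[_pair(reg_names[i], reg_names[j])] = RHO_REG

        # BI ~ I: uniform construct-intention correlation.
        r_bi_i = study.SCORE_CORRELATIONS[(f"BI_{suf}", f"I_{suf}")]
        r_ci = r_bi_i * bi_sd / (sigma_c[suf] * w.sum())
        for name in tpb:
            corr[_pair(name, f"I_{suf}")] = r_ci

        # BI ~ RAI within topic: construct-regulation correlation
        # proportional to the regulation weight (r0 * v_j / max|v|).
        r_bi_rai = study.SCORE_CORRELATIONS[(f"BI_{suf}", f"RAI_{suf}")]
        scale = (v * (v / np.abs(v).max())).sum()  # = sum v_j^2 / 2 = 5
        r0 = r_bi_rai * bi_sd * rai_sd / (sigma_c[suf] * sigma_r[suf] * w.sum() * scale)
        for name in tpb:
            for j, reg in enumerate(reg_names):
                corr[_pair(name, reg)] = r0 * v[j] / np.abs(v).max()

    # Cross-topic composites.
    w_h = study.PUBLISHED_WEIGHTS["health"].as_array()
    w_s = study.PUBLISHED_WEIGHTS["sustainability"].as_array()
    bi_h_sd = study.SCORE_MOMENTS["BI_H"][1]
    bi_s_sd = study.SCORE_MOMENTS["BI_S"][1]
    r_bb = study.SCORE_CORRELATIONS[("BI_H", "BI_S")] * bi_h_sd * bi_s_sd / (
        sigma_c["H"] * sigma_c["S"] * w_h.sum() * w_s.sum()
    )
    for ch in ("A", "SN", "PBC"):
        for cs in ("A", "SN", "PBC"):
            corr[_pair(f"{ch}_H", f"{cs}_S")] = r_bb

    rai_h_sd = study.SCORE_MOMENTS["RAI_H"][1]
    rai_s_sd = study.SCORE_MOMENTS["RAI_S"][1]
    r_rr = study.SCORE_CORRELATIONS[("RAI_H", "RAI_S")] * rai_h_sd * rai_s_sd / (
        (v**2).sum() * sigma_r["H"] * sigma_r["S"]
    )
    for r in regs:
        corr[_pair(f"{r}_H", f"{r}_S")] = r_rr

    config = GeneratorConfig(
        target_means=means, target_sds=sds, target_correlations=corr, **overrides
    )
    config.validate()
    return config


# ---------------------------------------------------------------------------
# correlation completion


def complete_correlation_matrix(
    partial: Mapping[tuple[str, str], float],
    names: list[str] | tuple[str, ...] = SCORE_NAMES,
    *,
    floor: float = 1e-6,
    tol: float = 0.02,
) -> pd.DataFrame:
    """Complete a partially specified correlation matrix to positive definite.

    Unspecified off-diagonal entries start at 0.  If the raw matrix has an
    eigenvalue below ``floor`` it is repaired by alternating projections:
    eigenvalue clipping with re-normalised unit diagonal, followed by
    re-imposition of the specified entries, iterated until the spectrum
    clears the floor — so the *unspecified* entries absorb the inconsistency
    wherever a valid completion exists.  A final clipping pass guarantees
    positive semi-definiteness; if any specified entry still deviates by more
    than ``tol``, the partial specification is deemed contradictory and a
    ``ValueError`` reports the worst deviation.
    """
    names = list(names)
    pos = {nm: i for i, nm in enumerate(names)}
    n = len(names)
    mat = np.eye(n)
    seen: dict[tuple[int, int], float] = {}
    for (a, b), r in partial.items():
        if a not in pos or b not in pos:
            raise ValueError(f"unknown score name in correlation key ({a!r}, {b!r})")
        if abs(r) > 1:
            raise ValueError(f"correlation {a}~{b} = {r} outside [-1, 1]")
        if a == b:
            if r != 1:
                raise ValueError(f"diagonal entry {a}~{a} must be 1, got {r}")
            continue
        i, j = sorted((pos[a], pos[b]))
        if (i, j) in seen and not np.isclose(seen[(i, j)], r):
            raise ValueError(
                f"conflicting specifications for {names[i]}~{names[j]}: "
                f"{seen[(i, j)]} vs {r}"
            )
        seen[(i, j)] = r
        mat[i, j] = mat[j, i] = r

    eigs = np.linalg.eigvalsh(mat)
    if eigs.min() < floor:
        logger.debug(
            "correlation matrix not PD (min eigenvalue %.3g); repairing with "
            "eigenvalue clipping at %.1g", eigs.min(), floor,
        )
        projected = mat.copy()
        for _ in range(500):
            if np.linalg.eigvalsh(projected).min() >= 0.999 * floor:
                break
            projected = corr_clipped(projected, threshold=floor)
            for (i, j), r in seen.items():
                projected[i, j] = projected[j, i] = r
            np.fill_diagonal(projected, 1.0)
        projected = corr_clipped(projected, threshold=floor)
    else:
        projected = mat
    if seen:
        devs = {k: abs(projected[k] - v) for k, v in seen.items()}
        (i, j), worst = max(devs.items(), key=lambda kv: kv[1])
        if worst > tol:
            raise ValueError(
                "partial correlation specification cannot be completed within "
                f"tolerance {tol}: worst deviation {worst:.4f} at "
                f"{names[i]}~{names[j]} (specified {seen[(i, j)]}, "
                f"projected {projected[i, j]:.4f})"
            )
    return pd.DataFrame(projected, index=names, columns=names)


# ---------------------------------------------------------------------------
# discretization-bias calibration


def _single_disc_moments(mu: float, sigma: float):
    """Mean, SD and latent covariance of ``round(clip(N(mu, sigma)))``."""
    z = (_CUTS - mu) / sigma
    cdf = np.concatenate(([0.0], sps.norm.cdf(z), [1.0]))
    pmf = np.diff(cdf)
    mean = float(_LEVELS @ pmf)
    var = float(_LEVELS**2 @ pmf) - mean**2
    pdf = np.concatenate(([0.0], sps.norm.pdf(z), [0.0]))
    cov = float(sigma * (_LEVELS * (pdf[:-1] - pdf[1:])).sum())
    return mean, np.sqrt(max(var, 0.0)), cov


def _construct_disc_moments(mu: float, sigma: float, k: int, noise_sd: float):
    """Moments of the k-item construct score built on latent N(mu, sigma).

    Items are ``round(clip(c) + eps_i)`` with iid N(0, noise_sd) noise; the
    score is their mean.  Integration over the latent is Gauss–Hermite; the
    within-item integrand is smooth because of the noise.
    """
    c = mu + np.sqrt(2) * sigma * _GH_X
    u = np.clip(c, -2.0, 2.0)
    z = (_CUTS[None, :] - u[:, None]) / noise_sd
    cdf = np.concatenate(
        [np.zeros((len(c), 1)), sps.norm.cdf(z), np.ones((len(c), 1))], axis=1
    )
    pmf = np.diff(cdf, axis=1)
    g = pmf @ _LEVELS
    s2 = pmf @ _LEVELS**2
    v = s2 - g**2
    mean = float(_GH_WN @ g)
    var = float(_GH_WN @ (g - mean) ** 2) + float(_GH_WN @ v) / k
    cov = float(_GH_WN @ ((c - mu) * g))
    return mean, np.sqrt(max(var, 0.0)), cov


@dataclasses.dataclass(frozen=True)
class _LatentParams:
    mu: float
    sigma: float
    lam: float  # corr(latent, observed score): attenuation factor


def _solve_latent(target_mean: float, target_sd: float, moments_fn) -> _LatentParams:
    def residual(theta):
        m, s, _ = moments_fn(theta[0], theta[1])
        return [m - target_mean, s - target_sd]

    fit = least_squares(
        residual,
        x0=[target_mean, max(target_sd, 0.3)],
        bounds=([-4.0, 0.02], [4.0, 4.0]),
        xtol=1e-12,
        ftol=1e-12,
    )
    mu, sigma = fit.x
    m, s, cov = moments_fn(mu, sigma)
    misfit = max(abs(m - target_mean), abs(s - target_sd))
    if misfit > 5e-3:
        logger.warning(
            "discretization calibration misfit %.4f for target (%.3f, %.3f)",
            misfit, target_mean, target_sd,
        )
    lam = cov / (sigma * s)
    return _LatentParams(mu=float(mu), sigma=float(sigma), lam=float(lam))


def _build_latent_model(config: GeneratorConfig):
    """Latent (mu, sigma) per score plus the completed latent correlation."""
    params: dict[str, _LatentParams] = {}
    for name in SCORE_NAMES:
        tm, ts = config.target_means[name], config.target_sds[name]
        construct = name.rsplit("_", 1)[0]
        if not config.calibrate_discretization:
            params[name] = _LatentParams(mu=tm, sigma=ts, lam=1.0)
            continue
        if construct in MULTI_ITEM_CONSTRUCTS and config.item_noise_sd > 0:
            k = config.items_per_construct
            fn = lambda mu, sg: _construct_disc_moments(mu, sg, k, config.item_noise_sd)
        else:
            fn = _single_disc_moments
        params[name] = _solve_latent(tm, ts, fn)

    corr: dict[tuple[str, str], float] = {}
    for (a, b), r in config.target_correlations.items():
        if config.calibrate_discretization:
            inflated = r / (params[a].lam * params[b].lam)
            if abs(inflated) > 0.99:
                logger.warning(
                    "inflated latent correlation %s~%s clipped from %.3f to ±0.99",
                    a, b, inflated,
                )
                inflated = np.clip(inflated, -0.99, 0.99)
            corr[_pair(a, b)] = float(inflated)
        else:
            corr[_pair(a, b)] = r
    matrix = complete_correlation_matrix(
        corr, SCORE_NAMES, floor=config.pd_floor, tol=config.corr_tol
    )
    vals, vecs = np.linalg.eigh(matrix.to_numpy())
    factor = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return params, matrix, factor


# ---------------------------------------------------------------------------
# generation


def _draw_latent(config: GeneratorConfig, rng: np.random.Generator, n: int) -> pd.DataFrame:
    params, _, factor = config.latent_model()
    z = rng.standard_normal((n, len(SCORE_NAMES)))
    x = z @ factor.T
    mus = np.array([params[s].mu for s in SCORE_NAMES])
    sigmas = np.array([params[s].sigma for s in SCORE_NAMES])
    return pd.DataFrame(mus + sigmas * x, columns=list(SCORE_NAMES))


def generate_scores(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Latent score table: MVN draw, truncated to the [-2, +2] score range.

    Identical (config, seed) pairs produce identical tables.  The SD
    attenuation caused by truncation is measured and logged per variable.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    latent = _draw_latent(config, rng, config.n_participants)
    truncated = latent.clip(-2.0, 2.0)
    for name in SCORE_NAMES:
        pre, post = latent[name].std(ddof=1), truncated[name].std(ddof=1)
        if pre > 0 and post < 0.995 * pre:
            logger.debug(
                "truncation attenuates SD of %s by factor %.3f", name, post / pre
            )
    truncated.index = [f"P{i + 1:04d}" for i in range(len(truncated))]
    return truncated


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> Cohort:
    """Full synthetic cohort in the survey item format.

    The first ``n_participants`` records are completers; the remaining
    starters answered only the first self-report section (``dropout_items``).
    ``dk_count_behavior`` completers, chosen uniformly, answer "Don't know"
    on ``dk_item``.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    layout = config.layout()
    n = config.n_starters
    latent = _draw_latent(config, rng, n).clip(-2.0, 2.0)
    ids = [f"P{i + 1:04d}" for i in range(n)]

    values = pd.DataFrame(np.nan, index=ids, columns=layout.item_names)
    for topic in TOPICS:
        for construct in MULTI_ITEM_CONSTRUCTS:
            items = layout.items_for(topic, construct)
            base = latent[score_name(construct, topic)].to_numpy()
            noise = rng.standard_normal((n, len(items))) * config.item_noise_sd
            emitted = np.clip(np.rint(base[:, None] + noise), -2, 2)
            values.loc[:, items] = emitted
    for topic in TOPICS:
        for construct in ("I", "B"):
            (item,) = layout.items_for(topic, construct)
            single = latent[score_name(construct, topic)].to_numpy()
            values[item] = np.clip(np.rint(single), -2, 2)

    # starters who dropped out keep only the early self-report items
    dropped_cols = [c for c in layout.item_names if c not in config.dropout_items]
    values.iloc[config.n_participants :, [values.columns.get_loc(c) for c in dropped_cols]] = np.nan

    dont_know = pd.DataFrame(False, index=ids, columns=layout.item_names)
    if config.dk_count_behavior:
        dk_rows = rng.choice(config.n_participants, size=config.dk_count_behavior, replace=False)
        dk_ids = [ids[i] for i in sorted(dk_rows)]
        values.loc[dk_ids, config.dk_item] = np.nan
        dont_know.loc[dk_ids, config.dk_item] = True

    return Cohort(values=values, dont_know=dont_know, layout=layout)
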