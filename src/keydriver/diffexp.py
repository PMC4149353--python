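"""Two-group differential expression and cross-list overlap statistics.

The test statistic is an empirical-Bayes moderated t: per-gene pooled
residual variances are shrunk toward a common prior variance ``s0^2``
with prior degrees of freedom ``d0``, both estimated from the data by a
method of moments on ``log s^2`` (the marginal distribution of the log
pooled variance under the hierarchical model is a shifted log-F, whose
first two moments are digamma/trigamma expressions; inverting the
trigamma identity yields ``d0``). The moderated statistic

    t~_g = (mean2_g - mean1_g) / (s~_g * sqrt(1/n1 + 1/n2)),
    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

is referred to a t distribution with ``d0 + d_g`` degrees of freedom
(standard normal when ``d0`` is infinite). With ``d0 = 0`` the statistic
reduces exactly to the classical pooled two-sample t; as ``d0 -> inf``
the variance shrinks entirely to ``s0^2``.

Transcript DEGs are called on linear fold change alone (strictly above
the cutoff, default 1.2); protein lists additionally gate on a p-value
(default 0.05) — both rules are explicit parameters of
:func:`call_degs`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
from scipy import special, stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Default linear fold-change cutoff for DEG calling.
DEFAULT_FC_CUT = 1.2
#: Default p-value gate for protein lists (transcripts use none).
PROTEIN_P_CUT = 0.05


@dataclass(frozen=True)
class GeneScoreRecord:
    """Per-gene differential-expression statistics.

    ``direction`` is ``"null"`` until thresholds are applied; after
    :func:`call_degs` it is ``"up"``/``"down"`` for called genes.
    """

    gene: str
    log2fc: float
    t_stat: float
    p_value: float
    direction: str = "null"


@dataclass(frozen=True)
class DEGList:
    """Up/down DEG calls with the thresholds that produced them."""

    up: tuple[str, ...]
    down: tuple[str, ...]
    fc_cut: float
    p_cut: float | None = None

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.up) | frozenset(self.down)

    def direction_of(self, gene: str) -> str:
        if gene in self.up:
            return "up"
        if gene in self.down:
            return "down"
        return "none"


@dataclass(frozen=True)
class OverlapResult:
    """Exact intersection between two gene lists, with the percentage
    expressed relative to one declared reference list and rounded
    half-up to one decimal."""

    n_a: int
    n_b: int
    n_intersection: int
    percent_of_reference: float
    reference: str  # "a" or "b"


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton, monotone decreasing)."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def _fit_prior(s2: np.ndarray, dg: int) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on log pooled variances."""
    ok = s2 > 0
    if ok.sum() < 2:
        return math.inf, float(np.mean(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(dg / 2.0) + math.log(dg / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, dg / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = math.exp(emean + float(special.digamma(d0 / 2.0))
                       - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s02 = math.exp(emean)
    return d0, s02


def moderated_t(matrix: ExpressionMatrix,
                prior_df: float | None = None) -> list[GeneScoreRecord]:
    """Empirical-Bayes moderated t-test for a two-group design.

    Parameters
    ----------
    matrix
        log2 expression, exactly two groups with >=2 samples each.
    prior_df
        Override the estimated prior degrees of freedom ``d0``; ``0``
        gives the classical pooled t, ``numpy.inf`` the constant-variance
        (z-like) limit. Default: estimate from the data.

    Returns
    -------
    One :class:`GeneScoreRecord` per gene, in matrix row order, with
    ``log2fc`` = mean(second group) - mean(first group), groups taken in
    sorted label order (e.g. disease - control).
    """
    groups = matrix.groups()
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    g1, g2 = groups
    x1 = matrix.values[matrix.group_samples(g1)].to_numpy(float)
    x2 = matrix.values[matrix.group_samples(g2)].to_numpy(float)
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >=2 samples "
                         f"(got {g1}: {n1}, {g2}: {n2})")
    dg = n1 + n2 - 2
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    diff = m2 - m1
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / dg

    if prior_df is None:
        d0, s02 = _fit_prior(s2, dg)
    else:
        d0 = float(prior_df)
        _, s02 = _fit_prior(s2, dg)
        if d0 < 0:
            raise ValueError("prior_df must be >= 0")

    if math.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = math.inf
    else:
        s2_post = (d0 * s02 + dg * s2) / (d0 + dg)
        df_total = d0 + dg

    se_scale = math.sqrt(1.0 / n1 + 1.0 / n2)
    tiny = np.finfo(float).tiny
    zero_var = s2_post <= 0
    if np.any(zero_var & (diff != 0)):
        logger.warning("%d gene(s) with zero variance and nonzero difference; "
                       "variance floored at machine minimum",
                       int(np.sum(zero_var & (diff != 0))))
    s2_safe = np.where(zero_var, tiny, s2_post)
    t = diff / (np.sqrt(s2_safe) * se_scale)
    t = np.where(zero_var & (diff == 0), 0.0, t)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(zero_var & (diff == 0), 1.0, p)

    return [GeneScoreRecord(g, float(fc), float(tt), float(pp))
            for g, fc, tt, pp in zip(matrix.genes, diff, t, p)]


def call_degs(records: Sequence[GeneScoreRecord],
              fc_cut: float = DEFAULT_FC_CUT,
              p_cut: float | None = None) -> DEGList:
    """Call DEGs: linear |FC| strictly above ``fc_cut``, optionally
    gated on ``p <= p_cut``. Direction follows the sign of log2fc."""
    if fc_cut < 1:
        raise ValueError(f"fc_cut must be >= 1 on the linear scale, got {fc_cut}")
    up: list[str] = []
    down: list[str] = []
    for rec in records:
        if 2.0 ** abs(rec.log2fc) <= fc_cut:
            continue
        if p_cut is not None and rec.p_value > p_cut:
            continue
        (up if rec.log2fc > 0 else down).append(rec.gene)
    return DEGList(tuple(up), tuple(down), fc_cut, p_cut)


def annotate_directions(records: Sequence[GeneScoreRecord],
                        degs: DEGList) -> list[GeneScoreRecord]:
    """Return records with ``direction`` set from a DEG call."""
    return [GeneScoreRecord(r.gene, r.log2fc, r.t_stat, r.p_value,
                            degs.direction_of(r.gene)
                            if r.gene in degs.genes else "null")
            for r in records]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (as printed percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def overlap_stats(a: Iterable[str], b: Iterable[str],
                  reference: str = "a") -> OverlapResult:
    """Exact set intersection of two gene lists with the percentage of the
    declared reference list, rounded half-up to one decimal."""
    if reference not in ("a", "b"):
        raise ValueError("reference must be 'a' or 'b'")
    sa, sb = set(a), set(b)
    inter = len(sa & sb)
    ref_size = len(sa) if reference == "a" else len(sb)
    if ref_size == 0:
        raise ValueError("reference list is empty; percentage undefined")
    percent = round_half_up(100.0 * inter / ref_size)
    return OverlapResult(len(sa), len(sb), inter, percent, reference)
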