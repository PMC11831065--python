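"""Edge-wise two-group inference and questionnaire summary-statistics tests.

Edge-wise comparison: per channel pair, a two-sided Mann–Whitney U test on
the subjects' band coherence values, corrected with the Benjamini–Hochberg
step-up FDR across all pairs of one (band, condition) family.

Small samples (n_case * n_control <= 100, no ties) use exact enumeration of
the U null distribution; otherwise the normal approximation with midranks,
tie correction, and continuity correction.

Also implements the printed-table style summaries: a pooled-variance
two-sample t recomputed from group means/SDs/sizes, and Cronbach's alpha for
scale reliability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError, DataError, NumericalError
from .spectral import CoherenceProfile, pair_list

logger = logging.getLogger(__name__)


@dataclass
class EdgeTestResult:
    """One channel pair's group comparison within one (band, condition)."""

    pair: tuple[str, str]
    band: str
    condition: str
    U: float
    p: float
    q: float
    median_case: float
    median_control: float

    @property
    def case_deficit(self) -> bool:
        return self.median_case < self.median_control


@dataclass(frozen=True)
class SummaryStats:
    """Group means/SDs/sizes for one questionnaire scale."""

    scale: str
    M_case: float
    SD_case: float
    n_case: int
    M_control: float
    SD_control: float
    n_control: int

    def __post_init__(self) -> None:
        if self.SD_case < 0 or self.SD_control < 0:
            raise ConfigurationError("SDs must be >= 0")
        if self.n_case < 2 or self.n_control < 2:
            raise ConfigurationError("group sizes must be >= 2")


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def mann_whitney_edge(
    values_case: np.ndarray, values_control: np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U, p).

    ``U`` counts (case, control) pairs with the case value larger (ties half).
    Exact enumeration when n_case * n_control <= 100 and there are no ties;
    otherwise normal approximation with tie and continuity corrections.
    """
    x = np.asarray(values_case, dtype=float)
    y = np.asarray(values_control, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DataError("each group needs at least 2 values")
    exact = len(x) * len(y) <= 100 and not _has_ties(np.concatenate([x, y]))
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order.

    q_(i) = min_{j >= i} (m * p_(j) / j), clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ConfigurationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def edgewise_comparison(
    profiles: list[CoherenceProfile], band: str, condition: str
) -> list[EdgeTestResult]:
    """All-pairs Mann–Whitney + BH-FDR for one (band, condition) family.

    The BH family is exactly the set of channel pairs of this band and
    condition.  Medians per group are attached to every result.
    """
    sel = [p for p in profiles if p.condition == condition]
    case = [p for p in sel if p.group == "case"]
    control = [p for p in sel if p.group == "control"]
    if len(case) < 2 or len(control) < 2:
        raise DataError("need at least 2 subjects per group")
    channels = sel[0].channels
    if any(p.channels != channels for p in sel):
        raise DataError("profiles have mismatched channel lists")

    pairs = pair_list(len(channels))
    iu = np.array([i for i, _ in pairs])
    ju = np.array([j for _, j in pairs])
    # (n_subjects, n_pairs) per group
    vals_case = np.stack([p.band_matrices[band][iu, ju] for p in case])
    vals_control = np.stack([p.band_matrices[band][iu, ju] for p in control])

    n1, n2 = len(case), len(control)
    if n1 * n2 > 100:
        res = sps.mannwhitneyu(
            vals_case, vals_control, alternative="two-sided",
            method="asymptotic", use_continuity=True, axis=0,
        )
        U = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
    else:
        U = np.empty(len(pairs))
        p = np.empty(len(pairs))
        for k in range(len(pairs)):
            U[k], p[k] = mann_whitney_edge(vals_case[:, k], vals_control[:, k])
    q = bh_fdr(np.clip(p, np.finfo(float).tiny, 1.0))
    med_case = np.median(vals_case, axis=0)
    med_control = np.median(vals_control, axis=0)

    logger.info(
        "edgewise %s/%s: %d pairs, n=%d+%d, %d BH-significant at q<=0.05",
        band, condition, len(pairs), n1, n2, int(np.sum(q <= 0.05)),
    )
    return [
        EdgeTestResult(
            pair=(channels[i], channels[j]),
            band=band,
            condition=condition,
            U=float(U[k]),
            p=float(p[k]),
            q=float(q[k]),
            median_case=float(med_case[k]),
            median_control=float(med_control[k]),
        )
        for k, (i, j) in enumerate(pairs)
    ]


def t_from_summary(s: SummaryStats) -> tuple[float, float]:
    """Pooled-variance two-sample t from group summary statistics.

    Returns ``(t, df)`` with ``df = n_case + n_control - 2`` and the sign
    convention control-minus-case over the pooled standard error (negative
    when the case group scores higher).
    """
    if s.SD_case == 0 and s.SD_control == 0:
        raise NumericalError("both group SDs are zero; t undefined")
    df = s.n_case + s.n_control - 2
    sp2 = ((s.n_case - 1) * s.SD_case**2 + (s.n_control - 1) * s.SD_control**2) / df
    se = np.sqrt(sp2 * (1.0 / s.n_case + 1.0 / s.n_control))
    t = (s.M_control - s.M_case) / se
    return float(t), float(df)


def cronbach_alpha(item_scores: np.ndarray) -> float:
    """Cronbach's alpha of a (subjects x items) score matrix.

    alpha = k/(k-1) * (1 - sum(item variances) / variance(total score)).
    """
    x = np.asarray(item_scores, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise DataError("need at least 2 subjects and 2 items")
    k = x.shape[1]
    total_var = np.var(x.sum(axis=1), ddof=1)
    if total_var == 0:
        raise NumericalError("zero total-score variance; alpha undefined")
    item_var = np.var(x, axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))
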