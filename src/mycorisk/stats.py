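"""Rank-based tests for locality comparisons and soil–tissue correlation.

Three tests cover the analysis: Kruskal–Wallis across localities, a
one-sample Wilcoxon signed-rank of each locality against a reference value
(the pooled median in the pipeline), and Spearman rank correlation among
soil, cap and stem concentrations.  All are rank-based, hence invariant
under strictly monotone transforms of the data, and all p-values are
two-sided.

The computational kernels are scipy.stats (``kruskal``, ``wilcoxon``,
``spearmanr``); this module fixes the branch policy (exact vs asymptotic),
tie handling, error contracts and the significance-star labelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateSampleError, DomainError

__all__ = [
    "TestResult",
    "stars_for",
    "kruskal_wallis",
    "wilcoxon_vs_value",
    "spearman",
    "bonferroni",
]

log = logging.getLogger(__name__)

#: Significance thresholds and their star labels, strongest first.
STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: tuple[int, ...]
    stars: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise DomainError(f"p-value out of [0,1]: {self.p_value}")


def stars_for(p: float) -> str:
    """Map a p-value to the conventional star label (ns if p >= 0.05)."""
    for threshold, label in STAR_THRESHOLDS:
        if p < threshold:
            return label
    return "ns"


def _result(statistic: float, p: float, n: tuple[int, ...]) -> TestResult:
    p = float(min(max(p, 0.0), 1.0))
    return TestResult(float(statistic), p, n, stars_for(p))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H test across two or more groups.

    Mid-ranks with tie correction; p from the chi-square approximation with
    k−1 degrees of freedom.  If every observation is identical the statistic
    is 0 and p is 1 (no evidence of any difference).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise DomainError("kruskal_wallis needs at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise DomainError("kruskal_wallis groups must be nonempty")
    if sum(a.size for a in arrays) < 3:
        raise DomainError("kruskal_wallis needs total n >= 3")
    pooled = np.concatenate(arrays)
    sizes = tuple(int(a.size) for a in arrays)
    if np.all(pooled == pooled[0]):
        return _result(0.0, 1.0, sizes)
    res = sps.kruskal(*arrays)
    return _result(res.statistic, res.pvalue, sizes)


def wilcoxon_vs_value(sample: Sequence[float], reference: float) -> TestResult:
    """Two-sided one-sample Wilcoxon signed-rank test against a reference.

    Differences exactly equal to zero are dropped.  The exact null
    distribution is used for n ≤ 25 when the absolute differences are free of
    ties; otherwise the normal approximation with tie and continuity
    correction applies (and the switch is logged).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 1:
        raise DomainError("wilcoxon_vs_value needs at least 1 observation")
    d = x - reference
    d = d[d != 0.0]
    if d.size == 0:
        raise DegenerateSampleError(
            "all observations equal the reference; signed-rank test undefined"
        )
    has_ties = np.unique(np.abs(d)).size < d.size
    if d.size <= 25 and not has_ties:
        method = "exact"
        res = sps.wilcoxon(d, alternative="two-sided", method="exact")
    else:
        if has_ties and d.size <= 25:
            log.info(
                "ties among |differences| (n=%d): using normal approximation", d.size
            )
        method = "approx"
        res = sps.wilcoxon(
            d, alternative="two-sided", method="approx", correction=True
        )
    del method
    return _result(res.statistic, res.pvalue, (int(d.size),))


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with mid-rank ties; p from the t approximation."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise DomainError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 3:
        raise DomainError("spearman needs n >= 3")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise DegenerateSampleError("constant input: rank correlation undefined")
    rho, p = sps.spearmanr(xa, ya)
    if np.isnan(rho):
        raise DegenerateSampleError("rank correlation undefined for this input")
    return _result(rho, p, (int(xa.size),))


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni-adjust a family of p-values (optional; off by default in the pipeline)."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]
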