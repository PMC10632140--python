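"""Small categorical statistics for responder/non-responder comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "responder_fraction",
    "fisher_two_sided_pvalue",
    "fisher_exact_2x2",
    "FisherResult",
]

# Relative tolerance for pmf ties in the two-sided sum, as used by R's
# fisher.test and scipy: tables whose probability exceeds the observed one
# by less than this relative margin still count as "as extreme".
_TIE_EPS = 1e-7


def responder_fraction(n_responders: int, n_total: int) -> float:
    """Fraction of responding cells, e.g. 5 of 43 glioma cells showing EPSCs."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_responders <= n_total:
        raise ValueError("n_responders must be between 0 and n_total")
    return n_responders / n_total


def _validate_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t2 = t.astype(float)
        if np.any(t2 < 0) or np.any(t2 != np.round(t2)):
            raise ValueError("table entries must be non-negative integers")
        t = t2.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all row and column margins must be positive")
    return t


def fisher_two_sided_pvalue(table) -> float:
    """Two-sided Fisher exact p-value by the probability-mass criterion.

    With the margins fixed, the p-value is the total hypergeometric
    probability of all tables whose probability does not exceed the observed
    table's (up to a tiny relative tie margin).  This is the convention of
    R's ``fisher.test`` and ``scipy.stats.fisher_exact``; it differs from
    doubling one tail.
    """
    t = _validate_table(table)
    a = t[0, 0]
    r1, r2 = t.sum(axis=1)
    c1 = t[:, 0].sum()
    n = r1 + r2
    support = np.arange(max(0, c1 - r2), min(c1, r1) + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1 + _TIE_EPS)].sum())
    return min(p, 1.0)


@dataclass
class FisherResult:
    """Two-sided Fisher exact test outcome for a 2x2 table."""

    p_value: float
    odds_ratio: float  # conditional maximum-likelihood estimate


def fisher_exact_2x2(table) -> FisherResult:
    """Two-sided Fisher exact test with the conditional (Fisher) odds ratio.

    The p-value is :func:`fisher_two_sided_pvalue`; the odds ratio is the
    conditional maximum-likelihood estimate under the noncentral
    hypergeometric model (``scipy.stats.contingency.odds_ratio``).
    """
    from scipy.stats.contingency import odds_ratio

    t = _validate_table(table)
    p = fisher_two_sided_pvalue(t)
    orr = odds_ratio(t, kind="conditional")
    return FisherResult(p_value=p, odds_ratio=float(orr.statistic))
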