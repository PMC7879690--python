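"""Exact two-library comparison of tag counts (Audic-Claverie statistic).

Given a contig observed ``x`` times in a reference library of ``N1`` total
mapped reads and ``y`` times in a second library of ``N2`` reads, the
conditional law of ``y`` given ``x`` under the null of equal relative
abundance is

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

which is algebraically a negative-binomial mass with size ``x + 1`` and
success probability ``N1 / (N1 + N2)``.  The mass is evaluated in log-gamma
space; tail probabilities use the regularized incomplete beta function, so
the test stays stable at the library depths (1e5-1e7 reads) and counts
where direct factorials overflow.

The two-sided p-value doubles the smaller tail, capped at 1 — the usual
convention for this test; the direction of change is recorded separately
rather than folded into the p-value.

Multiple testing within one pairwise library comparison is handled by the
Bonferroni correction (``p * m`` capped at 1), which controls the
family-wise error rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betainc, gammaln

from .count_model import CountTable

__all__ = [
    "ACResult",
    "ac_pmf",
    "ac_pvalue",
    "ac_direction",
    "bonferroni",
    "compare_libraries",
]


@dataclass(frozen=True)
class ACResult:
    """One Audic-Claverie comparison for one contig."""

    contig_id: str
    x: int
    y: int
    N1: int
    N2: int
    p_raw: float
    p_adj: float
    direction: str  # up / down / none, sign of y/N2 - x/N1


def _validate_counts(*arrays: np.ndarray) -> None:
    for a in arrays:
        if not np.issubdtype(a.dtype, np.integer):
            if not np.all(np.equal(np.mod(a, 1), 0)):
                raise ValueError("counts must be integers")
        if np.any(a < 0):
            raise ValueError("counts must be nonnegative")


def _validate_totals(*arrays: np.ndarray) -> None:
    for a in arrays:
        if np.any(a < 1):
            raise ValueError("library totals must be >= 1")


def ac_pmf(y, x, N1, N2):
    """Probability of observing ``y`` in library 2 given ``x`` in library 1.

    Computed as ``exp(y log r + lgamma(x+y+1) - lgamma(x+1) - lgamma(y+1)
    - (x+y+1) log(1+r))`` with ``r = N2/N1``; a single exponentiation at
    the end.  Scalar or array arguments broadcast.
    """
    y = np.asarray(y)
    x = np.asarray(x)
    N1 = np.asarray(N1, dtype=float)
    N2 = np.asarray(N2, dtype=float)
    _validate_counts(y, x)
    _validate_totals(N1, N2)
    yf = y.astype(float)
    xf = x.astype(float)
    log_r = np.log(N2) - np.log(N1)
    log_p = (
        yf * log_r
        + gammaln(xf + yf + 1.0)
        - gammaln(xf + 1.0)
        - gammaln(yf + 1.0)
        - (xf + yf + 1.0) * np.logaddexp(0.0, log_r)
    )
    out = np.exp(log_p)
    return out if out.shape else float(out)


def _tails(x, y, N1, N2):
    """Lower tail P(Y <= y | x) and upper tail P(Y >= y | x).

    The conditional law is NB(size = x+1, p = N1/(N1+N2)), whose CDF at k
    is the regularized incomplete beta I_p(x+1, k+1).
    """
    p = N1 / (N1 + N2)
    r = x.astype(float) + 1.0
    p_le = betainc(r, y.astype(float) + 1.0, p)
    # P(Y >= y) = 1 - P(Y <= y-1); betainc needs b > 0, so guard y = 0.
    y_pos = np.maximum(y, 1).astype(float)
    p_ge = np.where(y > 0, 1.0 - betainc(r, y_pos, p), 1.0)
    return p_le, p_ge


def ac_pvalue(x, y, N1, N2):
    """Two-sided exact p-value: ``min(1, 2 * min(P_le, P_ge))``."""
    x = np.asarray(x)
    y = np.asarray(y)
    N1 = np.asarray(N1, dtype=float)
    N2 = np.asarray(N2, dtype=float)
    _validate_counts(x, y)
    _validate_totals(N1, N2)
    p_le, p_ge = _tails(x, y, N1, N2)
    out = np.minimum(1.0, 2.0 * np.minimum(p_le, p_ge))
    return out if out.shape else float(out)


def ac_direction(x, y, N1, N2):
    """Sign of the relative-abundance change: up / down / none."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    diff = y / np.asarray(N2, dtype=float) - x / np.asarray(N1, dtype=float)
    labels = np.where(diff > 0, "up", np.where(diff < 0, "down", "none"))
    return labels if labels.shape else str(labels)


def bonferroni(p_values, m: int | None = None):
    """Bonferroni adjustment: each p becomes ``min(1, p * m)``.

    ``m`` defaults to the number of p-values and may be larger (e.g. the
    full contig family when only a subset is passed); it may not be
    smaller.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if m is None:
        m = n
    if m < n:
        raise ValueError(f"family size m={m} smaller than number of tests {n}")
    out = np.minimum(1.0, p * m)
    return out if out.shape else float(out)


def compare_libraries(
    table: CountTable,
    reference: str,
    other: str,
    m: int | None = None,
) -> pd.DataFrame:
    """Audic-Claverie test of every contig between two libraries.

    Returns a DataFrame indexed by contig with columns x, y, N1, N2,
    p_raw, p_adj, direction.  ``m`` is the Bonferroni family size
    (default: number of contigs in the table).
    """
    x = table.counts[reference].to_numpy()
    y = table.counts[other].to_numpy()
    N1 = int(table.library_totals.at[reference])
    N2 = int(table.library_totals.at[other])
    if len(x) == 0:
        return pd.DataFrame(
            columns=["x", "y", "N1", "N2", "p_raw", "p_adj", "direction"],
            index=pd.Index([], name="contig_id"),
        )
    p_raw = ac_pvalue(x, y, N1, N2)
    p_adj = bonferroni(p_raw, m if m is not None else len(x))
    direction = ac_direction(x, y, N1, N2)
    return pd.DataFrame(
        {
            "x": x,
            "y": y,
            "N1": N1,
            "N2": N2,
            "p_raw": np.atleast_1d(p_raw),
            "p_adj": np.atleast_1d(p_adj),
            "direction": np.atleast_1d(direction),
        },
        index=table.contig_ids.rename("contig_id"),
    )
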