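"""Independent oracles used by the test suite.

Deliberately avoids the code paths under test: tail probabilities come
from direct term-by-term summation of the conditional mass, with the
mass built by a multiplicative recurrence (no log-gamma, no incomplete
beta).
"""

from __future__ import annotations

import math

import numpy as np


def ac_tails_by_summation(x: int, N1: float, N2: float, y_max: int):
    """Lower/upper tails P(Y <= y), P(Y >= y) for y = 0..y_max.

    Terms follow the recurrence p(0) = p^(x+1), p(k) = p(k-1) * q *
    (x+k)/k with p = N1/(N1+N2), q = 1-p, summed (in log space via
    cumsum) far enough that the residual tail is below 1e-15.
    """
    p = N1 / (N1 + N2)
    q = 1.0 - p
    r = x + 1
    mean = r * q / p
    sd = math.sqrt(r * q) / p
    K = int(max(y_max + 10, mean + 60 * sd + 200))
    k = np.arange(1, K + 1)
    log_ratio = np.log(x + k) - np.log(k) + math.log(q)
    log_terms = np.empty(K + 1)
    log_terms[0] = r * math.log(p)
    log_terms[1:] = log_terms[0] + np.cumsum(log_ratio)
    terms = np.exp(log_terms)
    cum = np.cumsum(terms)
    # the low-order terms (k <= y_max) carry only ~y_max accumulation steps
    # and are accurate to ~1e-14; the far tail drifts by ~1e-11 over 5e5
    # log-space steps, which only affects this completeness check
    assert cum[-1] > 1.0 - 1e-9, "summation bound too short"
    p_le = cum[: y_max + 1].copy()
    p_ge = 1.0 - np.concatenate([[0.0], cum[:y_max]])
    return p_le, p_ge


def ac_pvalue_by_summation(x: int, y: int, N1: float, N2: float) -> float:
    """Two-sided p-value by direct summation (min(1, 2 * smaller tail))."""
    p_le, p_ge = ac_tails_by_summation(x, N1, N2, y)
    return min(1.0, 2.0 * min(p_le[y], p_ge[y]))


def nb_pmf_exact(x: int, N1: int, N2: int, y_max: int) -> np.ndarray:
    """Negative-binomial mass NB(x+1, N1/(N1+N2)) at y = 0..y_max,
    evaluated in exact integer arithmetic and rounded once to float.

    p(y) = C(x+y, y) * N1^(x+1) * N2^y / (N1+N2)^(x+y+1); the recurrence
    multiplies by (x+y)*N2 and divides by y (exact, the binomial stays
    integral) so every value is correct to 0.5 ulp.
    """
    from fractions import Fraction

    N1, N2 = int(N1), int(N2)
    num = N1 ** (x + 1)
    den = (N1 + N2) ** (x + 1)
    out = [float(Fraction(num, den))]
    for y in range(1, y_max + 1):
        num = num * (x + y) * N2 // y
        den *= N1 + N2
        out.append(float(Fraction(num, den)))
    return np.array(out)
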