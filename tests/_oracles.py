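"""Independent brute-force oracles used by the test suite.

Each oracle is a deliberately simple re-implementation kept separate
from the library code paths it checks: Fisher's exact test by direct
hypergeometric enumeration, the filtering allele frequency by bisection
on the Poisson survival function, and the evidence-combination table as
a literal transcription of its rows.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating all tables with fixed margins.

    Sums the probabilities of every table whose hypergeometric
    probability does not exceed the observed table's (with the
    conventional (1 + 1e-7) relative slack for floating-point ties).
    """
    from scipy.special import gammaln

    n1, n2, k = a + b, c + d, a + c
    n = n1 + n2
    xs = np.arange(max(0, k - n2), min(k, n1) + 1)

    def logc(nn: int, kk: np.ndarray) -> np.ndarray:
        return gammaln(nn + 1) - gammaln(kk + 1.0) - gammaln(nn - kk + 1.0)

    logpmf = logc(n1, xs) + logc(n2, k - xs) - float(logc(n, np.array([k]))[0])
    pmf = np.exp(logpmf)
    observed = pmf[xs == a][0]
    return float(pmf[pmf <= observed * (1 + 1e-7)].sum())


def fisher_oracle_group(n1: int, n2: int, k: int) -> dict[int, float]:
    """Two-sided Fisher p for every table with margins (n1, n2, k).

    Same enumeration as :func:`fisher_oracle`, computed once per margin
    group: returns {a: p} over the support of the case-carrier count.
    """
    from scipy.special import gammaln

    n = n1 + n2
    xs = np.arange(max(0, k - n2), min(k, n1) + 1)

    def logc(nn: int, kk: np.ndarray) -> np.ndarray:
        return gammaln(nn + 1) - gammaln(kk + 1.0) - gammaln(nn - kk + 1.0)

    pmf = np.exp(logc(n1, xs) + logc(n2, k - xs) - float(logc(n, np.array([k]))[0]))
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    csum = np.cumsum(sorted_pmf)
    out: dict[int, float] = {}
    for i, a in enumerate(xs):
        idx = np.searchsorted(sorted_pmf, pmf[i] * (1 + 1e-7), side="right")
        out[int(a)] = float(csum[idx - 1])
    return out


def faf_bisection_oracle(ac: int, an: int, confidence: float = 0.95) -> float:
    """Filtering AF by bisection on P(Poisson(p*AN) >= AC) = 1 - confidence."""
    if ac == 0:
        return 0.0
    alpha = 1.0 - confidence
    lo, hi = 0.0, ac / an
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if stats.poisson.sf(ac - 1, mid * an) >= alpha:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


#: benign < likely benign < uncertain < likely pathogenic < pathogenic
TIER_INDEX = {
    "benign": 0,
    "likely benign": 1,
    "uncertain significance": 2,
    "likely pathogenic": 3,
    "pathogenic": 4,
}


def combine_oracle(met: list[tuple[str, str, str]]) -> str:
    """Literal transcription of the combining table.

    ``met`` holds (code, direction, strength) triples of met rules.
    """
    sa = sum(1 for _, d, s in met if d == "benign" and s == "standalone")
    bs = sum(1 for _, d, s in met if d == "benign" and s == "strong")
    bp = sum(1 for _, d, s in met if d == "benign" and s == "supporting")
    vs = sum(1 for _, d, s in met if d == "pathogenic" and s == "very-strong")
    st = sum(1 for _, d, s in met if d == "pathogenic" and s == "strong")
    mo = sum(1 for _, d, s in met if d == "pathogenic" and s == "moderate")
    su = sum(1 for _, d, s in met if d == "pathogenic" and s == "supporting")
    n_path = vs + st + mo + su
    n_benign = sa + bs + bp

    if sa:
        return "benign"
    if n_path and n_benign:
        return "uncertain significance"
    if n_benign:
        if bs >= 2:
            return "benign"
        if (bs >= 1 and bp >= 1) or bp >= 2:
            return "likely benign"
        if n_benign == 1 and any(code == "BS1" for code, _, _ in met):
            return "likely benign"
        return "uncertain significance"
    pathogenic = (
        (vs >= 1 and (st >= 1 or mo >= 2 or (mo == 1 and su == 1) or su >= 2))
        or st >= 2
        or (st >= 1 and (mo >= 3 or (mo >= 2 and su >= 2) or (mo >= 1 and su >= 4)))
    )
    if pathogenic:
        return "pathogenic"
    likely = (
        (vs >= 1 and mo >= 1)
        or (st >= 1 and (mo >= 1 or su >= 2))
        or mo >= 3
        or (mo >= 2 and su >= 2)
        or (mo >= 1 and su >= 4)
    )
    if likely:
        return "likely pathogenic"
    return "uncertain significance"
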