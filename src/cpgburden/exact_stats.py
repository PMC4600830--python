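"""Exact 2x2 association statistics and Mantel-Haenszel stratified combination.

Conventions follow the standard exact-test implementation (R's
``fisher.test`` / ``mantelhaen.test``):

* two-sided p-value by the minimum-likelihood rule — the sum of all
  hypergeometric point probabilities not exceeding that of the observed
  table (with a small relative tolerance for ties);
* odds ratio as the conditional MLE of the Fisher noncentral
  hypergeometric likelihood, solving ``E[a | psi] = a`` by monotone
  bisection on ``log psi``;
* exact confidence bounds by inverting one-sided tail tests at
  ``(1 - level)/2`` per tail, with 0 / +inf bounds when the observed
  count sits on the edge of its support;
* Mantel-Haenszel common odds ratio with Robins-Breslow-Greenland
  variance on the log scale, and the continuity-corrected MH chi-square
  score test.

Point probabilities are accumulated through log-factorials so tables with
~1e5 alleles stay exact (required by the power search).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import chi2, norm

from .errors import ConfigurationError, DataIntegrityError

_REL_TIE = 1.0 + 1e-7  # tie tolerance on point probabilities, as in R
_LOG_TOL = 1e-8  # bisection tolerance on log psi


def _cells(table) -> tuple[int, int, int, int]:
    """Accept a StratumTable, a flat (a, b, c, d) or a nested 2x2."""
    if hasattr(table, "a"):
        cells = (table.a, table.b, table.c, table.d)
    else:
        rows = list(table)
        if len(rows) == 2:
            cells = (*rows[0], *rows[1])
        else:
            cells = tuple(rows)
    a, b, c, d = (int(x) for x in cells)
    if min(a, b, c, d) < 0:
        raise DataIntegrityError(f"negative cell in 2x2 table {cells}")
    return a, b, c, d


def _logsumexp(values: Sequence[float]) -> float:
    m = max(values)
    if m == -math.inf:
        return m
    return m + math.log(sum(math.exp(v - m) for v in values))


def _lchoose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _support(a: int, b: int, c: int, d: int) -> tuple[int, list[float]]:
    """Support of the conditioned count and its log-weights at psi = 1."""
    m1, m2, k = a + b, c + d, a + c
    lo, hi = max(0, k - m2), min(k, m1)
    logw = [_lchoose(m1, x) + _lchoose(m2, k - x) for x in range(lo, hi + 1)]
    return lo, logw


def _probs(logw: Sequence[float], log_psi: float) -> list[float]:
    shifted = [w + x * log_psi for x, w in enumerate(logw)]
    tot = _logsumexp(shifted)
    return [math.exp(v - tot) for v in shifted]


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p-value (minimum-likelihood rule)."""
    a, b, c, d = _cells(table)
    lo, logw = _support(a, b, c, d)
    if len(logw) == 1:
        return 1.0
    probs = _probs(logw, 0.0)
    p_obs = probs[a - lo]
    return min(1.0, sum(p for p in probs if p <= p_obs * _REL_TIE))


def _cond_mean(lo: int, logw: Sequence[float], log_psi: float) -> float:
    probs = _probs(logw, log_psi)
    return sum((lo + x) * p for x, p in enumerate(probs))


def _bisect(f, lo: float, hi: float, tol: float = _LOG_TOL) -> float:
    """Root of a monotone-increasing f on [lo, hi] by plain bisection."""
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:  # pragma: no cover - brackets are pre-expanded
        raise ArithmeticError("root not bracketed")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _expand_bracket(f) -> tuple[float, float]:
    """Find [lo, hi] with f(lo) <= 0 <= f(hi) for monotone-increasing f."""
    lo, hi = -1.0, 1.0
    for _ in range(80):
        if f(lo) <= 0:
            break
        lo *= 2
    for _ in range(80):
        if f(hi) >= 0:
            break
        hi *= 2
    return lo, hi


def conditional_mle_or(table) -> float:
    """Conditional-MLE odds ratio; +inf / 0 on support edges, NaN if degenerate."""
    a, b, c, d = _cells(table)
    lo, logw = _support(a, b, c, d)
    hi = lo + len(logw) - 1
    if lo == hi:
        return math.nan  # margins admit a single table: psi unidentifiable
    if a == hi:
        return math.inf
    if a == lo:
        return 0.0

    def f(log_psi: float) -> float:
        return _cond_mean(lo, logw, log_psi) - a

    return math.exp(_bisect(f, *_expand_bracket(f)))


def _tail_le(lo: int, logw: Sequence[float], a: int, log_psi: float) -> float:
    probs = _probs(logw, log_psi)
    return sum(probs[: a - lo + 1])


def exact_ci(table, level: float = 0.95) -> tuple[float, float]:
    """Exact confidence interval for the odds ratio by tail inversion.

    Each bound is solved at ``(1 - level)/2``; when the observed count sits
    on the lower (upper) edge of its support the corresponding bound is 0
    (+inf), making the interval one-sided as standard implementations do.
    """
    if not 0 < level < 1:
        raise ConfigurationError(f"confidence level {level} outside (0, 1)")
    a, b, c, d = _cells(table)
    lo, logw = _support(a, b, c, d)
    hi = lo + len(logw) - 1
    alpha = (1.0 - level) / 2.0

    if a == hi:
        upper = math.inf
    else:
        # P(X <= a | psi) decreases in psi; find psi with tail = alpha
        def f_up(log_psi: float) -> float:
            return alpha - _tail_le(lo, logw, a, log_psi)

        upper = math.exp(_bisect(f_up, *_expand_bracket(f_up)))

    if a == lo:
        lower = 0.0
    else:
        # P(X >= a | psi) increases in psi; find psi with tail = alpha
        def f_lo(log_psi: float) -> float:
            return (1.0 - _tail_le(lo, logw, a - 1, log_psi)) - alpha

        lower = math.exp(_bisect(f_lo, *_expand_bracket(f_lo)))

    return lower, upper


@dataclass(frozen=True)
class ExactTestResult:
    """Exact test summary for one 2x2 allele-count table."""

    p_two_sided: float
    or_cmle: float
    ci95: tuple[float, float]
    or_sample: float  # raw cross-product ratio a*d / (b*c), for transparency

    def __post_init__(self) -> None:
        lower, upper = self.ci95
        if not (math.isnan(self.or_cmle) or lower <= self.or_cmle <= upper):
            raise ArithmeticError("conditional MLE outside its confidence interval")


def exact_test(table, level: float = 0.95) -> ExactTestResult:
    """Bundle p-value, conditional-MLE OR, exact CI and sample OR."""
    a, b, c, d = _cells(table)
    if b * c == 0:
        or_sample = math.inf if a * d > 0 else math.nan
    else:
        or_sample = (a * d) / (b * c)
    return ExactTestResult(
        p_two_sided=fisher_two_sided(table),
        or_cmle=conditional_mle_or(table),
        ci95=exact_ci(table, level),
        or_sample=or_sample,
    )


# -- stratified combination ---------------------------------------------


@dataclass(frozen=True)
class MHResult:
    """Mantel-Haenszel combined estimate and score test over k strata."""

    or_mh: float
    ci95: tuple[float, float]
    chi_sq: float
    p: float
    k: int


def mantel_haenszel_or(tables: Iterable, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """MH common odds ratio with Robins-Breslow-Greenland interval."""
    cells = [_cells(t) for t in tables]
    if not cells:
        raise ConfigurationError("need at least one stratum")
    R = S = 0.0
    sum_pr = sum_psqr = sum_qs = 0.0
    for a, b, c, d in cells:
        n = a + b + c + d
        if n == 0:
            continue
        r_i, s_i = a * d / n, b * c / n
        p_i, q_i = (a + d) / n, (b + c) / n
        R += r_i
        S += s_i
        sum_pr += p_i * r_i
        sum_psqr += p_i * s_i + q_i * r_i
        sum_qs += q_i * s_i
    if S == 0.0:
        return math.inf, (math.nan, math.inf)
    if R == 0.0:
        return 0.0, (0.0, math.nan)
    or_mh = R / S
    var_log = sum_pr / (2 * R * R) + sum_psqr / (2 * R * S) + sum_qs / (2 * S * S)
    z = norm.ppf(1 - (1 - level) / 2)
    half = z * math.sqrt(var_log)
    return or_mh, (or_mh * math.exp(-half), or_mh * math.exp(half))


def mantel_haenszel_test(tables: Iterable, continuity: bool = True) -> tuple[float, float]:
    """Continuity-corrected MH chi-square score test (1 df)."""
    cells = [_cells(t) for t in tables]
    if not cells:
        raise ConfigurationError("need at least one stratum")
    sum_a = sum_e = sum_v = 0.0
    for a, b, c, d in cells:
        n = a + b + c + d
        if n < 2:
            continue
        m1, m2, k1, k2 = a + b, c + d, a + c, b + d
        sum_a += a
        sum_e += m1 * k1 / n
        sum_v += m1 * m2 * k1 * k2 / (n * n * (n - 1))
    if sum_v == 0.0:
        raise ConfigurationError("degenerate strata: zero conditional variance")
    diff = abs(sum_a - sum_e) - (0.5 if continuity else 0.0)
    chi_sq = max(diff, 0.0) ** 2 / sum_v
    return chi_sq, float(chi2.sf(chi_sq, 1))


def mantel_haenszel(tables: Sequence, level: float = 0.95, continuity: bool = True) -> MHResult:
    """Combined MH estimate, RBG interval and score test for k strata."""
    tables = list(tables)
    or_mh, ci = mantel_haenszel_or(tables, level=level)
    chi_sq, p = mantel_haenszel_test(tables, continuity=continuity)
    return MHResult(or_mh=or_mh, ci95=ci, chi_sq=chi_sq, p=p, k=len(tables))


def bonferroni(alpha_family: float, m: int) -> float:
    """Per-test significance level controlling the family-wise error."""
    if m < 1:
        raise ConfigurationError(f"number of tests m = {m} must be >= 1")
    if not 0 < alpha_family < 1:
        raise ConfigurationError(f"family alpha {alpha_family} outside (0, 1)")
    return alpha_family / m
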