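"""Rare-allele power search: control alleles needed to reach significance.

Answers the question a targeted-screening study faces when a candidate
variant is seen in cases but the available control panel is too small:
holding the observed case table and the control CARRIER count fixed, how
many control alleles would have to be genotyped before the two-sided
Fisher exact test becomes significant?  The control carrier count is held
fixed (not the control frequency) while the denominator grows, which is
the regime where significance is reachable for a case-only observation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .cohorts import StratumTable
from .errors import ConfigurationError, UnreachableSignificanceError
from .exact_stats import fisher_two_sided

_N_CAP = 1 << 34  # search ceiling on control alleles
_TIE_SLACK = 1 + 1e-9  # absorbs log-factorial rounding when p == alpha exactly


@dataclass(frozen=True)
class PowerQuery:
    """Fixed case table, fixed control carrier count, target alpha."""

    case_carrier_alleles: int
    case_total_alleles: int
    control_carrier_alleles: int
    alpha: float

    def __post_init__(self) -> None:
        if not 0 <= self.case_carrier_alleles <= self.case_total_alleles:
            raise ConfigurationError("case carriers must lie in 0..case_total_alleles")
        if self.case_total_alleles < 1 or self.control_carrier_alleles < 0:
            raise ConfigurationError("allele counts must be positive/non-negative")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha {self.alpha} outside (0, 1)")


def _p_at(query: PowerQuery, n_control: int) -> float:
    return fisher_two_sided(
        StratumTable(
            a=query.case_carrier_alleles,
            b=query.case_total_alleles - query.case_carrier_alleles,
            c=query.control_carrier_alleles,
            d=n_control - query.control_carrier_alleles,
        )
    )


def _significant(query: PowerQuery, n_control: int) -> bool:
    # a table whose exact p equals alpha as a rational number is significant;
    # the slack keeps float rounding from flipping that boundary case
    return _p_at(query, n_control) <= query.alpha * _TIE_SLACK


def min_control_alleles(query: PowerQuery) -> int:
    """Smallest control-allele total making the exact test significant.

    Searches by doubling then binary refinement; the p-value is
    non-increasing in the control total in the searched regime, and
    minimality is verified directly at the returned value.
    """
    if query.case_carrier_alleles == 0:
        raise UnreachableSignificanceError(
            "zero case carrier alleles: no control cohort size can reach significance"
        )
    # Regime floor: the smallest control total at which the control carrier
    # frequency does not exceed the case frequency.  Below it a small p-value
    # would signal control enrichment, the opposite of the question asked.
    floor = max(1, query.control_carrier_alleles + 1)
    if query.control_carrier_alleles > 0:
        floor = max(
            floor,
            math.ceil(
                query.control_carrier_alleles
                * query.case_total_alleles
                / query.case_carrier_alleles
            ),
        )
    if _significant(query, floor):
        return floor
    lo = n = floor
    while not _significant(query, n):
        if n >= _N_CAP:
            raise UnreachableSignificanceError(
                f"no significant configuration below {_N_CAP} control alleles"
            )
        lo, n = n, n * 2
    hi = n  # p(hi) <= alpha < p(lo)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _significant(query, mid):
            hi = mid
        else:
            lo = mid
    # local monotonicity guard: walk back over any flat stretch
    while hi - 1 >= floor and _significant(query, hi - 1):
        hi -= 1
    return hi


def closed_form_zero_controls(case_total_alleles: int, alpha: float) -> int:
    """Exact minimum for one case carrier allele and zero control carriers.

    With one variant allele total, the support has two tables and the
    two-sided p collapses to ``case_total / (case_total + N)``, giving
    ``N = ceil(case_total / alpha) - case_total``.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha {alpha} outside (0, 1)")
    return math.ceil(case_total_alleles / alpha) - case_total_alleles


def round_to_sig_figures(n: int, figures: int = 2) -> int:
    """Presentation rounding (e.g. 50284 -> 50000 at 2 significant figures)."""
    if n == 0:
        return 0
    exponent = int(math.floor(math.log10(abs(n)))) - figures + 1
    scale = 10 ** exponent
    return int(round(n / scale)) * scale
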