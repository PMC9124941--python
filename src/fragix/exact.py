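"""Exact conditional inference for 2x2 contingency tables.

A two-arm trial with a dichotomous outcome is summarised by a 2x2 table of
events/non-events per arm.  Conditioning on both margins, the event count in
the intervention arm follows a hypergeometric distribution under the null of
no association; the two-sided Fisher exact p-value sums the probabilities of
all margin-preserving tables no more probable than the observed one (the
minimum-likelihood rule used by mainstream exact-test implementations).

All point probabilities are accumulated in exact integer arithmetic (big-int
binomial-coefficient numerators over the common denominator C(N, n)) and
converted to a correctly-rounded float only at the end.  Fragility-index
iteration hinges on exact behaviour at the significance boundary — e.g. the
table (0, 2; 12, 2) has p = 6/120 = 0.05 exactly, which a log-factorial
floating-point accumulation misclassifies as significant — and integer
arithmetic also makes point-probability ties exact, so no tie tolerance is
needed in the two-sided sum.  No normal or chi-square approximation is ever
used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import NamedTuple

import numpy as np

__all__ = [
    "ContingencyTable",
    "PValue",
    "hypergeom_pmf",
    "fisher_exact_two_sided",
]


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 events/non-events table for a two-arm trial.

    Cell layout::

                        event        non-event
        intervention    events_intervention  nonevents_intervention
        control         events_control       nonevents_control

    All cells are non-negative integers and each arm must contain at least
    one randomized participant.
    """

    events_intervention: int
    nonevents_intervention: int
    events_control: int
    nonevents_control: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool) or not isinstance(v, (int, np.integer)):
                raise TypeError(f"{f.name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")
            object.__setattr__(self, f.name, int(v))
        if self.n_intervention < 1 or self.n_control < 1:
            raise ValueError("each arm must contain at least one participant")

    @property
    def n_intervention(self) -> int:
        return self.events_intervention + self.nonevents_intervention

    @property
    def n_control(self) -> int:
        return self.events_control + self.nonevents_control

    @property
    def n_total(self) -> int:
        return self.n_intervention + self.n_control

    @property
    def total_events(self) -> int:
        return self.events_intervention + self.events_control

    @property
    def total_nonevents(self) -> int:
        return self.nonevents_intervention + self.nonevents_control

    def cells(self) -> tuple[int, int, int, int]:
        return (
            self.events_intervention,
            self.nonevents_intervention,
            self.events_control,
            self.nonevents_control,
        )

    def with_events_moved(self, arm: str, k: int) -> "ContingencyTable":
        """Return the table with ``k`` non-events of ``arm`` reclassified as
        events.  Arm sizes and the total sample size are preserved."""
        if arm == "intervention":
            if k > self.nonevents_intervention:
                raise ValueError("not enough non-events in the intervention arm")
            return ContingencyTable(
                self.events_intervention + k,
                self.nonevents_intervention - k,
                self.events_control,
                self.nonevents_control,
            )
        if arm == "control":
            if k > self.nonevents_control:
                raise ValueError("not enough non-events in the control arm")
            return ContingencyTable(
                self.events_intervention,
                self.nonevents_intervention,
                self.events_control + k,
                self.nonevents_control - k,
            )
        raise ValueError(f"arm must be 'intervention' or 'control', got {arm!r}")


class PValue(NamedTuple):
    """A p-value together with the method that produced it."""

    value: float
    method: str = "fisher_exact_two_sided"


def _support_numerators(N: int, K: int, n: int) -> tuple[int, list[int]]:
    """Integer pmf numerators C(K, x)·C(N−K, n−x) over the support of
    Hypergeometric(N, K, n); returns (support_min, numerators).

    Built by the exact recurrence
    ``num(x+1) = num(x)·(K−x)(n−x) / ((x+1)(N−K−n+x+1))`` (the division is
    always exact), avoiding one binomial evaluation per support point.
    """
    lo = max(0, n + K - N)
    hi = min(n, K)
    nums = [math.comb(K, lo) * math.comb(N - K, n - lo)]
    for x in range(lo, hi):
        nums.append(nums[-1] * (K - x) * (n - x) // ((x + 1) * (N - K - n + x + 1)))
    return lo, nums


def hypergeom_pmf(x: int, N: int, K: int, n: int) -> float:
    """P(X = x) where X counts marked items in a size-``n`` draw without
    replacement from ``N`` items of which ``K`` are marked.

    Parameters mirror the conditional null of the 2x2 table: ``N`` total
    participants, ``K`` total events, ``n`` intervention-arm size, ``x``
    intervention-arm events.

    Raises ``ValueError`` when the parameters are inconsistent or ``x`` lies
    outside the support ``[max(0, n+K-N), min(n, K)]``.
    """
    if not (0 <= K <= N):
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not (1 <= n <= N):
        raise ValueError(f"require 1 <= n <= N, got n={n}, N={N}")
    if not (max(0, n + K - N) <= x <= min(n, K)):
        raise ValueError(f"x={x} outside support for N={N}, K={K}, n={n}")
    return (math.comb(K, x) * math.comb(N - K, n - x)) / math.comb(N, n)


def _fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for cells (a, b; c, d); fast internal path.

    Exact integer accumulation; the single float division at the end is
    correctly rounded, so comparisons against a significance threshold are
    exact up to half an ulp of the true rational p-value.
    """
    N = a + b + c + d
    K = a + c
    n = a + b
    lo, nums = _support_numerators(N, K, n)
    obs = nums[a - lo]
    return sum(v for v in nums if v <= obs) / math.comb(N, n)


def fisher_exact_two_sided(table: ContingencyTable) -> PValue:
    """Two-sided Fisher exact test of association in a 2x2 table.

    Uses the minimum-likelihood rule: the p-value is the sum of
    hypergeometric probabilities of every table with the observed margins
    whose point probability does not exceed that of the observed table.
    Point probabilities are compared as exact integers, so ties enter the
    two-sided sum exactly.  When either outcome margin is degenerate the
    conditional distribution is a point mass and p = 1.
    """
    return PValue(_fisher_p(*table.cells()))
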