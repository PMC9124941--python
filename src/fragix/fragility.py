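"""Fragility index and fragility quotient for significant 2x2 trial results.

The fragility index (FI) of a statistically significant dichotomous result is
the minimum number of participants in one arm whose outcome must be
reclassified from non-event to event — keeping arm sizes constant — for the
two-sided Fisher exact p-value to reach the significance threshold (p >= alpha).
The iteration always modifies the arm that had the smaller event count in the
original table; when the two arms tie, both directions are evaluated and the
smaller index wins.  The fragility quotient (FQ) normalises FI by the trial's
total randomized sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exact import ContingencyTable, _fisher_p

__all__ = [
    "FragilityResult",
    "fragility_index",
    "fragility_quotient",
    "nplfu_exceeds_fi",
]

ARM_INTERVENTION = "intervention"
ARM_CONTROL = "control"
ARM_NONE = "none"


@dataclass(frozen=True)
class FragilityResult:
    """Outcome of the fragility-index iteration on one 2x2 table.

    Attributes
    ----------
    fi : int
        Fragility index: smallest number of non-event -> event moves after
        which p >= alpha.  0 when the table is already non-significant.  When
        ``exhausted`` is true, the number of non-events consumed before the
        modifiable arm ran out.
    fq : float
        Fragility quotient, ``fi / n_total``.
    p_initial : float
        Two-sided Fisher exact p of the unmodified table.
    p_terminal : float
        p after the ``fi``-th modification (equal to ``p_initial`` when
        ``fi == 0``).
    modified_arm : str
        ``"intervention"``, ``"control"``, or ``"none"`` when no modification
        was needed.
    exhausted : bool
        True when the modifiable arm ran out of non-events while the result
        was still significant; such results carry no meaningful FI and are
        excluded from cohort summaries.
    """

    fi: int
    fq: float
    p_initial: float
    p_terminal: float
    modified_arm: str
    exhausted: bool


def _scan_arm(table: ContingencyTable, arm: str, alpha: float, p0: float):
    """Add events to ``arm`` one at a time until p >= alpha or the arm has no
    non-events left.  Returns (k, p_terminal, exhausted)."""
    n_avail = (
        table.nonevents_intervention
        if arm == ARM_INTERVENTION
        else table.nonevents_control
    )
    p_last = p0
    for k in range(1, n_avail + 1):
        p_last = _fisher_p(*table.with_events_moved(arm, k).cells())
        if p_last >= alpha:
            return k, p_last, False
    return n_avail, p_last, True


def fragility_index(
    table: ContingencyTable, alpha: float = 0.05
) -> FragilityResult:
    """Compute the fragility index of a 2x2 table at level ``alpha``.

    Events are added (and non-events simultaneously removed, so arm sizes and
    the total sample size never change) to the arm with the smaller event
    count in the *original* table; the arm choice is frozen for the whole
    iteration.  If the original event counts are equal, both arms are scanned
    and the smaller index is returned.

    Raises ``ValueError`` for ``alpha`` outside (0, 1).  A table that is
    already non-significant (p_initial >= alpha) has fi = 0 and
    ``modified_arm == "none"``.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(*table)
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")

    p0 = _fisher_p(*table.cells())
    n_total = table.n_total
    if p0 >= alpha:
        return FragilityResult(0, 0.0, p0, p0, ARM_NONE, False)

    if table.events_intervention < table.events_control:
        arms = [ARM_INTERVENTION]
    elif table.events_intervention > table.events_control:
        arms = [ARM_CONTROL]
    else:
        arms = [ARM_INTERVENTION, ARM_CONTROL]

    best = None
    for arm in arms:
        k, p_term, exhausted = _scan_arm(table, arm, alpha, p0)
        cand = (exhausted, k, arm, p_term)
        if best is None or cand[:2] < best[:2]:
            best = cand
    exhausted, fi, arm, p_term = best
    return FragilityResult(
        fi, fragility_quotient(fi, n_total), p0, p_term, arm, exhausted
    )


def fragility_quotient(fi: int, n_total: int) -> float:
    """FI divided by the trial's total randomized sample size."""
    if n_total < 1:
        raise ValueError(f"n_total must be >= 1, got {n_total}")
    if not (0 <= fi <= n_total):
        raise ValueError(f"fi must be in [0, n_total], got fi={fi}")
    return fi / n_total


def nplfu_exceeds_fi(n_lost: int, fi: int) -> bool:
    """True when the number of patients lost to follow-up strictly exceeds
    the fragility index — i.e. unobserved outcomes alone could overturn the
    trial's significance."""
    if n_lost < 0 or fi < 0:
        raise ValueError("counts must be non-negative")
    return n_lost > fi
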