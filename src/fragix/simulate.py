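"""Seeded generator of synthetic two-arm RCT corpora.

The generator emulates the population a fragility review samples from: 1:1
two-arm trials with a dichotomous endpoint that *reported a statistically
significant result* (the inclusion filter).  Each trial draws a shared arm
size (log-normal, rounded, floor 5), a control-arm event risk and a
multiplicative risk ratio for the intervention arm; event counts are binomial
per arm, and the trial is redrawn until the two-sided Fisher exact p-value is
below the significance level — mirroring how only significant results enter
the corpus.  Loss to follow-up is binomial over the randomized total, and
publication metadata (year, journal, design flags) is drawn categorically.

Default distribution parameters reflect a published cohort of 66 preterm-
neonate RCTs: median total sample size ~150 with IQR ~80-370, neonatal
endpoint risks in the 10-60% range, protective interventions (risk ratio
0.3-0.9), and Table-1 proportions for journals and design flags.

Reproducibility: trial ``i`` uses an independent PRNG substream keyed by
``(seed, i)``, so changing the corpus size never reshuffles earlier trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .corpus import CorpusTable, TrialRecord
from .exact import _fisher_p

__all__ = ["SimulationConfig", "SimulationError", "simulate_trial", "simulate_corpus"]

#: Minimum per-arm size after rounding the log-normal draw.
MIN_ARM_SIZE = 5

#: Categorical probabilities for design flags (yes, no, unsure); the yes
#: shares follow the reference cohort's Table-1 proportions.
P_MULTICENTER = (0.561, 0.300, 0.139)
P_DOUBLE_BLINDED = (0.333, 0.520, 0.147)
P_REGISTERED = (0.455, 0.400, 0.145)
P_ITT_YES = 0.591
P_PRIMARY_OUTCOME = 0.621

_JOURNAL_NAMES = {
    "NEJM": "New England Journal of Medicine",
    "J_Pediatrics": "Journal of Pediatrics",
    "Neonatology": "Neonatology",
    "Pediatrics": "Pediatrics",
    "JAMA": "JAMA",
    "Other": "Other Journal",
}


class SimulationError(RuntimeError):
    """Raised when a config cannot produce a significant trial within the
    rejection budget (effect too weak to ever pass the inclusion filter)."""


def _default_journal_weights() -> dict[str, float]:
    return {
        "NEJM": 0.182,
        "J_Pediatrics": 0.106,
        "Neonatology": 0.106,
        "Pediatrics": 0.106,
        "JAMA": 0.045,
        "Other": 0.455,
    }


@dataclass
class SimulationConfig:
    """Distributions governing the synthetic corpus generator.

    Parameters
    ----------
    seed : int
        Root seed (non-negative); every trial derives its own substream.
    n_trials : int
        Number of accepted (significant) trials to generate.
    arm_size_log_mean, arm_size_log_sd : float
        Per-arm size is ``round(LogNormal(mu, sd))`` with floor
        :data:`MIN_ARM_SIZE`; both arms share the draw (1:1 design).
    control_risk_range : (float, float)
        Uniform range of the control-arm event probability.
    risk_ratio_range : (float, float)
        Uniform range of the multiplicative effect applied to the
        intervention arm (intervention risk capped at 1).
    ltfu_rate_range : (float, float)
        Uniform range of the per-participant loss-to-follow-up probability.
    alpha : float
        Significance level of the inclusion filter.
    journal_weights : dict
        Sampling weights over the six journal groups (must sum to 1).
    year_range : (int, int)
        Inclusive publication-year range (uniform).
    max_rejection_draws : int
        Per-trial budget of redraws before :class:`SimulationError`.
    reported_test : str
        ``"fisher_exact"`` filters (and reports) the exact p; guarantees
        FI >= 1 for every accepted trial.  ``"chi_square"`` filters on an
        uncorrected chi-square p instead, which — as in real corpora, where
        the trial's own test can disagree with the exact test — lets FI = 0
        trials through.
    """

    seed: int
    n_trials: int = 66
    arm_size_log_mean: float = math.log(74.75)
    arm_size_log_sd: float = 1.10
    control_risk_range: tuple[float, float] = (0.10, 0.60)
    risk_ratio_range: tuple[float, float] = (0.30, 0.90)
    ltfu_rate_range: tuple[float, float] = (0.0, 0.10)
    alpha: float = 0.05
    journal_weights: dict[str, float] = field(default_factory=_default_journal_weights)
    year_range: tuple[int, int] = (1990, 2021)
    max_rejection_draws: int = 1000
    reported_test: str = "fisher_exact"

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise TypeError("seed must be an integer")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        for name in ("control_risk_range", "ltfu_rate_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must be an ordered range within [0, 1]")
        lo, hi = self.risk_ratio_range
        if not (0.0 <= lo <= hi):
            raise ValueError("risk_ratio_range must be an ordered non-negative range")
        y0, y1 = self.year_range
        if not (1900 <= y0 <= y1 <= 2100):
            raise ValueError("year_range must be ordered within [1900, 2100]")
        if self.max_rejection_draws < 1:
            raise ValueError("max_rejection_draws must be >= 1")
        if self.reported_test not in ("fisher_exact", "chi_square"):
            raise ValueError("reported_test must be 'fisher_exact' or 'chi_square'")
        missing = set(_JOURNAL_NAMES) - set(self.journal_weights)
        if missing:
            raise ValueError(f"journal_weights missing groups: {sorted(missing)}")
        total = sum(self.journal_weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"journal_weights must sum to 1, got {total}")


def _chi_square_p(a: int, b: int, c: int, d: int) -> float:
    """Uncorrected Pearson chi-square p; 1.0 on degenerate margins."""
    from scipy import stats

    if (a + c) == 0 or (b + d) == 0:
        return 1.0
    res = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    return float(res.pvalue)


def _trial_rng(seed: int, trial_index: int) -> np.random.Generator:
    return np.random.default_rng([seed, trial_index])


def simulate_trial(config: SimulationConfig, trial_index: int) -> TrialRecord:
    """Draw one synthetic trial that passes the significance inclusion filter.

    Redraws arm size, risks and event counts until the filtering p-value is
    below ``config.alpha``; raises :class:`SimulationError` when
    ``max_rejection_draws`` is exceeded.
    """
    rng = _trial_rng(config.seed, trial_index)
    p_filter = _chi_square_p if config.reported_test == "chi_square" else _fisher_p

    accepted = None
    for _ in range(config.max_rejection_draws):
        n = max(MIN_ARM_SIZE, int(round(rng.lognormal(
            config.arm_size_log_mean, config.arm_size_log_sd))))
        p0 = rng.uniform(*config.control_risk_range)
        rr = rng.uniform(*config.risk_ratio_range)
        p1 = min(1.0, rr * p0)
        events_ctl = int(rng.binomial(n, p0))
        events_int = int(rng.binomial(n, p1))
        p = p_filter(events_int, n - events_int, events_ctl, n - events_ctl)
        if p < config.alpha:
            accepted = (n, events_int, events_ctl, p)
            break
    if accepted is None:
        raise SimulationError(
            f"no significant trial within {config.max_rejection_draws} draws "
            f"(risk_ratio_range={config.risk_ratio_range}, "
            f"control_risk_range={config.control_risk_range}, alpha={config.alpha})"
        )
    n, events_int, events_ctl, p = accepted

    ltfu_rate = rng.uniform(*config.ltfu_rate_range)
    n_lost = int(rng.binomial(2 * n, ltfu_rate))
    year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
    groups = sorted(config.journal_weights)
    weights = np.array([config.journal_weights[g] for g in groups], dtype=float)
    journal = _JOURNAL_NAMES[groups[rng.choice(len(groups), p=weights / weights.sum())]]

    def tri(probs: tuple[float, float, float]) -> str:
        return ("yes", "no", "unsure")[rng.choice(3, p=np.array(probs) / sum(probs))]

    return TrialRecord(
        trial_id=f"T{trial_index + 1:04d}",
        first_author=f"Author_{trial_index + 1:04d}",
        year=year,
        journal=journal,
        multicenter=tri(P_MULTICENTER),
        double_blinded=tri(P_DOUBLE_BLINDED),
        registered=tri(P_REGISTERED),
        itt=bool(rng.random() < P_ITT_YES),
        outcome_used="primary" if rng.random() < P_PRIMARY_OUTCOME else "secondary",
        n_int=n,
        n_ctl=n,
        events_int=events_int,
        events_ctl=events_ctl,
        n_lost_followup=n_lost,
        reported_p=p,
    )


def simulate_corpus(config: SimulationConfig) -> CorpusTable:
    """Generate ``config.n_trials`` accepted trials; provenance records the
    root seed so a corpus is reproducible from its CSV header alone."""
    records = [simulate_trial(config, i) for i in range(config.n_trials)]
    return CorpusTable(records=records, provenance=f"synthetic:{config.seed}")
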