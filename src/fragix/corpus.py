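"""Trial-corpus data model, CSV I/O, validation and categorical derivations.

A corpus is a table with one row per randomized controlled trial, carrying
the fields a fragility review extracts: arm sizes and event counts for the
analysed dichotomous outcome, publication metadata, design flags and the
number of patients lost to follow-up (NPLFU).

CSV schema (UTF-8, comma-separated, header required)::

    trial_id, first_author, year, journal, multicenter, double_blinded,
    registered, itt, outcome_used, n_int, n_ctl, events_int, events_ctl,
    n_lost_followup, reported_p

``multicenter``, ``double_blinded`` and ``registered`` take ``yes``/``no``/
``unsure``; ``itt`` is ``yes``/``no``; ``outcome_used`` is ``primary`` or
``secondary``; ``reported_p`` (the p-value the trial itself reported for the
analysed outcome) may be empty.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

from .exact import ContingencyTable
from .fragility import FragilityResult, fragility_index, nplfu_exceeds_fi

__all__ = [
    "TrialRecord",
    "CorpusTable",
    "CorpusSchemaError",
    "CorpusValidationError",
    "CSV_COLUMNS",
    "TRI_STATE",
    "YEAR_BINS",
    "JOURNAL_GROUPS",
    "read_corpus",
    "write_corpus",
    "derive_year_bin",
    "derive_journal_group",
    "attach_fragility",
    "select_min_fi_outcome",
]

logger = logging.getLogger("fragix")

CSV_COLUMNS = [
    "trial_id",
    "first_author",
    "year",
    "journal",
    "multicenter",
    "double_blinded",
    "registered",
    "itt",
    "outcome_used",
    "n_int",
    "n_ctl",
    "events_int",
    "events_ctl",
    "n_lost_followup",
    "reported_p",
]

TRI_STATE = ("yes", "no", "unsure")
OUTCOME_KINDS = ("primary", "secondary")

YEAR_BINS = ("pre2000", "y2000_2010", "y2011_present")

#: Journal categories in report order; journals outside the five named ones
#: collapse to "Other".
JOURNAL_GROUPS = ("NEJM", "J_Pediatrics", "Neonatology", "Pediatrics", "JAMA", "Other")

_JOURNAL_CANON = {
    "new england journal of medicine": "NEJM",
    "journal of pediatrics": "J_Pediatrics",
    "neonatology": "Neonatology",
    "pediatrics": "Pediatrics",
    "jama": "JAMA",
}


class CorpusSchemaError(ValueError):
    """The CSV header does not match the documented corpus schema."""


class CorpusValidationError(ValueError):
    """One or more corpus rows violate the record invariants."""

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__("\n".join(self.messages))


@dataclass(frozen=True)
class TrialRecord:
    """One RCT's extracted fields for the analysed dichotomous outcome."""

    trial_id: str
    first_author: str
    year: int
    journal: str
    multicenter: str
    double_blinded: str
    registered: str
    itt: bool
    outcome_used: str
    n_int: int
    n_ctl: int
    events_int: int
    events_ctl: int
    n_lost_followup: int
    reported_p: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("year", "n_int", "n_ctl", "events_int", "events_ctl", "n_lost_followup"):
            v = getattr(self, name)
            if isinstance(v, bool) or not isinstance(v, int):
                raise TypeError(f"{name} must be an integer, got {v!r}")
        for name in ("n_int", "n_ctl", "events_int", "events_ctl", "n_lost_followup"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.events_int > self.n_int:
            raise ValueError("events_int exceeds n_int")
        if self.events_ctl > self.n_ctl:
            raise ValueError("events_ctl exceeds n_ctl")
        if self.n_total < 2:
            raise ValueError("total sample size must be >= 2")
        if self.n_lost_followup > self.n_total:
            raise ValueError("n_lost_followup exceeds the total sample size")
        for name in ("multicenter", "double_blinded", "registered"):
            if getattr(self, name) not in TRI_STATE:
                raise ValueError(f"{name} must be one of {TRI_STATE}")
        if not isinstance(self.itt, bool):
            raise TypeError("itt must be a boolean")
        if self.outcome_used not in OUTCOME_KINDS:
            raise ValueError(f"outcome_used must be one of {OUTCOME_KINDS}")
        if self.reported_p is not None and not (0.0 <= self.reported_p <= 1.0):
            raise ValueError("reported_p must lie in [0, 1]")

    @property
    def n_total(self) -> int:
        return self.n_int + self.n_ctl

    @property
    def total_events(self) -> int:
        return self.events_int + self.events_ctl

    def contingency_table(self) -> ContingencyTable:
        return ContingencyTable(
            self.events_int,
            self.n_int - self.events_int,
            self.events_ctl,
            self.n_ctl - self.events_ctl,
        )


@dataclass
class CorpusTable:
    """An ordered collection of validated trial records with provenance."""

    records: list[TrialRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.trial_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CorpusValidationError(
                [f"duplicated trial_id values: {', '.join(dupes)}"]
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {f.name: getattr(r, f.name) for f in fields(TrialRecord)}
            row["itt"] = "yes" if r.itt else "no"
            rows.append(row)
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _parse_int(value, row: int, name: str, errors: list[str]) -> Optional[int]:
    if pd.isna(value):
        errors.append(f"row {row}: {name} is missing")
        return None
    s = str(value).strip()
    try:
        return int(s)
    except ValueError:
        errors.append(f"row {row}: {name} must be an integer, got {s!r}")
        return None


def read_corpus(path) -> CorpusTable:
    """Read and validate a trial-corpus CSV.

    Raises :class:`CorpusSchemaError` when the header deviates from
    :data:`CSV_COLUMNS` and :class:`CorpusValidationError` (with row-numbered
    messages, header = row 1) when any row violates a record invariant or a
    ``trial_id`` repeats.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    unknown = [c for c in df.columns if c not in CSV_COLUMNS]
    if missing or unknown:
        raise CorpusSchemaError(
            f"corpus header mismatch: missing columns {missing}, unknown columns {unknown}"
        )

    errors: list[str] = []
    records: list[TrialRecord] = []
    for i, row in df.iterrows():
        rownum = int(i) + 2  # 1-based with header row
        kwargs = {}
        ok = True
        for name in ("year", "n_int", "n_ctl", "events_int", "events_ctl", "n_lost_followup"):
            v = _parse_int(row[name], rownum, name, errors)
            if v is None:
                ok = False
            kwargs[name] = v
        for name in ("trial_id", "first_author", "journal", "multicenter",
                     "double_blinded", "registered", "outcome_used"):
            kwargs[name] = "" if pd.isna(row[name]) else str(row[name]).strip()
        itt_raw = "" if pd.isna(row["itt"]) else str(row["itt"]).strip().lower()
        if itt_raw in ("yes", "true", "1"):
            kwargs["itt"] = True
        elif itt_raw in ("no", "false", "0"):
            kwargs["itt"] = False
        else:
            errors.append(f"row {rownum}: itt must be yes/no, got {itt_raw!r}")
            ok = False
        if pd.isna(row["reported_p"]) or str(row["reported_p"]).strip() == "":
            kwargs["reported_p"] = None
        else:
            try:
                kwargs["reported_p"] = float(row["reported_p"])
            except ValueError:
                errors.append(
                    f"row {rownum}: reported_p must be a number, got {row['reported_p']!r}"
                )
                ok = False
        if not ok:
            continue
        try:
            records.append(TrialRecord(**kwargs))
        except (TypeError, ValueError) as exc:
            errors.append(f"row {rownum}: {exc}")

    if errors:
        raise CorpusValidationError(errors)
    return CorpusTable(records=records, provenance=str(path))


def write_corpus(corpus: CorpusTable, path) -> None:
    """Serialise a corpus to the documented CSV schema (UTF-8)."""
    df = corpus.to_dataframe()
    df.to_csv(path, index=False)


def derive_year_bin(year: int) -> str:
    """Publication-period bin: before 2000, 2000-2010, or 2011-present."""
    if not (1900 <= year <= 2100):
        raise ValueError(f"implausible publication year {year}")
    if year < 2000:
        return "pre2000"
    if year <= 2010:
        return "y2000_2010"
    return "y2011_present"


def derive_journal_group(journal: str) -> str:
    """Collapse a journal name to the report's six categories.

    Matching is case-insensitive and exact (after trimming whitespace and a
    leading article); anything not among the five named journals is "Other".
    """
    key = journal.strip().lower()
    if key.startswith("the "):
        key = key[4:]
    return _JOURNAL_CANON.get(key, "Other")


def attach_fragility(corpus: CorpusTable, alpha: float = 0.05) -> pd.DataFrame:
    """Compute FI/FQ and derived categoricals for every record in a corpus.

    Returns a DataFrame with one row per trial: all extracted fields plus
    ``n_total``, ``total_events``, ``year_bin``, ``journal_group``, ``fi``,
    ``fq``, ``p_initial``, ``p_terminal``, ``modified_arm``, ``exhausted``
    and ``nplfu_exceeds_fi``.  Input records are never mutated.  Exhausted
    results (the iteration ran out of non-events while still significant)
    are flagged and logged; downstream summaries exclude them.
    """
    rows = []
    n_exhausted = 0
    for r in corpus:
        res: FragilityResult = fragility_index(r.contingency_table(), alpha=alpha)
        if res.exhausted:
            n_exhausted += 1
        rows.append(
            {
                "trial_id": r.trial_id,
                "first_author": r.first_author,
                "year": r.year,
                "journal": r.journal,
                "multicenter": r.multicenter,
                "double_blinded": r.double_blinded,
                "registered": r.registered,
                "itt": r.itt,
                "outcome_used": r.outcome_used,
                "n_int": r.n_int,
                "n_ctl": r.n_ctl,
                "events_int": r.events_int,
                "events_ctl": r.events_ctl,
                "n_lost_followup": r.n_lost_followup,
                "reported_p": math.nan if r.reported_p is None else r.reported_p,
                "n_total": r.n_total,
                "total_events": r.total_events,
                "year_bin": derive_year_bin(r.year),
                "journal_group": derive_journal_group(r.journal),
                "fi": res.fi,
                "fq": res.fq,
                "p_initial": res.p_initial,
                "p_terminal": res.p_terminal,
                "modified_arm": res.modified_arm,
                "exhausted": res.exhausted,
                "nplfu_exceeds_fi": nplfu_exceeds_fi(r.n_lost_followup, res.fi),
            }
        )
    if n_exhausted:
        logger.warning(
            "%d trial(s) exhausted their modifiable arm before losing "
            "significance; they are flagged and excluded from summaries",
            n_exhausted,
        )
    cols = CSV_COLUMNS + [
        "n_total", "total_events", "year_bin", "journal_group",
        "fi", "fq", "p_initial", "p_terminal", "modified_arm",
        "exhausted", "nplfu_exceeds_fi",
    ]
    return pd.DataFrame(rows, columns=cols)


def select_min_fi_outcome(
    tables: Iterable[ContingencyTable], alpha: float = 0.05
) -> tuple[int, FragilityResult]:
    """Among several candidate outcome tables for one trial, pick the one
    with the smallest fragility index (non-exhausted results preferred,
    earliest wins ties).  Returns ``(index, FragilityResult)``."""
    best = None
    for i, t in enumerate(tables):
        res = fragility_index(t, alpha=alpha)
        key = (res.exhausted, res.fi)
        if best is None or key < best[0]:
            best = (key, i, res)
    if best is None:
        raise ValueError("no candidate outcome tables supplied")
    return best[1], best[2]
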