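"""Billing-record ingestion and the clinical day / group corpus.

Hospital billing data arrives as a flat table with four columns: a trace
identifier (one hospital stay), an item name (the clinical activity), an
amount, and the hospitalized-day index on which the item was billed.  The
topic model treats each *clinical day* — all activities of one trace on one
day — as a document, and each unique activity within a day as a *group*
whose occurrences must share a topic.  This module parses the table,
normalizes amounts to integer multiplicities, and builds that structure.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BillingRecord",
    "Vocabulary",
    "ClinicalDay",
    "Corpus",
    "ConfigError",
    "load_billing",
    "normalize_amounts",
    "build_corpus",
    "write_day_file",
    "read_day_file",
    "DEFAULT_COLUMNS",
]

DEFAULT_COLUMNS = {
    "trace_id": "trace_id",
    "item_name": "item_name",
    "amount": "amount",
    "day": "day",
}


class ConfigError(ValueError):
    """Raised when the ingestion configuration does not match the file."""


@dataclass(frozen=True)
class BillingRecord:
    """One billing row: ``amount`` units of ``item_name`` on ``day`` of ``trace_id``."""

    trace_id: str
    item_name: str
    amount: float
    day: int


class Vocabulary:
    """Bijection between activity names and dense indices ``0..V-1``.

    Indices are assigned in sorted name order so the mapping is a pure
    function of the set of names, independent of record order.
    """

    def __init__(self, names):
        self._names = list(names)
        self._index = {n: i for i, n in enumerate(self._names)}
        if len(self._index) != len(self._names):
            raise ValueError("duplicate names in vocabulary")

    @classmethod
    def from_records(cls, records) -> "Vocabulary":
        return cls(sorted({r.item_name for r in records}))

    def index(self, name: str) -> int:
        return self._index[name]

    def name(self, v: int) -> str:
        return self._names[v]

    def __len__(self) -> int:
        return len(self._names)

    def __contains__(self, name) -> bool:
        return name in self._index

    def __iter__(self):
        return iter(self._names)

    def __eq__(self, other):
        return isinstance(other, Vocabulary) and self._names == other._names


@dataclass
class ClinicalDay:
    """All activities of one trace on one hospitalized day.

    ``groups`` holds ``(activity index, multiplicity)`` pairs sorted by
    activity index; each activity appears in at most one group.
    """

    trace_id: str
    day: int
    groups: list  # list[(v, A)] sorted by v

    @property
    def n_tokens(self) -> int:
        return sum(a for _, a in self.groups)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass
class Corpus:
    """Ordered clinical days (by trace id, then day index) over ``V`` activities."""

    days: list
    V: int

    @property
    def D(self) -> int:
        return len(self.days)

    @property
    def G(self) -> int:
        return sum(d.n_groups for d in self.days)

    @property
    def n_tokens(self) -> int:
        return sum(d.n_tokens for d in self.days)

    @property
    def traces(self) -> dict:
        """trace_id -> list of ClinicalDay in day order."""
        out: dict = defaultdict(list)
        for d in self.days:
            out[d.trace_id].append(d)
        return dict(out)


def load_billing(path, columns: dict | None = None, delimiter: str | None = None):
    """Read billing rows from a delimited text file.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file with a header row.
    columns : dict, optional
        Maps the roles ``trace_id``, ``item_name``, ``amount``, ``day`` to the
        column names used in the file.  Defaults to the role names themselves.
    delimiter : str, optional
        Field delimiter; sniffed from the file when omitted.

    Returns
    -------
    list of BillingRecord
        One record per retained row.  Rows with missing fields or
        non-positive amounts are dropped and the drop count logged.

    Raises
    ------
    ConfigError
        If a required column is absent.
    ValueError
        If any row has an unparseable amount or day (all offending rows are
        collected and reported together).
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    if delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        df = pd.read_csv(path, sep=delimiter, dtype=str)
    for role in ("trace_id", "item_name", "amount", "day"):
        if cols[role] not in df.columns:
            raise ConfigError(
                f"required column {cols[role]!r} (role {role!r}) not found; "
                f"file has columns {list(df.columns)}"
            )

    bad_rows = []
    records = []
    n_dropped = 0
    for idx, row in df.iterrows():
        trace = row[cols["trace_id"]]
        item = row[cols["item_name"]]
        raw_amount = row[cols["amount"]]
        raw_day = row[cols["day"]]
        if any(pd.isna(x) for x in (trace, item, raw_amount, raw_day)):
            n_dropped += 1
            continue
        try:
            amount = float(raw_amount)
            day = int(float(raw_day))
        except (TypeError, ValueError):
            bad_rows.append(int(idx) + 2)  # 1-based line number incl. header
            continue
        if amount <= 0 or day < 0:
            n_dropped += 1
            continue
        records.append(BillingRecord(str(trace), str(item), amount, day))
    if bad_rows:
        raise ValueError(
            f"unparseable amount/day on line(s) {bad_rows[:20]}"
            + (" ..." if len(bad_rows) > 20 else "")
        )
    if n_dropped:
        logger.info("dropped %d row(s) with missing fields or non-positive amount", n_dropped)
    return records


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def normalize_amounts(records, mode: str = "unit-scale"):
    """Convert raw amounts to positive integer multiplicities.

    Billing amounts for different items live on different scales (tablets,
    millilitres, fees); the sampler needs per-item occurrence counts.  Under
    ``"unit-scale"`` (default) each item's amounts are divided by that item's
    smallest observed amount and rounded half-up, so the most common dose
    counts as one occurrence.  Under ``"round"`` amounts are rounded half-up
    with a floor of 1.
    """
    if any(r.amount <= 0 for r in records):
        raise ValueError("all amounts must be positive before normalization")
    if mode == "unit-scale":
        min_amount: dict = {}
        for r in records:
            cur = min_amount.get(r.item_name)
            if cur is None or r.amount < cur:
                min_amount[r.item_name] = r.amount
        return [
            BillingRecord(
                r.trace_id,
                r.item_name,
                max(1, _round_half_up(r.amount / min_amount[r.item_name])),
                r.day,
            )
            for r in records
        ]
    if mode == "round":
        return [
            BillingRecord(r.trace_id, r.item_name, max(1, _round_half_up(r.amount)), r.day)
            for r in records
        ]
    raise ValueError(f"unknown normalization mode {mode!r}")


def build_corpus(records, vocabulary: Vocabulary | None = None):
    """Merge normalized records into the day/group corpus.

    Rows sharing ``(trace_id, day)`` form one clinical day; within a day,
    rows with the same item are merged into one group with summed
    multiplicity (billing rows are additive, never deduplicated).

    Returns
    -------
    (Corpus, Vocabulary)
    """
    records = list(records)
    if not records:
        raise ValueError("cannot build a corpus from zero records")
    vocab = vocabulary if vocabulary is not None else Vocabulary.from_records(records)
    day_groups: dict = defaultdict(lambda: defaultdict(int))
    for r in records:
        mult = int(r.amount)
        if mult != r.amount or mult < 1:
            raise ValueError(
                f"record {r} has non-integer multiplicity; run normalize_amounts first"
            )
        day_groups[(r.trace_id, r.day)][vocab.index(r.item_name)] += mult
    days = [
        ClinicalDay(trace_id=t, day=d, groups=sorted(groups.items()))
        for (t, d), groups in sorted(day_groups.items())
    ]
    return Corpus(days=days, V=len(vocab)), vocab


def write_day_file(corpus: Corpus, vocab: Vocabulary, path) -> None:
    """Serialize a corpus to a plain-text day file.

    One line per clinical day: ``trace_id<TAB>day<TAB>item:count item:count``.
    Self-contained — the vocabulary is reconstructed on read.
    """
    with open(path, "w") as fh:
        for d in corpus.days:
            pairs = " ".join(f"{vocab.name(v)}:{a}" for v, a in d.groups)
            fh.write(f"{d.trace_id}\t{d.day}\t{pairs}\n")


def read_day_file(path):
    """Inverse of :func:`write_day_file`; returns ``(Corpus, Vocabulary)``."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            trace, day, pairs = line.split("\t")
            for pair in pairs.split(" "):
                item, count = pair.rsplit(":", 1)
                records.append(BillingRecord(trace, item, int(count), int(day)))
    return build_corpus(records)
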