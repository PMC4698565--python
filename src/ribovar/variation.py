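"""Variable-column scanning and substitution/indel classification.

A column is *variable* when its rows do not all share one symbol; a gap
counts as a distinct state.  An *indel event* is a maximal run of gap
columns in one clone.  Two modes of event delimitation are provided:

``raw``
    Every maximal run of ``-`` in a row is one event.

``consensus-masked`` (default for summaries)
    Columns whose plurality state across clones is the gap are masked:
    they belong to the specimen's majority sequence as absences, so a
    clone gapped there is not deviating.  Each raw run is clipped to the
    consensus-base columns at both ends (interior masked columns stay
    inside the event, since the clone is continuously gapped across
    them); runs entirely inside masked columns disappear.  Plurality ties
    between gap and a base resolve to the base, keeping the column
    eventable.

Events shared by several clones (same start/end) are deduplicated in
summaries: a deletion inherited by many clones is one mutational event.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import asdict, dataclass, field

import pandas as pd

from .alignio import CloneAlignment
from .errors import ConfigurationError

MODES = ("raw", "consensus-masked")

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column state counts at one alignment column."""

    column: int  # 1-based index
    label: str  # user-facing label (usually str(column))
    state_counts: dict[str, int]
    n_base_states: int  # distinct non-gap, non-ambiguous symbols
    has_gap: bool

    @property
    def is_variable(self) -> bool:
        return self.n_base_states >= 2 or (self.has_gap and self.n_base_states >= 1)


@dataclass(frozen=True, order=True)
class IndelEvent:
    """A maximal gap run in one clone (1-based, inclusive coordinates)."""

    start: int
    end: int
    clone_id: str = field(compare=False)
    mode: str = field(compare=False)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def kind(self) -> str:
        return "mono" if self.length == 1 else "multi"


@dataclass
class VariationSummary:
    """Specimen-level counts behind a variable-position table."""

    specimen_id: str
    mode: str
    n_variable_columns: int
    n_substitution_sites: int
    n_mono_indel_events: int
    n_multi_indel_events: int
    #: events deduplicated across clones by (start, end)
    event_list: list[IndelEvent]

    def to_json(self) -> str:
        d = asdict(self)
        d["event_list"] = [
            {
                "start": e.start,
                "end": e.end,
                "length": e.length,
                "kind": e.kind,
                "clone_id": e.clone_id,
            }
            for e in self.event_list
        ]
        return json.dumps(d, indent=2)


def _profile(aln: CloneAlignment, j: int) -> ColumnProfile:
    col = aln.column(j)
    counts = dict(Counter(col))
    bases = {s for s in counts if s in _BASES}
    return ColumnProfile(
        column=j,
        label=aln.labels[j - 1],
        state_counts=counts,
        n_base_states=len(bases),
        has_gap="-" in counts,
    )


def scan_columns(aln: CloneAlignment) -> list[ColumnProfile]:
    """Return profiles of the variable columns only, sorted ascending.

    All-gap columns carry no state information and are dropped with a
    warning.
    """
    out = []
    for j in range(1, aln.n_columns + 1):
        p = _profile(aln, j)
        if p.n_base_states == 0 and p.has_gap:
            warnings.warn(
                f"column {p.label} is all-gap and was dropped", stacklevel=2
            )
            continue
        if p.is_variable:
            out.append(p)
    return out


def _gap_runs(row: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' in a row, 1-based inclusive."""
    runs = []
    start = None
    for j, sym in enumerate(row, start=1):
        if sym == "-":
            if start is None:
                start = j
        elif start is not None:
            runs.append((start, j - 1))
            start = None
    if start is not None:
        runs.append((start, len(row)))
    return runs


def gap_plurality_mask(aln: CloneAlignment) -> set[int]:
    """1-based columns whose plurality state is the gap (ties -> base)."""
    masked = set()
    for j in range(1, aln.n_columns + 1):
        counts = Counter(aln.column(j))
        n_gap = counts.get("-", 0)
        n_best_base = max(
            (c for s, c in counts.items() if s != "-"), default=0
        )
        if n_gap > n_best_base:
            masked.add(j)
    return masked


def detect_indel_events(aln: CloneAlignment, mode: str = "consensus-masked") -> list[IndelEvent]:
    """Delimit per-clone indel events under the given mode.

    Raw mode reports every maximal gap run.  Consensus-masked mode clips
    each run to the columns where the specimen's plurality state is a
    base, so events are reported relative to the majority sequence.
    """
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}; expected one of {MODES}")
    masked = gap_plurality_mask(aln) if mode == "consensus-masked" else set()
    events = []
    for cid, row in zip(aln.clone_ids, aln.rows):
        for start, end in _gap_runs(row):
            if mode == "consensus-masked":
                cols = [j for j in range(start, end + 1) if j not in masked]
                if not cols:
                    continue
                start, end = cols[0], cols[-1]
            events.append(IndelEvent(start=start, end=end, clone_id=cid, mode=mode))
    return events


def classify_variation(aln: CloneAlignment, mode: str = "consensus-masked") -> VariationSummary:
    """Count substitution sites and deduplicated mono/multi indel events.

    A substitution site is a column with at least two distinct non-gap
    states; a column may host both a substitution and an indel and is then
    counted in both tallies.
    """
    profiles = scan_columns(aln)
    n_sub = sum(1 for p in profiles if p.n_base_states >= 2)
    events = detect_indel_events(aln, mode)
    dedup: dict[tuple[int, int], IndelEvent] = {}
    for e in sorted(events, key=lambda e: (e.start, e.end)):
        dedup.setdefault((e.start, e.end), e)
    uniq = list(dedup.values())
    return VariationSummary(
        specimen_id=aln.specimen_id,
        mode=mode,
        n_variable_columns=len(profiles),
        n_substitution_sites=n_sub,
        n_mono_indel_events=sum(1 for e in uniq if e.kind == "mono"),
        n_multi_indel_events=sum(1 for e in uniq if e.kind == "multi"),
        event_list=uniq,
    )


def variable_position_table(aln: CloneAlignment) -> pd.DataFrame:
    """Clones x variable positions table of symbols.

    Rows are clones (input order), columns the 1-based labels of the
    variable positions.  Applying this to an alignment reconstructed from
    a variable-position fixture reproduces the fixture exactly.
    """
    profiles = scan_columns(aln)
    data = {
        p.label: [row[p.column - 1] for row in aln.rows] for p in profiles
    }
    return pd.DataFrame(data, index=list(aln.clone_ids))
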