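"""Simple indel coding: gaps as binary presence/absence characters.

Each distinct gap (identified by its start/end coordinates across all
clones) becomes one character, regardless of length, under the assumption
that a gap results from a single mutational event.  States per clone:

``1``  the clone has a gap run with exactly these coordinates;
``0``  no gap of the clone covers the range (including partial overlaps,
       scored as potential homoplasy rather than inapplicable);
``?``  a longer gap of the clone entirely spans the range with different
       coordinates — the character is inapplicable for that clone.

The resulting binary partition can be appended to a NEXUS matrix via
:func:`ribovar.alignio.write_partitioned_nexus`.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .alignio import CloneAlignment
from .variation import detect_indel_events


@dataclass
class IndelCharacterMatrix:
    """Binary indel characters with per-character 1-based coordinates."""

    clone_ids: list[str]
    characters: list[tuple[int, int]]  # unique, sorted by (start, end)
    states: list[list[str]]  # clone x character, entries in {"1","0","?"}

    @property
    def n_characters(self) -> int:
        return len(self.characters)


def simple_indel_coding(aln: CloneAlignment) -> IndelCharacterMatrix:
    """Code every distinct raw gap run of the alignment as one character."""
    events = detect_indel_events(aln, mode="raw")
    runs_by_clone: dict[str, set[tuple[int, int]]] = {c: set() for c in aln.clone_ids}
    for e in events:
        runs_by_clone[e.clone_id].add((e.start, e.end))
    characters = sorted({(e.start, e.end) for e in events})
    states = []
    for cid in aln.clone_ids:
        runs = runs_by_clone[cid]
        row = []
        for char in characters:
            if char in runs:
                row.append("1")
            elif any(
                r[0] <= char[0] and r[1] >= char[1] and r != char for r in runs
            ):
                row.append("?")
            else:
                row.append("0")
        states.append(row)
    return IndelCharacterMatrix(
        clone_ids=list(aln.clone_ids), characters=characters, states=states
    )


def coded_matrix_report(chars: IndelCharacterMatrix) -> pd.DataFrame:
    """Per-character coordinates, length and 1/0/? state counts."""
    rows = []
    for k, (start, end) in enumerate(chars.characters):
        col = [chars.states[i][k] for i in range(len(chars.clone_ids))]
        rows.append(
            {
                "start": start,
                "end": end,
                "length": end - start + 1,
                "n_present": col.count("1"),
                "n_absent": col.count("0"),
                "n_inapplicable": col.count("?"),
            }
        )
    return pd.DataFrame(
        rows, columns=["start", "end", "length", "n_present", "n_absent", "n_inapplicable"]
    )
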