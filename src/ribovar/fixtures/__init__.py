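"""In-study data shipped as fixtures.

The study's printed data are two tables: the variable positions among the
10 sequenced clones of each of five specimens, and the per-specimen
10x10 uncorrected p-distance matrices with their printed averages.  Both
are transcribed here as packaged JSON and exposed through typed loaders.

The full-length clone sequences were never printed, so
:func:`reconstruct_alignment` rebuilds an alignment by placing the
variable-position symbols on a constant backbone (default 512 columns,
the maximum spacer length observed in the study; fill base ``A``).  All
variation in a reconstruction therefore comes from the transcribed
table, and anything sensitive to the constant-column content (e.g.
absolute distance denominators) is *not* recoverable from it.

Specimen naming is unified to ``W136, W202, V145, Z704, W127``; the
tables' printed aliases (``Z04`` for Z704, ``V127`` for W127) are kept in
:data:`ALIASES`.  Decimal commas in the printed averages were normalized
to decimal points at transcription.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np

from ..alignio import CloneAlignment
from ..distance import DistanceMatrix
from ..errors import FixtureError

SPECIMENS = ("W136", "W202", "V145", "Z704", "W127")

#: printed name -> unified name, for the specimens the tables label differently
ALIASES = {"Z04": "Z704", "V127": "W127"}

_LABEL_RE = re.compile(r"^(\d+)([a-z]*)$")


def _load(name: str) -> dict:
    with resources.files(__package__).joinpath(f"data/{name}").open() as fh:
        return json.load(fh)


@dataclass
class Table1Fixture:
    """Variable positions among the sequenced clones of one specimen."""

    specimen_id: str
    species: str
    positions: list[str]  # ordered 1-based labels; "337b" marks an inserted column
    rows: dict[str, str]  # clone key ("#01") -> symbols, one per position

    def __post_init__(self) -> None:
        for key, row in self.rows.items():
            if len(row) != len(self.positions):
                raise FixtureError(
                    f"{self.specimen_id} {key}: {len(row)} symbols for "
                    f"{len(self.positions)} positions"
                )
            bad = set(row) - set("ACGT-")
            if bad:
                raise FixtureError(f"{self.specimen_id} {key}: bad symbols {bad}")


@dataclass
class Table2Fixture:
    """Transcribed p-distance matrix of one specimen, as printed."""

    specimen_id: str
    matrix: DistanceMatrix  # provenance="transcribed"
    printed_average: float


def _check_specimen(specimen_id: str) -> str:
    specimen_id = ALIASES.get(specimen_id, specimen_id)
    if specimen_id not in SPECIMENS:
        raise FixtureError(
            f"unknown specimen {specimen_id!r}; expected one of {SPECIMENS}"
        )
    return specimen_id


def load_table1(specimen_id: str) -> Table1Fixture:
    """Load the variable-position fixture of one specimen."""
    specimen_id = _check_specimen(specimen_id)
    d = _load("table1.json")[specimen_id]
    return Table1Fixture(
        specimen_id=specimen_id,
        species=d["species"],
        positions=list(d["positions"]),
        rows=dict(d["rows"]),
    )


def load_table2_fixture(specimen_id: str) -> Table2Fixture:
    """Load the transcribed distance matrix plus its printed average."""
    specimen_id = _check_specimen(specimen_id)
    d = _load("table2.json")[specimen_id]
    tri = d["lower_triangle"]
    k = len(tri) + 1
    m = np.zeros((k, k))
    for i, row in enumerate(tri, start=1):
        if len(row) != i:
            raise FixtureError(f"{specimen_id}: malformed lower triangle")
        for j, v in enumerate(row):
            m[i, j] = m[j, i] = v
    labels = [f"{specimen_id}_#{n:02d}" for n in range(1, k + 1)]
    matrix = DistanceMatrix(
        labels=labels, values=m, policy=None, provenance="transcribed"
    )
    return Table2Fixture(
        specimen_id=specimen_id,
        matrix=matrix,
        printed_average=float(d["printed_average"]),
    )


def load_table2(specimen_id: str) -> DistanceMatrix:
    """Symmetrized transcription of one specimen's printed distance matrix."""
    return load_table2_fixture(specimen_id).matrix


def reconstruct_alignment(
    t1: Table1Fixture, backbone_length: int = 512, fill_base: str = "A"
) -> CloneAlignment:
    """Place a variable-position fixture on a constant backbone.

    Every column not listed in the fixture holds ``fill_base`` in all
    clones, so all variation in the result comes from the fixture.
    Labels like ``"337b"`` occupy an extra column inserted immediately
    after their numeric parent, extending the alignment beyond
    ``backbone_length``.
    """
    if fill_base not in "ACGT":
        raise FixtureError(f"fill_base must be a base, got {fill_base!r}")
    labels = [str(i) for i in range(1, backbone_length + 1)]
    for label in t1.positions:
        m = _LABEL_RE.match(label)
        if m is None:
            raise FixtureError(f"unparseable position label {label!r}")
        num, suffix = int(m.group(1)), m.group(2)
        if num > backbone_length:
            raise FixtureError(
                f"position {label} exceeds backbone length {backbone_length}"
            )
        if suffix:  # inserted column, e.g. "337b" right after "337"
            anchor = labels.index(str(num))
            # keep earlier-suffix siblings before later ones
            insert_at = anchor + 1
            while insert_at < len(labels) and re.match(
                rf"^{num}[a-z]+$", labels[insert_at]
            ) and labels[insert_at] < label:
                insert_at += 1
            if label not in labels:
                labels.insert(insert_at, label)
    index = {lab: i for i, lab in enumerate(labels)}
    clone_ids, rows = [], []
    for key in t1.rows:
        seq = [fill_base] * len(labels)
        for lab, sym in zip(t1.positions, t1.rows[key]):
            seq[index[lab]] = sym
        clone_ids.append(f"{t1.specimen_id}_{key}")
        rows.append("".join(seq))
    return CloneAlignment(
        specimen_id=t1.specimen_id,
        clone_ids=clone_ids,
        rows=rows,
        column_labels=labels,
    )
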