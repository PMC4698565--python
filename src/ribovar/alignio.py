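"""Alignment container and I/O.

A clone library is a set of plasmid-derived sequences of one multicopy
locus from a single specimen, aligned into a gapped matrix.  The
:class:`CloneAlignment` container keeps that matrix together with the
specimen id and optional user-facing column labels.  All user-facing
coordinates are 1-based and inclusive.

FASTA reading/writing goes through Biopython.  The NEXUS writer emits the
combined nucleotide + binary-indel matrix either in the MrBayes
``datatype=mixed`` dialect (with a commented MrBayes command block applying
GTR to the nucleotide partition and the restriction model to the indel
partition) or in strictly standard NEXUS (``datatype=standard``), which any
conforming reader can parse.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentError,
    AlphabetError,
    ConsistencyError,
    InputError,
    LabelFormatError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .indelcode import IndelCharacterMatrix

#: Canonical residue alphabet.  IUPAC ambiguity letters are tolerated on
#: read (direct-sequencing inputs may contain them) but are recorded as
#: ambiguous sites and excluded from substitution counting downstream.
CANONICAL = frozenset("ACGT-")
IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHVN")

_LABEL_RE = re.compile(r"^(?P<specimen>.+)_#(?P<number>\d+)$")


@dataclass
class CloneAlignment:
    """A gapped multiple alignment of clone sequences from one specimen.

    Parameters
    ----------
    specimen_id
        Identifier of the source specimen (e.g. ``"W136"``).
    clone_ids
        Unique row labels, in input order (e.g. ``"W136_#01"``).
    rows
        Upper-case sequences over ``{A,C,G,T,-}`` (IUPAC ambiguity letters
        tolerated and flagged), all of identical length.
    column_labels
        Optional user-facing labels, one per column.  Defaults to
        ``"1" .. "n"``.  Reconstructed fixtures use labels like ``"337b"``
        for inserted columns.
    """

    specimen_id: str
    clone_ids: list[str]
    rows: list[str]
    column_labels: list[str] | None = None
    #: (clone_id, 1-based column, symbol) for every IUPAC-ambiguous residue.
    ambiguous_sites: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rows:
            raise InputError("alignment has no rows")
        if len(self.clone_ids) != len(self.rows):
            raise ConsistencyError(
                f"{len(self.clone_ids)} clone ids for {len(self.rows)} rows"
            )
        if len(set(self.clone_ids)) != len(self.clone_ids):
            raise ConsistencyError("clone ids are not unique")
        n = len(self.rows[0])
        self.rows = [r.upper() for r in self.rows]
        for cid, row in zip(self.clone_ids, self.rows):
            if len(row) != n:
                raise AlignmentError(
                    f"record {cid!r} has length {len(row)}, expected {n}"
                )
        found: list[tuple[str, int, str]] = []
        for cid, row in zip(self.clone_ids, self.rows):
            for j, sym in enumerate(row, start=1):
                if sym in CANONICAL:
                    continue
                if sym in IUPAC_AMBIGUOUS:
                    found.append((cid, j, sym))
                else:
                    raise AlphabetError(
                        f"illegal symbol {sym!r} in record {cid!r} at column {j}"
                    )
        if found and not self.ambiguous_sites:
            self.ambiguous_sites = found
        if self.column_labels is not None:
            if len(self.column_labels) != n:
                raise ConsistencyError(
                    f"{len(self.column_labels)} column labels for {n} columns"
                )
            if len(set(self.column_labels)) != n:
                raise ConsistencyError("column labels are not unique")

    @property
    def n_clones(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def labels(self) -> list[str]:
        """Column labels (defaults to ``"1" .. "n"``)."""
        if self.column_labels is not None:
            return list(self.column_labels)
        return [str(i) for i in range(1, self.n_columns + 1)]

    def column(self, j: int) -> str:
        """Symbols of 1-based column ``j``, in row order."""
        if not 1 <= j <= self.n_columns:
            raise IndexError(f"column {j} out of range 1..{self.n_columns}")
        return "".join(row[j - 1] for row in self.rows)

    def row(self, clone_id: str) -> str:
        return self.rows[self.clone_ids.index(clone_id)]


def parse_clone_label(label: str) -> tuple[str, int]:
    """Split ``"W136_#01"`` into ``("W136", 1)``.

    Leading zeros in the clone number carry no significance.
    """
    m = _LABEL_RE.match(label)
    if m is None:
        raise LabelFormatError(
            f"label {label!r} does not match '<specimen>_#<nn>'"
        )
    return m.group("specimen"), int(m.group("number"))


def read_fasta_alignment(path, specimen_id: str) -> CloneAlignment:
    """Read an aligned FASTA file into a :class:`CloneAlignment`.

    Record order is preserved and residues are upper-cased.  Raises
    :class:`InputError` on an empty file, :class:`AlignmentError` on
    unequal record lengths and :class:`AlphabetError` (naming the record
    and 1-based column) on symbols outside the alphabet.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    ids = [rec.id for rec in records]
    rows = [str(rec.seq).upper() for rec in records]
    return CloneAlignment(specimen_id=specimen_id, clone_ids=ids, rows=rows)


def write_fasta_alignment(aln: CloneAlignment, path) -> None:
    """Write the alignment as gapped FASTA, preserving row order."""
    records = [
        SeqRecord(Seq(row), id=cid, description="")
        for cid, row in zip(aln.clone_ids, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def _quote_taxon(label: str) -> str:
    if re.fullmatch(r"[A-Za-z0-9_.]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


_MRBAYES_BLOCK = """\
[
begin mrbayes;
    charset nucleotides = 1-{ndna};
    charset indels = {bstart}-{nchar};
    partition by_type = 2: nucleotides, indels;
    set partition = by_type;
    lset applyto=(1) nst=6 rates=gamma;  [ GTR+G on the nucleotide partition ]
    lset applyto=(2) coding=variable;    [ restriction-site (Mk) model on the indel partition ]
    unlink statefreq=(all) revmat=(all) shape=(all);
end;
]
"""


def write_partitioned_nexus(
    aln: CloneAlignment,
    chars: "IndelCharacterMatrix | None",
    path,
    dialect: str = "mrbayes",
) -> None:
    """Write a NEXUS DATA block combining nucleotides and indel characters.

    The binary presence/absence characters from simple indel coding are
    appended after the nucleotide columns, CHARSETs separate the two
    partitions, and a commented MrBayes command block applies GTR to the
    nucleotides and the restriction (Mk-style) model to the indels.

    ``dialect="mrbayes"`` uses ``datatype=mixed(dna:...,restriction:...)``
    as accepted by MrBayes; ``dialect="standard"`` emits strictly standard
    NEXUS (``datatype=standard symbols="ACGT01"``) parseable by any
    conforming reader.  With zero indel characters a pure-DNA file is
    written and no binary charset is declared.
    """
    from .errors import ConfigurationError

    if dialect not in ("mrbayes", "standard"):
        raise ConfigurationError(f"unknown NEXUS dialect {dialect!r}")
    n_bin = 0
    if chars is not None and chars.characters:
        if chars.clone_ids != aln.clone_ids:
            raise ConsistencyError(
                "indel character matrix rows do not match the alignment"
            )
        n_bin = len(chars.characters)
    ndna = aln.n_columns
    nchar = ndna + n_bin
    ntax = aln.n_clones

    if n_bin == 0:
        fmt = "datatype=dna gap=- missing=?;"
    elif dialect == "mrbayes":
        fmt = (
            f"datatype=mixed(dna:1-{ndna},restriction:{ndna + 1}-{nchar}) "
            "gap=- missing=?;"
        )
    else:
        fmt = 'datatype=standard symbols="ACGT01" gap=- missing=?;'

    width = max(len(_quote_taxon(c)) for c in aln.clone_ids)
    lines = ["#NEXUS", ""]
    lines += [
        "begin data;",
        f"    dimensions ntax={ntax} nchar={nchar};",
        f"    format {fmt}",
        "    matrix",
    ]
    for i, cid in enumerate(aln.clone_ids):
        seq = aln.rows[i]
        if n_bin:
            seq += "".join(chars.states[i])
        lines.append(f"    {_quote_taxon(cid):<{width}} {seq}")
    lines += ["    ;", "end;", ""]
    if n_bin:
        lines += [
            "begin sets;",
            f"    charset nucleotides = 1-{ndna};",
            f"    charset indels = {ndna + 1}-{nchar};",
            "end;",
            "",
            _MRBAYES_BLOCK.format(ndna=ndna, bstart=ndna + 1, nchar=nchar),
        ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
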