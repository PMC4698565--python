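"""Uncorrected p-distances under explicit gap policies.

The uncorrected p-distance between two aligned sequences is the
proportion of compared columns at which they differ.  Columns gapped in
both sequences are excluded under every policy; the policies differ in
how single-sided gaps enter the numerator and denominator:

``indel-event`` (default)
    Each maximal run of columns gapped in exactly one sequence counts as
    one difference (a gap is one mutational event regardless of length);
    denominator = all included columns.

``pairwise-deletion``
    Columns gapped in either sequence are excluded; only substitutions
    count; denominator = both-base columns.

``gap-as-state``
    Every single-sided gap column counts as a difference; denominator =
    all included columns.

IUPAC-ambiguous residues are treated as missing data: the column is
excluded from the comparison, like a both-gap column.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .alignio import CloneAlignment
from .errors import AlignmentError, ConfigurationError, DegenerateInputError

POLICIES = ("indel-event", "pairwise-deletion", "gap-as-state")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (Table-style reporting, not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def as_percent(p: float) -> float:
    """Proportion -> percent, rounded half-up to 2 decimals (1.34 style)."""
    return round_half_up(100.0 * p, 2)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise p-distance matrix for one specimen."""

    labels: list[str]
    values: np.ndarray  # square, symmetric, zero diagonal, entries in [0,1]
    policy: str | None  # None for transcribed matrices of unknown convention
    provenance: str = "computed"  # or "transcribed"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if v.shape != (k, k):
            raise AlignmentError(f"matrix shape {v.shape} does not fit {k} labels")
        if not np.allclose(v, v.T):
            raise AlignmentError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise AlignmentError("matrix diagonal is not zero")
        if v.min() < 0.0 or v.max() > 1.0:
            raise AlignmentError("entries outside [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_tsv_lower(self) -> str:
        """Lower-triangular TSV in the style of a printed distance table."""
        lines = ["\t".join([""] + self.labels)]
        for i, lab in enumerate(self.labels):
            cells = [f"{self.values[i, j]:.4f}" for j in range(i)] + ["-"]
            lines.append("\t".join([lab] + cells))
        return "\n".join(lines) + "\n"

    def to_phylip(self) -> str:
        """Square PHYLIP (relaxed names) distance format."""
        width = max(10, max(len(l) for l in self.labels) + 2)
        lines = [f"{self.n}"]
        for i, lab in enumerate(self.labels):
            row = " ".join(f"{x:.6f}" for x in self.values[i])
            lines.append(f"{lab:<{width}}{row}")
        return "\n".join(lines) + "\n"


@dataclass
class DiversitySummary:
    """Mean/min/max intragenomic distance and haplotype structure."""

    specimen_id: str
    mean_p: float
    min_p: float
    max_p: float
    argmax_pair: tuple[str, str]
    n_pairs: int
    n_zero_pairs: int
    n_haplotypes: int

    def to_json(self) -> str:
        d = {
            "specimen_id": self.specimen_id,
            "mean_p": self.mean_p,
            "min_p": self.min_p,
            "max_p": self.max_p,
            "mean_percent": as_percent(self.mean_p),
            "max_percent": as_percent(self.max_p),
            "argmax_pair": list(self.argmax_pair),
            "n_pairs": self.n_pairs,
            "n_zero_pairs": self.n_zero_pairs,
            "n_haplotypes": self.n_haplotypes,
        }
        return json.dumps(d, indent=2)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype="S1")


def _run_count(gap: np.ndarray) -> int:
    """Number of maximal True-runs in a boolean vector."""
    if gap.size == 0:
        return 0
    return int(gap[0]) + int(np.count_nonzero(gap[1:] & ~gap[:-1]))


def _pair_stats(x: np.ndarray, y: np.ndarray, policy: str) -> tuple[int, int]:
    """(numerator, denominator) for one pair under a policy."""
    gx, gy = x == b"-", y == b"-"
    ambiguous = ~np.isin(x, _BASES) & ~gx
    ambiguous |= ~np.isin(y, _BASES) & ~gy
    keep = ~(gx & gy) & ~ambiguous
    x, y = x[keep], y[keep]
    gx, gy = x == b"-", y == b"-"
    subs = int(np.count_nonzero(~gx & ~gy & (x != y)))
    if policy == "pairwise-deletion":
        both_base = ~gx & ~gy
        return subs, int(np.count_nonzero(both_base))
    if policy == "gap-as-state":
        return subs + int(np.count_nonzero(gx | gy)), x.size
    if policy == "indel-event":
        return subs + _run_count(gx) + _run_count(gy), x.size
    raise ConfigurationError(f"unknown gap policy {policy!r}; expected one of {POLICIES}")


def p_distance(x: str, y: str, policy: str = "indel-event") -> float:
    """Uncorrected p-distance between two equal-length gapped sequences.

    Returns 0.0 (with a warning) when every column is excluded.
    """
    if len(x) != len(y):
        raise AlignmentError(f"length mismatch: {len(x)} vs {len(y)}")
    num, den = _pair_stats(_encode(x.upper()), _encode(y.upper()), policy)
    if den == 0:
        warnings.warn("all columns excluded; distance reported as 0", stacklevel=2)
        return 0.0
    return num / den


def distance_matrix(aln: CloneAlignment, policy: str = "indel-event") -> DistanceMatrix:
    """All-pairs p-distance matrix of an alignment."""
    if aln.n_clones < 2:
        raise DegenerateInputError("need at least 2 rows for a distance matrix")
    if policy not in POLICIES:
        raise ConfigurationError(f"unknown gap policy {policy!r}; expected one of {POLICIES}")
    enc = [_encode(r) for r in aln.rows]
    k = aln.n_clones
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            num, den = _pair_stats(enc[i], enc[j], policy)
            if den == 0:
                warnings.warn(
                    f"pair ({aln.clone_ids[i]}, {aln.clone_ids[j]}): all columns "
                    "excluded; distance reported as 0",
                    stacklevel=2,
                )
                d = 0.0
            else:
                d = num / den
            m[i, j] = m[j, i] = d
    return DistanceMatrix(
        labels=list(aln.clone_ids), values=m, policy=policy, provenance="computed"
    )


def diversity_summary(m: DistanceMatrix) -> DiversitySummary:
    """Summary over the k(k-1)/2 unordered pairs of a distance matrix.

    Haplotype number is the number of groups under transitive closure of
    zero-distance pairs.  The argmax pair is the first pair attaining the
    maximum in row-major order.
    """
    k = m.n
    if k < 2:
        raise DegenerateInputError("diversity summary needs at least 2 labels")
    iu = np.triu_indices(k, 1)
    vals = m.values[iu]
    amax = int(np.argmax(vals))
    pair = (m.labels[iu[0][amax]], m.labels[iu[1][amax]])
    zero_adj = csr_matrix(m.values == 0.0)
    n_hap, _ = connected_components(zero_adj, directed=False)
    specimen = m.labels[0].rsplit("_#", 1)[0] if m.labels else ""
    return DiversitySummary(
        specimen_id=specimen,
        mean_p=float(vals.mean()),
        min_p=float(vals.min()),
        max_p=float(vals.max()),
        argmax_pair=pair,
        n_pairs=len(vals),
        n_zero_pairs=int(np.count_nonzero(vals == 0.0)),
        n_haplotypes=int(n_hap),
    )


def collapse_haplotypes(aln: CloneAlignment) -> list[list[str]]:
    """Group clone ids by identical full sequences.

    Groups are ordered by their first member's position in the alignment;
    members keep input order.
    """
    groups: dict[str, list[str]] = {}
    for cid, row in zip(aln.clone_ids, aln.rows):
        groups.setdefault(row, []).append(cid)
    return list(groups.values())
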