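"""Concerted-evolution clone-library simulator.

A tandemly repeated multicopy spacer evolves under three forces: per-copy
point substitutions, per-copy indels, and gene-conversion homogenization
(a copy is overwritten wholesale by another, the simplest mechanism by
which concerted evolution keeps repeats alike).  Intragenomic variation
persists when mutation outpaces homogenization; the simulator exposes
both rates so that balance can be explored.

The array is then sampled as a clone library: ``n_clones`` copies drawn
without replacement, optional per-base PCR/sequencing error applied, and
the clones emitted as a :class:`~ribovar.alignio.CloneAlignment` in the
ancestral coordinate frame (insertions occupy extra columns, deletions
become gaps), so no aligner is needed and every clone's differences from
the ancestor are known exactly.

All randomness flows from one ``numpy`` Generator seeded by
``config.seed`` and consumed in a fixed, documented order: (1) ancestral
sequence; (2) per copy in index order — substitution count, then each
substitution's position and replacement base; indel count, then each
indel's type coin, length, position and (for insertions) bases; (3) per
homogenization round, per copy in index order — the conversion coin and,
if triggered, the donor; (4) the clone sample; (5) per clone in sample
order, per residue — the error coin and replacement base.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignio import CloneAlignment
from .errors import ConfigurationError

_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Parameters of one simulated clone library.

    Defaults emulate the study system: an rDNA spacer of ~500 bp present
    in a few hundred tandem copies, sampled as a 10-clone library, with
    per-copy mutation pressure that yields intragenomic mean p-distances
    on the order of 1%.
    """

    seed: int = 0
    ancestral_length: int = 500
    n_copies: int = 200
    sub_rate: float = 2.5  # expected substitutions per copy (Poisson mean)
    indel_rate: float = 0.3  # expected indel events per copy (Poisson mean)
    indel_length_geometric_p: float = 0.5
    homogenization_prob: float = 0.1  # per copy per round
    homogenization_rounds: int = 5
    n_clones: int = 10
    clone_error_rate: float = 0.0  # per-base error probability

    def validate(self) -> None:
        if self.ancestral_length < 1:
            raise ConfigurationError("ancestral_length must be positive")
        if self.n_copies < 1:
            raise ConfigurationError("n_copies must be positive")
        if not 1 <= self.n_clones <= self.n_copies:
            raise ConfigurationError("need 1 <= n_clones <= n_copies")
        if self.sub_rate < 0 or self.indel_rate < 0:
            raise ConfigurationError("rates must be non-negative")
        if not 0.0 < self.indel_length_geometric_p <= 1.0:
            raise ConfigurationError("indel_length_geometric_p must be in (0, 1]")
        if not 0.0 <= self.homogenization_prob <= 1.0:
            raise ConfigurationError("homogenization_prob must be in [0, 1]")
        if self.homogenization_rounds < 0:
            raise ConfigurationError("homogenization_rounds must be non-negative")
        if not 0.0 <= self.clone_error_rate <= 1.0:
            raise ConfigurationError("clone_error_rate must be in [0, 1]")


@dataclass
class _Copy:
    """One array member: per-ancestral-position state plus insertions."""

    bases: list[str]  # length L; '-' marks a deleted ancestral position
    insertions: dict[int, str]  # after 1-based position (0 = before start)

    def clone(self) -> "_Copy":
        return _Copy(bases=list(self.bases), insertions=dict(self.insertions))

    def ungapped(self) -> str:
        parts = [self.insertions.get(0, "")]
        for pos, b in enumerate(self.bases, start=1):
            if b != "-":
                parts.append(b)
            parts.append(self.insertions.get(pos, ""))
        return "".join(parts)


@dataclass
class CloneTruth:
    """Exact pre-error differences of one sampled clone vs the ancestor."""

    clone_id: str
    copy_index: int
    substitutions: list[tuple[int, str, str]]  # (ancestral pos, from, to)
    deletions: list[tuple[int, int]]  # ancestral (start, end), inclusive
    insertions: list[tuple[int, str]]  # (after ancestral pos, bases)
    sequence_pre_error: str  # ungapped
    #: maximal gap runs of the clone's aligned row, in 1-based alignment
    #: columns (deleted ancestral positions plus unused insertion slots)
    alignment_gap_runs: list[tuple[int, int]]


@dataclass
class SimulatedLibrary:
    """A simulated clone library with full ground truth."""

    config: SimulationConfig
    ancestor: str
    true_copies: list[str]  # ungapped pre-error sequences of all copies
    clone_alignment: CloneAlignment  # sampled clones, errors applied
    truth: dict[str, CloneTruth]
    sampled_copy_indices: list[int]
    column_labels: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        """Stable serialization (used for determinism checks and the CLI)."""
        return json.dumps(
            {
                "config": vars(self.config),
                "ancestor": self.ancestor,
                "sampled_copy_indices": self.sampled_copy_indices,
                "clone_ids": self.clone_alignment.clone_ids,
                "rows": self.clone_alignment.rows,
                "column_labels": self.column_labels,
                "truth": {
                    cid: {
                        "copy_index": t.copy_index,
                        "substitutions": [list(s) for s in t.substitutions],
                        "deletions": [list(d) for d in t.deletions],
                        "insertions": [list(i) for i in t.insertions],
                        "sequence_pre_error": t.sequence_pre_error,
                        "alignment_gap_runs": [list(r) for r in t.alignment_gap_runs],
                    }
                    for cid, t in self.truth.items()
                },
            },
            indent=2,
        )


def _mutate_copy(copy: _Copy, cfg: SimulationConfig, rng: np.random.Generator) -> None:
    L = cfg.ancestral_length
    n_sub = rng.poisson(cfg.sub_rate)
    for _ in range(n_sub):
        pos = int(rng.integers(0, L))
        current = copy.bases[pos]
        alternatives = [b for b in _BASES if b != current]
        copy.bases[pos] = alternatives[int(rng.integers(0, 3))]
    n_indel = rng.poisson(cfg.indel_rate)
    for _ in range(n_indel):
        is_deletion = rng.random() < 0.5
        length = int(rng.geometric(cfg.indel_length_geometric_p))
        if is_deletion:
            start = int(rng.integers(1, L + 1))
            end = min(start + length - 1, L)
            for p in range(start - 1, end):
                copy.bases[p] = "-"
        else:
            after = int(rng.integers(0, L + 1))
            ins = "".join(_BASES[int(b)] for b in rng.integers(0, 4, size=length))
            copy.insertions[after] = copy.insertions.get(after, "") + ins


def _gap_runs_from_bool(gaps: list[bool]) -> list[tuple[int, int]]:
    runs, start = [], None
    for j, g in enumerate(gaps, start=1):
        if g and start is None:
            start = j
        elif not g and start is not None:
            runs.append((start, j - 1))
            start = None
    if start is not None:
        runs.append((start, len(gaps)))
    return runs


def simulate_library(config: SimulationConfig) -> SimulatedLibrary:
    """Run the full simulation pipeline; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.ancestral_length
    ancestor = "".join(_BASES[int(b)] for b in rng.integers(0, 4, size=L))

    copies = [_Copy(bases=list(ancestor), insertions={}) for _ in range(config.n_copies)]
    for copy in copies:
        _mutate_copy(copy, config, rng)

    for _ in range(config.homogenization_rounds):
        for i in range(config.n_copies):
            if rng.random() < config.homogenization_prob:
                donor = int(rng.integers(0, config.n_copies - 1))
                if donor >= i:
                    donor += 1  # uniform over the other copies
                copies[i] = copies[donor].clone()

    sampled = [int(i) for i in rng.choice(config.n_copies, size=config.n_clones, replace=False)]
    specimen = f"SIM{config.seed}"
    clone_ids = [f"{specimen}_#{k + 1:02d}" for k in range(config.n_clones)]

    # Column layout in the ancestral frame: every insertion slot used by a
    # sampled clone becomes a block of extra columns after its position.
    slot_width: dict[int, int] = {}
    for idx in sampled:
        for after, ins in copies[idx].insertions.items():
            slot_width[after] = max(slot_width.get(after, 0), len(ins))
    column_labels: list[str] = []
    layout: list[tuple[str, int, int]] = []  # ("anc", pos, 0) or ("ins", after, k)
    for k in range(slot_width.get(0, 0)):
        layout.append(("ins", 0, k))
        column_labels.append(f"0+{k + 1}")
    for pos in range(1, L + 1):
        layout.append(("anc", pos, 0))
        column_labels.append(str(pos))
        for k in range(slot_width.get(pos, 0)):
            layout.append(("ins", pos, k))
            column_labels.append(f"{pos}+{k + 1}")

    def aligned_row(copy: _Copy) -> str:
        out = []
        for kind, pos, k in layout:
            if kind == "anc":
                out.append(copy.bases[pos - 1])
            else:
                ins = copy.insertions.get(pos, "")
                out.append(ins[k] if k < len(ins) else "-")
        return "".join(out)

    truth: dict[str, CloneTruth] = {}
    rows = []
    for cid, idx in zip(clone_ids, sampled):
        copy = copies[idx]
        subs = [
            (p + 1, ancestor[p], copy.bases[p])
            for p in range(L)
            if copy.bases[p] != "-" and copy.bases[p] != ancestor[p]
        ]
        dels = _gap_runs_from_bool([b == "-" for b in copy.bases])
        gaps = []
        for kind, pos, k in layout:
            if kind == "anc":
                gaps.append(copy.bases[pos - 1] == "-")
            else:
                gaps.append(k >= len(copy.insertions.get(pos, "")))
        truth[cid] = CloneTruth(
            clone_id=cid,
            copy_index=idx,
            substitutions=subs,
            deletions=dels,
            insertions=sorted(copy.insertions.items()),
            sequence_pre_error=copy.ungapped(),
            alignment_gap_runs=_gap_runs_from_bool(gaps),
        )
        # per-base clone error (substitutions only, applied to residues)
        row = list(aligned_row(copy))
        if config.clone_error_rate > 0:
            for j, sym in enumerate(row):
                if sym != "-" and rng.random() < config.clone_error_rate:
                    alternatives = [b for b in _BASES if b != sym]
                    row[j] = alternatives[int(rng.integers(0, 3))]
        rows.append("".join(row))

    aln = CloneAlignment(
        specimen_id=specimen,
        clone_ids=clone_ids,
        rows=rows,
        column_labels=column_labels,
    )
    return SimulatedLibrary(
        config=config,
        ancestor=ancestor,
        true_copies=[c.ungapped() for c in copies],
        clone_alignment=aln,
        truth=truth,
        sampled_copy_indices=sampled,
        column_labels=column_labels,
    )


def apply_truth(ancestor: str, t: CloneTruth) -> str:
    """Re-derive a clone's pre-error ungapped sequence from its truth record.

    Used to verify that the truth exactly explains each clone: the result
    must equal ``t.sequence_pre_error``.
    """
    bases = list(ancestor)
    for pos, _from, to in t.substitutions:
        bases[pos - 1] = to
    for start, end in t.deletions:
        for p in range(start - 1, end):
            bases[p] = "-"
    ins = dict(t.insertions)
    parts = [ins.get(0, "")]
    for pos, b in enumerate(bases, start=1):
        if b != "-":
            parts.append(b)
        parts.append(ins.get(pos, ""))
    return "".join(parts)


def recovery_report(lib: SimulatedLibrary) -> pd.DataFrame:
    """Detected vs true variation on the simulated clone alignment.

    Runs the variable-column scanner and raw-mode event detector on the
    clone alignment and scores them against the simulation truth with
    exact-coordinate matching.  The mean pairwise p-distance (indel-event
    policy) is attached as ``df.attrs["mean_p_distance"]``.
    """
    from .distance import distance_matrix, diversity_summary
    from .variation import detect_indel_events, scan_columns

    aln = lib.clone_alignment
    detected_sub_cols = {
        p.column for p in scan_columns(aln) if p.n_base_states >= 2
    }
    # truth: columns where pre-error states of sampled clones show >= 2 bases
    n_cols = aln.n_columns
    true_sub_cols = set()
    for j in range(n_cols):
        states = set()
        for cid in aln.clone_ids:
            t = lib.truth[cid]
            # reconstruct the pre-error symbol at column j from truth
            sym = _pre_error_symbol(lib, cid, j)
            if sym != "-":
                states.add(sym)
        if len(states) >= 2:
            true_sub_cols.add(j + 1)

    detected_events = {
        (e.start, e.end) for e in detect_indel_events(aln, mode="raw")
    }
    true_events = {
        run for t in lib.truth.values() for run in t.alignment_gap_runs
    }

    def _row(true_set, det_set):
        tp = len(true_set & det_set)
        precision = tp / len(det_set) if det_set else 1.0
        recall = tp / len(true_set) if true_set else 1.0
        return {
            "n_true": len(true_set),
            "n_detected": len(det_set),
            "n_matched": tp,
            "precision": precision,
            "recall": recall,
        }

    df = pd.DataFrame(
        [_row(true_sub_cols, detected_sub_cols), _row(true_events, detected_events)],
        index=["substitution_sites", "indel_events"],
    )
    if aln.n_clones >= 2:
        div = diversity_summary(distance_matrix(aln, policy="indel-event"))
        df.attrs["mean_p_distance"] = div.mean_p
    return df


def _pre_error_symbol(lib: SimulatedLibrary, clone_id: str, col0: int) -> str:
    """Pre-error aligned symbol of a clone at 0-based column ``col0``."""
    label = lib.column_labels[col0]
    t = lib.truth[clone_id]
    ins = dict(t.insertions)
    if "+" in label:
        after, k = label.split("+")
        s = ins.get(int(after), "")
        k = int(k) - 1
        return s[k] if k < len(s) else "-"
    pos = int(label)
    for start, end in t.deletions:
        if start <= pos <= end:
            return "-"
    for p, _from, to in t.substitutions:
        if p == pos:
            return to
    return lib.ancestor[pos - 1]
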