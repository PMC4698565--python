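"""Idealized direct-sequencing traces of a mixed multicopy template.

When a multicopy locus is PCR-amplified and sequenced directly, every
genomic variant contributes to the chromatogram in proportion to its
abundance.  Two signatures distinguish the kinds of intragenomic
variation: an isolated *double peak* at a substitution site, and a
*persistent series of mixed peaks* downstream of an indel, where
length-shifted variants read out of register for the rest of the trace.

This module superposes variants into per-position base-fraction vectors
(idealized peak heights; no chromatogram noise model) and calls those two
signatures.  Positions are ungapped reading coordinates, as a sequencer
reads them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import AlphabetError, ConfigurationError, InputError

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"

#: IUPAC code for each non-empty set of bases.
IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass
class TraceProfile:
    """Per-position base-fraction vectors of a superposed trace.

    ``signal[p - 1]`` is the (A, C, G, T) fraction vector at reading
    position ``p``; each vector sums to 1.
    """

    signal: np.ndarray  # (L, 4), rows sum to 1
    weights: np.ndarray  # per-variant relative abundances, sum to 1

    @property
    def n_positions(self) -> int:
        return int(self.signal.shape[0])

    def fractions(self, position: int) -> dict[str, float]:
        """Base fractions at a 1-based reading position."""
        row = self.signal[position - 1]
        return {b: float(row[i]) for b, i in _BASE_INDEX.items()}


@dataclass
class HeterogeneityCall:
    """Mixed positions and (optionally) an indel breakpoint."""

    #: (1-based position, IUPAC code of the bases above threshold)
    het_positions: list[tuple[int, str]]
    breakpoint: int | None
    #: fraction of positions >= breakpoint that are mixed (0.0 if none)
    downstream_mixed_fraction: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "het_positions": [[p, c] for p, c in self.het_positions],
                "breakpoint": self.breakpoint,
                "downstream_mixed_fraction": self.downstream_mixed_fraction,
            },
            indent=2,
        )


def superpose_variants(variants: list[str], weights=None) -> TraceProfile:
    """Superpose ungapped variant sequences into a trace profile.

    Position ``p`` receives the weighted base frequencies across variants;
    variants shorter than ``p`` contribute nothing there and the remaining
    weight is renormalized.  Variants may differ in length; the profile
    spans the longest one.
    """
    if not variants:
        raise InputError("no variants to superpose")
    variants = [v.upper() for v in variants]
    for v in variants:
        bad = set(v) - set(_BASES)
        if bad:
            raise AlphabetError(f"variants must be ungapped A/C/G/T; found {bad}")
    if weights is None:
        w = np.full(len(variants), 1.0 / len(variants))
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.shape != (len(variants),):
            raise InputError(f"{w.size} weights for {len(variants)} variants")
        if np.any(w < 0) or w.sum() <= 0:
            raise InputError("weights must be non-negative with positive sum")
        w = w / w.sum()
    L = max(len(v) for v in variants)
    signal = np.zeros((L, 4))
    for v, wi in zip(variants, w):
        for p, base in enumerate(v):
            signal[p, _BASE_INDEX[base]] += wi
    totals = signal.sum(axis=1, keepdims=True)
    signal /= totals  # every position is covered by the longest variant
    return TraceProfile(signal=signal, weights=w)


def call_heterogeneity(
    profile: TraceProfile,
    secondary_threshold: float = 0.25,
    persistence: float = 0.6,
    min_mixed_run: int = 3,
) -> HeterogeneityCall:
    """Call double peaks and an indel breakpoint on a trace profile.

    A position is *mixed* iff its second-largest base fraction reaches
    ``secondary_threshold``; its IUPAC code combines all bases at or above
    the threshold.  The *breakpoint* is the first mixed position from
    which at least ``persistence`` of the remaining positions are mixed
    (and at least ``min_mixed_run`` of them, so a double peak at the very
    end of a read is not mistaken for frame-shift mixing).  Isolated mixed
    positions appear only in ``het_positions``.
    """
    if not 0.0 < secondary_threshold <= 0.5:
        raise ConfigurationError(
            f"secondary_threshold must be in (0, 0.5], got {secondary_threshold}"
        )
    if not 0.0 < persistence <= 1.0:
        raise ConfigurationError(f"persistence must be in (0, 1], got {persistence}")
    sig = profile.signal
    sorted_sig = np.sort(sig, axis=1)
    mixed = sorted_sig[:, -2] >= secondary_threshold
    het_positions = []
    for p in np.flatnonzero(mixed):
        bases = frozenset(_BASES[i] for i in range(4) if sig[p, i] >= secondary_threshold)
        het_positions.append((int(p) + 1, IUPAC[bases]))
    breakpoint = None
    downstream = 0.0
    n = mixed.size
    # suffix counts of mixed positions, scanned in one pass
    suffix_mixed = np.cumsum(mixed[::-1])[::-1]
    for p in np.flatnonzero(mixed):
        n_tail = n - p
        frac = suffix_mixed[p] / n_tail
        if frac >= persistence and suffix_mixed[p] >= min_mixed_run:
            breakpoint = int(p) + 1
            downstream = float(frac)
            break
    return HeterogeneityCall(
        het_positions=het_positions,
        breakpoint=breakpoint,
        downstream_mixed_fraction=downstream,
    )
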