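"""Isoform sequence comparison for interface loops: fraction of mutated
positions, fraction with different physicochemical class, and
class-composition tallies, under the three-axis residue classification
(charge / polarity / hydropathy) of Pommie et al.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .tables import CLASS_AXES

ALL_AXES = tuple(CLASS_AXES)


@dataclass(frozen=True)
class PositionReport:
    position: int                     # 1-based within the compared range
    residue_a: str
    residue_b: str
    mutated: bool
    differing_axes: tuple[str, ...]   # subset of charge/polarity/hydropathy


@dataclass
class RangeComparison:
    fraction_mutated: float
    fraction_class_different: float
    positions: list[PositionReport]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "position": p.position, "residue_a": p.residue_a,
            "residue_b": p.residue_b, "mutated": p.mutated,
            "differing_axes": ",".join(p.differing_axes),
        } for p in self.positions])


def residue_classes(aa: str) -> dict[str, str]:
    """Class on each axis for a one-letter residue code."""
    aa = aa.upper()
    out = {}
    for axis, table in CLASS_AXES.items():
        if aa not in table:
            raise KeyError(f"nonstandard residue {aa!r}")
        out[axis] = table[aa]
    return out


def compare_ranges(seq_a: str, seq_b: str,
                   ranges: Sequence[tuple[int, int]] | None = None,
                   axes: Sequence[str] = ALL_AXES,
                   require_all_axes: bool = False) -> RangeComparison:
    """Position-by-position comparison of aligned ranges of two sequences.

    ``ranges`` are 1-based inclusive (start, end) pairs applied to both
    sequences; by default the full (equal-length) sequences.  A position
    is *mutated* when the residues differ and *class-different* when they
    additionally differ on at least one classification axis (all axes if
    ``require_all_axes``) — the operational reading of "significantly
    different physicochemical properties".
    """
    if ranges is None:
        if len(seq_a) != len(seq_b):
            raise ValueError(
                f"sequence lengths differ ({len(seq_a)} vs {len(seq_b)}); "
                "supply aligned ranges or align first")
        ranges = [(1, len(seq_a))]
    reports: list[PositionReport] = []
    for start, end in ranges:
        if not (1 <= start <= end <= min(len(seq_a), len(seq_b))):
            raise ValueError(f"range ({start}, {end}) outside both sequences")
        for pos in range(start, end + 1):
            a, b = seq_a[pos - 1].upper(), seq_b[pos - 1].upper()
            mutated = a != b
            differing = ()
            if mutated:
                ca, cb = residue_classes(a), residue_classes(b)
                differing = tuple(ax for ax in axes if ca[ax] != cb[ax])
            reports.append(PositionReport(pos, a, b, mutated, differing))
    n = len(reports)
    n_mut = sum(p.mutated for p in reports)
    if require_all_axes:
        n_class = sum(len(p.differing_axes) == len(tuple(axes))
                      for p in reports if p.mutated)
    else:
        n_class = sum(bool(p.differing_axes) for p in reports)
    return RangeComparison(fraction_mutated=n_mut / n,
                           fraction_class_different=n_class / n,
                           positions=reports)


@dataclass
class Composition:
    length: int
    counts: dict[str, dict[str, int]]           # axis -> class -> count
    nonstandard: int

    def fraction(self, axis: str, cls: str) -> float:
        return self.counts[axis].get(cls, 0) / self.length


def composition_enrichment(seq: str) -> Composition:
    """Counts and fractions of charged / polar / hydrophilic (and the
    other classes) in a sequence; per-axis counts sum to the number of
    standard residues."""
    if not seq:
        raise ValueError("empty sequence")
    counts = {axis: {} for axis in CLASS_AXES}
    nonstandard = 0
    n_standard = 0
    for aa in seq.upper():
        if aa not in CLASS_AXES["charge"]:
            nonstandard += 1
            continue
        n_standard += 1
        for axis, table in CLASS_AXES.items():
            cls = table[aa]
            counts[axis][cls] = counts[axis].get(cls, 0) + 1
    if n_standard == 0:
        raise ValueError("no standard residues in sequence")
    return Composition(length=n_standard, counts=counts,
                       nonstandard=nonstandard)


def align_global(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global alignment (BLOSUM62, affine gaps) returning the two gapped
    sequences — a utility for mapping loop positions between isoforms
    when a pre-mapped correspondence is not supplied."""
    from Bio import Align
    from Bio.Align import substitution_matrices
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    aln = aligner.align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])
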