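"""From docked poses to contiguous interacting segments.

A cargo residue is part of the binding interface when it has at least
one receptor contact within the cutoff. Marked runs separated by short
unmarked gaps are merged, short leftovers dropped, and the survivors
reported in source numbering, the convention used for interface
peptides like ^166^MRHLPSMRYTPVGRSFFT^183^.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import ValidationError
from .scoring_engine import DockingResult
from .structures_io import CoarseStructure


@dataclass
class InterfaceSegment:
    protein_id: str
    start: int            # source numbering, 1-based inclusive
    end: int
    sequence: str
    mean_residue_energy: float

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError("segment start after end")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValidationError("segment sequence/span length mismatch")

    def render(self) -> str:
        """Superscript-style text form, e.g. ``^166^MRHL...^183^``."""
        return f"^{self.start}^{self.sequence}^{self.end}^"


def extract_interface(result: DockingResult, cargo: CoarseStructure,
                      cutoff: float = 6.5, max_gap: int = 2,
                      min_len: int = 5) -> list[InterfaceSegment]:
    """Contiguous interacting segments of a docked cargo.

    ``result`` must come from docking this cargo; peptide positions in
    its contact list index the cargo's bead order.
    """
    if len(result.per_residue) != len(cargo):
        raise ValidationError("docking result does not match this cargo")
    marked = sorted({p - 1 for p, _, d in result.contacts if d <= cutoff})
    if not marked:
        return []
    runs: list[list[int]] = [[marked[0], marked[0]]]
    for p in marked[1:]:
        if p - runs[-1][1] - 1 <= max_gap:
            runs[-1][1] = p
        else:
            runs.append([p, p])
    segments = []
    for lo, hi in runs:
        if hi - lo + 1 < min_len:
            continue
        beads = cargo.beads[lo:hi + 1]
        energies = result.per_residue[lo:hi + 1]
        segments.append(InterfaceSegment(
            protein_id=cargo.id,
            start=beads[0].residue_index,
            end=beads[-1].residue_index,
            sequence="".join(b.amino_acid for b in beads),
            mean_residue_energy=float(sum(energies) / len(energies))))
    return segments


def map_receptor_contacts(results: list[DockingResult],
                          receptor: CoarseStructure) -> Counter:
    """Histogram of contact occurrences per receptor bead index."""
    hist: Counter = Counter()
    for res in results:
        for _, ridx, _ in res.contacts:
            if not 0 <= ridx < len(receptor):
                raise ValidationError(
                    "docking result references a different receptor")
            hist[ridx] += 1
    return hist
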