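"""Ungapped alignment of minimal peptides and degenerate consensus calls.

Minimal binding peptides recovered from different cargoes are short,
near-exact repeats of one motif, so a center-star, ungapped alignment
against the longest peptide suffices. Each alignment column is reduced
to a single residue, a degenerate set rendered ``(A/B)``, or a wildcard,
the notation used for karyopherin recognition motifs such as
``EKRKI(E/R)(K/L/R/S/T)``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import ParseError, ValidationError
from .structures_io import CANONICAL

GAP = "-"
WILDCARD = "X"
DEFAULT_MAX_DEGENERATE = 6


@dataclass
class AlignmentRow:
    peptide_id: str
    sequence: str
    offset: int


@dataclass
class PeptideAlignment:
    reference_id: str
    rows: list[AlignmentRow]

    @property
    def span(self) -> tuple[int, int]:
        lo = min(r.offset for r in self.rows)
        hi = max(r.offset + len(r.sequence) for r in self.rows)
        return lo, hi

    @property
    def n_columns(self) -> int:
        lo, hi = self.span
        return hi - lo

    def padded_rows(self) -> list[tuple[str, str]]:
        """Rows padded with gap characters to the common span."""
        lo, hi = self.span
        out = []
        for r in self.rows:
            left = r.offset - lo
            right = hi - (r.offset + len(r.sequence))
            out.append((r.peptide_id, GAP * left + r.sequence + GAP * right))
        return out

    def column(self, j: int) -> Counter:
        lo, _ = self.span
        counts: Counter = Counter()
        for r in self.rows:
            i = lo + j - r.offset
            if 0 <= i < len(r.sequence):
                counts[r.sequence[i]] += 1
        return counts


@dataclass
class ConsensusPosition:
    freqs: dict[str, int]
    support: int
    call: frozenset[str]      # singleton, degenerate set, or all-20 wildcard


@dataclass
class ConsensusMotif:
    positions: list[ConsensusPosition] = field(default_factory=list)

    @property
    def render(self) -> str:
        return render_motif([p.call for p in self.positions])

    def __len__(self) -> int:
        return len(self.positions)


def _identity(ref: str, seq: str, offset: int) -> int:
    return sum(1 for i, ch in enumerate(seq)
               if 0 <= offset + i < len(ref) and ref[offset + i] == ch)


def align_peptides(peptides: list[tuple[str, str]]) -> PeptideAlignment:
    """Center-star ungapped alignment.

    The reference is the longest sequence (ties: lexicographically
    smallest sequence, then smallest id); every other peptide is placed
    at the integer offset maximizing identity to the reference, smallest
    offset on ties. Offsets may be negative; overhangs become gap
    columns. Input order never affects the result.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValidationError("no peptides to align")
    for pid, seq in peptides:
        if not seq:
            raise ValidationError(f"peptide {pid!r} is empty")
    ref_id, ref = min(peptides, key=lambda p: (-len(p[1]), p[1], p[0]))
    rows = []
    for pid, seq in peptides:
        if pid == ref_id and seq == ref:
            rows.append(AlignmentRow(pid, seq, 0))
            continue
        best = None
        for off in range(-(len(seq) - 1), len(ref)):
            score = _identity(ref, seq, off)
            if best is None or score > best[0]:
                best = (score, off)
        rows.append(AlignmentRow(pid, seq, best[1]))
    return PeptideAlignment(reference_id=ref_id, rows=rows)


def call_consensus(alignment: PeptideAlignment, majority: float = 0.5,
                   degenerate_cum: float = 0.7, min_coverage: float = 0.5,
                   max_degenerate: int = DEFAULT_MAX_DEGENERATE
                   ) -> ConsensusMotif:
    """Reduce each column to a single/degenerate/wildcard call.

    A residue with frequency strictly above ``majority`` is called
    alone; otherwise the smallest most-frequent set reaching cumulative
    frequency ``degenerate_cum`` is called degenerate (rendered
    ``(A/B)``), unless it needs more than ``max_degenerate`` residues,
    which yields a wildcard. Leading and trailing columns supported by
    fewer than ``min_coverage`` of the peptides are trimmed.
    """
    n_pep = len(alignment.rows)
    cols = [alignment.column(j) for j in range(alignment.n_columns)]
    keep = [j for j, c in enumerate(cols)
            if sum(c.values()) >= min_coverage * n_pep]
    if not keep:
        return ConsensusMotif(positions=[])
    positions = []
    for j in range(min(keep), max(keep) + 1):
        counts = cols[j]
        support = sum(counts.values())
        if support == 0:
            positions.append(ConsensusPosition({}, 0, frozenset(CANONICAL)))
            continue
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        top_res, top_n = ranked[0]
        if top_n / support > majority:
            call = frozenset({top_res})
        else:
            cum, chosen = 0, []
            for res, n in ranked:
                chosen.append(res)
                cum += n
                if cum / support >= degenerate_cum:
                    break
            call = (frozenset(chosen) if len(chosen) <= max_degenerate
                    else frozenset(CANONICAL))
        positions.append(ConsensusPosition(dict(counts), support, call))
    return ConsensusMotif(positions=positions)


# -- degenerate motif strings ---------------------------------------------

def parse_motif(text: str) -> list[frozenset[str]]:
    """Parse a degenerate motif string like ``KP(K/Y)LV`` to position sets."""
    if not text:
        raise ParseError("empty motif string")
    out: list[frozenset[str]] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "(":
            end = text.find(")", i)
            if end == -1:
                raise ParseError(f"unbalanced parenthesis at position {i}")
            letters = text[i + 1:end].split("/")
            if not letters or any(not l for l in letters):
                raise ParseError(f"empty group member at position {i}")
            for l in letters:
                if len(l) != 1 or l not in CANONICAL:
                    raise ParseError(
                        f"illegal residue {l!r} in group at position {i}")
            out.append(frozenset(letters))
            i = end + 1
        elif ch == WILDCARD:
            out.append(frozenset(CANONICAL))
            i += 1
        elif ch in CANONICAL:
            out.append(frozenset({ch}))
            i += 1
        else:
            raise ParseError(f"illegal character {ch!r} at position {i}")
    return out


def render_motif(position_sets) -> str:
    """Inverse of :func:`parse_motif` (groups alphabetical)."""
    parts = []
    for s in position_sets:
        s = frozenset(s)
        if not s:
            raise ValidationError("empty position set")
        if s == frozenset(CANONICAL):
            parts.append(WILDCARD)
        elif len(s) == 1:
            parts.append(next(iter(s)))
        else:
            parts.append("(" + "/".join(sorted(s)) + ")")
    return "".join(parts)
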