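"""Sliding-window scan of protein sequences for degenerate NLS motifs.

Ships the catalog of published karyopherin recognition motifs: the
importin-8 motif RRKLPVGRS, the importin-7 motif EKRKI(E/R)(K/L/R/S/T),
the importin-4 and -5 motifs LPPRS(G/P)P and KP(K/Y)LV, and the
classical importin-α motif KKKRK. Scoring is per position: 1.0 for a
residue in the position set, and (in class-aware mode) 0.5 for a
residue of the same physicochemical class as some member of the set.
"""

from __future__ import annotations

from dataclasses import dataclass

from .consensus_motif import parse_motif
from .errors import ValidationError
from .structures_io import CLASS_OF

#: Published recognition motifs, by importin.
CATALOG = {
    "NLS8": "RRKLPVGRS",
    "NLS7": "EKRKI(E/R)(K/L/R/S/T)",
    "NLS4": "LPPRS(G/P)P",
    "NLS5": "KP(K/Y)LV",
    "NLSalpha": "KKKRK",
}
_ALIASES = {"NLSα": "NLSalpha", "NLSA": "NLSalpha"}

DEFAULT_THRESHOLD = 6.0
CLASS_CREDIT = 0.5


@dataclass
class MotifMatch:
    protein_id: str
    start: int          # 1-based window start
    window: str
    score: float
    max_score: float


def catalog_motif(name: str) -> list[frozenset[str]]:
    """Look up a catalog motif by name, or parse a raw motif string."""
    key = _ALIASES.get(name, name)
    if key in CATALOG:
        return parse_motif(CATALOG[key])
    return parse_motif(name)


def _position_score(residue: str, pos_set: frozenset[str],
                    class_aware: bool, class_credit: float) -> float:
    if residue in pos_set:
        return 1.0
    if class_aware and residue in CLASS_OF:
        if CLASS_OF[residue] in {CLASS_OF[r] for r in pos_set}:
            return class_credit
    return 0.0


def scan_sequences(records, motif, mode: str = "identity",
                   threshold: float = DEFAULT_THRESHOLD,
                   class_credit: float = CLASS_CREDIT) -> list[MotifMatch]:
    """Slide the motif over every sequence and report scoring windows.

    ``records`` is an iterable of ``(protein_id, sequence)``. Windows
    with score >= threshold are returned sorted by descending score,
    then (protein_id, start). Overlapping matches are all reported.
    """
    if mode not in ("identity", "class_aware"):
        raise ValidationError(f"unknown scan mode {mode!r}")
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    if isinstance(motif, str):
        motif = catalog_motif(motif)
    L = len(motif)
    class_aware = mode == "class_aware"
    matches = []
    for pid, seq in records:
        for start in range(0, len(seq) - L + 1):
            window = seq[start:start + L]
            score = sum(_position_score(window[i], motif[i],
                                        class_aware, class_credit)
                        for i in range(L))
            if score >= threshold:
                matches.append(MotifMatch(
                    protein_id=pid, start=start + 1, window=window,
                    score=float(score), max_score=float(L)))
    matches.sort(key=lambda m: (-m.score, m.protein_id, m.start))
    return matches


def best_identity(motif_string: str, target_string: str):
    """Maximum exact-match count over all ungapped relative offsets.

    Partial overlaps are allowed; returns ``(best_score, offset)`` with
    the smallest offset on ties, where ``offset`` is the shift of the
    target along the motif.
    """
    if not motif_string or not target_string:
        raise ValidationError("both strings must be non-empty")
    lm, lt = len(motif_string), len(target_string)
    best_score, best_off = -1, None
    for off in range(-(lt - 1), lm):
        score = sum(1 for i in range(lm)
                    if 0 <= i - off < lt
                    and motif_string[i] == target_string[i - off])
        if score > best_score:
            best_score, best_off = score, off
    return best_score, best_off
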