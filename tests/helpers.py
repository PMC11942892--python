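"""Shared test utilities: random instances and independent oracles.

The docking oracle here is a deliberately plain triple loop over the
pose space (anchors x orientations x anchored residue), scoring each
pose with the public energy function. It shares none of the line-grid
or windowed-sum machinery of the production search, so agreement is a
meaningful cross-check.
"""

from __future__ import annotations

import numpy as np

from nlskit import CoarseStructure, ResidueBead, interaction_energy
from nlskit.scoring_engine import fibonacci_sphere
from nlskit.structures_io import CA_SPACING, CLASS_OF

AA20 = "ARNDCQEGHILKMFPSTWYV"


def random_receptor(rng, n_beads, box=8.0, id="rand"):
    beads = []
    for i in range(n_beads):
        aa = AA20[rng.integers(20)]
        beads.append(ResidueBead(
            chain_id="A", residue_index=i + 1, amino_acid=aa,
            res_class=CLASS_OF[aa],
            coordinate=tuple(rng.uniform(-box, box, 3)),
            weight=float(rng.uniform(0.5, 3.0))))
    return CoarseStructure(id=id, beads=beads)


def random_sequence(rng, length):
    return "".join(AA20[rng.integers(20)] for _ in range(length))


def oracle_dock(receptor, sequence, n_dir=64, stand_off=4.0):
    """Exhaustive plain-loop docking enumeration (no refinement).

    Returns the lexicographically first (energy, anchor, direction,
    anchor_residue) tuple over the whole pose space.
    """
    coords = receptor.coords
    centroid = coords.mean(axis=0)
    rel = coords - centroid
    norms = np.linalg.norm(rel, axis=1)
    by_dist = sorted(range(len(coords)), key=lambda j: (-norms[j], j))
    canon = fibonacci_sphere(n_dir)
    L = len(sequence)
    js = np.arange(L, dtype=float)
    best = None
    for i in range(len(coords)):
        n = (rel[i] / norms[i] if norms[i] > 1e-9
             else np.array([1.0, 0.0, 0.0]))
        t1 = None
        for j in by_dist:
            c = rel[j] - np.dot(rel[j], n) * n
            if np.linalg.norm(c) > 1e-6:
                t1 = c / np.linalg.norm(c)
                break
        if t1 is None:
            e = np.eye(3)[np.argmin(np.abs(n))]
            c = e - np.dot(e, n) * n
            t1 = c / np.linalg.norm(c)
        t2 = np.cross(n, t1)
        base = coords[i] + stand_off * n
        for k in range(n_dir):
            u = canon[k, 0] * t1 + canon[k, 1] * t2 + canon[k, 2] * n
            for a in range(1, L + 1):
                pc = (base[None, :]
                      + CA_SPACING * (js - (a - 1))[:, None] * u[None, :])
                e, _, _ = interaction_energy(receptor, pc, sequence)
                key = (e, i, k, a)
                if best is None or key < best:
                    best = key
    return best


def planted_segment(cohort, cargo_index, flank=3):
    """Ground-truth interface segment: planted motif with short flanks."""
    from nlskit.interface_mapper import InterfaceSegment

    cargo = cohort.cargoes[cargo_index]
    start = cohort.truth.motif_starts[cargo.id]
    lm = len(cohort.truth.motif)
    seg_start = start - flank
    seg_end = start + lm - 1 + flank
    seq = cargo.sequence[seg_start - 1:seg_end]
    return InterfaceSegment(protein_id=cargo.id, start=seg_start,
                            end=seg_end, sequence=seq,
                            mean_residue_energy=0.0)


def consensus_match_count(consensus, planted_motif):
    """Best ungapped agreement between a consensus and the planted motif.

    A position counts as matching when the planted residue is in the
    consensus call set at that aligned position; the offset maximizing
    the count is used.
    """
    calls = [p.call for p in consensus.positions]
    lm, lc = len(planted_motif), len(calls)
    best = 0
    for off in range(-(lc - 1), lm):
        n = sum(1 for i in range(lm)
                if 0 <= i - off < lc and planted_motif[i] in calls[i - off])
        best = max(best, n)
    return best
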