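"""Seeded receptor/cargo cohorts with a planted recognition motif.

The generator emulates the study geometry this pipeline assumes: a
receptor whose surface carries a contiguous groove complementary to one
short linear motif, and cargo proteins carrying that motif embedded in
weakly-binding flanks. Groove sites carry a large weight so that each
motif residue contributes a large favorable increment to the docked
score — removal of a single charged motif residue costs more than the
jump threshold — while flank residues contribute little. Every output
is a pure function of (spec, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .consensus_motif import parse_motif
from .errors import ValidationError
from .scoring_engine import fibonacci_sphere
from .structures_io import (
    CA_SPACING, CLASS_OF, MEMBERS_OF, CoarseStructure, ResidueBead,
    build_extended_peptide, write_fasta, write_pdb,
)

#: Class of the groove site placed opposite each motif residue class.
COMPLEMENT = {"POS": "NEG", "NEG": "POS", "HPH": "HPH",
              "POL": "POL", "SPC": "POL"}
#: Residue used to represent a groove site of each class.
REPRESENTATIVE = {"NEG": "D", "POS": "K", "HPH": "L", "POL": "S"}

CHARGED = ("D", "E", "H", "K", "R")
FLANK_ALPHABET = tuple(sorted(MEMBERS_OF["POL"] + MEMBERS_OF["HPH"]))

_STREAM = {"receptor": 0, "cargo": 1, "decoy": 2, "groove": 3}


@dataclass
class SyntheticSpec:
    motif: str = "RRKLPVGRS"
    groove_weight: float = 30.0
    n_cargoes: int = 8
    cargo_length: int = 40
    flank_charge_rate: float = 0.02
    motif_noise: float = 0.0
    n_decoy_receptors: int = 3
    n_receptor_beads: int = 150
    receptor_radius: float = 20.0
    seed: int = 0

    def __post_init__(self):
        parse_motif(self.motif)  # validates the alphabet
        if self.cargo_length < len(self.motif) + 6:
            raise ValidationError(
                "cargo_length must be at least motif length + 6")
        for p in (self.flank_charge_rate, self.motif_noise):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must be in [0, 1]")


@dataclass
class GroundTruth:
    motif: str
    motif_starts: dict[str, int]          # cargo id -> 1-based start
    realized_motifs: dict[str, str]       # after same-class noise
    groove_indices: list[int]             # receptor bead indices, site order
    decoy_ids: list[str]
    spec: SyntheticSpec


@dataclass
class Cohort:
    receptor: CoarseStructure
    decoys: list[CoarseStructure]
    cargoes: list[CoarseStructure]
    truth: GroundTruth


def _rng(spec: SyntheticSpec, purpose: str, index: int = 0):
    return np.random.default_rng(
        [int(spec.seed), _STREAM[purpose], int(index)])


def groove_site_classes(motif: str) -> list[str]:
    return [COMPLEMENT[CLASS_OF[aa]] for aa in motif]


def _groove_geometry(spec: SyntheticSpec):
    """Collinear groove site coordinates tangent to the receptor sphere."""
    rng = _rng(spec, "groove")
    c = rng.normal(size=3)
    c /= np.linalg.norm(c)
    t = rng.normal(size=3)
    t -= np.dot(t, c) * c
    t /= np.linalg.norm(t)
    L = len(spec.motif)
    offsets = (np.arange(L) - (L - 1) / 2.0) * CA_SPACING
    sites = spec.receptor_radius * c[None, :] + offsets[:, None] * t[None, :]
    return sites, c, t


def make_receptor(spec: SyntheticSpec):
    """Receptor lattice sphere with the complementary groove planted.

    Returns ``(structure, groove_indices)`` where the indices list the
    lattice beads replaced by groove sites, in motif-position order.
    Groove sites lie on a straight 3.8 Å-spaced line tangent to the
    sphere (a convex patch: a rigid straight peptide can reach it).
    """
    rng = _rng(spec, "receptor")
    coords = fibonacci_sphere(spec.n_receptor_beads) * spec.receptor_radius
    classes = [("POL", "HPH")[rng.integers(2)]
               for _ in range(spec.n_receptor_beads)]
    aas = [MEMBERS_OF[c][rng.integers(len(MEMBERS_OF[c]))] for c in classes]
    sites, _, _ = _groove_geometry(spec)
    site_classes = groove_site_classes(spec.motif)
    used: set[int] = set()
    groove_indices: list[int] = []
    for p, site in enumerate(sites):
        d = np.linalg.norm(coords - site[None, :], axis=1)
        d[list(used)] = np.inf
        idx = int(np.argmin(d))
        used.add(idx)
        groove_indices.append(idx)
        coords[idx] = site
        classes[idx] = site_classes[p]
        aas[idx] = REPRESENTATIVE[site_classes[p]]
    beads = [ResidueBead(chain_id="A", residue_index=i + 1,
                         amino_acid=aas[i], res_class=classes[i],
                         coordinate=tuple(map(float, coords[i])),
                         weight=(spec.groove_weight if i in used else 1.0))
             for i in range(spec.n_receptor_beads)]
    structure = CoarseStructure(id="receptor", beads=beads,
                                provenance=f"synthetic:seed={spec.seed}")
    return structure, groove_indices


def make_decoy(spec: SyntheticSpec, receptor: CoarseStructure,
               groove_indices: list[int], index: int) -> CoarseStructure:
    """Decoy receptor: same lattice, groove classes derangement-shuffled.

    Every groove position gets a class different from the true groove's
    class at that position, so the groove is still there (same weights,
    same geometry) but no longer complementary to the planted motif.
    """
    rng = _rng(spec, "decoy", index)
    true_classes = [receptor.beads[i].res_class for i in groove_indices]
    L = len(true_classes)
    shuffled = None
    for _ in range(1000):
        perm = rng.permutation(L)
        cand = [true_classes[p] for p in perm]
        if all(a != b for a, b in zip(cand, true_classes)):
            shuffled = cand
            break
    if shuffled is None:
        raise ValidationError("could not derange groove classes")
    beads = list(receptor.beads)
    for pos, idx in enumerate(groove_indices):
        b = beads[idx]
        aa = REPRESENTATIVE[shuffled[pos]]
        beads[idx] = dataclasses.replace(
            b, amino_acid=aa, res_class=shuffled[pos])
    return CoarseStructure(id=f"decoy_{index}", beads=beads,
                           provenance=f"synthetic:decoy:seed={spec.seed}")


def make_cargo(spec: SyntheticSpec, index: int):
    """One cargo: flank + motif (with same-class noise) + flank.

    Returns ``(structure, motif_start)`` with a 1-based start drawn
    uniformly so at least 3 flank residues surround the motif. The
    structure is an idealized extended chain.
    """
    rng = _rng(spec, "cargo", index)
    L, Lm = spec.cargo_length, len(spec.motif)
    start = int(rng.integers(4, L - Lm - 3 + 1))  # inclusive [4, L-Lm-3]
    realized = []
    for aa in spec.motif:
        if rng.random() < spec.motif_noise:
            members = MEMBERS_OF[CLASS_OF[aa]]
            realized.append(members[rng.integers(len(members))])
        else:
            realized.append(aa)
    realized = "".join(realized)

    def flank(n):
        out = []
        for _ in range(n):
            if rng.random() < spec.flank_charge_rate:
                out.append(CHARGED[rng.integers(len(CHARGED))])
            else:
                out.append(FLANK_ALPHABET[rng.integers(len(FLANK_ALPHABET))])
        return "".join(out)

    seq = flank(start - 1) + realized + flank(L - (start - 1) - Lm)
    structure = build_extended_peptide(seq, id=f"cargo_{index}")
    structure.provenance = f"synthetic:cargo:{index}:seed={spec.seed}"
    return structure, start, realized


def make_cohort(spec: SyntheticSpec) -> Cohort:
    receptor, groove_indices = make_receptor(spec)
    decoys = [make_decoy(spec, receptor, groove_indices, d)
              for d in range(spec.n_decoy_receptors)]
    cargoes, starts, realized = [], {}, {}
    for i in range(spec.n_cargoes):
        cargo, start, real = make_cargo(spec, i)
        cargoes.append(cargo)
        starts[cargo.id] = start
        realized[cargo.id] = real
    truth = GroundTruth(motif=spec.motif, motif_starts=starts,
                        realized_motifs=realized,
                        groove_indices=groove_indices,
                        decoy_ids=[d.id for d in decoys], spec=spec)
    return Cohort(receptor=receptor, decoys=decoys, cargoes=cargoes,
                  truth=truth)


def write_fixture(cohort: Cohort, directory) -> list[Path]:
    """Write receptor/decoy/cargo PDBs, a cargo FASTA, and truth.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    def put(name, text):
        path = directory / name
        path.write_text(text)
        written.append(path)

    put("receptor.pdb", write_pdb(cohort.receptor))
    for d in cohort.decoys:
        put(f"{d.id}.pdb", write_pdb(d))
    for c in cohort.cargoes:
        put(f"{c.id}.pdb", write_pdb(c))
    put("cargoes.fasta",
        write_fasta([(c.id, c.sequence) for c in cohort.cargoes]))
    truth = cohort.truth
    put("truth.json", json.dumps({
        "motif": truth.motif,
        "motif_starts": truth.motif_starts,
        "realized_motifs": truth.realized_motifs,
        "groove_indices": truth.groove_indices,
        "decoy_ids": truth.decoy_ids,
        "spec": dataclasses.asdict(truth.spec),
    }, indent=2, sort_keys=True) + "\n")
    return written


def direct_placement_coords(spec: SyntheticSpec, n_residues: int | None = None,
                            height: float = 4.0) -> np.ndarray:
    """Oracle pose: peptide beads directly above the groove sites.

    Independent of the docking search — used to verify by construction
    that a groove-complementary peptide can reach a deeply favorable
    score.
    """
    sites, c, _ = _groove_geometry(spec)
    if n_residues is None:
        n_residues = len(spec.motif)
    if n_residues > len(sites):
        raise ValidationError("more residues than groove sites")
    return sites[:n_residues] + height * c[None, :]
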