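"""Coarse-grained structure and sequence I/O.

Every protein is represented at one bead per residue, placed on the CA
atom. A bead carries a physicochemical class used by the contact energy
model and a non-negative weight (binding-site beads in synthetic
receptors carry large weights; everything else defaults to 1.0).
"""

from __future__ import annotations

import io
import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .errors import ValidationError, ParseError

log = logging.getLogger(__name__)

#: CA-CA spacing of an idealized extended chain, in Å.
CA_SPACING = 3.8

# Physicochemical classes: positively charged, negatively charged, polar,
# hydrophobic, and special (glycine/proline). Histidine is counted positive.
POS, NEG, POL, HPH, SPC = "POS", "NEG", "POL", "HPH", "SPC"
RES_CLASSES = (POS, NEG, POL, HPH, SPC)

CLASS_OF = {
    "R": POS, "K": POS, "H": POS,
    "D": NEG, "E": NEG,
    "S": POL, "T": POL, "N": POL, "Q": POL, "C": POL, "Y": POL,
    "A": HPH, "V": HPH, "L": HPH, "I": HPH, "M": HPH, "F": HPH, "W": HPH,
    "G": SPC, "P": SPC,
}
CANONICAL = frozenset(CLASS_OF)
MEMBERS_OF = {c: tuple(sorted(a for a, k in CLASS_OF.items() if k == c))
              for c in RES_CLASSES}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass(frozen=True)
class ResidueBead:
    """One residue reduced to a single point at its CA position."""

    chain_id: str
    residue_index: int          # source numbering, 1-based
    amino_acid: str             # one-letter code
    res_class: str
    coordinate: tuple[float, float, float]
    weight: float = 1.0

    def __post_init__(self):
        if self.amino_acid not in CANONICAL:
            raise ValidationError(
                f"non-canonical amino acid {self.amino_acid!r}")
        if self.res_class != CLASS_OF[self.amino_acid]:
            raise ValidationError(
                f"class {self.res_class} does not match residue "
                f"{self.amino_acid}")
        if self.weight < 0:
            raise ValidationError("bead weight must be non-negative")
        if not all(math.isfinite(x) for x in self.coordinate):
            raise ValidationError("bead coordinate must be finite")


@dataclass
class CoarseStructure:
    """Ordered bead list for a receptor, cargo, or built peptide."""

    id: str
    beads: list[ResidueBead]
    provenance: str = ""

    def __post_init__(self):
        if not self.beads:
            raise ValidationError(f"structure {self.id!r} has no beads")
        last: dict[str, int] = {}
        for b in self.beads:
            if b.chain_id in last and b.residue_index <= last[b.chain_id]:
                raise ValidationError(
                    f"structure {self.id!r}: residue_index not strictly "
                    f"increasing in chain {b.chain_id!r}")
            last[b.chain_id] = b.residue_index

    def __len__(self) -> int:
        return len(self.beads)

    @property
    def sequence(self) -> str:
        return "".join(b.amino_acid for b in self.beads)

    @property
    def coords(self) -> np.ndarray:
        return np.array([b.coordinate for b in self.beads], dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return np.array([b.weight for b in self.beads], dtype=float)

    @property
    def class_indices(self) -> np.ndarray:
        lut = {c: i for i, c in enumerate(RES_CLASSES)}
        return np.array([lut[b.res_class] for b in self.beads], dtype=int)

    def with_coords(self, coords: np.ndarray) -> "CoarseStructure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.beads), 3):
            raise ValidationError("coordinate array shape mismatch")
        beads = [replace(b, coordinate=tuple(map(float, xyz)))
                 for b, xyz in zip(self.beads, coords)]
        return CoarseStructure(self.id, beads, self.provenance)


def load_structure(pdb_text: str, id: str) -> CoarseStructure:
    """Parse PDB text into one bead per residue, at the CA atom.

    Residues without a CA and residues with non-canonical names are
    skipped with a warning; for alternate conformers the first-listed
    (lowest serial number) CA is kept. Bead weight is restored from the
    B-factor column, the slot this package's own PDB writer uses for it.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Biopython PDBConstructionWarning
        parser = PDBParser(QUIET=True)
        model = parser.get_structure(id, io.StringIO(pdb_text))
    beads: list[ResidueBead] = []
    for chain in model.get_chains():
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag.strip():
                continue
            if icode.strip():
                log.warning("%s: skipping residue %s%s with insertion code",
                            id, resseq, icode)
                continue
            resname = res.get_resname().strip()
            if resname not in THREE_TO_ONE:
                log.warning("%s: skipping non-canonical residue %s %s",
                            id, resname, resseq)
                continue
            if "CA" not in res:
                log.warning("%s: residue %s %s has no CA atom, skipped",
                            id, resname, resseq)
                continue
            atom = res["CA"]
            if atom.is_disordered():
                # first-listed conformer, not highest occupancy
                atom = min(atom.disordered_get_list(),
                           key=lambda a: a.get_serial_number())
            aa = THREE_TO_ONE[resname]
            weight = float(atom.get_bfactor())
            if weight < 0:
                log.warning("%s: negative B-factor at residue %s, weight "
                            "clamped to 0", id, resseq)
                weight = 0.0
            beads.append(ResidueBead(
                chain_id=chain.id, residue_index=int(resseq),
                amino_acid=aa, res_class=CLASS_OF[aa],
                # PDB coordinates carry exactly 3 decimals; undo float32
                coordinate=tuple(round(float(x), 3)
                                 for x in atom.get_coord()),
                weight=weight))
        break  # first model only
    if not beads:
        raise ParseError(f"{id}: no CA atoms in input")
    return CoarseStructure(id=id, beads=beads, provenance=f"pdb:{id}")


def write_pdb(structure: CoarseStructure) -> str:
    """Render a coarse structure as PDB text, one CA ATOM per bead.

    The bead weight goes in the B-factor column so that
    :func:`load_structure` round-trips it.
    """
    lines = []
    for serial, b in enumerate(structure.beads, start=1):
        x, y, z = b.coordinate
        lines.append(
            f"ATOM  {serial:5d}  CA  {ONE_TO_THREE[b.amino_acid]:<3s}"
            f"{b.chain_id[:1] or 'A'}{b.residue_index:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b.weight:6.2f}"
            f"          {'C':>2s}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def build_extended_peptide(sequence: str, id: str = "peptide",
                           start_index: int = 1) -> CoarseStructure:
    """Build an idealized straight peptide along +x at 3.8 Å CA spacing."""
    if not sequence:
        raise ValidationError("empty peptide sequence")
    for ch in sequence:
        if ch not in CANONICAL:
            raise ValidationError(
                f"illegal amino acid {ch!r} in sequence {sequence!r}")
    beads = [ResidueBead(chain_id="A", residue_index=start_index + i,
                         amino_acid=aa, res_class=CLASS_OF[aa],
                         coordinate=(CA_SPACING * i, 0.0, 0.0))
             for i, aa in enumerate(sequence)]
    return CoarseStructure(id=id, beads=beads, provenance="built:extended")


def read_fasta(text: str) -> list[tuple[str, str]]:
    """Parse FASTA text into (id, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(io.StringIO(text), "fasta")]


def write_fasta(records: list[tuple[str, str]]) -> str:
    out = io.StringIO()
    SeqIO.write([SeqRecord(Seq(seq), id=rid, description="")
                 for rid, seq in records], out, "fasta")
    return out.getvalue()


def kabsch_superpose(coords_a, coords_b):
    """Least-squares rigid superposition of ``coords_b`` onto ``coords_a``.

    Returns ``(rotation, translation, rmsd)`` where
    ``rotation @ b + translation`` best matches ``a`` and ``rotation`` is
    proper (determinant +1).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3 or a.shape != b.shape or len(a) < 1:
        raise ValidationError("coordinate lists must be equal-length Nx3")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (b - cb).T @ (a - ca)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ca - rot @ cb
    moved = (rot @ b.T).T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return rot, trans, rmsd
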