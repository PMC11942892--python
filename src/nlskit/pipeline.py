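"""End-to-end NLS discovery: dock, map, truncate, align, call consensus.

One call runs the whole procedure for a receptor and a set of cargo
structures: each cargo is docked, interacting segments are extracted,
every segment is truncation-scanned for its minimal binding peptide,
and the converged minimal peptides are aligned into a degenerate
consensus motif. All thresholds live in one config object with
documented defaults; runs are deterministic, and written artifacts
contain no timestamps so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus_motif import (
    ConsensusMotif, PeptideAlignment, align_peptides, call_consensus,
)
from .errors import ValidationError
from .interface_mapper import (
    InterfaceSegment, extract_interface, map_receptor_contacts,
)
from .scoring_engine import (
    DockingEngine, DockingResult, EnergyModel, SearchConfig,
    default_pair_potential,
)
from .structures_io import RES_CLASSES, CoarseStructure, write_fasta
from .truncation_scan import (
    DeltaGCurve, MinimalPeptide, minimal_sequence, truncation_curves,
)

log = logging.getLogger(__name__)

_CLASS_INDEX = {c: i for i, c in enumerate(RES_CLASSES)}

_SEARCH_KEYS = {"n_dir", "stand_off", "refine_step", "refine_max_iter",
                "refine"}
_ENERGY_KEYS = {"r_on", "r_off", "clash_distance", "clash_penalty",
                "pair_potential"}


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with its default."""

    # docking search
    n_dir: int = 64
    stand_off: float = 4.0
    refine_step: float = 0.5
    refine_max_iter: int = 50
    refine: bool = True
    # energy model
    r_on: float = 5.0
    r_off: float = 6.5
    clash_distance: float = 3.0
    clash_penalty: float = 10.0
    pair_potential: dict = field(default_factory=dict)  # "POS/NEG" -> a.u.
    # interface extraction
    cutoff: float = 6.5
    max_gap: int = 2
    min_len: int = 5
    # truncation scan
    J: float = 50.0
    l_min: int = 3
    jump_versus_full: bool = False
    # consensus
    majority: float = 0.5
    degenerate_cum: float = 0.7
    min_coverage: float = 0.5
    max_degenerate: int = 6
    # motif scanning
    scan_threshold: float = 6.0
    class_credit: float = 0.5
    # admission of minimal peptides into the alignment
    lenient: bool = False
    # synthetic-data seed (used by the synth stage only)
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(
                f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValidationError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def search_config(self) -> SearchConfig:
        return SearchConfig(n_dir=self.n_dir, stand_off=self.stand_off,
                            refine_step=self.refine_step,
                            refine_max_iter=self.refine_max_iter,
                            refine=self.refine)

    def energy_model(self) -> EnergyModel:
        table = default_pair_potential()
        for key, value in self.pair_potential.items():
            try:
                a, b = key.replace(",", "/").split("/")
                i, j = _CLASS_INDEX[a.strip()], _CLASS_INDEX[b.strip()]
            except (ValueError, KeyError):
                raise ValidationError(
                    f"bad pair_potential key {key!r}; expected e.g. "
                    f"'POS/NEG'") from None
            table[i, j] = table[j, i] = float(value)
        return EnergyModel(pair_potential=table, r_on=self.r_on,
                           r_off=self.r_off,
                           clash_distance=self.clash_distance,
                           clash_penalty=self.clash_penalty)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class CargoResult:
    cargo_id: str
    docking: DockingResult
    segments: list[InterfaceSegment]
    curves: list[tuple[DeltaGCurve, DeltaGCurve]]
    minimal_peptides: list[MinimalPeptide]


@dataclass
class DiscoveryReport:
    config: PipelineConfig
    cargo_results: list[CargoResult]
    alignment: PeptideAlignment | None
    consensus: ConsensusMotif | None
    receptor_contacts: dict[int, int]
    warnings: list[str] = field(default_factory=list)

    @property
    def consensus_render(self) -> str | None:
        return self.consensus.render if self.consensus else None


def discover_nls(receptor: CoarseStructure,
                 cargoes: list[CoarseStructure],
                 config: PipelineConfig | None = None,
                 out_dir=None) -> DiscoveryReport:
    """Run the full discovery procedure against one receptor.

    By default only minimal peptides whose truncation curves converged
    at both termini enter the alignment; ``config.lenient`` admits
    single-terminus convergence. If no cargo yields a converged minimal
    peptide the report carries an empty consensus and a warning.
    """
    cargoes = list(cargoes)
    if not cargoes:
        raise ValidationError("at least one cargo is required")
    config = config or PipelineConfig()
    engine = DockingEngine(receptor, config.search_config(),
                           config.energy_model())
    engine.prepare(max(len(c) for c in cargoes))
    cargo_results: list[CargoResult] = []
    warnings: list[str] = []
    admitted: list[tuple[str, str]] = []
    for cargo in cargoes:
        docking = engine.dock_structure(cargo)
        segments = extract_interface(docking, cargo, cutoff=config.cutoff,
                                     max_gap=config.max_gap,
                                     min_len=config.min_len)
        curves, peptides = [], []
        for seg in segments:
            curve_n, curve_c = truncation_curves(
                receptor, seg, l_min=config.l_min, engine=engine)
            mp = minimal_sequence(curve_n, curve_c, J=config.J,
                                  versus_full=config.jump_versus_full)
            if mp.delta_g_minimal != mp.delta_g_minimal:  # NaN: re-dock
                mp.delta_g_minimal = engine.dock_sequence(
                    mp.sequence).delta_g
            curves.append((curve_n, curve_c))
            peptides.append(mp)
            ok = (mp.converged if not config.lenient
                  else (mp.n_converged or mp.c_converged))
            if ok:
                admitted.append(
                    (f"{cargo.id}:{mp.start}-{mp.end}", mp.sequence))
        if not segments:
            warnings.append(f"{cargo.id}: no interface segments")
        cargo_results.append(CargoResult(
            cargo_id=cargo.id, docking=docking, segments=segments,
            curves=curves, minimal_peptides=peptides))
    if admitted:
        alignment = align_peptides(admitted)
        consensus = call_consensus(
            alignment, majority=config.majority,
            degenerate_cum=config.degenerate_cum,
            min_coverage=config.min_coverage,
            max_degenerate=config.max_degenerate)
    else:
        alignment, consensus = None, None
        warnings.append("no converged minimal peptides; empty consensus")
    contacts = dict(map_receptor_contacts(
        [cr.docking for cr in cargo_results], receptor))
    report = DiscoveryReport(config=config, cargo_results=cargo_results,
                             alignment=alignment, consensus=consensus,
                             receptor_contacts=contacts, warnings=warnings)
    for w in warnings:
        log.warning(w)
    if out_dir is not None:
        write_report(report, receptor, out_dir)
    return report


# -- artifact writing ------------------------------------------------------

def _fmt(x: float) -> float:
    return float(np.round(x, 6))


def write_report(report: DiscoveryReport, receptor: CoarseStructure,
                 out_dir) -> dict:
    """Write all artifacts; returns the report.json index dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    seg_rows, curve_rows, mp_rows = [], [], []
    for cr in report.cargo_results:
        for seg in cr.segments:
            seg_rows.append({
                "protein_id": seg.protein_id, "start": seg.start,
                "end": seg.end, "sequence": seg.sequence,
                "mean_residue_energy": _fmt(seg.mean_residue_energy),
                "rendering": seg.render()})
        for curve_n, curve_c in cr.curves:
            for curve in (curve_n, curve_c):
                for e in curve.entries:
                    curve_rows.append({
                        "protein_id": curve.segment.protein_id,
                        "segment_start": curve.segment.start,
                        "segment_end": curve.segment.end,
                        "terminus": curve.terminus, "k": e.k,
                        "remaining_start": e.remaining_start,
                        "remaining_end": e.remaining_end,
                        "delta_g": _fmt(e.delta_g)})
        for mp in cr.minimal_peptides:
            mp_rows.append({
                "protein_id": mp.source.protein_id,
                "segment_start": mp.source.start,
                "segment_end": mp.source.end,
                "start": mp.start, "end": mp.end, "sequence": mp.sequence,
                "delta_g_full": _fmt(mp.delta_g_full),
                "delta_g_minimal": _fmt(mp.delta_g_minimal),
                "n_jump": "" if mp.n_jump is None else _fmt(mp.n_jump),
                "c_jump": "" if mp.c_jump is None else _fmt(mp.c_jump),
                "n_converged": mp.n_converged,
                "c_converged": mp.c_converged})

    def tsv(name, rows, columns):
        df = pd.DataFrame(rows, columns=columns)
        df.to_csv(out / name, sep="\t", index=False)

    tsv("segments.tsv", seg_rows,
        ["protein_id", "start", "end", "sequence", "mean_residue_energy",
         "rendering"])
    tsv("curves.tsv", curve_rows,
        ["protein_id", "segment_start", "segment_end", "terminus", "k",
         "remaining_start", "remaining_end", "delta_g"])
    tsv("minimal_peptides.tsv", mp_rows,
        ["protein_id", "segment_start", "segment_end", "start", "end",
         "sequence", "delta_g_full", "delta_g_minimal", "n_jump", "c_jump",
         "n_converged", "c_converged"])

    contact_rows = [{"bead_index": i,
                     "residue_index": receptor.beads[i].residue_index,
                     "count": n}
                    for i, n in sorted(report.receptor_contacts.items())]
    tsv("receptor_contacts.tsv", contact_rows,
        ["bead_index", "residue_index", "count"])

    if report.alignment is not None:
        (out / "alignment.fasta").write_text(
            write_fasta(report.alignment.padded_rows()))
    if report.consensus is not None:
        (out / "consensus.txt").write_text(report.consensus.render + "\n")
        freq_rows = [{"position": i + 1, "support": p.support,
                      "call": "".join(sorted(p.call)) if len(p.call) < 20
                      else "X",
                      "frequencies": json.dumps(p.freqs, sort_keys=True)}
                     for i, p in enumerate(report.consensus.positions)]
        tsv("consensus_positions.tsv", freq_rows,
            ["position", "support", "call", "frequencies"])

    index = {
        "version": __version__,
        "config": report.config.to_dict(),
        "config_hash": report.config.config_hash(),
        "receptor_id": receptor.id,
        "cargo_ids": [cr.cargo_id for cr in report.cargo_results],
        "consensus": report.consensus_render,
        "warnings": report.warnings,
        "artifacts": sorted(p.name for p in out.iterdir()
                            if p.name != "report.json"),
    }
    (out / "report.json").write_text(
        json.dumps(index, indent=2, sort_keys=True) + "\n")
    return index
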