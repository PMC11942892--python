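"""Energy model, docking search vs plain-loop oracle, scans, ranking."""

import numpy as np
import pytest

from nlskit import (
    CoarseStructure, ResidueBead, SearchConfig, ValidationError,
    alanine_scan, compare_receptors, dock, interaction_energy,
)
from nlskit.scoring_engine import DockingEngine, EnergyModel
from nlskit.synthetic_data import direct_placement_coords

from helpers import (
    oracle_dock, planted_segment, random_receptor, random_sequence,
)


def single_bead_receptor(aa="D", weight=1.0):
    from nlskit.structures_io import CLASS_OF
    return CoarseStructure("r", [ResidueBead(
        "A", 1, aa, CLASS_OF[aa], (0.0, 0.0, 0.0), weight)])


class TestInteractionEnergy:
    @pytest.mark.parametrize("dist,expected", [
        (4.0, -2.0),    # full-weight shell: eps(POS,NEG) = -2
        (5.75, -1.0),   # halfway through the switching region
        (2.0, 8.0),     # clash: -2 + 10
        (7.0, 0.0),     # beyond r_off
    ])
    def test_arg_asp_pair(self, dist, expected):
        rec = single_bead_receptor("D")
        dg, per_res, contacts = interaction_energy(
            rec, [[dist, 0.0, 0.0]], "R")
        assert dg == pytest.approx(expected)
        assert sum(per_res) == pytest.approx(dg)
        assert bool(contacts) == (dist <= 6.5)

    def test_receptor_weight_scales_pair_terms(self):
        rec = single_bead_receptor("D", weight=30.0)
        dg, _, _ = interaction_energy(rec, [[4.0, 0.0, 0.0]], "R")
        assert dg == pytest.approx(-60.0)

    def test_decomposition_conservation_random(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            rec = random_receptor(rng, int(rng.integers(2, 20)))
            L = int(rng.integers(1, 12))
            coords = rng.uniform(-10, 10, (L, 3))
            dg, per_res, _ = interaction_energy(
                rec, coords, random_sequence(rng, L))
            assert abs(sum(per_res) - dg) < 1e-6

    def test_contacts_within_cutoff(self):
        rng = np.random.default_rng(5)
        rec = random_receptor(rng, 15)
        coords = rng.uniform(-10, 10, (6, 3))
        _, _, contacts = interaction_energy(
            rec, coords, random_sequence(rng, 6))
        assert all(d <= 6.5 for _, _, d in contacts)


class TestEnergyModel:
    def test_table_must_be_symmetric(self):
        bad = np.zeros((5, 5))
        bad[0, 1] = 1.0
        with pytest.raises(ValidationError):
            EnergyModel(pair_potential=bad)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValidationError):
            EnergyModel(r_on=7.0, r_off=6.5)


class TestDock:
    def test_single_pair_settles_in_contact_shell(self):
        res = dock(single_bead_receptor("D"), "R")
        assert res.delta_g == pytest.approx(-2.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            dock(single_bead_receptor(), "")

    def test_matches_plain_loop_oracle_without_refinement(self):
        rng = np.random.default_rng(21)
        cfg = SearchConfig(refine=False)
        for _ in range(8):
            rec = random_receptor(rng, int(rng.integers(3, 13)))
            seq = random_sequence(rng, int(rng.integers(1, 6)))
            got = dock(rec, seq, cfg).delta_g
            expected = oracle_dock(rec, seq)[0]
            assert got == pytest.approx(expected, abs=1e-9)

    def test_refinement_only_lowers_energy(self):
        rng = np.random.default_rng(22)
        for _ in range(5):
            rec = random_receptor(rng, 10)
            seq = random_sequence(rng, 4)
            base = dock(rec, seq, SearchConfig(refine=False)).delta_g
            refined = dock(rec, seq, SearchConfig(refine=True)).delta_g
            assert refined <= base + 1e-9

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(23)
        rec = random_receptor(rng, 12)
        seq = "RKLPV"
        e0 = dock(rec, seq).delta_g
        for state in range(3):
            rot = Rotation.random(random_state=state).as_matrix()
            shift = rng.uniform(-20, 20, 3)
            moved = rec.with_coords(rec.coords @ rot.T + shift)
            assert abs(dock(moved, seq).delta_g - e0) < 1e-6

    def test_groove_weight_monotonicity(self, cohort_seed1, spec_seed1):
        """Raising a contacted groove bead's weight never weakens binding."""
        import dataclasses
        rec = cohort_seed1.receptor
        motif = spec_seed1.motif
        base = dock(rec, motif).delta_g
        idx = cohort_seed1.truth.groove_indices[0]
        beads = list(rec.beads)
        beads[idx] = dataclasses.replace(beads[idx], weight=60.0)
        heavier = CoarseStructure("receptor+", beads)
        assert dock(heavier, motif).delta_g <= base + 1e-9

    def test_synthetic_groove_binds_planted_motif_deeply(
            self, cohort_seed1, spec_seed1):
        oracle = direct_placement_coords(spec_seed1)
        dg_direct, _, _ = interaction_energy(
            cohort_seed1.receptor, oracle, spec_seed1.motif)
        assert dg_direct <= -300.0
        assert dock(cohort_seed1.receptor,
                    spec_seed1.motif).delta_g <= min(-300.0, dg_direct + 1e-9)


class TestAlanineScan:
    def test_position_already_alanine_is_zero(self):
        rec = single_bead_receptor("D")
        results = alanine_scan(rec, "RAK", [2])
        assert results == [(2, 0.0)]

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValidationError):
            alanine_scan(single_bead_receptor(), "RK", [3])

    def test_charged_motif_positions_dominate_flanks(self, cohort_seed1):
        """Mutating a charged groove-facing residue costs far more than
        mutating a flank residue: the in silico mutagenesis contrast."""
        seg = planted_segment(cohort_seed1, 0)
        seq = seg.sequence
        motif = cohort_seed1.truth.motif
        motif_off = seq.index(motif)
        charged = [motif_off + i + 1 for i, aa in enumerate(motif)
                   if aa in "RKH"]
        flanks = [p for p in range(1, len(seq) + 1)
                  if not motif_off < p <= motif_off + len(motif)]
        dd = dict(alanine_scan(cohort_seed1.receptor, seq, charged + flanks))
        assert min(dd[p] for p in charged) > 40.0
        assert all(dd[p] < dd[q] for p in flanks for q in charged)
        assert all(abs(dd[p]) < 10.0 for p in flanks)


class TestCompareReceptors:
    def test_single_receptor_single_row(self):
        rows = compare_receptors([single_bead_receptor()], "R")
        assert len(rows) == 1 and rows[0][0] == "r"

    def test_identical_receptors_tie_broken_by_id(self):
        a = single_bead_receptor()
        a.id = "a"
        b = single_bead_receptor()
        b.id = "b"
        rows = compare_receptors([b, a], "RK")
        assert [r[0] for r in rows] == ["a", "b"]
        assert rows[0][1] == pytest.approx(rows[1][1])

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            compare_receptors([], "R")

    def test_true_receptor_outranks_decoys(self, cohort_seed1, spec_seed1):
        rows = compare_receptors(
            [cohort_seed1.receptor] + cohort_seed1.decoys, spec_seed1.motif)
        assert rows[0][0] == "receptor"


def test_dock_structure_matches_sequence_for_extended_chain(cohort_seed1):
    from nlskit import build_extended_peptide
    eng = DockingEngine(cohort_seed1.receptor)
    seq = "RRKLPVGRS"
    a = eng.dock_structure(build_extended_peptide(seq))
    b = eng.dock_sequence(seq)
    assert a.delta_g == pytest.approx(b.delta_g)
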