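"""Truncation curves and jump-based minimal-peptide calling."""

import pytest

from nlskit import (
    InterfaceSegment, ValidationError, minimal_sequence, truncation_curves,
)
from nlskit.scoring_engine import DockingEngine
from nlskit.truncation_scan import CurveEntry, DeltaGCurve, plot_curves

from helpers import planted_segment


def make_curve(terminus, segment, values):
    """Curve with the given ΔG series, k = 0..len(values)-1."""
    entries = []
    for k, dg in enumerate(values):
        if terminus == "N":
            entries.append(CurveEntry(k, segment.start + k, segment.end, dg))
        else:
            entries.append(CurveEntry(k, segment.start, segment.end - k, dg))
    return DeltaGCurve(terminus, segment, entries)


@pytest.fixture
def segment10():
    return InterfaceSegment("p", 101, 110, "RRKLPVGRSA", 0.0)


class TestMinimalSequenceRule:
    def test_jump_at_first_step_keeps_full_segment(self, segment10):
        vals = [-500.0, -400.0, -300.0]
        mp = minimal_sequence(make_curve("N", segment10, vals),
                              make_curve("C", segment10, vals), J=50)
        assert (mp.start, mp.end) == (segment10.start, segment10.end)
        assert mp.converged
        assert mp.sequence == segment10.sequence

    def test_flat_curves_unconverged(self, segment10):
        vals = [-500.0, -495.0, -490.0, -485.0]
        mp = minimal_sequence(make_curve("N", segment10, vals),
                              make_curve("C", segment10, vals), J=50)
        assert (mp.start, mp.end) == (segment10.start, segment10.end)
        assert not mp.n_converged and not mp.c_converged

    def test_interior_jump_sets_boundary_at_critical_residue(self, segment10):
        n_vals = [-500.0, -498.0, -497.0, -400.0]   # jump at k=3
        c_vals = [-500.0, -440.0, -430.0]            # jump at k=1
        mp = minimal_sequence(make_curve("N", segment10, n_vals),
                              make_curve("C", segment10, c_vals), J=50)
        assert mp.start == segment10.start + 2   # residue removed at k=3
        assert mp.end == segment10.end           # critical at first removal
        assert mp.converged
        assert mp.n_jump == pytest.approx(97.0)
        assert mp.c_jump == pytest.approx(60.0)

    def test_crossed_boundaries_fall_back_to_full_segment(self, segment10):
        # jumps only at the last steps from both ends -> start > end
        n_vals = [-500.0] * 7 + [-400.0]
        c_vals = [-500.0] * 7 + [-400.0]
        mp = minimal_sequence(make_curve("N", segment10, n_vals),
                              make_curve("C", segment10, c_vals), J=50)
        assert (mp.start, mp.end) == (segment10.start, segment10.end)
        assert not mp.converged

    def test_mismatched_curves_rejected(self, segment10):
        other = InterfaceSegment("p", 1, 10, "RRKLPVGRSA", 0.0)
        with pytest.raises(ValidationError):
            minimal_sequence(make_curve("N", segment10, [-1.0]),
                             make_curve("C", other, [-1.0]))


class TestTruncationCurves:
    def test_segment_at_l_min_gives_single_entry(self, cohort_seed1):
        seg = InterfaceSegment("p", 1, 3, "RRK", 0.0)
        cn, cc = truncation_curves(cohort_seed1.receptor, seg, l_min=3)
        assert len(cn.entries) == len(cc.entries) == 1
        assert cn.entries[0].delta_g == cc.entries[0].delta_g

    def test_entry_count_and_shared_k0(self, cohort_seed1):
        seg = planted_segment(cohort_seed1, 0)
        L = len(seg.sequence)
        cn, cc = truncation_curves(cohort_seed1.receptor, seg, l_min=3)
        assert len(cn.entries) == L - 3 + 1
        assert cn.entries[0].delta_g == cc.entries[0].delta_g
        for k, e in enumerate(cn.entries):
            assert e.k == k
            assert e.remaining_end - e.remaining_start + 1 == L - k

    def test_too_short_segment_rejected(self, cohort_seed1):
        seg = InterfaceSegment("p", 1, 2, "RR", 0.0)
        with pytest.raises(ValidationError):
            truncation_curves(cohort_seed1.receptor, seg, l_min=3)

    def test_flanks_cheap_then_motif_edge_jumps(self, cohort_seed1):
        """N-curve stays near-flat while flanks go, then rises sharply
        when the first planted motif residue is removed."""
        seg = planted_segment(cohort_seed1, 0, flank=3)
        eng = DockingEngine(cohort_seed1.receptor)
        cn, _ = truncation_curves(cohort_seed1.receptor, seg, engine=eng)
        steps = [cn.entries[k].delta_g - cn.entries[k - 1].delta_g
                 for k in range(1, 5)]
        # flank removals stay well below the jump threshold J=50; the
        # flank residue adjacent to the motif has a small real groove
        # interaction, so "near-flat" means small relative to J
        assert all(abs(s) < 20.0 for s in steps[:3])
        assert steps[3] > 50.0

    def test_curves_reproducible(self, cohort_seed1):
        seg = planted_segment(cohort_seed1, 1)
        a = truncation_curves(cohort_seed1.receptor, seg)
        b = truncation_curves(cohort_seed1.receptor, seg)
        assert ([e.delta_g for e in a[0].entries]
                == [e.delta_g for e in b[0].entries])


class TestBoundaryRecovery:
    def test_minimal_peptide_within_one_of_planted_span(self, cohort_seed1):
        truth = cohort_seed1.truth
        lm = len(truth.motif)
        eng = DockingEngine(cohort_seed1.receptor)
        for idx in range(3):
            seg = planted_segment(cohort_seed1, idx)
            cn, cc = truncation_curves(cohort_seed1.receptor, seg,
                                       engine=eng)
            mp = minimal_sequence(cn, cc)
            s = truth.motif_starts[cohort_seed1.cargoes[idx].id]
            assert abs(mp.start - s) <= 1
            assert abs(mp.end - (s + lm - 1)) <= 1


def test_plot_curves_writes_figure(tmp_path, segment10):
    vals = [-500.0, -495.0, -400.0]
    out = tmp_path / "curves.png"
    plot_curves(make_curve("N", segment10, vals),
                make_curve("C", segment10, vals), out)
    assert out.stat().st_size > 0
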