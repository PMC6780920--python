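import numpy as np
import pytest

from conftest import make_channel
from metadia.dia import (AnnotationConstraint, annotate_aif, dia_report,
                         group_across_energies, score_dia)
from metadia.library import MSMSLibraryEntry
from metadia.msio import split_by_energy
from metadia.scoring import verdict
from metadia.simulate import demo_msms_library, demo_truth, simulate_run

GLN = 147.0764
FRAGS = [84.0444, 130.0499]


def gln_entry():
    return MSMSLibraryEntry("glutamine", "[M+H]+", GLN, list(FRAGS),
                            polarity="positive")


def channels(frag_rts=(0.25, 0.25), prec_rt=0.25, fp=0.5, apex=1e6,
             n_scans=40):
    ms1 = make_channel([(GLN, prec_rt, 0.04, apex)], n_scans=n_scans,
                       energy="0", ms_level=1)
    msms = make_channel(
        [(mz, rt, 0.04, fp * apex) for mz, rt in zip(FRAGS, frag_rts)],
        rt0=0.5 / 240.0, n_scans=n_scans, energy="10", ms_level=2, id0=1000)
    return ms1, msms


class TestAnnotateAif:
    def test_coeluting_fragments_grouped(self):
        ms1, msms = channels()
        (group,) = annotate_aif(ms1, msms, [gln_entry()])
        assert group.n_matched == 2 and group.n_library_fragments == 2
        for m in group.fragments:
            assert abs(m.d_rt) <= 0.08
            assert abs(m.ppm) <= 5.0

    def test_displaced_fragment_not_matched(self):
        # second fragment 0.2 min late: outside the 0.08 min tolerance
        ms1, msms = channels(frag_rts=(0.25, 0.45))
        (group,) = annotate_aif(ms1, msms, [gln_entry()])
        assert group.n_matched == 1
        assert group.fragments[0].library_mz == pytest.approx(84.0444)

    def test_all_fragment_constraint_discards_partial_groups(self):
        ms1, msms = channels(frag_rts=(0.25, 0.45))
        all_req = annotate_aif(ms1, msms, [gln_entry()],
                               AnnotationConstraint(min_fragments="all"))
        one_req = annotate_aif(ms1, msms, [gln_entry()],
                               AnnotationConstraint(min_fragments=1))
        assert all_req == [] and len(one_req) == 1

    def test_missing_ms1_channel_rejected(self):
        _, msms = channels()
        with pytest.raises(ValueError, match="MS1"):
            annotate_aif(None, msms, [gln_entry()])

    def test_closest_rt_candidate_wins(self):
        ms1 = make_channel([(GLN, 0.30, 0.04, 1e6)], n_scans=60)
        msms = make_channel([(84.0444, 0.29, 0.015, 9e5),
                             # second, more intense peak further in RT
                             (84.0447, 0.36, 0.015, 5e6)],
                            n_scans=60, energy="10", ms_level=2, id0=1000)
        entry = MSMSLibraryEntry("glutamine", "[M+H]+", GLN, [84.0444])
        (group,) = annotate_aif(ms1, msms, [entry])
        (m,) = group.fragments
        assert m.peak.t_rmax == pytest.approx(0.29, abs=0.01)


class TestGroupAcrossEnergies:
    def test_one_row_per_energy(self):
        ms1, _ = channels()
        per_energy = {}
        for e in ("5", "10", "20"):
            msms = make_channel([(mz, 0.25, 0.04, 5e5) for mz in FRAGS],
                                n_scans=40, energy=e, ms_level=2, id0=1000)
            per_energy[e] = annotate_aif(ms1, msms, [gln_entry()])
        table = group_across_energies(per_energy)
        assert len(table) == 3
        assert set(table["energy"]) == {"5", "10", "20"}
        assert (table["n_matched"] == 2).all()

    def test_fragment_inventory_differs_per_energy(self):
        # one fragment vanishes at high CE, as happens physically
        ms1, _ = channels()
        per_energy = {
            "10": annotate_aif(ms1, make_channel(
                [(mz, 0.25, 0.04, 5e5) for mz in FRAGS], n_scans=40,
                energy="10", ms_level=2, id0=1000), [gln_entry()]),
            "20": annotate_aif(ms1, make_channel(
                [(84.0444, 0.25, 0.04, 5e5)], n_scans=40,
                energy="20", ms_level=2, id0=2000), [gln_entry()]),
        }
        table = group_across_energies(per_energy)
        inv = dict(zip(table["energy"], table["n_matched"]))
        assert inv == {"10": 2, "20": 1}

    def test_empty_input(self):
        assert len(group_across_energies({})) == 0


class TestScoreDia:
    def test_scaled_identical_traces(self):
        # fragment = precursor trace x 0.5: PPC 1, PPS 1, F/P 0.5
        ms1, msms = channels(fp=0.5)
        (group,) = annotate_aif(ms1, msms, [gln_entry()])
        scores = score_dia(group)
        for fs in scores.fragments:
            assert fs.ppc.r == pytest.approx(1.0, abs=1e-3)
            assert fs.pps == pytest.approx(1.0, abs=0.05)
            assert fs.fp_ratio == pytest.approx(0.5, rel=0.01)
            assert fs.accepted

    def test_fp_invariant_under_joint_rescale(self):
        r1 = self._fp(apex=1e6)
        r2 = self._fp(apex=5e7)
        assert r1 == pytest.approx(r2, rel=1e-6)

    @staticmethod
    def _fp(apex):
        ms1, msms = channels(apex=apex, fp=0.3)
        (group,) = annotate_aif(ms1, msms, [gln_entry()])
        return score_dia(group).fragments[0].fp_ratio

    def test_insufficient_shared_scans_flagged(self):
        # fragment detected from only 3 scans at the very peak edge region
        ms1 = make_channel([(GLN, 0.25, 0.04, 1e6)], n_scans=8,
                           period=0.005)
        msms = make_channel([(84.0444, 0.25, 0.003, 1e5)], n_scans=8,
                            period=0.005, rt0=0.02, energy="10",
                            ms_level=2, id0=1000)
        entry = MSMSLibraryEntry("glutamine", "[M+H]+", GLN, [84.0444])
        groups = annotate_aif(ms1, msms, [entry],
                              AnnotationConstraint(min_scans=3))
        if groups:
            sc = score_dia(groups[0])
            for fs in sc.fragments:
                if not fs.ppc.defined:
                    assert not fs.accepted
                    assert "insufficient scans" in fs.reasons[0]

    def test_report_shape(self):
        ms1, msms = channels()
        (group,) = annotate_aif(ms1, msms, [gln_entry()])
        rep = dia_report([score_dia(group)])
        assert len(rep) == 2
        assert list(rep["fragment_mz"]) == pytest.approx(FRAGS, abs=1e-4)
        assert set(rep["verdict"]) == {"accept"}


class TestVerdictEngine:
    @pytest.mark.parametrize("ppc_v, pps_v, accept, reason_part", [
        (0.93, 0.22, False, "PPS"),    # shape ratio below the band
        (0.67, 0.40, False, "PPC"),    # correlation below the cutoff
        (0.60, 3.00, False, "PPC"),    # PPS exactly at the inclusive limit
        (0.87, 0.67, True, None),
        (0.70, 0.30, True, None),      # both at inclusive boundaries
        (0.70, 3.00, True, None),
        (None, 1.00, False, "insufficient"),
    ])
    def test_accept_reject_rules(self, ppc_v, pps_v, accept, reason_part):
        ok, reasons = verdict(ppc_v, pps_v)
        assert ok is accept
        if reason_part:
            assert any(reason_part in r for r in reasons)
        if accept:
            assert reasons == []


class TestMonotonicityAndRecovery:
    def test_fragment_constraint_monotonic_on_seeded_runs(self):
        # "all fragments" annotations are a subset of ">=1 fragment" ones
        for seed in range(10):
            truth = demo_truth(["glutamine", "phenylalanine", "tyrosine"],
                               energies=("10",))
            # drop one tyrosine fragment so the constraint bites sometimes
            truth[2].fragments["10"] = truth[2].fragments["10"][:1]
            scans = simulate_run(truth, energies=("0", "10"), seed=seed,
                                 noise_floor=100.0, rt_end=0.8)
            chans = split_by_energy(scans)
            lib = demo_msms_library()
            lax = annotate_aif(chans["0"], chans["10"], lib,
                               AnnotationConstraint(min_fragments=1))
            strict = annotate_aif(chans["0"], chans["10"], lib,
                                  AnnotationConstraint(min_fragments="all"))
            lax_keys = {(g.metabolite, g.adduct) for g in lax}
            strict_keys = {(g.metabolite, g.adduct) for g in strict}
            assert strict_keys <= lax_keys
            assert "tyrosine" not in {m for m, _ in strict_keys}

    def test_fp_ratio_recovered_from_synthetic_run(self):
        truth = demo_truth(["glutamine"], energies=("10",), fp_ratio=0.4)
        scans = simulate_run(truth, energies=("0", "10"), seed=17,
                             noise_floor=100.0, rt_end=0.6)
        chans = split_by_energy(scans)
        (group,) = annotate_aif(chans["0"], chans["10"],
                                demo_msms_library()[:1])
        for fs in score_dia(group).fragments:
            assert fs.fp_ratio == pytest.approx(0.4, rel=0.1)

    def test_no_annotation_violates_tolerances(self, demo_run):
        scans, _ = demo_run
        chans = split_by_energy(scans)
        c = AnnotationConstraint()
        for label, ch in chans.items():
            if ch.is_ms1:
                continue
            for g in annotate_aif(chans["0"], ch, demo_msms_library(), c):
                for m in g.fragments:
                    assert abs(m.d_rt) <= c.rt_tol
                    assert abs(m.ppm) <= c.ppm_tol
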