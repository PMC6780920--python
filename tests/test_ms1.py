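import numpy as np
import pytest

from conftest import make_channel, make_eic
from metadia.chem import adduct_mz, isotopologue_mz, monoisotopic_mass
from metadia.library import LibraryEntry
from metadia.ms1 import annotate_ms1, group_ms1, ms1_report, score_ms1
from metadia.peaks import detect_peaks, smooth_peak
from metadia.scoring import ipir, ppc, pps
from metadia.simulate import demo_truth, simulate_run
from metadia.msio import split_by_energy

GLN_MASS = monoisotopic_mass("C5H10N2O3")
GLN_MH = adduct_mz(GLN_MASS, "[M+H]+")
GLN_NH4 = adduct_mz(GLN_MASS, "[M+NH4]+")


def gln_entry():
    from metadia.chem import Formula
    return LibraryEntry("glutamine", GLN_MASS, "positive",
                        formula=Formula.parse("C5H10N2O3"))


class TestAnnotateMs1:
    def test_both_adducts_annotated(self):
        ch = make_channel([
            (GLN_MH, 0.25, 0.04, 1e6),
            (isotopologue_mz(GLN_MH), 0.25, 0.04, 1e6 / 8),
            (GLN_NH4, 0.25, 0.04, 4e5),
        ], n_scans=40)
        anns = annotate_ms1(ch, [gln_entry()])
        keys = {(a.adduct, a.isotopologue) for a in anns}
        assert ("[M+H]+", 0) in keys and ("[M+NH4]+", 0) in keys
        assert ("[M+H]+", 1) in keys
        for a in anns:
            assert abs(a.ppm) < 1.0  # noiseless fixture: sub-ppm agreement

    def test_absent_metabolite_not_annotated(self):
        ch = make_channel([(300.0, 0.25, 0.04, 1e6)], n_scans=30)
        assert annotate_ms1(ch, [gln_entry()]) == []

    def test_isotopologue_gated_on_monoisotopic(self):
        # stray peak at the +1 position only: no annotation at all
        ch = make_channel([(isotopologue_mz(GLN_MH), 0.25, 0.04, 1e6)],
                          n_scans=30)
        anns = annotate_ms1(ch, [gln_entry()])
        assert anns == []

    def test_isotopologue_must_coelute(self):
        ch = make_channel([
            (GLN_MH, 0.15, 0.03, 1e6),
            (isotopologue_mz(GLN_MH), 0.45, 0.03, 1e5),  # 0.3 min away
        ], n_scans=40)
        anns = annotate_ms1(ch, [gln_entry()])
        assert {(a.adduct, a.isotopologue) for a in anns} == {("[M+H]+", 0)}

    def test_rt_constraint_applied_when_both_present(self):
        entry = LibraryEntry("glutamine", GLN_MASS, "positive", rt_min=0.9)
        ch = make_channel([(GLN_MH, 0.25, 0.04, 1e6)], n_scans=40)
        assert annotate_ms1(ch, [entry], rt_tol=0.1) == []
        entry2 = LibraryEntry("glutamine", GLN_MASS, "positive", rt_min=0.27)
        assert len(annotate_ms1(ch, [entry2], rt_tol=0.1)) >= 1

    def test_empty_library_warns(self):
        ch = make_channel([(GLN_MH, 0.25, 0.04, 1e6)], n_scans=10)
        with pytest.warns(UserWarning, match="empty"):
            assert annotate_ms1(ch, []) == []

    def test_ppm_soundness_on_jittered_run(self):
        truth = demo_truth(["glutamine", "tyrosine"])
        scans = simulate_run(truth, seed=3, mz_jitter_ppm=3.0,
                             noise_floor=50.0)
        channels = split_by_energy(scans)
        ms1 = [c for c in channels.values() if c.is_ms1][0]
        from metadia.simulate import demo_ms1_library
        anns = annotate_ms1(ms1, demo_ms1_library(), ppm_tol=5.0)
        assert anns
        for a in anns:
            assert abs(a.ppm) <= 5.0


class TestGroupMs1:
    def test_partition_by_metabolite(self):
        ch = make_channel([
            (GLN_MH, 0.25, 0.04, 1e6),
            (isotopologue_mz(GLN_MH), 0.25, 0.04, 1e5),
            (GLN_NH4, 0.25, 0.04, 4e5),
        ], n_scans=40)
        anns = annotate_ms1(ch, [gln_entry()])
        (group,) = group_ms1(anns)
        assert group.metabolite == "glutamine"
        assert len(group.members) == len(anns) >= 3
        assert group.rt_spread < 0.05

    def test_two_metabolites_two_groups(self):
        phe = LibraryEntry("phenylalanine", monoisotopic_mass("C9H11NO2"),
                           "positive")
        ch = make_channel([
            (GLN_MH, 0.2, 0.04, 1e6),
            (adduct_mz(phe.neutral_mass, "[M+H]+"), 0.4, 0.04, 1e6),
        ], n_scans=40)
        anns = annotate_ms1(ch, [gln_entry(), phe])
        groups = group_ms1(anns)
        assert [g.metabolite for g in groups] == ["glutamine", "phenylalanine"]
        assert sum(len(g.members) for g in groups) == len(anns)

    def test_empty_input(self):
        assert group_ms1([]) == []


class TestScoreMs1:
    def test_identical_coeluting_peaks_score_perfectly(self):
        ch = make_channel([
            (GLN_MH, 0.25, 0.04, 1e6),
            (GLN_NH4, 0.25, 0.04, 5e5),
        ], n_scans=40)
        anns = annotate_ms1(ch, [gln_entry()])
        (group,) = group_ms1(anns)
        scores = score_ms1(group)
        (pair,) = scores.pairs
        assert pair.ppc.r == pytest.approx(1.0, abs=1e-6)
        assert pair.pps == pytest.approx(1.0, abs=1e-6)
        assert pair.accepted

    def test_non_overlapping_peaks_ppc_undefined(self):
        # the two adducts elute far apart: no shared above-zero scans
        ch = make_channel([
            (GLN_MH, 0.10, 0.015, 1e6),
            (GLN_NH4, 0.55, 0.015, 1e6),
        ], n_scans=45)
        anns = annotate_ms1(ch, [gln_entry()])
        (group,) = group_ms1(anns)
        (pair,) = score_ms1(group).pairs
        assert not pair.ppc.defined
        assert not pair.accepted and "insufficient scans" in pair.reasons[0]

    def test_ipir_magnitude_and_rule(self):
        ch = make_channel([
            (GLN_MH, 0.25, 0.04, 1000.0),
            (isotopologue_mz(GLN_MH), 0.25, 0.04, 122.0),
        ], n_scans=40)
        anns = annotate_ms1(ch, [gln_entry()])
        (group,) = group_ms1(anns)
        (iso,) = score_ms1(group).isotopes
        assert iso.ipir == pytest.approx(1000 / 122, rel=1e-6)  # ~8.2
        assert iso.passed is True

    def test_ipir_rule_suppressed_for_sulfur(self):
        from metadia.chem import Formula
        met_mass = monoisotopic_mass("C5H11NO2S")
        entry = LibraryEntry("methionine", met_mass, "positive",
                             formula=Formula.parse("C5H11NO2S"))
        mh = adduct_mz(met_mass, "[M+H]+")
        ch = make_channel([
            (mh, 0.25, 0.04, 1e6),
            (isotopologue_mz(mh), 0.25, 0.04, 2e6),  # inverted ratio
        ], n_scans=40)
        (group,) = group_ms1(annotate_ms1(ch, [entry]))
        (iso,) = score_ms1(group).isotopes
        assert iso.ipir < 1 and iso.passed is None  # verdict suppressed

    def test_report_columns(self):
        ch = make_channel([
            (GLN_MH, 0.25, 0.04, 1e6),
            (isotopologue_mz(GLN_MH), 0.25, 0.04, 1.25e5),
        ], n_scans=40)
        anns = annotate_ms1(ch, [gln_entry()])
        scores = [score_ms1(g) for g in group_ms1(anns)]
        rep = ms1_report(anns, scores)
        assert set(rep.columns) >= {"metabolite", "adduct", "isotopologue",
                                    "theoretical_mz", "observed_mz",
                                    "ppm_error", "f", "IPIR", "PPC", "PPS",
                                    "verdict"}
        assert len(rep) == len(anns)


class TestScoreProperties:
    def make_pair(self, rng, n=15):
        y1 = rng.uniform(10, 1000, n)
        y2 = rng.uniform(10, 1000, n)
        e1, e2 = make_eic(y1), make_eic(y2)
        p1 = detect_peaks(e1, min_scans=3, min_intensity=0.0, valley_frac=0.0)
        p2 = detect_peaks(e2, min_scans=3, min_intensity=0.0, valley_frac=0.0)
        return p1[0], p2[0]

    def test_ppc_symmetric_self_unity_bounded(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p1, p2 = self.make_pair(rng)
            s1 = smooth_peak(p1, "cubic-spline")
            s2 = smooth_peak(p2, "cubic-spline")
            ab = ppc(s1, s2)
            ba = ppc(s2, s1)
            if ab.defined:
                assert ab.r == pytest.approx(ba.r, abs=1e-12)
                assert -1.0 - 1e-12 <= ab.r <= 1.0 + 1e-12
            self_score = ppc(s1, s1)
            assert self_score.r == pytest.approx(1.0)

    def test_ppc_matches_textbook_pearson(self):
        # independent oracle: explicit sum formula
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = rng.integers(4, 30)
            y1 = rng.uniform(1, 1000, n)
            y2 = rng.uniform(1, 1000, n)
            p1 = detect_peaks(make_eic(y1), min_intensity=0.0,
                              valley_frac=0.0)[0]
            p2 = detect_peaks(make_eic(y2), min_intensity=0.0,
                              valley_frac=0.0)[0]
            score = ppc(smooth_peak(p1, "cubic-spline"),
                        smooth_peak(p2, "cubic-spline"))
            _, ia, ib = np.intersect1d(p1.scan_ids, p2.scan_ids,
                                       return_indices=True)
            a, b = p1.intensity[ia], p2.intensity[ib]
            if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
                assert not score.defined
                continue
            num = np.sum((a - a.mean()) * (b - b.mean()))
            den = np.sqrt(np.sum((a - a.mean()) ** 2)
                          * np.sum((b - b.mean()) ** 2))
            assert score.r == pytest.approx(num / den, abs=1e-9)

    def test_pps_reciprocal_identity(self):
        rng = np.random.default_rng(21)
        found = 0
        for _ in range(100):
            p1, p2 = self.make_pair(rng)
            if p1.f != 0 and p2.f != 0:
                found += 1
                assert pps(p1, p2) * pps(p2, p1) == pytest.approx(1.0)
        assert found > 20

    def test_ipir_recovery_on_seeded_replicates(self):
        # median recovered IPIR over 50 replicates within 5% of truth
        true_ratio = 8.0
        values = []
        for seed in range(50):
            truth = demo_truth(["glutamine"], energies=())
            truth[0].isotope_ratio = true_ratio
            scans = simulate_run(truth, energies=("0",), rt_end=0.6,
                                 seed=seed, mz_jitter_ppm=2.0,
                                 noise_floor=50.0)
            ms1 = split_by_energy(scans)["0"]
            from metadia.simulate import demo_ms1_library
            anns = annotate_ms1(ms1, demo_ms1_library(),
                                adducts=["[M+H]+"])
            (group,) = group_ms1(anns)
            (iso,) = score_ms1(group).isotopes
            values.append(iso.ipir)
        assert np.median(values) == pytest.approx(true_ratio, rel=0.05)
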