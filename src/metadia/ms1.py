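"""Targeted full-scan MS1 annotation, grouping and scoring.

For every (library entry x adduct x isotopologue 0/+1) the theoretical m/z
is computed, an EIC is extracted from the 0-energy channel, and detected
peaks inside the mass (and optional retention-time) tolerance become
annotations.  Annotations are grouped per metabolite and scored pairwise:
IPIR for monoisotopic/+1 isotopologue pairs, PPC on the smoothed shared
scans and PPS on asymmetry factors for every member pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .chem import adduct_mz, isotopologue_mz, ppm_error, ADDUCTS, AdductSpec
from .library import LibraryEntry
from .msio import ScanChannel
from .peaks import EICPeak, detect_peaks, extract_eic, smooth_peak
from .scoring import (PPC_CUTOFF, PPS_BAND, PairScore, ipir, ppc, pps,
                      verdict)

__all__ = ["MS1Annotation", "MS1Group", "MS1Scores",
           "annotate_ms1", "group_ms1", "score_ms1", "ms1_report"]


@dataclass
class MS1Annotation:
    entry: LibraryEntry
    adduct: str
    isotopologue: int          # 0 = monoisotopic, 1 = +1 channel
    peak: EICPeak
    theoretical_mz: float
    alternates: list[EICPeak] = field(default_factory=list)

    @property
    def observed_mz(self) -> float:
        return self.peak.apex_mz

    @property
    def ppm(self) -> float:
        return ppm_error(self.observed_mz, self.theoretical_mz)

    @property
    def metabolite(self) -> str:
        return self.entry.name


@dataclass
class MS1Group:
    metabolite: str
    members: list[MS1Annotation]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("group must be non-empty")
        if any(m.metabolite != self.metabolite for m in self.members):
            raise ValueError("group members must share a metabolite name")

    @property
    def rt_spread(self) -> float:
        apexes = [m.peak.t_rmax for m in self.members]
        return max(apexes) - min(apexes)


@dataclass
class MS1PairScore:
    member_a: MS1Annotation
    member_b: MS1Annotation
    ppc: PairScore
    pps: float
    accepted: bool
    reasons: list[str]


@dataclass
class MS1IsotopeScore:
    adduct: str
    ipir: float
    passed: bool | None    # None = suppressed (S or Br in the formula)


@dataclass
class MS1Scores:
    group: MS1Group
    pairs: list[MS1PairScore]
    isotopes: list[MS1IsotopeScore]


def annotate_ms1(channel: ScanChannel, library: list[LibraryEntry],
                 adducts: list[str] | None = None,
                 ppm_tol: float = 5.0, mz_window: float = 0.005,
                 rt_tol: float | None = None,
                 min_scans: int = 3, min_intensity: float = 0.0,
                 iso_rt_tol: float = 0.08) -> list[MS1Annotation]:
    """Annotate the MS1 channel against a neutral-mass library.

    The +1 isotopologue is only reported when the monoisotopic ion was
    found, and must co-elute with it (apex within ``iso_rt_tol`` minutes).
    All detected candidate peaks are ranked by apex intensity; rank 1 is
    the annotation, the rest are kept as ``alternates``.
    """
    if not library:
        warnings.warn("empty MS1 library; nothing to annotate")
        return []
    if adducts is None:
        adducts = [a for a in ADDUCTS]
    annotations: list[MS1Annotation] = []
    for entry in sorted(library, key=lambda e: e.name):
        for label in adducts:
            spec = ADDUCTS[label] if isinstance(label, str) else label
            if entry.polarity != "any" and spec.polarity != entry.polarity:
                continue
            if channel.polarity != "unknown" and spec.polarity != channel.polarity:
                continue
            mono = _find(channel, adduct_mz(entry.neutral_mass, spec.label),
                         ppm_tol, mz_window, min_scans, min_intensity,
                         entry.rt_min if rt_tol is not None else None, rt_tol)
            if mono is None:
                continue
            ann0 = MS1Annotation(entry, spec.label, 0, mono[0],
                                 adduct_mz(entry.neutral_mass, spec.label),
                                 alternates=mono[1])
            annotations.append(ann0)
            plus1 = _find(channel,
                          isotopologue_mz(ann0.theoretical_mz, 1,
                                          spec.charge),
                          ppm_tol, mz_window, min_scans, min_intensity,
                          ann0.peak.t_rmax, iso_rt_tol)
            if plus1 is not None:
                annotations.append(MS1Annotation(
                    entry, spec.label, 1, plus1[0],
                    isotopologue_mz(ann0.theoretical_mz, 1, spec.charge),
                    alternates=plus1[1]))
    annotations.sort(key=lambda a: (a.metabolite, a.adduct, a.isotopologue))
    return annotations


def _find(channel: ScanChannel, theo_mz: float, ppm_tol: float,
          mz_window: float, min_scans: int, min_intensity: float,
          rt_anchor: float | None, rt_tol: float | None
          ) -> tuple[EICPeak, list[EICPeak]] | None:
    eic = extract_eic(channel, theo_mz, ppm_tol, mz_window)
    peaks = detect_peaks(eic, min_scans=min_scans, min_intensity=min_intensity)
    if rt_anchor is not None and rt_tol is not None:
        peaks = [p for p in peaks if abs(p.t_rmax - rt_anchor) <= rt_tol]
    peaks = [p for p in peaks
             if abs(ppm_error(p.apex_mz, theo_mz)) <= ppm_tol]
    if not peaks:
        return None
    ranked = sorted(peaks, key=lambda p: p.apex_intensity, reverse=True)
    return ranked[0], ranked[1:]


def group_ms1(annotations: list[MS1Annotation]) -> list[MS1Group]:
    """Partition annotations by metabolite name."""
    by_name: dict[str, list[MS1Annotation]] = {}
    for a in annotations:
        by_name.setdefault(a.metabolite, []).append(a)
    return [MS1Group(name, members) for name, members in sorted(by_name.items())]


def score_ms1(group: MS1Group, smoother: str = "smoothing-spline",
              ppc_cutoff: float = PPC_CUTOFF,
              pps_band: tuple[float, float] = PPS_BAND) -> MS1Scores:
    """Score all member pairs of one metabolite's MS1 group.

    PPC is evaluated on spline-smoothed traces; PPS on raw-peak asymmetry
    factors.  IPIR is reported per adduct with a mono and a +1 member; its
    pass rule (IPIR > 1) is suppressed when the formula contains S or Br,
    whose isotope patterns legitimately invert the ratio.
    """
    smoothed = {id(m): smooth_peak(m.peak, smoother) for m in group.members}
    pairs: list[MS1PairScore] = []
    for a, b in combinations(group.members, 2):
        score = ppc(smoothed[id(a)], smoothed[id(b)])
        shape = pps(a.peak, b.peak)
        ok, reasons = verdict(score.r, shape, ppc_cutoff, pps_band,
                              n_shared=score.n_shared)
        pairs.append(MS1PairScore(a, b, score, shape, ok, reasons))
    isotopes: list[MS1IsotopeScore] = []
    by_adduct: dict[str, dict[int, MS1Annotation]] = {}
    for m in group.members:
        by_adduct.setdefault(m.adduct, {})[m.isotopologue] = m
    for adduct, isos in sorted(by_adduct.items()):
        if 0 in isos and 1 in isos:
            r = ipir(isos[0].peak, isos[1].peak)
            formula = isos[0].entry.formula
            suppressed = formula is not None and ("S" in formula or "Br" in formula)
            isotopes.append(MS1IsotopeScore(
                adduct, r, None if suppressed else r > 1.0))
    return MS1Scores(group, pairs, isotopes)


def ms1_report(annotations: list[MS1Annotation],
               scores: list[MS1Scores] | None = None) -> pd.DataFrame:
    """Flat results table (one row per annotation) for CSV export."""
    rows = []
    iso_by_key: dict[tuple[str, str], MS1IsotopeScore] = {}
    pair_by_member: dict[int, MS1PairScore] = {}
    if scores:
        for sc in scores:
            for iso in sc.isotopes:
                iso_by_key[(sc.group.metabolite, iso.adduct)] = iso
            for pr in sc.pairs:
                for m in (pr.member_a, pr.member_b):
                    pair_by_member.setdefault(id(m), pr)
    for a in annotations:
        iso = iso_by_key.get((a.metabolite, a.adduct))
        pr = pair_by_member.get(id(a))
        rows.append({
            "metabolite": a.metabolite,
            "adduct": a.adduct,
            "isotopologue": a.isotopologue,
            "theoretical_mz": round(a.theoretical_mz, 6),
            "observed_mz": round(a.observed_mz, 6),
            "ppm_error": round(a.ppm, 3),
            "rt_apex_min": round(a.peak.t_rmax, 4),
            "apex_intensity": a.peak.apex_intensity,
            "area": a.peak.area,
            "f": round(a.peak.f, 4),
            "IPIR": None if iso is None else round(iso.ipir, 4),
            "IPIR_pass": None if iso is None else iso.passed,
            "PPC": None if pr is None or not pr.ppc.defined else round(pr.ppc.r, 4),
            "PPC_p": None if pr is None or not pr.ppc.defined else pr.ppc.p_value,
            "PPS": None if pr is None else round(pr.pps, 4),
            "verdict": None if pr is None else ("accept" if pr.accepted
                                                else "; ".join(pr.reasons)),
        })
    return pd.DataFrame(rows)
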