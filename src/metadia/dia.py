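"""All-ion-fragmentation annotation: precursor-fragment co-elution groups.

In AIF data every MS/MS scan fragments everything in the isolation range,
so fragments are re-associated with their precursor chromatographically:
the precursor peak is anchored on the 0-energy MS1 channel, each library
fragment is searched on one MS/MS collision-energy channel, and a match
requires both the mass tolerance (5 ppm default) and apex-to-apex
retention-time agreement (0.08 min default).  Groups that match fewer
fragments than the configured minimum (1 ... all) are discarded.  Each
surviving precursor-fragment pair is then scored with PPC, PPS and the
fragment/precursor maximum-intensity ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import ppm_error
from .library import MSMSLibraryEntry
from .msio import ScanChannel
from .peaks import EICPeak, detect_peaks, extract_eic, smooth_peak
from .scoring import (PPC_CUTOFF, PPS_BAND, PairScore, fp_ratio, ppc, pps,
                      verdict)

__all__ = ["AnnotationConstraint", "FragmentMatch", "PeakGroup", "DIAScores",
           "annotate_aif", "group_across_energies", "score_dia", "dia_report"]


@dataclass
class AnnotationConstraint:
    """Matching tolerances and the minimum-fragment co-elution requirement.

    ``min_fragments`` is an integer count or the string ``"all"`` (every
    library fragment must co-elute).
    """

    min_fragments: int | str = 1
    ppm_tol: float = 5.0
    mz_window: float = 0.005
    rt_tol: float = 0.08       # minutes, apex-to-apex
    min_scans: int = 3
    min_intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.ppm_tol <= 0 or self.rt_tol <= 0 or self.mz_window <= 0:
            raise ValueError("tolerances must be positive")
        if self.min_fragments != "all" and int(self.min_fragments) < 1:
            raise ValueError("min_fragments must be >= 1 or 'all'")

    def required(self, n_library_fragments: int) -> int:
        if self.min_fragments == "all":
            return n_library_fragments
        return min(int(self.min_fragments), n_library_fragments)


@dataclass
class FragmentMatch:
    library_mz: float
    peak: EICPeak
    ppm: float
    d_rt: float    # apex RT minus precursor apex RT, minutes


@dataclass
class PeakGroup:
    """An aligned precursor peak plus its fragment matches at one energy."""

    entry: MSMSLibraryEntry
    energy: str
    precursor_peak: EICPeak
    fragments: list[FragmentMatch]
    n_library_fragments: int

    @property
    def metabolite(self) -> str:
        return self.entry.name

    @property
    def adduct(self) -> str:
        return self.entry.adduct

    @property
    def n_matched(self) -> int:
        return len(self.fragments)


@dataclass
class FragmentScore:
    match: FragmentMatch
    ppc: PairScore
    pps: float
    fp_ratio: float
    accepted: bool
    reasons: list[str]


@dataclass
class DIAScores:
    group: PeakGroup
    fragments: list[FragmentScore]


def annotate_aif(ms1_channel: ScanChannel, msms_channel: ScanChannel,
                 library: list[MSMSLibraryEntry],
                 constraint: AnnotationConstraint | None = None
                 ) -> list[PeakGroup]:
    """Match library precursors and fragments across the MS1/MSMS channels.

    The precursor anchor peak always comes from the MS1 (energy 0) channel;
    a precursor surviving inside the MS/MS spectra should be listed as an
    ordinary library fragment.  When several fragment peaks satisfy both
    tolerances the smallest apex-RT difference wins, ties broken by apex
    intensity.
    """
    if ms1_channel is None:
        raise ValueError("MS1 channel is mandatory (precursor anchor)")
    c = constraint or AnnotationConstraint()
    groups: list[PeakGroup] = []
    for entry in sorted(library, key=lambda e: (e.name, e.adduct)):
        if (entry.polarity != "any" and msms_channel.polarity != "unknown"
                and entry.polarity != msms_channel.polarity):
            continue
        prec_eic = extract_eic(ms1_channel, entry.precursor_mz,
                               c.ppm_tol, c.mz_window)
        prec_peaks = [p for p in detect_peaks(prec_eic, c.min_scans,
                                              c.min_intensity)
                      if abs(ppm_error(p.apex_mz, entry.precursor_mz))
                      <= c.ppm_tol]
        if not prec_peaks:
            continue
        precursor = max(prec_peaks, key=lambda p: p.apex_intensity)
        matches: list[FragmentMatch] = []
        for frag_mz in entry.fragments:
            eic = extract_eic(msms_channel, frag_mz, c.ppm_tol, c.mz_window)
            candidates = [
                p for p in detect_peaks(eic, c.min_scans, c.min_intensity)
                if abs(ppm_error(p.apex_mz, frag_mz)) <= c.ppm_tol
                and abs(p.t_rmax - precursor.t_rmax) <= c.rt_tol
            ]
            if not candidates:
                continue
            best = min(candidates,
                       key=lambda p: (abs(p.t_rmax - precursor.t_rmax),
                                      -p.apex_intensity))
            matches.append(FragmentMatch(
                frag_mz, best, ppm_error(best.apex_mz, frag_mz),
                best.t_rmax - precursor.t_rmax))
        if len(matches) >= c.required(len(entry.fragments)):
            groups.append(PeakGroup(entry, msms_channel.energy, precursor,
                                    matches, len(entry.fragments)))
    return groups


def group_across_energies(groups_per_energy: dict[str, list[PeakGroup]]
                          ) -> pd.DataFrame:
    """Union table keyed (metabolite, adduct, energy) with the per-energy
    fragment inventory, enabling collision-energy comparisons."""
    rows = []
    for energy, groups in sorted(groups_per_energy.items()):
        for g in groups:
            rows.append({
                "metabolite": g.metabolite,
                "adduct": g.adduct,
                "energy": energy,
                "precursor_mz": round(g.entry.precursor_mz, 6),
                "rt_apex_min": round(g.precursor_peak.t_rmax, 4),
                "n_library_fragments": g.n_library_fragments,
                "n_matched": g.n_matched,
                "matched_fragments": ";".join(
                    f"{m.library_mz:.4f}" for m in g.fragments),
            })
    df = pd.DataFrame(rows, columns=[
        "metabolite", "adduct", "energy", "precursor_mz", "rt_apex_min",
        "n_library_fragments", "n_matched", "matched_fragments"])
    return df.sort_values(["metabolite", "adduct", "energy"],
                          ignore_index=True) if len(df) else df


def score_dia(group: PeakGroup, ppc_cutoff: float = PPC_CUTOFF,
              pps_band: tuple[float, float] = PPS_BAND,
              smoother: str = "smoothing-spline") -> DIAScores:
    """Score every fragment of a peak group against its precursor.

    PPC pairs scans by nearest retention time (precursor and fragment live
    on different collision-energy channels); PPS divides the fragment's
    asymmetry factor by the precursor's; the F/P ratio divides raw maximum
    EIC intensities, with the precursor maximum taken from the MS1-channel
    EIC.  Accept iff PPC >= cutoff and PPS inside the band.
    """
    prec_smooth = smooth_peak(group.precursor_peak, smoother)
    out: list[FragmentScore] = []
    for m in group.fragments:
        frag_smooth = smooth_peak(m.peak, smoother)
        score = ppc(frag_smooth, prec_smooth, same_channel=False)
        shape = pps(m.peak, group.precursor_peak)
        ratio = fp_ratio(m.peak, group.precursor_peak)
        ok, reasons = verdict(score.r, shape, ppc_cutoff, pps_band,
                              n_shared=score.n_shared)
        out.append(FragmentScore(m, score, shape, ratio, ok, reasons))
    return DIAScores(group, out)


def dia_report(scored: list[DIAScores]) -> pd.DataFrame:
    """Flat results table (one row per precursor-fragment pair)."""
    rows = []
    for sc in scored:
        g = sc.group
        for fs in sc.fragments:
            rows.append({
                "metabolite": g.metabolite,
                "adduct": g.adduct,
                "energy": g.energy,
                "precursor_mz": round(g.entry.precursor_mz, 6),
                "fragment_mz": round(fs.match.library_mz, 6),
                "observed_mz": round(fs.match.peak.apex_mz, 6),
                "ppm_error": round(fs.match.ppm, 3),
                "dRT_min": round(fs.match.d_rt, 4),
                "PPC": None if not fs.ppc.defined else round(fs.ppc.r, 4),
                "PPC_p": None if not fs.ppc.defined else fs.ppc.p_value,
                "n_shared_scans": fs.ppc.n_shared,
                "PPS": round(fs.pps, 4),
                "FP_ratio": round(fs.fp_ratio, 4),
                "verdict": "accept" if fs.accepted else "; ".join(fs.reasons),
            })
    return pd.DataFrame(rows, columns=[
        "metabolite", "adduct", "energy", "precursor_mz", "fragment_mz",
        "observed_mz", "ppm_error", "dRT_min", "PPC", "PPC_p",
        "n_shared_scans", "PPS", "FP_ratio", "verdict"])
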