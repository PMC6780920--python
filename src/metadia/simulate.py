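"""Synthetic multiplexed DIA runs with known ground truth.

Emulates a stepped-collision-energy acquisition: the instrument cycles
through one full-scan channel per collision energy (default CID 0, 5, 10,
20 eV at four spectra per second, i.e. each channel sampled once per
second).  Every ground-truth metabolite renders as a chromatographic peak
— Gaussian, or exponentially-modified Gaussian when a tailing parameter is
set — sampled on each channel's retention-time grid:

* the precursor ion and its +1 isotopologue (at the stated isotope ratio)
  on the 0-energy MS1 channel;
* each declared fragment on its collision-energy channel, scaled to the
  stated fragment/precursor apex ratio;
* centroid m/z jittered uniformly within a ppm bound;
* uniform-m/z noise centroids with exponentially distributed intensity at
  the noise floor.

Identical seeds give byte-identical mzML output.  What the simulator does
not emulate: isotope fine structure, adduct equilibria, detector
saturation, chromatographic drift between channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import exponnorm

from .chem import (Formula, adduct_mz, fragment_cation_mz, isotopologue_mz,
                   monoisotopic_mass)
from .library import LibraryEntry, MSMSLibraryEntry
from .msio import Scan, write_mzml

__all__ = ["GroundTruthPeak", "simulate_run", "truth_table",
           "demo_ms1_library", "demo_msms_library", "demo_truth"]


@dataclass
class GroundTruthPeak:
    """One metabolite's true chromatographic/spectral signature."""

    metabolite: str
    adduct: str
    mz: float                   # precursor m/z
    rt_apex: float              # minutes
    sigma: float = 0.04        # Gaussian width, minutes (~14 s FWHM)
    apex_intensity: float = 1e6
    isotope_ratio: float = 8.0  # true IPIR = I_mono / I_plus1; 0 disables +1
    #: energy label -> list of (fragment m/z, fragment/precursor apex ratio)
    fragments: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    tailing_tau: float = 0.0    # EMG tail constant, minutes; 0 = symmetric

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.apex_intensity <= 0:
            raise ValueError("sigma and apex intensity must be positive")
        if self.isotope_ratio < 0:
            raise ValueError("isotope ratio must be >= 0")
        for frags in self.fragments.values():
            for _, ratio in frags:
                if ratio < 0:
                    raise ValueError("F/P ratios must be >= 0")

    def shape(self, t: np.ndarray) -> np.ndarray:
        """Unit-apex elution profile sampled at times ``t`` (minutes)."""
        if self.tailing_tau > 0:
            k = self.tailing_tau / self.sigma
            dense = np.linspace(self.rt_apex - 6 * self.sigma,
                                self.rt_apex + 6 * self.sigma + 8 * self.tailing_tau,
                                2001)
            pdf_max = exponnorm.pdf(dense, k, loc=self.rt_apex,
                                    scale=self.sigma).max()
            return exponnorm.pdf(t, k, loc=self.rt_apex,
                                 scale=self.sigma) / pdf_max
        return np.exp(-0.5 * ((t - self.rt_apex) / self.sigma) ** 2)


def simulate_run(truth: list[GroundTruthPeak],
                 energies: tuple[str, ...] = ("0", "5", "10", "20"),
                 rt_start: float = 0.0, rt_end: float = 1.0,
                 scan_period: float = 1.0 / 60.0,
                 mz_jitter_ppm: float = 2.0,
                 noise_floor: float = 0.0,
                 noise_peaks_per_scan: int = 20,
                 mz_range: tuple[float, float] = (50.0, 750.0),
                 seed: int = 0,
                 path: str | Path | None = None
                 ) -> list[Scan]:
    """Render ground-truth peaks into an interleaved multi-energy scan list.

    ``scan_period`` is the per-channel sampling period in minutes (default
    1 s, matching a 4-spectra/s cycle over four energies).  Scans are
    written to ``path`` as mzML when given.  Overlapping truth peaks closer
    than one scan period are allowed (valley-split testing) — no warning
    is raised below two periods.
    """
    if scan_period <= 0:
        raise ValueError("scan period must be positive")
    rng = np.random.default_rng(seed)
    n_channels = len(energies)
    dwell = scan_period / n_channels
    cycle_starts = np.arange(rt_start, rt_end, scan_period)
    scans: list[Scan] = []
    scan_id = 0
    intensity_floor = 1.0  # centroids below one count are not recorded
    for t0 in cycle_starts:
        for ci, energy in enumerate(energies):
            scan_id += 1
            t = t0 + ci * dwell
            mz_list: list[float] = []
            int_list: list[float] = []
            is_ms1 = float(energy) == 0.0 if _is_number(energy) else False
            for peak in truth:
                amp = peak.apex_intensity * float(peak.shape(np.array([t]))[0])
                if is_ms1:
                    _add(mz_list, int_list, peak.mz, amp, mz_jitter_ppm, rng,
                         intensity_floor)
                    if peak.isotope_ratio > 0:
                        _add(mz_list, int_list, isotopologue_mz(peak.mz),
                             amp / peak.isotope_ratio, mz_jitter_ppm, rng,
                             intensity_floor)
                else:
                    for frag_mz, ratio in peak.fragments.get(energy, []):
                        _add(mz_list, int_list, frag_mz, ratio * amp,
                             mz_jitter_ppm, rng, intensity_floor)
            if noise_floor > 0 and noise_peaks_per_scan > 0:
                noise_mz = rng.uniform(*mz_range, size=noise_peaks_per_scan)
                noise_int = rng.exponential(noise_floor,
                                            size=noise_peaks_per_scan)
                keep = noise_int >= intensity_floor
                mz_list.extend(noise_mz[keep])
                int_list.extend(noise_int[keep])
            scans.append(Scan(scan_id, t, 1 if is_ms1 else 2, energy,
                              "positive", np.array(mz_list),
                              np.array(int_list)))
    if path is not None:
        write_mzml(scans, path)
    return scans


def _is_number(label: str) -> bool:
    try:
        float(label)
        return True
    except ValueError:
        return False


def _add(mz_list, int_list, mz, intensity, jitter_ppm, rng, floor) -> None:
    jitter = rng.uniform(-jitter_ppm, jitter_ppm) * 1e-6 * mz
    if intensity >= floor:
        mz_list.append(mz + jitter)
        int_list.append(intensity)


def truth_table(truth: list[GroundTruthPeak]) -> pd.DataFrame:
    """One row per ground-truth peak, for writing alongside the mzML."""
    rows = []
    for p in truth:
        rows.append({
            "metabolite": p.metabolite,
            "adduct": p.adduct,
            "mz": p.mz,
            "rt_apex_min": p.rt_apex,
            "sigma_min": p.sigma,
            "apex_intensity": p.apex_intensity,
            "isotope_ratio": p.isotope_ratio,
            "tailing_tau_min": p.tailing_tau,
            "fragments": "|".join(
                f"{e}:{mz:.5f}:{r:.4f}"
                for e, frags in sorted(p.fragments.items())
                for mz, r in frags),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# demo library: a small panel of urine/cell metabolites with theoretical
# masses, used by tests and the worked example.

_DEMO_COMPOUNDS = [
    # name, formula, polarity
    ("alanine", "C3H7NO2", "positive"),
    ("betaine", "C5H11NO2", "positive"),
    ("caffeine", "C8H10N4O2", "positive"),
    ("creatinine", "C4H7N3O", "positive"),
    ("citrulline", "C6H13N3O3", "positive"),
    ("glutamic acid", "C5H9NO4", "positive"),
    ("glutamine", "C5H10N2O3", "positive"),
    ("glutathione", "C10H17N3O6S", "positive"),
    ("hippuric acid", "C9H9NO3", "positive"),
    ("methionine", "C5H11NO2S", "positive"),
    ("phenylacetylglutamine", "C13H16N2O4", "positive"),
    ("phenylalanine", "C9H11NO2", "positive"),
    ("serine", "C3H7NO3", "positive"),
    ("tryptophan", "C11H12N2O2", "positive"),
    ("tyrosine", "C9H11NO3", "positive"),
]

#: AIF fragment ions (singly charged cation formulas) per metabolite.
_DEMO_FRAGMENTS = {
    "glutamine": ["C4H6NO", "C5H8NO3"],            # 84.0444, 130.0499
    "phenylalanine": ["C8H7", "C8H10N"],           # 103.0542, 120.0808
    "phenylacetylglutamine": ["C4H6NO", "C5H8NO3", "C8H10NO", "C5H11N2O3"],
    "glutathione": ["C5H8NO3", "C4H6NO"],
    "methionine": ["C4H10NS", "C5H9O2S"],          # 104.0528, 133.0318
    "tyrosine": ["C8H10NO", "C7H7O2", "C7H7"],     # 136.0757, 123.0441, 91.0542
}


def demo_ms1_library() -> list[LibraryEntry]:
    """Fifteen common metabolites with formula-derived neutral masses."""
    return [
        LibraryEntry(name, monoisotopic_mass(formula), polarity,
                     formula=Formula.parse(formula))
        for name, formula, polarity in _DEMO_COMPOUNDS
    ]


def demo_msms_library(adduct: str = "[M+H]+") -> list[MSMSLibraryEntry]:
    """AIF entries for the demo metabolites with theoretical fragment m/z."""
    mass_by_name = {name: monoisotopic_mass(f)
                    for name, f, _ in _DEMO_COMPOUNDS}
    entries = []
    for name, frag_formulas in _DEMO_FRAGMENTS.items():
        entries.append(MSMSLibraryEntry(
            name, adduct, adduct_mz(mass_by_name[name], adduct),
            [fragment_cation_mz(f) for f in frag_formulas],
            polarity="positive"))
    return entries


def demo_truth(metabolites: list[str] | None = None,
               energies: tuple[str, ...] = ("5", "10", "20"),
               rt_start: float = 0.15, rt_spacing: float = 0.22,
               apex_intensity: float = 1e6,
               fp_ratio: float = 0.5, isotope_ratio: float = 8.0,
               ) -> list[GroundTruthPeak]:
    """Ground truth matching the demo MS/MS library: one peak per
    metabolite, apexes spaced ``rt_spacing`` minutes apart, every library
    fragment present in every MS/MS channel at the same F/P ratio."""
    lib = {e.name: e for e in demo_msms_library()}
    names = metabolites or ["glutamine", "phenylalanine", "tyrosine"]
    truth = []
    for i, name in enumerate(names):
        entry = lib[name]
        truth.append(GroundTruthPeak(
            metabolite=name, adduct=entry.adduct, mz=entry.precursor_mz,
            rt_apex=rt_start + i * rt_spacing,
            apex_intensity=apex_intensity,
            isotope_ratio=isotope_ratio,
            fragments={e: [(mz, fp_ratio) for mz in entry.fragments]
                       for e in energies},
        ))
    return truth
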