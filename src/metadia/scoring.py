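"""Quality scores for co-eluting peak pairs.

Five statistics assess whether two extracted-ion-chromatogram peaks belong
to the same eluting metabolite:

* **asymmetry factor f** — per peak; see :mod:`metadia.peaks`.
* **IPIR** (isotope peak intensity ratio) — apex intensity of the
  monoisotopic peak over the +1 isotopologue, ``I_k / I_{k+1}``; expected
  above 1 for formulas without S or Br, whose heavy isotopes would invert
  the pattern.
* **PPC** (peak-to-peak Pearson correlation) — Pearson r of the two
  smoothed intensity traces over their shared scans, with a two-sided
  p-value; needs at least 3 shared scans.  Recommended cutoff 0.7.
* **PPS** (peak-to-peak shape ratio) — ratio of the two peaks' asymmetry
  factors ``f1 / f2``; acceptance band 0.3-3 (inclusive).
* **F/P ion ratio** — fragment over precursor maximum EIC intensity
  ``I_max,F / I_max,P``; reported, no cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .peaks import EICPeak, SmoothedPeak

__all__ = [
    "PPC_CUTOFF",
    "PPS_BAND",
    "PairScore",
    "pair_scans",
    "ppc",
    "pps",
    "ipir",
    "fp_ratio",
    "verdict",
]

PPC_CUTOFF = 0.7
PPS_BAND = (0.3, 3.0)
MIN_SHARED_SCANS = 3


@dataclass
class PairScore:
    """PPC of one peak pair over shared scans."""

    r: float | None          # None when undefined
    p_value: float | None
    n_shared: int
    reason: str | None = None  # why r is undefined

    @property
    def defined(self) -> bool:
        return self.r is not None


def pair_scans(a: SmoothedPeak, b: SmoothedPeak,
               same_channel: bool | None = None,
               max_dt: float | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Intensity vectors of the scans shared by two peaks.

    Peaks on the same channel are matched by scan id; peaks on different
    channels (e.g. a precursor on the MS1 channel and a fragment on an
    MS/MS channel) are matched by nearest retention time within half the
    median scan period.
    """
    if same_channel is None:
        shared = np.intersect1d(a.scan_ids, b.scan_ids)
        same_channel = shared.size > 0
    if same_channel:
        common, ia, ib = np.intersect1d(a.scan_ids, b.scan_ids,
                                        return_indices=True)
        return a.intensity[ia], b.intensity[ib]
    # nearest-RT pairing across channels
    rt_a, rt_b = a.rt, b.rt
    if max_dt is None:
        periods = np.concatenate([np.diff(rt_a), np.diff(rt_b)])
        max_dt = 0.5 * float(np.median(periods)) if periods.size else np.inf
    ia, ib = [], []
    used_b: set[int] = set()
    for i, t in enumerate(rt_a):
        j = int(np.argmin(np.abs(rt_b - t)))
        if j not in used_b and abs(rt_b[j] - t) <= max_dt:
            ia.append(i)
            ib.append(j)
            used_b.add(j)
    return a.intensity[np.array(ia, dtype=int)], b.intensity[np.array(ib, dtype=int)]


def ppc(a: SmoothedPeak, b: SmoothedPeak, **pair_kwargs) -> PairScore:
    """Pearson correlation of two smoothed peaks over their shared scans."""
    xa, xb = pair_scans(a, b, **pair_kwargs)
    n = int(xa.size)
    if n < MIN_SHARED_SCANS:
        return PairScore(None, None, n, reason=f"only {n} shared scan(s)")
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        return PairScore(None, None, n, reason="constant trace")
    r, p = stats.pearsonr(xa, xb)
    return PairScore(float(r), float(p), n)


def pps(peak1: EICPeak | float, peak2: EICPeak | float) -> float:
    """Shape ratio f1/f2 of two peaks' asymmetry factors (0 when either
    factor is degenerate)."""
    f1 = peak1 if isinstance(peak1, (int, float)) else peak1.f
    f2 = peak2 if isinstance(peak2, (int, float)) else peak2.f
    if f2 == 0:
        return 0.0
    return f1 / f2


def ipir(mono: EICPeak | float, plus1: EICPeak | float) -> float:
    """Monoisotopic over +1 isotopologue apex-intensity ratio I_k/I_{k+1}."""
    i0 = mono if isinstance(mono, (int, float)) else mono.apex_intensity
    i1 = plus1 if isinstance(plus1, (int, float)) else plus1.apex_intensity
    if i1 <= 0:
        return float("inf")
    return i0 / i1


def fp_ratio(fragment: EICPeak | float, precursor: EICPeak | float) -> float:
    """Fragment over precursor maximum EIC intensity I_max,F/I_max,P."""
    i_f = fragment if isinstance(fragment, (int, float)) else fragment.apex_intensity
    i_p = precursor if isinstance(precursor, (int, float)) else precursor.apex_intensity
    if i_p <= 0:
        raise ValueError("precursor apex intensity must be positive")
    return i_f / i_p


def verdict(ppc_value: float | None, pps_value: float | None,
            ppc_cutoff: float = PPC_CUTOFF,
            pps_band: tuple[float, float] = PPS_BAND,
            n_shared: int | None = None) -> tuple[bool, list[str]]:
    """Accept/reject a precursor-product (or adduct-pair) association.

    Accept iff PPC >= cutoff and PPS inside the band, both bounds
    inclusive.  Returns ``(accepted, reasons)`` with one reason string per
    failed rule; an undefined PPC (too few shared scans) rejects with
    reason "insufficient scans".
    """
    reasons: list[str] = []
    if ppc_value is None:
        detail = f" ({n_shared} shared)" if n_shared is not None else ""
        reasons.append(f"insufficient scans{detail}")
    elif ppc_value < ppc_cutoff:
        reasons.append(f"PPC {ppc_value:.2f} < {ppc_cutoff:g}")
    if pps_value is not None:
        lo, hi = pps_band
        if not (lo <= pps_value <= hi):
            reasons.append(f"PPS {pps_value:.2f} outside [{lo:g}, {hi:g}]")
    return (not reasons, reasons)
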