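"""Extracted-ion-chromatogram construction, peak detection, shape metrics.

The workflow is targeted: for each library m/z an EIC is pulled from one
collision-energy channel (most intense centroid per scan inside a joint
5 ppm / 0.005 Da window), chromatographic peaks are detected as contiguous
above-threshold runs split at deep interior valleys, and each peak carries
the tailing-sensitive asymmetry factor

    f = (tRf - tRmax) / (tRmax - tRi)

where tRi, tRmax, tRf are the retention times of the first scan, the apex
scan and the last scan of the peak.  f = 1 indicates a symmetric peak; the
factor is defined as 0 when the peak has fewer than three scans or the apex
falls on an edge scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline

from .msio import ScanChannel

__all__ = [
    "EIC",
    "EICPeak",
    "SmoothedPeak",
    "extract_eic",
    "detect_peaks",
    "asymmetry_factor",
    "smooth_peak",
]


@dataclass
class EIC:
    """Per-scan trace of the best centroid near a target m/z.

    Scans with no centroid inside the window get a zero-intensity
    placeholder with NaN observed m/z, so the RT grid always matches the
    source channel.
    """

    target_mz: float
    ppm_tol: float
    mz_window: float
    scan_ids: np.ndarray
    rt: np.ndarray          # minutes
    intensity: np.ndarray
    observed_mz: np.ndarray  # NaN where no centroid matched

    @property
    def ppm_dev(self) -> np.ndarray:
        """Signed per-scan mass deviation in ppm (NaN on placeholders)."""
        return 1e6 * (self.observed_mz - self.target_mz) / self.target_mz

    @property
    def da_tolerance(self) -> float:
        return min(self.ppm_tol * 1e-6 * self.target_mz, self.mz_window)

    def __len__(self) -> int:
        return int(self.rt.size)


@dataclass
class EICPeak:
    """One detected chromatographic peak on an EIC."""

    eic: EIC
    first: int   # index into the EIC arrays
    apex: int
    last: int

    @property
    def slice(self) -> slice:
        return slice(self.first, self.last + 1)

    @property
    def rt(self) -> np.ndarray:
        return self.eic.rt[self.slice]

    @property
    def intensity(self) -> np.ndarray:
        return self.eic.intensity[self.slice]

    @property
    def scan_ids(self) -> np.ndarray:
        return self.eic.scan_ids[self.slice]

    @property
    def t_ri(self) -> float:
        return float(self.eic.rt[self.first])

    @property
    def t_rmax(self) -> float:
        return float(self.eic.rt[self.apex])

    @property
    def t_rf(self) -> float:
        return float(self.eic.rt[self.last])

    @property
    def apex_intensity(self) -> float:
        return float(self.eic.intensity[self.apex])

    @property
    def apex_mz(self) -> float:
        mz = self.eic.observed_mz[self.apex]
        return float(mz)

    @property
    def n_scans(self) -> int:
        return self.last - self.first + 1

    @property
    def area(self) -> float:
        """Trapezoidal area on the raw (unsmoothed) trace."""
        return float(np.trapezoid(self.intensity, self.rt))

    @property
    def mean_ppm_dev(self) -> float:
        dev = self.eic.ppm_dev[self.slice]
        dev = dev[np.isfinite(dev)]
        return float(np.mean(dev)) if dev.size else float("nan")

    @property
    def f(self) -> float:
        return asymmetry_factor(self)


@dataclass
class SmoothedPeak:
    """Spline-smoothed intensities of a peak on its original RT grid."""

    peak: EICPeak
    intensity: np.ndarray
    method: str
    smoothed: bool  # False when the peak was too short and passed through

    @property
    def rt(self) -> np.ndarray:
        return self.peak.rt

    @property
    def scan_ids(self) -> np.ndarray:
        return self.peak.scan_ids


def extract_eic(channel: ScanChannel, target_mz: float,
                ppm_tol: float = 5.0, mz_window: float = 0.005) -> EIC:
    """Build the EIC for ``target_mz`` over every scan of a channel.

    The match window is the tighter of the relative ppm tolerance and the
    absolute Da window; with the 5 ppm / 0.005 Da defaults the Da cap binds
    only above m/z 1000.  When several centroids of one scan fall inside the
    window the most intense is kept.
    """
    if ppm_tol <= 0 or mz_window <= 0:
        raise ValueError("tolerances must be positive")
    tol = min(ppm_tol * 1e-6 * target_mz, mz_window)
    n = len(channel.scans)
    scan_ids = np.empty(n, dtype=int)
    rt = np.empty(n)
    inten = np.zeros(n)
    obs = np.full(n, np.nan)
    for i, scan in enumerate(channel.scans):
        scan_ids[i] = scan.scan_id
        rt[i] = scan.rt_min
        lo = np.searchsorted(scan.mz, target_mz - tol, side="left")
        hi = np.searchsorted(scan.mz, target_mz + tol, side="right")
        if hi > lo:
            j = lo + int(np.argmax(scan.intensity[lo:hi]))
            inten[i] = scan.intensity[j]
            obs[i] = scan.mz[j]
    return EIC(target_mz, ppm_tol, mz_window, scan_ids, rt, inten, obs)


def detect_peaks(eic: EIC, min_scans: int = 3, min_intensity: float = 0.0,
                 valley_frac: float = 0.5) -> list[EICPeak]:
    """Detect chromatographic peaks as above-threshold runs split at valleys.

    A run of consecutive points with intensity above ``min_intensity``
    (strictly above zero when the threshold is zero, so placeholders never
    join a peak) is split at interior local minima lower than
    ``valley_frac`` times the smaller of the two flanking local maxima.
    Runs shorter than ``min_scans`` are dropped.  Peaks are returned in RT
    order with disjoint spans.
    """
    y = eic.intensity
    above = y > max(min_intensity, 0.0)
    peaks: list[EICPeak] = []
    i = 0
    n = y.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        peaks.extend(_split_run(eic, i, j, valley_frac, min_scans))
        i = j + 1
    return peaks


def _split_run(eic: EIC, first: int, last: int,
               valley_frac: float, min_scans: int) -> list[EICPeak]:
    y = eic.intensity
    seg = y[first:last + 1]
    if seg.size < 3:
        return _emit(eic, first, last, min_scans)
    # interior local minima that drop below valley_frac of both flanking maxima
    cut_points = []
    for k in range(1, seg.size - 1):
        if seg[k] <= seg[k - 1] and seg[k] <= seg[k + 1]:
            left_max = seg[:k].max()
            right_max = seg[k + 1:].max()
            if seg[k] < valley_frac * min(left_max, right_max):
                cut_points.append(k)
    if not cut_points:
        return _emit(eic, first, last, min_scans)
    # keep only the deepest valley between successive apexes: greedy split at
    # the global deepest qualifying valley, then recurse on both halves
    k = min(cut_points, key=lambda k: seg[k])
    return (_split_run(eic, first, first + k, valley_frac, min_scans)
            + _split_run(eic, first + k, last, valley_frac, min_scans))


def _emit(eic: EIC, first: int, last: int, min_scans: int) -> list[EICPeak]:
    if last - first + 1 < min_scans:
        return []
    apex = first + int(np.argmax(eic.intensity[first:last + 1]))
    return [EICPeak(eic, first, apex, last)]


def asymmetry_factor(peak: EICPeak) -> float:
    """Edge-to-apex retention-time ratio (tRf - tRmax)/(tRmax - tRi).

    Returns 0 for degenerate peaks: fewer than 3 scans, or the apex on the
    first or last scan (where a denominator or numerator vanishes).
    """
    if peak.n_scans < 3 or peak.apex in (peak.first, peak.last):
        return 0.0
    return (peak.t_rf - peak.t_rmax) / (peak.t_rmax - peak.t_ri)


def smooth_peak(peak: EICPeak, method: str = "smoothing-spline",
                parameter: float | None = None) -> SmoothedPeak:
    """Spline-smooth a peak's intensities on its own RT grid.

    ``method="cubic-spline"`` interpolates exactly (s=0); the default
    ``"smoothing-spline"`` picks the smoothing factor from the local noise
    level estimated by second differences unless ``parameter`` (the spline
    residual budget ``s``) is given.  Peaks with fewer than 4 scans pass
    through unsmoothed.  Fitted negatives are clamped to 0.
    """
    y = peak.intensity.astype(float)
    x = peak.rt
    if y.size < 4:
        return SmoothedPeak(peak, y.copy(), method, smoothed=False)
    if method == "cubic-spline":
        s = 0.0
    elif method == "smoothing-spline":
        if parameter is not None:
            s = float(parameter)
        else:
            # noise variance from second differences: var ~ mean(d2^2)/6
            d2 = np.diff(y, n=2)
            s = y.size * float(np.mean(d2 ** 2)) / 6.0 if d2.size else 0.0
    else:
        raise ValueError(f"unknown smoothing method {method!r}")
    k = min(3, y.size - 1)
    spl = UnivariateSpline(x, y, k=k, s=s)
    smoothed = np.clip(spl(x), 0.0, None)
    return SmoothedPeak(peak, smoothed, method, smoothed=True)
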