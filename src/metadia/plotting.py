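"""QC plots: annotated EICs with per-scan mass deviation, and
precursor-fragment co-elution overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .dia import DIAScores
from .ms1 import MS1Annotation
from .peaks import EICPeak

__all__ = ["plot_eic", "plot_coelution"]


def plot_eic(annotation: MS1Annotation | EICPeak, path: str | Path) -> None:
    """EIC trace with apex marker plus a per-scan m/z-deviation panel."""
    peak = annotation.peak if isinstance(annotation, MS1Annotation) else annotation
    eic = peak.eic
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(6, 5),
                                   height_ratios=[2, 1])
    ax1.plot(eic.rt, eic.intensity, "-o", ms=3, color="steelblue")
    ax1.axvline(peak.t_rmax, color="crimson", ls="--", lw=0.8)
    ax1.axvspan(peak.t_ri, peak.t_rf, alpha=0.15, color="steelblue")
    title = f"m/z {eic.target_mz:.4f}  f={peak.f:.2f}"
    if isinstance(annotation, MS1Annotation):
        title = (f"{annotation.metabolite} {annotation.adduct} "
                 f"+{annotation.isotopologue}  " + title)
    ax1.set_title(title, fontsize=10)
    ax1.set_ylabel("intensity")
    ax2.plot(eic.rt, eic.ppm_dev, "s", ms=3, color="gray")
    ax2.axhline(0, color="k", lw=0.5)
    ax2.set_ylabel("Δm/z (ppm)")
    ax2.set_xlabel("retention time (min)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_coelution(scores: DIAScores, path: str | Path) -> None:
    """Precursor + fragment traces overlaid, one panel per fragment pair."""
    group = scores.group
    n = max(len(scores.fragments), 1)
    fig, axes = plt.subplots(n, 1, sharex=True, figsize=(6, 2.2 * n),
                             squeeze=False)
    prec = group.precursor_peak
    for ax, fs in zip(axes.ravel(), scores.fragments):
        frag = fs.match.peak
        ax.plot(prec.rt, prec.intensity / prec.apex_intensity, "-o", ms=3,
                color="steelblue",
                label=f"precursor {group.entry.precursor_mz:.4f}")
        ax.plot(frag.rt, frag.intensity / prec.apex_intensity, "-s", ms=3,
                color="crimson", label=f"fragment {fs.match.library_mz:.4f}")
        ppc_txt = "n/a" if not fs.ppc.defined else f"{fs.ppc.r:.2f}"
        ax.set_title(f"PPC {ppc_txt}  PPS {fs.pps:.2f}  "
                     f"F/P {fs.fp_ratio:.2f}", fontsize=9)
        ax.legend(fontsize=7)
        ax.set_ylabel("rel. intensity")
    axes.ravel()[-1].set_xlabel("retention time (min)")
    fig.suptitle(f"{group.metabolite} {group.adduct} @ CE {group.energy}",
                 fontsize=10)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
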