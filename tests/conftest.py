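import base64
import struct
import zlib

import numpy as np
import pytest

from metadia.msio import Scan, ScanChannel
from metadia.peaks import EIC
from metadia.simulate import (demo_ms1_library, demo_msms_library, demo_truth,
                              simulate_run)


def make_eic(intensities, target_mz=147.0764, rt0=0.0, period=1.0 / 60.0,
             observed=None):
    """EIC directly from an intensity vector on a uniform RT grid."""
    y = np.asarray(intensities, dtype=float)
    n = y.size
    rt = rt0 + period * np.arange(n)
    if observed is None:
        observed = np.where(y > 0, target_mz, np.nan)
    return EIC(target_mz, 5.0, 0.005, np.arange(1, n + 1), rt, y,
               np.asarray(observed, dtype=float))


def make_channel(traces, rt0=0.0, period=1.0 / 60.0, n_scans=30,
                 energy="0", ms_level=1, polarity="positive", id0=1):
    """Channel whose scans contain Gaussian traces.

    ``traces`` is a list of (mz, apex_rt, sigma_min, apex_intensity).
    """
    scans = []
    for i in range(n_scans):
        t = rt0 + i * period
        mzs, ints = [], []
        for mz, apex_rt, sigma, apex in traces:
            inten = apex * np.exp(-0.5 * ((t - apex_rt) / sigma) ** 2)
            if inten >= 1.0:
                mzs.append(mz)
                ints.append(inten)
        scans.append(Scan(id0 + i, t, ms_level, energy, polarity,
                          np.array(mzs), np.array(ints)))
    return ScanChannel(energy, ms_level, polarity, scans)


def write_mzxml(scans, path):
    """Minimal mzXML 3.2 writer (network-order packed peaks) for fixtures."""
    lines = ['<?xml version="1.0" encoding="ISO-8859-1"?>',
             '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/'
             'mzXML_3.2">',
             f'  <msRun scanCount="{len(scans)}">']
    for s in scans:
        packed = b"".join(struct.pack(">ff", m, i)
                          for m, i in zip(s.mz, s.intensity))
        b64 = base64.b64encode(packed).decode()
        pol = {"positive": "+", "negative": "-"}.get(s.polarity, "")
        ce = (f' collisionEnergy="{float(s.collision_energy):g}"'
              if s.collision_energy not in (None, "unknown") else "")
        lines.append(
            f'    <scan num="{s.scan_id}" msLevel="{s.ms_level}" '
            f'retentionTime="PT{s.rt_min * 60:.4f}S" polarity="{pol}"'
            f'{ce} peaksCount="{s.n_peaks}">')
        lines.append('      <peaks precision="32" byteOrder="network" '
                     f'compressionType="none">{b64}</peaks>')
        lines.append('    </scan>')
    lines += ['  </msRun>', '</mzXML>']
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


@pytest.fixture(scope="session")
def ms1_library():
    return demo_ms1_library()


@pytest.fixture(scope="session")
def msms_library():
    return demo_msms_library()


@pytest.fixture(scope="session")
def demo_run():
    """One synthetic 4-channel run plus its ground truth."""
    truth = demo_truth()
    scans = simulate_run(truth, seed=7, noise_floor=100.0)
    return scans, truth
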