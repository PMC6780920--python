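"""Reading and writing centroided LC-MS runs, and collision-energy demultiplexing.

Multiplexed DIA runs interleave full-scan spectra acquired at several
collision energies (e.g. CID 0/5/10/20 eV on a q-TOF, or HCD 0/30% on a
q-Orbitrap).  This module parses mzML 1.1 and mzXML 3.x files into
:class:`Scan` objects and splits them into per-energy :class:`ScanChannel`
streams; the 0-energy channel is the intact-molecule MS1 channel, the others
carry all-ion-fragmentation MS/MS spectra.

The parser is a self-contained lxml implementation of the two PSI formats
(centroid spectra only): base64-encoded little-endian 32/64-bit float peak
arrays, optionally zlib-compressed.  A deterministic mzML writer is provided
for synthetic runs and round-trip tests.
"""

from __future__ import annotations

import base64
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

__all__ = [
    "Scan",
    "ScanChannel",
    "read_run",
    "write_mzml",
    "split_by_energy",
    "energy_label",
]

_MZML_NS = "http://psi.hupo.org/ms/mzml"
_MZXML_NS = "http://sashimi.sourceforge.net/schema_revision/mzXML_3.2"


@dataclass
class Scan:
    """One centroided spectrum.

    Retention time is always minutes; collision energy is kept in instrument
    units as a string label ("0", "5", "30" ...), "unknown" when the file
    carries no energy metadata.
    """

    scan_id: int
    rt_min: float
    ms_level: int
    collision_energy: str
    polarity: str  # "positive" | "negative" | "unknown"
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt_min < 0:
            raise ValueError("retention time must be >= 0")
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass
class ScanChannel:
    """Time-ordered scans sharing one (ms level, collision energy, polarity)."""

    energy: str
    ms_level: int
    polarity: str
    scans: list[Scan] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.scans)

    def __iter__(self):
        return iter(self.scans)

    @property
    def rt(self) -> np.ndarray:
        return np.array([s.rt_min for s in self.scans])

    @property
    def is_ms1(self) -> bool:
        """Energy 0 at any ms level is treated as the intact-molecule channel."""
        return _energy_value(self.energy) == 0.0

    def median_scan_period(self) -> float:
        rts = self.rt
        if rts.size < 2:
            return 0.0
        return float(np.median(np.diff(rts)))


def energy_label(value) -> str:
    """Normalize a collision-energy value to a canonical string label."""
    if value is None:
        return "unknown"
    try:
        v = float(value)
    except (TypeError, ValueError):
        return str(value)
    return str(int(v)) if v == int(v) else f"{v:g}"


def _energy_value(label: str) -> float | None:
    try:
        return float(label)
    except (TypeError, ValueError):
        return None


# ---------------------------------------------------------------------------
# binary peak arrays

def _decode_array(binary_text: str, precision: int, compressed: bool) -> np.ndarray:
    raw = base64.b64decode(binary_text)
    if compressed:
        raw = zlib.decompress(raw)
    dtype = "<f8" if precision == 64 else "<f4"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _encode_array(values: np.ndarray) -> str:
    return base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode("ascii")


# ---------------------------------------------------------------------------
# mzML reading

def _lname(elem) -> str:
    return etree.QName(elem).localname


def _cv_params(elem) -> dict[str, str]:
    out = {}
    for cv in elem:
        if _lname(cv) == "cvParam":
            out[cv.get("name")] = cv.get("value", "")
    return out


def _rt_minutes(value: float, unit: str | None) -> float:
    if unit and unit.lower().startswith("sec"):
        return value / 60.0
    if unit and unit.lower().startswith("milli"):
        return value / 60000.0
    return value  # minutes (mzML default for scan start time varies; unit attr rules)


def _parse_mzml_spectrum(spec, index: int) -> Scan:
    ms_level = 1
    polarity = "unknown"
    rt = 0.0
    energy: str = "unknown"
    mz = np.array([])
    inten = np.array([])
    centroided = True
    for child in spec.iter():
        name = _lname(child)
        if name == "cvParam":
            acc, val = child.get("accession", ""), child.get("value", "")
            if acc == "MS:1000511":
                ms_level = int(val)
            elif acc == "MS:1000130":
                polarity = "positive"
            elif acc == "MS:1000129":
                polarity = "negative"
            elif acc == "MS:1000128":
                centroided = False
            elif acc == "MS:1000016":
                rt = _rt_minutes(float(val), child.get("unitName"))
            elif acc == "MS:1000045":
                energy = energy_label(val)
    if not centroided:
        raise ValueError(
            f"spectrum index {index} is profile mode; centroid the data first"
        )
    for bda in spec.iter(f"{{{_MZML_NS}}}binaryDataArray"):
        params = {cv.get("accession"): cv.get("value", "")
                  for cv in bda if _lname(cv) == "cvParam"}
        precision = 64 if "MS:1000523" in params else 32
        compressed = "MS:1000574" in params
        binary = bda.find(f"{{{_MZML_NS}}}binary")
        arr = _decode_array(binary.text or "", precision, compressed)
        if "MS:1000514" in params:
            mz = arr
        elif "MS:1000515" in params:
            inten = arr
    sid = spec.get("id", "")
    scan_number = index + 1
    for token in sid.split():
        if token.startswith("scan="):
            scan_number = int(token.split("=", 1)[1])
    return Scan(scan_number, rt, ms_level, energy, polarity, mz, inten)


def _read_mzml(path: Path) -> list[Scan]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed mzML {path}: {exc}") from exc
    scans = []
    for i, spec in enumerate(tree.iter(f"{{{_MZML_NS}}}spectrum")):
        scans.append(_parse_mzml_spectrum(spec, i))
    return scans


# ---------------------------------------------------------------------------
# mzXML reading

def _parse_mzxml_rt(text: str) -> float:
    # xsd:duration like "PT63.5S" or "PT1.2M"
    text = text.strip()
    if text.startswith("PT"):
        body = text[2:]
        if body.endswith("S"):
            return float(body[:-1]) / 60.0
        if body.endswith("M"):
            return float(body[:-1])
    return float(text)


def _read_mzxml(path: Path) -> list[Scan]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed mzXML {path}: {exc}") from exc
    scans = []
    for elem in tree.iter():
        if _lname(elem) != "scan":
            continue
        num = int(elem.get("num", len(scans) + 1))
        rt = _parse_mzxml_rt(elem.get("retentionTime", "PT0S"))
        ms_level = int(elem.get("msLevel", "1"))
        ce = elem.get("collisionEnergy")
        energy = energy_label(ce) if ce is not None else "unknown"
        pol = {"+": "positive", "-": "negative"}.get(elem.get("polarity", ""), "unknown")
        if elem.get("centroided", "1") == "0":
            raise ValueError(f"scan {num} is profile mode; centroid the data first")
        mz = inten = np.array([])
        for child in elem:
            if _lname(child) == "peaks":
                precision = int(child.get("precision", "32"))
                compressed = child.get("compressionType", "none") == "zlib"
                raw = base64.b64decode(child.text or "")
                if compressed:
                    raw = zlib.decompress(raw)
                # mzXML packs network-order (big-endian) interleaved m/z,intensity
                dtype = ">f8" if precision == 64 else ">f4"
                arr = np.frombuffer(raw, dtype=dtype).astype(float)
                mz, inten = arr[0::2], arr[1::2]
        scans.append(Scan(num, rt, ms_level, energy, pol, mz, inten))
    return scans


def read_run(path: str | Path, format: str | None = None,
             energy_cycle: list | None = None) -> list[Scan]:
    """Read a centroided mzML or mzXML run into a list of :class:`Scan`.

    Parameters
    ----------
    path : file path; format inferred from the extension unless ``format``
        ("mzML" or "mzXML") is given.
    energy_cycle : optional fallback cycle of collision energies (e.g.
        ``[0, 5, 10, 20]``) assigned by scan order to scans whose file
        metadata carries no energy.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "mzml":
        scans = _read_mzml(path)
    elif fmt == "mzxml":
        scans = _read_mzxml(path)
    else:
        raise ValueError(f"unsupported format {fmt!r}; expected mzML or mzXML")
    missing = [s for s in scans if s.collision_energy == "unknown"]
    if missing:
        if energy_cycle:
            labels = [energy_label(e) for e in energy_cycle]
            for i, s in enumerate(scans):
                if s.collision_energy == "unknown":
                    s.collision_energy = labels[i % len(labels)]
        else:
            warnings.warn(
                f"{len(missing)} scan(s) lack collision-energy metadata; "
                "recorded as 'unknown' (pass energy_cycle to assign by order)"
            )
    return scans


# ---------------------------------------------------------------------------
# mzML writing (deterministic; used by the simulator and round-trip tests)

def write_mzml(scans: list[Scan], path: str | Path) -> None:
    """Write scans to a minimal, schema-shaped mzML 1.1 document.

    Output is byte-deterministic for identical input (no timestamps),
    64-bit float arrays, no compression.
    """
    nsmap = {None: _MZML_NS}
    root = etree.Element(f"{{{_MZML_NS}}}mzML", nsmap=nsmap, version="1.1.0")
    run = etree.SubElement(root, f"{{{_MZML_NS}}}run", id="run")
    slist = etree.SubElement(run, f"{{{_MZML_NS}}}spectrumList",
                             count=str(len(scans)))

    def cv(parent, accession, name, value="", **extra):
        etree.SubElement(parent, f"{{{_MZML_NS}}}cvParam", cvRef="MS",
                         accession=accession, name=name, value=value, **extra)

    for i, s in enumerate(scans):
        spec = etree.SubElement(
            slist, f"{{{_MZML_NS}}}spectrum", index=str(i),
            id=f"scan={s.scan_id}", defaultArrayLength=str(s.n_peaks))
        cv(spec, "MS:1000511", "ms level", str(s.ms_level))
        cv(spec, "MS:1000127", "centroid spectrum")
        if s.polarity == "positive":
            cv(spec, "MS:1000130", "positive scan")
        elif s.polarity == "negative":
            cv(spec, "MS:1000129", "negative scan")
        scan_list = etree.SubElement(spec, f"{{{_MZML_NS}}}scanList", count="1")
        scan_el = etree.SubElement(scan_list, f"{{{_MZML_NS}}}scan")
        cv(scan_el, "MS:1000016", "scan start time", f"{s.rt_min:.8f}",
           unitAccession="UO:0000031", unitName="minute", unitCvRef="UO")
        ev = _energy_value(s.collision_energy)
        if ev is not None:
            plist = etree.SubElement(spec, f"{{{_MZML_NS}}}precursorList", count="1")
            prec = etree.SubElement(plist, f"{{{_MZML_NS}}}precursor")
            act = etree.SubElement(prec, f"{{{_MZML_NS}}}activation")
            cv(act, "MS:1000045", "collision energy", f"{ev:g}",
               unitAccession="UO:0000266", unitName="electronvolt", unitCvRef="UO")
        bdal = etree.SubElement(spec, f"{{{_MZML_NS}}}binaryDataArrayList", count="2")
        for acc, name, arr in (("MS:1000514", "m/z array", s.mz),
                               ("MS:1000515", "intensity array", s.intensity)):
            enc = _encode_array(arr)
            bda = etree.SubElement(bdal, f"{{{_MZML_NS}}}binaryDataArray",
                                   encodedLength=str(len(enc)))
            cv(bda, "MS:1000523", "64-bit float")
            cv(bda, "MS:1000576", "no compression")
            cv(bda, acc, name)
            etree.SubElement(bda, f"{{{_MZML_NS}}}binary").text = enc
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8",
               pretty_print=True)


# ---------------------------------------------------------------------------
# demultiplexing

def split_by_energy(scans: list[Scan],
                    polarity: str | None = None) -> dict[str, ScanChannel]:
    """Partition time-ordered scans into per-collision-energy channels.

    Channels are keyed jointly on (ms level, energy label); energy 0 at any
    ms level is the MS1 channel.  An optional polarity filter is applied
    before the split (fast polarity-switching runs interleave both).
    Every retained scan lands in exactly one channel and within-channel RT
    order is preserved.
    """
    if polarity is not None:
        scans = [s for s in scans if s.polarity == polarity]
    grouped: dict[tuple[int, str], list[Scan]] = {}
    for s in scans:
        grouped.setdefault((s.ms_level, s.collision_energy), []).append(s)
    # label channels by energy alone unless one energy spans several ms levels
    levels_per_energy: dict[str, set[int]] = {}
    for level, energy in grouped:
        levels_per_energy.setdefault(energy, set()).add(level)
    channels: dict[str, ScanChannel] = {}
    for (level, energy), members in grouped.items():
        label = energy if len(levels_per_energy[energy]) == 1 else f"{energy}@ms{level}"
        members.sort(key=lambda s: s.rt_min)
        channels[label] = ScanChannel(energy, level, members[0].polarity, members)
    return channels
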