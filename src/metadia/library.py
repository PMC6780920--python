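"""CSV metabolite libraries for targeted MS1 and AIF MS/MS annotation.

Two dialects, both plain UTF-8 CSV:

* **MS1 (neutral-mass) library** — columns ``name, formula, neutral_mass,
  polarity, rt``.  Either ``formula`` or ``neutral_mass`` must be present
  per row; when both are given they must agree.  ``polarity`` is
  ``positive``/``negative``/``any`` (blank = any); ``rt`` (minutes) is an
  optional retention-time constraint.

* **AIF MS/MS library** — long layout with columns ``name, adduct,
  precursor_mz, fragment_mz, ce, polarity`` (one row per fragment), or wide
  layout where a ``fragments`` column holds a ``;``-separated m/z list.
  An optional ``neutral_mass`` column is cross-checked against
  ``precursor_mz`` through the adduct registry at load time.

Curation checks mirror common AIF-library hygiene: entries whose every
fragment lies below m/z 50 are unusable on instruments scanning from m/z 50,
and entries supported by a single ubiquitous fragment (one shared by many
other library entries, e.g. the m/z 72.0444 alanine immonium ion) carry no
specificity.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import Formula, adduct_mz, monoisotopic_mass, ppm_error

__all__ = [
    "LibraryEntry",
    "MSMSLibraryEntry",
    "load_ms1_library",
    "load_msms_library",
    "save_ms1_library",
    "save_msms_library",
    "validate_library",
]


@dataclass
class LibraryEntry:
    name: str
    neutral_mass: float
    polarity: str = "any"  # "positive" | "negative" | "any"
    rt_min: float | None = None
    formula: Formula | None = None

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError(f"{self.name}: neutral mass must be positive")
        if self.rt_min is not None and self.rt_min < 0:
            raise ValueError(f"{self.name}: retention time must be >= 0")


@dataclass
class MSMSLibraryEntry:
    name: str
    adduct: str
    precursor_mz: float
    fragments: list[float]            # sorted ascending, 1-ppm deduplicated
    fragment_ce: list[str | None] = field(default_factory=list)
    polarity: str = "any"

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError(f"{self.name}: at least one fragment required")
        if not self.fragment_ce:
            self.fragment_ce = [None] * len(self.fragments)
        order = np.argsort(self.fragments)
        self.fragments = [float(self.fragments[i]) for i in order]
        self.fragment_ce = [self.fragment_ce[i] for i in order]
        self.fragments, self.fragment_ce = _dedup_ppm(
            self.fragments, self.fragment_ce, ppm=1.0)
        for f in self.fragments:
            if f > self.precursor_mz + 0.5:
                raise ValueError(
                    f"{self.name}: fragment {f} exceeds precursor "
                    f"{self.precursor_mz} by more than 0.5 Da")


def _dedup_ppm(mzs: list[float], ces: list, ppm: float = 1.0):
    out_mz: list[float] = []
    out_ce: list = []
    for mz, ce in zip(mzs, ces):
        if out_mz and abs(ppm_error(mz, out_mz[-1])) <= ppm:
            continue
        out_mz.append(mz)
        out_ce.append(ce)
    return out_mz, out_ce


def _norm_polarity(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "any"
    v = str(value).strip().lower()
    if v in ("", "any", "neutral"):
        return "any"
    if v in ("positive", "pos", "+"):
        return "positive"
    if v in ("negative", "neg", "-"):
        return "negative"
    raise ValueError(f"unknown polarity {value!r}")


def _read_csv(path: str | Path, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing mandatory column(s): {', '.join(sorted(missing))}")
    return df


def load_ms1_library(path: str | Path) -> list[LibraryEntry]:
    """Load the neutral-mass library; masses derived from formulas when the
    mass column is blank.  Duplicate (name, polarity) rows abort the load."""
    df = _read_csv(path, required={"name"})
    if "formula" not in df.columns and "neutral_mass" not in df.columns:
        raise ValueError(f"{path}: need a 'formula' or 'neutral_mass' column")
    entries: list[LibraryEntry] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        name = str(row["name"]).strip()
        formula = None
        raw_formula = row.get("formula")
        if isinstance(raw_formula, str) and raw_formula.strip():
            formula = Formula.parse(raw_formula)
        raw_mass = row.get("neutral_mass")
        if isinstance(raw_mass, str) and raw_mass.strip():
            try:
                mass = float(raw_mass)
            except ValueError:
                raise ValueError(
                    f"{path}:{line}: non-numeric neutral_mass {raw_mass!r}")
            if formula is not None:
                calc = monoisotopic_mass(formula)
                if abs(ppm_error(mass, calc)) > 20:
                    raise ValueError(
                        f"{path}:{line}: neutral_mass {mass} disagrees with "
                        f"formula {formula} ({calc:.5f})")
        elif formula is not None:
            mass = monoisotopic_mass(formula)
        else:
            raise ValueError(f"{path}:{line}: row has neither mass nor formula")
        rt_raw = row.get("rt")
        rt = float(rt_raw) if isinstance(rt_raw, str) and rt_raw.strip() else None
        entries.append(LibraryEntry(name, mass, _norm_polarity(row.get("polarity")),
                                    rt, formula))
    dupes = _duplicates((e.name, e.polarity) for e in entries)
    if dupes:
        raise ValueError(f"{path}: duplicate entries: {sorted(dupes)}")
    if not entries:
        warnings.warn(f"{path}: library is empty")
    return entries


def _duplicates(keys) -> set:
    seen, dup = set(), set()
    for k in keys:
        if k in seen:
            dup.add(k)
        seen.add(k)
    return dup


def load_msms_library(path: str | Path) -> list[MSMSLibraryEntry]:
    """Load the AIF MS/MS library (long or wide fragment layout).

    One entry is produced per (metabolite, adduct); fragment lists are
    sorted and deduplicated within 1 ppm.  When a ``neutral_mass`` column is
    present the stated precursor m/z is cross-checked against the adduct
    registry (20 ppm).
    """
    df = _read_csv(path, required={"name", "adduct", "precursor_mz"})
    long_layout = "fragment_mz" in df.columns
    if not long_layout and "fragments" not in df.columns:
        raise ValueError(f"{path}: need a 'fragment_mz' (long) or "
                         f"'fragments' (wide) column")
    groups: dict[tuple[str, str], dict] = {}
    for i, row in df.iterrows():
        line = i + 2
        name = str(row["name"]).strip()
        adduct = str(row["adduct"]).strip()
        prec = float(row["precursor_mz"])
        raw_nm = row.get("neutral_mass")
        if isinstance(raw_nm, str) and raw_nm.strip():
            expected = adduct_mz(float(raw_nm), adduct)
            if abs(ppm_error(prec, expected)) > 20:
                raise ValueError(
                    f"{path}:{line}: precursor_mz {prec} disagrees with "
                    f"neutral_mass + {adduct} ({expected:.5f})")
        key = (name, adduct)
        g = groups.setdefault(key, {"prec": prec, "frags": [], "ces": [],
                                    "polarity": _norm_polarity(row.get("polarity"))})
        ce_raw = row.get("ce")
        ce = str(ce_raw).strip() if isinstance(ce_raw, str) and ce_raw.strip() else None
        if long_layout:
            frag = float(row["fragment_mz"])
            if frag > prec + 0.5:
                raise ValueError(
                    f"{path}:{line}: fragment {frag} above precursor {prec} "
                    f"by more than 0.5 Da")
            g["frags"].append(frag)
            g["ces"].append(ce)
        else:
            for tok in str(row["fragments"]).split(";"):
                tok = tok.strip()
                if tok:
                    g["frags"].append(float(tok))
                    g["ces"].append(ce)
    entries = [
        MSMSLibraryEntry(name, adduct, g["prec"], g["frags"], g["ces"],
                         g["polarity"])
        for (name, adduct), g in groups.items()
    ]
    if not entries:
        warnings.warn(f"{path}: library is empty")
    return entries


def save_ms1_library(entries: list[LibraryEntry], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "formula", "neutral_mass", "polarity", "rt"])
        for e in entries:
            w.writerow([e.name, str(e.formula) if e.formula else "",
                        f"{e.neutral_mass:.6f}", e.polarity,
                        "" if e.rt_min is None else f"{e.rt_min:.4f}"])


def save_msms_library(entries: list[MSMSLibraryEntry], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "adduct", "precursor_mz", "fragment_mz", "ce",
                    "polarity"])
        for e in entries:
            for frag, ce in zip(e.fragments, e.fragment_ce):
                w.writerow([e.name, e.adduct, f"{e.precursor_mz:.6f}",
                            f"{frag:.6f}", ce or "", e.polarity])


@dataclass
class LibraryIssue:
    name: str
    adduct: str
    rule: str       # "all-fragments-below-50" | "single-ubiquitous-fragment"
    detail: str


def validate_library(entries: list[MSMSLibraryEntry],
                     ubiquity_k: int = 5, min_fragment_mz: float = 50.0,
                     strict: bool = False
                     ) -> tuple[list[LibraryIssue], list[MSMSLibraryEntry]]:
    """Flag low-specificity AIF library entries.

    Returns ``(issues, entries)``; the returned entry list drops flagged
    entries only when ``strict`` is set.  Rules: every fragment below the
    instrument's low-m/z cutoff (default 50), or a single fragment shared
    (within 5 ppm) with more than ``ubiquity_k`` other entries.
    """
    issues: list[LibraryIssue] = []
    flagged: set[int] = set()
    for idx, e in enumerate(entries):
        if all(f < min_fragment_mz for f in e.fragments):
            issues.append(LibraryIssue(
                e.name, e.adduct, "all-fragments-below-50",
                f"fragments {e.fragments} all below m/z {min_fragment_mz:g}"))
            flagged.add(idx)
        if len(e.fragments) == 1:
            frag = e.fragments[0]
            sharers = [
                o.name for j, o in enumerate(entries) if j != idx
                and any(abs(ppm_error(frag, f)) <= 5.0 for f in o.fragments)
            ]
            if len(sharers) > ubiquity_k:
                issues.append(LibraryIssue(
                    e.name, e.adduct, "single-ubiquitous-fragment",
                    f"only fragment {frag} shared with {len(sharers)} entries"))
                flagged.add(idx)
    kept = ([e for i, e in enumerate(entries) if i not in flagged]
            if strict else list(entries))
    return issues, kept
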