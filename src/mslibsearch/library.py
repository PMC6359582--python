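"""Spectral-library container: compounds with collision-energy series.

A library stores one :class:`CompoundRecord` per compound, each holding the
compound's whole series of reference spectra acquired at different collision
energies; state-of-the-art libraries carry such multi-spectrum series so that
a query acquired at an arbitrary energy still finds a comparable reference.
Candidate retrieval is by precursor m/z through a sorted index; candidate
selection is per spectrum, aggregation per compound (a compound may own
entries at several precursor m/z values: isotopes, adducts, in-source
fragments).
"""

from __future__ import annotations

import bisect
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Tuple, Union

from .spectra import CID, HCD, UNKNOWN, CollisionEnergy, Peak, Spectrum

logger = logging.getLogger(__name__)

INSTRUMENT_CLASSES = ("QqTOF", "Orbitrap", "mixed", "synthetic")


@dataclass
class CompoundInfo:
    """Compound-level metadata attached to each incoming spectrum."""

    compound_key: str
    name: str = ""
    formula: Optional[str] = None
    monoisotopic_mass: Optional[float] = None


def compound_key_from(inchikey: Optional[str] = None, name: Optional[str] = None) -> str:
    """Canonical compound key: InChIKey skeleton block, else case-folded name.

    The first 14 characters of an InChIKey identify the 2D skeleton, which
    lets the same compound match across libraries that differ in salt or
    protonation records.
    """
    if inchikey:
        return inchikey.strip()[:14]
    if name:
        return " ".join(name.casefold().split())
    raise ValueError("need an InChIKey or a name to build a compound key")


@dataclass
class CompoundRecord:
    """A library compound and its series of reference spectra."""

    compound_key: str
    name: str = ""
    formula: Optional[str] = None
    monoisotopic_mass: Optional[float] = None
    spectra: list[Spectrum] = field(default_factory=list)

    def validate(self) -> None:
        if not self.spectra:
            raise ValueError(f"compound {self.compound_key} has no spectra")
        for s in self.spectra:
            if s.compound_id != self.compound_key:
                raise ValueError(
                    f"spectrum {s.source_id} carries compound_id {s.compound_id!r}, "
                    f"expected {self.compound_key!r}"
                )


@dataclass
class LibraryStats:
    n_compounds: int
    n_spectra: int
    n_by_activation: dict
    n_by_ce: dict  # CollisionEnergy (or None for absent) -> count


@dataclass
class SpectralLibrary:
    """A named spectral library with a precursor-m/z index."""

    name: str
    instrument_class: str
    compounds: dict  # compound_key -> CompoundRecord, sorted by key
    _index_mz: list = field(default_factory=list, repr=False)
    _index_entries: list = field(default_factory=list, repr=False)  # (key, Spectrum)

    def __post_init__(self) -> None:
        if self.instrument_class not in INSTRUMENT_CLASSES:
            raise ValueError(f"instrument_class must be one of {INSTRUMENT_CLASSES}")
        self._rebuild_index()

    def _rebuild_index(self) -> None:
        entries = [
            (s.precursor_mz, key, s)
            for key, rec in self.compounds.items()
            for s in rec.spectra
        ]
        entries.sort(key=lambda e: (e[0], e[1], e[2].source_id))
        self._index_mz = [e[0] for e in entries]
        self._index_entries = [(e[1], e[2]) for e in entries]

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def n_spectra(self) -> int:
        return len(self._index_entries)

    def all_spectra(self) -> list:
        """(compound_key, Spectrum) pairs in deterministic (key, source) order."""
        return [
            (key, s)
            for key, rec in self.compounds.items()
            for s in sorted(rec.spectra, key=lambda q: q.source_id)
        ]


def build_library(
    records: Iterable[Tuple[CompoundInfo, Spectrum]],
    name: str,
    instrument_class: str,
) -> SpectralLibrary:
    """Group (metadata, spectrum) pairs into a library.

    Conflicting metadata for one compound key (e.g. two different formulas)
    logs a warning and keeps the first value seen.  Iteration order is sorted
    by compound key, so rebuilding from the same records is deterministic.
    """
    grouped: dict = {}
    for info, spectrum in records:
        if not info.compound_key:
            raise ValueError("record without a usable compound identifier")
        rec = grouped.get(info.compound_key)
        if rec is None:
            rec = CompoundRecord(
                compound_key=info.compound_key,
                name=info.name,
                formula=info.formula,
                monoisotopic_mass=info.monoisotopic_mass,
            )
            grouped[info.compound_key] = rec
        else:
            for attr in ("name", "formula", "monoisotopic_mass"):
                new = getattr(info, attr)
                old = getattr(rec, attr)
                if new and old and new != old:
                    logger.warning(
                        "conflicting %s for compound %s (%r vs %r); keeping the first",
                        attr, info.compound_key, old, new,
                    )
                elif new and not old:
                    setattr(rec, attr, new)
        if spectrum.compound_id != info.compound_key:
            spectrum = Spectrum(
                peaks=spectrum.peaks,
                precursor_mz=spectrum.precursor_mz,
                charge=spectrum.charge,
                collision_energy=spectrum.collision_energy,
                activation=spectrum.activation,
                resolution=spectrum.resolution,
                compound_id=info.compound_key,
                source_id=spectrum.source_id,
            )
        rec.spectra.append(spectrum)
    if not grouped:
        raise ValueError("cannot build a library from an empty record list")
    for rec in grouped.values():
        rec.validate()
    ordered = {key: grouped[key] for key in sorted(grouped)}
    return SpectralLibrary(name=name, instrument_class=instrument_class, compounds=ordered)


def candidates(
    library: SpectralLibrary, precursor_mz: float, precursor_tol: float
) -> list:
    """Compounds with ≥1 spectrum whose precursor lies within ±tol (closed).

    Returns :class:`CompoundRecord` objects sorted by compound key.
    """
    if not (precursor_tol > 0):
        raise ValueError("precursor_tol must be positive")
    lo = bisect.bisect_left(library._index_mz, precursor_mz - precursor_tol)
    hi = bisect.bisect_right(library._index_mz, precursor_mz + precursor_tol)
    keys = set()
    for key, spectrum in library._index_entries[lo:hi]:
        if abs(spectrum.precursor_mz - precursor_mz) <= precursor_tol:
            keys.add(key)
    return [library.compounds[key] for key in sorted(keys)]


def library_overlap(
    lib_a: SpectralLibrary, lib_b: SpectralLibrary
) -> Tuple[set, set, set]:
    """(shared, a-only, b-only) compound-key sets; a disjoint partition."""
    a = set(lib_a.compounds)
    b = set(lib_b.compounds)
    return a & b, a - b, b - a


def library_stats(library: SpectralLibrary) -> LibraryStats:
    n_by_activation = {CID: 0, HCD: 0, UNKNOWN: 0}
    n_by_ce: dict = {}
    for _, spectrum in library.all_spectra():
        n_by_activation[spectrum.activation] += 1
        n_by_ce[spectrum.collision_energy] = n_by_ce.get(spectrum.collision_energy, 0) + 1
    return LibraryStats(
        n_compounds=library.n_compounds,
        n_spectra=library.n_spectra,
        n_by_activation=n_by_activation,
        n_by_ce=n_by_ce,
    )


# ---------------------------------------------------------------------------
# JSON-lines serialization (diffable fixture format)


def save_library(library: SpectralLibrary, path: Union[str, Path]) -> None:
    """Serialize as JSON lines: a header line, then one line per spectrum.

    The layout is deterministic (compounds by key, spectra by source_id), so
    two renders from the same seed produce byte-identical files.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as handle:
        header = {
            "library": library.name,
            "instrument_class": library.instrument_class,
            "n_compounds": library.n_compounds,
            "n_spectra": library.n_spectra,
        }
        handle.write(json.dumps(header, sort_keys=True) + "\n")
        for key, spectrum in library.all_spectra():
            rec = library.compounds[key]
            row = {
                "compound_key": key,
                "name": rec.name,
                "formula": rec.formula,
                "monoisotopic_mass": rec.monoisotopic_mass,
                "precursor_mz": spectrum.precursor_mz,
                "charge": spectrum.charge,
                "ce_value": spectrum.collision_energy.value if spectrum.collision_energy else None,
                "ce_scheme": spectrum.collision_energy.scheme if spectrum.collision_energy else None,
                "ce_spread": spectrum.collision_energy.spread if spectrum.collision_energy else None,
                "activation": spectrum.activation,
                "resolution": spectrum.resolution,
                "source_id": spectrum.source_id,
                "peaks": [[p.mz, p.intensity] for p in spectrum.peaks],
            }
            handle.write(json.dumps(row, sort_keys=True) + "\n")


def load_library(path: Union[str, Path]) -> SpectralLibrary:
    """Load a library serialized by :func:`save_library`."""
    path = Path(path)
    records = []
    with open(path, "r", encoding="utf-8") as handle:
        header = json.loads(handle.readline())
        for line in handle:
            if not line.strip():
                continue
            row = json.loads(line)
            ce = None
            if row["ce_scheme"] is not None:
                ce = CollisionEnergy(
                    row["ce_scheme"], row["ce_value"], row.get("ce_spread") or 0.0
                )
            spectrum = Spectrum(
                peaks=[Peak(mz, i) for mz, i in row["peaks"]],
                precursor_mz=row["precursor_mz"],
                charge=row["charge"],
                collision_energy=ce,
                activation=row["activation"],
                resolution=row["resolution"],
                compound_id=row["compound_key"],
                source_id=row["source_id"],
            )
            info = CompoundInfo(
                compound_key=row["compound_key"],
                name=row["name"] or "",
                formula=row["formula"],
                monoisotopic_mass=row["monoisotopic_mass"],
            )
            records.append((info, spectrum))
    return build_library(records, name=header["library"], instrument_class=header["instrument_class"])
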