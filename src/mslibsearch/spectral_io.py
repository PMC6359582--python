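"""Readers and writers for the spectrum formats the workflow touches.

Supported formats:

* Mascot Generic Format (MGF) — DDA runs exported by vendor converters.
  The reader is deliberately strict (parse errors carry line numbers) but
  accepts common dialect variation: ``PEPMASS=mz`` with or without a trailing
  intensity, unknown headers are ignored, a peak line without an intensity
  gets intensity 1.0.
* MassBank record flat files — one reference spectrum plus compound
  metadata per record (``CH$``/``AC$``/``MS$``/``PK$`` tags).
* A plain-text peak-list format (one file per spectrum, ``#``-prefixed
  header lines then ``mz<TAB>intensity`` rows) used by the extraction step
  that splits a run into individual query spectra.

Collision-energy strings in the wild are free text; parsing goes through a
single data-driven pattern table (:data:`CE_PATTERNS`) that callers can
extend.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

from .spectra import CID, EV, HCD, NCE, UNKNOWN, CollisionEnergy, Peak, Spectrum

logger = logging.getLogger(__name__)

Source = Union[str, Path, IO[str]]


class MGFParseError(ValueError):
    """Raised for malformed MGF input; message names the offending line."""


class MassBankRecordError(ValueError):
    """Raised when a MassBank record cannot yield a usable spectrum."""


# ---------------------------------------------------------------------------
# collision-energy string parsing


#: (regex, scheme) table mapping free-text collision-energy strings to a
#: scheme.  Groups: ``v`` = value, optional ``spread`` = eV half-spread.
CE_PATTERNS: list[tuple[re.Pattern, str]] = [
    # MassBank Orbitrap style: "45 % (nominal)", "45% (nominal)"
    (re.compile(r"^\s*(?P<v>\d+(?:\.\d+)?)\s*%?\s*\(nominal\)\s*$", re.I), NCE),
    # explicit NCE: "45 NCE", "NCE 45", "HCD 45", "45 %"
    (re.compile(r"^\s*(?:NCE|HCD)?\s*(?P<v>\d+(?:\.\d+)?)\s*(?:NCE|%)\s*$", re.I), NCE),
    (re.compile(r"^\s*(?:NCE|HCD)\s+(?P<v>\d+(?:\.\d+)?)\s*$", re.I), NCE),
    # electron volts, optional spread: "35 eV", "35 eV (spread 10)", "35±10 eV"
    (
        re.compile(
            r"^\s*(?P<v>\d+(?:\.\d+)?)\s*(?:±\s*(?P<spread>\d+(?:\.\d+)?)\s*)?eV"
            r"(?:\s*\(spread\s+(?P<spread2>\d+(?:\.\d+)?)\))?\s*$",
            re.I,
        ),
        EV,
    ),
    # "CID 35 eV" style
    (re.compile(r"^\s*CID\s+(?P<v>\d+(?:\.\d+)?)\s*eV\s*$", re.I), EV),
]


def parse_collision_energy(
    text: str,
    extra_patterns: Optional[Sequence[tuple[re.Pattern, str]]] = None,
) -> Optional[CollisionEnergy]:
    """Map a free-text collision-energy string to a :class:`CollisionEnergy`.

    Returns ``None`` when no pattern matches (the record is kept, the energy
    is recorded as absent).
    """
    patterns = list(CE_PATTERNS)
    if extra_patterns:
        patterns = list(extra_patterns) + patterns
    for pattern, scheme in patterns:
        m = pattern.match(text)
        if m:
            value = float(m.group("v"))
            spread = 0.0
            groups = m.groupdict()
            for key in ("spread", "spread2"):
                if groups.get(key):
                    spread = float(groups[key])
            if scheme == NCE:
                return CollisionEnergy(NCE, value)
            return CollisionEnergy(EV, value, spread)
    logger.warning("unparseable collision-energy string %r; recording as absent", text)
    return None


# ---------------------------------------------------------------------------
# MGF


def _open_text(source: Source):
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


_NUMERIC = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _parse_charge(text: str) -> int:
    text = text.strip().split()[0].rstrip(",")
    if text.endswith("+"):
        return int(text[:-1] or 1)
    if text.endswith("-"):
        return -int(text[:-1] or 1)
    return int(float(text))


def read_mgf(source: Source) -> list[Spectrum]:
    """Parse an MGF stream into a list of :class:`Spectrum`, in file order.

    Blocks with zero peaks are returned (empty peak list) and logged, not
    dropped, so run-level accounting stays honest.  An unterminated block or
    a non-numeric peak line raises :class:`MGFParseError` naming the line.
    """
    handle, owned = _open_text(source)
    try:
        return _read_mgf_handle(handle)
    finally:
        if owned:
            handle.close()


def _read_mgf_handle(handle: IO[str]) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    in_block = False
    begin_line = 0
    headers: dict[str, str] = {}
    peaks: list[Peak] = []
    n_line = 0
    for n_line, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.upper() == "BEGIN IONS":
            if in_block:
                raise MGFParseError(
                    f"line {n_line}: BEGIN IONS inside block opened at line {begin_line}"
                )
            in_block = True
            begin_line = n_line
            headers = {}
            peaks = []
            continue
        if line.upper() == "END IONS":
            if not in_block:
                raise MGFParseError(f"line {n_line}: END IONS without BEGIN IONS")
            spectra.append(_finish_mgf_block(headers, peaks, begin_line, len(spectra)))
            in_block = False
            continue
        if not in_block:
            continue  # file-level headers (e.g. COM=, SEARCH=) are ignored
        if "=" in line and not _NUMERIC.match(line.split(None, 1)[0]):
            key, value = line.split("=", 1)
            headers[key.strip().upper()] = value.strip()
            continue
        fields = line.split()
        if not all(_NUMERIC.match(f) for f in fields[:2]):
            raise MGFParseError(f"line {n_line}: non-numeric peak line {line!r}")
        mz = float(fields[0])
        intensity = float(fields[1]) if len(fields) > 1 else 1.0
        peaks.append(Peak(mz, intensity))
    if in_block:
        raise MGFParseError(
            f"line {begin_line}: BEGIN IONS without matching END IONS (unterminated block)"
        )
    return spectra


def _finish_mgf_block(
    headers: dict[str, str], peaks: list[Peak], begin_line: int, index: int
) -> Spectrum:
    if "PEPMASS" not in headers:
        raise MGFParseError(f"line {begin_line}: block has no PEPMASS header")
    pepmass = float(headers["PEPMASS"].split()[0])
    charge = _parse_charge(headers["CHARGE"]) if "CHARGE" in headers else 1
    ce = None
    for key in ("COLLISION_ENERGY", "COLLISIONENERGY", "CE"):
        if key in headers:
            ce = parse_collision_energy(headers[key])
            break
    spread = headers.get("COLLISION_ENERGY_SPREAD")
    if ce is not None and ce.scheme == EV and spread is not None:
        ce = CollisionEnergy(EV, ce.value, float(spread))
    activation = headers.get("ACTIVATION", UNKNOWN)
    if activation not in (CID, HCD):
        activation = UNKNOWN
    resolution = float(headers["RESOLUTION"]) if "RESOLUTION" in headers else None
    source_id = headers.get("TITLE", f"mgf#{index}")
    if not peaks:
        logger.warning("MGF block at line %d (%s) has zero peaks", begin_line, source_id)
    return Spectrum(
        peaks=peaks,
        precursor_mz=pepmass,
        charge=charge,
        collision_energy=ce,
        activation=activation,
        resolution=resolution,
        compound_id=headers.get("COMPOUND") or None,
        source_id=source_id,
    )


def write_mgf(spectra: Iterable[Spectrum], sink: Source) -> int:
    """Write spectra as MGF; returns the number of bytes written.

    Round-trip safe with :func:`read_mgf`: peaks and precursor m/z survive to
    six decimal places.  Negative charges use the ``1-`` dialect.
    """
    handle, owned = _open_text_write(sink)
    n_bytes = 0
    try:
        for spectrum in spectra:
            n_bytes += _write_one_mgf(spectrum, handle)
        return n_bytes
    finally:
        if owned:
            handle.close()


def _open_text_write(sink: Source):
    if isinstance(sink, (str, Path)):
        return open(sink, "w", encoding="utf-8"), True
    return sink, False


def _write_one_mgf(s: Spectrum, handle: IO[str]) -> int:
    lines = ["BEGIN IONS"]
    if s.source_id:
        lines.append(f"TITLE={s.source_id}")
    lines.append(f"PEPMASS={s.precursor_mz:.6f}")
    sign = "-" if s.charge < 0 else "+"
    lines.append(f"CHARGE={abs(s.charge)}{sign}")
    if s.collision_energy is not None:
        ce = s.collision_energy
        if ce.scheme == NCE:
            lines.append(f"COLLISION_ENERGY={ce.value:g} NCE")
        else:
            lines.append(f"COLLISION_ENERGY={ce.value:g} eV")
            if ce.spread:
                lines.append(f"COLLISION_ENERGY_SPREAD={ce.spread:g}")
    if s.activation != UNKNOWN:
        lines.append(f"ACTIVATION={s.activation}")
    if s.resolution is not None:
        lines.append(f"RESOLUTION={s.resolution:g}")
    if s.compound_id:
        lines.append(f"COMPOUND={s.compound_id}")
    for p in s.peaks:
        lines.append(f"{p.mz:.6f} {p.intensity:.6f}")
    lines.append("END IONS")
    lines.append("")
    text = "\n".join(lines) + "\n"
    handle.write(text)
    return len(text.encode("utf-8"))


# ---------------------------------------------------------------------------
# MassBank records


@dataclass
class MassBankRecord:
    """Compound metadata plus the single spectrum a MassBank record carries."""

    accession: str
    name: str
    spectrum: Spectrum
    inchikey: Optional[str] = None
    formula: Optional[str] = None
    exact_mass: Optional[float] = None
    smiles: Optional[str] = None


def read_massbank_record(source: Source) -> MassBankRecord:
    """Parse one MassBank record flat file.

    Collision-energy strings such as ``"45 % (nominal)"`` map to the NCE
    scheme, ``"35 eV"`` to eV; an unparseable string keeps the record with an
    absent collision energy (a warning is logged).  A record without a
    ``PK$PEAK`` table or without ``MS$FOCUSED_ION: PRECURSOR_M/Z`` is
    rejected with :class:`MassBankRecordError`.
    """
    handle, owned = _open_text(source)
    try:
        lines = handle.read().splitlines()
    finally:
        if owned:
            handle.close()

    accession = ""
    name = ""
    inchikey = None
    formula = None
    exact_mass = None
    smiles = None
    ce: Optional[CollisionEnergy] = None
    activation = UNKNOWN
    resolution = None
    precursor_mz = None
    charge = 1
    peaks: list[Peak] = []
    in_peaks = False

    for raw in lines:
        if in_peaks:
            if raw.startswith("  ") and raw.strip() and raw.strip() != "//":
                fields = raw.split()
                try:
                    peaks.append(Peak(float(fields[0]), float(fields[1])))
                except (ValueError, IndexError) as exc:
                    raise MassBankRecordError(
                        f"{accession or '<record>'}: malformed peak line {raw.strip()!r}"
                    ) from exc
                continue
            in_peaks = False
        line = raw.strip()
        if line.startswith("ACCESSION:"):
            accession = line.split(":", 1)[1].strip()
        elif line.startswith("CH$NAME:") and not name:
            name = line.split(":", 1)[1].strip()
        elif line.startswith("CH$FORMULA:"):
            formula = line.split(":", 1)[1].strip()
        elif line.startswith("CH$EXACT_MASS:"):
            try:
                exact_mass = float(line.split(":", 1)[1].strip())
            except ValueError:
                exact_mass = None
        elif line.startswith("CH$SMILES:"):
            smiles = line.split(":", 1)[1].strip()
        elif line.startswith("CH$LINK: INCHIKEY"):
            inchikey = line.split("INCHIKEY", 1)[1].strip()
        elif line.startswith("AC$MASS_SPECTROMETRY: COLLISION_ENERGY"):
            ce = parse_collision_energy(line.split("COLLISION_ENERGY", 1)[1].strip())
        elif line.startswith("AC$MASS_SPECTROMETRY: FRAGMENTATION_MODE"):
            mode = line.split("FRAGMENTATION_MODE", 1)[1].strip().upper()
            activation = mode if mode in (CID, HCD) else UNKNOWN
        elif line.startswith("AC$MASS_SPECTROMETRY: RESOLUTION"):
            try:
                resolution = float(line.split("RESOLUTION", 1)[1].strip())
            except ValueError:
                resolution = None
        elif line.startswith("AC$MASS_SPECTROMETRY: ION_MODE"):
            if "NEGATIVE" in line.upper():
                charge = -1
        elif line.startswith("MS$FOCUSED_ION: PRECURSOR_M/Z"):
            try:
                precursor_mz = float(line.split("PRECURSOR_M/Z", 1)[1].strip())
            except ValueError:
                precursor_mz = None
        elif line.startswith("PK$PEAK:"):
            in_peaks = True

    if precursor_mz is None:
        raise MassBankRecordError(f"{accession or '<record>'}: no PRECURSOR_M/Z")
    if not peaks:
        raise MassBankRecordError(f"{accession or '<record>'}: no peaks")
    if not (accession or name):
        raise MassBankRecordError("record has no compound identifier")

    spectrum = Spectrum(
        peaks=peaks,
        precursor_mz=precursor_mz,
        charge=charge,
        collision_energy=ce,
        activation=activation,
        resolution=resolution,
        compound_id=None,
        source_id=accession or name,
    )
    return MassBankRecord(
        accession=accession,
        name=name,
        spectrum=spectrum,
        inchikey=inchikey,
        formula=formula,
        exact_mass=exact_mass,
        smiles=smiles,
    )


def write_massbank_record(record: MassBankRecord, sink: Source) -> int:
    """Write a minimal MassBank-style record (synthetic-library export)."""
    s = record.spectrum
    lines = [f"ACCESSION: {record.accession}", "RECORD_TITLE: synthetic record"]
    lines.append(f"CH$NAME: {record.name}")
    if record.formula:
        lines.append(f"CH$FORMULA: {record.formula}")
    if record.exact_mass is not None:
        lines.append(f"CH$EXACT_MASS: {record.exact_mass:.6f}")
    if record.smiles:
        lines.append(f"CH$SMILES: {record.smiles}")
    if record.inchikey:
        lines.append(f"CH$LINK: INCHIKEY {record.inchikey}")
    if s.activation != UNKNOWN:
        lines.append(f"AC$MASS_SPECTROMETRY: FRAGMENTATION_MODE {s.activation}")
    if s.collision_energy is not None:
        ce = s.collision_energy
        if ce.scheme == NCE:
            lines.append(f"AC$MASS_SPECTROMETRY: COLLISION_ENERGY {ce.value:g} % (nominal)")
        else:
            lines.append(f"AC$MASS_SPECTROMETRY: COLLISION_ENERGY {ce.value:g} eV")
    if s.resolution is not None:
        lines.append(f"AC$MASS_SPECTROMETRY: RESOLUTION {s.resolution:g}")
    lines.append(f"AC$MASS_SPECTROMETRY: ION_MODE {'POSITIVE' if s.charge >= 0 else 'NEGATIVE'}")
    lines.append(f"MS$FOCUSED_ION: PRECURSOR_M/Z {s.precursor_mz:.6f}")
    base = s.base_peak_intensity if s.peaks else 1.0
    lines.append("PK$NUM_PEAK: %d" % len(s.peaks))
    lines.append("PK$PEAK: m/z int. rel.int.")
    for p in s.peaks:
        lines.append(f"  {p.mz:.6f} {p.intensity:.6f} {max(1, round(999 * p.intensity / base))}")
    lines.append("//")
    text = "\n".join(lines) + "\n"
    handle, owned = _open_text_write(sink)
    try:
        handle.write(text)
    finally:
        if owned:
            handle.close()
    return len(text.encode("utf-8"))


# ---------------------------------------------------------------------------
# plain-text peak lists (the run → per-spectrum extraction step)


def write_peaklist(spectrum: Spectrum, sink: Source) -> int:
    """Write one spectrum as a plain-text peak list (TSV with # headers)."""
    lines = [f"# PRECURSOR_MZ\t{spectrum.precursor_mz:.6f}", f"# CHARGE\t{spectrum.charge}"]
    if spectrum.collision_energy is not None:
        lines.append(f"# COLLISION_ENERGY\t{spectrum.collision_energy.label()}")
    if spectrum.source_id:
        lines.append(f"# SOURCE\t{spectrum.source_id}")
    for p in spectrum.peaks:
        lines.append(f"{p.mz:.6f}\t{p.intensity:.6f}")
    text = "\n".join(lines) + "\n"
    handle, owned = _open_text_write(sink)
    try:
        handle.write(text)
    finally:
        if owned:
            handle.close()
    return len(text.encode("utf-8"))


def read_peaklist(source: Source) -> Spectrum:
    """Read a plain-text peak list written by :func:`write_peaklist`."""
    handle, owned = _open_text(source)
    try:
        lines = handle.read().splitlines()
    finally:
        if owned:
            handle.close()
    precursor = None
    charge = 1
    ce = None
    source_id = ""
    peaks: list[Peak] = []
    for line in lines:
        if not line.strip():
            continue
        if line.startswith("#"):
            fields = line[1:].strip().split("\t")
            key = fields[0].strip().upper()
            value = fields[1].strip() if len(fields) > 1 else ""
            if key == "PRECURSOR_MZ":
                precursor = float(value)
            elif key == "CHARGE":
                charge = int(value)
            elif key == "COLLISION_ENERGY":
                ce = parse_collision_energy(value)
            elif key == "SOURCE":
                source_id = value
            continue
        fields = line.split()
        peaks.append(Peak(float(fields[0]), float(fields[1])))
    if precursor is None:
        raise MGFParseError("peak list lacks a PRECURSOR_MZ header")
    return Spectrum(
        peaks=peaks, precursor_mz=precursor, charge=charge,
        collision_energy=ce, source_id=source_id,
    )


_UNSAFE = re.compile(r"[^A-Za-z0-9._-]+")


def extract_spectra(run: Sequence[Spectrum], out_dir: Union[str, Path]) -> int:
    """Split a parsed run into one plain-text peak-list file per spectrum.

    Spectra with zero peaks are skipped (and logged); the return value is the
    number of files written, i.e. the number of non-empty spectra.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_written = 0
    for i, spectrum in enumerate(run):
        if not spectrum.peaks:
            logger.info("skipping empty spectrum %s (index %d)", spectrum.source_id, i)
            continue
        stem = _UNSAFE.sub("_", spectrum.source_id) or "spectrum"
        write_peaklist(spectrum, out / f"{i:05d}_{stem}.txt")
        n_written += 1
    return n_written
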