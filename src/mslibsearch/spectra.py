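"""Core containers for product-ion spectra.

A :class:`Spectrum` is a peak list plus the acquisition context that the
search and benchmarking layers care about: precursor m/z, charge polarity,
collision-energy descriptor, activation type (CID/HCD) and provenance.
Collision energies on QqTOF instruments are physical electron-volts; on
Orbitrap instruments they are nominal collision energy (NCE) units.  The two
scales are kept apart via :class:`CollisionEnergy.scheme` and never compared
numerically across schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Optional

EV = "eV"
NCE = "NCE"

CID = "CID"
HCD = "HCD"
UNKNOWN = "unknown"

_ACTIVATIONS = (CID, HCD, UNKNOWN)


class Peak(NamedTuple):
    """One fragment ion: mass-to-charge ratio (Th) and abundance (a.u.)."""

    mz: float
    intensity: float


@dataclass(frozen=True, order=True)
class CollisionEnergy:
    """Collision-energy setting with its unit scheme.

    Parameters
    ----------
    value:
        Non-negative energy in the scheme's units (eV or NCE).
    scheme:
        ``"eV"`` for physical collision energy (QqTOF CID), ``"NCE"`` for
        nominal collision energy units (Orbitrap HCD/CID).
    spread:
        Half-spread in eV for ramped acquisitions (e.g. "35 eV with a
        collision energy spread of 10 eV"); only meaningful for ``eV``.
    """

    scheme: str
    value: float
    spread: float = 0.0

    def __post_init__(self) -> None:
        if self.scheme not in (EV, NCE):
            raise ValueError(f"unknown collision-energy scheme {self.scheme!r}")
        if self.value < 0:
            raise ValueError("collision energy must be non-negative")
        if self.spread < 0:
            raise ValueError("collision-energy spread must be non-negative")
        if self.scheme == NCE and self.spread != 0.0:
            raise ValueError("spread is only meaningful for the eV scheme")

    def label(self) -> str:
        if self.scheme == EV:
            if self.spread:
                return f"{self.value:g} eV (spread {self.spread:g})"
            return f"{self.value:g} eV"
        return f"{self.value:g} NCE"


def merge_peaks(peaks: Iterable[Peak]) -> list[Peak]:
    """Sort peaks by m/z and merge exact duplicates by summing intensity."""
    out: list[Peak] = []
    for p in sorted(peaks, key=lambda q: q.mz):
        if out and out[-1].mz == p.mz:
            out[-1] = Peak(p.mz, out[-1].intensity + p.intensity)
        else:
            out.append(Peak(p.mz, p.intensity))
    return out


@dataclass
class Spectrum:
    """One product-ion spectrum.

    Peaks are kept strictly ascending in m/z; duplicate m/z values are merged
    (intensities summed) at construction.  ``charge`` carries the polarity in
    its sign.  ``compound_id`` is set for library spectra; ``source_id``
    records provenance (file and block/record identifier).
    """

    peaks: list[Peak]
    precursor_mz: float
    charge: int = 1
    collision_energy: Optional[CollisionEnergy] = None
    activation: str = UNKNOWN
    resolution: Optional[float] = None
    compound_id: Optional[str] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if not (self.precursor_mz > 0):
            raise ValueError("precursor_mz must be positive")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        for p in self.peaks:
            if not (p.mz > 0):
                raise ValueError(f"peak m/z must be positive, got {p.mz}")
            if p.intensity < 0:
                raise ValueError(f"peak intensity must be non-negative, got {p.intensity}")
        self.peaks = merge_peaks(Peak(float(p.mz), float(p.intensity)) for p in self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def base_peak_intensity(self) -> float:
        if not self.peaks:
            raise ValueError("spectrum has no peaks")
        return max(p.intensity for p in self.peaks)

    @property
    def total_intensity(self) -> float:
        return sum(p.intensity for p in self.peaks)

    def with_peaks(self, peaks: Iterable[Peak]) -> "Spectrum":
        """Copy of this spectrum with a replacement peak list."""
        return replace(self, peaks=list(peaks))
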