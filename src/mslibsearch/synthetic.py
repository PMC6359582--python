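"""Synthetic paired-library generator.

Emulates what the analysis assumes about real reference collections without
any downloads: per-compound fragment ladders whose intensities follow
collision-energy breakdown curves, rendered through two instrument views
(QqTOF CID with energies in eV, Orbitrap HCD with energies in NCE units)
that share a single canonical eV axis, plus DDA-like query spectra with the
corruption modes seen in complex samples (interfering peaks, diffuse noise).

The breakdown model is deliberately minimal: precursor survival is a
logistic decay in collision energy, and each fragment channel has a
Gaussian efficiency window on the canonical axis.  At very low energies
spectra are precursor-dominated; at very high energies the total ion yield
collapses and peak detection becomes stochastic (a Poisson-style detection
probability on the raw channel intensity), so spectra turn sparse and
irreproducible.  Between instruments, the eV↔NCE correspondence holds only
on average: each compound carries a small random offset on the canonical
axis per instrument view (``ce_map_sigma``), emulating the fact that
nominal collision energy is not directly equal to eV and that the two views
produce differing intensity profiles.  Together these give the qualitative
phenomenology the cross-instrument benchmark needs — high sensitivity
across the mid collision-energy working range, degradation at both extremes
— with no claim of physical fidelity.

All randomness flows from one integer seed through ``numpy`` SeedSequence
spawning (plus a CRC32-keyed per-compound stream for the CE-map offsets),
so every fixture is reproducible bit-for-bit across platforms.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .library import CompoundInfo, SpectralLibrary, build_library
from .spectra import CID, EV, HCD, NCE, CollisionEnergy, Peak, Spectrum

#: relative-intensity floor (base peak = 100) below which rendered peaks vanish
RENDER_FLOOR = 0.1


@dataclass(frozen=True)
class FragmentSpec:
    """One fragment channel: m/z plus its collision-energy efficiency window."""

    mz: float
    center_ce: float  # canonical eV at which the channel is most efficient
    width_ce: float  # Gaussian width (eV)
    max_weight: float  # relative channel strength in (0, 1]


@dataclass(frozen=True)
class SyntheticCompoundSpec:
    """A synthetic compound: protonated precursor plus fragment channels."""

    compound_key: str
    precursor_mz: float
    fragments: Tuple[FragmentSpec, ...]

    def __post_init__(self) -> None:
        for f in self.fragments:
            if not (f.mz < self.precursor_mz):
                raise ValueError("fragment m/z must lie strictly below the precursor")
            if f.center_ce <= 0:
                raise ValueError("fragment CE centers must be positive")


@dataclass(frozen=True)
class BreakdownModel:
    """Logistic precursor survival on the canonical eV axis.

    survival(ce) = 1 / (1 + exp((ce − e50) / slope)) — strictly decreasing,
    0.5 at ``precursor_e50``.  The defaults put the fragment-rich regime at
    roughly 20–50 canonical eV, matching the working range a QqTOF/Orbitrap
    library pair exhibits.
    """

    precursor_e50: float = 25.0
    precursor_slope: float = 4.0

    def survival(self, ce: float) -> float:
        return 1.0 / (1.0 + math.exp((ce - self.precursor_e50) / self.precursor_slope))


def _raw_channels(
    spec: SyntheticCompoundSpec, breakdown: BreakdownModel, ce_canonical: float
) -> list:
    """(m/z, raw intensity) per channel at one canonical energy, precursor first."""
    s = breakdown.survival(ce_canonical)
    raw = [(spec.precursor_mz, s)]
    for f in spec.fragments:
        gauss = math.exp(-((ce_canonical - f.center_ce) ** 2) / (2.0 * f.width_ce**2))
        raw.append((f.mz, (1.0 - s) * f.max_weight * gauss))
    return raw


def ion_yield(
    spec: SyntheticCompoundSpec, breakdown: BreakdownModel, ce_canonical: float
) -> float:
    """Total raw ion yield at one canonical energy (order 1 in the working range)."""
    return sum(v for _, v in _raw_channels(spec, breakdown, ce_canonical))


@dataclass(frozen=True)
class InstrumentModel:
    """An instrument view of the canonical collision-energy axis.

    ``ce_scale``/``ce_offset`` form the affine map instrument-units =
    scale · eV + offset (identity for a QqTOF reporting physical eV; the
    default Orbitrap view uses NCE = 1.2·eV + 6, which places the canonical
    20–50 eV working band at 30–66 NCE).  ``ce_map_sigma`` adds a
    compound-specific Gaussian offset (eV) to that map, constant per
    (instrument, compound): the empirical eV↔NCE correspondence holds on
    average, not per compound.

    Noise terms: ``mz_sigma`` is Gaussian m/z jitter in Th; ``intensity_cv``
    a log-normal intensity coefficient of variation; ``detection_scale``
    sets a Poisson-style detection probability ``1 − exp(−raw/scale)`` on
    each channel's raw intensity (peaks from low-yield spectra flicker);
    peaks below ``dropout_floor`` (relative intensity, base = 100) are
    additionally lost with probability ``p_drop``.  With every noise term
    zero the render is exactly the ideal spectrum.
    """

    name: str
    scheme: str  # EV or NCE
    ce_scale: float = 1.0
    ce_offset: float = 0.0
    ce_map_sigma: float = 0.0
    mz_sigma: float = 0.002
    intensity_cv: float = 0.10
    detection_scale: float = 0.04
    dropout_floor: float = 2.0
    p_drop: float = 0.10

    def __post_init__(self) -> None:
        if self.ce_scale <= 0:
            raise ValueError("ce_scale must be positive")
        if self.mz_sigma < 0:
            raise ValueError("mz_sigma must be non-negative")
        if not (0.0 <= self.p_drop <= 1.0):
            raise ValueError("p_drop must be in [0, 1]")

    def to_canonical(self, instrument_ce: float) -> float:
        return (instrument_ce - self.ce_offset) / self.ce_scale

    def from_canonical(self, canonical_ev: float) -> float:
        return self.ce_scale * canonical_ev + self.ce_offset

    def ce_map_offset(self, spec: SyntheticCompoundSpec) -> float:
        """Deterministic per-compound offset (eV) of this view's CE map."""
        if self.ce_map_sigma == 0.0:
            return 0.0
        key = f"{self.name}/{spec.compound_key}/{spec.precursor_mz:.6f}".encode()
        stream = np.random.default_rng(zlib.crc32(key) % (2**31))
        return float(stream.normal(0.0, self.ce_map_sigma))


QQTOF = InstrumentModel(name="QqTOF-sim", scheme=EV, ce_map_sigma=2.0)
ORBITRAP = InstrumentModel(
    name="Orbitrap-sim", scheme=NCE, ce_scale=1.2, ce_offset=6.0, ce_map_sigma=4.0
)

QQTOF_GRID = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0)  # eV
ORBITRAP_GRID = (15.0, 30.0, 45.0, 60.0, 75.0, 90.0)  # NCE


@dataclass(frozen=True)
class CorruptionSpec:
    """Query-spectrum corruption: interfering peaks and/or diffuse noise."""

    mode: str = "clean"  # clean | interference | noise | both
    n_interference: int = 5
    interference_rel_intensity: float = 0.5  # fraction of base peak
    noise_peaks: int = 30
    noise_rel_intensity: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("clean", "interference", "noise", "both"):
            raise ValueError(f"unknown corruption mode {self.mode!r}")
        if self.n_interference < 0 or self.noise_peaks < 0:
            raise ValueError("corruption counts must be non-negative")
        if self.interference_rel_intensity < 0 or self.noise_rel_intensity < 0:
            raise ValueError("corruption intensities must be non-negative")


SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_compounds(n: int, seed: SeedLike) -> list:
    """Draw ``n`` synthetic compound specs, deterministic given the seed.

    Precursors are uniform in 150–800 Th; each compound gets 5–15 fragment
    channels at least 1 Th apart.  Efficiency centers are spread over the
    10–45 eV canonical range: below that range spectra are
    precursor-dominated, well above it the ion yield collapses.
    """
    if n < 1:
        raise ValueError("need at least one compound")
    rng = _rng(seed)
    compounds = []
    for i in range(n):
        precursor = float(rng.uniform(150.0, 800.0))
        n_frag = int(rng.integers(5, 16))
        mzs: list = []
        while len(mzs) < n_frag:
            mz = float(rng.uniform(50.0, precursor - 20.0))
            if all(abs(mz - other) >= 1.0 for other in mzs):
                mzs.append(mz)
        mzs.sort()
        fragments = tuple(
            FragmentSpec(
                mz=mz,
                center_ce=float(rng.uniform(10.0, 45.0)),
                width_ce=float(rng.uniform(5.0, 10.0)),
                max_weight=float(rng.uniform(0.2, 1.0)),
            )
            for mz in mzs
        )
        compounds.append(
            SyntheticCompoundSpec(
                compound_key=f"SYN-{i:05d}",
                precursor_mz=precursor,
                fragments=fragments,
            )
        )
    return compounds


def ideal_spectrum(
    spec: SyntheticCompoundSpec,
    breakdown: BreakdownModel,
    ce_canonical: float,
    source_id: str = "",
) -> Spectrum:
    """Noise-free spectrum of one compound at a canonical collision energy.

    Precursor intensity follows the survival curve; fragment ``f`` gets
    ``(1 − survival) · max_weight_f · exp(−(ce − center_f)² / (2·width_f²))``.
    The result is rescaled to base peak 100 and peaks below 0.1 relative are
    dropped (emulating curated, filtered library spectra).
    """
    if ce_canonical < 0:
        raise ValueError("collision energy must be non-negative")
    raw = _raw_channels(spec, breakdown, ce_canonical)
    top = max(v for _, v in raw)
    scale = 100.0 / top
    peaks = [Peak(mz, v * scale) for mz, v in raw if v * scale >= RENDER_FLOOR]
    return Spectrum(
        peaks=peaks,
        precursor_mz=spec.precursor_mz,
        charge=1,
        collision_energy=CollisionEnergy(EV, ce_canonical),
        activation=CID,
        compound_id=spec.compound_key,
        source_id=source_id or f"ideal:{spec.compound_key}@{ce_canonical:g}eV",
    )


def _render_peaks(
    spec: SyntheticCompoundSpec,
    breakdown: BreakdownModel,
    instrument: InstrumentModel,
    ce_canonical: float,
    rng: np.random.Generator,
) -> list:
    """Peak list of one noisy render; identical to the ideal at zero noise."""
    raw = _raw_channels(spec, breakdown, ce_canonical)
    detected = []
    for mz, v in raw:
        if v <= 0.0:
            continue
        # Poisson-style detection on the raw channel intensity
        u_detect = rng.uniform()
        if instrument.detection_scale > 0.0 and u_detect > -math.expm1(
            -v / instrument.detection_scale
        ):
            continue
        mz_obs = mz + rng.normal(0.0, instrument.mz_sigma) if instrument.mz_sigma else mz
        v_obs = v * math.exp(instrument.intensity_cv * rng.standard_normal())
        detected.append((mz_obs, v_obs))
    if not detected:  # keep the strongest channel: a spectrum is never empty
        mz, v = max(raw, key=lambda t: t[1])
        detected = [(mz, v)]
    top = max(v for _, v in detected)
    scale = 100.0 / top
    peaks = []
    for mz, v in detected:
        rel = v * scale
        if rel < RENDER_FLOOR:
            continue
        if rel < instrument.dropout_floor and rng.uniform() < instrument.p_drop:
            continue
        peaks.append(Peak(mz, rel))
    if not peaks:
        mz, v = max(detected, key=lambda t: t[1])
        peaks = [Peak(mz, 100.0)]
    return peaks


def render_library(
    compounds: Sequence[SyntheticCompoundSpec],
    breakdown: BreakdownModel,
    instrument: InstrumentModel,
    ce_grid: Sequence[float],
    seed: SeedLike,
    name: Optional[str] = None,
) -> SpectralLibrary:
    """Render a reference library: every compound at every grid energy.

    The grid is in instrument units; each point maps back to the canonical
    axis (plus the compound's CE-map offset for this view), the ideal
    spectrum is rendered there and perturbed with the instrument's noise
    model.  Deterministic given the seed.
    """
    if not ce_grid:
        raise ValueError("collision-energy grid must be non-empty")
    rng = _rng(seed)
    activation = HCD if instrument.scheme == NCE else CID
    records = []
    for spec in compounds:
        offset = instrument.ce_map_offset(spec)
        info = CompoundInfo(compound_key=spec.compound_key, name=spec.compound_key)
        for ce in ce_grid:
            canonical = max(0.0, instrument.to_canonical(ce) + offset)
            peaks = _render_peaks(spec, breakdown, instrument, canonical, rng)
            spectrum = Spectrum(
                peaks=peaks,
                precursor_mz=spec.precursor_mz,
                charge=1,
                collision_energy=CollisionEnergy(instrument.scheme, ce),
                activation=activation,
                compound_id=spec.compound_key,
                source_id=f"{instrument.name}:{spec.compound_key}@{ce:g}",
            )
            records.append((info, spectrum))
    return build_library(
        records,
        name=name or f"{instrument.name}-library",
        instrument_class="synthetic",
    )


def render_query(
    spec: SyntheticCompoundSpec,
    breakdown: BreakdownModel,
    instrument: InstrumentModel,
    ce: float,
    corruption: CorruptionSpec = CorruptionSpec(),
    seed: Optional[SeedLike] = None,
) -> Spectrum:
    """Render one DDA-like query spectrum at an instrument-units energy.

    Instrument noise is applied first; then, depending on the corruption
    mode, interfering peaks (few, strong — coeluting precursors inside the
    DDA isolation window) and/or noise peaks (many, weak) are added at
    uniform random m/z in (50, precursor + 50).  Randomness comes from
    ``corruption.seed`` unless an explicit seed is given.
    """
    rng = _rng(corruption.seed if seed is None else seed)
    canonical = max(0.0, instrument.to_canonical(ce) + instrument.ce_map_offset(spec))
    peaks = list(_render_peaks(spec, breakdown, instrument, canonical, rng))
    base = max(p.intensity for p in peaks)
    lo, hi = 50.0, spec.precursor_mz + 50.0
    if corruption.mode in ("interference", "both"):
        for _ in range(corruption.n_interference):
            peaks.append(
                Peak(float(rng.uniform(lo, hi)), base * corruption.interference_rel_intensity)
            )
    if corruption.mode in ("noise", "both"):
        for _ in range(corruption.noise_peaks):
            peaks.append(
                Peak(
                    float(rng.uniform(lo, hi)),
                    base * corruption.noise_rel_intensity * float(rng.uniform(0.2, 1.0)),
                )
            )
    top = max(p.intensity for p in peaks)
    scale = 100.0 / top
    return Spectrum(
        peaks=[Peak(p.mz, p.intensity * scale) for p in peaks],
        precursor_mz=spec.precursor_mz,
        charge=1,
        collision_energy=CollisionEnergy(instrument.scheme, ce),
        activation=HCD if instrument.scheme == NCE else CID,
        compound_id=spec.compound_key,
        source_id=f"query:{instrument.name}:{spec.compound_key}@{ce:g}:{corruption.mode}",
    )


# ---------------------------------------------------------------------------
# full benchmark scenario


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for the paired-library benchmark scenario.

    ``n_compounds`` is the per-library compound count and ``overlap`` the
    fraction of each library's compounds shared with the other (emulating
    the shared-compound structure cross-library validation relies on).
    """

    n_compounds: int = 50
    overlap: float = 0.6
    seed: int = 0
    breakdown: BreakdownModel = field(default_factory=BreakdownModel)
    qqtof: InstrumentModel = QQTOF
    orbitrap: InstrumentModel = ORBITRAP
    qqtof_grid: Tuple[float, ...] = QQTOF_GRID
    orbitrap_grid: Tuple[float, ...] = ORBITRAP_GRID

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap <= 1.0):
            raise ValueError("overlap fraction must be in [0, 1]")
        if self.n_compounds < 1:
            raise ValueError("need at least one compound per library")


@dataclass
class QueryCase:
    """One truth-labelled query spectrum."""

    spectrum: Spectrum
    true_compound_key: str
    instrument: str
    ce: float  # instrument units


@dataclass
class Scenario:
    config: ScenarioConfig
    lib_qqtof: SpectralLibrary
    lib_orbitrap: SpectralLibrary
    shared_keys: set
    queries: dict  # instrument name -> list[QueryCase]
    compounds_qqtof: list = field(default_factory=list)
    compounds_orbitrap: list = field(default_factory=list)

    def shared_compounds(self) -> list:
        """Specs of the compounds present in both libraries."""
        return [c for c in self.compounds_qqtof if c.compound_key in self.shared_keys]


def generate_benchmark_scenario(config: ScenarioConfig = ScenarioConfig()) -> Scenario:
    """Build the paired two-instrument benchmark scenario.

    Both libraries hold ``n_compounds`` compounds; ``round(overlap · n)`` of
    them are shared.  Each library renders its compounds over its own
    collision-energy grid with its own noise; query sets (one clean query
    per compound × grid energy, per instrument) carry truth labels.  Fully
    reproducible from ``config.seed``.
    """
    n = config.n_compounds
    n_shared = int(round(config.overlap * n))
    n_total = 2 * n - n_shared
    root = np.random.SeedSequence(config.seed)
    ss_compounds, ss_lib_q, ss_lib_o, ss_query_q, ss_query_o = root.spawn(5)

    compounds = make_compounds(n_total, ss_compounds)
    shared = compounds[:n_shared]
    qqtof_only = compounds[n_shared:n]
    orbitrap_only = compounds[n:]
    qqtof_compounds = shared + qqtof_only
    orbitrap_compounds = shared + orbitrap_only

    lib_qqtof = render_library(
        qqtof_compounds, config.breakdown, config.qqtof, config.qqtof_grid,
        ss_lib_q, name="qqtof-synthetic",
    )
    lib_orbitrap = render_library(
        orbitrap_compounds, config.breakdown, config.orbitrap, config.orbitrap_grid,
        ss_lib_o, name="orbitrap-synthetic",
    )

    queries: dict = {}
    for instrument, grid, members, ss in (
        (config.qqtof, config.qqtof_grid, qqtof_compounds, ss_query_q),
        (config.orbitrap, config.orbitrap_grid, orbitrap_compounds, ss_query_o),
    ):
        children = ss.spawn(len(members))
        cases = []
        for spec, child in zip(members, children):
            grain = child.spawn(len(grid))
            for ce, g in zip(grid, grain):
                spectrum = render_query(
                    spec, config.breakdown, instrument, ce,
                    CorruptionSpec(mode="clean"), seed=g,
                )
                cases.append(QueryCase(spectrum, spec.compound_key, instrument.name, ce))
        queries[instrument.name] = cases
    return Scenario(
        config=config,
        lib_qqtof=lib_qqtof,
        lib_orbitrap=lib_orbitrap,
        shared_keys={c.compound_key for c in shared},
        queries=queries,
        compounds_qqtof=qqtof_compounds,
        compounds_orbitrap=orbitrap_compounds,
    )


def write_scenario(scenario: Scenario, out_dir: Union[str, Path]) -> dict:
    """Write both libraries, per-instrument query MGFs and a truth TSV.

    Libraries go out in the internal JSON-lines format and as MassBank-style
    record files; returns a manifest of written paths.
    """
    from .library import save_library
    from .spectral_io import MassBankRecord, write_massbank_record, write_mgf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {}
    for label, lib in (("qqtof", scenario.lib_qqtof), ("orbitrap", scenario.lib_orbitrap)):
        lib_path = out / f"library_{label}.jsonl"
        save_library(lib, lib_path)
        manifest[f"library_{label}"] = str(lib_path)
        record_dir = out / f"massbank_{label}"
        record_dir.mkdir(exist_ok=True)
        for i, (key, spectrum) in enumerate(lib.all_spectra()):
            record = MassBankRecord(
                accession=f"SYNT{label[:2].upper()}{i:05d}",
                name=key,
                spectrum=spectrum,
            )
            write_massbank_record(record, record_dir / f"{record.accession}.txt")
        manifest[f"massbank_{label}"] = str(record_dir)
    truth_rows = []
    short = {
        scenario.config.qqtof.name: "qqtof",
        scenario.config.orbitrap.name: "orbitrap",
    }
    for instrument, cases in scenario.queries.items():
        label = short.get(instrument, instrument)
        mgf_path = out / f"queries_{label}.mgf"
        write_mgf([c.spectrum for c in cases], mgf_path)
        manifest[f"queries_{label}"] = str(mgf_path)
        for c in cases:
            truth_rows.append(
                f"{c.spectrum.source_id}\t{c.true_compound_key}\t{label}\t{c.ce:g}"
            )
    truth_path = out / "truth.tsv"
    with open(truth_path, "w", encoding="utf-8") as handle:
        handle.write("query_id\tcompound_key\tinstrument\tce\n")
        handle.write("\n".join(truth_rows) + "\n")
    manifest["truth"] = str(truth_path)
    return manifest
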