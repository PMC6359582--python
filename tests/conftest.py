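"""Shared fixtures: hand-built spectra and small seeded synthetic objects."""

import numpy as np
import pytest

from mslibsearch import (
    CollisionEnergy,
    CompoundInfo,
    MatchParams,
    Peak,
    ScenarioConfig,
    Spectrum,
    build_library,
    generate_benchmark_scenario,
)


@pytest.fixture
def params():
    return MatchParams()


@pytest.fixture
def simple_spectrum():
    return Spectrum(
        peaks=[Peak(100.0, 50.0), Peak(150.0, 100.0)],
        precursor_mz=300.10,
        collision_energy=CollisionEnergy("eV", 35.0),
        source_id="simple",
    )


def random_spectrum(rng, n_peaks=None, precursor=None, min_spacing=0.05):
    """Random spectrum with peak spacing well above 2×(default m/z tolerance),
    so fragment assignment is unambiguous."""
    n = int(n_peaks or rng.integers(3, 12))
    precursor = float(precursor or rng.uniform(150.0, 800.0))
    mzs = []
    while len(mzs) < n:
        mz = float(rng.uniform(50.0, precursor))
        if all(abs(mz - m) >= min_spacing for m in mzs):
            mzs.append(mz)
    return Spectrum(
        peaks=[Peak(mz, float(rng.uniform(2.0, 100.0))) for mz in sorted(mzs)],
        precursor_mz=precursor,
        source_id=f"rand-{rng.integers(1 << 30)}",
    )


def random_library(rng, n_compounds, spectra_per_compound=3, name="rand"):
    """Random small library with distinct compounds, variable precursors."""
    records = []
    for i in range(n_compounds):
        key = f"C{i:03d}"
        precursor = float(rng.uniform(150.0, 800.0))
        for j in range(spectra_per_compound):
            s = random_spectrum(rng, precursor=precursor)
            s = Spectrum(
                peaks=s.peaks,
                precursor_mz=precursor,
                compound_id=key,
                source_id=f"{name}:{key}#{j}",
            )
            records.append((CompoundInfo(key, key), s))
    return build_library(records, name=name, instrument_class="synthetic")


@pytest.fixture(scope="session")
def scenario():
    """One default benchmark scenario, shared across tests for speed."""
    return generate_benchmark_scenario(ScenarioConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
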