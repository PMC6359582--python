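"""Nontargeted screening pipeline: MGF run → per-spectrum library search →
thresholded identifications → per-sample and cross-sample reports.

Every MS/MS spectrum that carries precursor and fragment information is
matched directly against each configured library (no peak picking or feature
detection: the data-mining approach deliberately bypasses XIC-based
workflows).  The rank-1 candidate is accepted as a Level 2a identification
(probable structure via spectral match) when its amp and ramp clear the
configured thresholds.  Accepted hits carry machine QC flags — the matched
intensity fraction and the number of unexplained major peaks — in place of
manual expert review; the flags never auto-reject.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from .library import load_library
from .matching import MatchParams, SearchResult, preprocess, search
from .spectra import Spectrum
from .spectral_io import read_mgf

logger = logging.getLogger(__name__)

ACCEPTED = "accepted"
REJECTED = "rejected"

BELOW_AMP = "below_amp"
BELOW_RAMP = "below_ramp"
NO_CANDIDATES = "no_candidates"
EMPTY_SPECTRUM = "empty_spectrum"

LEVEL_2A = "Level 2a"

#: proton mass (Da) — used to turn a neutral monoisotopic mass into the
#: [M+H]+ precursor anchor of the mass-defect filter.
PROTON = 1.007276466


@dataclass
class ScreeningConfig:
    """Thresholds, tolerances and libraries for one screening run.

    Default thresholds sit at the stringent end of the recommended bands
    (amp > 1–10, ramp > 30–50): conservative defaults minimize false
    positives.  Both cleanup filters are off by default.
    """

    amp_min: float = 10.0
    ramp_min: float = 50.0
    params: MatchParams = field(default_factory=MatchParams)
    libraries: list = field(default_factory=list)  # (name, SpectralLibrary)
    precursor_filter: bool = False
    mass_defect_filter: bool = False
    mass_defect_delta: float = 0.03

    def library_names(self) -> list:
        return [name for name, _ in self.libraries]


@dataclass
class Identification:
    """One query × library screening outcome (accepted or rejected)."""

    sample_id: str
    query_id: str
    library: str
    compound_key: Optional[str]
    compound_name: Optional[str]
    amp: Optional[float]
    ramp: Optional[float]
    decision: str
    reject_reason: Optional[str] = None
    confidence_label: Optional[str] = None
    matched_intensity_fraction: Optional[float] = None
    n_unexplained_major: Optional[int] = None

    @property
    def accepted(self) -> bool:
        return self.decision == ACCEPTED


@dataclass
class VennCounts:
    """Two-library identification accounting over (compound, sample) units."""

    library_a: str
    library_b: str
    only_a: int
    only_b: int
    both: int

    @property
    def total(self) -> int:
        return self.only_a + self.only_b + self.both


@dataclass
class ScreeningReport:
    """Aggregated screening outcome across samples and libraries."""

    sample_ids: list
    library_names: list
    identifications: list
    log: dict = field(default_factory=dict)

    @property
    def accepted(self) -> list:
        return [i for i in self.identifications if i.accepted]

    def accepted_units(self) -> dict:
        """(compound_key, sample_id) → set of library names that accepted it."""
        units: dict = {}
        for ident in self.accepted:
            units.setdefault((ident.compound_key, ident.sample_id), set()).add(ident.library)
        return units

    def per_library_counts(self) -> dict:
        counts = {name: 0 for name in self.library_names}
        for ident in self.accepted:
            counts[ident.library] += 1
        return counts

    def presence_matrix(self) -> pd.DataFrame:
        """Boolean compound × sample matrix of accepted identifications."""
        units = self.accepted_units()
        compounds = sorted({key for key, _ in units})
        matrix = pd.DataFrame(False, index=compounds, columns=self.sample_ids)
        for (compound, sample), _ in units.items():
            matrix.loc[compound, sample] = True
        return matrix

    def venn(self) -> Optional[VennCounts]:
        """Identification counts unique to / shared between two libraries.

        Defined for exactly two configured libraries; the three counts
        partition the distinct (compound, sample) identification units.
        """
        if len(self.library_names) != 2:
            return None
        name_a, name_b = self.library_names
        only_a = only_b = both = 0
        for _, libs in self.accepted_units().items():
            in_a, in_b = name_a in libs, name_b in libs
            if in_a and in_b:
                both += 1
            elif in_a:
                only_a += 1
            elif in_b:
                only_b += 1
        counts = VennCounts(name_a, name_b, only_a, only_b, both)
        assert counts.total == len(self.accepted_units()), "venn counts must partition"
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [vars(i).copy() for i in self.identifications]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spectral cleanup


def _monoisotopic_from_formula(formula: str) -> float:
    from pyteomics import mass

    return float(mass.calculate_mass(formula=formula))


def cleanup_spectrum(
    spectrum: Spectrum,
    formula_or_mass: Union[str, float, None] = None,
    *,
    precursor_filter: bool = False,
    mass_defect_filter: bool = False,
    mz_tol: float = 0.01,
    defect_delta: float = 0.03,
) -> Spectrum:
    """Remove likely interference peaks before searching.

    ``precursor_filter`` drops fragment peaks above the precursor m/z (plus
    tolerance): a fragment cannot be heavier than its precursor.
    ``mass_defect_filter`` drops peaks whose fractional mass falls outside a
    linear mass-defect envelope anchored at the precursor: a fragment at m/z
    m is expected to carry roughly ``defect(precursor) × m / precursor`` of
    the precursor's mass defect, within ±``defect_delta``.  The anchor is the
    precursor m/z unless a neutral monoisotopic mass or molecular formula is
    supplied (formula masses are computed with pyteomics; [M+H]+ assumed).

    Both filters are off by default; fractional masses are taken modulo 1, so
    compounds whose true defect is near the wrap-around (≳0.5, e.g. heavily
    halogenated species at high m/z) are outside the envelope model.
    """
    if not (precursor_filter or mass_defect_filter):
        return spectrum
    anchor_mz = spectrum.precursor_mz
    if isinstance(formula_or_mass, str):
        anchor_mz = _monoisotopic_from_formula(formula_or_mass) + PROTON
    elif isinstance(formula_or_mass, (int, float)) and formula_or_mass:
        anchor_mz = float(formula_or_mass)
    kept = list(spectrum.peaks)
    if precursor_filter:
        kept = [p for p in kept if p.mz <= spectrum.precursor_mz + mz_tol]
    if mass_defect_filter:
        anchor_defect = anchor_mz - math.floor(anchor_mz)
        out = []
        for p in kept:
            expected = anchor_defect * (p.mz / anchor_mz)
            defect = p.mz - math.floor(p.mz)
            if abs(defect - expected) <= defect_delta:
                out.append(p)
        kept = out
    return spectrum.with_peaks(kept)


# ---------------------------------------------------------------------------
# classification


def _qc_flags(result: SearchResult, best) -> Tuple[Optional[float], Optional[int]]:
    """Matched-intensity fraction and count of unexplained major peaks.

    Computed from the best (highest-mp) spectrum match of the accepted
    compound, on the preprocessed query: major = relative intensity > 10.
    """
    if not best.spectrum_matches:
        return None, None
    top = max(best.spectrum_matches, key=lambda sm: sm.mp)
    q = preprocess(result.query, result.params)
    total = q.total_intensity
    matched_mzs = {m.sample_peak.mz for m in top.matches}
    matched_intensity = sum(p.intensity for p in q.peaks if p.mz in matched_mzs)
    unexplained_major = sum(
        1 for p in q.peaks if p.intensity > 10.0 and p.mz not in matched_mzs
    )
    return (matched_intensity / total if total > 0 else None), unexplained_major


def classify(
    result: SearchResult,
    config: ScreeningConfig,
    library_name: str,
    sample_id: str = "",
    compound_names: Optional[dict] = None,
) -> list:
    """Turn one search result into screening identifications.

    At most one accepted identification per (query, library): the rank-1
    candidate, iff amp > amp_min and ramp > ramp_min (strict).  Rejected
    outcomes carry a reason (below_amp / below_ramp / no_candidates).
    """
    names = compound_names or {}
    query_id = result.query.source_id
    if not result.candidates:
        return [
            Identification(
                sample_id, query_id, library_name,
                None, None, None, None, REJECTED, NO_CANDIDATES,
            )
        ]
    best = result.candidates[0]
    amp, ramp = best.amp, best.ramp
    if amp <= config.amp_min:
        decision, reason = REJECTED, BELOW_AMP
    elif ramp <= config.ramp_min:
        decision, reason = REJECTED, BELOW_RAMP
    else:
        decision, reason = ACCEPTED, None
    mif = n_major = None
    label = None
    if decision == ACCEPTED:
        label = LEVEL_2A
        mif, n_major = _qc_flags(result, best)
    return [
        Identification(
            sample_id, query_id, library_name,
            best.compound_key, names.get(best.compound_key), amp, ramp,
            decision, reason, label, mif, n_major,
        )
    ]


# ---------------------------------------------------------------------------
# run-level screening


def screen_spectra(
    spectra: Sequence[Spectrum],
    config: ScreeningConfig,
    sample_id: str,
) -> ScreeningReport:
    """Search every non-empty spectrum of one sample against each library."""
    if not config.libraries:
        raise ValueError("screening requires at least one library")
    name_maps = {
        name: {k: rec.name for k, rec in library.compounds.items()}
        for name, library in config.libraries
    }
    identifications: list = []
    n_searched = 0
    n_nonempty = 0
    for spectrum in spectra:
        if not spectrum.peaks:
            for name, _ in config.libraries:
                identifications.append(
                    Identification(
                        sample_id, spectrum.source_id, name,
                        None, None, None, None, REJECTED, EMPTY_SPECTRUM,
                    )
                )
            continue
        n_nonempty += 1
        query = cleanup_spectrum(
            spectrum,
            precursor_filter=config.precursor_filter,
            mass_defect_filter=config.mass_defect_filter,
            mz_tol=config.params.mz_tol,
            defect_delta=config.mass_defect_delta,
        )
        if not query.peaks:
            for name, _ in config.libraries:
                identifications.append(
                    Identification(
                        sample_id, spectrum.source_id, name,
                        None, None, None, None, REJECTED, EMPTY_SPECTRUM,
                    )
                )
            continue
        n_searched += 1
        for name, library in config.libraries:
            result = search(query, library, config.params)
            identifications.extend(
                classify(result, config, name, sample_id, name_maps[name])
            )
    n_accepted = sum(1 for i in identifications if i.accepted)
    log = {
        sample_id: {
            "read": len(spectra),
            "non_empty": n_nonempty,
            "searched": n_searched,
            "accepted": n_accepted,
        }
    }
    logger.info("sample %s: %s", sample_id, log[sample_id])
    return ScreeningReport(
        sample_ids=[sample_id],
        library_names=config.library_names(),
        identifications=identifications,
        log=log,
    )


def screen_run(
    mgf_path: Union[str, Path],
    config: ScreeningConfig,
    sample_id: Optional[str] = None,
) -> ScreeningReport:
    """Screen one MGF run file; the sample id defaults to the file stem."""
    mgf_path = Path(mgf_path)
    spectra = read_mgf(mgf_path)
    return screen_spectra(spectra, config, sample_id or mgf_path.stem)


def aggregate_reports(reports: Sequence[ScreeningReport]) -> ScreeningReport:
    """Pool per-sample reports into one cross-sample report.

    All reports must have been produced with the same library set.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    names = reports[0].library_names
    for rep in reports[1:]:
        if rep.library_names != names:
            raise ValueError(
                f"mismatched library sets: {rep.library_names} vs {names}"
            )
    sample_ids: list = []
    identifications: list = []
    log: dict = {}
    for rep in reports:
        for sid in rep.sample_ids:
            if sid not in sample_ids:
                sample_ids.append(sid)
        identifications.extend(rep.identifications)
        log.update(rep.log)
    return ScreeningReport(sample_ids, names, identifications, log)


# ---------------------------------------------------------------------------
# report / config I/O


def write_report(report: ScreeningReport, out_dir: Union[str, Path]) -> None:
    """Write identifications TSV, venn summary TSV and a JSON run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_frame().to_csv(out / "identifications.tsv", sep="\t", index=False)
    venn = report.venn()
    if venn is not None:
        pd.DataFrame(
            [
                {"partition": f"only {venn.library_a}", "count": venn.only_a},
                {"partition": f"only {venn.library_b}", "count": venn.only_b},
                {"partition": "both", "count": venn.both},
                {"partition": "total", "count": venn.total},
            ]
        ).to_csv(out / "venn.tsv", sep="\t", index=False)
    with open(out / "run_log.json", "w", encoding="utf-8") as handle:
        json.dump(report.log, handle, indent=2, sort_keys=True)


def config_from_yaml(path: Union[str, Path]) -> ScreeningConfig:
    """Load a ScreeningConfig from YAML (library values are file paths)."""
    with open(path, "r", encoding="utf-8") as handle:
        data = yaml.safe_load(handle) or {}
    params = MatchParams(
        mz_tol=data.get("mz_tol", 0.01),
        intensity_cutoff_factor=data.get("cutoff", 0.01),
        precursor_tol=data.get("precursor_tol", 0.01),
    )
    libraries = [
        (name, load_library(lib_path))
        for name, lib_path in (data.get("libraries") or {}).items()
    ]
    return ScreeningConfig(
        amp_min=data.get("amp_min", 10.0),
        ramp_min=data.get("ramp_min", 50.0),
        params=params,
        libraries=libraries,
        precursor_filter=data.get("precursor_filter", False),
        mass_defect_filter=data.get("mass_defect_filter", False),
        mass_defect_delta=data.get("mass_defect_delta", 0.03),
    )
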