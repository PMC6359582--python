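"""Match-probability spectral search.

The search compares a query spectrum against every reference spectrum of
every candidate compound (candidates selected by precursor m/z) and reports
three scores, each on a 0–100 scale:

* ``mp`` — reference-spectrum-specific match probability: how well the query
  matches one library spectrum.  The score implemented here is a symmetric
  composite of the matched-peak-count fraction and the mean matched-intensity
  fraction::

      mp = 100 · [2·n_m / (n_s + n_r)] · [(I_ms/I_s + I_mr/I_r) / 2]

  with ``n_s``/``n_r`` the query/reference peak counts, ``n_m`` the number of
  matching fragments, ``I_s``/``I_r`` the total intensities and
  ``I_ms``/``I_mr`` the matched intensities.  It is 100 for identical
  spectra, 0 for disjoint ones, and symmetric in the two roles.  All scoring
  goes through :func:`compute_mp`, so an alternative mp definition can be
  swapped in at a single point.
* ``amp`` — average match probability: the mean mp over *all* of a
  compound's library spectra (its whole collision-energy series).  Spectra
  acquired at energies far from the query's contribute low mp values and pull
  amp down; that is what makes amp collision-energy aware.
* ``ramp`` — relative average match probability: a compound's share of the
  candidate set's total amp, scaled to 100.  A sole candidate scores 100.

The compound with the highest amp and ramp is the best match.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .library import SpectralLibrary, candidates
from .spectra import Peak, Spectrum


@dataclass(frozen=True)
class MatchParams:
    """Search tolerances.

    ``mz_tol``: fragment m/z tolerance (Th, ± closed interval).
    ``intensity_cutoff_factor``: peaks below this fraction of the base peak
    are removed before matching.
    ``precursor_tol``: precursor m/z tolerance for candidate selection (Th).
    """

    mz_tol: float = 0.01
    intensity_cutoff_factor: float = 0.01
    precursor_tol: float = 0.01

    def __post_init__(self) -> None:
        if not (self.mz_tol > 0 and self.precursor_tol > 0):
            raise ValueError("tolerances must be strictly positive")
        if not (0 < self.intensity_cutoff_factor < 1):
            raise ValueError("intensity_cutoff_factor must be in (0, 1)")


@dataclass(frozen=True)
class FragmentMatch:
    """A fragment ion present in both spectra being compared."""

    sample_peak: Peak
    reference_peak: Peak
    delta_mz: float  # sample − reference, signed


@dataclass
class SpectrumMatch:
    """Outcome of comparing the query with one reference spectrum."""

    reference_spectrum: Spectrum
    matches: list
    mp: float


@dataclass
class CompoundMatch:
    """Per-candidate outcome: one SpectrumMatch per library spectrum."""

    compound_key: str
    spectrum_matches: list
    amp: float = 0.0
    ramp: float = 0.0


@dataclass
class SearchResult:
    query: Spectrum
    candidates: list  # CompoundMatch, sorted by (amp, ramp) desc, key asc
    params: MatchParams

    @property
    def best(self) -> Optional[CompoundMatch]:
        return self.candidates[0] if self.candidates else None


def preprocess(spectrum: Spectrum, params: MatchParams) -> Spectrum:
    """Rescale to base peak 100 and drop peaks below the intensity cutoff.

    Raises ``ValueError`` for a spectrum with no peaks.
    """
    if not spectrum.peaks:
        raise ValueError("no peaks")
    base = spectrum.base_peak_intensity
    if base <= 0:
        raise ValueError("no peaks above zero intensity")
    scale = 100.0 / base
    cutoff = 100.0 * params.intensity_cutoff_factor
    kept = [
        Peak(p.mz, p.intensity * scale)
        for p in spectrum.peaks
        if p.intensity * scale >= cutoff
    ]
    return spectrum.with_peaks(kept)


def match_fragments(
    sample: Spectrum, reference: Spectrum, mz_tol: float
) -> list:
    """One-to-one matched-fragment assignment within ±mz_tol.

    Greedy by ascending |Δm/z|; ties break toward the lower reference m/z
    (then lower sample m/z), so the assignment is total and deterministic.
    Each peak on either side is used at most once.
    """
    ref_mzs = [p.mz for p in reference.peaks]
    pairs = []
    for i, sp in enumerate(sample.peaks):
        lo = bisect.bisect_left(ref_mzs, sp.mz - mz_tol)
        hi = bisect.bisect_right(ref_mzs, sp.mz + mz_tol)
        for j in range(lo, hi):
            delta = sp.mz - ref_mzs[j]
            if abs(delta) <= mz_tol:
                pairs.append((abs(delta), ref_mzs[j], sp.mz, i, j, delta))
    pairs.sort()
    used_sample: set = set()
    used_reference: set = set()
    out = []
    for _, _, _, i, j, delta in pairs:
        if i in used_sample or j in used_reference:
            continue
        used_sample.add(i)
        used_reference.add(j)
        out.append(FragmentMatch(sample.peaks[i], reference.peaks[j], delta))
    out.sort(key=lambda m: m.sample_peak.mz)
    return out


def compute_mp(sample: Spectrum, reference: Spectrum, params: MatchParams) -> SpectrumMatch:
    """Reference-spectrum-specific match probability for two preprocessed spectra."""
    matches = match_fragments(sample, reference, params.mz_tol)
    n_s = len(sample.peaks)
    n_r = len(reference.peaks)
    if n_s == 0 or n_r == 0:
        raise ValueError("compute_mp requires non-empty preprocessed spectra")
    n_m = len(matches)
    if n_m == 0:
        return SpectrumMatch(reference, matches, 0.0)
    i_s = sample.total_intensity
    i_r = reference.total_intensity
    i_ms = sum(m.sample_peak.intensity for m in matches)
    i_mr = sum(m.reference_peak.intensity for m in matches)
    count_factor = 2.0 * n_m / (n_s + n_r)
    intensity_factor = 0.5 * (i_ms / i_s + i_mr / i_r)
    mp = 100.0 * count_factor * intensity_factor
    return SpectrumMatch(reference, matches, min(mp, 100.0))


def compute_amp_ramp(candidate_matches: Sequence[CompoundMatch]) -> list:
    """Fill amp (mean mp over a compound's whole spectrum series) and ramp.

    ramp is the compound's share of the candidate set's summed amp, ×100; if
    every candidate has amp 0, all ramps are 0.
    """
    out = []
    for cm in candidate_matches:
        if not cm.spectrum_matches:
            raise ValueError(f"candidate {cm.compound_key} has no spectrum matches")
        amp = sum(sm.mp for sm in cm.spectrum_matches) / len(cm.spectrum_matches)
        out.append(replace_amp(cm, amp))
    total = sum(cm.amp for cm in out)
    for cm in out:
        cm.ramp = 100.0 * cm.amp / total if total > 0 else 0.0
    return out


def replace_amp(cm: CompoundMatch, amp: float) -> CompoundMatch:
    return CompoundMatch(cm.compound_key, cm.spectrum_matches, amp, cm.ramp)


def search(
    query: Spectrum,
    library: SpectralLibrary,
    params: Optional[MatchParams] = None,
    exclude_source_id: Optional[str] = None,
) -> SearchResult:
    """Rank library compounds against one query spectrum.

    Candidates are the compounds with at least one reference spectrum whose
    precursor m/z lies within ``params.precursor_tol`` of the query's; mp is
    then computed against *every* spectrum of each candidate, and amp/ramp
    over the candidate set.  ``exclude_source_id`` removes one reference
    spectrum from scoring (leave-one-out self tests).
    """
    params = params or MatchParams()
    if not (query.precursor_mz > 0) or not math.isfinite(query.precursor_mz):
        raise ValueError("query spectrum has no usable precursor m/z")
    q = preprocess(query, params)
    cands = candidates(library, query.precursor_mz, params.precursor_tol)
    compound_matches = []
    for rec in cands:
        spectrum_matches = []
        for ref in sorted(rec.spectra, key=lambda s: s.source_id):
            if exclude_source_id is not None and ref.source_id == exclude_source_id:
                continue
            ref_pre = preprocess(ref, params)
            spectrum_matches.append(compute_mp(q, ref_pre, params))
        if spectrum_matches:
            compound_matches.append(CompoundMatch(rec.compound_key, spectrum_matches))
    compound_matches = compute_amp_ramp(compound_matches)
    compound_matches.sort(key=lambda cm: (-cm.amp, -cm.ramp, cm.compound_key))
    return SearchResult(query=query, candidates=compound_matches, params=params)
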