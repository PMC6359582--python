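"""Match-probability scoring: preprocessing, fragment assignment, mp/amp/ramp."""

import itertools

import numpy as np
import pytest

from mslibsearch import (
    CompoundMatch,
    Peak,
    Spectrum,
    compute_amp_ramp,
    compute_mp,
    match_fragments,
    preprocess,
    search,
)
from conftest import random_library, random_spectrum


def spec(pairs, precursor=500.0):
    return Spectrum(peaks=[Peak(m, i) for m, i in pairs], precursor_mz=precursor)


class TestPreprocess:
    def test_base_peak_rescaled_to_100(self, params):
        out = preprocess(spec([(100.0, 1000.0)]), params)
        assert out.peaks == [Peak(100.0, 100.0)]

    def test_cutoff_removes_sub_percent_peaks(self, params):
        out = preprocess(spec([(100.0, 1000.0), (200.0, 5.0)]), params)
        assert [p.mz for p in out.peaks] == [100.0]  # 5/1000 = 0.005 < 0.01

    def test_equal_peaks_all_retained(self, params):
        out = preprocess(spec([(100.0, 7.0), (200.0, 7.0), (300.0, 7.0)]), params)
        assert len(out.peaks) == 3
        assert all(p.intensity == pytest.approx(100.0) for p in out.peaks)

    def test_empty_spectrum_raises(self, params):
        with pytest.raises(ValueError, match="no peaks"):
            preprocess(spec([]), params)


class TestMatchFragments:
    def test_within_tolerance(self):
        out = match_fragments(spec([(100.000, 1)]), spec([(100.009, 1)]), 0.01)
        assert len(out) == 1
        assert out[0].delta_mz == pytest.approx(-0.009)

    def test_outside_tolerance(self):
        assert match_fragments(spec([(100.000, 1)]), spec([(100.011, 1)]), 0.01) == []

    def test_equidistant_tie_goes_to_lower_reference_mz(self):
        out = match_fragments(
            spec([(100.000, 1)]), spec([(99.995, 1), (100.005, 1)]), 0.01
        )
        assert len(out) == 1
        assert out[0].reference_peak.mz == pytest.approx(99.995)

    def test_one_to_one_assignment(self):
        sample = spec([(100.000, 1), (100.004, 1)])
        reference = spec([(100.002, 1)])
        out = match_fragments(sample, reference, 0.01)
        assert len(out) == 1  # a reference peak is used at most once


class TestComputeMP:
    def test_identity_is_100(self, params, rng):
        for _ in range(20):
            s = preprocess(random_spectrum(rng), params)
            assert compute_mp(s, s, params).mp == pytest.approx(100.0)

    def test_disjoint_is_0(self, params):
        a = preprocess(spec([(100.0, 1), (200.0, 1)]), params)
        b = preprocess(spec([(300.0, 1), (400.0, 1)]), params)
        assert compute_mp(a, b, params).mp == 0.0

    def test_half_overlap_hand_value(self, params):
        # n_m=1 of 2+2 peaks: count factor 0.5; half the intensity matched on
        # each side: intensity factor 0.5; mp = 100 * 0.5 * 0.5 = 25
        a = preprocess(spec([(100.0, 100.0), (200.0, 100.0)]), params)
        b = preprocess(spec([(100.0, 100.0), (300.0, 100.0)]), params)
        assert compute_mp(a, b, params).mp == pytest.approx(25.0)

    def test_symmetry(self, params, rng):
        """mp is invariant under swapping the sample and reference roles."""
        for _ in range(50):
            a = preprocess(random_spectrum(rng), params)
            b = preprocess(random_spectrum(rng, precursor=a.precursor_mz), params)
            assert compute_mp(a, b, params).mp == pytest.approx(
                compute_mp(b, a, params).mp, abs=1e-12
            )

    def test_removing_matched_fragment_never_increases_mp(self, params, rng):
        for _ in range(30):
            a = preprocess(random_spectrum(rng, n_peaks=8), params)
            b = preprocess(random_spectrum(rng, n_peaks=8, precursor=a.precursor_mz), params)
            # overlay half of b's peaks onto a so there are real matches; keep
            # the rest of a well clear of b so removal cannot re-pair anything
            a_clear = [
                p for p in a.peaks
                if all(abs(p.mz - q.mz) > 3 * params.mz_tol for q in b.peaks)
            ]
            merged = Spectrum(
                peaks=a_clear + b.peaks[::2], precursor_mz=a.precursor_mz
            )
            merged = preprocess(merged, params)
            base = compute_mp(merged, b, params)
            for m in base.matches:
                reduced = merged.with_peaks(
                    [p for p in merged.peaks if p.mz != m.sample_peak.mz]
                )
                if not reduced.peaks:
                    continue
                assert compute_mp(reduced, b, params).mp <= base.mp + 1e-9


class TestAmpRamp:
    def _cm(self, key, mps):
        from mslibsearch.matching import SpectrumMatch

        return CompoundMatch(key, [SpectrumMatch(None, [None], mp) for mp in mps])

    def test_mean_and_sole_candidate(self):
        (out,) = compute_amp_ramp([self._cm("a", [100.0, 50.0])])
        assert out.amp == pytest.approx(75.0)
        assert out.ramp == pytest.approx(100.0)

    def test_two_candidate_normalization(self):
        out = compute_amp_ramp([self._cm("a", [60.0]), self._cm("b", [20.0])])
        assert [c.ramp for c in out] == [pytest.approx(75.0), pytest.approx(25.0)]

    def test_all_zero(self):
        out = compute_amp_ramp([self._cm("a", [0.0]), self._cm("b", [0.0, 0.0])])
        assert all(c.amp == 0.0 and c.ramp == 0.0 for c in out)

    def test_ramp_sum_is_0_or_100(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 6))
            cms = [
                self._cm(f"c{i}", list(rng.uniform(0, 100, rng.integers(1, 5))))
                for i in range(n)
            ]
            total = sum(c.ramp for c in compute_amp_ramp(cms))
            assert total == pytest.approx(100.0, abs=1e-9) or total == 0.0


def brute_force_search(query, library, params):
    """Direct-definition oracle: no precursor index, no shared helpers.

    Scans all spectra, selects candidate compounds by the closed precursor
    window, scores with an O(n²) pair enumeration and the mp formula, then
    averages and normalizes.
    """
    q = preprocess(query, params)
    amps = {}
    for key, rec in library.compounds.items():
        mps = []
        in_window = any(
            abs(s.precursor_mz - query.precursor_mz) <= params.precursor_tol
            for s in rec.spectra
        )
        if not in_window:
            continue
        for ref in rec.spectra:
            r = preprocess(ref, params)
            pairs = sorted(
                (
                    (abs(sp.mz - rp.mz), rp.mz, sp.mz, si, ri)
                    for (si, sp), (ri, rp) in itertools.product(
                        enumerate(q.peaks), enumerate(r.peaks)
                    )
                    if abs(sp.mz - rp.mz) <= params.mz_tol
                ),
            )
            used_s, used_r, matches = set(), set(), []
            for _, _, _, si, ri in pairs:
                if si in used_s or ri in used_r:
                    continue
                used_s.add(si)
                used_r.add(ri)
                matches.append((q.peaks[si], r.peaks[ri]))
            if not matches:
                mps.append(0.0)
                continue
            n_m = len(matches)
            i_ms = sum(p.intensity for p, _ in matches)
            i_mr = sum(p.intensity for _, p in matches)
            mp = (
                100.0
                * (2.0 * n_m / (len(q.peaks) + len(r.peaks)))
                * 0.5
                * (i_ms / q.total_intensity + i_mr / r.total_intensity)
            )
            mps.append(mp)
        amps[key] = sum(mps) / len(mps)
    total = sum(amps.values())
    ranked = sorted(
        (
            (key, amp, 100.0 * amp / total if total > 0 else 0.0)
            for key, amp in amps.items()
        ),
        key=lambda t: (-t[1], -t[2], t[0]),
    )
    return ranked


class TestSearch:
    def test_identity_query_ranks_first(self, rng, params):
        lib = random_library(rng, 5)
        key, query = lib.all_spectra()[0]
        result = search(query, lib, params)
        assert result.best.compound_key == key
        assert max(sm.mp for sm in result.best.spectrum_matches) == pytest.approx(100.0)

    def test_no_precursor_match_gives_empty_candidates(self, rng, params):
        lib = random_library(rng, 3)
        query = random_spectrum(rng, precursor=1200.0)
        assert search(query, lib, params).candidates == []

    def test_fragment_free_candidate_ranks_last_with_zero_scores(self, params):
        from mslibsearch import CompoundInfo, build_library

        s_a = spec([(100.0, 50.0), (150.0, 100.0)], precursor=300.1)
        s_b = spec([(222.0, 100.0)], precursor=300.1)
        lib = build_library(
            [
                (CompoundInfo("a", "a"), s_a.with_peaks(s_a.peaks)),
                (CompoundInfo("b", "b"), s_b.with_peaks(s_b.peaks)),
            ],
            "t", "synthetic",
        )
        result = search(s_a, lib, params)
        assert [c.compound_key for c in result.candidates] == ["a", "b"]
        assert result.candidates[1].amp == 0.0
        assert result.candidates[1].ramp == 0.0

    def test_matches_brute_force_oracle(self, params):
        """Indexed search equals direct all-pairs scoring on random libraries."""
        rng = np.random.default_rng(777)
        for trial in range(20):
            lib = random_library(rng, int(rng.integers(2, 12)), name=f"lib{trial}")
            key, query = lib.all_spectra()[int(rng.integers(lib.n_spectra))]
            result = search(query, lib, params)
            expected = brute_force_search(query, lib, params)
            got = [(c.compound_key, c.amp, c.ramp) for c in result.candidates]
            assert [g[0] for g in got] == [e[0] for e in expected]
            for g, e in zip(got, expected):
                assert g[1] == pytest.approx(e[1], abs=1e-9)
                assert g[2] == pytest.approx(e[2], abs=1e-9)
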