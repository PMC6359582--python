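# Methods

This note documents the models and procedures implemented in `mslibsearch`,
the parameters that matter, and the design choices made where the design was
genuinely open.

## Spectral matching

**Preprocessing.** Each spectrum is rescaled so its base peak is 100 and
peaks below `intensity_cutoff_factor` (default 0.01) of the base peak are
removed. Duplicate m/z values are merged (intensities summed) when a
spectrum is constructed, so fragment positions are unique.

**Fragment assignment.** Matching fragments are pairs of peaks within
±`mz_tol` (default 0.01 Th, closed interval). Assignment is one-to-one and
greedy by ascending |Δm/z|, with ties broken toward the lower reference m/z
and then the lower sample m/z. The tie rules exist purely to make the
assignment total and deterministic; with realistically separated peaks
(spacing ≫ tolerance) the assignment is unique and the rules never fire.

**Scores.** The reference-spectrum match probability is

    mp = 100 · [2·n_m/(n_s+n_r)] · [(I_ms/I_s + I_mr/I_r)/2]

a symmetric composite of the matched-count fraction and the mean
matched-intensity fraction. Properties relied on elsewhere: mp ∈ [0, 100];
mp = 100 iff the preprocessed spectra are identical under the tolerance;
mp = 0 iff no fragments match; removing a matched sample fragment never
increases mp (provable from the formula when removal cannot re-pair peaks,
i.e. at realistic peak spacing). The historical search engine this score
emulates does not publish its formula; this one is a declared variant kept
behind `compute_mp` so it can be swapped, and no claim of numerical
equivalence with any external implementation is made.

`amp` is the mean mp over **all** of a candidate compound's library
spectra, including zero-mp ones. Averaging over the full collision-energy
series is deliberate: it rewards compounds whose series brackets the
query's effective energy and penalizes single-spectrum coincidences, and it
is what produces the collision-energy dependence of sensitivity. `ramp` is
100·amp/Σamp over the candidate set (all ramps 0 when every amp is 0), so
it measures the share of total match mass; a sole candidate scores 100.
Ranking is by (amp, ramp) descending with compound-key tie-break.

**Candidate selection** is per spectrum (any library spectrum whose
precursor m/z is within ±`precursor_tol`, default 0.01 Th, closed) but
aggregation is per compound, so compounds with entries at several precursor
m/z values (isotopes, adducts, in-source fragments) are handled naturally.

## Screening pipeline

Every spectrum of a run that carries precursor and fragment information is
searched directly against each configured library — no peak picking or
XIC-based feature detection, by design. The rank-1 candidate is accepted
("Level 2a", probable structure via spectral match) iff amp > `amp_min`
and ramp > `ramp_min`, strict inequalities. Defaults sit at the stringent
end of the recommended bands (amp_min 10 of 1–10, ramp_min 50 of 30–50):
conservative defaults minimize false positives. One query may yield at most
one accepted identification per library (rank-1 only); isomer co-reporting
is out of scope.

Manual expert review of accepted matches is replaced by machine QC flags
attached to accepted identifications — the matched-intensity fraction and
the count of unexplained major peaks (>10% of base) in the best-matching
reference comparison. Flags never auto-reject.

Optional spectral cleanup before searching: a *precursor filter* drops
fragment peaks heavier than the precursor (plus tolerance), and a *mass
defect filter* drops peaks whose fractional mass deviates more than
`defect_delta` (default 0.03) from a linear envelope
`defect(precursor)·(m/precursor)` anchored at the precursor (or at a
user-supplied neutral mass/formula; formula masses via pyteomics, [M+H]+
assumed). Both are off by default. The envelope uses fractional masses
modulo 1 and does not model the wrap-around of defects ≳ 0.5 (heavily
halogenated, high-mass species) — a known limitation.

Identification units for cross-library accounting are (compound, sample)
pairs. The venn split (only A / only B / both) partitions the accepted
units; the false-negative denominator is the set of units whose compound is
available in both libraries and which at least one library accepted.

## Benchmarking

Cross-library evaluation mirrors the standard positive/negative-control
design: querying library Q against reference library R, spectra of
compounds present in both collections are positive controls, all other Q
spectra negative controls. A positive counts as TP only when the accepted
rank-1 hit is the true compound (the stricter reading); a negative counts
as FP when anything is accepted for it. Self-matching queries every
spectrum of a library against the entire library, query included
(leave-one-out is available but off by default). CE-stratified sensitivity
bins positives by exact (scheme, value); ramped eV acquisitions bin at
their center value; spectra without a collision energy fall into an
"unknown" bin.

## Synthetic data generator

The generator provides the study conditions for all quantitative tests.
Per compound: a protonated precursor (uniform 150–800 Th) and 5–15 fragment
channels (≥1 Th apart, ≥20 Th below the precursor). On a canonical eV axis,
precursor survival is logistic, `1/(1+exp((ce−e50)/slope))` with defaults
e50 = 25 eV, slope = 4 eV; channel efficiency is Gaussian with centers
uniform in 10–45 eV, widths 5–10 eV, weights 0.2–1. The defaults place the
fragment-rich regime at roughly 20–50 canonical eV: below it spectra are
precursor-dominated, above it total ion yield collapses.

Each instrument view maps the canonical axis affinely: the QqTOF view is
the identity (eV), the Orbitrap view uses NCE = 1.2·eV + 6, which puts the
20–50 eV band at 30–66 NCE — the empirical correspondence between the two
scales. On top of the affine map each (instrument, compound) pair carries a
fixed Gaussian offset (`ce_map_sigma`; 2 eV QqTOF, 4 eV Orbitrap),
reflecting that nominal collision energy is not directly equal to eV and
the correspondence holds on average, not per compound. The offset is keyed
deterministically (CRC32 of instrument and compound identity), so all
renders within one instrument view are self-consistent.

Noise model, applied to raw (pre-normalization) channel intensities:
Poisson-style detection with probability `1 − exp(−raw/detection_scale)`
(default 0.04 — peaks from low-yield spectra flicker in and out); Gaussian
m/z jitter (σ 0.002 Th); log-normal intensity noise (CV 0.10); and an
additional dropout of weak peaks (< 2 relative) with probability 0.10.
With all noise terms zero a render equals the ideal spectrum exactly — a
tested invariant. Query corruption emulates complex-matrix DDA spectra:
interference mode adds a few strong peaks (default 5 at 50% of base) at
uniform random m/z in (50, precursor+50), noise mode many weak ones
(default 30 at ≤5%).

The default benchmark scenario builds two 50-compound libraries with 60%
compound overlap, renders the QqTOF view on a 10–70 eV grid (7 spectra per
compound) and the Orbitrap view on a 15–90 NCE grid (6 per compound), and
draws one clean truth-labelled query per compound × grid energy per
instrument. All randomness descends from a single integer seed through
numpy `SeedSequence` spawning; libraries serialize byte-identically for a
given seed.

Breakdown and noise defaults are free parameters of an intentionally
minimal model, chosen once so that the generator reproduces the qualitative
phenomenology the benchmark needs robustly across seeds — near-perfect
self-matching, ≥95% cross-instrument sensitivity in the mid energy range,
and degradation at both grid extremes — and they are not fitted to any
measured instrument. What passing tests show is that the *search and
accounting machinery* behaves correctly under these conditions; they say
nothing about absolute sensitivities on real libraries, which depend on
fragmentation chemistry, calibration and curation that this model does not
attempt (no fragment formulas, isotope patterns, adducts, retention times,
or profile-mode effects).

## Problem sizes and numerics

Quantitative tests and the acceptance script use the default scenario
(50 compounds/library, 350 + 300 spectra) over five seeds, ~200-spectrum
identity batteries, 20-library oracle-equivalence sweeps, and 100 paired
corruption trials; the full suite runs in well under a minute on one CPU.
Scores are plain float64 arithmetic; ramp sums are asserted to 1e-9;
serialized m/z and intensities carry six decimals (round-trip tolerance
1e-6). Degenerate inputs are defined, not special-cased: empty spectra are
rejected by `preprocess` with "no peaks" errors, kept-but-flagged by
the MGF reader, and skipped with a log line by the extraction step;
rate denominators of zero yield absent (None) rates rather than NaN.

## Positive-mode scope

Only positive-mode behavior is exercised by the tests (the intended
applications are positive mode); negative polarity is parsed and carried
through but not specially handled.
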