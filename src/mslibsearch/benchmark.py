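"""Cross-library performance evaluation.

Two libraries built on different instruments are searched against each
other.  Spectra of compounds present in both collections are positive
controls (the search should recover the compound); all other query-library
spectra are negative controls (any accepted hit is spurious).  From the
resulting confusion counts the module reports sensitivity (true positive
rate) and specificity (true negative rate), optionally stratified by the
collision energy at which each positive-control spectrum was acquired —
the stratification that exposes the usable collision-energy working range
of a library pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .library import SpectralLibrary, library_overlap
from .matching import search
from .pipeline import ScreeningConfig, ScreeningReport, classify
from .spectra import CollisionEnergy, Spectrum

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """tp/fn from positive controls, tn/fp from negative controls."""

    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    @property
    def n_positives(self) -> int:
        return self.tp + self.fn

    @property
    def n_negatives(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> Optional[float]:
        """True positive rate; None when there are no positive controls."""
        return self.tp / self.n_positives if self.n_positives else None

    @property
    def specificity(self) -> Optional[float]:
        """True negative rate; None when there are no negative controls."""
        return self.tn / self.n_negatives if self.n_negatives else None

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fn + other.fn,
            self.tn + other.tn, self.fp + other.fp,
        )


@dataclass
class ControlPartition:
    """Positive/negative control split of one query library vs a reference."""

    query_library: str
    reference_library: str
    positives: list  # (Spectrum, true compound_key)
    negatives: list  # Spectrum


@dataclass
class CEBin:
    """Confusion counts for positives acquired at one collision energy."""

    collision_energy: Optional[CollisionEnergy]
    counts: ConfusionCounts


def partition_controls(
    query_lib: SpectralLibrary, reference_lib: SpectralLibrary
) -> ControlPartition:
    """Split the query library's spectra into positive and negative controls.

    Positives: spectra of compounds shared with the reference library.
    Negatives: every other query-library spectrum.  The two lists partition
    the query library.
    """
    shared, _, _ = library_overlap(query_lib, reference_lib)
    if not shared:
        logger.warning(
            "libraries %s and %s share no compounds: empty positive set",
            query_lib.name, reference_lib.name,
        )
    positives = []
    negatives = []
    for key, spectrum in query_lib.all_spectra():
        if key in shared:
            positives.append((spectrum, key))
        else:
            negatives.append(spectrum)
    return ControlPartition(query_lib.name, reference_lib.name, positives, negatives)


def _accepted_key(
    spectrum: Spectrum,
    reference_lib: SpectralLibrary,
    config: ScreeningConfig,
    exclude_source_id: Optional[str] = None,
) -> Optional[str]:
    """Compound key of the accepted rank-1 identification, or None."""
    result = search(spectrum, reference_lib, config.params, exclude_source_id)
    idents = classify(result, config, reference_lib.name)
    ident = idents[0]
    return ident.compound_key if ident.accepted else None


def evaluate(
    partition: ControlPartition,
    reference_lib: SpectralLibrary,
    config: ScreeningConfig,
) -> ConfusionCounts:
    """Score every control spectrum against the reference library.

    A positive control counts as TP only when the accepted rank-1 hit is its
    true compound; a negative control counts as FP when anything at all is
    accepted for it.
    """
    counts = ConfusionCounts()
    for spectrum, true_key in partition.positives:
        accepted = _accepted_key(spectrum, reference_lib, config)
        if accepted == true_key:
            counts.tp += 1
        else:
            counts.fn += 1
    for spectrum in partition.negatives:
        accepted = _accepted_key(spectrum, reference_lib, config)
        if accepted is None:
            counts.tn += 1
        else:
            counts.fp += 1
    return counts


def self_match(
    library: SpectralLibrary,
    config: ScreeningConfig,
    leave_one_out: bool = False,
) -> ConfusionCounts:
    """Match each spectrum of a library against the entire library itself.

    By default the query spectrum stays in the reference set (the library is
    queried as-is); ``leave_one_out`` removes it from scoring.
    """
    if library.n_spectra == 0:
        raise ValueError("cannot self-match an empty library")
    counts = ConfusionCounts()
    for key, spectrum in library.all_spectra():
        exclude = spectrum.source_id if leave_one_out else None
        accepted = _accepted_key(spectrum, library, config, exclude)
        if accepted == key:
            counts.tp += 1
        else:
            counts.fn += 1
    return counts


def ce_stratified_sensitivity(
    partition: ControlPartition,
    reference_lib: SpectralLibrary,
    config: ScreeningConfig,
) -> list:
    """Per-collision-energy sensitivity over the positive controls.

    Positives are grouped by exact (scheme, value); ramped eV acquisitions
    bin at their center value.  Spectra without a collision-energy
    descriptor are collected into an "unknown" bin (key None).  Bins come
    back sorted by scheme then value, the unknown bin last.
    """
    groups: dict = {}
    for spectrum, true_key in partition.positives:
        ce = spectrum.collision_energy
        key = (ce.scheme, ce.value) if ce is not None else None
        groups.setdefault(key, []).append((spectrum, true_key))
    bins = []
    for key in sorted([k for k in groups if k is not None]) + (
        [None] if None in groups else []
    ):
        members = groups[key]
        counts = ConfusionCounts()
        for spectrum, true_key in members:
            accepted = _accepted_key(spectrum, reference_lib, config)
            if accepted == true_key:
                counts.tp += 1
            else:
                counts.fn += 1
        ce = members[0][0].collision_energy if key is not None else None
        if ce is None and key is not None:  # pragma: no cover - defensive
            continue
        if key is None:
            logger.info("%d positive spectra lack a collision energy", counts.n_positives)
        bins.append(CEBin(ce, counts))
    return bins


def false_negative_rate(report: ScreeningReport, shared_keys: set) -> dict:
    """Per-library false-negative accounting over shared-compound hits.

    The denominator is the set of (compound, sample) identification units
    whose compound is available in both libraries and which at least one
    library accepted; a library's false negatives are the units it missed.
    Returns ``{library: (count, rate)}``, or ``{library: None}`` when the
    denominator is empty.
    """
    units = {
        unit: libs
        for unit, libs in report.accepted_units().items()
        if unit[0] in shared_keys
    }
    out: dict = {}
    for name in report.library_names:
        if not units:
            out[name] = None
            continue
        missed = sum(1 for libs in units.values() if name not in libs)
        out[name] = (missed, missed / len(units))
    return out


# ---------------------------------------------------------------------------
# outputs


def confusion_frame(counts: ConfusionCounts):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "tp": counts.tp, "fn": counts.fn,
                "tn": counts.tn, "fp": counts.fp,
                "sensitivity": counts.sensitivity,
                "specificity": counts.specificity,
            }
        ]
    )


def ce_bins_frame(bins: Sequence[CEBin]):
    import pandas as pd

    rows = []
    for b in bins:
        rows.append(
            {
                "ce_scheme": b.collision_energy.scheme if b.collision_energy else "unknown",
                "ce_value": b.collision_energy.value if b.collision_energy else None,
                "n_positives": b.counts.n_positives,
                "sensitivity": b.counts.sensitivity,
            }
        )
    return pd.DataFrame(rows)


def plot_sensitivity_vs_ce(bins: Sequence[CEBin], path: Union[str, Path]) -> None:
    """Sensitivity-vs-collision-energy plot, one line per CE scheme."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by_scheme: dict = {}
    for b in bins:
        if b.collision_energy is None or b.counts.sensitivity is None:
            continue
        by_scheme.setdefault(b.collision_energy.scheme, []).append(
            (b.collision_energy.value, 100.0 * b.counts.sensitivity)
        )
    fig, ax = plt.subplots(figsize=(6, 4))
    for scheme, points in sorted(by_scheme.items()):
        points.sort()
        ax.plot([p[0] for p in points], [p[1] for p in points], "o-", label=scheme)
    ax.set_xlabel("collision energy (instrument units)")
    ax.set_ylabel("sensitivity (%)")
    ax.set_ylim(0, 105)
    ax.legend(title="CE scheme")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
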