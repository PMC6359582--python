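"""Search one query spectrum against a library and read the mp/amp/ramp scores.

Renders a DDA-like query for one compound at 45 NCE and ranks the candidate
compounds of the QqTOF library.  amp is the mean match probability over a
candidate's entire collision-energy spectrum series; ramp is its share of the
candidate set's total amp (a sole candidate scores 100).
"""

from mslibsearch import (
    CorruptionSpec,
    ScenarioConfig,
    generate_benchmark_scenario,
    render_query,
    search,
)

scenario = generate_benchmark_scenario(ScenarioConfig(seed=1))
compound = scenario.shared_compounds()[0]

query = render_query(
    compound, scenario.config.breakdown, scenario.config.orbitrap, 45.0,
    CorruptionSpec(mode="clean"), seed=123,
)
print(f"query: {compound.compound_key} at 45 NCE, {len(query.peaks)} peaks, "
      f"precursor m/z {query.precursor_mz:.4f}")

result = search(query, scenario.lib_qqtof)
for rank, cm in enumerate(result.candidates, start=1):
    mps = ", ".join(f"{sm.mp:.0f}" for sm in cm.spectrum_matches)
    print(f"  rank {rank}: {cm.compound_key}  amp={cm.amp:.1f}  ramp={cm.ramp:.1f}  "
          f"(mp per reference spectrum: {mps})")
# The per-spectrum mp values trace the breakdown curve: reference spectra
# acquired near the query's collision energy match well, the extremes poorly;
# amp averages over the whole series, which is what makes the search robust
# to a moderate collision-energy mismatch.
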