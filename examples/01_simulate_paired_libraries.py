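"""Generate a paired QqTOF/Orbitrap synthetic library scenario.

Builds two reference libraries of the same 50 compounds (60% shared) from
parametric breakdown curves: the QqTOF view renders CID spectra on a 10–70 eV
grid, the Orbitrap view HCD spectra on a 15–90 NCE grid.  Prints the library
composition a curator would check first.
"""

from mslibsearch import ScenarioConfig, generate_benchmark_scenario, library_overlap, library_stats

scenario = generate_benchmark_scenario(ScenarioConfig(n_compounds=50, overlap=0.6, seed=1))

for lib in (scenario.lib_qqtof, scenario.lib_orbitrap):
    stats = library_stats(lib)
    print(f"{lib.name}: {stats.n_compounds} compounds, {stats.n_spectra} spectra "
          f"({stats.n_by_activation['CID']} CID, {stats.n_by_activation['HCD']} HCD)")

shared, a_only, b_only = library_overlap(scenario.lib_qqtof, scenario.lib_orbitrap)
print(f"overlap: {len(shared)} compounds in both collections, "
      f"{len(a_only)} QqTOF-only, {len(b_only)} Orbitrap-only")
# The shared compounds are the positive controls of every cross-library
# benchmark: their spectra must be recoverable from the other instrument's
# library; everything else serves as negative controls.
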