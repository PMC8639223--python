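"""Generate a synthetic Treg-product methylation time course with planted truth.

The design mimics an EPIC-style manufacturing study: 3 donors x 2 production
runs x days 0/10/23, bimodal beta baselines, donor and run batch effects,
20 planted DMRs with early or late kinetics, PMD drift and Treg-DR coupling.
"""

from tregmeth.synthdata import SimDesign, simulate_manifest, simulate_timecourse

design = SimDesign(seed=1)
world = simulate_manifest(design)
matrix, sheet, truth = simulate_timecourse(design, world)

print(f"probes: {matrix.n_probes}, samples: {matrix.n_samples}")
print(f"genes in toy model: {len(world.gene_model.genes)}")
print(f"region sets: {sorted(world.region_sets)}")
print("\nplanted truth (first rows):")
print(truth.head(4).to_string(index=False))
print(
    "\nEach truth row is one planted DMR: its interval, direction "
    "(hyper/hypo), kinetic class and beta effect size at the final day."
)
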