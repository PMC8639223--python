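"""Cross-run shared DMRs and Early/Late kinetic classification.

Shared DMRs are run-1 regions covered >= 50% by same-direction run-2
regions; Early means already significant at day 10 (and still at day 23),
Late means significant only at day 23."""

from tregmeth.evaluation import preprocess_for_contrasts, _run_contrast_dmrs, recovery_design
from tregmeth.kinetics import classify_shared_kinetics, match_shared_dmrs, summarize_shared
from tregmeth.synthdata import simulate_manifest, simulate_timecourse

design = recovery_design(seed=1)
world = simulate_manifest(design)
matrix, sheet, truth = simulate_timecourse(design, world)
m_adj, beta_adj, kept = preprocess_for_contrasts(matrix, sheet, world.manifest)

dmrs = {}
for run in ("R1", "R2"):
    for day in (10, 23):
        _, dmrs[(run, day)] = _run_contrast_dmrs(m_adj, beta_adj, kept, sheet, run, day)

shared, discordant = match_shared_dmrs(dmrs[("R1", 23)], dmrs[("R2", 23)])
shared = classify_shared_kinetics(
    shared, dmrs[("R1", 10)], dmrs[("R1", 23)], dmrs[("R2", 10)], dmrs[("R2", 23)]
)
summary = summarize_shared(shared)
print(f"shared DMRs: {summary['n_shared']} (direction-discordant pairs: {discordant})")
print(summary["by_direction"])
print(summary["by_kinetics"])
print(f"kinetics discordant between runs: {summary['kinetics_discordant_fraction']:.2%}")
print(
    "\nThe planted design has balanced hyper/hypo and early/late classes; the "
    "early/early and late/late cells recover them."
)
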