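"""Proliferation and identity signatures: PMD drift, Treg-DR stability,
and exhaustion-DMR calling from bisulfite counts."""

from scipy import stats

from tregmeth.annotate import intersect_region_sets
from tregmeth.evaluation import tregdr_cohort_design
from tregmeth.signatures import pmd_median_track, stability_table, wgbs_dmps, wgbs_dmrs
from tregmeth.synthdata import SimDesign, simulate_manifest, simulate_timecourse, simulate_wgbs

# PMD drift in the product time course
design = SimDesign(seed=1)
world = simulate_manifest(design)
matrix, sheet, _ = simulate_timecourse(design, world)
core = intersect_region_sets([world.region_sets[k] for k in ("pmd_CM", "pmd_EM", "pmd_TEMRA", "pmd_Treg")])
track = pmd_median_track(matrix.data, core, world.manifest, sheet)
rho = stats.spearmanr(track["median_pmd_beta"], track["log10_expansion"]).statistic
print(f"PMD median beta vs log10 expansion: Spearman rho = {rho:.3f}")

# Treg-DR stability in a FACS-sorted Treg cohort (9 samples)
cohort = tregdr_cohort_design(seed=1)
cworld = simulate_manifest(cohort)
cmatrix, csheet, _ = simulate_timecourse(cohort, cworld)
stab = stability_table(cmatrix.data, cworld.manifest, cworld.region_sets["tregdr"], csheet)
anchors = set(cworld.probe_roles.loc[cworld.probe_roles["anchor"], "probe_id"])
is_anchor = stab["probe_id"].isin(anchors)
print(f"Treg-DR CpGs: {len(stab)}; destabilized (slope>0, R^2>0.4, p<0.05): "
      f"{int(stab['classified_destabilized'].sum())}")
print(f"  anchors (FOXP3-like/TNFRSF1B-like) destabilized: "
      f"{int(stab.loc[is_anchor, 'classified_destabilized'].sum())} of {int(is_anchor.sum())}")

# exhaustion DMRs from WGBS-style counts (60x depth for a clear demonstration)
a, b, truth = simulate_wgbs(2000, 60, [(10, 0.3), (10, -0.3)], seed=3)
exh = wgbs_dmrs(wgbs_dmps(a, b))
print(f"\nWGBS (60x): {len(truth)} planted blocks, {len(exh)} exhDMRs called")
print(
    "\nPMD methylation falls with accumulated divisions; non-anchor Treg-DRs "
    "remethylate with expansion (identity destabilization) while anchors stay flat."
)
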