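"""Call DMPs (moderated t) and DMRs (kernel smoothing + Stouffer) for the
day-23 vs day-0 contrast of one production run, and compare with the truth."""

from tregmeth.evaluation import preprocess_for_contrasts, _run_contrast_dmrs
from tregmeth.evaluation import recovery_design
from tregmeth.synthdata import simulate_manifest, simulate_timecourse

design = recovery_design(seed=1)
world = simulate_manifest(design)
matrix, sheet, truth = simulate_timecourse(design, world)
m_adj, beta_adj, kept = preprocess_for_contrasts(matrix, sheet, world.manifest)

dmps, dmrs = _run_contrast_dmrs(m_adj, beta_adj, kept, sheet, "R1", 23)
print(f"significant DMPs (FDR < 0.05): {int(dmps['significant'].sum())} of {len(dmps)}")
print(f"DMRs (lambda=500, C=3, >=3 CpGs, Stouffer < 0.05): {len(dmrs)}")
print(dmrs.head(4)[["chrom", "start", "end", "n_cpgs", "mean_delta_beta", "direction"]].to_string(index=False))

recovered = 0
for _, reg in truth.iterrows():
    hit = dmrs[(dmrs.chrom == reg.chrom) & (dmrs.start < reg.end) & (dmrs.end > reg.start)]
    recovered += bool(len(hit))
print(f"\nplanted regions recovered: {recovered} / {len(truth)}")
print("Each DMR row is a called region with its mean beta change and direction.")
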