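"""Probe QC, normalization, M values, batch adjustment and PCA.

Prints the filtering report, the batch-mean shift before/after the
empirical-Bayes adjustment, and the leading PCA variance fractions.
"""

import numpy as np

from tregmeth.preprocess import (
    combat_adjust,
    drop_sex_chromosomes,
    filter_probes,
    matrix_to_m,
    pca_scores,
    quantile_normalize,
)
from tregmeth.synthdata import SimDesign, simulate_manifest, simulate_timecourse

design = SimDesign(seed=1)
world = simulate_manifest(design)
matrix, sheet, _ = simulate_timecourse(design, world)

filtered, report = filter_probes(matrix, world.manifest)
filtered = drop_sex_chromosomes(filtered, world.manifest)
print(report.to_string(index=False))

m_mat = matrix_to_m(quantile_normalize(filtered))
runs = sheet.set_index("sample_id").loc[m_mat.sample_ids, "run"]


def batch_gap(mat):
    """Root-mean-square per-probe difference between run means."""
    a = mat.data.loc[:, (runs == "R1").to_numpy()].mean(axis=1)
    b = mat.data.loc[:, (runs == "R2").to_numpy()].mean(axis=1)
    return float(np.sqrt(((b - a) ** 2).mean()))


days = sheet.set_index("sample_id").loc[m_mat.sample_ids, "day"]
cov = np.column_stack([(days == d).to_numpy(float) for d in (10, 23)])
adjusted = combat_adjust(m_mat, runs.to_numpy(), cov)
print(f"\nper-probe RMS run gap on M: before {batch_gap(m_mat):.3f}, after {batch_gap(adjusted):.3f}")

scores, frac = pca_scores(adjusted, 4)
print("PCA variance fractions:", np.round(frac, 3))
print(
    "\nThe planted run batch effect (~0.6 on the M scale) is removed by the "
    "adjustment; the remaining leading components reflect culture day and donor."
)
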