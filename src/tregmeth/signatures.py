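"""Identity and proliferation signatures: PMD drift, Treg-DR stability,
and exhaustion-DMR concordance from bisulfite count data.

The stability model regresses a CpG's beta values on log10 cumulative
expansion rate; a locus is called destabilized when R^2 > 0.4 and the slope
p-value is < 0.05 (log-expansion adjusts for donor-specific differences in
day-to-day proliferation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import probes_in_regions, region_labels_at
from .containers import RegionSet
from .diffmeth import bh_adjust, call_dmrs


# --- PMD drift --------------------------------------------------------------

def pmd_median_track(
    beta: pd.DataFrame,
    pmd_core: RegionSet,
    manifest: pd.DataFrame,
    sample_sheet: pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample median beta over PMD probes, joined with expansion rate."""
    probes = [p for p in probes_in_regions(manifest, pmd_core) if p in beta.index]
    if not probes:
        raise ValueError("no probes fall inside the PMD core set")
    med = beta.loc[probes].median(axis=0)
    sheet = sample_sheet.set_index("sample_id")
    out = pd.DataFrame({"median_pmd_beta": med})
    out = out.join(sheet[["donor", "run", "day", "cumulative_expansion_rate"]])
    out["log10_expansion"] = np.log10(out["cumulative_expansion_rate"])
    return out.reset_index(names="sample_id")


# --- group t-tests ----------------------------------------------------------

def cpg_group_ttest(
    beta: pd.DataFrame,
    probes: list[str],
    group_a: list[str],
    group_b: list[str],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sided two-sample t-test per CpG (pooled variance by default)."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    a = beta.loc[probes, group_a].to_numpy(dtype=float)
    b = beta.loc[probes, group_b].to_numpy(dtype=float)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0) & (a.mean(axis=1) == b.mean(axis=1))
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {
            "probe_id": probes,
            "mean_a": a.mean(axis=1),
            "mean_b": b.mean(axis=1),
            "t": t,
            "p": p,
            "significant": p < 0.05,
        }
    )


# --- stability regression ---------------------------------------------------

@dataclass(frozen=True)
class StabilityResult:
    probe_id: str
    region_label: str
    slope: float          # delta beta per log10 expansion unit
    intercept: float
    r_squared: float
    p: float
    classified_destabilized: bool
    slope_ci_low: float
    slope_ci_high: float


def stability_regression(
    beta_values,
    expansion,
    probe_id: str = "",
    region_label: str = "",
    r2_threshold: float = 0.4,
    p_threshold: float = 0.05,
) -> StabilityResult:
    """OLS of beta on log10(expansion).

    A locus is classified destabilized when it *gains* methylation with
    expansion (slope > 0) with R^2 above threshold and a significant slope;
    expansion-coupled loss is not Treg-identity destabilization.
    """
    y = np.asarray(beta_values, dtype=float)
    exp_rate = np.asarray(expansion, dtype=float)
    if np.any(exp_rate <= 0):
        raise ValueError("expansion rates must be positive")
    x = np.log10(exp_rate)
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct expansion values")
    if np.ptp(y) == 0:  # constant methylation: no relationship by definition
        return StabilityResult(probe_id, region_label, 0.0, float(y[0]), 0.0, 1.0, False, 0.0, 0.0)
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    # 95% CI on the slope
    tcrit = stats.t.ppf(0.975, len(x) - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return StabilityResult(
        probe_id=probe_id,
        region_label=region_label,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        p=float(res.pvalue),
        classified_destabilized=bool(res.slope > 0 and r2 > r2_threshold and res.pvalue < p_threshold),
        slope_ci_low=float(ci[0]),
        slope_ci_high=float(ci[1]),
    )


def stability_table(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    tregdr: RegionSet,
    sample_sheet: pd.DataFrame,
    cell_type: str | None = "Treg",
    r2_threshold: float = 0.4,
) -> pd.DataFrame:
    """Stability regression for every array CpG inside the Treg-DR set."""
    sheet = sample_sheet
    if cell_type is not None and (sheet["cell_type"] == cell_type).any():
        sheet = sheet[sheet["cell_type"] == cell_type]
    samples = [s for s in sheet["sample_id"] if s in beta.columns]
    exp_rate = sheet.set_index("sample_id").loc[samples, "cumulative_expansion_rate"].to_numpy()
    probes = [p for p in probes_in_regions(manifest, tregdr) if p in beta.index]
    labels = region_labels_at(manifest, tregdr)
    rows = []
    for p in probes:
        res = stability_regression(
            beta.loc[p, samples].to_numpy(),
            exp_rate,
            probe_id=p,
            region_label=str(labels.get(p, "")),
            r2_threshold=r2_threshold,
        )
        rows.append(res.__dict__)
    return pd.DataFrame(rows)


# --- chromatin-state cross-tabulation ---------------------------------------

def crosstab_chromatin_states(
    manifest: pd.DataFrame,
    probes: list[str],
    stateset_a: RegionSet,
    stateset_b: RegionSet,
) -> pd.DataFrame:
    """Contingency table of (state in A, state in B) labels per probe."""
    sub = manifest[manifest["probe_id"].isin(set(probes))]
    lab_a = region_labels_at(sub, stateset_a)
    lab_b = region_labels_at(sub, stateset_b)
    return pd.crosstab(lab_a, lab_b, rownames=["state_a"], colnames=["state_b"])


# --- WGBS-style differential methylation ------------------------------------

def wgbs_dmps(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    min_coverage: int = 10,
) -> pd.DataFrame:
    """Per-CpG two-proportion z-test on group-collapsed bisulfite counts.

    CpGs must reach ``min_coverage`` total reads in both groups; the z-test
    uses the pooled proportion; p-values are BH-adjusted.
    """
    key = ["chrom", "start"]
    merged = counts_a.merge(counts_b, on=key, suffixes=("_a", "_b"))
    keep = (merged["total_a"] >= min_coverage) & (merged["total_b"] >= min_coverage)
    merged = merged[keep].reset_index(drop=True)
    if not len(merged):
        raise ValueError(f"no CpG reaches {min_coverage}x coverage in both groups")
    ma, na = merged["methylated_a"].to_numpy(float), merged["total_a"].to_numpy(float)
    mb, nb = merged["methylated_b"].to_numpy(float), merged["total_b"].to_numpy(float)
    pa, pb = ma / na, mb / nb
    pooled = (ma + mb) / (na + nb)
    se = np.sqrt(pooled * (1 - pooled) * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (pa - pb) / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "start": merged["start"],
            "end": merged["end_a"],
            "delta": pa - pb,
            "z": z,
            "p": p,
            "fdr": bh_adjust(p),
            "coverage_a": na.astype(int),
            "coverage_b": nb.astype(int),
        }
    )
    return out


def wgbs_dmrs(
    dmps: pd.DataFrame,
    lambda_: float = 500.0,
    C: float = 3.0,
    min_cpgs: int = 3,
    stouffer_threshold: float = 0.05,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """DMRs from WGBS per-CpG z statistics using the array DMR machinery."""
    stats_df = pd.DataFrame(
        {
            "chrom": dmps["chrom"],
            "pos": dmps["start"] + 1,  # 1-based CpG position
            "probe_id": [
                f"{c}:{s}" for c, s in zip(dmps["chrom"], dmps["start"])
            ],
            "t": dmps["z"],
            "p": dmps["p"],
            "delta_beta": dmps["delta"],
        }
    )
    return call_dmrs(
        stats_df,
        lambda_=lambda_,
        C=C,
        min_cpgs=min_cpgs,
        stouffer_threshold=stouffer_threshold,
        fdr_threshold=fdr_threshold,
    )


# --- exhaustion concordance --------------------------------------------------

def exh_concordance(
    late_shared: pd.DataFrame,
    exhdmrs: pd.DataFrame,
    min_fraction: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Overlap of Late shared DMRs with exhaustion DMRs and direction concordance.

    Each late shared DMR counts as overlapping when an exhDMR covers at
    least ``min_fraction`` of the shared DMR's length (largest single
    contributor).  The summary reports the overlap fraction, per-direction
    concordance fractions and, when a ``feature`` column is present, the
    fraction of concordant-hyper DMRs mapping to promoters.
    """
    rows = []
    exh_by_chrom = dict(tuple(exhdmrs.groupby("chrom"))) if len(exhdmrs) else {}
    for row in late_shared.itertuples():
        cands = exh_by_chrom.get(row.chrom)
        if cands is None:
            continue
        inter = np.minimum(row.end, cands["end"]) - np.maximum(row.start, cands["start"])
        inter = inter.to_numpy()
        if inter.max(initial=0) / (row.end - row.start) < min_fraction:
            continue
        best = cands.iloc[int(np.argmax(inter))]
        shared_delta = getattr(row, "mean_delta", getattr(row, "mean_delta_beta", np.nan))
        rows.append(
            {
                "chrom": row.chrom,
                "start": int(row.start),
                "end": int(row.end),
                "shared_delta": float(shared_delta),
                "exh_delta": float(best.mean_delta_beta),
                "exh_direction": str(best.direction),
                "concordant": bool(np.sign(shared_delta) == np.sign(best.mean_delta_beta)),
                "feature": getattr(row, "feature", None),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "shared_delta", "exh_delta", "exh_direction", "concordant", "feature"],
    )
    n_late = len(late_shared)
    summary: dict = {
        "n_late_shared": n_late,
        "n_overlapping": len(table),
        "overlap_fraction": len(table) / n_late if n_late else 0.0,
    }
    for direction in ("hyper", "hypo"):
        sub = table[table["exh_direction"] == direction]
        summary[f"n_exh_{direction}"] = len(sub)
        summary[f"concordant_{direction}_fraction"] = (
            float(sub["concordant"].mean()) if len(sub) else float("nan")
        )
    conc_hyper = table[(table["exh_direction"] == "hyper") & table["concordant"]]
    if len(conc_hyper) and conc_hyper["feature"].notna().any():
        summary["concordant_hyper_promoter_fraction"] = float(
            (conc_hyper["feature"] == "promoter").mean()
        )
    else:
        summary["concordant_hyper_promoter_fraction"] = float("nan")
    return table, summary
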