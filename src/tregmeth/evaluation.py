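"""Benchmarks of the pipeline against planted synthetic truth.

Each function re-simulates data under the default study conditions, runs the
relevant stage, and measures recovery/calibration quantities.  These power
both the acceptance test suite and ``scripts/acceptance.py``.  Oracles used
for cross-checks (brute-force convolution, per-base bitmaps, closed-form
enumeration) are implemented here, independently of the library code paths
they validate.
"""

from __future__ import annotations

import hashlib
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MethylationMatrix, RegionSet
from .diffmeth import Contrast, bh_adjust, call_dmrs, dmps_to_dmr_input, fit_dmps, smooth_stats, stouffer_combine
from .kinetics import classify_kinetics, match_shared_dmrs
from .preprocess import (
    combat_adjust,
    drop_sex_chromosomes,
    filter_probes,
    matrix_to_beta,
    matrix_to_m,
)
from .signatures import cpg_group_ttest, stability_regression, stability_table, wgbs_dmps, crosstab_chromatin_states
from .annotate import intersect_region_sets, probes_in_regions
from .synthdata import SimDesign, SimWorld, default_planted, simulate_manifest, simulate_timecourse


# --- shared helpers ---------------------------------------------------------

def preprocess_for_contrasts(matrix, sheet, manifest):
    """Filter -> drop sex chromosomes -> M -> batch adjust.

    Quantile normalization is deliberately omitted on synthetic data: the
    generator produces samples that are exchangeable up to the modeled batch
    and donor effects (which the empirical-Bayes adjustment removes), so
    forcing identical per-sample distributions only perturbs the per-probe
    noise structure the calibration benchmarks measure.
    """
    filtered, _ = filter_probes(matrix, manifest)
    filtered = drop_sex_chromosomes(filtered, manifest)
    m_mat = matrix_to_m(filtered)
    meta = sheet.set_index("sample_id").loc[m_mat.sample_ids]
    days = sorted(meta["day"].unique())
    cov = np.column_stack([(meta["day"] == d).to_numpy(float) for d in days[1:]]) if len(days) > 1 else None
    adjusted = combat_adjust(m_mat, meta["run"].to_numpy(), cov)
    kept = manifest[manifest["probe_id"].isin(set(adjusted.probe_ids))].reset_index(drop=True)
    return adjusted, matrix_to_beta(adjusted), kept


def _run_contrast_dmrs(m_adj, beta_adj, kept, sheet, run, day):
    sub = sheet[sheet["run"] == run]
    g_a = list(sub.loc[sub["day"] == day, "sample_id"])
    g_b = list(sub.loc[sub["day"] == 0, "sample_id"])
    contrast = Contrast(f"{run}_d{day}", g_a, g_b, dict(zip(sub["sample_id"], sub["donor"])))
    dmps = fit_dmps(
        m_adj.subset_samples(contrast.samples),
        beta_adj.subset_samples(contrast.samples),
        contrast,
        kept,
    )
    return dmps, call_dmrs(dmps_to_dmr_input(dmps))


def _overlaps(call_row, region) -> bool:
    return (
        call_row["chrom"] == region["chrom"]
        and min(call_row["end"], region["end"]) > max(call_row["start"], region["start"])
    )


def _drift_regions(world: SimWorld) -> pd.DataFrame:
    frames = [
        world.region_sets[k].df for k in world.region_sets if k.startswith("pmd_") or k == "tregdr"
    ]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=["chrom", "start", "end"])


# --- planted-DMR recovery + kinetics ----------------------------------------

def recovery_design(seed: int) -> SimDesign:
    """The planted-DMR benchmark: 10k probes, 20 planted 5-CpG regions of
    delta-beta 0.2, 3 donors x 2 runs x 3 days, and no expansion-coupled
    signature effects (PMD drift and Treg-DR coupling carry genuine
    non-planted differential signal and are benchmarked separately)."""
    return SimDesign(pmd_fraction=0.0, tregdr_count=0, seed=seed)


def evaluate_planted_recovery(n_seeds: int = 25, base_seed: int = 1) -> dict:
    """Recall/precision/direction agreement of DMR calling against planted truth,
    plus per-seed Early/Late kinetic-recovery accuracy."""
    recalls, precisions = [], []
    dir_total = dir_agree = 0
    kin_per_seed = []
    for s in range(n_seeds):
        design = recovery_design(base_seed + s)
        world = simulate_manifest(design)
        matrix, sheet, truth = simulate_timecourse(design, world)
        m_adj, beta_adj, kept = preprocess_for_contrasts(matrix, sheet, world.manifest)
        drift = _drift_regions(world)
        seed_recalls, seed_precisions = [], []
        kin_total = kin_correct = 0
        final_day = design.final_day
        mid_day = design.days[1]
        for run in design.runs:
            _, dmrs_final = _run_contrast_dmrs(m_adj, beta_adj, kept, sheet, run, final_day)
            _, dmrs_mid = _run_contrast_dmrs(m_adj, beta_adj, kept, sheet, run, mid_day)
            hit = np.zeros(len(truth), dtype=bool)
            n_tp = n_considered = 0
            for _, call in dmrs_final.iterrows():
                t_hits = [
                    i for i, (_, reg) in enumerate(truth.iterrows()) if _overlaps(call, reg)
                ]
                in_drift = any(_overlaps(call, reg) for _, reg in drift.iterrows())
                if t_hits:
                    hit[t_hits] = True
                    n_tp += 1
                    n_considered += 1
                    dir_total += 1
                    if call["direction"] == truth.iloc[t_hits[0]]["direction"]:
                        dir_agree += 1
                    kin = classify_kinetics(call, dmrs_mid, dmrs_final)
                    kin_total += 1
                    if kin == truth.iloc[t_hits[0]]["kinetics"]:
                        kin_correct += 1
                elif not in_drift:
                    n_considered += 1
            seed_recalls.append(hit.mean())
            seed_precisions.append(n_tp / n_considered if n_considered else 1.0)
        recalls.append(float(np.mean(seed_recalls)))
        precisions.append(float(np.mean(seed_precisions)))
        kin_per_seed.append(kin_correct / kin_total if kin_total else float("nan"))
    return {
        "recall_per_seed": recalls,
        "precision_per_seed": precisions,
        "recall": float(np.mean(recalls)),
        "precision": float(np.mean(precisions)),
        "direction_agreement": dir_agree / dir_total if dir_total else float("nan"),
        "kinetics_accuracy_per_seed": kin_per_seed,
        "kinetics_accuracy_min": float(np.nanmin(kin_per_seed)),
        "kinetics_accuracy_mean": float(np.nanmean(kin_per_seed)),
        "n_seeds": n_seeds,
    }


# --- null calibration -------------------------------------------------------

def null_design(seed: int) -> SimDesign:
    """No planted effects: no DMRs, no PMD drift, no Treg-DR coupling."""
    return SimDesign(
        n_probes=2000,
        runs=("R1",),
        days=(0, 23),
        planted_dmrs=[],
        pmd_fraction=0.0,
        tregdr_count=0,
        seed=seed,
    )


def evaluate_null_fdr(n_seeds: int = 100, base_seed: int = 2000) -> dict:
    """Per-seed false-discovery proportion of DMPs and DMR yield under the null."""
    fdps, any_dmr = [], []
    for s in range(n_seeds):
        design = null_design(base_seed + s)
        world = simulate_manifest(design)
        matrix, sheet, _ = simulate_timecourse(design, world)
        m_adj, beta_adj, kept = preprocess_for_contrasts(matrix, sheet, world.manifest)
        dmps, dmrs = _run_contrast_dmrs(m_adj, beta_adj, kept, sheet, "R1", 23)
        n_sig = int(dmps["significant"].sum())
        fdps.append(1.0 if n_sig > 0 else 0.0)  # every discovery is false under the null
        any_dmr.append(1.0 if len(dmrs) else 0.0)
    fdps = np.asarray(fdps)
    return {
        "mean_fdp": float(fdps.mean()),
        "fdp_mc_se": float(fdps.std(ddof=1) / math.sqrt(n_seeds)),
        "dmr_seed_fraction": float(np.mean(any_dmr)),
        "n_seeds": n_seeds,
    }


# --- batch-correction recovery ----------------------------------------------

def evaluate_batch_correction(
    n_seeds: int = 50,
    base_seed: int = 3000,
    n_probes: int = 50,
    shift: float = 1.0,
    day_delta: float = 1.0,
    noise_sd: float = 0.3,
) -> dict:
    """Planted additive M-scale batch shift: variance removed, day effect kept."""
    reductions, perturbations = [], []
    n_per_cell = 3  # 2 batches x 2 days x 3 samples
    batch = np.repeat(["A", "B"], 2 * n_per_cell)
    day = np.tile(np.repeat([0, 1], n_per_cell), 2)
    n_samples = len(batch)
    planted = np.arange(10)
    for s in range(n_seeds):
        rng = np.random.default_rng(base_seed + s)
        base = rng.normal(0, 1.5, size=n_probes)
        clean = base[:, None] + rng.normal(0, noise_sd, size=(n_probes, n_samples))
        clean[np.ix_(planted, np.flatnonzero(day == 1))] += day_delta
        batched = clean + shift * (batch == "B")[None, :]
        cols = [f"s{i}" for i in range(n_samples)]
        mat = MethylationMatrix(pd.DataFrame(batched, columns=cols), "M")
        adj = combat_adjust(mat, batch, covariates=day.astype(float))
        adj_x = adj.data.to_numpy()

        def _batch_var(x):
            means = np.column_stack([x[:, batch == b].mean(axis=1) for b in ("A", "B")])
            return means.var(axis=1, ddof=1).mean()

        reductions.append(1.0 - _batch_var(adj_x) / _batch_var(batched))

        def _day_eff(x):
            return x[np.ix_(planted, np.flatnonzero(day == 1))].mean(axis=1) - x[
                np.ix_(planted, np.flatnonzero(day == 0))
            ].mean(axis=1)

        perturbations.append(
            np.abs(_day_eff(adj_x) - _day_eff(clean)).mean() / np.abs(_day_eff(clean)).mean()
        )
    return {
        "variance_reduction": float(np.mean(reductions)),
        "day_effect_perturbation": float(np.mean(perturbations)),
        "n_seeds": n_seeds,
    }


# --- smoothing oracle -------------------------------------------------------

def brute_force_smooth(positions, t_stats, lambda_=500.0, C=3.0):
    """Direct double-loop convolution + Satterthwaite null (independent oracle)."""
    sigma = lambda_ / C
    pos = np.asarray(positions, float)
    t2 = np.asarray(t_stats, float) ** 2
    n = len(pos)
    y = np.zeros(n)
    dfs = np.zeros(n)
    for i in range(n):
        ws = []
        for j in range(n):
            d = abs(pos[i] - pos[j])
            ws.append(math.exp(-(d**2) / (2 * sigma**2)) if d <= lambda_ else 0.0)
        wsum = sum(ws)
        y[i] = sum(w * v for w, v in zip(ws, t2)) / wsum
        dfs[i] = wsum**2 / sum(w**2 for w in ws)
    p = stats.chi2.sf(y * dfs, dfs)
    return y, p


def evaluate_smoothing_oracle(n_instances: int = 1000, seed: int = 6000) -> dict:
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(1, 21))
        pos = np.cumsum(rng.integers(1, 600, size=n)) + 100
        t = rng.normal(0, 2.5, size=n)
        sm = smooth_stats(pos, t)
        y_o, p_o = brute_force_smooth(pos, t)
        max_diff = max(
            max_diff,
            float(np.max(np.abs(sm["smoothed_stat"].to_numpy() - y_o))),
            float(np.max(np.abs(sm["smoothed_p"].to_numpy() - p_o))),
        )
    return {"max_abs_diff": max_diff, "n_instances": n_instances}


# --- interval oracles -------------------------------------------------------

def _random_dmr_frame(rng, n, span=2000):
    rows = []
    for _ in range(n):
        s = int(rng.integers(0, span))
        e = s + int(rng.integers(20, 300))
        rows.append(
            {
                "chrom": "chr1",
                "start": s,
                "end": e,
                "n_cpgs": 3,
                "mean_delta_beta": float(rng.normal()),
                "max_delta_beta": 0.0,
                "stouffer_p": 0.01,
                "direction": str(rng.choice(["hyper", "hypo"])),
                "probes": (),
            }
        )
    return pd.DataFrame(rows).sort_values("start").reset_index(drop=True)


def _brute_shared(run1, run2, min_fraction=0.5):
    out = []
    for _, r1 in run1.iterrows():
        length = r1.end - r1.start
        covered = set()
        best, best_ov = None, 0
        for _, r2 in run2.iterrows():
            lo, hi = max(r1.start, r2.start), min(r1.end, r2.end)
            if hi > lo:
                covered.update(range(lo, hi))
                if hi - lo > best_ov:
                    best, best_ov = r2, hi - lo
        if len(covered) / length >= min_fraction and best is not None:
            if best.direction == r1.direction:
                out.append((int(r1.start), int(r1.end), int(best.start), int(best.end)))
    return sorted(out)


def evaluate_interval_oracles(n_instances: int = 500, seed: int = 7000) -> dict:
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_instances):
        # match_shared_dmrs vs per-pair scan
        r1 = _random_dmr_frame(rng, int(rng.integers(1, 8)))
        r2 = _random_dmr_frame(rng, int(rng.integers(1, 8)))
        shared, _ = match_shared_dmrs(r1, r2)
        got = sorted(
            zip(shared["run1_start"], shared["run1_end"], shared["run2_start"], shared["run2_end"])
        )
        if [tuple(map(int, g)) for g in got] != _brute_shared(r1, r2):
            mismatches += 1

        # intersect_region_sets vs per-base bitmap (<= 10 kb)
        span = 2000
        sets = []
        for _k in range(int(rng.integers(2, 4))):
            rows = []
            for _j in range(int(rng.integers(1, 6))):
                s = int(rng.integers(0, span))
                e = s + int(rng.integers(1, 400))
                rows.append(("chr1", s, e, "."))
            sets.append(RegionSet(f"s{_k}", pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])))
        inter = intersect_region_sets(sets)
        bitmap = np.ones(span + 500, dtype=bool)
        for rs in sets:
            m = np.zeros_like(bitmap)
            for _, row in rs.df.iterrows():
                m[row.start : row.end] = True
            bitmap &= m
        got_b = np.zeros_like(bitmap)
        for _, row in inter.df.iterrows():
            got_b[row.start : row.end] = True
        if not np.array_equal(bitmap, got_b):
            mismatches += 1

        # probes_in_regions vs linear scan
        n_probes = int(rng.integers(5, 30))
        pos = np.sort(rng.choice(np.arange(1, span), size=n_probes, replace=False))
        mani = pd.DataFrame(
            {"probe_id": [f"p{i}" for i in range(n_probes)], "chrom": "chr1", "pos": pos}
        )
        rs = sets[0]
        got_probes = set(probes_in_regions(mani, rs))
        exp_probes = {
            f"p{i}"
            for i in range(n_probes)
            if any(row.start <= pos[i] - 1 < row.end for _, row in rs.df.iterrows())
        }
        if got_probes != exp_probes:
            mismatches += 1

        # crosstab vs per-probe lookup on random partitions
        def _partition(labels):
            cuts = np.sort(rng.choice(np.arange(1, span), size=3, replace=False))
            edges = [0, *cuts, span]
            rows = [
                ("chr1", edges[i], edges[i + 1], str(rng.choice(labels)))
                for i in range(len(edges) - 1)
            ]
            return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])

        part_a = RegionSet("a", _partition(["s1", "s2"]))
        part_b = RegionSet("b", _partition(["t1", "t2"]))
        tab = crosstab_chromatin_states(mani, list(mani["probe_id"]), part_a, part_b)
        exp: dict[tuple[str, str], int] = {}
        for i in range(n_probes):
            pt = pos[i] - 1
            la = next(r.label for _, r in part_a.df.iterrows() if r.start <= pt < r.end)
            lb = next(r.label for _, r in part_b.df.iterrows() if r.start <= pt < r.end)
            exp[(la, lb)] = exp.get((la, lb), 0) + 1
        for (la, lb), cnt in exp.items():
            if tab.loc[la, lb] != cnt:
                mismatches += 1
                break
        if int(tab.to_numpy().sum()) != n_probes:
            mismatches += 1
    return {"mismatches": mismatches, "n_instances": n_instances}


# --- stability regression ---------------------------------------------------

def evaluate_stability_coverage(
    n_seeds: int = 200, base_seed: int = 4000, slope: float = 0.1, noise_sd: float = 0.02, n: int = 9
) -> dict:
    from .synthdata import simulate_stability_series

    covered = 0
    for s in range(n_seeds):
        beta, exp_rate = simulate_stability_series(slope, noise_sd, n, base_seed + s)
        res = stability_regression(beta, exp_rate)
        if res.slope_ci_low <= slope <= res.slope_ci_high:
            covered += 1
    return {"ci_coverage": covered / n_seeds, "n_seeds": n_seeds}


def tregdr_cohort_design(seed: int) -> SimDesign:
    """Nine FACS-sorted Treg samples (3 donors x 3 days) with 33 Treg-DRs."""
    return SimDesign(
        n_probes=600,
        n_chromosomes=3,
        runs=("R1",),
        cell_types=("Treg",),
        planted_dmrs=[],
        pmd_fraction=0.0,
        tregdr_count=33,
        batch_shift=0.0,
        seed=seed,
    )


def evaluate_tregdr_classification(n_seeds: int = 40, base_seed: int = 5000) -> dict:
    """Anchor loci stay stable; expansion-coupled Treg-DR loci destabilize."""
    anchor_stable = anchor_total = coupled_dest = coupled_total = 0
    for s in range(n_seeds):
        design = tregdr_cohort_design(base_seed + s)
        world = simulate_manifest(design)
        matrix, sheet, _ = simulate_timecourse(design, world)
        stab = stability_table(
            matrix.data, world.manifest, world.region_sets["tregdr"], sheet, cell_type="Treg"
        )
        anchors = world.probe_roles.loc[world.probe_roles["anchor"], "probe_id"]
        is_anchor = stab["probe_id"].isin(set(anchors))
        anchor_total += int(is_anchor.sum())
        anchor_stable += int((~stab.loc[is_anchor, "classified_destabilized"]).sum())
        coupled = stab[(stab["region_label"] != "unannotated") & ~is_anchor]
        coupled_total += len(coupled)
        coupled_dest += int(coupled["classified_destabilized"].sum())
    return {
        "anchor_stable_fraction": anchor_stable / anchor_total,
        "coupled_destabilized_fraction": coupled_dest / coupled_total,
        "n_seeds": n_seeds,
    }


# --- closed-form statistics -------------------------------------------------

def evaluate_closed_forms() -> dict:
    """Worked examples vs independent closed-form/enumeration oracles."""
    errs = []

    # BH step-up, hand rule: q_i = min_{j>=i} m p_(j) / j
    p = np.array([0.01, 0.02, 0.03, 0.04])
    order = np.argsort(p)
    m = len(p)
    raw = m * p[order] / np.arange(1, m + 1)
    expected = np.minimum.accumulate(raw[::-1])[::-1]
    errs.append(np.max(np.abs(bh_adjust(p) - expected[np.argsort(order)])))
    errs.append(np.max(np.abs(bh_adjust(p) - 0.04)))

    # Stouffer: two aligned one-sided p = 0.025 (z = 1.96 each)
    z, sp = stouffer_combine([0.025, 0.025], [1, 1], two_sided=False)
    z_exp = 2 * stats.norm.isf(0.025) / math.sqrt(2)
    errs.append(abs(z - z_exp))
    errs.append(abs(sp - stats.norm.sf(z_exp)))
    _, sp_half = stouffer_combine([0.5, 0.5, 0.5], [1, 1, 1], two_sided=False)
    errs.append(abs(sp_half - 0.5))

    # hypergeometric: N=20, K=5, n=5, k=3 vs explicit sum
    from math import comb

    from .enrichment import ora_hypergeometric

    universe = [f"g{i}" for i in range(20)]
    term = {"T": universe[:5]}
    query = universe[:3] + universe[5:7]  # overlap k = 3
    res = ora_hypergeometric(query, universe, term)
    p_exp = sum(comb(5, i) * comb(15, 5 - i) for i in (3, 4, 5)) / comb(20, 5)
    errs.append(abs(res.loc[0, "p"] - p_exp))

    # pooled-variance t-test vs hand formula
    a, b = np.array([0.1, 0.2, 0.15]), np.array([0.8, 0.85, 0.9])
    beta = pd.DataFrame([np.concatenate([a, b])], index=["cg1"], columns=list("abcdef"))
    tt = cpg_group_ttest(beta, ["cg1"], list("abc"), list("def"))
    sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
    t_exp = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
    errs.append(abs(tt.loc[0, "t"] - t_exp))
    errs.append(abs(tt.loc[0, "p"] - 2 * stats.t.sf(abs(t_exp), 4)))

    # two-proportion z: equal proportions -> z = 0, p = 1
    ca = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [102], "methylated": [50], "total": [100]})
    cb = ca.copy()
    res_w = wgbs_dmps(ca, cb, min_coverage=10)
    errs.append(abs(res_w.loc[0, "z"]))
    errs.append(abs(res_w.loc[0, "p"] - 1.0))

    # small-count z-test p vs exact binomial enumeration under the pooled null
    ma, na, mb, nb = 18, 30, 8, 30
    ca = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [102], "methylated": [ma], "total": [na]})
    cb = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [102], "methylated": [mb], "total": [nb]})
    p_z = float(wgbs_dmps(ca, cb, min_coverage=10).loc[0, "p"])
    p0 = (ma + mb) / (na + nb)
    obs = abs(ma / na - mb / nb)
    pa = stats.binom.pmf(np.arange(na + 1), na, p0)
    pb = stats.binom.pmf(np.arange(nb + 1), nb, p0)
    diff = np.abs(np.arange(na + 1)[:, None] / na - np.arange(nb + 1)[None, :] / nb)
    p_exact = float((pa[:, None] * pb[None, :])[diff >= obs - 1e-12].sum())
    return {
        "max_error_exact": float(np.max(errs)),
        "wgbs_enumeration_abs_diff": abs(p_z - p_exact),
    }


# --- end-to-end determinism -------------------------------------------------

def small_pipeline_design(seed: int) -> SimDesign:
    return SimDesign(
        n_probes=1500,
        n_chromosomes=3,
        planted_dmrs=default_planted(6),
        tregdr_count=12,
        seed=seed,
    )


def _tree_digest(root: Path) -> dict[str, str]:
    out = {}
    for p in sorted(root.rglob("*")):
        if p.is_file():
            out[str(p.relative_to(root))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def evaluate_pipeline_determinism(workdir, seed: int = 11) -> dict:
    """Run the full pipeline twice from one dataset; compare result trees byte-wise."""
    from .pipeline import PipelineConfig, run_pipeline
    from .synthdata import simulate_wgbs, write_dataset

    workdir = Path(workdir)
    design = small_pipeline_design(seed)
    world = simulate_manifest(design)
    matrix, sheet, truth = simulate_timecourse(design, world)
    wgbs = simulate_wgbs(800, 30.0, [(8, 0.3), (8, -0.3)], seed=seed + 1)
    cfg_dict = write_dataset(world, matrix, sheet, truth, workdir / "data", wgbs=wgbs)
    digests = []
    for rep in ("run1", "run2"):
        cfg = PipelineConfig(**{**cfg_dict, "out_dir": str(workdir / rep)})
        run_pipeline(cfg)
        digests.append(_tree_digest(workdir / rep))
    return {
        "identical": digests[0] == digests[1],
        "n_files": len(digests[0]),
    }
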