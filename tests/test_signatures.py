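"""PMD drift, group t-tests, stability regression, WGBS differential methylation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tregmeth.annotate import intersect_region_sets, probes_in_regions
from tregmeth.containers import RegionSet
from tregmeth.signatures import (
    cpg_group_ttest,
    crosstab_chromatin_states,
    exh_concordance,
    pmd_median_track,
    stability_regression,
    stability_table,
    wgbs_dmps,
    wgbs_dmrs,
)
from tregmeth.synthdata import SimDesign, simulate_manifest, simulate_timecourse, simulate_wgbs


# --- PMD ---------------------------------------------------------------------

def test_pmd_median_constant_and_perturbation_invariance(small_world, small_dataset):
    matrix, sheet, _ = small_dataset
    pmd_core = intersect_region_sets(
        [small_world.region_sets[k] for k in ("pmd_CM", "pmd_EM", "pmd_TEMRA", "pmd_Treg")]
    )
    beta = matrix.data.copy()
    pmd_probes = set(probes_in_regions(small_world.manifest, pmd_core))
    assert pmd_probes
    beta.loc[beta.index.isin(pmd_probes), :] = 0.6
    track = pmd_median_track(beta, pmd_core, small_world.manifest, sheet)
    assert np.allclose(track["median_pmd_beta"], 0.6)
    # perturbing non-PMD probes does not move the PMD median
    beta2 = beta.copy()
    beta2.loc[~beta2.index.isin(pmd_probes), :] = 0.99
    track2 = pmd_median_track(beta2, pmd_core, small_world.manifest, sheet)
    np.testing.assert_allclose(track["median_pmd_beta"], track2["median_pmd_beta"])


def test_pmd_median_tracks_expansion(small_world, small_dataset):
    matrix, sheet, _ = small_dataset
    pmd_core = intersect_region_sets(
        [small_world.region_sets[k] for k in ("pmd_CM", "pmd_EM", "pmd_TEMRA", "pmd_Treg")]
    )
    track = pmd_median_track(matrix.data, pmd_core, small_world.manifest, sheet)
    rho = stats.spearmanr(track["median_pmd_beta"], track["log10_expansion"]).statistic
    assert rho <= -0.9


def test_pmd_median_empty_set_rejected(small_world, small_dataset):
    matrix, sheet, _ = small_dataset
    empty = RegionSet("none", pd.DataFrame([("chr1", 1, 2, ".")],
                                           columns=["chrom", "start", "end", "label"]))
    with pytest.raises(ValueError, match="no probes"):
        pmd_median_track(matrix.data, empty, small_world.manifest, sheet)


# --- t-tests -----------------------------------------------------------------

def test_ttest_identical_groups_degenerate():
    beta = pd.DataFrame([[0.4, 0.4, 0.4, 0.4]], index=["cg1"], columns=list("abcd"))
    res = cpg_group_ttest(beta, ["cg1"], ["a", "b"], ["c", "d"])
    assert res.loc[0, "t"] == 0.0 and res.loc[0, "p"] == 1.0


def test_ttest_matches_pooled_formula_and_swap():
    a = np.array([0.1, 0.2, 0.15])
    b = np.array([0.8, 0.85, 0.9])
    beta = pd.DataFrame([np.r_[a, b]], index=["cg1"], columns=list("abcdef"))
    res = cpg_group_ttest(beta, ["cg1"], list("abc"), list("def"))
    sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
    t_exp = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
    assert res.loc[0, "t"] == pytest.approx(t_exp)
    swapped = cpg_group_ttest(beta, ["cg1"], list("def"), list("abc"))
    assert swapped.loc[0, "t"] == pytest.approx(-t_exp)
    assert swapped.loc[0, "p"] == pytest.approx(res.loc[0, "p"])


def test_ttest_requires_group_sizes():
    beta = pd.DataFrame([[0.1, 0.2, 0.3]], index=["cg1"], columns=list("abc"))
    with pytest.raises(ValueError):
        cpg_group_ttest(beta, ["cg1"], ["a"], ["b", "c"])


# --- stability regression ----------------------------------------------------

def test_stability_exact_linear_gain():
    x = np.array([1, 10, 100, 1000, 10_000], dtype=float)
    beta = 0.1 + 0.05 * np.log10(x)
    res = stability_regression(beta, x)
    assert res.r_squared == pytest.approx(1.0)
    assert res.slope == pytest.approx(0.05)
    assert res.classified_destabilized


def test_stability_constant_beta_not_destabilized():
    x = np.array([1, 10, 100, 1000], dtype=float)
    res = stability_regression(np.full(4, 0.3), x)
    assert res.slope == pytest.approx(0.0)
    assert res.r_squared == pytest.approx(0.0, abs=1e-12)
    assert not res.classified_destabilized


def test_stability_loss_is_not_destabilization():
    x = np.array([1, 10, 100, 1000], dtype=float)
    res = stability_regression(0.9 - 0.1 * np.log10(x), x)
    assert res.r_squared == pytest.approx(1.0)
    assert not res.classified_destabilized  # losing methylation is not remethylation


def test_stability_constant_expansion_rejected():
    with pytest.raises(ValueError):
        stability_regression([0.1, 0.2, 0.3], [10.0, 10.0, 10.0])


def test_stability_r2_equals_squared_pearson():
    rng = np.random.default_rng(0)
    x = 10 ** rng.uniform(0, 3, size=12)
    y = 0.2 + 0.1 * np.log10(x) + rng.normal(0, 0.05, 12)
    res = stability_regression(y, x)
    r = np.corrcoef(np.log10(x), y)[0, 1]
    assert res.r_squared == pytest.approx(r**2)


def test_stability_table_on_treg_cohort():
    design = SimDesign(
        n_probes=600, n_chromosomes=3, runs=("R1",), cell_types=("Treg",),
        planted_dmrs=[], pmd_fraction=0.0, tregdr_count=20, batch_shift=0.0, seed=21,
    )
    world = simulate_manifest(design)
    matrix, sheet, _ = simulate_timecourse(design, world)
    stab = stability_table(matrix.data, world.manifest, world.region_sets["tregdr"], sheet)
    assert len(stab) > 0
    anchors = set(world.probe_roles.loc[world.probe_roles["anchor"], "probe_id"])
    coupled = stab[~stab["probe_id"].isin(anchors)]
    assert coupled["classified_destabilized"].mean() > 0.8
    assert (coupled["slope"].mean()) == pytest.approx(0.15, abs=0.05)


# --- chromatin-state crosstab ------------------------------------------------

def test_crosstab_identical_sets_is_diagonal(small_world):
    states = small_world.region_sets["states_treg"]
    probes = list(small_world.manifest["probe_id"][:200])
    tab = crosstab_chromatin_states(small_world.manifest, probes, states, states)
    assert int(tab.to_numpy().sum()) == 200
    off_diag = tab.to_numpy().sum() - np.trace(
        tab.reindex(index=tab.columns, columns=tab.columns).fillna(0).to_numpy()
    )
    assert off_diag == 0


# --- WGBS --------------------------------------------------------------------

def test_wgbs_coverage_filter():
    a = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [100, 200], "end": [102, 202],
                      "methylated": [5, 9], "total": [9, 20]})
    b = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [100, 200], "end": [102, 202],
                      "methylated": [5, 3], "total": [20, 20]})
    res = wgbs_dmps(a, b, min_coverage=10)
    assert list(res["start"]) == [200]  # the 9x CpG is excluded
    with pytest.raises(ValueError, match="coverage"):
        wgbs_dmps(a.assign(total=5), b, min_coverage=10)


def test_wgbs_equal_proportions_give_null():
    a = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [102],
                      "methylated": [50], "total": [100]})
    res = wgbs_dmps(a, a.copy())
    assert res.loc[0, "z"] == 0.0 and res.loc[0, "p"] == 1.0


def test_wgbs_group_swap_flips_sign():
    a, b, _ = simulate_wgbs(300, 30, [(8, 0.3)], seed=5)
    r1 = wgbs_dmps(a, b)
    r2 = wgbs_dmps(b, a)
    np.testing.assert_allclose(r1["z"], -r2["z"], atol=1e-12)
    np.testing.assert_allclose(r1["delta"], -r2["delta"], atol=1e-12)
    np.testing.assert_allclose(r1["p"], r2["p"], atol=1e-12)


def test_wgbs_planted_block_detected_with_direction():
    """Planted 10-CpG blocks (delta 0.3, 30x) are recovered with the correct
    direction; per-CpG power at this depth (z ~ 2.4) makes block detection
    partial, so the rate bound is set below the measured ~65%."""
    detected = total = 0
    for seed in range(15):
        a, b, truth = simulate_wgbs(1500, 30, [(10, 0.3), (10, -0.3)], seed=50 + seed)
        dmrs = wgbs_dmrs(wgbs_dmps(a, b))
        for _, reg in truth.iterrows():
            total += 1
            hits = dmrs[(dmrs["start"] < reg.end) & (dmrs["end"] > reg.start)]
            if len(hits):
                detected += 1
                expected_dir = "hyper" if reg.delta > 0 else "hypo"
                assert (hits["direction"] == expected_dir).all()
    assert detected >= 0.4 * total


def test_wgbs_two_cpg_block_not_reported():
    a, b, truth = simulate_wgbs(800, 40, [(2, 0.4)], seed=31)
    dmrs = wgbs_dmrs(wgbs_dmps(a, b))
    for _, reg in truth.iterrows():
        hits = dmrs[(dmrs["start"] < reg.end) & (dmrs["end"] > reg.start)]
        assert hits.empty


def test_wgbs_null_rarely_yields_regions():
    n_with = 0
    for seed in range(60):
        a, b, _ = simulate_wgbs(800, 30, None, seed=600 + seed)
        if len(wgbs_dmrs(wgbs_dmps(a, b))):
            n_with += 1
    assert n_with <= 6


# --- exhaustion concordance --------------------------------------------------

def _late(chrom, start, end, delta, feature="promoter"):
    return {
        "chrom": chrom, "start": start, "end": end, "mean_delta": delta,
        "direction": "hyper" if delta > 0 else "hypo", "feature": feature,
    }


def _exh(chrom, start, end, delta):
    return {
        "chrom": chrom, "start": start, "end": end, "n_cpgs": 5,
        "mean_delta_beta": delta, "max_delta_beta": delta, "stouffer_p": 1e-5,
        "direction": "hyper" if delta > 0 else "hypo", "probes": (),
    }


def test_exh_concordance_no_overlap():
    late = pd.DataFrame([_late("chr1", 0, 100, 0.2)])
    exh = pd.DataFrame([_exh("chr2", 0, 100, 0.2)])
    _, summary = exh_concordance(late, exh)
    assert summary["overlap_fraction"] == 0.0


def test_exh_concordance_full_agreement():
    late = pd.DataFrame([_late("chr1", 0, 100, 0.2), _late("chr1", 1000, 1100, -0.2)])
    exh = pd.DataFrame([_exh("chr1", 0, 100, 0.3), _exh("chr1", 990, 1120, -0.25)])
    table, summary = exh_concordance(late, exh)
    assert summary["overlap_fraction"] == 1.0
    assert summary["concordant_hyper_fraction"] == 1.0
    assert summary["concordant_hypo_fraction"] == 1.0
    assert summary["concordant_hyper_promoter_fraction"] == 1.0
    assert summary["n_exh_hyper"] + summary["n_exh_hypo"] == len(table)


def test_exh_concordance_planted_rate_recovered():
    rng = np.random.default_rng(2)
    late_rows, exh_rows = [], []
    n, p_conc = 200, 0.7
    concordant_truth = rng.random(n) < p_conc
    for i in range(n):
        start = i * 10_000
        late_rows.append(_late("chr1", start, start + 500, 0.2))
        exh_delta = 0.3 if concordant_truth[i] else -0.3
        exh_rows.append(_exh("chr1", start - 100, start + 600, exh_delta))
    table, summary = exh_concordance(pd.DataFrame(late_rows), pd.DataFrame(exh_rows))
    assert summary["overlap_fraction"] == 1.0
    observed = table["concordant"].mean()
    assert abs(observed - concordant_truth.mean()) < 1e-12
    assert abs(observed - p_conc) < 4 * np.sqrt(p_conc * (1 - p_conc) / n)
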