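"""Moderated t, BH, Stouffer, kernel smoothing and region calling."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tregmeth.containers import MethylationMatrix
from tregmeth.diffmeth import (
    Contrast,
    bh_adjust,
    call_dmrs,
    fit_dmps,
    smooth_stats,
    stouffer_combine,
)
from tregmeth.evaluation import brute_force_smooth
from tregmeth.preprocess import m_to_beta


def _pair(x, samples=None):
    x = np.asarray(x, dtype=float)
    samples = samples or [f"s{j}" for j in range(x.shape[1])]
    probes = [f"cg{i}" for i in range(x.shape[0])]
    m = MethylationMatrix(pd.DataFrame(x, index=probes, columns=samples), "M")
    b = MethylationMatrix(pd.DataFrame(m_to_beta(x), index=probes, columns=samples), "beta")
    return m, b


# --- BH ----------------------------------------------------------------------

def test_bh_step_up_hand_example():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    assert bh_adjust([0.3])[0] == pytest.approx(0.3)
    p = np.random.default_rng(0).random(100)
    q = bh_adjust(p)
    assert (q >= p - 1e-12).all()
    with pytest.raises(ValueError):
        bh_adjust([1.2])


# --- Stouffer ----------------------------------------------------------------

def test_stouffer_worked_examples():
    z, p = stouffer_combine([0.025, 0.025], [1, 1], two_sided=False)
    assert z == pytest.approx(2.772, abs=1e-3)
    assert p == pytest.approx(0.0028, abs=2e-4)
    _, p_single = stouffer_combine([0.07], [1], two_sided=False)
    assert p_single == pytest.approx(0.07)
    z0, p0 = stouffer_combine([0.5, 0.5, 0.5], [1, 1, 1], two_sided=False)
    assert z0 == pytest.approx(0.0, abs=1e-12)
    assert p0 == pytest.approx(0.5)
    with pytest.raises(ValueError):
        stouffer_combine([], [])


def test_stouffer_two_sided_alignment():
    # a two-sided p of 0.05 aligned with the region direction is z = +1.96
    z, _ = stouffer_combine([0.05], [1], two_sided=True)
    assert z == pytest.approx(stats.norm.isf(0.025), abs=1e-6)
    z_anti, _ = stouffer_combine([0.05], [-1], two_sided=True)
    assert z_anti == pytest.approx(-z)


# --- moderated t -------------------------------------------------------------

def test_fit_dmps_null_probe_and_constant_probe():
    x = np.array(
        [
            [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],  # equal group means, variance > 0
            [0.5] * 6,                        # constant probe
            [0.1, 0.3, 0.2, 1.4, 1.2, 1.6],  # shifted probe
        ]
    )
    m, b = _pair(x)
    contrast = Contrast("c", ["s0", "s1", "s2"], ["s3", "s4", "s5"])
    res = fit_dmps(m, b, contrast)
    assert res.loc[0, "t_mod"] == pytest.approx(0.0, abs=1e-10)
    assert not res.loc[0, "significant"]
    assert res.loc[1, "t_mod"] == 0.0 and res.loc[1, "p"] == 1.0
    assert res.loc[2, "t_mod"] < 0  # group A (first three) minus group B


def test_fit_dmps_swap_groups_negates_statistics():
    rng = np.random.default_rng(5)
    m, b = _pair(rng.normal(size=(30, 8)))
    g1, g2 = [f"s{j}" for j in range(4)], [f"s{j}" for j in range(4, 8)]
    r1 = fit_dmps(m, b, Contrast("a", g1, g2))
    r2 = fit_dmps(m, b, Contrast("b", g2, g1))
    np.testing.assert_allclose(r1["t_mod"], -r2["t_mod"], atol=1e-10)
    np.testing.assert_allclose(r1["delta_beta"], -r2["delta_beta"], atol=1e-12)
    np.testing.assert_allclose(r1["p"], r2["p"], atol=1e-12)


def test_fit_dmps_invariant_to_sample_order():
    rng = np.random.default_rng(6)
    x = rng.normal(size=(20, 6))
    m, b = _pair(x)
    perm = ["s3", "s0", "s5", "s1", "s4", "s2"]
    m2 = MethylationMatrix(m.data[perm], "M")
    b2 = MethylationMatrix(b.data[perm], "beta")
    c = Contrast("c", ["s0", "s1", "s2"], ["s3", "s4", "s5"])
    np.testing.assert_allclose(
        fit_dmps(m, b, c)["t_mod"], fit_dmps(m2, b2, c)["t_mod"], atol=1e-10
    )


def test_fit_dmps_homoskedastic_limit_matches_pooled_z():
    """When all residual variances are equal the prior df is infinite and the
    moderated t equals the effect over the pooled-variance standard error."""
    rng = np.random.default_rng(7)
    base = rng.normal(size=6)
    x = np.array([base * 1.0 + i for i in range(40)])  # identical residuals per probe
    m, b = _pair(x)
    c = Contrast("c", ["s0", "s1", "s2"], ["s3", "s4", "s5"])
    res = fit_dmps(m, b, c)
    # pooled residual variance is the common per-probe variance
    grp = np.array([1.0, 1, 1, 0, 0, 0])
    design = np.column_stack([np.ones(6), grp])
    h = design @ np.linalg.inv(design.T @ design) @ design.T
    resid = base - h @ base
    s2 = (resid**2).sum() / 4
    # infinite prior df: the prior variance is the bias-corrected estimate of
    # sigma^2 from the log residual variance, E[log s^2] = log sigma^2 +
    # digamma(d/2) - log(d/2) with d = 4 residual df
    from scipy.special import digamma

    s0_sq = np.exp(np.log(s2) - digamma(2.0) + np.log(2.0))
    coef = base[:3].mean() - base[3:].mean()
    t_exp = coef / np.sqrt(s0_sq * (1 / 3 + 1 / 3))
    np.testing.assert_allclose(res["t_mod"], t_exp, rtol=1e-6)


def test_fit_dmps_null_fdp_controlled():
    """BH at 0.05 on pure-noise probes keeps the mean false-positive proportion
    at or below the nominal level."""
    rng = np.random.default_rng(8)
    fdps = []
    for _ in range(100):
        m, b = _pair(rng.normal(size=(1000, 6)))
        res = fit_dmps(m, b, Contrast("c", ["s0", "s1", "s2"], ["s3", "s4", "s5"]))
        n_sig = int(res["significant"].sum())
        fdps.append(1.0 if n_sig else 0.0)
    se = np.std(fdps, ddof=1) / np.sqrt(len(fdps)) if np.std(fdps) > 0 else 0.0
    assert np.mean(fdps) <= 0.05 + 2 * se + 1e-9


def test_fit_dmps_matches_reference_implementation(tmp_path):
    """Parity of the moderated t with the R reference (limma lmFit + eBayes)."""
    rng = np.random.default_rng(11)
    x = rng.normal(size=(60, 8)) * rng.uniform(0.5, 2.0, size=(60, 1))
    x[:10, :4] += 1.0
    m, b = _pair(x)
    c = Contrast("c", [f"s{j}" for j in range(4)], [f"s{j}" for j in range(4, 8)])
    ours = fit_dmps(m, b, c)

    dat = tmp_path / "dat.tsv"
    pd.DataFrame(x).to_csv(dat, sep="\t", index=False)
    script = tmp_path / "limma.R"
    script.write_text(
        textwrap.dedent(
            f"""
            suppressMessages(library(limma))
            dat <- as.matrix(read.table("{dat}", sep="\\t", header=TRUE))
            group <- c(rep(1, 4), rep(0, 4))
            design <- cbind(Intercept=1, Group=group)
            fit <- eBayes(lmFit(dat, design))
            out <- data.frame(t=fit$t[, "Group"], p=fit$p.value[, "Group"])
            write.table(out, "{tmp_path / 'out.tsv'}", sep="\\t", row.names=FALSE)
            """
        )
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    theirs = pd.read_csv(tmp_path / "out.tsv", sep="\t")
    np.testing.assert_allclose(ours["t_mod"], theirs["t"], rtol=1e-5, atol=1e-8)
    np.testing.assert_allclose(ours["p"], theirs["p"], rtol=1e-5, atol=1e-12)


# --- kernel smoothing --------------------------------------------------------

def test_smooth_isolated_cpg_is_chi2_1():
    res = smooth_stats(np.array([1000]), np.array([2.0]))
    assert res.loc[0, "smoothed_stat"] == pytest.approx(4.0)
    assert res.loc[0, "df"] == pytest.approx(1.0)
    assert res.loc[0, "smoothed_p"] == pytest.approx(stats.chi2.sf(4.0, 1))


def test_smooth_coincident_cpgs_share_equal_weights():
    res = smooth_stats(np.array([500, 500]), np.array([1.0, np.sqrt(3.0)]))
    np.testing.assert_allclose(res["smoothed_stat"], [2.0, 2.0])


def test_smooth_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(9)
    for _ in range(150):
        n = int(rng.integers(1, 21))
        pos = np.cumsum(rng.integers(1, 600, size=n)) + 10
        t = rng.normal(0, 3, size=n)
        res = smooth_stats(pos, t)
        y, p = brute_force_smooth(pos, t)
        np.testing.assert_allclose(res["smoothed_stat"], y, atol=1e-9)
        np.testing.assert_allclose(res["smoothed_p"], p, atol=1e-9)


def test_smooth_rejects_unsorted_positions():
    with pytest.raises(ValueError, match="sorted"):
        smooth_stats(np.array([300, 100]), np.array([1.0, 1.0]))


# --- region calling ----------------------------------------------------------

def _stats_frame(positions, t, delta, chrom="chr1"):
    t = np.asarray(t, float)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "probe_id": [f"cg{i}" for i in range(len(positions))],
            "t": t,
            "p": 2 * stats.norm.sf(np.abs(t)),
            "delta_beta": delta,
        }
    )


def test_call_dmrs_basic_region():
    df = _stats_frame([100, 200, 300, 400, 500], [6, 7, 6.5, 7, 6], [0.2] * 5)
    # pad with null CpGs far away so BH has a realistic mix
    null = _stats_frame(np.arange(10_000, 13_000, 100), np.full(30, 0.1), np.zeros(30))
    null["probe_id"] = [f"n{i}" for i in range(30)]
    dmrs = call_dmrs(pd.concat([df, null], ignore_index=True))
    assert len(dmrs) == 1
    row = dmrs.iloc[0]
    assert row.n_cpgs == 5 and row.direction == "hyper"
    assert row.start == 99 and row.end == 500


def test_call_dmrs_requires_min_cpgs():
    df = _stats_frame([100, 200], [8, 8], [0.2, 0.2])
    assert len(call_dmrs(df)) == 0


def test_call_dmrs_splits_mixed_direction_runs():
    pos = [100, 200, 300, 400, 500, 600]
    df = _stats_frame(pos, [7, 7, 7, 7, 7, 7], [0.2, 0.25, 0.2, -0.2, -0.25, -0.2])
    dmrs = call_dmrs(df)
    assert len(dmrs) == 2
    assert set(dmrs["direction"]) == {"hyper", "hypo"}


def test_call_dmrs_gap_larger_than_lambda_breaks_region():
    pos = [100, 200, 300, 1000, 1100, 1200]
    df = _stats_frame(pos, [7] * 6, [0.2] * 6)
    dmrs = call_dmrs(df)
    assert len(dmrs) == 2
    assert list(dmrs["n_cpgs"]) == [3, 3]
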