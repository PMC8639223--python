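"""Probe filtering, normalization, beta/M transforms, batch adjustment, PCA."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from tregmeth.containers import MethylationMatrix
from tregmeth.preprocess import (
    beta_to_m,
    combat_adjust,
    drop_sex_chromosomes,
    filter_probes,
    m_to_beta,
    matrix_to_m,
    pca_scores,
    quantile_normalize,
)


def _matrix(beta, detp=None, probes=None, samples=None, scale="beta"):
    probes = probes or [f"cg{i}" for i in range(len(beta))]
    samples = samples or [f"s{j}" for j in range(len(beta[0]))]
    data = pd.DataFrame(beta, index=probes, columns=samples)
    dp = pd.DataFrame(detp, index=probes, columns=samples) if detp is not None else None
    return MethylationMatrix(data, scale, dp)


@pytest.fixture
def qc_matrix():
    beta = np.full((6, 3), 0.5)
    detp = np.full((6, 3), 0.001)
    detp[1, 2] = 0.06  # fails detection in one sample
    m = _matrix(beta.tolist(), detp.tolist())
    manifest = pd.DataFrame(
        {
            "probe_id": m.probe_ids,
            "chrom": ["chr1"] * 6,
            "pos": [100, 200, 300, 400, 500, 600],
            "snp_distance": [np.nan, np.nan, 3, 4, np.nan, np.nan],
            "cross_reactive": [False, False, False, False, True, False],
            "dropped_by_vendor": [False] * 6,
        }
    )
    return m, manifest


def test_filter_probes_reasons(qc_matrix):
    m, manifest = qc_matrix
    out, report = filter_probes(m, manifest)
    kept = set(out.probe_ids)
    assert "cg1" not in kept  # detection p 0.06 >= 0.05 in one sample
    assert "cg2" not in kept  # snp_distance == 3 (within window)
    assert "cg3" in kept      # snp_distance == 4 (outside window)
    assert "cg4" not in kept  # cross-reactive
    rep = dict(zip(report["reason"], report["count"]))
    assert rep["detection_p"] == 1 and rep["snp_proximal"] == 1 and rep["cross_reactive"] == 1
    assert rep["kept"] == 3


def test_filter_probes_clean_identity_and_idempotence(qc_matrix):
    m, manifest = qc_matrix
    clean = manifest.copy()
    clean["snp_distance"] = np.nan
    clean["cross_reactive"] = False
    detp = pd.DataFrame(0.001, index=m.data.index, columns=m.data.columns)
    m2 = MethylationMatrix(m.data, "beta", detp)
    out, _ = filter_probes(m2, clean)
    assert list(out.probe_ids) == list(m2.probe_ids)
    once, _ = filter_probes(m, manifest)
    twice, _ = filter_probes(once, manifest)
    assert list(once.probe_ids) == list(twice.probe_ids)


def test_filter_all_removed_names_dominant_reason(qc_matrix):
    m, manifest = qc_matrix
    bad = manifest.copy()
    bad["cross_reactive"] = True
    with pytest.raises(ValueError, match="cross_reactive"):
        filter_probes(m, bad)


def test_drop_sex_chromosomes_counts_and_label_normalization():
    n = 100
    chroms = ["chr1"] * 85 + ["X"] * 5 + ["chrX"] * 5 + ["chrY"] * 5
    m = _matrix(np.full((n, 2), 0.5).tolist())
    manifest = pd.DataFrame({"probe_id": m.probe_ids, "chrom": chroms, "pos": range(1, n + 1)})
    out = drop_sex_chromosomes(m, manifest)
    assert out.n_probes == 85
    autosomal = drop_sex_chromosomes(out, manifest)
    assert list(autosomal.probe_ids) == list(out.probe_ids)


def test_quantile_normalize_hand_example():
    m = _matrix([[1, 4], [2, 5], [3, 6]], scale="M")
    out = quantile_normalize(m)
    expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
    np.testing.assert_allclose(out.data.to_numpy(), expected)


def test_quantile_normalize_identical_samples_unchanged():
    m = _matrix([[0.1, 0.1], [0.5, 0.5], [0.9, 0.9]])
    out = quantile_normalize(m)
    np.testing.assert_allclose(out.data.to_numpy(), m.data.to_numpy())


def test_quantile_normalize_rank_preservation_and_identical_quantiles():
    rng = np.random.default_rng(0)
    x = rng.random((50, 4))
    m = _matrix(x.tolist())
    out = quantile_normalize(m).data.to_numpy()
    for j in range(4):
        assert (np.argsort(x[:, j]) == np.argsort(out[:, j])).all()
    sorted_cols = np.sort(out, axis=0)
    for j in range(1, 4):
        np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])


def test_quantile_normalize_rejects_missing():
    m = _matrix([[0.1, 0.2], [0.5, np.nan]])
    with pytest.raises(ValueError, match="missing"):
        quantile_normalize(m)


def test_beta_m_transforms():
    assert beta_to_m(0.5) == pytest.approx(0.0)
    assert beta_to_m(0.8, offset=0) == pytest.approx(2.0)
    assert np.isfinite(beta_to_m(0.0))
    grid = np.linspace(1e-3, 1 - 1e-3, 101)
    np.testing.assert_allclose(m_to_beta(beta_to_m(grid)), grid, atol=1e-6)
    assert (np.diff(beta_to_m(grid)) > 0).all()


# --- batch adjustment --------------------------------------------------------

def test_combat_single_batch_is_identity():
    rng = np.random.default_rng(1)
    m = _matrix(rng.normal(size=(20, 6)).tolist(), scale="M")
    out = combat_adjust(m, ["b1"] * 6)
    np.testing.assert_allclose(out.data.to_numpy(), m.data.to_numpy())


def test_combat_singleton_batch_rejected():
    rng = np.random.default_rng(1)
    m = _matrix(rng.normal(size=(20, 5)).tolist(), scale="M")
    with pytest.raises(ValueError, match="singleton"):
        combat_adjust(m, ["b1", "b1", "b1", "b1", "b2"])


def test_combat_confounded_covariate_rejected():
    rng = np.random.default_rng(1)
    m = _matrix(rng.normal(size=(20, 6)).tolist(), scale="M")
    batch = ["b1"] * 3 + ["b2"] * 3
    cov = np.array([0.0, 0, 0, 1, 1, 1])  # identical to the batch indicator
    with pytest.raises(ValueError, match="confounded"):
        combat_adjust(m, batch, covariates=cov)


def test_combat_removes_planted_shift():
    """A +1 M-scale shift on batch 2 is reduced to |mean difference| < 0.05."""
    resid = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 0.05, size=(50, 10)) + rng.normal(0, 2, size=(50, 1))
        batch = np.array(["a"] * 5 + ["b"] * 5)
        x[:, batch == "b"] += 1.0
        out = combat_adjust(_matrix(x.tolist(), scale="M"), batch).data.to_numpy()
        resid.append(np.abs(out[:, 5:].mean(axis=1) - out[:, :5].mean(axis=1)).mean())
    assert np.mean(resid) < 0.05


def test_combat_null_perturbation_small():
    """Without a planted batch effect the adjustment barely changes the data."""
    rng = np.random.default_rng(3)
    x = rng.normal(0, 0.3, size=(100, 12)) + rng.normal(0, 2, size=(100, 1))
    batch = ["a"] * 6 + ["b"] * 6
    out = combat_adjust(_matrix(x.tolist(), scale="M"), batch).data.to_numpy()
    rmse = np.sqrt(np.mean((out - x) ** 2))
    assert rmse < 0.1 * x.std()


def test_combat_matches_reference_implementation(tmp_path):
    """Parity with the empirical-Bayes reference in R (sva::ComBat)."""
    rng = np.random.default_rng(42)
    x = rng.normal(0, 1, size=(30, 9)) + rng.normal(0, 1.5, size=(30, 1))
    batch = ["a"] * 4 + ["b"] * 5
    x[:, 4:] += 0.8
    ours = combat_adjust(_matrix(x.tolist(), scale="M"), batch).data.to_numpy()

    dat_path = tmp_path / "dat.tsv"
    pd.DataFrame(x).to_csv(dat_path, sep="\t", index=False)
    script = tmp_path / "combat.R"
    script.write_text(
        textwrap.dedent(
            f"""
            suppressMessages(library(sva))
            dat <- as.matrix(read.table("{dat_path}", sep="\\t", header=TRUE))
            batch <- c(rep("a", 4), rep("b", 5))
            out <- ComBat(dat=dat, batch=batch, mod=NULL, par.prior=TRUE)
            write.table(out, "{tmp_path / 'out.tsv'}", sep="\\t", row.names=FALSE, col.names=FALSE)
            """
        )
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    theirs = np.loadtxt(tmp_path / "out.tsv")
    np.testing.assert_allclose(ours, theirs, atol=1e-4)


# --- PCA ---------------------------------------------------------------------

def test_pca_duplicate_samples_get_identical_scores():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(40, 5))
    x[:, 4] = x[:, 0]
    scores, _ = pca_scores(_matrix(x.tolist(), scale="M"), 2)
    np.testing.assert_allclose(scores.iloc[0], scores.iloc[4], atol=1e-8)


def test_pca_rank1_structure_dominates():
    rng = np.random.default_rng(1)
    direction = rng.normal(size=40)
    weights = np.linspace(-2, 2, 8)
    x = np.outer(direction, weights) + rng.normal(0, 0.05, size=(40, 8))
    scores, frac = pca_scores(_matrix(x.tolist(), scale="M"), 3)
    assert frac[0] > 0.9
    assert (np.diff(frac) <= 1e-12).all()


def test_pca_too_many_components_rejected():
    rng = np.random.default_rng(2)
    m = _matrix(rng.normal(size=(10, 3)).tolist(), scale="M")
    with pytest.raises(ValueError, match="components"):
        pca_scores(m, 4)


def test_matrix_to_m_requires_beta_scale():
    m = _matrix([[0.5, 0.5]], scale="M")
    with pytest.raises(ValueError):
        matrix_to_m(m)
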