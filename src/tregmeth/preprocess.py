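"""Probe QC, normalization, beta/M conversion, batch adjustment, PCA.

The batch correction is the parametric empirical-Bayes location/scale model:
per-probe standardization given covariates, per-batch additive and
multiplicative effects shrunk toward moment-matched batch-level priors
(normal for the location, inverse-gamma for the scale) and removed, with
covariate effects restored afterwards.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import BETA_SCALE, M_SCALE, MethylationMatrix, is_sex_chrom, validate_manifest

LN2 = np.log(2.0)

REMOVAL_REASONS = ["detection_p", "cross_reactive", "dropped_by_vendor", "snp_proximal"]


def filter_probes(
    m: MethylationMatrix,
    manifest: pd.DataFrame,
    detp_threshold: float = 0.05,
    snp_window: int = 3,
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Remove failing probes; returns the filtered matrix and a per-reason report.

    A probe is removed when its detection p-value fails (p >= threshold) in
    any sample, when it is flagged cross-reactive or vendor-dropped, or when
    its CpG lies within ``snp_window`` nucleotides of a SNP.
    """
    if m.scale != BETA_SCALE:
        raise ValueError("filter_probes expects a beta-scale matrix")
    if m.detection_p is None:
        raise ValueError("detection p-value matrix required")
    mani = validate_manifest(manifest).set_index("probe_id")
    mani = mani.reindex(m.probe_ids)

    fails = {
        "detection_p": (m.detection_p.to_numpy() >= detp_threshold).any(axis=1),
        "cross_reactive": mani["cross_reactive"].fillna(False).to_numpy(dtype=bool),
        "dropped_by_vendor": mani["dropped_by_vendor"].fillna(False).to_numpy(dtype=bool),
        "snp_proximal": (mani["snp_distance"].to_numpy(dtype=float) <= snp_window),
    }
    fails["snp_proximal"] = np.nan_to_num(fails["snp_proximal"], nan=0).astype(bool)
    removed = np.zeros(m.n_probes, dtype=bool)
    counts = {}
    for reason in REMOVAL_REASONS:
        counts[reason] = int(fails[reason].sum())
        removed |= fails[reason]
    report = pd.DataFrame(
        {"reason": REMOVAL_REASONS + ["total_removed", "kept"],
         "count": [counts[r] for r in REMOVAL_REASONS] + [int(removed.sum()), int((~removed).sum())]}
    )
    if removed.all():
        dominant = max(counts, key=counts.get)
        raise ValueError(f"all probes removed by filtering (dominant reason: {dominant})")
    return m.subset_probes(m.probe_ids[~removed]), report


def drop_sex_chromosomes(m: MethylationMatrix, manifest: pd.DataFrame) -> MethylationMatrix:
    """Remove probes on chromosomes X or Y (label variants are normalized)."""
    mani = validate_manifest(manifest).set_index("probe_id")
    chrom = mani.reindex(m.probe_ids)["chrom"]
    if chrom.isna().any():
        missing = list(m.probe_ids[chrom.isna()][:3])
        raise ValueError(f"manifest does not cover probes: {missing}")
    keep = ~chrom.map(is_sex_chrom).to_numpy(dtype=bool)
    return m.subset_probes(m.probe_ids[keep])


def quantile_normalize(m: MethylationMatrix) -> MethylationMatrix:
    """Force every sample to the cross-sample mean distribution.

    Each sample's sorted vector is replaced by the mean of the per-sample
    sorted vectors; ties within a sample receive the mean reference value of
    their tied ranks (average-rank convention).
    """
    x = m.data.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values present; imputation is out of scope")
    n = x.shape[0]
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    from scipy.stats import rankdata

    grid = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, ref)
    data = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return MethylationMatrix(data, m.scale, m.detection_p)


def beta_to_m(beta, offset: float = 1e-3):
    """Logit2 transform with symmetric clipping: M = log2(b / (1 - b)), b in [offset, 1-offset]."""
    arr = np.clip(np.asarray(beta, dtype=float), offset, 1.0 - offset)
    return np.log2(arr / (1.0 - arr))


def m_to_beta(m_values):
    return expit(np.asarray(m_values, dtype=float) * LN2)


def matrix_to_m(m: MethylationMatrix, offset: float = 1e-3) -> MethylationMatrix:
    if m.scale != BETA_SCALE:
        raise ValueError("matrix already on M scale")
    data = pd.DataFrame(beta_to_m(m.data.to_numpy(), offset), index=m.data.index, columns=m.data.columns)
    return MethylationMatrix(data, M_SCALE, m.detection_p)


def matrix_to_beta(m: MethylationMatrix) -> MethylationMatrix:
    if m.scale != M_SCALE:
        raise ValueError("matrix already on beta scale")
    data = pd.DataFrame(m_to_beta(m.data.to_numpy()), index=m.data.index, columns=m.data.columns)
    return MethylationMatrix(data, BETA_SCALE, m.detection_p)


# --- empirical-Bayes batch adjustment ---------------------------------------

def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    n = sdat.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((sdat - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2 + a - 1)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old)),
            np.max(np.abs(d_new - d_old) / np.abs(d_old)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_adjust(
    m: MethylationMatrix,
    batch,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> MethylationMatrix:
    """Remove batch effects from an M-scale matrix by parametric empirical Bayes.

    ``batch`` is one label per sample; ``covariates`` are additional design
    columns (no intercept) whose effects are preserved.  With a single batch
    the input is returned unchanged.
    """
    if m.scale != M_SCALE:
        raise ValueError("combat_adjust expects an M-scale matrix")
    batch = pd.Series(list(batch), index=m.sample_ids)
    levels = list(pd.unique(batch))
    if len(levels) == 1:
        return m.copy()
    sizes = batch.value_counts()
    if (sizes < 2).any():
        singles = list(sizes[sizes < 2].index)
        raise ValueError(f"singleton batches not allowed: {singles}")

    dat = m.data.to_numpy(dtype=float)
    n_array = dat.shape[1]
    batch_design = np.column_stack([(batch == lv).to_numpy(dtype=float) for lv in levels])
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        design = np.hstack([batch_design, cov])
        if np.linalg.matrix_rank(design) < len(levels) + cov.shape[1]:
            raise ValueError("covariates are confounded with batch")
    else:
        cov = None
        design = batch_design

    # standardize: grand mean + covariate effects, pooled variance
    b_hat = np.linalg.solve(design.T @ design, design.T @ dat.T)  # (p_design, n_probes)
    n_batches = batch_design.sum(axis=0)
    grand_mean = (n_batches / n_array) @ b_hat[: len(levels), :]
    var_pooled = ((dat - (design @ b_hat).T) ** 2) @ np.full(n_array, 1.0 / n_array)
    var_pooled = np.maximum(var_pooled, 1e-12)
    stand_mean = grand_mean[:, None] @ np.ones((1, n_array))
    if cov is not None:
        tmp = design.copy()
        tmp[:, : len(levels)] = 0
        stand_mean = stand_mean + (tmp @ b_hat).T
    s_data = (dat - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_hat = np.linalg.solve(batch_design.T @ batch_design, batch_design.T @ s_data.T)
    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(gamma_hat)
    for i, lv in enumerate(levels):
        cols = (batch == lv).to_numpy()
        sdat_b = s_data[:, cols]
        d_hat = sdat_b.var(axis=1, ddof=1)
        d_hat = np.maximum(d_hat, 1e-12)
        g_bar = gamma_hat[i].mean()
        t2 = gamma_hat[i].var(ddof=1)
        a, b = _aprior(d_hat), _bprior(d_hat)
        g_star, d_star = _it_sol(sdat_b, gamma_hat[i], d_hat, g_bar, t2, a, b)
        gamma_star[i], delta_star[i] = g_star, d_star

    bayes = s_data.copy()
    for i, lv in enumerate(levels):
        cols = (batch == lv).to_numpy()
        bayes[:, cols] = (bayes[:, cols] - gamma_star[i][:, None]) / np.sqrt(delta_star[i])[:, None]
    adjusted = bayes * np.sqrt(var_pooled)[:, None] + stand_mean
    data = pd.DataFrame(adjusted, index=m.data.index, columns=m.data.columns)
    return MethylationMatrix(data, M_SCALE, m.detection_p)


def pca_scores(m: MethylationMatrix, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-space PCA on probe-centered values.

    Returns per-sample scores and the per-component explained-variance
    fractions.  The sign of each component is fixed so that its
    largest-magnitude probe loading is positive.
    """
    from sklearn.decomposition import PCA

    x = m.data.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values present")
    if n_components > m.n_samples:
        raise ValueError(f"requested {n_components} components for {m.n_samples} samples")
    xs = (x - x.mean(axis=1, keepdims=True)).T  # samples x probes
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(xs)
    for c in range(n_components):
        j = np.argmax(np.abs(pca.components_[c]))
        if pca.components_[c, j] < 0:
            scores[:, c] *= -1
            pca.components_[c] *= -1
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=m.sample_ids, columns=cols),
        pca.explained_variance_ratio_.copy(),
    )
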