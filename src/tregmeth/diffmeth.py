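"""Per-CpG moderated differential methylation and kernel-smoothed DMR calling.

DMPs come from a per-probe linear model on M values with empirical-Bayes
variance shrinkage (moderated t).  DMRs come from a Gaussian-kernel
smoothing of squared per-CpG statistics (bandwidth sigma = lambda / C,
kernel truncated at +/- lambda), a scaled chi-square null with Satterthwaite
moment matching, BH selection of significant CpGs, grouping of consecutive
significant CpGs within lambda, and a region-level Stouffer combination of
the member DMP p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .containers import DMR_COLUMNS, M_SCALE, MethylationMatrix


@dataclass
class Contrast:
    """Two disjoint sample groups, optionally blocked by donor."""

    name: str
    group_a: list[str]
    group_b: list[str]
    block: dict[str, str] | None = None  # sample -> donor label

    def __post_init__(self):
        if set(self.group_a) & set(self.group_b):
            raise ValueError("contrast groups must be disjoint")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError("each group needs >= 2 samples")

    @property
    def samples(self) -> list[str]:
        return list(self.group_a) + list(self.group_b)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-8:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior on log residual variances.

    Returns ``(d0, s0_squared)``; ``d0`` may be ``inf`` when the observed
    log-variance spread is no wider than expected under a common variance.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - _trigamma(df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return float(d0), float(s0_sq)


def fit_dmps(
    m: MethylationMatrix,
    beta: MethylationMatrix,
    contrast: Contrast,
    manifest: pd.DataFrame | None = None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Moderated-t differential methylation per probe.

    The linear model is fit on M values (group effect plus optional donor
    blocking); residual variances are shrunk toward a moment-matched prior;
    ``delta_beta`` is the group-A-minus-group-B difference of beta means.
    """
    if m.scale != M_SCALE:
        raise ValueError("fit_dmps expects an M-scale matrix")
    if not m.probe_ids.equals(beta.probe_ids):
        raise ValueError("M and beta matrices must have identical probes")
    samples = contrast.samples
    y = m.data[samples].to_numpy(dtype=float)
    b = beta.data[samples].to_numpy(dtype=float)

    group = np.array([1.0 if s in set(contrast.group_a) else 0.0 for s in samples])
    cols = [np.ones(len(samples)), group]
    if contrast.block:
        donors = [contrast.block[s] for s in samples]
        levels = sorted(set(donors))
        for lv in levels[1:]:
            cols.append(np.array([1.0 if d == lv else 0.0 for d in donors]))
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    df_resid = len(samples) - rank
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")

    xtx_inv = np.linalg.pinv(x.T @ x)
    coefs = y @ x @ xtx_inv.T  # probes x params
    fitted = coefs @ x.T
    resid = y - fitted
    s2 = (resid**2).sum(axis=1) / df_resid
    se_unscaled = np.sqrt(xtx_inv[1, 1])

    constant = s2 <= 1e-30
    s2_fit = s2.copy()
    if constant.all():
        raise ValueError("all probes constant; cannot estimate variances")
    d0, s0_sq = squeeze_variances(s2_fit[~constant], df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    df_total = min(df_total, df_resid * len(s2))  # cap at the pooled df

    t_mod = coefs[:, 1] / (se_unscaled * np.sqrt(s2_post))
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    t_mod[constant] = 0.0
    p[constant] = 1.0

    delta_beta = b[:, group == 1].mean(axis=1) - b[:, group == 0].mean(axis=1)
    fdr = bh_adjust(p)
    out = pd.DataFrame(
        {
            "probe_id": m.probe_ids,
            "delta_beta": delta_beta,
            "t_mod": t_mod,
            "p": p,
            "fdr": fdr,
            "significant": fdr < fdr_threshold,
        }
    )
    if manifest is not None:
        coords = manifest.set_index("probe_id")[["chrom", "pos"]]
        out = out.join(coords, on="probe_id")
        out = out[["probe_id", "chrom", "pos", "delta_beta", "t_mod", "p", "fdr", "significant"]]
    return out.reset_index(drop=True)


# --- kernel smoothing -------------------------------------------------------

def smooth_stats(
    positions: np.ndarray,
    t_stats: np.ndarray,
    lambda_: float = 500.0,
    C: float = 3.0,
) -> pd.DataFrame:
    """Gaussian-kernel smoothing of squared statistics along one chromosome.

    ``Y_i = sum_j w_ij t_j^2 / sum_j w_ij`` with ``w_ij =
    exp(-(pos_i - pos_j)^2 / (2 sigma^2))``, ``sigma = lambda / C``, kernel
    truncated at ``|pos_i - pos_j| <= lambda``.  The null is a scaled
    chi-square with Satterthwaite moment matching of chi-square(1) members.
    """
    pos = np.asarray(positions, dtype=np.int64)
    t = np.asarray(t_stats, dtype=float)
    if len(pos) != len(t):
        raise ValueError("positions and statistics differ in length")
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted ascending")
    sigma = lambda_ / C
    t2 = t**2
    n = len(pos)
    y = np.empty(n)
    k_df = np.empty(n)
    # probes further apart than lambda never interact: process blocks
    breaks = np.flatnonzero(np.diff(pos) > lambda_) + 1
    for block in np.split(np.arange(n), breaks):
        bp = pos[block].astype(float)
        d = bp[:, None] - bp[None, :]
        w = np.exp(-(d**2) / (2 * sigma**2))
        w[np.abs(d) > lambda_] = 0.0
        wsum = w.sum(axis=1)
        y[block] = (w @ t2[block]) / wsum
        k_df[block] = wsum**2 / (w**2).sum(axis=1)
    p = stats.chi2.sf(y * k_df, k_df)
    return pd.DataFrame({"pos": pos, "smoothed_stat": y, "df": k_df, "smoothed_p": p})


def stouffer_combine(p_values, directions, two_sided: bool = True) -> tuple[float, float]:
    """Stouffer combination of member p-values aligned to a region direction.

    ``directions`` are +/-1 per member relative to the region direction.
    With ``two_sided=True`` each p is converted via ``z = Phi^-1(1 - p/2)``;
    one-sided inputs use ``z = Phi^-1(1 - p)``.  Returns ``(Z, p_one_sided)``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p <= 0) | (p > 1)):
        p = np.clip(p, 1e-300, 1.0)
    d = np.asarray(directions, dtype=float)
    z = stats.norm.isf(p / 2.0) if two_sided else stats.norm.isf(p)
    z = z * d
    z_comb = z.sum() / np.sqrt(len(z))
    return float(z_comb), float(stats.norm.sf(z_comb))


def _split_sign_runs(deltas: np.ndarray) -> list[np.ndarray]:
    """Split member indices at sign changes of delta_beta; zeros follow the current run."""
    signs = np.sign(deltas)
    runs: list[list[int]] = []
    current_sign = 0.0
    for i, s in enumerate(signs):
        if s == 0:
            s = current_sign
        if not runs or (s != current_sign and s != 0 and current_sign != 0):
            runs.append([])
            current_sign = s
        elif current_sign == 0 and s != 0:
            current_sign = s
        runs[-1].append(i)
    return [np.asarray(r) for r in runs]


def call_dmrs(
    stats_df: pd.DataFrame,
    lambda_: float = 500.0,
    C: float = 3.0,
    min_cpgs: int = 3,
    stouffer_threshold: float = 0.05,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Group kernel-smoothed significant CpGs into differentially methylated regions.

    ``stats_df`` needs columns chrom, pos (1-based), probe_id, t (the per-CpG
    statistic), p (the per-CpG DMP p-value) and delta_beta.  Consecutive
    significant CpGs within ``lambda_`` bp form a region; mixed-direction
    regions are split at delta_beta sign changes; regions keep >= ``min_cpgs``
    members and a Stouffer combination of member DMP p-values below the
    threshold.
    """
    required = {"chrom", "pos", "probe_id", "t", "p", "delta_beta"}
    if not required.issubset(stats_df.columns):
        raise ValueError(f"stats_df needs columns {sorted(required)}")
    pieces = []
    for chrom, grp in stats_df.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="mergesort")
        sm = smooth_stats(grp["pos"].to_numpy(), grp["t"].to_numpy(), lambda_, C)
        grp = grp.reset_index(drop=True)
        grp["smoothed_stat"] = sm["smoothed_stat"].to_numpy()
        grp["smoothed_p"] = sm["smoothed_p"].to_numpy()
        pieces.append(grp)
    merged = pd.concat(pieces, ignore_index=True)
    merged["smoothed_fdr"] = bh_adjust(merged["smoothed_p"].to_numpy())

    records = []
    sig = merged[merged["smoothed_fdr"] < fdr_threshold]
    for chrom, grp in sig.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="mergesort").reset_index(drop=True)
        gaps = np.diff(grp["pos"].to_numpy())
        group_breaks = np.flatnonzero(gaps > lambda_) + 1
        for idx in np.split(np.arange(len(grp)), group_breaks):
            members = grp.iloc[idx]
            for run in _split_sign_runs(members["delta_beta"].to_numpy()):
                sub = members.iloc[run]
                if len(sub) < min_cpgs:
                    continue
                deltas = sub["delta_beta"].to_numpy()
                direction = "hyper" if deltas.mean() >= 0 else "hypo"
                dir_sign = 1.0 if direction == "hyper" else -1.0
                align = np.where(np.sign(deltas) == 0, 1.0, np.sign(deltas) * dir_sign)
                z, sp = stouffer_combine(sub["p"].to_numpy(), align, two_sided=True)
                if sp >= stouffer_threshold:
                    continue
                pos = sub["pos"].to_numpy()
                records.append(
                    {
                        "chrom": chrom,
                        "start": int(pos.min()) - 1,
                        "end": int(pos.max()),
                        "n_cpgs": int(len(sub)),
                        "mean_delta_beta": float(deltas.mean()),
                        "max_delta_beta": float(deltas[np.argmax(np.abs(deltas))]),
                        "stouffer_p": sp,
                        "direction": direction,
                        "probes": tuple(sub["probe_id"]),
                    }
                )
    out = pd.DataFrame(records, columns=DMR_COLUMNS)
    if len(out):
        out = out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return out


def dmps_to_dmr_input(dmps: pd.DataFrame) -> pd.DataFrame:
    """Adapt a fit_dmps result to the call_dmrs input schema."""
    df = dmps.rename(columns={"t_mod": "t"})
    return df[["chrom", "pos", "probe_id", "t", "p", "delta_beta"]]
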