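"""Synthetic EPIC-like and WGBS-like datasets with planted ground truth.

The generator emulates the statistical structure of an array-based
methylation time course of in-vitro expanded Treg products:

* bimodal baseline beta values (unmethylated mode near 0.1, methylated mode
  near 0.85), with noise generated on the M scale so that batch effects are
  additive in the space where the empirical-Bayes correction model operates;
* donor random intercepts and run-specific additive + multiplicative batch
  effects on the M scale;
* planted differentially methylated regions with early-saturating or
  late-accelerating kinetics;
* partially methylated domains (PMDs) that lose methylation linearly in
  log10 cumulative expansion;
* Treg-specific demethylated regions (Treg-DRs) that start demethylated in
  Treg samples and remethylate with expansion, except for FOXP3-like and
  TNFRSF1B-like anchor loci which stay stably demethylated;
* overdispersed bisulfite-sequencing count tables for two cell populations.

Probe clusters are isolated by more than the DMR-calling bandwidth so that
planted regions map one-to-one onto callable regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import Gene, GeneModel
from .containers import MethylationMatrix, RegionSet
from . import io as tio

LN2 = math.log(2.0)

TREGDR_GENE_POOL = [
    "FOXP3", "FOXP3", "TNFRSF1B", "IKZF2", "IKZF4", "IL2RA", "CTLA4", "TIGIT",
    "LRRC32", "TNFRSF9", "IL2RB", "IKZF1", "STAT5A", "TNFRSF18", "CCR4",
    "ENTPD1", "NT5E", "LAG3", "CD27", "ICOS",
]
ANCHOR_GENES = {"FOXP3", "TNFRSF1B"}

STATE_VOCAB = ["TssA", "EnhA", "EnhG", "Tx", "WeakTx", "WeakEnh", "ReprPC", "Quies"]
STATE_WEIGHTS = [0.08, 0.08, 0.04, 0.12, 0.08, 0.10, 0.10, 0.40]
TREG_ACTIVE_STATES = ["TssA", "EnhG", "EnhA"]
CD4_REPRESSED_STATES = ["ReprPC", "Quies", "WeakEnh"]


def child_seed(seed: int, k: int) -> int:
    return (int(seed) * 1_000_003 + 7919 * (k + 1)) % (2**31)


@dataclass
class PlantedRegion:
    """A planted DMR; coordinates are assigned by :func:`simulate_manifest`."""

    n_cpgs: int
    direction: str  # hyper | hypo
    kinetics: str  # early | late
    delta_beta: float
    chrom: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self):
        if self.n_cpgs < 3:
            raise ValueError("planted regions need >= 3 CpGs")
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"direction {self.direction!r}")
        if self.kinetics not in ("early", "late"):
            raise ValueError(f"kinetics {self.kinetics!r}")
        if not 0 <= self.delta_beta <= 0.5:
            raise ValueError("delta_beta must be in [0, 0.5]")

    @property
    def sign(self) -> int:
        return 1 if self.direction == "hyper" else -1


def default_planted(
    n_regions: int = 20, n_cpgs: int = 5, delta_beta: float = 0.2
) -> list[PlantedRegion]:
    """Planted regions cycling through hyper/hypo x early/late."""
    out = []
    for i in range(n_regions):
        out.append(
            PlantedRegion(
                n_cpgs=n_cpgs,
                direction="hyper" if i % 2 == 0 else "hypo",
                kinetics="early" if (i // 2) % 2 == 0 else "late",
                delta_beta=delta_beta,
            )
        )
    return out


@dataclass
class SimDesign:
    """Layout and effect sizes of a simulated EPIC-style time course."""

    n_probes: int = 10_000
    n_chromosomes: int = 5
    donors: tuple[str, ...] = ("D1", "D2", "D3")
    runs: tuple[str, ...] = ("R1", "R2")
    days: tuple[int, ...] = (0, 10, 23)
    cells_per_group: int = 1
    cell_types: tuple[str, ...] = ("TregProduct",)
    planted_dmrs: list[PlantedRegion] = field(default_factory=default_planted)
    pmd_fraction: float = 0.15
    tregdr_count: int = 33
    seed: int = 0
    # nuisance / noise parameters (beta or M scale as noted)
    noise_sd: float = 0.2            # residual SD on M scale
    donor_sd: float = 0.15           # donor random-intercept SD on M scale
    batch_shift: float = 0.6         # additive M-scale shift per run step
    batch_gamma_sd: float = 0.3      # per-probe spread of the batch shift
    batch_scale: float = 1.3         # multiplicative noise factor per run step
    detp_fail_rate: float = 0.002    # fraction of failed detection p entries
    sex_probe_fraction: float = 0.03
    cross_reactive_fraction: float = 0.01
    snp_fraction: float = 0.02
    vendor_dropped_fraction: float = 0.005
    pmd_slope: float = 0.08          # beta lost per log10 expansion in PMDs
    tregdr_slope: float = 0.15       # beta gained per log10 expansion at Treg-DRs
    tregdr_noise_beta: float = 0.03  # approximate beta-scale noise SD at Treg-DRs
    expansion_log10_per_day: float = 0.13
    expansion_rate_sd: float = 0.015

    def validate(self) -> None:
        if sorted(self.days) != list(self.days) or 0 not in self.days:
            raise ValueError("days must be sorted ascending and include 0")
        if len(self.days) < 2:
            raise ValueError("need at least two time points")
        if self.n_probes < 10 * max(1, len(self.planted_dmrs)):
            raise ValueError("n_probes must be >= 10x the number of planted regions")
        if self.cells_per_group < 1:
            raise ValueError("cells_per_group must be >= 1")
        if not 0 <= self.pmd_fraction < 1:
            raise ValueError("pmd_fraction must be in [0, 1)")

    @property
    def final_day(self) -> int:
        return max(self.days)


def kinetic_fraction(day, kinetics: str, final_day: int) -> np.ndarray:
    """Fraction of the full effect present at ``day``.

    Early regions saturate (~92% of the effect by day 10 of 23); late regions
    accelerate (~16% by day 10), reaching the full effect at the final day.
    """
    d = np.asarray(day, dtype=float)
    if kinetics == "early":
        tau = final_day / 5.75  # 4.0 for a 23-day course
        return (1.0 - np.exp(-d / tau)) / (1.0 - np.exp(-final_day / tau))
    if kinetics == "late":
        return (d / final_day) ** 2.2
    raise ValueError(f"kinetics {kinetics!r}")


@dataclass
class SimWorld:
    """Realized genome layout: manifest, gene model, region sets, planted truth."""

    design: SimDesign
    manifest: pd.DataFrame
    gene_model: GeneModel
    region_sets: dict[str, RegionSet]
    planted: list[PlantedRegion]
    probe_roles: pd.DataFrame
    gene_sets: dict[str, list[str]]
    chrom_lengths: dict[str, int]


def _beta_to_m(mu: np.ndarray) -> np.ndarray:
    return np.log2(mu / (1.0 - mu))


def _m_to_beta(m: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-m * LN2))


def simulate_manifest(design: SimDesign) -> SimWorld:
    """Place probe clusters, genes and region sets on a toy genome."""
    design.validate()
    rng = np.random.default_rng(child_seed(design.seed, 0))

    n_planted_probes = sum(p.n_cpgs for p in design.planted_dmrs)
    n_sex = int(round(design.sex_probe_fraction * design.n_probes))
    n_pmd = int(round(design.pmd_fraction * design.n_probes))
    tregdr_sizes = rng.integers(1, 3, size=design.tregdr_count)
    n_tregdr = int(tregdr_sizes.sum())
    n_special = n_planted_probes + n_sex + n_pmd + n_tregdr
    n_bg = design.n_probes - n_special
    if n_bg < 5 * design.n_chromosomes:
        raise ValueError(
            f"n_probes={design.n_probes} too small to host "
            f"{len(design.planted_dmrs)} planted regions plus PMD/Treg-DR/sex probes"
        )

    # cluster descriptors: (type, size, payload)
    clusters: list[tuple[str, int, object]] = []
    for i, pr in enumerate(design.planted_dmrs):
        clusters.append(("planted", pr.n_cpgs, i))
    labels = list(TREGDR_GENE_POOL) + [
        f"TREGDR{i:02d}" for i in range(len(TREGDR_GENE_POOL), design.tregdr_count)
    ]
    for i in range(design.tregdr_count):
        clusters.append(("tregdr", int(tregdr_sizes[i]), labels[i]))
    remaining = n_bg
    while remaining > 0:
        size = int(min(remaining, rng.integers(2, 9)))
        clusters.append(("background", size, None))
        remaining -= size
    pmd_clusters: list[tuple[str, int, object]] = []
    remaining = n_pmd
    while remaining > 0:
        size = int(min(remaining, rng.integers(4, 9)))
        pmd_clusters.append(("pmd", size, None))
        remaining -= size

    # round-robin chromosome assignment; PMD clusters form one block per chromosome
    autosomes = [f"chr{i + 1}" for i in range(design.n_chromosomes)]
    per_chrom: dict[str, list[tuple[str, int, object]]] = {c: [] for c in autosomes}
    for i, cl in enumerate(clusters):
        per_chrom[autosomes[i % len(autosomes)]].append(cl)
    pmd_per_chrom: dict[str, list[tuple[str, int, object]]] = {c: [] for c in autosomes}
    for i, cl in enumerate(pmd_clusters):
        pmd_per_chrom[autosomes[i % len(autosomes)]].append(cl)
    for chrom in autosomes:
        seq = per_chrom[chrom]
        order = rng.permutation(len(seq))
        seq = [seq[i] for i in order]
        mid = len(seq) // 2
        per_chrom[chrom] = seq[:mid] + pmd_per_chrom[chrom] + seq[mid:]

    # sex-chromosome clusters
    sex_chroms: dict[str, list[tuple[str, int, object]]] = {"chrX": [], "chrY": []}
    remaining = n_sex
    toggle = 0
    while remaining > 0:
        size = int(min(remaining, rng.integers(3, 7)))
        sex_chroms["chrX" if toggle % 2 == 0 else "chrY"].append(("sex", size, None))
        remaining -= size
        toggle += 1

    probe_rows = []  # (chrom, point, role, payload, cluster_id)
    planted_coords: dict[int, tuple[str, int, int]] = {}
    tregdr_rows = []
    pmd_core: dict[str, tuple[int, int]] = {}
    gene_list: list[Gene] = []
    cluster_gene: dict[int, str] = {}
    chrom_lengths: dict[str, int] = {}
    gene_counter = 0
    cluster_id = 0

    def _make_gene(chrom, c_start, c_end, next_start, name=None):
        nonlocal gene_counter
        gene_counter += 1
        gid = f"g{gene_counter:05d}"
        gname = name or f"GENE{gene_counter:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            g_start = max(0, c_start - int(rng.integers(0, 1500)))
            g_end = c_end + int(rng.integers(2500, 6000))
            if next_start is not None:
                g_end = min(g_end, next_start - 100)
            g_end = max(g_end, g_start + 1500)
        else:
            g_end = c_end + int(rng.integers(0, 1500))
            g_start = max(0, c_start - int(rng.integers(2500, 6000)))
            g_start = min(g_start, g_end - 1500)
            g_start = max(g_start, 0)
        length = g_end - g_start
        e1 = (g_start, g_start + min(200, length // 4))
        mid = g_start + length // 2
        e2 = (mid, min(mid + 150, g_end))
        e3 = (max(g_end - 250, e2[1] + 1), g_end)
        if strand == "+":
            five = ((g_start, g_start + 80),)
            three = ((g_end - 100, g_end),)
        else:
            five = ((g_end - 80, g_end),)
            three = ((g_start, g_start + 100),)
        gene_list.append(
            Gene(gid, gname, chrom, strand, g_start, g_end, (e1, e2, e3), five, three)
        )
        return gid

    all_chrom_layouts = {**per_chrom, **sex_chroms}
    for chrom in autosomes + ["chrX", "chrY"]:
        seq = all_chrom_layouts[chrom]
        cursor = 10_000
        # precompute cluster spans to know each next cluster's start
        spans = []
        for ctype, size, payload in seq:
            spacings = rng.integers(40, 121, size=max(size - 1, 0))
            points = cursor + np.concatenate([[0], np.cumsum(spacings)]).astype(np.int64)
            spans.append((ctype, payload, points))
            cursor = int(points[-1]) + int(rng.integers(3000, 12001))
        chrom_lengths[chrom] = cursor + 50_000
        pmd_span = None
        for k, (ctype, payload, points) in enumerate(spans):
            c_start, c_end = int(points[0]), int(points[-1]) + 1
            for p in points:
                probe_rows.append((chrom, int(p), ctype, payload, cluster_id))
            next_start = int(spans[k + 1][2][0]) if k + 1 < len(spans) else None
            if ctype == "planted":
                planted_coords[int(payload)] = (chrom, c_start, c_end)
                cluster_gene[cluster_id] = _make_gene(chrom, c_start, c_end, next_start)
            elif ctype == "tregdr":
                tregdr_rows.append((chrom, c_start - 50, c_end + 50, str(payload)))
                cluster_gene[cluster_id] = _make_gene(
                    chrom, c_start, c_end, next_start, name=str(payload)
                )
            elif ctype == "pmd":
                pmd_span = (
                    (c_start, c_end)
                    if pmd_span is None
                    else (pmd_span[0], max(pmd_span[1], c_end))
                )
            elif ctype == "background" and rng.random() < 0.55:
                cluster_gene[cluster_id] = _make_gene(chrom, c_start, c_end, next_start)
            cluster_id += 1
        if pmd_span is not None:
            pmd_core[chrom] = (pmd_span[0] - 200, pmd_span[1] + 200)

    probes = pd.DataFrame(
        probe_rows, columns=["chrom", "point", "role", "payload", "cluster"]
    )
    probes = probes.sort_values(["chrom", "point"], kind="mergesort").reset_index(drop=True)
    probes["probe_id"] = [f"cg{i:08d}" for i in range(len(probes))]

    n = len(probes)
    snp_flag = rng.random(n) < design.snp_fraction
    snp_distance = np.where(snp_flag, rng.integers(0, 4, size=n), -1).astype(float)
    snp_distance[snp_distance < 0] = np.nan
    cross_reactive = rng.random(n) < design.cross_reactive_fraction
    dropped = rng.random(n) < design.vendor_dropped_fraction

    manifest = pd.DataFrame(
        {
            "probe_id": probes["probe_id"],
            "chrom": probes["chrom"],
            "pos": probes["point"] + 1,  # manifests are 1-based
            "snp_distance": snp_distance,
            "cross_reactive": cross_reactive,
            "dropped_by_vendor": dropped,
        }
    )
    probe_roles = probes[["probe_id", "chrom", "point", "role", "payload", "cluster"]].copy()
    probe_roles["anchor"] = (probe_roles["role"] == "tregdr") & probe_roles[
        "payload"
    ].isin(ANCHOR_GENES)

    planted = []
    for i, pr in enumerate(design.planted_dmrs):
        chrom, start, end = planted_coords[i]
        planted.append(
            PlantedRegion(pr.n_cpgs, pr.direction, pr.kinetics, pr.delta_beta, chrom, start, end)
        )

    # region sets ------------------------------------------------------------
    pmd_sets: dict[str, RegionSet] = {}
    for subset in ("CM", "EM", "TEMRA", "Treg"):
        rows = []
        for chrom, (s, e) in sorted(pmd_core.items()):
            j1, j2 = int(rng.integers(100, 401)), int(rng.integers(100, 401))
            rows.append((chrom, max(0, s - j1), e + j2, f"PMD_{subset}"))
        pmd_sets[f"pmd_{subset}"] = RegionSet(
            f"pmd_{subset}", pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
        )

    tregdr_set = RegionSet(
        "tregdr", pd.DataFrame(tregdr_rows, columns=["chrom", "start", "end", "label"])
    )

    def _states_for(active: bool) -> RegionSet:
        rows = []
        for chrom in autosomes:
            length = chrom_lengths[chrom]
            td = tregdr_set.df[tregdr_set.df["chrom"] == chrom]
            td_start = td["start"].to_numpy()
            td_end = td["end"].to_numpy()
            breaks = {0, length}
            breaks.update(int(x) for x in td_start)
            breaks.update(int(x) for x in td_end)
            cursor = 0
            while cursor < length:
                cursor += int(rng.integers(5_000, 40_000))
                if cursor < length:
                    breaks.add(cursor)
            pts = sorted(breaks)
            for s, e in zip(pts[:-1], pts[1:]):
                inside = bool(np.any((td_start <= s) & (td_end >= e)))
                if inside:
                    lab = str(rng.choice(TREG_ACTIVE_STATES if active else CD4_REPRESSED_STATES))
                else:
                    lab = str(rng.choice(STATE_VOCAB, p=STATE_WEIGHTS))
                rows.append((chrom, s, e, lab))
        name = "states_treg" if active else "states_cd4mem"
        return RegionSet(name, pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))

    states_treg = _states_for(True)
    states_cd4 = _states_for(False)

    bl_rows = []
    dropped_probes = probes.loc[dropped]
    for _, r in dropped_probes.sample(
        n=min(10, len(dropped_probes)), random_state=int(child_seed(design.seed, 5)) % (2**32)
    ).iterrows():
        bl_rows.append((r.chrom, max(0, r.point - 100), r.point + 100, "blacklist"))
    blacklist = RegionSet(
        "blacklist", pd.DataFrame(bl_rows, columns=["chrom", "start", "end", "label"])
    )

    planted_rs = RegionSet(
        "planted",
        pd.DataFrame(
            [(p.chrom, p.start, p.end, f"{p.direction}_{p.kinetics}") for p in planted],
            columns=["chrom", "start", "end", "label"],
        ),
    )

    gene_model = GeneModel(gene_list)
    all_gene_names = sorted({g.name for g in gene_list})
    gene_sets: dict[str, list[str]] = {}
    planted_clusters = set(probes.loc[probes["role"] == "planted", "cluster"])
    planted_gene_ids = {gid for cid, gid in cluster_gene.items() if cid in planted_clusters}
    id_to_name = {g.gene_id: g.name for g in gene_list}
    planted_genes = sorted({id_to_name[g] for g in planted_gene_ids})
    if planted_genes:
        extra = [g for g in all_gene_names if g not in planted_genes]
        pad = list(rng.choice(extra, size=min(5, len(extra)), replace=False)) if extra else []
        gene_sets["PLANTED_PATHWAY"] = planted_genes + sorted(pad)
    for i in range(12):
        size = int(rng.integers(10, 41))
        members = sorted(rng.choice(all_gene_names, size=min(size, len(all_gene_names)), replace=False))
        gene_sets[f"RANDOM_SET_{i:02d}"] = members

    region_sets = {
        **pmd_sets,
        "tregdr": tregdr_set,
        "states_treg": states_treg,
        "states_cd4mem": states_cd4,
        "blacklist": blacklist,
        "planted": planted_rs,
    }
    return SimWorld(
        design=design,
        manifest=manifest,
        gene_model=gene_model,
        region_sets=region_sets,
        planted=planted,
        probe_roles=probe_roles,
        gene_sets=gene_sets,
        chrom_lengths=chrom_lengths,
    )


# --- sample sheet / expansion ----------------------------------------------

_CELL_SLOPE_MEAN = {"TregProduct": 0.13, "Treg": 0.10, "CD4mem": 0.12}


def simulate_expansion(design: SimDesign) -> pd.DataFrame:
    """Sample sheet including the cumulative expansion rate (fold since day 0)."""
    rng = np.random.default_rng(child_seed(design.seed, 2))
    rows = []
    for cell in design.cell_types:
        for run in design.runs:
            for donor in design.donors:
                slope = rng.normal(
                    _CELL_SLOPE_MEAN.get(cell, design.expansion_log10_per_day),
                    design.expansion_rate_sd,
                )
                slope = max(slope, 0.01)
                for day in design.days:
                    for rep in range(design.cells_per_group):
                        sid = f"{cell}_{donor}_{run}_d{day}"
                        if design.cells_per_group > 1:
                            sid += f"_r{rep + 1}"
                        rows.append(
                            {
                                "sample_id": sid,
                                "donor": donor,
                                "run": run,
                                "day": day,
                                "cell_type": cell,
                                "cumulative_expansion_rate": float(10 ** (slope * day)),
                            }
                        )
    return pd.DataFrame(rows)


def simulate_timecourse(
    design: SimDesign, world: SimWorld, expansion: pd.DataFrame | None = None
) -> tuple[MethylationMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate the beta/detection-p matrices, sample sheet and truth table."""
    design.validate()
    sheet = simulate_expansion(design)
    if expansion is not None:
        ov = expansion.set_index("sample_id")["cumulative_expansion_rate"]
        missing = set(sheet["sample_id"]) - set(ov.index)
        if missing:
            raise ValueError(f"expansion series missing samples: {sorted(missing)[:5]}")
        if (ov.loc[sheet.loc[sheet["day"] == 0, "sample_id"]] != 1).any():
            raise ValueError("expansion series must equal 1 at day 0")
        sheet = sheet.copy()
        sheet["cumulative_expansion_rate"] = ov.loc[sheet["sample_id"]].to_numpy()

    rng = np.random.default_rng(child_seed(design.seed, 1))
    roles = world.probe_roles
    n_probes = len(roles)
    n_samples = len(sheet)
    role = roles["role"].to_numpy()
    cluster = roles["cluster"].to_numpy()
    anchor = roles["anchor"].to_numpy()

    # baseline beta per probe (draw order fixed for determinism)
    baseline = np.empty(n_probes)
    bg_mask = np.isin(role, ["background", "sex"])
    n_bg = int(bg_mask.sum())
    lo = rng.beta(2, 18, size=n_bg)
    hi = rng.beta(17, 3, size=n_bg)
    pick_hi = rng.random(n_bg) < 0.55
    baseline[bg_mask] = np.where(pick_hi, hi, lo)
    pmd_mask = role == "pmd"
    baseline[pmd_mask] = rng.uniform(0.55, 0.80, size=int(pmd_mask.sum()))
    tregdr_mask = role == "tregdr"
    baseline[tregdr_mask] = 0.1  # placeholder; set per cell type below
    planted_mask = role == "planted"
    for i, pr in enumerate(world.planted):
        sel = planted_mask & (roles["payload"].to_numpy() == i)
        if pr.direction == "hyper":
            baseline[sel] = rng.uniform(0.25, 0.50, size=int(sel.sum()))
        else:
            baseline[sel] = rng.uniform(0.50, 0.75, size=int(sel.sum()))

    days = sheet["day"].to_numpy()
    log10_exp = np.log10(sheet["cumulative_expansion_rate"].to_numpy())
    cell_types = sheet["cell_type"].to_numpy()

    mu = np.tile(baseline[:, None], (1, n_samples))
    for i, pr in enumerate(world.planted):
        sel = planted_mask & (roles["payload"].to_numpy() == i)
        frac = kinetic_fraction(days, pr.kinetics, design.final_day)
        mu[sel, :] += pr.sign * pr.delta_beta * frac[None, :]
    if pmd_mask.any():
        mu[pmd_mask, :] -= design.pmd_slope * log10_exp[None, :]
    if tregdr_mask.any():
        for j in range(n_samples):
            cell = cell_types[j]
            if cell == "CD4mem":
                mu[tregdr_mask, j] = 0.75
            elif cell == "Treg":
                base = np.where(anchor[tregdr_mask], 0.08, 0.08 + design.tregdr_slope * log10_exp[j])
                mu[tregdr_mask, j] = base
            else:  # TregProduct: impure starting material sits between Treg and CD4mem
                base = np.where(anchor[tregdr_mask], 0.35, 0.40 + design.tregdr_slope * log10_exp[j])
                mu[tregdr_mask, j] = base
    mu = np.clip(mu, 0.02, 0.98)
    m_mean = _beta_to_m(mu)

    donors = list(design.donors)
    donor_eff = rng.normal(0.0, design.donor_sd, size=(n_probes, len(donors))) if design.donor_sd > 0 else np.zeros((n_probes, len(donors)))
    runs = list(design.runs)
    gamma = np.empty((n_probes, len(runs)))
    for r_idx in range(len(runs)):
        gamma[:, r_idx] = rng.normal(design.batch_shift * r_idx, design.batch_gamma_sd, size=n_probes) if (design.batch_shift != 0 or design.batch_gamma_sd > 0) else 0.0
    scale_by_run = np.array([design.batch_scale**r for r in range(len(runs))])

    donor_idx = np.array([donors.index(d) for d in sheet["donor"]])
    run_idx = np.array([runs.index(r) for r in sheet["run"]])

    eps = rng.standard_normal((n_probes, n_samples))
    sd = np.full((n_probes, n_samples), design.noise_sd)
    if tregdr_mask.any():
        local = design.tregdr_noise_beta / (mu[tregdr_mask, :] * (1 - mu[tregdr_mask, :]) * LN2)
        sd[tregdr_mask, :] = np.clip(local, 0.01, 1.5)
    sd = sd * scale_by_run[run_idx][None, :]

    m_vals = (
        m_mean
        + donor_eff[:, donor_idx]
        + gamma[:, run_idx]
        + eps * sd
    )
    beta = _m_to_beta(m_vals)

    detp = rng.uniform(1e-8, 0.0099, size=(n_probes, n_samples))
    fail = rng.random((n_probes, n_samples)) < design.detp_fail_rate
    detp[fail] = rng.uniform(0.051, 0.6, size=int(fail.sum()))

    probe_ids = roles["probe_id"].to_numpy()
    sample_ids = sheet["sample_id"].to_numpy()
    beta_df = pd.DataFrame(beta, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    detp_df = pd.DataFrame(detp, index=beta_df.index, columns=sample_ids)
    matrix = MethylationMatrix(beta_df, "beta", detp_df)

    truth = pd.DataFrame(
        {
            "region_id": [f"planted{i:03d}" for i in range(len(world.planted))],
            "chrom": [p.chrom for p in world.planted],
            "start": [p.start for p in world.planted],
            "end": [p.end for p in world.planted],
            "n_cpgs": [p.n_cpgs for p in world.planted],
            "direction": [p.direction for p in world.planted],
            "kinetics": [p.kinetics for p in world.planted],
            "delta_beta": [p.sign * p.delta_beta for p in world.planted],
        }
    )
    return matrix, sheet, truth


# --- WGBS-like counts -------------------------------------------------------

def simulate_wgbs(
    n_cpgs: int,
    mean_coverage: float,
    group_effects: list[tuple[int, float]] | None,
    seed: int,
    nb_size: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two-group bisulfite count tables with planted differential blocks.

    Coverage is negative-binomial with mean ``mean_coverage`` and size
    ``nb_size``; methylated counts are binomial given the per-CpG methylation
    level.  ``group_effects`` is a list of ``(block_n_cpgs, delta)`` blocks;
    ``delta`` is added to group A inside the block.
    """
    if mean_coverage < 1:
        raise ValueError("mean_coverage must be >= 1")
    if n_cpgs < 10:
        raise ValueError("n_cpgs too small")
    rng = np.random.default_rng(int(seed) % (2**31))
    group_effects = [ge for ge in (group_effects or [])]
    need = sum(b for b, _ in group_effects)
    if need + 10 * max(1, len(group_effects)) > n_cpgs:
        raise ValueError("n_cpgs too small to host the requested blocks")

    spacing = rng.integers(30, 301, size=n_cpgs)
    starts = 1000 + np.cumsum(spacing)
    p0 = np.where(rng.random(n_cpgs) < 0.45, rng.beta(2, 18, n_cpgs), rng.beta(17, 3, n_cpgs))

    delta = np.zeros(n_cpgs)
    taken = np.zeros(n_cpgs, dtype=bool)
    truth_rows = []
    for block, d in group_effects:
        for _ in range(1000):
            i0 = int(rng.integers(0, n_cpgs - block))
            lo, hi = max(0, i0 - 5), min(n_cpgs, i0 + block + 5)
            if not taken[lo:hi].any():
                break
        else:
            raise ValueError("could not place differential blocks")
        taken[i0 : i0 + block] = True
        p0[i0 : i0 + block] = rng.uniform(0.2, 0.6, size=block)
        delta[i0 : i0 + block] = d
        if d != 0:
            truth_rows.append(
                (
                    "chr1",
                    int(starts[i0]),
                    int(starts[i0 + block - 1]) + 2,
                    block,
                    float(d),
                )
            )

    p_a = np.clip(p0 + delta, 0.01, 0.99)
    p_b = np.clip(p0, 0.01, 0.99)
    prob = nb_size / (nb_size + mean_coverage)
    tables = []
    for p in (p_a, p_b):
        cov = rng.negative_binomial(nb_size, prob, size=n_cpgs)
        meth = rng.binomial(cov, p)
        tables.append(
            pd.DataFrame(
                {
                    "chrom": "chr1",
                    "start": starts.astype(np.int64),
                    "end": (starts + 2).astype(np.int64),
                    "methylated": meth,
                    "total": cov,
                }
            )
        )
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "start", "end", "n_cpgs", "delta"]
    )
    return tables[0], tables[1], truth


def expected_low_coverage_fraction(mean_coverage: float, min_coverage: int = 10, nb_size: float = 5.0) -> float:
    """Closed-form fraction of CpGs below ``min_coverage`` under the coverage model."""
    from scipy import stats

    prob = nb_size / (nb_size + mean_coverage)
    return float(stats.nbinom.cdf(min_coverage - 1, nb_size, prob))


def simulate_stability_series(
    slope: float,
    noise_sd: float,
    n: int,
    seed: int,
    intercept: float = 0.1,
    log10_range: tuple[float, float] = (0.0, 3.0),
) -> tuple[np.ndarray, np.ndarray]:
    """A single probe's beta values across samples with known expansion coupling."""
    rng = np.random.default_rng(int(seed) % (2**31))
    x = np.linspace(log10_range[0], log10_range[1], n)
    beta = intercept + slope * x + rng.normal(0, noise_sd, size=n)
    return np.clip(beta, 0.0, 1.0), 10.0**x


# --- dataset writer ---------------------------------------------------------

def write_dataset(
    world: SimWorld,
    matrix: MethylationMatrix,
    sheet: pd.DataFrame,
    truth: pd.DataFrame,
    outdir,
    wgbs: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame] | None = None,
) -> dict:
    """Write the full synthetic dataset plus a pipeline config; returns the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tio.write_matrix_tsv(matrix.data, outdir / "beta.tsv")
    tio.write_matrix_tsv(matrix.detection_p, outdir / "detection_p.tsv")
    tio.write_table(sheet, outdir / "sample_sheet.tsv")
    tio.write_table(world.manifest, outdir / "manifest.tsv")
    tio.write_table(truth, outdir / "truth.tsv")
    world.gene_model.to_gff3(outdir / "genes.gff3")
    for name, rs in world.region_sets.items():
        tio.write_bed(rs, outdir / f"{name}.bed")
    tio.write_gmt(world.gene_sets, outdir / "gene_sets.gmt")
    if wgbs is None:
        wgbs = simulate_wgbs(
            2000, 30.0, [(10, 0.3), (10, -0.3), (8, 0.25)], seed=child_seed(world.design.seed, 3)
        )
    wgbs_a, wgbs_b, wgbs_truth = wgbs
    tio.write_bs_counts(wgbs_a, outdir / "wgbs_groupA.tsv")
    tio.write_bs_counts(wgbs_b, outdir / "wgbs_groupB.tsv")
    tio.write_table(wgbs_truth, outdir / "wgbs_truth.tsv")

    design_dict = asdict(world.design)
    design_dict["planted_dmrs"] = [asdict(p) for p in world.design.planted_dmrs]
    tio.write_provenance({"design": design_dict}, outdir / "provenance.yaml")

    config = {
        "seed": int(world.design.seed),
        "out_dir": str(outdir / "results"),
        "inputs": {
            "beta_tsv": str(outdir / "beta.tsv"),
            "detection_p_tsv": str(outdir / "detection_p.tsv"),
            "sample_sheet_tsv": str(outdir / "sample_sheet.tsv"),
            "manifest_tsv": str(outdir / "manifest.tsv"),
            "gene_model": str(outdir / "genes.gff3"),
            "pmd_beds": [
                str(outdir / "pmd_CM.bed"),
                str(outdir / "pmd_EM.bed"),
                str(outdir / "pmd_TEMRA.bed"),
                str(outdir / "pmd_Treg.bed"),
            ],
            "tregdr_bed": str(outdir / "tregdr.bed"),
            "states_treg_bed": str(outdir / "states_treg.bed"),
            "states_cd4_bed": str(outdir / "states_cd4mem.bed"),
            "wgbs_a_tsv": str(outdir / "wgbs_groupA.tsv"),
            "wgbs_b_tsv": str(outdir / "wgbs_groupB.tsv"),
            "gene_sets_gmt": str(outdir / "gene_sets.gmt"),
        },
        "params": {},
    }
    tio.write_provenance(config, outdir / "config.yaml")
    return config
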