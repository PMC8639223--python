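"""End-to-end orchestration: preprocessing -> DMPs/DMRs -> annotation ->
kinetics -> signatures -> enrichment, with YAML configuration and
deterministic, provenance-stamped outputs."""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from . import io as tio
from .annotate import annotate_dmr_table, intersect_region_sets, load_gene_model
from .containers import slugify, validate_manifest, validate_sample_sheet
from .diffmeth import Contrast, call_dmrs, dmps_to_dmr_input, fit_dmps
from .enrichment import gsea_preranked, ora_hypergeometric
from .kinetics import (
    classify_shared_kinetics,
    match_shared_dmrs,
    mean_dmr_methylation_track,
    summarize_shared,
)
from .preprocess import (
    combat_adjust,
    drop_sex_chromosomes,
    filter_probes,
    matrix_to_beta,
    matrix_to_m,
    pca_scores,
    quantile_normalize,
)
from .signatures import (
    exh_concordance,
    pmd_median_track,
    stability_table,
    wgbs_dmps,
    wgbs_dmrs,
)

STAGES = ["preprocess", "diffmeth", "annotate", "kinetics", "signatures", "enrichment"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class Params(BaseModel):
    """All tunable thresholds; defaults are the published analysis settings."""

    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    detection_p: float = 0.05
    snp_window: int = 3
    fdr: float = 0.05
    lambda_: float = Field(500.0, alias="lambda")
    C: float = 3.0
    min_cpgs: int = 3
    stouffer: float = 0.05
    shared_overlap: float = 0.5
    wgbs_coverage: int = 10
    r2: float = 0.4
    m_offset: float = 1e-3
    promoter_window: int = 3000
    downstream_window: int = 300
    pca_components: int = 5
    gsea_permutations: int = 200
    reverse_contrasts: bool = False
    quantile_normalize: bool = True

    @field_validator("detection_p", "fdr", "stouffer")
    @classmethod
    def _open_unit(cls, v, info):
        if not 0 < v < 1:
            raise ValueError(f"{info.field_name} must be in (0, 1)")
        return v

    @field_validator("shared_overlap", "r2")
    @classmethod
    def _unit(cls, v, info):
        if not 0 < v <= 1:
            raise ValueError(f"{info.field_name} must be in (0, 1]")
        return v

    @field_validator("snp_window", "min_cpgs", "wgbs_coverage", "promoter_window", "downstream_window")
    @classmethod
    def _nonneg(cls, v, info):
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0")
        return v

    @field_validator("lambda_", "C")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0")
        return v


class Inputs(BaseModel):
    model_config = ConfigDict(extra="forbid")

    beta_tsv: str
    detection_p_tsv: str
    sample_sheet_tsv: str
    manifest_tsv: str
    gene_model: str
    pmd_beds: list[str] = []
    tregdr_bed: str | None = None
    states_treg_bed: str | None = None
    states_cd4_bed: str | None = None
    wgbs_a_tsv: str | None = None
    wgbs_b_tsv: str | None = None
    gene_sets_gmt: str | None = None


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "results"
    inputs: Inputs
    params: Params = Params()

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (inputs, params, seed);
        the output location does not change what is computed."""
        payload = self.model_dump(by_alias=True)
        payload.pop("out_dir", None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def load_config(path, **overrides) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw.update({k: v for k, v in overrides.items() if v is not None and k != "params"})
    if "params" in overrides and overrides["params"]:
        raw.setdefault("params", {}).update(overrides["params"])
    return PipelineConfig(**raw)


class _Logger:
    def __init__(self, path: Path):
        self.path = path
        path.parent.mkdir(parents=True, exist_ok=True)
        self.fh = open(path, "w")

    def log(self, stage: str, **fields):
        rec = json.dumps({"stage": stage, **fields}, sort_keys=True)
        print(rec, file=sys.stderr)
        self.fh.write(rec + "\n")
        self.fh.flush()

    def close(self):
        self.fh.close()


def _header(config: PipelineConfig, convention: str = "0-based half-open") -> list[str]:
    return [
        f"tregmeth {__version__}",
        f"config_hash {config.config_hash()}",
        f"coordinates {convention}",
    ]


def _gene_universe(manifest: pd.DataFrame, model, promoter_window: int) -> list[str]:
    """Genes whose span or promoter window holds >= 1 surviving probe."""
    pts_by_chrom = {
        chrom: np.sort(g["pos"].to_numpy() - 1) for chrom, g in manifest.groupby("chrom")
    }
    names = set()
    for g in model.genes:
        pts = pts_by_chrom.get(g.chrom)
        if pts is None:
            continue
        lo = min(g.start, g.tss - promoter_window)
        hi = max(g.end, g.tss + promoter_window + 1)
        i = np.searchsorted(pts, lo, side="left")
        j = np.searchsorted(pts, hi, side="left")
        if j > i:
            names.add(g.name)
    return sorted(names)


def run_pipeline(config: PipelineConfig, stop_after: str | None = None) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger = _Logger(out / "log.jsonl")
    hdr = _header(config)
    manifest_out: dict = {
        "tool_version": __version__,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    stop_idx = STAGES.index(stop_after) if stop_after else len(STAGES) - 1

    state: dict = {}
    try:
        _load_inputs(config, state)
        for stage in STAGES[: stop_idx + 1]:
            try:
                info = _STAGE_FUNCS[stage](config, state, out, hdr, logger)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(stage, exc) from exc
            manifest_out["stages"][stage] = info
    finally:
        logger.close()
    tio.write_json(manifest_out, out / "run_manifest.json")
    return manifest_out


def _load_inputs(config: PipelineConfig, state: dict) -> None:
    inp = config.inputs
    state["matrix"] = tio.read_methylation(inp.beta_tsv, inp.detection_p_tsv)
    state["sheet"] = validate_sample_sheet(tio.read_table(inp.sample_sheet_tsv), state["matrix"])
    state["manifest"] = validate_manifest(tio.read_table(inp.manifest_tsv))
    state["model"] = load_gene_model(inp.gene_model)
    state["gene_names"] = {g.gene_id: g.name for g in state["model"].genes}
    state["pmd_sets"] = [tio.read_bed(p) for p in inp.pmd_beds]
    state["tregdr"] = tio.read_bed(inp.tregdr_bed) if inp.tregdr_bed else None
    state["states_treg"] = tio.read_bed(inp.states_treg_bed) if inp.states_treg_bed else None
    state["states_cd4"] = tio.read_bed(inp.states_cd4_bed) if inp.states_cd4_bed else None
    state["wgbs_a"] = tio.read_bs_counts(inp.wgbs_a_tsv) if inp.wgbs_a_tsv else None
    state["wgbs_b"] = tio.read_bs_counts(inp.wgbs_b_tsv) if inp.wgbs_b_tsv else None
    state["gene_sets"] = tio.read_gmt(inp.gene_sets_gmt) if inp.gene_sets_gmt else None


def _stage_preprocess(config, state, out, hdr, logger) -> dict:
    par = config.params
    matrix, sheet, manifest = state["matrix"], state["sheet"], state["manifest"]
    n_in = matrix.n_probes
    filtered, report = filter_probes(matrix, manifest, par.detection_p, par.snp_window)
    filtered = drop_sex_chromosomes(filtered, manifest)
    normed = quantile_normalize(filtered) if par.quantile_normalize else filtered
    m_mat = matrix_to_m(normed, par.m_offset)
    batch = sheet.set_index("sample_id").loc[m_mat.sample_ids]
    batch_labels = batch["run"].astype(str)
    if "processing_site" in batch.columns and batch["processing_site"].nunique() > 1:
        batch_labels = batch_labels + "|" + batch["processing_site"].astype(str)
    days = sorted(batch["day"].unique())
    cov_cols = [
        (batch["day"] == d).to_numpy(dtype=float) for d in days[1:]
    ]
    covariates = np.column_stack(cov_cols) if cov_cols else None
    adjusted = combat_adjust(m_mat, batch_labels.to_numpy(), covariates)
    beta_adj = matrix_to_beta(adjusted)
    n_comp = min(par.pca_components, adjusted.n_samples - 1)
    scores, varfrac = pca_scores(adjusted, n_comp)
    tio.write_table(report, out / "preprocess" / "filter_report.tsv", hdr)
    pca_df = scores.reset_index(names="sample_id")
    tio.write_table(pca_df, out / "preprocess" / "pca_scores.tsv", hdr)
    tio.write_table(
        pd.DataFrame({"component": pca_df.columns[1:], "variance_fraction": varfrac}),
        out / "preprocess" / "pca_variance.tsv",
        hdr,
    )
    tio.write_matrix_tsv(adjusted.data, out / "preprocess" / "m_adjusted.tsv", hdr)
    state["m_adj"] = adjusted
    state["beta_adj"] = beta_adj
    state["manifest_kept"] = manifest[manifest["probe_id"].isin(set(adjusted.probe_ids))].reset_index(drop=True)
    info = {"probes_in": int(n_in), "probes_out": int(adjusted.n_probes)}
    logger.log("preprocess", **info)
    return info


def _contrast_cells(sheet: pd.DataFrame) -> pd.DataFrame:
    if (sheet["cell_type"] == "TregProduct").any():
        return sheet[sheet["cell_type"] == "TregProduct"]
    return sheet


def _stage_diffmeth(config, state, out, hdr, logger) -> dict:
    par = config.params
    sheet = _contrast_cells(state["sheet"])
    m_adj, beta_adj = state["m_adj"], state["beta_adj"]
    days = sorted(sheet["day"].unique())
    runs = sorted(sheet["run"].unique())
    state["dmps"], state["dmrs"] = {}, {}
    counts = {}
    for run in runs:
        sub = sheet[sheet["run"] == run]
        day0 = list(sub.loc[sub["day"] == 0, "sample_id"])
        for day in days[1:]:
            dayx = list(sub.loc[sub["day"] == day, "sample_id"])
            if len(day0) < 2 or len(dayx) < 2:
                continue
            group_a, group_b = (day0, dayx) if par.reverse_contrasts else (dayx, day0)
            name = f"{run}_day{day}_vs_day0" if not par.reverse_contrasts else f"{run}_day0_vs_day{day}"
            block = dict(zip(sub["sample_id"], sub["donor"]))
            contrast = Contrast(name, group_a, group_b, block)
            dmps = fit_dmps(
                m_adj.subset_samples(contrast.samples),
                beta_adj.subset_samples(contrast.samples),
                contrast,
                state["manifest_kept"],
                par.fdr,
            )
            dmrs = call_dmrs(
                dmps_to_dmr_input(dmps),
                lambda_=par.lambda_,
                C=par.C,
                min_cpgs=par.min_cpgs,
                stouffer_threshold=par.stouffer,
                fdr_threshold=par.fdr,
            )
            state["dmps"][(run, day)] = dmps
            state["dmrs"][(run, day)] = dmrs
            tag = slugify(name)
            tio.write_table(dmps, out / "diffmeth" / f"dmps_{tag}.tsv", hdr)
            dmr_out = dmrs.copy()
            dmr_out["probes"] = dmr_out["probes"].map(lambda t: ",".join(t))
            tio.write_table(dmr_out, out / "diffmeth" / f"dmrs_{tag}.tsv", hdr)
            tio.write_dmrs_bed6(dmrs, out / "diffmeth" / f"dmrs_{tag}.bed", name)
            counts[name] = {
                "dmps_significant": int(dmps["significant"].sum()),
                "dmrs": int(len(dmrs)),
            }
    logger.log("diffmeth", **{k: v for k, v in counts.items()})
    return counts


def _stage_annotate(config, state, out, hdr, logger) -> dict:
    par = config.params
    model, names = state["model"], state["gene_names"]
    kwargs = dict(
        promoter_up=par.promoter_window,
        promoter_down=par.promoter_window,
        downstream_window=par.downstream_window,
    )
    info = {}
    for key, dmrs in state["dmrs"].items():
        if not len(dmrs):
            state["dmrs"][key] = dmrs.assign(feature=None, gene_id=None, distance_to_tss=None)
            continue
        ann = annotate_dmr_table(dmrs, model, names, **kwargs)
        state["dmrs"][key] = ann
        info[f"{key[0]}_day{key[1]}"] = ann["feature"].value_counts().to_dict()
    logger.log("annotate", **info)
    return info


def _stage_kinetics(config, state, out, hdr, logger) -> dict:
    par = config.params
    sheet = _contrast_cells(state["sheet"])
    days = sorted(sheet["day"].unique())
    runs = sorted(sheet["run"].unique())
    info: dict = {}
    if len(runs) < 2 or len(days) < 3:
        state["shared"] = pd.DataFrame()
        logger.log("kinetics", skipped="need >= 2 runs and >= 3 days")
        return {"skipped": True}
    mid, final = days[1], days[-1]
    r1, r2 = runs[0], runs[1]
    empty = state["dmrs"].get((r1, final), pd.DataFrame())
    shared, discordant = match_shared_dmrs(
        state["dmrs"].get((r1, final), empty),
        state["dmrs"].get((r2, final), empty),
        min_fraction=par.shared_overlap,
    )
    shared = classify_shared_kinetics(
        shared,
        state["dmrs"].get((r1, mid), empty),
        state["dmrs"].get((r1, final), empty),
        state["dmrs"].get((r2, mid), empty),
        state["dmrs"].get((r2, final), empty),
        min_fraction=par.shared_overlap,
    )
    if len(shared):
        shared = annotate_dmr_table(
            shared,
            state["model"],
            state["gene_names"],
            promoter_up=par.promoter_window,
            promoter_down=par.promoter_window,
            downstream_window=par.downstream_window,
        )
    state["shared"] = shared
    summary = summarize_shared(shared)
    track = mean_dmr_methylation_track(
        state["beta_adj"].data, shared, state["manifest_kept"], sheet
    )
    tio.write_table(shared, out / "kinetics" / "shared_dmrs.tsv", hdr)
    tio.write_table(track, out / "kinetics" / "dmr_methylation_track.tsv", hdr)
    summary_json = {
        "n_shared": summary["n_shared"],
        "discordant_direction_pairs": discordant,
        "by_direction": summary["by_direction"]["count"].to_dict(),
        "kinetics_discordant_fraction": summary.get("kinetics_discordant_fraction"),
    }
    if "by_kinetics" in summary:
        summary_json["by_kinetics"] = summary["by_kinetics"]["count"].to_dict()
    tio.write_json(summary_json, out / "kinetics" / "summary.json")
    logger.log("kinetics", **summary_json)
    return summary_json


def _stage_signatures(config, state, out, hdr, logger) -> dict:
    from scipy import stats as sps

    par = config.params
    info: dict = {}
    sheet = state["sheet"]
    if len(state["pmd_sets"]) >= 2:
        pmd_core = intersect_region_sets(state["pmd_sets"], "pmd_core")
    elif state["pmd_sets"]:
        pmd_core = state["pmd_sets"][0]
    else:
        pmd_core = None
    if pmd_core is not None and len(pmd_core):
        track = pmd_median_track(state["beta_adj"].data, pmd_core, state["manifest_kept"], sheet)
        tio.write_table(track, out / "signatures" / "pmd_median_track.tsv", hdr)
        moving = track[track["log10_expansion"] > 0]
        if len(moving) >= 3:
            rho = sps.spearmanr(track["median_pmd_beta"], track["log10_expansion"]).statistic
            info["pmd_expansion_spearman"] = float(rho)
    if state["tregdr"] is not None and len(state["tregdr"]):
        stab = stability_table(
            state["beta_adj"].data,
            state["manifest_kept"],
            state["tregdr"],
            sheet,
            cell_type="Treg",
            r2_threshold=par.r2,
        )
        tio.write_table(stab, out / "signatures" / "tregdr_stability.tsv", hdr)
        info["tregdr_cpgs"] = int(len(stab))
        info["tregdr_destabilized"] = int(stab["classified_destabilized"].sum())
    if state["wgbs_a"] is not None and state["wgbs_b"] is not None:
        dmps = wgbs_dmps(state["wgbs_a"], state["wgbs_b"], par.wgbs_coverage)
        exh = wgbs_dmrs(
            dmps, par.lambda_, par.C, par.min_cpgs, par.stouffer, par.fdr
        )
        tio.write_table(dmps, out / "signatures" / "wgbs_dmps.tsv", hdr)
        exh_out = exh.copy()
        exh_out["probes"] = exh_out["probes"].map(lambda t: ",".join(t))
        tio.write_table(exh_out, out / "signatures" / "exhdmrs.tsv", hdr)
        tio.write_dmrs_bed6(exh, out / "signatures" / "exhdmrs.bed", "exhDMR")
        info["wgbs_cpgs_tested"] = int(len(dmps))
        info["exhdmrs"] = int(len(exh))
        shared = state.get("shared", pd.DataFrame())
        if len(shared) and "kinetic_run1" in shared.columns:
            late = shared[(shared["kinetic_run1"] == "late") & (shared["kinetic_run2"] == "late")]
            table, summary = exh_concordance(late, exh, par.shared_overlap)
            tio.write_table(table, out / "signatures" / "exh_concordance.tsv", hdr)
            tio.write_json(summary, out / "signatures" / "exh_concordance_summary.json")
            info["exh_overlap_fraction"] = summary["overlap_fraction"]
    logger.log("signatures", **info)
    return info


def _stage_enrichment(config, state, out, hdr, logger) -> dict:
    par = config.params
    info: dict = {}
    if state["gene_sets"] is None:
        logger.log("enrichment", skipped="no gene sets provided")
        return {"skipped": True}
    universe = _gene_universe(state["manifest_kept"], state["model"], par.promoter_window)
    shared = state.get("shared", pd.DataFrame())
    if len(shared) and "gene_name" in shared.columns:
        query = sorted({g for g in shared["gene_name"].dropna() if g in set(universe)})
    else:
        query = []
    if query:
        ora = ora_hypergeometric(query, universe, state["gene_sets"], par.fdr)
        tio.write_table(ora, out / "enrichment" / "ora_shared_dmrs.tsv", hdr)
        info["ora_terms_significant"] = int(ora["significant"].sum()) if len(ora) else 0
    scores = pd.Series(0.0, index=pd.Index(universe, name="gene"))
    if len(shared) and "gene_name" in shared.columns:
        per_gene = shared.groupby("gene_name")["mean_delta"].mean()
        for g, v in per_gene.items():
            if g in scores.index:
                scores[g] = v
    gsea = gsea_preranked(
        scores,
        state["gene_sets"],
        n_permutations=par.gsea_permutations,
        seed=config.seed,
        weight=1.0,
    )
    tio.write_table(gsea, out / "enrichment" / "gsea_preranked.tsv", hdr)
    info["gsea_sets_tested"] = int(len(gsea))
    logger.log("enrichment", **info)
    return info


_STAGE_FUNCS = {
    "preprocess": _stage_preprocess,
    "diffmeth": _stage_diffmeth,
    "annotate": _stage_annotate,
    "kinetics": _stage_kinetics,
    "signatures": _stage_signatures,
    "enrichment": _stage_enrichment,
}
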