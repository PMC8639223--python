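"""Core in-memory containers shared across the pipeline.

Coordinates are 0-based half-open everywhere internally.  Array manifests
carry a 1-based ``pos`` column (the convention of Infinium manifests); the
conversion to a 0-based point (``pos - 1``) happens exactly once, in
:func:`tregmeth.annotate.probes_in_regions` and friends.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BETA_SCALE = "beta"
M_SCALE = "M"

MANIFEST_COLUMNS = [
    "probe_id",
    "chrom",
    "pos",
    "snp_distance",
    "cross_reactive",
    "dropped_by_vendor",
]

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "donor",
    "run",
    "day",
    "cell_type",
    "cumulative_expansion_rate",
]


def normalize_chrom(chrom: str) -> str:
    """Canonicalize chromosome labels: ``1``/``chr1`` -> ``chr1``, ``x`` -> ``chrX``."""
    s = str(chrom).strip()
    core = s[3:] if s.lower().startswith("chr") else s
    if core.upper() in {"X", "Y", "M", "MT"}:
        core = core.upper()
    return f"chr{core}"


_SEX_CHROMS = {"chrX", "chrY"}


def is_sex_chrom(chrom: str) -> bool:
    return normalize_chrom(chrom) in _SEX_CHROMS


@dataclass
class MethylationMatrix:
    """Probes x samples methylation matrix on the beta or M scale.

    Parameters
    ----------
    data
        DataFrame indexed by probe id, columns are sample ids.
    scale
        ``"beta"`` (values in [0, 1]) or ``"M"`` (logit2 values).
    detection_p
        Optional matching detection p-value matrix (values in (0, 1]).
    """

    data: pd.DataFrame
    scale: str = BETA_SCALE
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in (BETA_SCALE, M_SCALE):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate probe ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.scale == BETA_SCALE:
            vals = self.data.to_numpy()
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("beta-scale values outside [0, 1]")
        if self.detection_p is not None:
            if not self.detection_p.index.equals(self.data.index) or not (
                self.detection_p.columns.equals(self.data.columns)
            ):
                raise ValueError("detection_p not aligned with data")

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_probes(self, probe_ids) -> "MethylationMatrix":
        detp = None if self.detection_p is None else self.detection_p.loc[probe_ids]
        return MethylationMatrix(self.data.loc[probe_ids], self.scale, detp)

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        detp = None if self.detection_p is None else self.detection_p[list(sample_ids)]
        return MethylationMatrix(self.data[list(sample_ids)], self.scale, detp)

    def copy(self) -> "MethylationMatrix":
        detp = None if self.detection_p is None else self.detection_p.copy()
        return MethylationMatrix(self.data.copy(), self.scale, detp)


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("probe_id", "chrom", "pos") if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    if (manifest["pos"] < 1).any():
        raise ValueError("manifest pos must be 1-based (>= 1)")
    out = manifest.copy()
    out["chrom"] = out["chrom"].map(normalize_chrom)
    for col, default in (
        ("snp_distance", np.nan),
        ("cross_reactive", False),
        ("dropped_by_vendor", False),
    ):
        if col not in out.columns:
            out[col] = default
    return out


def validate_sample_sheet(sheet: pd.DataFrame, matrix: MethylationMatrix | None = None) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns {missing}")
    if (sheet["day"] < 0).any():
        raise ValueError("day must be >= 0")
    if (sheet["cumulative_expansion_rate"] <= 0).any():
        raise ValueError("cumulative_expansion_rate must be positive")
    if matrix is not None:
        absent = set(matrix.sample_ids) - set(sheet["sample_id"])
        if absent:
            raise ValueError(f"samples missing from sheet: {sorted(absent)}")
    return sheet


@dataclass
class RegionSet:
    """Named collection of genomic intervals in 0-based half-open coordinates."""

    name: str
    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "label"]))

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "label" not in df.columns:
            df["label"] = "."
        df = df[["chrom", "start", "end", "label"]]
        if len(df):
            if (df["start"] >= df["end"]).any():
                raise ValueError(f"region set {self.name!r}: start must be < end")
            df["chrom"] = df["chrom"].map(normalize_chrom)
            df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
            df["start"] = df["start"].astype(np.int64)
            df["end"] = df["end"].astype(np.int64)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def by_chrom(self) -> dict[str, pd.DataFrame]:
        return {str(c): g for c, g in self.df.groupby("chrom", sort=True)}

    def total_bp(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())


# --- differential methylation result frames ---------------------------------

DMP_COLUMNS = [
    "probe_id", "chrom", "pos", "delta_beta", "t_mod", "p", "fdr", "significant",
]

DMR_COLUMNS = [
    "chrom", "start", "end", "n_cpgs", "mean_delta_beta", "max_delta_beta",
    "stouffer_p", "direction", "probes",
]


@dataclass(frozen=True)
class FeatureCall:
    """A single genomic-feature assignment for a position or region."""

    feature: str
    gene_id: str | None
    distance_to_tss: int | None
    flagged: bool = False


FEATURE_PRIORITY = [
    "promoter",
    "five_utr",
    "three_utr",
    "exon",
    "intron",
    "downstream",
    "distal_intergenic",
]


_slug_re = re.compile(r"[^A-Za-z0-9_.-]+")


def slugify(name: str) -> str:
    """File-system safe token for contrast/run names."""
    return _slug_re.sub("_", str(name))
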