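"""Readers and writers for the plain-text formats used by the pipeline.

All tabular outputs are TSV.  BED files are 0-based half-open, GFF3 is
1-based inclusive, array manifests carry a 1-based ``pos`` column; each
reader converts to the internal 0-based half-open convention on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import MethylationMatrix, RegionSet, validate_manifest

FLOAT_FORMAT = "%.8g"


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return pd.read_csv(path, sep="\t", comment="#")


def write_matrix_tsv(matrix: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        matrix.to_csv(fh, sep="\t", index_label="probe_id", float_format=FLOAT_FORMAT)


def read_matrix_tsv(path) -> pd.DataFrame:
    df = _read_tsv(path)
    return df.set_index("probe_id")


def read_methylation(beta_path, detection_p_path=None) -> MethylationMatrix:
    beta = read_matrix_tsv(beta_path)
    detp = read_matrix_tsv(detection_p_path) if detection_p_path else None
    return MethylationMatrix(beta, "beta", detp)


def write_table(df: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


read_table = _read_tsv


def read_manifest(path) -> pd.DataFrame:
    return validate_manifest(_read_tsv(path))


# --- BED --------------------------------------------------------------------

def write_bed(regions: RegionSet, path, scores=None) -> None:
    """Write as BED4 (chrom, start, end, label); coordinates stay 0-based half-open."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = regions.df.copy()
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.label}\n")


def read_bed(path, name: str | None = None) -> RegionSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: malformed BED record")
            label = parts[3] if len(parts) > 3 else "."
            rows.append((parts[0], int(parts[1]), int(parts[2]), label))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return RegionSet(name or path.stem, df)


def write_dmrs_bed6(dmrs: pd.DataFrame, path, contrast_name: str) -> None:
    """BED6 export: name = contrast|direction, score = -log10 Stouffer p."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for _, row in dmrs.iterrows():
            score = -np.log10(max(float(row.stouffer_p), 1e-300))
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t"
                f"{contrast_name}|{row.direction}\t{score:.4f}\t.\n"
            )


# --- WGBS count tables ------------------------------------------------------

def write_bs_counts(counts: pd.DataFrame, path) -> None:
    """bedGraph-like TSV: chrom, start, end, methylated, total (0-based half-open)."""
    write_table(counts[["chrom", "start", "end", "methylated", "total"]], path)


def read_bs_counts(path) -> pd.DataFrame:
    df = _read_tsv(path)
    need = {"chrom", "start", "end", "methylated", "total"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    if ((df["methylated"] < 0) | (df["methylated"] > df["total"])).any():
        raise ValueError(f"{path}: methylated counts outside [0, total]")
    return df


# --- gene sets (GMT) --------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for term, genes in sets.items():
            fh.write("\t".join([term, term] + list(genes)) + "\n")


# --- provenance -------------------------------------------------------------

def write_provenance(params: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
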