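"""Genomic annotation: gene models, feature assignment, and interval algebra.

Feature assignment follows the peak-annotation convention: one feature per
query, resolved by the priority order promoter > 5'UTR > 3'UTR > exon >
intron > downstream > distal intergenic, with ties across genes broken by
the smallest absolute distance to a TSS.  The promoter window (TSS +/- 3 kb)
and the immediate-downstream window (300 bp past the gene 3' end) are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FEATURE_PRIORITY, FeatureCall, RegionSet, normalize_chrom

_PRIORITY = {f: i for i, f in enumerate(FEATURE_PRIORITY)}


@dataclass(frozen=True)
class Gene:
    """One gene in 0-based half-open coordinates; ``tss`` is a 0-based point."""

    gene_id: str
    name: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()
    five_utr: tuple[tuple[int, int], ...] = ()
    three_utr: tuple[tuple[int, int], ...] = ()

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: empty span")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon outside span")


@dataclass
class GeneModel:
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self):
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(normalize_chrom(g.chrom), []).append(g)

    def genes_on(self, chrom: str) -> list[Gene]:
        return self._by_chrom.get(normalize_chrom(chrom), [])

    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    def to_gff3(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                attrs = f"ID={g.gene_id};Name={g.name}"
                fh.write(
                    f"{g.chrom}\tsynth\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                tid = f"{g.gene_id}.t1"
                fh.write(
                    f"{g.chrom}\tsynth\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={tid};Parent={g.gene_id}\n"
                )
                for ftype, ivals in (
                    ("exon", g.exons),
                    ("five_prime_UTR", g.five_utr),
                    ("three_prime_UTR", g.three_utr),
                ):
                    for s, e in ivals:
                        fh.write(
                            f"{g.chrom}\tsynth\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                            f"Parent={tid}\n"
                        )


def _validate_gff3_lines(path: Path) -> None:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{i}: malformed GFF3 record (expected 9 fields)")
            try:
                s, e = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: non-integer coordinates") from exc
            if s < 1 or e < s:
                raise ValueError(f"{path}:{i}: invalid coordinate range {s}..{e}")


def _load_gff3(path: Path) -> GeneModel:
    import gffutils

    _validate_gff3_lines(path)
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        exons, five, three = [], [], []
        for child in db.children(feat.id):
            ival = (child.start - 1, child.end)  # GFF3 is 1-based inclusive
            if child.featuretype == "exon":
                exons.append(ival)
            elif child.featuretype == "five_prime_UTR":
                five.append(ival)
            elif child.featuretype == "three_prime_UTR":
                three.append(ival)
        name = feat.attributes.get("Name", [feat.id])[0]
        genes.append(
            Gene(
                gene_id=feat.id,
                name=name,
                chrom=feat.seqid,
                strand=feat.strand,
                start=feat.start - 1,
                end=feat.end,
                exons=tuple(sorted(exons)),
                five_utr=tuple(sorted(five)),
                three_utr=tuple(sorted(three)),
            )
        )
    return GeneModel(genes)


def _load_bed12(path: Path) -> GeneModel:
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{i}: malformed BED12 record (expected 12 fields)")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5]
            thick_s, thick_e = int(parts[6]), int(parts[7])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + sz) for o, sz in zip(offsets, sizes))
            five, three = [], []
            for es, ee in exons:
                left = (max(es, start), min(ee, thick_s))
                right = (max(es, thick_e), min(ee, end))
                for (us, ue), side in ((left, "left"), (right, "right")):
                    if ue > us:
                        is_five = (side == "left") == (strand == "+")
                        (five if is_five else three).append((us, ue))
            genes.append(
                Gene(
                    gene_id=name,
                    name=name,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                    five_utr=tuple(five),
                    three_utr=tuple(three),
                )
            )
    return GeneModel(genes)


def load_gene_model(path, format: str | None = None) -> GeneModel:
    """Load a gene model from GFF3 (1-based inclusive) or BED12 (0-based half-open)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene model not found: {path}")
    if format is None:
        format = "BED12" if path.suffix.lower() in (".bed", ".bed12") else "GFF3"
    fmt = format.upper()
    if fmt == "GFF3":
        return _load_gff3(path)
    if fmt == "BED12":
        return _load_bed12(path)
    raise ValueError(f"unknown gene model format {format!r}")


# --- feature assignment -----------------------------------------------------

def _point_in(pos: int, intervals) -> bool:
    return any(s <= pos < e for s, e in intervals)


def _gene_feature_at(
    gene: Gene, pos: int, promoter_up: int, promoter_down: int, downstream_window: int
) -> str | None:
    if gene.strand == "+":
        dist = pos - gene.tss
        downstream = gene.end <= pos < gene.end + downstream_window
    else:
        dist = gene.tss - pos
        downstream = gene.start - downstream_window <= pos < gene.start
    if -promoter_up <= dist <= promoter_down:
        return "promoter"
    if gene.start <= pos < gene.end:
        if _point_in(pos, gene.five_utr):
            return "five_utr"
        if _point_in(pos, gene.three_utr):
            return "three_utr"
        if _point_in(pos, gene.exons):
            return "exon"
        return "intron"
    if downstream:
        return "downstream"
    return None


def _signed_tss_distance(gene: Gene, pos: int) -> int:
    return pos - gene.tss if gene.strand == "+" else gene.tss - pos


def annotate_position(
    chrom: str,
    pos: int,
    model: GeneModel,
    promoter_up: int = 3000,
    promoter_down: int = 3000,
    downstream_window: int = 300,
) -> FeatureCall:
    """Assign exactly one genomic feature to a 0-based point position."""
    genes = model.genes_on(chrom)
    if not genes:
        return FeatureCall("distal_intergenic", None, None, flagged=True)
    candidates = []
    for g in genes:
        feat = _gene_feature_at(g, pos, promoter_up, promoter_down, downstream_window)
        if feat is not None:
            candidates.append((g, feat))
    if candidates:
        g, feat = min(
            candidates, key=lambda c: (_PRIORITY[c[1]], abs(_signed_tss_distance(c[0], pos)), c[0].gene_id)
        )
        return FeatureCall(feat, g.gene_id, _signed_tss_distance(g, pos))
    nearest = min(genes, key=lambda g: (abs(_signed_tss_distance(g, pos)), g.gene_id))
    return FeatureCall("distal_intergenic", nearest.gene_id, _signed_tss_distance(nearest, pos))


def annotate_region(
    chrom: str,
    start: int,
    end: int,
    model: GeneModel,
    mode: str = "midpoint",
    promoter_up: int = 3000,
    promoter_down: int = 3000,
    downstream_window: int = 300,
) -> FeatureCall:
    """Annotate a region by its midpoint (default) or by best-priority overlap."""
    if mode == "midpoint":
        return annotate_position(
            chrom, (start + end) // 2, model, promoter_up, promoter_down, downstream_window
        )
    if mode != "any_overlap":
        raise ValueError(f"unknown mode {mode!r}")
    genes = model.genes_on(chrom)
    if not genes:
        return FeatureCall("distal_intergenic", None, None, flagged=True)
    mid = (start + end) // 2
    candidates = []
    for g in genes:
        if g.strand == "+":
            prom = (g.tss - promoter_up, g.tss + promoter_down + 1)
            down = (g.end, g.end + downstream_window)
        else:
            prom = (g.tss - promoter_down, g.tss + promoter_up + 1)
            down = (g.start - downstream_window, g.start)
        pieces = [("promoter", [prom])]
        pieces += [("five_utr", g.five_utr), ("three_utr", g.three_utr), ("exon", g.exons)]
        pieces += [("intron", [(g.start, g.end)]), ("downstream", [down])]
        for feat, ivals in pieces:
            if any(max(start, s) < min(end, e) for s, e in ivals):
                candidates.append((g, feat))
                break  # pieces are listed in priority order for this gene
    if candidates:
        g, feat = min(
            candidates, key=lambda c: (_PRIORITY[c[1]], abs(_signed_tss_distance(c[0], mid)), c[0].gene_id)
        )
        return FeatureCall(feat, g.gene_id, _signed_tss_distance(g, mid))
    nearest = min(genes, key=lambda g: (abs(_signed_tss_distance(g, mid)), g.gene_id))
    return FeatureCall("distal_intergenic", nearest.gene_id, _signed_tss_distance(nearest, mid))


def annotate_dmr_table(
    dmrs: pd.DataFrame, model: GeneModel, gene_names: dict[str, str] | None = None, **kwargs
) -> pd.DataFrame:
    """Add feature/gene_id/distance_to_tss columns to a DMR table."""
    calls = [
        annotate_region(row.chrom, int(row.start), int(row.end), model, **kwargs)
        for row in dmrs.itertuples()
    ]
    out = dmrs.copy()
    out["feature"] = [c.feature for c in calls]
    out["gene_id"] = [c.gene_id for c in calls]
    out["distance_to_tss"] = [c.distance_to_tss for c in calls]
    if gene_names:
        out["gene_name"] = out["gene_id"].map(lambda g: gene_names.get(g, g))
    return out


# --- interval algebra -------------------------------------------------------

def overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Fraction of interval ``a`` covered by interval ``b`` (same chromosome)."""
    a_start, a_end = a
    if a_end <= a_start:
        raise ValueError("zero-length interval a")
    inter = max(0, min(a_end, b[1]) - max(a_start, b[0]))
    return inter / (a_end - a_start)


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent sorted/unsorted intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _intersect_pair(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect_region_sets(sets: list[RegionSet], name: str = "intersection") -> RegionSet:
    """Base-pair-level intersection across all sets; adjacent intervals merged."""
    if len(sets) < 2:
        raise ValueError("need at least 2 region sets")
    per_chrom: list[dict[str, list[tuple[int, int]]]] = []
    for rs in sets:
        d = {
            chrom: merge_intervals(list(zip(g["start"], g["end"])))
            for chrom, g in rs.by_chrom().items()
        }
        per_chrom.append(d)
    common = set(per_chrom[0])
    for d in per_chrom[1:]:
        common &= set(d)
    rows = []
    for chrom in sorted(common):
        acc = per_chrom[0][chrom]
        for d in per_chrom[1:]:
            acc = _intersect_pair(acc, d[chrom])
        for s, e in merge_intervals(acc):
            rows.append((chrom, s, e, "."))
    return RegionSet(name, pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


def probes_in_regions(manifest: pd.DataFrame, regions: RegionSet) -> list[str]:
    """Probe ids whose CpG point (1-based ``pos`` - 1) lies inside any interval."""
    hits = _probe_hit_mask(manifest, regions)
    return list(manifest.loc[hits, "probe_id"])


def _probe_hit_mask(manifest: pd.DataFrame, regions: RegionSet) -> np.ndarray:
    by_chrom = {
        chrom: merge_intervals(list(zip(g["start"], g["end"])))
        for chrom, g in regions.by_chrom().items()
    }
    chroms = manifest["chrom"].map(normalize_chrom).to_numpy()
    points = manifest["pos"].to_numpy() - 1
    mask = np.zeros(len(manifest), dtype=bool)
    for chrom, ivals in by_chrom.items():
        sel = chroms == chrom
        if not sel.any() or not ivals:
            continue
        starts = np.array([s for s, _ in ivals])
        ends = np.array([e for _, e in ivals])
        idx = np.searchsorted(starts, points[sel], side="right") - 1
        ok = (idx >= 0) & (points[sel] < ends[np.clip(idx, 0, None)])
        mask[np.flatnonzero(sel)[ok]] = True
    return mask


def region_labels_at(manifest: pd.DataFrame, regions: RegionSet, default: str = "unannotated") -> pd.Series:
    """Label of the (non-overlapping) interval containing each probe's CpG point."""
    chroms = manifest["chrom"].map(normalize_chrom).to_numpy()
    points = manifest["pos"].to_numpy() - 1
    labels = np.full(len(manifest), default, dtype=object)
    for chrom, g in regions.by_chrom().items():
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        labs = g["label"].to_numpy()
        idx = np.searchsorted(starts, points[sel], side="right") - 1
        ok = (idx >= 0) & (points[sel] < ends[np.clip(idx, 0, None)])
        target = np.flatnonzero(sel)[ok]
        labels[target] = labs[idx[ok]]
    return pd.Series(labels, index=manifest["probe_id"].to_numpy(), name="state")
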