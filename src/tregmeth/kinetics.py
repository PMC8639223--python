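"""Cross-run shared-DMR matching and Early/Late kinetic classification.

A run-1 DMR is "shared" when run-2 DMRs of the same direction cover at least
half of its length; it is matched to the single largest contributor.  A DMR
is "Early" when a matching region (>= 50% overlap, same direction) exists in
the day10-vs-day0 contrast and the day23-vs-day0 contrast of the same run,
and "Late" when it appears only in the day23-vs-day0 contrast.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .annotate import merge_intervals, probes_in_regions
from .containers import RegionSet


def _covered_fraction(start: int, end: int, others: pd.DataFrame) -> float:
    ivals = [
        (max(start, s), min(end, e))
        for s, e in zip(others["start"], others["end"])
        if min(end, e) > max(start, s)
    ]
    if not ivals:
        return 0.0
    covered = sum(e - s for s, e in merge_intervals(ivals))
    return covered / (end - start)


def match_shared_dmrs(
    run1_dmrs: pd.DataFrame,
    run2_dmrs: pd.DataFrame,
    min_fraction: float = 0.5,
    symmetric: bool = False,
) -> tuple[pd.DataFrame, int]:
    """Match run-1 DMRs to run-2 DMRs by fractional overlap.

    The covered fraction is computed on the run-1 DMR's length (the union of
    all overlapping run-2 DMRs counts toward coverage); with
    ``symmetric=True`` the same-fraction requirement is applied on both
    sides of the best pair.  Direction-discordant matches are excluded and
    counted separately.  Returns ``(shared table, discordant count)``.
    """
    records = []
    discordant = 0
    r2_by_chrom = dict(tuple(run2_dmrs.groupby("chrom"))) if len(run2_dmrs) else {}
    for row in run1_dmrs.itertuples():
        cands = r2_by_chrom.get(row.chrom)
        if cands is None:
            continue
        frac = _covered_fraction(row.start, row.end, cands)
        if frac < min_fraction:
            continue
        inter = np.minimum(row.end, cands["end"]) - np.maximum(row.start, cands["start"])
        best_idx = int(np.argmax(inter.to_numpy()))
        best = cands.iloc[best_idx]
        if symmetric:
            back = _covered_fraction(int(best.start), int(best.end), run1_dmrs[run1_dmrs["chrom"] == row.chrom])
            if back < min_fraction:
                continue
        if best.direction != row.direction:
            discordant += 1
            continue
        records.append(
            {
                "chrom": row.chrom,
                "start": int(min(row.start, best.start)),
                "end": int(max(row.end, best.end)),
                "run1_start": int(row.start),
                "run1_end": int(row.end),
                "run2_start": int(best.start),
                "run2_end": int(best.end),
                "direction": row.direction,
                "overlap_fraction": float(frac),
                "run1_delta": float(row.mean_delta_beta),
                "run2_delta": float(best.mean_delta_beta),
                "mean_delta": float((row.mean_delta_beta + best.mean_delta_beta) / 2),
                "run1_stouffer_p": float(row.stouffer_p),
                "run2_stouffer_p": float(best.stouffer_p),
            }
        )
    cols = [
        "chrom", "start", "end", "run1_start", "run1_end", "run2_start", "run2_end",
        "direction", "overlap_fraction", "run1_delta", "run2_delta", "mean_delta",
        "run1_stouffer_p", "run2_stouffer_p",
    ]
    return pd.DataFrame(records, columns=cols), discordant


def _in_dmr_set(
    chrom: str, start: int, end: int, direction: str, dmr_set: pd.DataFrame, min_fraction: float
) -> bool:
    if not len(dmr_set):
        return False
    cands = dmr_set[(dmr_set["chrom"] == chrom) & (dmr_set["direction"] == direction)]
    if not len(cands):
        return False
    return _covered_fraction(start, end, cands) >= min_fraction


def classify_kinetics(
    dmr,
    sig_day10_vs_day0: pd.DataFrame,
    sig_day23_vs_day0: pd.DataFrame,
    min_fraction: float = 0.5,
) -> str:
    """Early/Late/none classification of one DMR against the two contrasts.

    early: present (>= ``min_fraction`` overlap, same direction) in both the
    day10-vs-day0 and day23-vs-day0 DMR sets; late: present only in
    day23-vs-day0; none otherwise.
    """
    chrom, start, end, direction = dmr["chrom"], int(dmr["start"]), int(dmr["end"]), dmr["direction"]
    in10 = _in_dmr_set(chrom, start, end, direction, sig_day10_vs_day0, min_fraction)
    in23 = _in_dmr_set(chrom, start, end, direction, sig_day23_vs_day0, min_fraction)
    if in10 and in23:
        return "early"
    if in23:
        return "late"
    return "none"


def classify_shared_kinetics(
    shared: pd.DataFrame,
    run1_day10: pd.DataFrame,
    run1_day23: pd.DataFrame,
    run2_day10: pd.DataFrame,
    run2_day23: pd.DataFrame,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Attach per-run kinetic labels and a consistency flag to a shared-DMR table."""
    out = shared.copy()
    k1, k2 = [], []
    for row in shared.itertuples():
        d1 = {"chrom": row.chrom, "start": row.run1_start, "end": row.run1_end, "direction": row.direction}
        d2 = {"chrom": row.chrom, "start": row.run2_start, "end": row.run2_end, "direction": row.direction}
        k1.append(classify_kinetics(d1, run1_day10, run1_day23, min_fraction))
        k2.append(classify_kinetics(d2, run2_day10, run2_day23, min_fraction))
    out["kinetic_run1"] = k1
    out["kinetic_run2"] = k2
    out["consistent_kinetics"] = out["kinetic_run1"] == out["kinetic_run2"]
    return out


def summarize_shared(shared: pd.DataFrame) -> dict:
    """Counts and fractions by direction, kinetic consistency and feature."""
    n = len(shared)
    def _tab(col):
        counts = shared[col].value_counts().sort_index() if n else pd.Series(dtype=int)
        return pd.DataFrame({"count": counts, "fraction": counts / n if n else counts})

    out = {"n_shared": n, "by_direction": _tab("direction")}
    if "kinetic_run1" in shared.columns:
        combo = shared["kinetic_run1"] + "/" + shared["kinetic_run2"]
        counts = combo.value_counts().sort_index()
        out["by_kinetics"] = pd.DataFrame({"count": counts, "fraction": counts / n if n else counts})
        out["kinetics_discordant_fraction"] = (
            float((shared["kinetic_run1"] != shared["kinetic_run2"]).mean()) if n else float("nan")
        )
    if "feature" in shared.columns:
        out["by_feature"] = _tab("feature")
    return out


def mean_dmr_methylation_track(
    beta: pd.DataFrame,
    shared: pd.DataFrame,
    manifest: pd.DataFrame,
    sample_sheet: pd.DataFrame,
) -> pd.DataFrame:
    """Per-DMR, per-(run, day) mean beta across member CpGs, long format."""
    sheet = sample_sheet.set_index("sample_id")
    rows = []
    for i, row in enumerate(shared.itertuples()):
        rs = RegionSet(
            "dmr",
            pd.DataFrame([(row.chrom, row.start, row.end, ".")], columns=["chrom", "start", "end", "label"]),
        )
        probes = [p for p in probes_in_regions(manifest, rs) if p in beta.index]
        if not probes:
            warnings.warn(f"shared DMR {row.chrom}:{row.start}-{row.end} has no surviving probes; dropped")
            continue
        sub = beta.loc[probes]
        for (run, day), samples in sheet.groupby(["run", "day"], sort=True).groups.items():
            cols = [s for s in samples if s in sub.columns]
            if not cols:
                continue
            rows.append(
                {
                    "dmr_id": f"shared{i:04d}",
                    "chrom": row.chrom,
                    "start": row.start,
                    "end": row.end,
                    "run": run,
                    "day": int(day),
                    "mean_beta": float(sub[cols].to_numpy().mean()),
                }
            )
    return pd.DataFrame(rows, columns=["dmr_id", "chrom", "start", "end", "run", "day", "mean_beta"])
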