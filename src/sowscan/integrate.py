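"""Intersection of significant GWAS windows with CNV regions.

A window and a CNVR are reported together whenever they share at least one
base pair; overlap lengths are carried so users can filter further. An
optional gene-interval table can be joined onto the overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .cnvr import Cnvr
from .errors import DataError
from .wssgwas import WindowResult


@dataclass
class OverlapRecord:
    """One (significant window, CNVR) pair sharing ≥ 1 bp."""

    chrom: int
    window_start_bp: int
    window_end_bp: int
    cnvr_start_bp: int
    cnvr_end_bp: int
    cnvr_state: str
    overlap_bp: int
    pct_variance: float

    def __post_init__(self):
        if self.overlap_bp < 1:
            raise DataError("overlap must be at least 1 bp")


def overlap_windows_cnvrs(
    windows: list[WindowResult], cnvrs: list[Cnvr]
) -> list[OverlapRecord]:
    """All (window, CNVR) pairs with ≥ 1 bp overlap, 1-based inclusive."""
    trees: dict[int, IntervalTree] = {}
    for r in cnvrs:
        # intervaltree is half-open; widen the end by 1
        trees.setdefault(int(r.chrom), IntervalTree()).addi(
            r.start_bp, r.end_bp + 1, r
        )
    records = []
    for w in windows:
        tree = trees.get(int(w.chrom))
        if tree is None:
            continue
        for iv in sorted(tree.overlap(w.start_bp, w.end_bp + 1)):
            r: Cnvr = iv.data
            ov = min(w.end_bp, r.end_bp) - max(w.start_bp, r.start_bp) + 1
            records.append(
                OverlapRecord(
                    chrom=int(w.chrom),
                    window_start_bp=w.start_bp,
                    window_end_bp=w.end_bp,
                    cnvr_start_bp=r.start_bp,
                    cnvr_end_bp=r.end_bp,
                    cnvr_state=r.state,
                    overlap_bp=int(ov),
                    pct_variance=w.pct_variance,
                )
            )
    return records


def annotate_with_genes(
    overlaps: list[OverlapRecord], genes: pd.DataFrame
) -> pd.DataFrame:
    """Join gene intervals (chrom, start_bp, end_bp, name; 1-based) onto overlaps."""
    trees: dict[int, IntervalTree] = {}
    for g in genes.itertuples(index=False):
        trees.setdefault(int(g.chrom), IntervalTree()).addi(
            int(g.start_bp), int(g.end_bp) + 1, g.name
        )
    rows = []
    for o in overlaps:
        tree = trees.get(o.chrom)
        hits = (
            sorted(iv.data for iv in tree.overlap(o.window_start_bp, o.window_end_bp + 1))
            if tree is not None
            else []
        )
        rows.append({**o.__dict__, "genes": ",".join(map(str, hits))})
    return pd.DataFrame(rows)


def overlaps_to_frame(overlaps: list[OverlapRecord]) -> pd.DataFrame:
    cols = [
        "chrom",
        "window_start_bp",
        "window_end_bp",
        "cnvr_start_bp",
        "cnvr_end_bp",
        "cnvr_state",
        "overlap_bp",
        "pct_variance",
    ]
    return pd.DataFrame([o.__dict__ for o in overlaps], columns=cols)


def build_report(
    overlaps: list[OverlapRecord],
    windows: list[WindowResult],
    cnvr_per_chrom: pd.DataFrame,
    cnvr_overall: dict,
) -> str:
    """Human-readable markdown combining windows, CNVR summary and overlaps."""
    lines = ["# Combined GWAS / CNVR report", ""]
    lines.append(f"## Significant windows ({len(windows)})")
    if windows:
        lines.append("")
        lines.append("| chrom | start_bp | end_bp | n_snps | % additive variance |")
        lines.append("|---|---|---|---|---|")
        for w in sorted(windows, key=lambda w: (w.chrom, w.start_bp)):
            lines.append(
                f"| {w.chrom} | {w.start_bp} | {w.end_bp} | {w.n_snps} "
                f"| {w.pct_variance:.2f} |"
            )
    else:
        lines.append("\nNo window exceeded the variance threshold.")
    lines.append("")
    lines.append(
        f"## CNVR summary: {cnvr_overall.get('n_cnvr', 0)} regions, "
        f"mean size {cnvr_overall.get('mean_size_bp', 0):.0f} bp, "
        f"{cnvr_overall.get('genome_coverage_pct', 0):.2f}% of the genome"
    )
    lines.append("")
    lines.append(cnvr_per_chrom.to_string(index=False))
    lines.append("")
    if overlaps:
        lines.append(f"## Window–CNVR overlaps ({len(overlaps)})")
        lines.append("")
        for o in overlaps:
            lines.append(
                f"- chr{o.chrom}: window {o.window_start_bp}-{o.window_end_bp} "
                f"({o.pct_variance:.2f}%) ∩ CNVR {o.cnvr_start_bp}-{o.cnvr_end_bp} "
                f"[{o.cnvr_state}] = {o.overlap_bp} bp"
            )
    else:
        lines.append("## Window–CNVR overlaps: zero overlap candidates")
    lines.append("")
    return "\n".join(lines)
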