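"""CNV-call QC, CNV-region (CNVR) inference and summaries.

Per-sample signal QC keeps a sample only if call rate > 0.98, call
frequency > 0.90 and — when signal metrics are present — BAF drift < 0.01,
LRR SD < 0.30 and GC wave factor < 0.05 (all strict). Calls spanning fewer
than three consecutive SNPs are discarded. Overlapping calls on the same
chromosome are concatenated transitively into CNVRs (union span), which
resolves inconsistent boundary calling; regions carried by a single
sample, with carrier frequency below 0.5%, or with overlap density
(recurrence) below 0.1 are dropped. Coordinates are 1-based inclusive
throughout; BED export converts at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .simulate import CnvCall


@dataclass
class QcThresholds:
    """Strict per-sample QC cut-offs."""

    min_call_rate: float = 0.98
    min_call_frequency: float = 0.90
    max_baf_drift: float = 0.01
    max_lrr_sd: float = 0.30
    max_gc_wave_factor: float = 0.05


@dataclass
class Cnvr:
    """A CNV region: the union of overlapping calls across samples."""

    chrom: int
    start_bp: int
    end_bp: int
    state: str  # "gain" | "loss" | "both"
    carriers: set = field(default_factory=set)
    n_carriers: int = 0
    frequency: float = 0.0
    recurrence: float = 0.0

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def qc_samples(
    metrics: pd.DataFrame, thresholds: QcThresholds | None = None
) -> tuple[list, pd.DataFrame]:
    """Split samples into pass list and fail table with violated rules.

    ``metrics`` columns: sample_id, call_rate, call_frequency and,
    optionally, lrr_sd, baf_drift, gc_wave_factor (NaN = not measured;
    a missing signal metric is not a failure).
    """
    th = thresholds or QcThresholds()
    if metrics["sample_id"].duplicated().any():
        dup = metrics.loc[metrics["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DataError(f"duplicate sample id in metrics: {dup!r}")
    passed, failures = [], []
    for row in metrics.itertuples(index=False):
        reasons = []
        if not row.call_rate > th.min_call_rate:
            reasons.append(f"call_rate <= {th.min_call_rate}")
        if not row.call_frequency > th.min_call_frequency:
            reasons.append(f"call_frequency <= {th.min_call_frequency}")
        for name, cap in (
            ("baf_drift", th.max_baf_drift),
            ("lrr_sd", th.max_lrr_sd),
            ("gc_wave_factor", th.max_gc_wave_factor),
        ):
            val = getattr(row, name, None)
            if val is not None and not pd.isna(val) and not val < cap:
                reasons.append(f"{name} >= {cap}")
        if reasons:
            failures.append((row.sample_id, "; ".join(reasons)))
        else:
            passed.append(row.sample_id)
    return passed, pd.DataFrame(failures, columns=["sample_id", "reasons"])


def qc_calls(calls: list[CnvCall], min_snps: int = 3) -> list[CnvCall]:
    """Drop calls spanning fewer than ``min_snps`` consecutive SNPs."""
    return [c for c in calls if c.num_snps >= min_snps]


def merge_cnvrs(
    calls: list[CnvCall],
    total_samples: int,
    min_freq: float = 0.005,
    min_recurrence: float = 0.1,
) -> list[Cnvr]:
    """Concatenate overlapping calls into CNVRs and filter.

    Overlap criterion is ≥ 1 bp with transitive closure; the region span is
    the union of member intervals. Regions are kept only if carried by at
    least two distinct samples, with frequency (carriers / total samples)
    ≥ ``min_freq`` and recurrence ≥ ``min_recurrence``. Recurrence is the
    mean, over member calls, of call length / region length — a density in
    (0, 1] that is low when a region is inflated by a few long outliers.
    State is gain/loss from the member calls, or "both" when mixed.
    """
    if total_samples <= 0:
        raise DataError("total_samples must be positive")
    regions: list[Cnvr] = []
    by_chrom: dict[int, list[CnvCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom in sorted(by_chrom):
        chunk = sorted(by_chrom[chrom], key=lambda c: (c.start_bp, c.end_bp))
        cluster: list[CnvCall] = []
        cur_end = None
        for call in chunk:
            if cluster and call.start_bp > cur_end:
                regions.append(_finish_cluster(chrom, cluster, total_samples))
                cluster = []
                cur_end = None
            cluster.append(call)
            cur_end = call.end_bp if cur_end is None else max(cur_end, call.end_bp)
        if cluster:
            regions.append(_finish_cluster(chrom, cluster, total_samples))
    kept = [
        r
        for r in regions
        if r.n_carriers >= 2 and r.frequency >= min_freq and r.recurrence >= min_recurrence
    ]
    return kept


def _finish_cluster(chrom: int, cluster: list[CnvCall], total_samples: int) -> Cnvr:
    start = min(c.start_bp for c in cluster)
    end = max(c.end_bp for c in cluster)
    states = {c.state for c in cluster}
    state = states.pop() if len(states) == 1 else "both"
    carriers = {c.sample_id for c in cluster}
    length = end - start + 1
    recurrence = float(np.mean([c.length_bp / length for c in cluster]))
    return Cnvr(
        chrom=chrom,
        start_bp=start,
        end_bp=end,
        state=state,
        carriers=carriers,
        n_carriers=len(carriers),
        frequency=len(carriers) / total_samples,
        recurrence=recurrence,
    )


def loss_gain_ratio(n_loss: int, n_gain: int, n_both: int) -> float:
    """Loss:gain ratio counting mixed-state regions on both sides."""
    denom = n_gain + n_both
    if denom == 0:
        raise DataError("loss:gain ratio undefined without gain or both regions")
    return (n_loss + n_both) / denom


def coverage_percent(cnvr_length_bp: int, chrom_length_bp: int) -> float:
    """Percent of a chromosome (or genome) covered by CNVRs."""
    if chrom_length_bp <= 0:
        raise DataError("chromosome length must be positive")
    return 100.0 * cnvr_length_bp / chrom_length_bp


def summarize_cnvrs(
    cnvrs: list[Cnvr], chrom_lengths: dict[int, int]
) -> tuple[pd.DataFrame, dict]:
    """Per-chromosome table and overall summary of a CNVR set.

    The per-chromosome table has count, summed CNVR length and percent
    coverage; the overall dict carries count, mean/min/max/total size,
    percent of the genome covered, state counts and the loss:gain ratio.
    """
    for r in cnvrs:
        if r.chrom not in chrom_lengths:
            raise DataError(f"no length supplied for chromosome {r.chrom}")
    rows = []
    for chrom in sorted(chrom_lengths):
        sub = [r for r in cnvrs if r.chrom == chrom]
        total_len = sum(r.length_bp for r in sub)
        rows.append(
            {
                "chrom": chrom,
                "chrom_length_bp": chrom_lengths[chrom],
                "n_cnvr": len(sub),
                "cnvr_length_bp": total_len,
                "coverage_pct": coverage_percent(total_len, chrom_lengths[chrom]),
            }
        )
    per_chrom = pd.DataFrame(rows)
    sizes = [r.length_bp for r in cnvrs]
    n_loss = sum(r.state == "loss" for r in cnvrs)
    n_gain = sum(r.state == "gain" for r in cnvrs)
    n_both = sum(r.state == "both" for r in cnvrs)
    genome = sum(chrom_lengths.values())
    overall = {
        "n_cnvr": len(cnvrs),
        "mean_size_bp": float(np.mean(sizes)) if sizes else 0.0,
        "min_size_bp": int(min(sizes)) if sizes else 0,
        "max_size_bp": int(max(sizes)) if sizes else 0,
        "total_length_bp": int(sum(sizes)),
        "genome_coverage_pct": coverage_percent(int(sum(sizes)), genome),
        "n_loss": n_loss,
        "n_gain": n_gain,
        "n_both": n_both,
    }
    if n_gain + n_both > 0:
        overall["loss_gain_ratio"] = loss_gain_ratio(n_loss, n_gain, n_both)
    return per_chrom, overall
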