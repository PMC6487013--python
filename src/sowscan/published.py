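"""Published reference summaries from a large Duroc litter-size study.

Small plain-text tables bundled with the package: the per-chromosome CNVR
summary and the list of 1-Mb GWAS windows exceeding 1% of additive genetic
variance reported for number of piglets born alive in a commercial Duroc
population. They serve as fixed arithmetic inputs for validating the
summary routines (ratios, means, coverage, threshold filters) — they are
not outputs of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .wssgwas import WindowResult

#: CNVR state tallies in the reference population
REFERENCE_STATE_COUNTS = {"loss": 342, "gain": 19, "both": 64}

#: genome length printed in the reference table's total row. Note: this is
#: NOT the sum of the listed per-chromosome lengths (2,450,713,522 bp); the
#: reference's genome-coverage percentage (7.01%) was computed against this
#: printed total, so it is kept verbatim for the arithmetic checks.
REFERENCE_GENOME_LENGTH_BP = 2_808_509_378

#: individual CNV-call tallies (all calls and non-redundant calls)
REFERENCE_CALL_COUNTS = {
    "gain_calls": 4892,
    "loss_calls": 41226,
    "nonredundant_gain": 645,
    "nonredundant_loss": 7507,
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("sowscan.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_reference_cnvr_summary() -> pd.DataFrame:
    """Per-chromosome CNVR counts and lengths (18 autosomes)."""
    return _read("duroc_cnvr_chromosome_summary.tsv")


def load_reference_windows() -> list[WindowResult]:
    """The reference study's significant 1-Mb windows as WindowResult objects."""
    df = _read("duroc_gwas_windows.tsv")
    return [
        WindowResult(
            chrom=int(r.chrom),
            start_bp=int(r.start_bp),
            end_bp=int(r.end_bp),
            n_snps=1,  # per-window SNP counts are not part of the published table
            pct_variance=float(r.pct_variance),
        )
        for r in df.itertuples(index=False)
    ]
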