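"""Synthetic populations with the data structure a single-step sow analysis assumes.

Generates a multi-generation pedigree with a genotyped subset, biallelic
SNP genotypes by gene-dropping, repeated litter-size records from the
repeatability animal model

    y = Xb + Wa + K·pe + e,   a ~ (0, A σ²a),  pe ~ (0, I σ²pe),  e ~ (0, I σ²e)

and per-individual CNV calls clustered into latent regions with a strong
excess of copy losses. Default variance components (0.78, 0.57, 5.68) give
h² ≈ 0.11, the regime of number of piglets born alive; the default
loss:gain odds of 8.4 mirrors the loss excess SNP-array callers report in
pigs. Everything is driven by one seed through named sub-streams, so each
component is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .relationship import UNKNOWN, GenotypePanel, Pedigree


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults are chosen to emulate, at desk scale, a commercial Duroc
    population: 18 autosomes, maternal trait with repeated records (1–12
    parities), nine contemporary groups, and CNV calls dominated by losses.
    """

    n_founders: int = 200
    n_generations: int = 4
    n_animals_per_gen: int = 1000
    n_snps: int = 5000
    n_chromosomes: int = 18
    chrom_length_bp: int = 10_000_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 5
    qtl_variance_fraction: float = 0.4
    sigma_a2: float = 0.78
    sigma_pe2: float = 0.57
    sigma_e2: float = 5.68
    trait_mean: float = 10.5
    records_per_sow_range: tuple[int, int] = (1, 12)
    n_contemporary_groups: int = 9
    genotyped_fraction: float = 0.95
    genotype_females_only: bool = True
    cnv_n_latent_regions: int = 60
    cnv_loss_gain_odds: float = 8.4
    cnv_carrier_freq_range: tuple[float, float] = (0.01, 0.3)
    cnv_boundary_jitter_snps: int = 2
    cnv_min_span_snps: int = 6
    seed: int = 7

    def __post_init__(self):
        if self.n_founders < 2 or self.n_generations < 1:
            raise ConfigError("need at least 2 founders and 1 generation")
        if self.n_animals_per_gen < 1:
            raise ConfigError("n_animals_per_gen must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range bounds must lie in (0, 0.5]")
        for name in ("sigma_a2", "sigma_pe2", "sigma_e2"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0.0 < self.genotyped_fraction <= 1.0:
            raise ConfigError("genotyped_fraction must be in (0, 1]")
        rlo, rhi = self.records_per_sow_range
        if not 1 <= rlo <= rhi <= 12:
            raise ConfigError("records_per_sow_range must lie within [1, 12]")
        if not 0.0 <= self.qtl_variance_fraction < 1.0:
            raise ConfigError("qtl_variance_fraction must be in [0, 1)")
        clo, chi = self.cnv_carrier_freq_range
        if not 0.0 < clo <= chi <= 1.0:
            raise ConfigError("cnv_carrier_freq_range must lie in (0, 1]")
        if self.cnv_min_span_snps < 2 * self.cnv_boundary_jitter_snps + 2:
            raise ConfigError(
                "cnv_min_span_snps must exceed twice the boundary jitter + 1"
            )

    def rng(self, component: str) -> np.random.Generator:
        """Deterministic per-component sub-stream of the master seed."""
        streams = {"pedigree": 0, "genotypes": 1, "phenotypes": 2, "cnv": 3, "qc": 4}
        key = streams.get(component)
        if key is None:
            raise ConfigError(f"unknown random sub-stream {component!r}")
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CnvCall:
    """One per-sample CNV call (1-based inclusive coordinates)."""

    sample_id: object
    chrom: int
    start_bp: int
    end_bp: int
    state: str  # "gain" | "loss"
    copy_number: int
    num_snps: int
    confidence: float | None = None

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise DataError("CNV call start must not exceed end")
        if self.num_snps < 1:
            raise DataError("CNV call must span at least one SNP")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class TruthRecord:
    """Ground truth retained from simulation for parameter-recovery tests."""

    true_breeding_values: np.ndarray | None = None
    qtl_snp_index: np.ndarray | None = None
    qtl_effects: np.ndarray | None = None
    cnvr_intervals: pd.DataFrame | None = None
    contemporary_group_means: np.ndarray | None = None
    permanent_environment: np.ndarray | None = None
    merged: dict = field(default_factory=dict)

    def update(self, other: "TruthRecord") -> "TruthRecord":
        for name in (
            "true_breeding_values",
            "qtl_snp_index",
            "qtl_effects",
            "cnvr_intervals",
            "contemporary_group_means",
            "permanent_environment",
        ):
            val = getattr(other, name)
            if val is not None:
                setattr(self, name, val)
        return self


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Discrete-generation pedigree: founders then random-mated generations.

    Sexes alternate within each cohort (random tie-break for odd cohort
    sizes); each non-founder draws a sire and dam from the previous
    generation. Output is topologically ordered by construction.
    """
    rng = config.rng("pedigree")
    n0 = config.n_founders
    sire = [UNKNOWN] * n0
    dam = [UNKNOWN] * n0
    sex = list(np.arange(n0) % 2)
    if n0 % 2 == 1 and rng.random() < 0.5:
        sex[-1] = 1 - sex[-1]
    prev = np.arange(n0)
    for _ in range(config.n_generations):
        prev_sex = np.array([sex[i] for i in prev])
        males = prev[prev_sex == 0]
        females = prev[prev_sex == 1]
        if males.size == 0 or females.size == 0:
            raise ConfigError("a generation lacks one sex; increase cohort sizes")
        k = config.n_animals_per_gen
        sires = rng.choice(males, size=k)
        dams = rng.choice(females, size=k)
        start = len(sire)
        sire.extend(sires.tolist())
        dam.extend(dams.tolist())
        cohort_sex = list(np.arange(k) % 2)
        if k % 2 == 1 and rng.random() < 0.5:
            cohort_sex[-1] = 1 - cohort_sex[-1]
        sex.extend(cohort_sex)
        prev = np.arange(start, start + k)
    n = len(sire)
    return Pedigree(
        ids=np.arange(1, n + 1),
        sire=np.array(sire),
        dam=np.array(dam),
        sex=np.array(sex, dtype=np.int64),
    )


def _simulate_map(config: SimConfig, rng: np.random.Generator):
    """SNP map: positions uniform per chromosome, strictly increasing."""
    per_chrom = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per_chrom[: config.n_snps % config.n_chromosomes] += 1
    chroms, positions = [], []
    for c in range(config.n_chromosomes):
        m = per_chrom[c]
        pos = np.sort(
            rng.choice(np.arange(1, config.chrom_length_bp + 1), size=m, replace=False)
        )
        chroms.append(np.full(m, c + 1))
        positions.append(pos)
    return np.concatenate(chroms), np.concatenate(positions)


def simulate_genotypes(pedigree: Pedigree, config: SimConfig) -> GenotypePanel:
    """Gene-dropping through the pedigree (no linkage beyond co-ancestry).

    Founder haplotypes are Bernoulli draws at per-SNP frequencies uniform in
    ``maf_range``; each offspring inherits, per locus, one random allele of
    each parent. The genotyped subset is the most recent
    ``genotyped_fraction`` of the pedigree (recent cohorts are the ones
    genotyped in practice).
    """
    rng = config.rng("genotypes")
    chrom, pos = _simulate_map(config, rng)
    m = config.n_snps
    n = len(pedigree)
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    hap1 = np.zeros((n, m), dtype=np.int8)
    hap2 = np.zeros((n, m), dtype=np.int8)
    founders = pedigree.sire == UNKNOWN
    nf = int(founders.sum())
    hap1[founders] = rng.random((nf, m)) < p
    hap2[founders] = rng.random((nf, m)) < p
    for i in np.nonzero(~founders)[0]:
        s, d = pedigree.sire[i], pedigree.dam[i]
        pick_s = rng.random(m) < 0.5
        pick_d = rng.random(m) < 0.5
        hap1[i] = np.where(pick_s, hap1[s], hap2[s])
        hap2[i] = np.where(pick_d, hap1[d], hap2[d])
    genotypes = (hap1 + hap2).astype(np.int8)
    # the genotyped subset emulates a sow SNP panel: the most recent
    # genotyped_fraction of sows (or of all animals when sex is absent)
    if config.genotype_females_only and pedigree.sex is not None:
        pool = np.nonzero(pedigree.sex == 1)[0]
    else:
        pool = np.arange(n)
    n_geno = max(1, int(np.ceil(config.genotyped_fraction * pool.size)))
    sample_pos = pool[-n_geno:]
    panel = GenotypePanel(
        sample_ids=pedigree.ids[sample_pos],
        sample_pos=sample_pos,
        genotypes=genotypes[sample_pos],
        snp_ids=np.array([f"snp{c}_{b}" for c, b in zip(chrom, pos)]),
        chrom=chrom,
        pos_bp=pos,
    )
    # full-pedigree genotypes kept for QTL planting in simulate_phenotypes
    panel.pedigree_genotypes = genotypes
    return panel


def _polygenic_values(pedigree: Pedigree, sigma2: float, rng) -> np.ndarray:
    """Breeding values by the pedigree recursion a_i = ½(a_s + a_d) + m_i."""
    n = len(pedigree)
    a = np.zeros(n)
    F = pedigree.inbreeding
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            dvar = 0.5 - 0.25 * (F[s] + F[d])
            a[i] = 0.5 * (a[s] + a[d]) + rng.normal(0.0, np.sqrt(sigma2 * dvar))
        elif s != UNKNOWN or d != UNKNOWN:
            par = s if s != UNKNOWN else d
            dvar = 0.75 - 0.25 * F[par]
            a[i] = 0.5 * a[par] + rng.normal(0.0, np.sqrt(sigma2 * dvar))
        else:
            a[i] = rng.normal(0.0, np.sqrt(sigma2))
    return a


def simulate_phenotypes(
    pedigree: Pedigree,
    config: SimConfig,
    panel: GenotypePanel | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Repeated records for sows from y = Xb + Wa + K·pe + e.

    Breeding values are purely polygenic unless ``panel`` is given and
    ``n_qtl`` > 0, in which case ``qtl_variance_fraction`` of σ²a comes from
    additive QTL placed on genotyped SNPs (effects scaled so the realised
    QTL variance among all animals matches the requested fraction) and the
    remainder from the pedigree recursion. Only females receive records.
    """
    rng = config.rng("phenotypes")
    n = len(pedigree)
    truth = TruthRecord()

    frac = config.qtl_variance_fraction if (panel is not None and config.n_qtl > 0) else 0.0
    a = _polygenic_values(pedigree, config.sigma_a2 * (1.0 - frac), rng)
    if frac > 0.0:
        geno_all = getattr(panel, "pedigree_genotypes", None)
        if geno_all is None:
            raise DataError(
                "QTL planting needs full-pedigree genotypes; use a panel from "
                "simulate_genotypes or set n_qtl=0"
            )
        # QTL drawn among reasonably common SNPs so each carries variance
        p = panel.allele_frequencies()
        eligible = np.nonzero((p >= 0.1) & (p <= 0.9))[0]
        qtl_idx = np.sort(rng.choice(eligible, size=config.n_qtl, replace=False))
        signs = rng.choice([-1.0, 1.0], size=config.n_qtl)
        # equal per-QTL effects on the unit scale, then one global rescale so
        # the realised QTL variance is exactly frac·σ²a in this pedigree
        g = (geno_all[:, qtl_idx].astype(float) * signs).sum(axis=1)
        sd = g.std()
        if sd == 0:
            raise DataError("QTL loci are monomorphic in the pedigree")
        scale = np.sqrt(config.sigma_a2 * frac) / sd
        effects = signs * scale
        a = a + (g - g.mean()) * scale
        truth.qtl_snp_index = qtl_idx
        truth.qtl_effects = effects

    females = np.nonzero(pedigree.sex == 1)[0] if pedigree.sex is not None else np.arange(n)
    if females.size == 0:
        raise DataError("no sows in the pedigree; cannot simulate a sow trait")
    rlo, rhi = config.records_per_sow_range
    n_records = rng.integers(rlo, rhi + 1, size=females.size)
    cg_means = config.trait_mean + rng.normal(0.0, 1.0, size=config.n_contemporary_groups)
    pe = rng.normal(0.0, np.sqrt(config.sigma_pe2), size=n)

    rows = []
    for sow, k in zip(females, n_records):
        cgs = rng.integers(0, config.n_contemporary_groups, size=k)
        e = rng.normal(0.0, np.sqrt(config.sigma_e2), size=k)
        for parity in range(k):
            cg = cgs[parity]
            rows.append(
                (
                    pedigree.ids[sow],
                    int(cg),
                    parity + 1,
                    cg_means[cg] + a[sow] + pe[sow] + e[parity],
                )
            )
    table = pd.DataFrame(rows, columns=["animal", "cg", "parity", "value"])
    truth.true_breeding_values = a
    truth.contemporary_group_means = cg_means
    truth.permanent_environment = pe
    return table, truth


def simulate_cnv_calls(
    panel: GenotypePanel, config: SimConfig
) -> tuple[list[CnvCall], TruthRecord]:
    """CNV calls clustered in latent regions, loss-dominated.

    Latent regions are placed on the SNP map; each gets a state drawn with
    odds ``cnv_loss_gain_odds`` (loss:gain) and a carrier frequency uniform
    in ``cnv_carrier_freq_range``. Carrier samples emit one call whose
    endpoints are jittered by up to ``cnv_boundary_jitter_snps`` map
    positions — the boundary inconsistency CNVR concatenation must absorb.
    """
    rng = config.rng("cnv")
    truth = TruthRecord()
    calls: list[CnvCall] = []
    regions = []
    if config.cnv_n_latent_regions == 0:
        truth.cnvr_intervals = pd.DataFrame(
            columns=["chrom", "start_bp", "end_bp", "state", "carrier_freq"]
        )
        return calls, truth

    chrom, pos = panel.chrom, panel.pos_bp
    m = panel.n_snps
    span = config.cnv_min_span_snps
    jit = config.cnv_boundary_jitter_snps
    p_loss = config.cnv_loss_gain_odds / (1.0 + config.cnv_loss_gain_odds)
    for r in range(config.cnv_n_latent_regions):
        for _ in range(200):
            start_i = int(rng.integers(0, m - span))
            end_i = start_i + span - 1
            if chrom[start_i] == chrom[end_i]:
                break
        else:
            raise DataError("latent CNV region does not fit on the simulated map")
        if not (0 <= start_i <= end_i < m):
            raise DataError("latent CNV region off the simulated map")
        state = "loss" if rng.random() < p_loss else "gain"
        freq = rng.uniform(*config.cnv_carrier_freq_range)
        regions.append(
            (int(chrom[start_i]), int(pos[start_i]), int(pos[end_i]), state, freq)
        )
        carriers = np.nonzero(rng.random(panel.n_samples) < freq)[0]
        for s in carriers:
            lo = start_i + int(rng.integers(-jit, jit + 1))
            hi = end_i + int(rng.integers(-jit, jit + 1))
            lo = max(lo, 0)
            hi = min(hi, m - 1)
            # clamp jitter to the region's chromosome
            while chrom[lo] != chrom[start_i]:
                lo += 1
            while chrom[hi] != chrom[end_i]:
                hi -= 1
            cn = 1 if state == "loss" else 3
            calls.append(
                CnvCall(
                    sample_id=panel.sample_ids[s],
                    chrom=int(chrom[start_i]),
                    start_bp=int(pos[lo]),
                    end_bp=int(pos[hi]),
                    state=state,
                    copy_number=cn,
                    num_snps=int(hi - lo + 1),
                )
            )
    truth.cnvr_intervals = pd.DataFrame(
        regions, columns=["chrom", "start_bp", "end_bp", "state", "carrier_freq"]
    )
    return calls, truth


def simulate_qc_metrics(
    panel: GenotypePanel, config: SimConfig, fail_fraction: float = 0.05
) -> pd.DataFrame:
    """Per-sample signal-QC metrics, a small fraction engineered to fail."""
    rng = config.rng("qc")
    n = panel.n_samples
    df = pd.DataFrame(
        {
            "sample_id": panel.sample_ids,
            "call_rate": rng.uniform(0.985, 1.0, size=n),
            "call_frequency": rng.uniform(0.92, 1.0, size=n),
            "lrr_sd": rng.uniform(0.05, 0.25, size=n),
            "baf_drift": rng.uniform(0.0, 0.008, size=n),
            "gc_wave_factor": rng.uniform(0.0, 0.04, size=n),
        }
    )
    bad = rng.random(n) < fail_fraction
    df.loc[bad, "lrr_sd"] = rng.uniform(0.31, 0.5, size=int(bad.sum()))
    return df
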