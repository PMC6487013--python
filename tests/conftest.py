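import numpy as np
import pytest

from sowscan import Pedigree, SimConfig
from sowscan.relationship import UNKNOWN, GenotypePanel


@pytest.fixture
def trio():
    """Two unrelated founders and their offspring."""
    return Pedigree(ids=np.array([1, 2, 3]), sire=np.array([UNKNOWN, UNKNOWN, 0]),
                    dam=np.array([UNKNOWN, UNKNOWN, 1]))


@pytest.fixture
def small_config():
    return SimConfig(
        n_founders=30,
        n_generations=2,
        n_animals_per_gen=50,
        n_snps=200,
        n_chromosomes=3,
        chrom_length_bp=2_000_000,
        n_qtl=0,
        records_per_sow_range=(2, 4),
        cnv_n_latent_regions=8,
        seed=11,
    )


def random_pedigree(n_founders, n_total, rng):
    """Random valid pedigree: each non-founder picks two earlier parents."""
    sire = [UNKNOWN] * n_founders
    dam = [UNKNOWN] * n_founders
    for i in range(n_founders, n_total):
        s, d = rng.choice(i, size=2, replace=False)
        sire.append(int(s))
        dam.append(int(d))
    return Pedigree(ids=np.arange(1, n_total + 1), sire=np.array(sire), dam=np.array(dam))


def tiny_panel(genotypes, chrom=None, pos=None, sample_pos=None):
    g = np.asarray(genotypes)
    n, m = g.shape
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom)
    pos = np.arange(1, m + 1) * 1000 if pos is None else np.asarray(pos)
    sample_pos = np.arange(n) if sample_pos is None else np.asarray(sample_pos)
    return GenotypePanel(
        sample_ids=np.arange(1, n + 1),
        sample_pos=sample_pos,
        genotypes=g,
        snp_ids=np.array([f"s{i}" for i in range(m)]),
        chrom=chrom,
        pos_bp=pos,
    )
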