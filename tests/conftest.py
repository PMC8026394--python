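import numpy as np
import pandas as pd
import pytest

from ntracts import formats_io, synthetic_data


@pytest.fixture
def small_map():
    """Two chromosomes, 100 cM total, 1 cM = 1 Mb."""
    return formats_io.GeneticMap({
        "1": (np.array([0.0, 60e6]), np.array([0.0, 60.0])),
        "2": (np.array([0.0, 40e6]), np.array([0.0, 40.0])),
    })


@pytest.fixture
def small_panel(small_map):
    panel, freqs = synthetic_data.archaic_panel(small_map, snps_per_cm=40,
                                                seed=11)
    return panel, freqs


@pytest.fixture
def empty_truth(small_map):
    return synthetic_data.TruthSet(
        map=small_map,
        hap_intervals=[{"1": [], "2": []}, {"1": [], "2": []}],
        params={},
    )


def random_genotypes(n_snps=200, n_samples=6, seed=0, missing_frac=0.05):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, 50_000_000), n_snps, replace=False))
    snp = pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(n_snps)],
        "chrom": "1",
        "pos_bp": pos,
        "cm": pos / 1e6,
        "ref_allele": rng.choice(list("ACGT"), n_snps),
        "alt_allele": "T",
    })
    # avoid ref == alt
    snp.loc[snp.ref_allele == "T", "ref_allele"] = "G"
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n_samples)],
        "population": [f"P{i % 3}" for i in range(n_samples)],
    })
    geno = rng.integers(0, 3, size=(n_snps, n_samples)).astype(np.int8)
    geno[rng.random(geno.shape) < missing_frac] = formats_io.MISSING
    return formats_io.make_genotype_data(snp, samples, geno)
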