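import numpy as np
import pandas as pd
import pytest

from introscan.genio import GenotypeMatrix, LOCUS_COLUMNS
from introscan.simdata import SimConfig, YearCohort, simulate_dataset


def make_matrix(rows, samples=None):
    """GenotypeMatrix from a list of per-sample dosage lists (None = missing)."""
    arr = np.array([[np.nan if v is None else float(v) for v in r] for r in rows])
    samples = samples or [f"s{i}" for i in range(len(rows))]
    return GenotypeMatrix(samples, arr)


def make_loci(n, chrom="chr1", rad_size=1, start=1000, step=100):
    """Simple locus table: n SNPs, grouped into RAD loci of rad_size."""
    return pd.DataFrame(
        {
            "snp_id": [f"snp_{i}" for i in range(n)],
            "radlocus_id": [f"rad_{i // rad_size}" for i in range(n)],
            "chrom": chrom,
            "pos": [start + i * step for i in range(n)],
            "ref": "A",
            "alt": "G",
        },
        columns=LOCUS_COLUMNS,
    )


def make_popmap(samples, groups, years=None):
    return pd.DataFrame(
        {
            "sample": samples,
            "group": groups,
            "year": years if years is not None else ["1"] * len(samples),
        }
    )


@pytest.fixture(scope="session")
def swarm_sim():
    """Two diverged parental groups + hybrid swarm, multi-SNP RAD loci, missingness."""
    cfg = SimConfig(
        n_loci=800, n_chromosomes=8, snps_per_radlocus=2, target_fst=0.1,
        n_parvulus=15, n_pauper=15, n_f1=5, n_backcross=5,
        missing_rate=0.05, planted_outliers=3, seed=2,
    )
    return cfg, *simulate_dataset(cfg)


@pytest.fixture(scope="session")
def two_year_sim():
    """Hybrid swarm sampled in two years (11 vs 4 hybrids) with drift between."""
    cfg = SimConfig(
        n_loci=400, n_chromosomes=5, snps_per_radlocus=1, target_fst=0.08,
        years=[
            YearCohort("2005", n_parvulus=12, n_pauper=10, n_f1=5, n_backcross=6),
            YearCohort("2013", n_parvulus=10, n_pauper=8, n_f1=2, n_backcross=2),
        ],
        drift_ne=200, missing_rate=0.05, seed=11,
    )
    return cfg, *simulate_dataset(cfg)


@pytest.fixture(scope="session")
def parental_panel():
    """Clean two-cluster panel at the scale the ancestry examples use."""
    cfg = SimConfig(
        n_loci=5000, n_chromosomes=10, snps_per_radlocus=1, target_fst=0.1,
        n_parvulus=20, n_pauper=20, n_f1=5, n_backcross=0, missing_rate=0.0, seed=3,
    )
    return cfg, *simulate_dataset(cfg)
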