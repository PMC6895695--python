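import numpy as np
import pandas as pd
import pytest

from cardiofate import synthetic


@pytest.fixture(scope="session")
def profiles():
    return synthetic.simulate_reference_profiles(n_genes=1500, seed=11)


@pytest.fixture(scope="session")
def cohort(profiles):
    """Mid-size cohort with a clear planted signature."""
    return synthetic.simulate_ipsc_cohort(
        profiles,
        n_lines=90,
        n_terminated=12,
        n_signature=30,
        effect_size=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def null_cohort(profiles):
    """Cohort with no planted expression effects (global null)."""
    return synthetic.simulate_ipsc_cohort(
        profiles,
        n_lines=60,
        n_terminated=8,
        n_signature=10,
        effect_size=0.0,
        seed=13,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def par_gene_fixture():
    """Twenty chrX/autosomal genes straddling the pseudoautosomal regions."""
    rows = [
        # inside PAR1 (60,001-2,699,520)
        ("PG01", "chrX", 100_000, 105_000, True),
        ("PG02", "chrX", 60_001, 61_000, True),
        ("PG03", "chrX", 2_600_000, 2_699_520, True),
        ("PG04", "chrX", 59_000, 60_001, True),       # right edge touches PAR1 start
        ("PG05", "chrX", 2_699_520, 2_710_000, True), # left edge touches PAR1 end
        # inside PAR2 (154,931,044-155,260,560)
        ("PG06", "chrX", 154_931_044, 154_940_000, True),
        ("PG07", "chrX", 155_000_000, 155_100_000, True),
        ("PG08", "chrX", 154_930_000, 154_931_044, True),
        # chrX outside both PARs
        ("XG01", "chrX", 3_000_000, 3_010_000, False),
        ("XG02", "chrX", 2_699_521, 2_705_000, False),
        ("XG03", "chrX", 50_000_000, 50_005_000, False),
        ("XG04", "chrX", 154_000_000, 154_010_000, False),
        ("XG05", "chrX", 155_260_561, 155_270_000, False),
        ("XG06", "chrX", 10_000, 59_999, False),      # ends just before PAR1
        # autosomes, coordinates inside PAR ranges must stay unmasked
        ("AG01", "chr1", 100_000, 105_000, False),
        ("AG02", "chr2", 2_600_000, 2_699_520, False),
        ("AG03", "chr7", 155_000_000, 155_100_000, False),
        ("AG04", "chr12", 3_000_000, 3_010_000, False),
        ("AG05", "chr21", 60_001, 61_000, False),
        ("AG06", "chr22", 154_931_044, 154_940_000, False),
    ]
    df = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "expect_par"])
    df["sample"] = "S1"
    df["ref_count"] = 30
    df["alt_count"] = 30
    return df
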