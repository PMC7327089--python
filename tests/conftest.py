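import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from aeipipe import SimulationConfig, simulate_cohort


def make_counts(rows):
    """Counts frame from (sample, tissue, snp, gene, ref_count, alt_count) tuples."""
    recs = []
    for i, (sample, tissue, snp, gene, rx, ax) in enumerate(rows):
        recs.append(
            {
                "sample_id": sample,
                "patient_id": sample.split("-")[0],
                "tissue": tissue,
                "chrom": "chr1",
                "pos": 1000 + 10 * i,
                "snp_id": snp,
                "gene_id": gene,
                "ref": "C",
                "alt": "T",
                "ref_count": rx,
                "alt_count": ax,
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest paired cohort with DNA counts, shared across read-only tests."""
    config = SimulationConfig(n_pairs=20, n_genes=300, seed=11, frac_dna_bias=0.1)
    return simulate_cohort(config)
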