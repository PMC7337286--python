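import numpy as np
import pandas as pd
import pytest

from protmr.simulate import LDBlockSpec, TruthRecord, ar1_corr, simulate_ld_panel


@pytest.fixture(scope="session")
def ar_panel():
    """15-variant AR(0.85) reference panel used across locus-level tests."""
    return simulate_ld_panel([LDBlockSpec(15, ar1_corr(15, 0.85))], 200, seed=11)


@pytest.fixture(scope="session")
def causal_truth(ar_panel):
    ids = list(ar_panel.variants["rsid"])
    return TruthRecord("PROT", [ids[7]], [0.8], "causal", 0.1, "TRAIT")


def make_variants(n, chrom=1, start=1_000_000, step=10_000):
    """Minimal variant metadata table for hand-built fixtures."""
    alleles = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": start + step * np.arange(n),
            "rsid": [f"rs{i + 1}" for i in range(n)],
            "a1": [alleles[i % 4][0] for i in range(n)],
            "a0": [alleles[i % 4][1] for i in range(n)],
            "info": 1.0,
        }
    )
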