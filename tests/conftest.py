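import numpy as np
import pandas as pd
import pytest

from cwas.data_io import GenotypePanel
from cwas.simulator import (SimulationSpec, simulate_genotypes,
                            simulate_weights_and_signature)
from cwas.grp_engine import deconvolve, impute_expression, transform_weights


def make_panel(dosages, rsids=None, chrom="1", positions=None,
               counted=None, other=None):
    """Hand-built GenotypePanel from a dosage matrix."""
    dosages = np.asarray(dosages, float)
    n, p = dosages.shape
    rsids = rsids or [f"rs{j + 1}" for j in range(p)]
    positions = positions if positions is not None else 1000 * (np.arange(p) + 1)
    counted = counted or ["A"] * p
    other = other or ["G"] * p
    freq = dosages.mean(axis=0) / 2.0
    snps = pd.DataFrame({
        "rsid": rsids, "chrom": chrom, "pos": positions,
        "counted_allele": counted, "other_allele": other,
        "maf": np.minimum(freq, 1 - freq),
    })
    return GenotypePanel(sample_ids=[f"s{i}" for i in range(n)],
                         snps=snps, dosages=dosages)


@pytest.fixture(scope="session")
def small_study():
    """One small synthetic study shared across read-only tests."""
    rng = np.random.default_rng(42)
    panel = simulate_genotypes(800, 240, ld=0.3, rng=rng)
    weights, sig = simulate_weights_and_signature(panel, 24, 4, rng=rng)
    tw = transform_weights(weights, sig, min_genes=10)
    b = impute_expression(panel, weights)
    grp = deconvolve(b, tw, sig)
    return {"panel": panel, "weights": weights, "sig": sig, "tw": tw,
            "b": b, "grp": grp}
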