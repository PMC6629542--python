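import numpy as np
import pandas as pd
import pytest

from polyscore import SimConfig, simulate_study
from polyscore.genotype_io import GenotypeDataset


@pytest.fixture(scope="session")
def small_study():
    """A modest simulated study shared by read-only tests."""
    cfg = SimConfig(n_samples=800, m_snps=300, n_causal=40, h2=0.4, seed=11)
    return simulate_study(cfg)


def make_dataset(hardcalls, positions=None, chrom="1", rng=None):
    """Wrap a raw hard-call matrix in a GenotypeDataset with simple metadata."""
    hc = np.asarray(hardcalls, dtype=np.int8)
    n, m = hc.shape
    pos = positions if positions is not None else (np.arange(m) + 1) * 1000
    variants = pd.DataFrame(
        {
            "id": [f"rs{i}" for i in range(m)],
            "chrom": [chrom] * m,
            "pos": np.asarray(pos, dtype=np.int64),
            "a1": ["A"] * m,
            "a2": ["G"] * m,
        }
    )
    samples = pd.DataFrame(
        {"fid": [f"F{i}" for i in range(n)], "iid": [f"S{i}" for i in range(n)]}
    )
    return GenotypeDataset(samples=samples, variants=variants, hardcalls=hc)


def make_panel(dataset, betas=None, pvalues=None, actions=None):
    """HarmonizedPanel over all variants of a dataset, canonical P order."""
    from collections import Counter

    from polyscore.sumstats import HarmonizedPanel

    m = dataset.n_variants
    betas = np.ones(m) if betas is None else np.asarray(betas, dtype=float)
    pvalues = (
        np.linspace(0.01, 0.99, m) if pvalues is None else np.asarray(pvalues, dtype=float)
    )
    actions = ["match"] * m if actions is None else list(actions)
    entries = pd.DataFrame(
        {
            "variant_idx": np.arange(m),
            "id": dataset.variants["id"],
            "chrom": dataset.variants["chrom"],
            "pos": dataset.variants["pos"],
            "beta": betas,
            "pvalue": pvalues,
            "action": actions,
        }
    ).sort_values(["pvalue", "chrom", "pos", "id"], kind="mergesort").reset_index(drop=True)
    return HarmonizedPanel(entries=entries, drop_log=Counter())
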