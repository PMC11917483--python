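import numpy as np
import pandas as pd
import pytest

from landgea import synthetic


@pytest.fixture(scope="session")
def env_landscape():
    """Smooth 20x20 six-variable landscape with 90 sampled sites."""
    return synthetic.simulate_env_landscape(20, 20, 6, seed=11, n_sites=90)


@pytest.fixture(scope="session")
def sim_study(env_landscape):
    """A 3-population, 2,000-locus study with planted adaptive loci and
    the observed missing-data rate."""
    _, sites = env_landscape
    cfg = synthetic.SimConfig(
        n_pops=3, n_per_pop=30, n_loci=2000, fst_neutral=0.05,
        n_adaptive=20, beta_env=2.0, missing_rate=0.1438, seed=11,
    )
    G, truth = synthetic.simulate_structured_genotypes(cfg, sites)
    return G, truth, sites, cfg


@pytest.fixture()
def tiny_gff(tmp_path):
    """Two genes on chrom 1A (one per strand) for proximity annotation."""
    text = "\n".join([
        "##gff-version 3",
        "1A\ttest\tgene\t5000\t8000\t.\t+\t.\tID=geneA",
        "1A\ttest\tgene\t20000\t25000\t.\t-\t.\tID=geneB",
        "",
    ])
    path = tmp_path / "genes.gff3"
    path.write_text(text)
    return path
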