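"""Shared fixtures: small simulated trials reused across test modules."""

import numpy as np
import pytest

from treegs.relatedness import blend, build_A, build_G
from treegs.simulate import SimConfig, simulate_dataset


def single_site_config(seed: int, **overrides) -> SimConfig:
    """One-site, one-trait trial (n = 608) used by evaluation-level tests."""
    base = dict(
        seed=seed,
        n_snps=500,
        n_sites=1,
        offspring_per_family_per_site=16,
        trait_names=("height",),
        h2_true=(0.46,),
        genetic_corr_true=np.array([[1.0]]),
        drought_corr_traits=(0.5,),
        pheno_means=(784.0,),
        pheno_sds=(158.4,),
        site_offset_sd_units=(0.0,),
        drought_year_per_site=(2010,),
        drought_multiplier_mean=(0.94,),
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def trial():
    """Default two-site trial (38 families x 8 offspring x 2 sites, 500 SNPs)."""
    return simulate_dataset(SimConfig(seed=7))


@pytest.fixture(scope="session")
def eval_trial():
    """Single-site single-trait trial with its relationship matrices."""
    data = simulate_dataset(single_site_config(11))
    G = build_G(data.genotypes)
    Gb = blend(G)
    A = build_A(data.pedigree).submatrix(list(data.meta["id"]))
    return data, G, Gb, A
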