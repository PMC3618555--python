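import numpy as np
import pytest

import trmscan as t
from trmscan.mars_engine import MarsConfig
from trmscan.rf_screen import ForestConfig
from trmscan.synthetic_data import InteractionEffect, MainEffect

#: dominant x dominant interaction cells: both SNPs carry >= 1 minor allele
DOM_DOM_CELLS = frozenset((a, b) for a in (1, 2) for b in (1, 2))


def scaled_forest(seed: int = 5, first: int = 100, iter_: int = 40) -> ForestConfig:
    """Forest settings scaled for test runtimes (full-study defaults are
    5000/2000 trees; see docs/methods.md)."""
    return ForestConfig(n_trees_first=first, n_trees_iter=iter_,
                        drop_fraction=0.6, min_leaf=32, seed=seed)


def scaled_trm(seed: int = 5, first: int = 100, iter_: int = 40,
               **kw) -> t.TrmConfig:
    return t.TrmConfig(forest=scaled_forest(seed, first, iter_),
                       mars=MarsConfig(penalty_d=3.0, seed=seed),
                       seed=seed, **kw)


@pytest.fixture(scope="session")
def planted_pair_cohort():
    """Study-shaped cohort (659/492) with one pure dominant x dominant
    interaction (OR 2.2) planted among 200 SNPs."""
    spec = t.CohortSpec(
        n_snps=200, missing_rate=0.0, seed=3,
        interactions=[InteractionEffect(snp_a=20, snp_b=40,
                                        cells=DOM_DOM_CELLS, or_=2.2)])
    gm, phen = t.simulate_cohort(spec)
    return spec, gm, phen


@pytest.fixture(scope="session")
def planted_main_cohort():
    """Cohort with a single dominant main effect (OR 2.0) among 100 SNPs."""
    spec = t.CohortSpec(
        n_snps=100, missing_rate=0.0, seed=17,
        main_effects=[MainEffect(snp=30, model=t.ModelCode.DOMINANT, or_=2.0)])
    gm, phen = t.simulate_cohort(spec)
    return spec, gm, phen


@pytest.fixture(scope="session")
def null_cohort():
    """Genotypes with no planted effects and an outcome independent of them."""
    spec = t.CohortSpec(n_snps=100, missing_rate=0.0, seed=23)
    gm, phen = t.simulate_cohort(spec)
    return spec, gm, phen
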