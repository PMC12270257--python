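import dataclasses
import io

import numpy as np
import pytest
from scipy import special

from penfam.model import BaselineRisk, WeibullParams
from penfam.pedigrees import Pedigree, parse_pedigrees
from penfam.simulate import SimDesign, poisson, simulate_family


def discrete_ks_pvalue(draws, cdf_at_support, support):
    """KS test for integer-valued draws against a discrete CDF.

    Compares the empirical CDF with the model CDF at the support points
    (both inclusive of the atom) and applies the asymptotic Kolmogorov
    p-value, which is conservative for discrete distributions.
    """
    draws = np.asarray(draws)
    n = draws.size
    ecdf = np.array([(draws <= k).mean() for k in support])
    d = np.max(np.abs(ecdf - np.asarray(cdf_at_support)))
    return float(special.kolmogorov(d * np.sqrt(n)))


NUCLEAR_CSV = """PedigreeID,ID,Sex,MotherID,FatherID,isProband,CurAge,isAff,Age,Geno
1,1,0,NA,NA,0,70,0,NA,NA
1,2,1,NA,NA,0,75,1,60,NA
1,3,0,1,2,1,45,1,40,1
1,4,1,1,2,0,42,0,NA,NA
"""


@pytest.fixture
def nuclear_pedigree() -> Pedigree:
    return parse_pedigrees(io.StringIO(NUCLEAR_CSV))[0]


@pytest.fixture
def baseline() -> BaselineRisk:
    return BaselineRisk.from_points(
        [30, 50, 70, 94], [0.001, 0.005, 0.02, 0.04], [0.001, 0.006, 0.025, 0.05]
    )


@pytest.fixture
def theta() -> WeibullParams:
    return WeibullParams(alpha=40.0, beta=2.6, gamma=0.6, delta=18.0)


def small_design(prevalence=0.1, **kw) -> SimDesign:
    """A design producing small families, suitable for enumeration oracles."""
    defaults = dict(
        n_probands=1,
        prevalence=prevalence,
        sibs=poisson(1.0),
        aunts_uncles_per_side=poisson(0.4),
        cousins_per_aunt_uncle=poisson(0.7),
        children_per_couple=poisson(0.5),
    )
    defaults.update(kw)
    return SimDesign(**defaults)


def random_small_family(rng, max_members=12, mask_rate=0.2, **design_kw):
    """A random simulated family of at most ``max_members`` with random missingness."""
    design = small_design(
        prevalence=float(rng.uniform(0.01, 0.5)),
        theta_female=WeibullParams(
            float(rng.uniform(20, 50)),
            float(rng.uniform(1, 5)),
            float(rng.uniform(0.2, 0.9)),
            float(rng.uniform(5, 30)),
        ),
        theta_male=WeibullParams(
            float(rng.uniform(20, 50)),
            float(rng.uniform(1, 5)),
            float(rng.uniform(0.2, 0.9)),
            float(rng.uniform(5, 30)),
        ),
        geno_obs_rate=float(rng.uniform(0, 0.5)),
        **design_kw,
    )
    while True:
        ped, _ = simulate_family(design, rng)
        if len(ped) <= max_members:
            break
    members = []
    for m in ped.members:
        m2 = dataclasses.replace(m)
        if rng.uniform() < mask_rate:
            m2.is_aff, m2.onset_age = None, None
        if rng.uniform() < mask_rate and m2.is_aff != 1:
            m2.cur_age = None
        members.append(m2)
    return Pedigree(family_id=ped.family_id, members=members), design
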