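"""Synthetic family-study generator with known ground truth.

Families are built as three generations around an ascertained proband:
four grandparents, two parents, aunts/uncles with spouses and children,
siblings, and offspring of the proband and siblings.  Founder genotypes
follow Hardy-Weinberg at the design prevalence, children follow Mendelian
transmission, and families are rejection-resampled until the proband is a
carrier.  Phenotypes arise from the carrier (sex-specific Weibull) or
noncarrier (baseline) annual onset distribution, censored at an
individual-specific censoring age.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .likelihood import founder_genotype_probs, transmission_matrix
from .model import (
    DEFAULT_MAX_AGE,
    FEMALE,
    MALE,
    BaselineRisk,
    WeibullParams,
    annual_onset_prob,
)
from .pedigrees import IndividualRecord, Pedigree

_T = transmission_matrix()


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CountDist:
    """A small nonnegative count distribution: fixed or Poisson."""

    kind: str  # 'fixed' | 'poisson'
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "poisson"):
            raise SimulationError(f"unknown count distribution {self.kind!r}")
        if self.value < 0:
            raise SimulationError("count distribution mean must be nonnegative")

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "fixed":
            return int(self.value)
        return int(rng.poisson(self.value))

    @property
    def mean(self) -> float:
        return float(self.value)


def fixed(k: int) -> CountDist:
    return CountDist("fixed", k)


def poisson(mean: float) -> CountDist:
    return CountDist("poisson", mean)


@dataclass
class SimDesign:
    n_probands: int = 130
    sibs: CountDist = field(default_factory=lambda: poisson(2.0))
    aunts_uncles_per_side: CountDist = field(default_factory=lambda: poisson(2.0))
    cousins_per_aunt_uncle: CountDist = field(default_factory=lambda: poisson(2.2))
    children_per_couple: CountDist = field(default_factory=lambda: poisson(2.0))
    prevalence: float = 0.005
    theta_female: WeibullParams = field(
        default_factory=lambda: WeibullParams(alpha=40.0, beta=2.6, gamma=0.6, delta=18.0)
    )
    theta_male: WeibullParams = field(
        default_factory=lambda: WeibullParams(alpha=38.0, beta=2.8, gamma=0.65, delta=18.0)
    )
    baseline: BaselineRisk | None = None
    censor_mean: float = 60.0
    censor_sd: float = 15.0
    proband_carrier: bool = True
    proband_affected: bool = False
    geno_obs_rate: float = 0.0  # probability a relative's genotype is observed
    max_age: int = DEFAULT_MAX_AGE
    max_rejection: int = 100000

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise SimulationError("prevalence must lie in (0,1)")
        if self.baseline is None:
            self.baseline = default_crc_baseline(self.max_age)

    def expected_family_size(self) -> float:
        """Analytic mean family size implied by the design distributions."""
        s = self.sibs.mean
        a = 2.0 * self.aunts_uncles_per_side.mean
        k = self.cousins_per_aunt_uncle.mean
        ch = self.children_per_couple.mean
        return 7.0 + s + 2.0 * a + a * k + (1.0 + s) * (1.0 + ch)


def default_crc_baseline(max_age: int = DEFAULT_MAX_AGE) -> BaselineRisk:
    """SEER-style colorectal-cancer-like cumulative risk reaching ~4-5% by old age."""
    ages = [30, 40, 50, 60, 70, 80, max_age]
    female = [0.0003, 0.001, 0.003, 0.008, 0.017, 0.030, 0.041]
    male = [0.0003, 0.001, 0.0035, 0.010, 0.021, 0.035, 0.047]
    return BaselineRisk.from_points(ages, female, male, max_age=max_age)


class _Builder:
    def __init__(self):
        self.rows: list[dict] = []
        self._next = 1

    def add(self, sex, mother=None, father=None, proband=False):
        ind = str(self._next)
        self._next += 1
        self.rows.append(
            dict(id=ind, sex=sex, mother=mother, father=father, proband=proband)
        )
        return ind


def _rand_sex(rng) -> str:
    return FEMALE if rng.uniform() < 0.5 else MALE


def _couple(b: _Builder, person_id: str, person_sex: str, spouse_id: str):
    """Order (mother, father) for a couple given one member's sex."""
    return (person_id, spouse_id) if person_sex == FEMALE else (spouse_id, person_id)


def simulate_structure(design: SimDesign, rng: np.random.Generator) -> Pedigree:
    """One family skeleton (ids, sexes, parent links, proband flag)."""
    b = _Builder()
    mgm = b.add(FEMALE)
    mgf = b.add(MALE)
    pgm = b.add(FEMALE)
    pgf = b.add(MALE)
    mother = b.add(FEMALE, mother=mgm, father=mgf)
    father = b.add(MALE, mother=pgm, father=pgf)
    proband = b.add(_rand_sex(rng), mother=mother, father=father, proband=True)

    for side_gm, side_gf in ((mgm, mgf), (pgm, pgf)):
        for _ in range(design.aunts_uncles_per_side.sample(rng)):
            au_sex = _rand_sex(rng)
            au = b.add(au_sex, mother=side_gm, father=side_gf)
            spouse = b.add(FEMALE if au_sex == MALE else MALE)
            mo, fa = _couple(b, au, au_sex, spouse)
            for _ in range(design.cousins_per_aunt_uncle.sample(rng)):
                b.add(_rand_sex(rng), mother=mo, father=fa)

    own_couples = []
    pr_sex = next(r["sex"] for r in b.rows if r["id"] == proband)
    own_couples.append((proband, pr_sex))
    for _ in range(design.sibs.sample(rng)):
        sib_sex = _rand_sex(rng)
        sib = b.add(sib_sex, mother=mother, father=father)
        own_couples.append((sib, sib_sex))

    for person, sex in own_couples:
        spouse = b.add(FEMALE if sex == MALE else MALE)
        mo, fa = _couple(b, person, sex, spouse)
        for _ in range(design.children_per_couple.sample(rng)):
            b.add(_rand_sex(rng), mother=mo, father=fa)

    members = [
        IndividualRecord(
            id=r["id"],
            sex=r["sex"],
            mother_id=r["mother"],
            father_id=r["father"],
            is_proband=r["proband"],
        )
        for r in b.rows
    ]
    return Pedigree(family_id="sim", members=members)


def _assign_genotypes(skeleton: Pedigree, probs: np.ndarray, rng) -> dict[str, int]:
    """True genotype (0/1/2 = aa/Aa/AA) per member; parents precede children."""
    geno: dict[str, int] = {}
    for m in skeleton.members:  # construction order guarantees parents first
        if m.is_founder:
            geno[m.id] = int(rng.choice(3, p=probs))
        else:
            gm_, gf_ = geno[m.mother_id], geno[m.father_id]
            geno[m.id] = int(rng.choice(3, p=_T[:, gm_, gf_]))
    return geno


def drop_genotypes(
    skeleton: Pedigree, design: SimDesign, rng: np.random.Generator
) -> dict[str, int]:
    """True genotypes, rejection-resampled until the proband is a carrier."""
    probs = founder_genotype_probs(design.prevalence)
    proband = skeleton.proband_ids[0]
    for _ in range(design.max_rejection):
        geno = _assign_genotypes(skeleton, probs, rng)
        if not design.proband_carrier or geno[proband] >= 1:
            return geno
    raise SimulationError(
        "rejection sampling failed to produce a carrier proband; "
        "prevalence may be too small for the attempt budget"
    )


def _censor_age(design: SimDesign, rng) -> int:
    a = rng.normal(design.censor_mean, design.censor_sd)
    return int(np.clip(round(a), 1, design.max_age))


def simulate_phenotypes(
    skeleton: Pedigree,
    true_geno: dict[str, int],
    design: SimDesign,
    rng: np.random.Generator,
    censor_at: int | None = None,
) -> Pedigree:
    """Attach censoring ages, onsets and observed genotypes to a skeleton.

    ``censor_at`` forces a common censoring age (used by fidelity checks).
    """
    onset_annual = {
        (1, FEMALE): annual_onset_prob(design.theta_female, design.max_age),
        (1, MALE): annual_onset_prob(design.theta_male, design.max_age),
        (0, FEMALE): design.baseline.annual(FEMALE),
        (0, MALE): design.baseline.annual(MALE),
    }
    cums = {k: np.cumsum(v) for k, v in onset_annual.items()}

    members = []
    for m in skeleton.members:
        carrier = 1 if true_geno[m.id] >= 1 else 0
        cum = cums[(carrier, m.sex)]
        cur = censor_at if censor_at is not None else _censor_age(design, rng)
        u = rng.uniform()
        if u < cum[-1]:
            onset = int(np.searchsorted(cum, u) + 1)
        else:
            onset = None
        if onset is not None and onset <= cur:
            is_aff, onset_age = 1, onset
        else:
            is_aff, onset_age = 0, None

        if m.is_proband:
            geno_obs = 1 if carrier else 0
        elif design.geno_obs_rate > 0 and rng.uniform() < design.geno_obs_rate:
            geno_obs = carrier
        else:
            geno_obs = None
        members.append(
            IndividualRecord(
                id=m.id,
                sex=m.sex,
                mother_id=m.mother_id,
                father_id=m.father_id,
                is_proband=m.is_proband,
                cur_age=cur,
                is_aff=is_aff,
                onset_age=onset_age,
                geno=geno_obs,
            )
        )
    return Pedigree(family_id=skeleton.family_id, members=members)


def simulate_family(
    design: SimDesign, rng: np.random.Generator, family_id: str = "1"
) -> tuple[Pedigree, dict[str, int]]:
    """One complete family honoring the proband ascertainment conditions."""
    for _ in range(design.max_rejection):
        skeleton = simulate_structure(design, rng)
        geno = drop_genotypes(skeleton, design, rng)
        ped = simulate_phenotypes(skeleton, geno, design, rng)
        proband = ped.proband_ids[0]
        if design.proband_affected and ped[proband].is_aff != 1:
            continue
        members = [IndividualRecord(**{**m.__dict__}) for m in ped.members]
        return Pedigree(family_id=family_id, members=members), geno
    raise SimulationError("could not satisfy proband ascertainment conditions")


def simulate_study(
    design: SimDesign, seed: int | np.random.Generator = 0
) -> tuple[list[Pedigree], dict]:
    """A full study of ``design.n_probands`` ascertained families plus a truth record."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    peds, genos = [], {}
    for i in range(design.n_probands):
        ped, geno = simulate_family(design, rng, family_id=str(i + 1))
        peds.append(ped)
        genos[ped.family_id] = geno
    truth = {
        "theta_female": asdict(design.theta_female),
        "theta_male": asdict(design.theta_male),
        "prevalence": design.prevalence,
        "n_probands": design.n_probands,
        "true_genotypes": genos,
    }
    return peds, truth
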