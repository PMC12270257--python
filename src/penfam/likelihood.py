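"""Pedigree likelihood for a single autosomal biallelic locus.

Genotypes are ordered (aa, Aa, AA) with A the risk allele; Aa and AA share
the carrier penetrance (dominant risk model) but are kept as distinct
states so Mendelian transmission is exact.  Founder genotypes follow
Hardy-Weinberg with allele frequency f = 1 - sqrt(1 - prevalence), which
makes the founder carrier probability equal the supplied prevalence.

The likelihood of a family is the sum over all genotype configurations of
founder priors x Mendelian transmissions x per-individual phenotype terms.
It is computed by peeling (dynamic programming on the tree of nuclear
families; linear in family size for loop-free pedigrees), cross-checked in
the test suite against explicit enumeration over all 3^n configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import (
    DEFAULT_MAX_AGE,
    FEMALE,
    MALE,
    BaselineRisk,
    WeibullParams,
    annual_onset_prob,
    penetrance_cdf,
)
from .pedigrees import Pedigree

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

AA_REF, HET, HOM = 0, 1, 2  # genotype state order: aa, Aa, AA

_NEG_INF = float("-inf")


class LikelihoodError(ValueError):
    pass


class LoopedPedigreeError(LikelihoodError):
    """Peeling requires loop-free pedigrees; loops must be resolved upstream."""


def founder_genotype_probs(prevalence: float) -> np.ndarray:
    """Hardy-Weinberg founder probabilities (aa, Aa, AA) for a given carrier prevalence."""
    if not (0.0 < prevalence < 1.0):
        raise LikelihoodError(f"prevalence must lie in (0,1), got {prevalence}")
    f = 1.0 - math.sqrt(1.0 - prevalence)
    return np.array([(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f * f])


def transmission_matrix() -> np.ndarray:
    """T[child, mother, father]: Mendelian segregation for a biallelic locus."""
    pass_prob = np.array([0.0, 0.5, 1.0])  # P(transmit risk allele | genotype)
    T = np.zeros((3, 3, 3))
    for gm in range(3):
        for gf in range(3):
            pm, pf = pass_prob[gm], pass_prob[gf]
            T[HOM, gm, gf] = pm * pf
            T[HET, gm, gf] = pm * (1.0 - pf) + (1.0 - pm) * pf
            T[AA_REF, gm, gf] = (1.0 - pm) * (1.0 - pf)
    return T


_T = transmission_matrix()


def transmission_prob(child_g: int, mother_g: int, father_g: int) -> float:
    return float(_T[child_g, mother_g, father_g])


@dataclass(frozen=True)
class GenotypeModel:
    """Founder genotype prior implied by a carrier prevalence."""

    prevalence: float

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise LikelihoodError(f"prevalence must lie in (0,1), got {self.prevalence}")

    @property
    def allele_freq(self) -> float:
        return 1.0 - math.sqrt(1.0 - self.prevalence)

    @property
    def founder_probs(self) -> np.ndarray:
        return founder_genotype_probs(self.prevalence)


class PenetranceSet:
    """Per-sex, per-carrier-class annual onset and cumulative risk vectors.

    Index 0 of each per-sex array corresponds to age 1.  A third sex slot
    (index 2) holds the female/male average used for unknown-sex members.
    """

    def __init__(
        self,
        theta_female: WeibullParams,
        theta_male: WeibullParams,
        baseline: BaselineRisk,
        max_age: int = DEFAULT_MAX_AGE,
    ):
        self.max_age = max_age
        self.theta = {FEMALE: theta_female, MALE: theta_male}
        ages = np.arange(1, max_age + 1, dtype=float)

        def stack(f_vec, m_vec):
            return np.vstack([f_vec, m_vec, 0.5 * (f_vec + m_vec)])

        car_onset_f = annual_onset_prob(theta_female, max_age)
        car_onset_m = annual_onset_prob(theta_male, max_age)
        car_cum_f = np.asarray(penetrance_cdf(theta_female, ages))
        car_cum_m = np.asarray(penetrance_cdf(theta_male, ages))
        nc_onset_f = baseline.annual(FEMALE)
        nc_onset_m = baseline.annual(MALE)
        nc_cum_f = baseline.cumulative(FEMALE)
        nc_cum_m = baseline.cumulative(MALE)

        # rows: sex 0=F, 1=M, 2=unknown (average); columns: age-1
        self.carrier_onset = stack(car_onset_f, car_onset_m)
        self.carrier_surv = stack(1.0 - car_cum_f, 1.0 - car_cum_m)
        self.noncarrier_onset = stack(nc_onset_f, nc_onset_m)
        self.noncarrier_surv = stack(1.0 - nc_cum_f, 1.0 - nc_cum_m)


# ---------------------------------------------------------------------------
# individual-level data arrays and phenotype likelihood vectors


_SEX_TO_CODE = {FEMALE: 0, MALE: 1, "U": 2}


class IndividualArrays:
    """Flat per-individual observation arrays across a pedigree collection.

    Missing integers are coded -1.  ``onset`` / ``cur`` may be overwritten
    by the imputation machinery; structural fields are fixed.
    """

    def __init__(self, peds: list[Pedigree]):
        index: dict[tuple[str, str], int] = {}
        sex, aff, onset, cur, geno, fam = [], [], [], [], [], []
        for fi, p in enumerate(peds):
            for m in p.members:
                index[(p.family_id, m.id)] = len(sex)
                sex.append(_SEX_TO_CODE[m.sex])
                aff.append(-1 if m.is_aff is None else m.is_aff)
                onset.append(-1 if m.onset_age is None else m.onset_age)
                cur.append(-1 if m.cur_age is None else m.cur_age)
                geno.append(-1 if m.geno is None else m.geno)
                fam.append(fi)
        self.index = index
        self.sex = np.array(sex, dtype=np.int64)
        self.aff = np.array(aff, dtype=np.int64)
        self.onset = np.array(onset, dtype=np.int64)
        self.cur = np.array(cur, dtype=np.int64)
        self.geno = np.array(geno, dtype=np.int64)
        self.fam = np.array(fam, dtype=np.int64)
        self.n = len(sex)


def phenotype_matrix(arrays: IndividualArrays, pen: PenetranceSet) -> np.ndarray:
    """(n, 3) matrix of P(observation | genotype) per individual.

    Affected members contribute the onset probability in their diagnosis
    year; unaffected members the survival to their censoring age; unknown
    phenotypes contribute ones.  Observed genotypes enter as indicators.
    """
    n = arrays.n
    out = np.ones((n, 3))

    affected = arrays.aff == 1
    if np.any(affected & (arrays.onset < 0)):
        bad = np.where(affected & (arrays.onset < 0))[0]
        raise LikelihoodError(
            f"{bad.size} affected individual(s) have no onset age; "
            "enable age imputation or supply onset ages"
        )
    if np.any(affected):
        idx = np.where(affected)[0]
        a = arrays.onset[idx] - 1
        s = arrays.sex[idx]
        car = pen.carrier_onset[s, a]
        out[idx, HET] = car
        out[idx, HOM] = car
        out[idx, AA_REF] = pen.noncarrier_onset[s, a]

    unaff = (arrays.aff == 0) & (arrays.cur >= 1)
    if np.any(unaff):
        idx = np.where(unaff)[0]
        c = arrays.cur[idx] - 1
        s = arrays.sex[idx]
        car = pen.carrier_surv[s, c]
        out[idx, HET] = car
        out[idx, HOM] = car
        out[idx, AA_REF] = pen.noncarrier_surv[s, c]

    out[arrays.geno == 1, AA_REF] = 0.0
    noncar = arrays.geno == 0
    out[noncar, HET] = 0.0
    out[noncar, HOM] = 0.0
    return out


def phenotype_likelihood(record, pen: PenetranceSet) -> np.ndarray:
    """Per-genotype likelihood 3-vector for one :class:`IndividualRecord`."""
    from .pedigrees import Pedigree as _P

    arr = IndividualArrays([_P(family_id="_", members=[record])])
    return phenotype_matrix(arr, pen)[0]


# ---------------------------------------------------------------------------
# peeling engine


def _peel_kernel_py(
    part,
    st_mother,
    st_father,
    st_cstart,
    st_ccount,
    children,
    st_pivot,
    st_spouse,
    st_pivot_cpos,
    st_fam,
    root_idx,
    root_fam,
    iso_idx,
    iso_fam,
    T,
    out,
):
    nsteps = st_pivot.shape[0]
    msg = np.zeros(3)
    for s in range(nsteps):
        fidx = st_fam[s]
        if out[fidx] == _NEG_INF:
            continue
        m = st_mother[s]
        f = st_father[s]
        q = st_pivot[s]
        c0 = st_cstart[s]
        nc = st_ccount[s]
        cpos = st_pivot_cpos[s]
        for g in range(3):
            msg[g] = 0.0
        if cpos < 0:
            sp = st_spouse[s]
            for gq in range(3):
                acc = 0.0
                for gs in range(3):
                    w = part[sp, gs]
                    if w == 0.0:
                        continue
                    prod = 1.0
                    for k in range(nc):
                        c = children[c0 + k]
                        t = 0.0
                        for gc in range(3):
                            t += T[gc, gq, gs] * part[c, gc]
                        prod *= t
                        if prod == 0.0:
                            break
                    acc += w * prod
                msg[gq] = acc
        else:
            for gm in range(3):
                wm = part[m, gm]
                if wm == 0.0:
                    continue
                for gf in range(3):
                    wf = part[f, gf]
                    if wf == 0.0:
                        continue
                    prod = 1.0
                    for k in range(nc):
                        if k == cpos:
                            continue
                        c = children[c0 + k]
                        t = 0.0
                        for gc in range(3):
                            t += T[gc, gm, gf] * part[c, gc]
                        prod *= t
                        if prod == 0.0:
                            break
                    w = wm * wf * prod
                    if w == 0.0:
                        continue
                    for gq in range(3):
                        msg[gq] += w * T[gq, gm, gf]
        mx = 0.0
        for g in range(3):
            part[q, g] *= msg[g]
            if part[q, g] > mx:
                mx = part[q, g]
        if mx <= 0.0:
            out[fidx] = _NEG_INF
        else:
            for g in range(3):
                part[q, g] /= mx
            out[fidx] += math.log(mx)

    for r in range(root_idx.shape[0]):
        fidx = root_fam[r]
        if out[fidx] == _NEG_INF:
            continue
        tot = part[root_idx[r], 0] + part[root_idx[r], 1] + part[root_idx[r], 2]
        if tot <= 0.0:
            out[fidx] = _NEG_INF
        else:
            out[fidx] += math.log(tot)

    for r in range(iso_idx.shape[0]):
        fidx = iso_fam[r]
        if out[fidx] == _NEG_INF:
            continue
        tot = part[iso_idx[r], 0] + part[iso_idx[r], 1] + part[iso_idx[r], 2]
        if tot <= 0.0:
            out[fidx] = _NEG_INF
        else:
            out[fidx] += math.log(tot)


if _HAVE_NUMBA:
    _peel_kernel = njit(cache=False)(_peel_kernel_py)
else:  # pragma: no cover
    _peel_kernel = _peel_kernel_py


class PeelingEngine:
    """Precompiled peeling schedules for a fixed pedigree collection.

    The schedule depends only on pedigree structure, so it is built once and
    the per-evaluation cost is a single pass over flat arrays given a fresh
    phenotype matrix.
    """

    def __init__(self, peds: list[Pedigree], gm: GenotypeModel):
        self.peds = peds
        self.gm = gm
        self.arrays = IndividualArrays(peds)
        self.n_fam = len(peds)
        self.founder_mask = np.zeros(self.arrays.n, dtype=bool)

        st_mother, st_father, st_cstart, st_ccount = [], [], [], []
        st_pivot, st_spouse, st_cpos, st_fam = [], [], [], []
        children_flat: list[int] = []
        root_idx, root_fam = [], []
        iso_idx, iso_fam = [], []
        self._fam_step_range: list[tuple[int, int]] = []

        for fi, p in enumerate(peds):
            gidx = {m.id: self.arrays.index[(p.family_id, m.id)] for m in p.members}
            for m in p.members:
                if m.is_founder:
                    self.founder_mask[gidx[m.id]] = True

            fams = list(p.nuclear_families().items())
            # membership: individual -> nuclear family slots
            member_fams: dict[str, list[int]] = {m.id: [] for m in p.members}
            for k, ((mo, fa), kids) in enumerate(fams):
                for ind in (mo, fa, *kids):
                    member_fams[ind].append(k)
                # loop check: an individual appearing twice in one family
                if len({mo, fa, *kids}) != 2 + len(kids):
                    raise LoopedPedigreeError(
                        f"family {p.family_id}: individual repeated within a nuclear family"
                    )

            # cycle detection via union-find over bipartite membership edges
            parent = list(range(len(p.members) + len(fams)))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            local = {m.id: j for j, m in enumerate(p.members)}
            for k, ((mo, fa), kids) in enumerate(fams):
                fnode = len(p.members) + k
                for ind in (mo, fa, *kids):
                    a, b = find(local[ind]), find(fnode)
                    if a == b:
                        raise LoopedPedigreeError(
                            f"family {p.family_id}: pedigree contains a loop"
                        )
                    parent[a] = b

            step0 = len(st_pivot)
            visited_fam = set()
            for ind, fs in member_fams.items():
                if not fs:
                    iso_idx.append(gidx[ind])
                    iso_fam.append(fi)

            for k0 in range(len(fams)):
                if k0 in visited_fam:
                    continue
                # BFS over the family tree of this connected component
                order = [(k0, None)]  # (family slot, connector individual toward parent)
                visited_fam.add(k0)
                qi = 0
                while qi < len(order):
                    k, _ = order[qi]
                    qi += 1
                    (mo, fa), kids = fams[k]
                    for ind in (mo, fa, *kids):
                        for k2 in member_fams[ind]:
                            if k2 not in visited_fam:
                                visited_fam.add(k2)
                                order.append((k2, ind))

                # process in reverse BFS order (leaves first)
                for k, connector in reversed(order):
                    (mo, fa), kids = fams[k]
                    pivot = connector if connector is not None else mo
                    st_mother.append(gidx[mo])
                    st_father.append(gidx[fa])
                    st_cstart.append(len(children_flat))
                    st_ccount.append(len(kids))
                    children_flat.extend(gidx[c] for c in kids)
                    st_pivot.append(gidx[pivot])
                    if pivot in kids:
                        st_cpos.append(kids.index(pivot))
                        st_spouse.append(-1)
                    else:
                        st_cpos.append(-1)
                        st_spouse.append(gidx[fa] if pivot == mo else gidx[mo])
                    st_fam.append(fi)
                root_pivot = fams[k0][0][0]  # mother of the BFS root family
                root_idx.append(gidx[root_pivot])
                root_fam.append(fi)
            self._fam_step_range.append((step0, len(st_pivot)))

        as_i = lambda x: np.asarray(x, dtype=np.int64)
        self._st = (
            as_i(st_mother),
            as_i(st_father),
            as_i(st_cstart),
            as_i(st_ccount),
            as_i(children_flat),
            as_i(st_pivot),
            as_i(st_spouse),
            as_i(st_cpos),
            as_i(st_fam),
        )
        self._roots = (as_i(root_idx), as_i(root_fam))
        self._iso = (as_i(iso_idx), as_i(iso_fam))

    def loglik_per_family(self, penmat: np.ndarray) -> np.ndarray:
        """Per-family log-likelihoods given an (n, 3) phenotype matrix."""
        part = penmat.copy()
        part[self.founder_mask] *= self.gm.founder_probs
        out = np.zeros(self.n_fam)
        _peel_kernel(part, *self._st, *self._roots, *self._iso, _T, out)
        return out

    def loglik_total(self, penmat: np.ndarray) -> float:
        return float(np.sum(self.loglik_per_family(penmat)))

    def carrier_posterior_from_penmat(self, penmat: np.ndarray, gi: int) -> float:
        """P(individual gi is a carrier | family data) from a phenotype matrix."""
        fi = int(self.arrays.fam[gi])
        full = self.loglik_per_family(penmat)[fi]
        restricted = penmat.copy()
        restricted[gi, AA_REF] = 0.0
        part = restricted
        part[self.founder_mask] *= self.gm.founder_probs
        out = np.zeros(self.n_fam)
        _peel_kernel(part, *self._st, *self._roots, *self._iso, _T, out)
        r = out[fi]
        if full == _NEG_INF:
            raise LikelihoodError("family data have probability zero")
        if r == _NEG_INF:
            return 0.0
        return float(min(1.0, math.exp(r - full)))


def peel_loglikelihood(p: Pedigree, gm: GenotypeModel, pen: PenetranceSet) -> float:
    """Log-likelihood of one family by peeling (loop-free pedigrees only)."""
    eng = PeelingEngine([p], gm)
    penmat = phenotype_matrix(eng.arrays, pen)
    return float(eng.loglik_per_family(penmat)[0])


def brute_force_loglikelihood(
    p: Pedigree, gm: GenotypeModel, pen: PenetranceSet, max_members: int = 15
) -> float:
    """Explicit sum over all 3^n genotype configurations (test oracle)."""
    n = len(p)
    if n > max_members:
        raise LikelihoodError(f"brute force refused for {n} > {max_members} members")
    eng_arrays = IndividualArrays([p])
    penmat = phenotype_matrix(eng_arrays, pen)
    prior = gm.founder_probs

    combos = np.stack(
        np.meshgrid(*([np.arange(3)] * n), indexing="ij"), axis=-1
    ).reshape(-1, n)
    like = np.ones(combos.shape[0])
    local = {m.id: j for j, m in enumerate(p.members)}
    for j, m in enumerate(p.members):
        g = combos[:, j]
        like *= penmat[j, g]
        if m.is_founder:
            like *= prior[g]
        else:
            gm_idx = combos[:, local[m.mother_id]]
            gf_idx = combos[:, local[m.father_id]]
            like *= _T[g, gm_idx, gf_idx]
    total = float(np.sum(like))
    if total <= 0.0:
        return _NEG_INF
    return math.log(total)


def carrier_posterior(
    p: Pedigree, gm: GenotypeModel, pen: PenetranceSet, individual_id: str
) -> float:
    """Posterior probability that one member carries the risk allele."""
    eng = PeelingEngine([p], gm)
    penmat = phenotype_matrix(eng.arrays, pen)
    gi = eng.arrays.index[(p.family_id, individual_id)]
    return eng.carrier_posterior_from_penmat(penmat, gi)
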