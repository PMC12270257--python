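"""In-chain imputation of missing onset and censoring ages.

Missing onset ages of affected members are first filled from the empirical
onset-age distribution of observed affected members in the same sex
stratum (falling back to the baseline-risk onset distribution), and then
periodically redrawn during sampling from a carrier-probability-weighted
mixture of the current carrier onset distribution and the noncarrier
baseline, truncated to the individual's feasible age window.  The redraw
is an approximation: no Metropolis correction is applied to the age draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .likelihood import PeelingEngine, PenetranceSet, phenotype_matrix
from .model import DEFAULT_MAX_AGE, FEMALE, MALE, BaselineRisk, QuantileParams, quantiles_to_weibull
from .pedigrees import Pedigree

logger = logging.getLogger(__name__)

MIN_CENSOR_AGE = 20  # adults only; lower bound for drawn censoring ages


@dataclass(frozen=True)
class ImputationTarget:
    global_index: int
    family_id: str
    individual_id: str
    kind: str  # 'onset' or 'censor'
    sex_code: int  # 0 female, 1 male, 2 unknown
    affected: bool


@dataclass
class ImputationPlan:
    targets: list[ImputationTarget] = field(default_factory=list)
    schedule: int = 100

    @property
    def onset_targets(self) -> list[ImputationTarget]:
        return [t for t in self.targets if t.kind == "onset"]

    @property
    def censor_targets(self) -> list[ImputationTarget]:
        return [t for t in self.targets if t.kind == "censor"]


_SEX_CODE = {FEMALE: 0, MALE: 1, "U": 2}


def build_plan(peds: list[Pedigree], schedule: int = 100) -> ImputationPlan:
    """Enumerate individuals whose likelihood contribution needs an age.

    Affected members missing their onset age become onset targets; any
    member missing a censoring age (including unknown-affection members)
    becomes a censoring-age target.
    """
    plan = ImputationPlan(schedule=schedule)
    gi = 0
    for p in peds:
        for m in p.members:
            if m.is_aff == 1 and m.onset_age is None:
                plan.targets.append(
                    ImputationTarget(gi, p.family_id, m.id, "onset", _SEX_CODE[m.sex], True)
                )
            if m.cur_age is None:
                plan.targets.append(
                    ImputationTarget(
                        gi, p.family_id, m.id, "censor", _SEX_CODE[m.sex], m.is_aff == 1
                    )
                )
            gi += 1
    return plan


def _draw_from_annual(probs: np.ndarray, rng: np.random.Generator) -> int | None:
    """Sample an onset year (1-based) from a (possibly subnormalized) annual vector."""
    total = float(probs.sum())
    if total <= 0.0:
        return None
    u = rng.uniform() * total
    return int(np.searchsorted(np.cumsum(probs), u) + 1)


def initial_impute(
    plan: ImputationPlan,
    arrays,
    baseline: BaselineRisk,
    rng: np.random.Generator,
    max_age: int = DEFAULT_MAX_AGE,
) -> None:
    """Fill missing ages in-place in the engine's individual arrays."""
    observed = arrays.onset[(arrays.aff == 1) & (arrays.onset >= 1)]
    pools = {
        0: arrays.onset[(arrays.aff == 1) & (arrays.onset >= 1) & (arrays.sex == 0)],
        1: arrays.onset[(arrays.aff == 1) & (arrays.onset >= 1) & (arrays.sex == 1)],
        2: observed,
    }
    base_annual = {
        0: baseline.annual(FEMALE),
        1: baseline.annual(MALE),
        2: 0.5 * (baseline.annual(FEMALE) + baseline.annual(MALE)),
    }

    for t in plan.onset_targets:
        hi = arrays.cur[t.global_index]
        hi = int(hi) if hi >= 1 else max_age
        pool = pools[t.sex_code]
        if pool.size > 0:
            age = int(rng.choice(pool)) + int(rng.integers(-2, 3))
        else:
            drawn = _draw_from_annual(base_annual[t.sex_code][:hi], rng)
            age = drawn if drawn is not None else int(rng.integers(1, hi + 1))
        arrays.onset[t.global_index] = int(np.clip(age, 1, hi))

    for t in plan.censor_targets:
        draw = int(rng.integers(MIN_CENSOR_AGE, max_age + 1))
        onset = arrays.onset[t.global_index]
        if t.affected and onset >= 1:
            draw = max(draw, int(onset))
        arrays.cur[t.global_index] = draw


def reimpute(
    plan: ImputationPlan,
    engine: PeelingEngine,
    qs: dict[str, QuantileParams],
    baseline: BaselineRisk,
    rng: np.random.Generator,
    max_age: int = DEFAULT_MAX_AGE,
) -> None:
    """Redraw missing ages under the current parameters (in place).

    Onset ages are drawn from w * carrier onset + (1 - w) * baseline onset,
    where w is the individual's posterior carrier probability given all
    current family data; censoring ages are redrawn uniformly on their
    feasible window.
    """
    arrays = engine.arrays
    pen = PenetranceSet(
        quantiles_to_weibull(qs[FEMALE]), quantiles_to_weibull(qs[MALE]), baseline, max_age
    )
    penmat = phenotype_matrix(arrays, pen)
    base_annual = {
        0: baseline.annual(FEMALE),
        1: baseline.annual(MALE),
        2: 0.5 * (baseline.annual(FEMALE) + baseline.annual(MALE)),
    }

    for t in plan.onset_targets:
        gi = t.global_index
        hi = arrays.cur[gi]
        hi = int(hi) if hi >= 1 else max_age
        w = engine.carrier_posterior_from_penmat(penmat, gi)
        carrier = pen.carrier_onset[t.sex_code][:hi]
        noncar = base_annual[t.sex_code][:hi]
        mix = w * carrier + (1.0 - w) * noncar
        drawn = _draw_from_annual(mix, rng)
        if drawn is None:
            logger.warning(
                "family %s individual %s: zero-mass onset window, keeping previous value",
                t.family_id,
                t.individual_id,
            )
            continue
        arrays.onset[gi] = drawn

    for t in plan.censor_targets:
        gi = t.global_index
        lo = MIN_CENSOR_AGE
        onset = arrays.onset[gi]
        if t.affected and onset >= 1:
            lo = max(lo, int(onset))
        arrays.cur[gi] = int(rng.integers(lo, max_age + 1))
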