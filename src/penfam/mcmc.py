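"""Adaptive random-walk Metropolis sampler over the quantile-space parameters.

The state vector is (q1, med, gamma, delta) — one block, or a female block
followed by a male block when estimation is sex-specific.  Proposals are
multivariate Gaussian; after ``adapt_start`` iterations the proposal
covariance is 2.38^2/d times the running empirical covariance of the chain
history plus a small diagonal regularizer (Haario-style adaptive
Metropolis).  Proposals violating the parameter bounds (threshold within
its prior support, delta < q1 < med < max_age, gamma in (0,1)) are
rejected before any likelihood work.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .likelihood import GenotypeModel, PeelingEngine, phenotype_matrix, PenetranceSet
from .model import (
    DEFAULT_MAX_AGE,
    FEMALE,
    MALE,
    BaselineRisk,
    ModelDomainError,
    QuantileParams,
    quantiles_to_weibull,
)
from .pedigrees import Pedigree
from .priors import PriorSet, log_prior_density, prior_component_sd, sample_prior

logger = logging.getLogger(__name__)

BLOCK = ["q1", "med", "gamma", "delta"]


class McmcError(RuntimeError):
    pass


@dataclass
class McmcConfig:
    n_chains: int = 4
    n_iter: int = 20000
    burn_in: float = 0.1
    seed: int = 0
    adapt_start: int = 200
    adapt_epsilon: float = 1e-6
    sex_specific: bool = True
    age_imputation: bool = False
    impute_every: int = 100
    remove_proband: bool = False
    max_age: int = DEFAULT_MAX_AGE
    thin: int = 1
    init_scale: float = 0.1
    adapt_refresh: int = 25  # iterations between proposal-covariance refreshes

    def __post_init__(self) -> None:
        if self.n_iter <= 0:
            raise McmcError("n_iter must be positive")
        if not (0.0 <= self.burn_in < 1.0):
            raise McmcError("burn_in must lie in [0, 1)")
        if self.thin < 1:
            raise McmcError("thin must be >= 1")

    @property
    def dim(self) -> int:
        return 8 if self.sex_specific else 4

    @property
    def n_discard(self) -> int:
        return int(math.floor(self.burn_in * self.n_iter))


def param_names(cfg: McmcConfig) -> list[str]:
    if cfg.sex_specific:
        return [f"{s}.{p}" for s in (FEMALE, MALE) for p in BLOCK]
    return list(BLOCK)


def vector_to_qparams(x: np.ndarray, cfg: McmcConfig) -> dict[str, QuantileParams]:
    """Split the state vector into per-sex QuantileParams (shared if not sex-specific)."""
    def block(v):
        return QuantileParams(q1=v[0], med=v[1], gamma=v[2], delta=v[3])

    if cfg.sex_specific:
        return {FEMALE: block(x[:4]), MALE: block(x[4:])}
    q = block(x)
    return {FEMALE: q, MALE: q}


def qparams_to_vector(qs: dict[str, QuantileParams], cfg: McmcConfig) -> np.ndarray:
    def block(q):
        return [q.q1, q.med, q.gamma, q.delta]

    if cfg.sex_specific:
        return np.array(block(qs[FEMALE]) + block(qs[MALE]))
    return np.array(block(qs[FEMALE]))


def check_bounds(x: np.ndarray, ps: PriorSet, cfg: McmcConfig) -> bool:
    """True iff every per-sex block satisfies the hard parameter constraints."""
    lo, hi = ps.delta_bounds
    for j in range(0, cfg.dim, 4):
        q1, med, gamma, delta = x[j : j + 4]
        if not (lo < delta < hi):
            return False
        if not (delta < q1 < med < cfg.max_age):
            return False
        if not (0.0 < gamma < 1.0):
            return False
    return True


@dataclass
class ChainState:
    current: np.ndarray
    current_log_posterior: float
    initial_diag: np.ndarray  # initial proposal variances (diagonal)
    iteration: int = 0
    accepted: int = 0
    # running moments of the chain history (Welford)
    hist_n: int = 0
    hist_mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    hist_m2: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        d = self.current.shape[0]
        if self.hist_mean is None:
            self.hist_mean = np.zeros(d)
        if self.hist_m2 is None:
            self.hist_m2 = np.zeros((d, d))

    def update_history(self, x: np.ndarray) -> None:
        self.hist_n += 1
        delta = x - self.hist_mean
        self.hist_mean += delta / self.hist_n
        self.hist_m2 += np.outer(delta, x - self.hist_mean)

    def empirical_cov(self) -> np.ndarray:
        if self.hist_n < 2:
            return np.diag(self.initial_diag)
        return self.hist_m2 / (self.hist_n - 1)

    def proposal_covariance(self, cfg: McmcConfig) -> np.ndarray:
        d = self.current.shape[0]
        if self.iteration < cfg.adapt_start or self.hist_n <= d:
            return np.diag(self.initial_diag)
        sd = 2.38**2 / d
        return sd * (self.empirical_cov() + cfg.adapt_epsilon * np.eye(d))

    def proposal_cholesky(self, cfg: McmcConfig) -> np.ndarray:
        """Cached Cholesky factor, refreshed every ``cfg.adapt_refresh`` iterations."""
        chol = getattr(self, "_chol", None)
        if chol is None or self.iteration % cfg.adapt_refresh == 0:
            cov = self.proposal_covariance(cfg)
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                chol = np.linalg.cholesky(cov + 1e-9 * np.eye(cov.shape[0]))
            self._chol = chol
        return chol


def _empirical_init_block(
    onsets: np.ndarray,
    gamma_init: float,
    ps: PriorSet,
    cfg: McmcConfig,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Jittered empirical quartiles for one sex block; None if no onsets."""
    if onsets.size == 0:
        return None
    lo, hi = ps.delta_bounds
    min_onset = float(onsets.min())
    hi_eff = min(hi, min_onset - 0.5)
    if hi_eff <= lo:
        delta = rng.uniform(lo, min(hi, lo + 1.0))
    else:
        delta = rng.uniform(lo, hi_eff)
    q1 = float(np.percentile(onsets, 25)) + rng.normal(0.0, 1.0)
    med = float(np.percentile(onsets, 50)) + rng.normal(0.0, 1.0)
    q1 = min(max(q1, delta + 1.0), cfg.max_age - 2.0)
    med = min(max(med, q1 + 1.0), cfg.max_age - 1.0)
    return np.array([q1, med, gamma_init, delta])


def initialize_state(
    peds: list[Pedigree],
    ps: PriorSet,
    cfg: McmcConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Initial parameter vector from the empirical onset-age distribution.

    q1/med start at the jittered 25th/50th percentiles of observed onset
    ages (per sex when sex-specific), gamma at the observed affected
    proportion among genotyped carriers (clamped to (0.05, 0.95)), delta
    uniformly on the part of its prior support below the minimum observed
    onset.  Strata with no observed onsets fall back to a prior draw.
    """
    onsets = {FEMALE: [], MALE: []}
    n_carrier = n_carrier_aff = 0
    n_all = n_all_aff = 0
    for p in peds:
        for m in p.members:
            if m.is_aff == 1 and m.onset_age is not None:
                if m.sex in onsets:
                    onsets[m.sex].append(m.onset_age)
                else:
                    onsets[FEMALE].append(m.onset_age)
                    onsets[MALE].append(m.onset_age)
            if m.geno == 1:
                n_carrier += 1
                n_carrier_aff += int(m.is_aff == 1)
            n_all += 1
            n_all_aff += int(m.is_aff == 1)

    if n_carrier > 0:
        gamma_init = n_carrier_aff / n_carrier
    elif n_all > 0:
        gamma_init = n_all_aff / n_all
    else:
        gamma_init = 0.5
    gamma_init = float(np.clip(gamma_init, 0.05, 0.95))

    def block_for(ages: list[int]) -> np.ndarray:
        b = _empirical_init_block(np.asarray(ages, dtype=float), gamma_init, ps, cfg, rng)
        if b is None:
            logger.info("no observed onset ages in stratum; initializing from prior draw")
            q = sample_prior(ps, rng, cfg.max_age)
            b = np.array([q.q1, q.med, q.gamma, q.delta])
        return b

    if cfg.sex_specific:
        return np.concatenate([block_for(onsets[FEMALE]), block_for(onsets[MALE])])
    return block_for(onsets[FEMALE] + onsets[MALE])


def propose(state: ChainState, cfg: McmcConfig, rng: np.random.Generator) -> np.ndarray:
    chol = state.proposal_cholesky(cfg)
    return state.current + chol @ rng.standard_normal(state.current.shape[0])


def mh_step(
    state: ChainState,
    posterior_fn,
    ps: PriorSet,
    cfg: McmcConfig,
    rng: np.random.Generator,
) -> ChainState:
    """One Metropolis step with bound pre-rejection; mutates and returns ``state``."""
    proposal = propose(state, cfg, rng)
    u = rng.uniform()  # drawn unconditionally to keep the stream aligned
    if check_bounds(proposal, ps, cfg):
        lp = posterior_fn(proposal)
        if math.isfinite(lp) and math.log(u) < lp - state.current_log_posterior:
            state.current = proposal
            state.current_log_posterior = lp
            state.accepted += 1
    state.iteration += 1
    state.update_history(state.current)
    return state


@dataclass
class ChainResult:
    draws: np.ndarray  # retained (post burn-in, thinned) draws
    trace: np.ndarray  # full pre-burn-in trace
    accept_rate: float
    log_posterior: np.ndarray
    seed_entropy: object


@dataclass
class PosteriorSamples:
    param_names: list[str]
    chains: list[ChainResult]
    config: McmcConfig

    @property
    def n_retained(self) -> int:
        return sum(c.draws.shape[0] for c in self.chains)

    def pooled(self) -> np.ndarray:
        return np.vstack([c.draws for c in self.chains])

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for i, c in enumerate(self.chains):
            df = pd.DataFrame(c.draws, columns=self.param_names)
            df.insert(0, "chain", i)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def save(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def config_dict(self) -> dict:
        return asdict(self.config)


def run_chains(
    peds: list[Pedigree],
    gm: GenotypeModel | None,
    baseline: BaselineRisk,
    ps: PriorSet,
    cfg: McmcConfig,
) -> PosteriorSamples:
    """Run ``cfg.n_chains`` independent adaptive Metropolis chains.

    Each chain receives its own spawned random stream, so results do not
    depend on execution order.  Burn-in removes the first
    ``floor(burn_in * n_iter)`` draws of each chain.
    """
    from .imputation import build_plan, initial_impute, reimpute  # cycle-free at call time

    d = cfg.dim
    names = param_names(cfg)
    if peds and gm is None:
        raise McmcError("a genotype model (prevalence) is required when families are supplied")
    engine = PeelingEngine(peds, gm) if peds else None

    plan = build_plan(peds) if cfg.age_imputation else None
    if plan is not None and not plan.targets:
        plan = None

    prior_sd = prior_component_sd(ps, cfg.max_age)
    init_diag = np.tile((cfg.init_scale * prior_sd) ** 2, d // 4)

    root_ss = np.random.SeedSequence(cfg.seed)
    chain_seeds = root_ss.spawn(cfg.n_chains)

    chains: list[ChainResult] = []
    for ci in range(cfg.n_chains):
        ss = chain_seeds[ci]
        rng = np.random.Generator(np.random.PCG64(ss))
        imp_rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))

        if engine is not None:
            arrays = engine.arrays
            base_onset = arrays.onset.copy()
            base_cur = arrays.cur.copy()
            if plan is not None:
                initial_impute(plan, arrays, baseline, imp_rng, cfg.max_age)

            def log_post(x, _arrays=arrays, _engine=engine):
                qs = vector_to_qparams(x, cfg)
                lp = 0.0
                for sex in (FEMALE, MALE) if cfg.sex_specific else (FEMALE,):
                    lp += log_prior_density(ps, qs[sex], cfg.max_age)
                if not math.isfinite(lp):
                    return -math.inf
                try:
                    theta_f = quantiles_to_weibull(qs[FEMALE])
                    theta_m = quantiles_to_weibull(qs[MALE])
                except ModelDomainError:
                    return -math.inf
                pen = PenetranceSet(theta_f, theta_m, baseline, cfg.max_age)
                penmat = phenotype_matrix(_arrays, pen)
                return lp + _engine.loglik_total(penmat)

        else:

            def log_post(x):
                qs = vector_to_qparams(x, cfg)
                lp = 0.0
                for sex in (FEMALE, MALE) if cfg.sex_specific else (FEMALE,):
                    lp += log_prior_density(ps, qs[sex], cfg.max_age)
                return lp

        # initialization: empirical, retried from the prior until finite
        state = None
        for attempt in range(100):
            if attempt == 0:
                x0 = initialize_state(peds, ps, cfg, rng)
            else:
                x0 = np.concatenate(
                    [
                        np.array([q.q1, q.med, q.gamma, q.delta])
                        for q in [
                            sample_prior(ps, rng, cfg.max_age) for _ in range(d // 4)
                        ]
                    ]
                )
            if not check_bounds(x0, ps, cfg):
                continue
            lp0 = log_post(x0)
            if math.isfinite(lp0):
                state = ChainState(
                    current=x0, current_log_posterior=lp0, initial_diag=init_diag.copy()
                )
                break
        if state is None:
            raise McmcError(f"chain {ci}: could not find a finite-posterior starting point")

        trace = np.empty((cfg.n_iter, d))
        lp_trace = np.empty(cfg.n_iter)
        for it in range(cfg.n_iter):
            if plan is not None and it > 0 and it % cfg.impute_every == 0:
                qs = vector_to_qparams(state.current, cfg)
                reimpute(
                    plan,
                    engine,
                    qs,
                    baseline,
                    imp_rng,
                    cfg.max_age,
                )
                state.current_log_posterior = log_post(state.current)
            mh_step(state, log_post, ps, cfg, rng)
            trace[it] = state.current
            lp_trace[it] = state.current_log_posterior

        if engine is not None:
            # restore observed data so subsequent chains impute independently
            engine.arrays.onset[:] = base_onset
            engine.arrays.cur[:] = base_cur

        retained = trace[cfg.n_discard :][:: cfg.thin].copy()
        chains.append(
            ChainResult(
                draws=retained,
                trace=trace,
                accept_rate=state.accepted / cfg.n_iter,
                log_posterior=lp_trace,
                seed_entropy=ss.entropy,
            )
        )
        logger.info("chain %d: acceptance rate %.3f", ci, chains[-1].accept_rate)

    return PosteriorSamples(param_names=names, chains=chains, config=cfg)
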