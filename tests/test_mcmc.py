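import math

import numpy as np
import pytest

from penfam.likelihood import GenotypeModel
from penfam.mcmc import (
    ChainState,
    McmcConfig,
    McmcError,
    check_bounds,
    initialize_state,
    mh_step,
    param_names,
    propose,
    run_chains,
    vector_to_qparams,
)
from penfam.model import BaselineRisk
from penfam.pedigrees import IndividualRecord, Pedigree
from penfam.priors import default_priors
from penfam.simulate import SimDesign, simulate_study


@pytest.fixture
def ps():
    return default_priors()


def make_state(x, diag=None, lp=0.0):
    x = np.asarray(x, dtype=float)
    return ChainState(
        current=x,
        current_log_posterior=lp,
        initial_diag=np.full(x.shape[0], 0.01) if diag is None else np.asarray(diag),
    )


class TestConfig:
    def test_defaults_match_published_run(self):
        cfg = McmcConfig()
        assert cfg.n_chains == 4
        assert cfg.n_iter == 20000
        assert cfg.burn_in == 0.1
        assert cfg.sex_specific is True
        assert cfg.age_imputation is False
        assert cfg.remove_proband is False
        assert cfg.max_age == 94

    def test_burn_in_discard_count(self):
        assert McmcConfig(n_iter=20000, burn_in=0.1).n_discard == 2000
        assert McmcConfig(n_iter=999, burn_in=0.1).n_discard == 99
        assert McmcConfig(n_iter=100, burn_in=0.0).n_discard == 0

    def test_invalid(self):
        with pytest.raises(McmcError):
            McmcConfig(n_iter=0)
        with pytest.raises(McmcError):
            McmcConfig(burn_in=1.0)

    def test_dim(self):
        assert McmcConfig(sex_specific=True).dim == 8
        assert McmcConfig(sex_specific=False).dim == 4

    def test_param_names(self):
        assert param_names(McmcConfig(sex_specific=False)) == ["q1", "med", "gamma", "delta"]
        assert param_names(McmcConfig(sex_specific=True))[:5] == [
            "F.q1", "F.med", "F.gamma", "F.delta", "M.q1",
        ]


class TestBounds:
    def test_gamma_above_one(self, ps):
        cfg = McmcConfig(sex_specific=False)
        assert not check_bounds(np.array([45, 55, 1.2, 20]), ps, cfg)

    def test_ordering(self, ps):
        cfg = McmcConfig(sex_specific=False)
        assert not check_bounds(np.array([55, 45, 0.5, 20]), ps, cfg)

    def test_delta_support(self, ps):
        cfg = McmcConfig(sex_specific=False)
        assert not check_bounds(np.array([45, 55, 0.5, 40]), ps, cfg)
        assert not check_bounds(np.array([45, 55, 0.5, 3]), ps, cfg)

    def test_valid(self, ps):
        cfg = McmcConfig(sex_specific=False)
        assert check_bounds(np.array([45, 55, 0.5, 20]), ps, cfg)

    def test_sex_specific_blocks(self, ps):
        cfg = McmcConfig(sex_specific=True)
        good = np.array([45, 55, 0.5, 20, 40, 50, 0.6, 15])
        bad = good.copy()
        bad[6] = 1.5
        assert check_bounds(good, ps, cfg)
        assert not check_bounds(bad, ps, cfg)


class TestPropose:
    def test_proposal_covariance_monte_carlo(self):
        # before adaptation: proposals use the initial diagonal
        rng = np.random.default_rng(0)
        diag = np.array([4.0, 1.0, 0.04, 0.25])
        state = make_state([45, 55, 0.5, 20], diag=diag)
        cfg = McmcConfig(sex_specific=False, adapt_start=10**9)
        steps = np.array([propose(state, cfg, rng) - state.current for _ in range(100_000)])
        emp = np.cov(steps.T)
        target = np.diag(diag)
        rel = np.linalg.norm(emp - target) / np.linalg.norm(target)
        assert rel < 0.05

    def test_adapted_covariance_formula(self):
        rng = np.random.default_rng(1)
        cfg = McmcConfig(sex_specific=False, adapt_start=0, adapt_epsilon=1e-6)
        state = make_state([45, 55, 0.5, 20])
        cov_true = np.diag([9.0, 4.0, 0.01, 1.0])
        draws = rng.multivariate_normal(state.current, cov_true, size=5000)
        for x in draws:
            state.update_history(x)
        state.iteration = 5000
        expected = 2.38**2 / 4 * (np.cov(draws.T) + 1e-6 * np.eye(4))
        np.testing.assert_allclose(state.proposal_covariance(cfg), expected, rtol=1e-8)

    def test_dimensionality(self, ps):
        rng = np.random.default_rng(2)
        for sex_specific, d in ((True, 8), (False, 4)):
            cfg = McmcConfig(sex_specific=sex_specific)
            x = np.tile([45, 55, 0.5, 20.0], d // 4)
            state = make_state(x, diag=np.full(d, 0.01))
            assert propose(state, cfg, rng).shape == (d,)

    def test_epsilon_floor_keeps_nondegenerate(self):
        rng = np.random.default_rng(3)
        cfg = McmcConfig(sex_specific=False, adapt_start=0, adapt_epsilon=1e-4)
        state = make_state([45, 55, 0.5, 20])
        for _ in range(50):
            state.update_history(state.current)  # zero-variance history
        state.iteration = 50
        cov = state.proposal_covariance(cfg)
        assert np.all(np.linalg.eigvalsh(cov) > 0)


class TestMhStep:
    def test_flat_posterior_accepts_in_bounds(self, ps):
        cfg = McmcConfig(sex_specific=False, adapt_start=10**9)
        rng = np.random.default_rng(4)
        state = make_state([45, 55, 0.5, 20], diag=np.full(4, 1e-6), lp=0.0)
        for _ in range(500):
            mh_step(state, lambda x: 0.0, ps, cfg, rng)
        # tiny steps from mid-support never leave bounds -> all accepted
        assert state.accepted == 500

    def test_bound_rejection_skips_posterior(self, ps):
        cfg = McmcConfig(sex_specific=False, adapt_start=10**9)
        rng = np.random.default_rng(5)
        calls = []

        def posterior(x):
            calls.append(x)
            return 0.0

        # huge steps: most proposals out of bounds and must not call posterior
        state = make_state([45, 55, 0.5, 20], diag=np.full(4, 1e6), lp=0.0)
        for _ in range(200):
            mh_step(state, posterior, ps, cfg, rng)
        assert len(calls) < 200

    def test_nonfinite_posterior_treated_as_rejection(self, ps):
        cfg = McmcConfig(sex_specific=False, adapt_start=10**9)
        rng = np.random.default_rng(6)
        state = make_state([45, 55, 0.5, 20], diag=np.full(4, 1e-6), lp=0.0)
        for _ in range(50):
            mh_step(state, lambda x: -math.inf, ps, cfg, rng)
        assert state.accepted == 0
        np.testing.assert_array_equal(state.current, [45, 55, 0.5, 20])


class TestInitialization:
    def make_peds(self, female_onsets):
        members = [
            IndividualRecord(
                id=str(i), sex="F", is_aff=1, onset_age=a, cur_age=min(a + 5, 94),
                is_proband=(i == 0), geno=1,
            )
            for i, a in enumerate(female_onsets)
        ]
        members.append(IndividualRecord(id="u", sex="M", cur_age=60, is_aff=0))
        return [Pedigree(family_id="1", members=members)]

    def test_empirical_quartiles(self, ps):
        peds = self.make_peds([40, 50, 60, 70])
        cfg = McmcConfig(sex_specific=False)
        inits = [
            initialize_state(peds, ps, cfg, np.random.default_rng(s)) for s in range(50)
        ]
        q1s = np.array([x[0] for x in inits])
        meds = np.array([x[1] for x in inits])
        # empirical 25th percentile 47.5, median 55, jitter sd 1
        assert abs(q1s.mean() - 47.5) < 1.0
        assert abs(meds.mean() - 55.0) < 1.0
        # gamma: 4 of 4 genotyped carriers affected -> clamped to 0.95
        assert all(x[2] == pytest.approx(0.95) for x in inits)
        # delta below the minimum observed onset
        assert all(x[3] < 40 for x in inits)

    def test_no_affected_stratum_falls_back_to_prior(self, ps):
        peds = self.make_peds([40, 50])  # no affected males
        cfg = McmcConfig(sex_specific=True)
        x = initialize_state(peds, ps, cfg, np.random.default_rng(0))
        assert check_bounds(x, ps, cfg)

    def test_deterministic_given_seed(self, ps):
        peds = self.make_peds([40, 50, 60])
        cfg = McmcConfig(sex_specific=True)
        a = initialize_state(peds, ps, cfg, np.random.default_rng(9))
        b = initialize_state(peds, ps, cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)


class TestRunChains:
    def test_retained_count_invariant(self, ps):
        cfg = McmcConfig(n_chains=2, n_iter=950, burn_in=0.13, seed=1, sex_specific=False)
        s = run_chains([], None, BaselineRisk.zero(), ps, cfg)
        expected = 950 - math.floor(0.13 * 950)
        for c in s.chains:
            assert c.draws.shape == (expected, 4)
            assert c.trace.shape == (950, 4)

    def test_burn_in_zero_retains_all(self, ps):
        cfg = McmcConfig(n_chains=1, n_iter=200, burn_in=0.0, seed=1, sex_specific=False)
        s = run_chains([], None, BaselineRisk.zero(), ps, cfg)
        assert s.chains[0].draws.shape[0] == 200

    def test_seed_determinism(self, ps, baseline):
        design = SimDesign(n_probands=3, prevalence=0.05)
        peds, _ = simulate_study(design, seed=3)
        cfg = McmcConfig(n_chains=2, n_iter=150, burn_in=0.1, seed=42, sex_specific=True)
        gm = GenotypeModel(0.05)
        a = run_chains(peds, gm, baseline, ps, cfg)
        b = run_chains(peds, gm, baseline, ps, cfg)
        for ca, cb in zip(a.chains, b.chains):
            np.testing.assert_array_equal(ca.draws, cb.draws)

    def test_draws_respect_bounds(self, ps):
        cfg = McmcConfig(n_chains=1, n_iter=2000, burn_in=0.1, seed=7, sex_specific=False)
        s = run_chains([], None, BaselineRisk.zero(), ps, cfg)
        for x in s.pooled()[::50]:
            assert check_bounds(x, ps, cfg)
            vector_to_qparams(x, cfg)  # constructible

    def test_dataframe_round_trip(self, ps, tmp_path):
        cfg = McmcConfig(n_chains=2, n_iter=100, burn_in=0.0, seed=2, sex_specific=False)
        s = run_chains([], None, BaselineRisk.zero(), ps, cfg)
        df = s.to_dataframe()
        assert list(df.columns) == ["chain", "q1", "med", "gamma", "delta"]
        assert len(df) == 200
        path = tmp_path / "samples.csv"
        s.save(path)
        assert path.exists()

    def test_acceptance_rate_sane_on_data(self, ps, baseline):
        design = SimDesign(n_probands=10, prevalence=0.02)
        peds, _ = simulate_study(design, seed=8)
        cfg = McmcConfig(n_chains=1, n_iter=2000, burn_in=0.1, seed=9, sex_specific=False)
        s = run_chains(peds, GenotypeModel(0.02), baseline, ps, cfg)
        assert 0.05 < s.chains[0].accept_rate < 0.6
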