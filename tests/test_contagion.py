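"""Synchronous SIR transitions on contact graphs and coupled outbreaks."""

import math

import numpy as np
import pytest
from scipy import stats

import flocksir as fs
from flocksir.contagion import (
    EpidemicState,
    contagion_step,
    infection_probability,
    run_outbreak,
    seed_infections,
)
from flocksir.model_core import build_contact_graph

from conftest import make_state


def complete_graph_state(n, spacing=0.1):
    """n agents packed within r_int of each other (complete contact graph)."""
    pos = 5.0 + spacing * np.column_stack(
        [np.arange(n) % 3, np.arange(n) // 3]
    ).astype(float)
    return make_state(pos)


class TestInfectionProbability:
    def test_single_contact_is_beta_dt(self):
        assert infection_probability(1, 0.1, 0.1) == pytest.approx(0.01)

    def test_no_contacts_no_infection(self):
        assert infection_probability(0, 5.0, 0.1) == 0.0

    def test_independent_channels_sum(self):
        assert infection_probability(3, 0.1, 0.1) == pytest.approx(0.03)

    def test_capped_at_one_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert infection_probability(30, 1.0, 0.1) == 1.0

    def test_warns_when_linearization_strained(self):
        with pytest.warns(RuntimeWarning):
            infection_probability(2, 1.0, 0.1)


class TestContagionStep:
    def test_no_transmission_without_beta(self, rng):
        state = complete_graph_state(6)
        g = build_contact_graph(state, 1.0, 10.0)
        es = EpidemicState(np.array([1, 0, 0, 0, 0, 2], dtype=np.int8))
        ep = fs.EpidemicParams(beta_b=0.0, gamma=0.05)
        out = contagion_step(es, g, ep, 0.1, rng)
        assert out.n_S == es.n_S  # no S->I ever

    def test_all_recovered_is_absorbing(self, rng):
        state = complete_graph_state(5)
        g = build_contact_graph(state, 1.0, 10.0)
        es = EpidemicState(np.full(5, 2, dtype=np.int8))
        ep = fs.EpidemicParams(beta_b=5.0, gamma=0.5)
        for _ in range(20):
            es = contagion_step(es, g, ep, 0.1, rng)
        assert es.n_R == 5

    def test_new_infections_binomial_on_complete_graph(self):
        """Complete graph on 5 agents, 1 infected, per-contact step
        probability 0.2: each susceptible is infected independently, so
        the count of new infections per step is Binomial(4, 0.2)."""
        state = complete_graph_state(5)
        g = build_contact_graph(state, 1.0, 10.0)
        labels0 = np.array([1, 0, 0, 0, 0], dtype=np.int8)
        ep = fs.EpidemicParams(beta_b=2.0, gamma=1e-12)
        rng = np.random.default_rng(99)
        n_rep = 3000
        counts = np.zeros(5, dtype=int)
        for _ in range(n_rep):
            out = contagion_step(EpidemicState(labels0.copy()), g, ep, 0.1, rng)
            counts[out.n_I - 1] += 1
        expected = n_rep * stats.binom.pmf(np.arange(5), 4, 0.2)
        chi2 = ((counts - expected) ** 2 / expected).sum()
        # 4 dof; 0.999 quantile ~ 18.5 (seeded run, no flake)
        assert chi2 < stats.chi2.ppf(0.999, 4)

    def test_newly_infected_cannot_act_within_step(self, rng):
        """Synchronous update: an agent infected this step neither
        transmits nor recovers in the same step."""
        # chain 0-1-2: agent 0 infected, beta*dt=1 -> 1 becomes I, but 2
        # (only adjacent to 1) cannot be infected in the same step
        state = make_state([[5.0, 5.0], [5.9, 5.0], [6.8, 5.0]])
        g = build_contact_graph(state, 1.0, 20.0)
        es = EpidemicState(np.array([1, 0, 0], dtype=np.int8))
        ep = fs.EpidemicParams(beta_b=10.0, gamma=1e-12)
        out = contagion_step(es, g, ep, 0.1, rng)
        assert out.labels[1] == 1
        assert out.labels[2] == 0

    def test_rejects_coarse_recovery_step(self, rng):
        state = complete_graph_state(3)
        g = build_contact_graph(state, 1.0, 10.0)
        es = EpidemicState(np.array([1, 0, 0], dtype=np.int8))
        with pytest.raises(ValueError):
            contagion_step(es, g, fs.EpidemicParams(beta_b=0.0, gamma=20.0), 0.1, rng)


class TestSeeding:
    def test_random_seeding_fraction(self, rng):
        es = seed_infections(EpidemicState.all_susceptible(10000),
                             n_seed=100, rng=rng)
        assert es.n_I == 100
        assert es.rho_I == pytest.approx(0.01)

    def test_localized_seeding_nearest_to_center(self, rng):
        mp = fs.ModelParams.from_dimensionless(32, 1, N=200)
        state = fs.random_particle_state(mp, rng)
        es = seed_infections(
            EpidemicState.all_susceptible(200), mode="localized", n_seed=10,
            state=state, L=mp.L,
        )
        center = np.array([mp.L / 2, mp.L / 2])
        d = state.positions - center
        d -= mp.L * np.floor(d / mp.L + 0.5)
        order = np.argsort(np.hypot(d[:, 0], d[:, 1]))
        assert set(np.flatnonzero(es.labels == 1)) == set(order[:10])

    def test_seed_everyone(self, rng):
        es = seed_infections(EpidemicState.all_susceptible(50), n_seed=50, rng=rng)
        assert es.rho_I == 1.0 and es.rho_S == 0.0

    def test_rejects_too_many_seeds(self, rng):
        with pytest.raises(ValueError):
            seed_infections(EpidemicState.all_susceptible(5), n_seed=6, rng=rng)


class TestRunOutbreak:
    def test_no_spread_final_size_equals_seed_fraction(self, rng):
        """beta_b=0: the seeds recover and nobody else is ever infected."""
        mp = fs.ModelParams.from_dimensionless(32, 1, N=500)
        state = fs.random_particle_state(mp, rng)
        es = seed_infections(EpidemicState.all_susceptible(500), n_seed=5, rng=rng)
        ep = fs.EpidemicParams(beta_b=0.0, gamma=0.05)
        res = run_outbreak(state, es, mp, ep,
                           rng_spatial=np.random.default_rng(1),
                           rng_infection=np.random.default_rng(2),
                           rng_recovery=np.random.default_rng(3))
        assert res.finished
        assert res.rho_R_final == pytest.approx(5 / 500, abs=0)
        assert res.rho_I_peak == pytest.approx(5 / 500, abs=0)

    def test_overwhelming_transmissibility_infects_connected_cluster(self):
        """A static dense cluster with Theta=10^3: percolation reaches
        every agent, final recovered fraction 1."""
        n = 40
        rng = np.random.default_rng(6)
        pos = 10.0 + rng.random((n, 2)) * 2.0  # blob of diameter ~2
        mp = fs.ModelParams(N=n, v0=1e-8, r_int=1.0, sigma=1e-8, tau=100.0,
                            L=40.0, dt=0.1)
        state = fs.ParticleState(pos, np.zeros(n))
        g = build_contact_graph(state, 1.0, 40.0)
        # require the cluster to be connected for the claim to apply
        assert fs.largest_cluster_fraction(g) == 1.0
        es = seed_infections(EpidemicState.all_susceptible(n), n_seed=1,
                             rng=np.random.default_rng(7))
        ep = fs.EpidemicParams.from_theta(1e3, 100.0)
        res = run_outbreak(state, es, mp, ep,
                           rng_spatial=np.random.default_rng(1),
                           rng_infection=np.random.default_rng(2),
                           rng_recovery=np.random.default_rng(3))
        assert res.finished
        assert res.rho_R_final == 1.0

    def test_duration_matches_order_statistic_of_recovery_times(self):
        """beta_b=0: the outbreak lasts until the last seed recovers.
        Step counts are i.i.d. Geometric(gamma dt), so the mean duration
        is E[max of m geometrics] * dt, computed exactly by summing the
        survival function. Checked within 3 standard errors."""
        m_seeds, gamma, dt = 10, 0.1, 0.1
        p = gamma * dt
        mp = fs.ModelParams.from_dimensionless(32, 1, N=100)
        ep = fs.EpidemicParams(beta_b=0.0, gamma=gamma)
        # exact mean of the max of m geometric lifetimes (in steps)
        t = np.arange(0, 4000)
        surv = 1.0 - (1.0 - (1.0 - p) ** t) ** m_seeds
        expected_steps = surv.sum()
        durations = []
        master = np.random.default_rng(31)
        state = fs.random_particle_state(mp, master)
        for _ in range(200):
            es = seed_infections(EpidemicState.all_susceptible(100),
                                 n_seed=m_seeds, rng=master)
            res = run_outbreak(state, es, mp, ep, dt=dt,
                               rng_spatial=np.random.default_rng(master.integers(2**31)),
                               rng_infection=np.random.default_rng(master.integers(2**31)),
                               rng_recovery=np.random.default_rng(master.integers(2**31)))
            durations.append(res.duration / dt)
        durations = np.asarray(durations)
        se = durations.std(ddof=1) / math.sqrt(len(durations))
        assert abs(durations.mean() - expected_steps) < 3 * se

    def test_conservation_and_monotonicity_random_runs(self):
        """S+I+R = N after every step; rho_R never decreases and rho_S
        never increases, across 100 randomized short runs."""
        master = np.random.default_rng(17)
        for _ in range(100):
            n = int(master.integers(20, 80))
            mp = fs.ModelParams.from_dimensionless(
                Pe=float(master.uniform(8, 256)),
                g=float(master.uniform(0.5, 64)),
                N=n,
            )
            state = fs.random_particle_state(mp, master)
            es = seed_infections(
                EpidemicState.all_susceptible(n),
                n_seed=int(master.integers(1, max(2, n // 5))), rng=master,
            )
            ep = fs.EpidemicParams(
                beta_b=float(master.uniform(0, 1.0)),
                gamma=float(master.uniform(0.05, 0.5)),
            )
            res = run_outbreak(
                state, es, mp, ep, time_cap=30.0, record_dt=mp.dt,
                rng_spatial=np.random.default_rng(master.integers(2**31)),
                rng_infection=np.random.default_rng(master.integers(2**31)),
                rng_recovery=np.random.default_rng(master.integers(2**31)),
            )
            ts = res.time_series
            assert (ts[["n_S", "n_I", "n_R"]].sum(axis=1) == n).all()
            assert (ts["n_R"].diff().dropna() >= 0).all()
            assert (ts["n_S"].diff().dropna() <= 0).all()
            if res.finished:
                assert ts["n_I"].iloc[-1] == 0
                assert res.rho_R_final == ts["n_R"].iloc[-1] / n

    def test_matches_independent_static_graph_oracle(self):
        """On a frozen spatial configuration the outbreak must be
        statistically indistinguishable from an independent discrete-time
        SIR run directly on the fixed contact graph (two-sample KS on
        final sizes, n=500 each)."""
        n = 150
        rng = np.random.default_rng(23)
        L = 14.0  # dense enough for a giant component
        pos = rng.random((n, 2)) * L
        state = make_state(pos)
        g = build_contact_graph(state, 1.0, L)
        p_inf_unit, p_rec = 0.06, 0.02
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n):
            adj[i, g.neighbors(i)] = True

        def oracle_final(rng_o):
            labels = np.zeros(n, dtype=np.int8)
            labels[rng_o.choice(n, 3, replace=False)] = 1
            while (labels == 1).any():
                k = adj[:, labels == 1].sum(axis=1)
                p = np.minimum(1.0, k * p_inf_unit)
                new_inf = (labels == 0) & (rng_o.random(n) < p)
                recov = (labels == 1) & (rng_o.random(n) < p_rec)
                labels[new_inf] = 1
                labels[recov] = 2
            return (labels == 2).sum() / n

        ep = fs.EpidemicParams(beta_b=p_inf_unit / 0.1, gamma=p_rec / 0.1)
        rng_mine = np.random.default_rng(41)

        def mine_final():
            es = seed_infections(EpidemicState.all_susceptible(n), n_seed=3,
                                 rng=rng_mine)
            while es.n_I > 0:
                es = contagion_step(es, g, ep, 0.1, rng_mine)
            return es.rho_R

        rng_o = np.random.default_rng(59)
        finals_oracle = np.array([oracle_final(rng_o) for _ in range(500)])
        finals_mine = np.array([mine_final() for _ in range(500)])
        ks = stats.ks_2samp(finals_mine, finals_oracle)
        assert ks.pvalue > 1e-3  # seeded; indistinguishable distributions

    def test_requires_infected_seed(self, rng):
        mp = fs.ModelParams.from_dimensionless(32, 1, N=50)
        state = fs.random_particle_state(mp, rng)
        with pytest.raises(ValueError):
            run_outbreak(state, EpidemicState.all_susceptible(50), mp,
                         fs.EpidemicParams(beta_b=0.1, gamma=0.1),
                         rng_spatial=rng, rng_infection=rng, rng_recovery=rng)


class TestEpidemicSubclock:
    def test_subclock_is_exact_composition_of_kernel_updates(self):
        """With fast contagion rates run_outbreak advances the SIR state in
        n_sub substeps per spatial frame; the result must be bit-identical
        to manually composing the kernel updates with the same streams."""
        from flocksir import _kernels as K

        mp = fs.ModelParams.from_dimensionless(32, 8, N=200)
        ep = fs.EpidemicParams.from_theta(2.0, 0.5)  # gamma=2, beta_b=4
        dt = mp.dt
        dt_epi_max = fs.contagion_dt(mp, ep)
        n_sub = int(np.ceil(dt / dt_epi_max - 1e-9))
        assert n_sub > 1  # the subclock must actually engage here
        dt_epi = dt / n_sub

        master = np.random.default_rng(71)
        base = fs.random_particle_state(mp, master)
        es0 = seed_infections(EpidemicState.all_susceptible(200), n_seed=5,
                              rng=np.random.default_rng(11))

        res = run_outbreak(
            base, es0, mp, ep, dt=dt, keep_final_state=True,
            rng_spatial=np.random.default_rng(1),
            rng_infection=np.random.default_rng(2),
            rng_recovery=np.random.default_rng(3),
        )

        # manual composition with identical streams
        pos = base.positions.copy()
        theta = base.headings.copy()
        labels = es0.labels.copy()
        r_sp = np.random.default_rng(1)
        r_inf = np.random.default_rng(2)
        r_rec = np.random.default_rng(3)
        n_I = int((labels == 1).sum())
        while n_I > 0:
            ii, jj = K.pair_list(pos, mp.L, mp.r_int)
            for _ in range(n_sub):
                d_inf, d_rec, _ = K.sir_update_pairs(
                    labels, ii, jj, ep.beta_b * dt_epi, ep.gamma * dt_epi,
                    r_inf, r_rec,
                )
                n_I += d_inf - d_rec
                if n_I == 0:
                    break
            if n_I > 0:
                K.spatial_update_pairs(pos, theta, ii, jj, mp.L, mp.v0,
                                       mp.r_int, mp.sigma, mp.tau, dt, r_sp)
        assert res.finished
        np.testing.assert_array_equal(res.final_epidemic_state.labels, labels)
        np.testing.assert_array_equal(res.final_particle_state.positions, pos)
        assert res.rho_R_final == (labels == 2).sum() / 200


class TestContagionDt:
    def test_auto_reduction_for_fast_rates(self):
        mp = fs.ModelParams.from_dimensionless(32, 128, N=100)
        ep = fs.EpidemicParams.from_theta(2.0, 0.01)  # gamma=100, beta_b=200
        dt = fs.contagion_dt(mp, ep)
        assert ep.beta_b * dt <= 0.1 + 1e-12
        assert ep.gamma * dt <= 0.1 + 1e-12

    def test_no_reduction_needed_for_slow_rates(self):
        mp = fs.ModelParams.from_dimensionless(32, 1, N=100)
        ep = fs.EpidemicParams.from_theta(2.0, 20.0)
        assert fs.contagion_dt(mp, ep) == mp.dt
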