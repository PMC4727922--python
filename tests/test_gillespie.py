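"""Stochastic simulation: reaction bookkeeping, exactness, stationary stats."""

import numpy as np
import pytest
from scipy import stats as sps

from cernacap import (
    SPECIES,
    build_reaction_system,
    moment_scan,
    simulate,
    stationary_moments,
    stationary_stats,
    steady_state,
)
from cernacap.gillespie import REACTION_LABELS


class TestReactionSystem:
    def test_fourteen_reactions_with_constant_synthesis(self, fig2):
        occ = fig2.occ.replace(n1=0.5)
        system = build_reaction_system(fig2.params, occ)
        assert len(system.rates) == len(REACTION_LABELS) == 14
        a = system.propensities(np.zeros(5))
        # at the empty state only the three syntheses fire, at b*n rates
        assert a[0] == pytest.approx(fig2.params.b1 * 0.5)
        assert a[1] == pytest.approx(fig2.params.b2 * occ.n2)
        assert a[2] == pytest.approx(fig2.params.beta * occ.nmu)
        assert np.all(a[3:] == 0.0)

    def test_mass_action_association_propensity(self, fig2):
        system = build_reaction_system(fig2.params, fig2.occ)
        state = np.array([2, 0, 3, 0, 0])
        a = system.propensities(state)
        i = REACTION_LABELS.index("association_1")
        assert a[i] == pytest.approx(fig2.params.kplus1 * 2 * 3)  # 0.002*6

    def test_catalytic_vs_stoichiometric_stoichiometry(self, fig2):
        system = build_reaction_system(fig2.params, fig2.occ)
        cat = system.stoich[REACTION_LABELS.index("catalytic_decay_c1")]
        sto = system.stoich[REACTION_LABELS.index("stoichiometric_decay_c1")]
        # catalytic decay recycles the miRNA; stoichiometric destroys it
        assert list(cat) == [0, 0, +1, -1, 0]
        assert list(sto) == [0, 0, 0, -1, 0]

    def test_decoupling_when_no_binding(self, birth_death):
        params, occ = birth_death
        system = build_reaction_system(params, occ)
        state = np.array([10, 10, 10, 5, 5])
        a = system.propensities(state)
        for label in ("association_1", "association_2"):
            assert a[REACTION_LABELS.index(label)] == 0.0


class TestSimulate:
    def test_absorbing_empty_state(self, birth_death):
        params, occ = birth_death
        system = build_reaction_system(params.replace(b1=0, b2=0, beta=0),
                                       occ.replace(n1=0, n2=0, nmu=0))
        traj = simulate(system, t_end=50.0, seed=1, initial_state=np.zeros(5, int))
        assert traj.states.shape[0] == 1
        assert np.all(traj.states == 0)

    def test_seed_determinism(self, fig2):
        occ = fig2.occ.replace(n1=0.5)
        system = build_reaction_system(fig2.params, occ)
        x0 = np.array([100, 100, 100, 10, 10])
        t1 = simulate(system, 50.0, seed=7, initial_state=x0)
        t2 = simulate(system, 50.0, seed=7, initial_state=x0)
        assert np.array_equal(t1.times, t2.times)
        assert np.array_equal(t1.states, t2.states)
        t3 = simulate(system, 50.0, seed=8, initial_state=x0)
        assert not np.array_equal(t1.times, t3.times)

    def test_non_negative_integer_states(self, fig2):
        occ = fig2.occ.replace(n1=0.8)
        system = build_reaction_system(fig2.params, occ)
        traj = simulate(system, 200.0, seed=5,
                        initial_state=np.array([0, 0, 0, 0, 0]))
        assert np.all(traj.states >= 0)
        assert np.all(np.diff(traj.times) > 0)
        # consecutive states differ by exactly one reaction's stoichiometry
        diffs = np.diff(traj.states, axis=0)
        stoich_set = {tuple(r) for r in system.stoich}
        assert {tuple(d) for d in diffs} <= stoich_set

    def test_trajectory_export(self, fig2, tmp_path):
        occ = fig2.occ.replace(n1=0.5)
        system = build_reaction_system(fig2.params, occ)
        traj = simulate(system, 10.0, seed=2,
                        initial_state=np.array([10, 10, 10, 0, 0]))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "time," + ",".join(SPECIES)


class TestStationaryStats:
    def test_constant_trajectory_degenerate(self, birth_death):
        # complexes with no decay channel are inert: their occupancy is a
        # constant path with zero variance and zero Fano factor
        params, occ = birth_death
        system = build_reaction_system(params.replace(b1=0, b2=0, beta=0),
                                       occ.replace(n1=0, n2=0, nmu=0))
        traj = simulate(system, 100.0, seed=1,
                        initial_state=np.array([0, 0, 0, 3, 3]))
        stats = stationary_stats(traj, burn_in=10.0)
        assert np.all(stats.mean[3:] == 3.0)
        assert np.all(stats.variance[3:] == 0.0)
        assert np.all(stats.fano[3:] == 0.0)
        assert np.all(np.isnan(stats.fano[:3]))  # flagged where the mean is 0
        with pytest.raises(ValueError):
            stationary_stats(traj, burn_in=200.0)

    def test_birth_death_poisson_moments(self, birth_death):
        """Pure birth-death species: time-averaged mean b*n/d and FF = 1."""
        params, occ = birth_death
        mean, cov, se_mean, se_var, n_events = stationary_moments(
            params, occ, seed=11, replicates=6, window=1500.0
        )
        for i, (b, n, d) in enumerate(
            [(params.b1, occ.n1, params.d1), (params.b2, occ.n2, params.d2),
             (params.beta, occ.nmu, params.delta)]
        ):
            expected = b * n / d
            assert abs(mean[i] - expected) < 3 * se_mean[i]
            ff = cov[i, i] / mean[i]
            assert ff == pytest.approx(1.0, abs=0.15)

    def test_birth_death_distribution_is_poisson(self, birth_death):
        """Chi-square goodness of fit of the time-weighted occupancy of a
        birth-death species against its Poisson stationary law."""
        params, occ = birth_death
        p = params.replace(b2=2.0)  # mean m2 = 2*0.99/0.1 ~ 20: countable states
        system = build_reaction_system(p, occ)
        traj = simulate(system, 30000.0, seed=13,
                        initial_state=np.array([0, 20, 0, 0, 0]),
                        max_events=5_000_000)
        edges = np.append(traj.times, traj.t_end)
        w = np.diff(edges)
        burn = edges[:-1] >= 500.0
        lam = p.b2 * occ.n2 / p.d2
        counts = np.bincount(traj.states[burn, 1], weights=w[burn])
        total = counts.sum()
        pmf = sps.poisson.pmf(np.arange(len(counts)), lam)
        # pool states into bins with adequate expected occupancy
        expected = pmf * total
        keep = expected > total * 0.01
        chi2 = np.sum((counts[keep] - expected[keep]) ** 2 / expected[keep])
        # effective dof unknown (correlated path); require only gross agreement
        assert chi2 / keep.sum() < 10.0
        # sharper: first two moments
        emp_mean = np.sum(np.arange(len(counts)) * counts) / total
        assert emp_mean == pytest.approx(lam, rel=0.05)


class TestMomentScan:
    def test_flat_without_cross_talk(self, birth_death):
        params, occ = birth_death
        df = moment_scan(params, "miRNA", np.array([0.0, 10.0, 30.0]),
                         replicates=2, seed=3, occ_base=occ, window=300.0)
        # no binding: the target cannot sense the competitor's activator
        expected = params.b2 * occ.n2 / params.d2
        assert np.allclose(df["mean_m2"], expected, rtol=0.05)

    def test_cross_talk_signature(self, fig2):
        """Raising f1 titrates free miRNA down and lifts the target up."""
        df = moment_scan(fig2.params, "miRNA", np.array([2.0, 8.0, 20.0]),
                         replicates=2, seed=4, occ_base=fig2.occ, window=800.0)
        assert df["mean_mu"].iloc[0] > df["mean_mu"].iloc[-1]
        assert df["mean_m2"].iloc[0] < df["mean_m2"].iloc[-1]

    def test_scan_is_reproducible(self, birth_death):
        params, occ = birth_death
        kwargs = dict(replicates=2, seed=9, occ_base=occ, window=200.0)
        a = moment_scan(params, "TF", np.array([5.0, 15.0]), **kwargs)
        b = moment_scan(params, "TF", np.array([5.0, 15.0]), **kwargs)
        assert a.equals(b)
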