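import numpy as np
import pytest

import hybridscape as hs
from hybridscape.demography import ChronologyError, ParameterMismatchError
from hybridscape.popstats import hudson_fst_from_sfs


class TestCompileTwoPop:
    def test_si_rejects_migration(self):
        p = hs.ScenarioParams(nu1=1, nu2=1, Ts=1, M12=2.0)
        with pytest.raises(ParameterMismatchError, match="SI"):
            hs.compile_two_pop("SI", p)

    def test_missing_parameter_named(self):
        with pytest.raises(ParameterMismatchError, match="Tam"):
            hs.compile_two_pop("AM", hs.ScenarioParams(nu1=1, nu2=1, Ts=1, M12=1, M21=1))

    def test_am_migration_adjacent_to_split_only(self):
        p = hs.ScenarioParams(nu1=1, nu2=1, M12=2.0, M21=1.0, Ts=2.0, Tam=0.5)
        comp = hs.compile_two_pop("AM", p)
        sched = comp.schedules[0][0]
        np.testing.assert_allclose(sched.epoch_times[:3], [0.0, 1.5, 2.0])
        assert sched.mig[0].sum() == 0  # no gene flow after divergence
        assert sched.mig[1, 1, 0] == pytest.approx(1.0)  # M12/2 backward into pop 1
        assert sched.mig[1, 0, 1] == pytest.approx(0.5)
        assert sched.mig[2].sum() == 0

    def test_sc_migration_adjacent_to_present(self):
        p = hs.ScenarioParams(nu1=1, nu2=1, M12=2.0, M21=2.0, Ts=2.0, Tsc=0.3)
        sched = hs.compile_two_pop("SC", p).schedules[0][0]
        assert sched.mig[0].sum() > 0
        assert sched.mig[1].sum() == 0

    def test_2m_weights_and_p_zero_limit(self):
        p = hs.ScenarioParams(
            nu1=1, nu2=1, M12=2.0, M21=2.0, me12=0.1, me21=0.1, Ts=1.0, P=0.0, O=1.0
        )
        comp = hs.compile_two_pop("IM2m", p)
        assert [w for _, w in comp.schedules] == [1.0, 0.0]
        plain = hs.compile_two_pop("IM", hs.ScenarioParams(nu1=1, nu2=1, M12=2.0, M21=2.0, Ts=1.0))
        a = hs.expected_jafs(comp, (10, 10), n_reps=400, seed=9)
        b = hs.expected_jafs(plain, (10, 10), n_reps=400, seed=9)
        np.testing.assert_allclose(a.entries, b.entries)

    def test_growth_model_slices_terminal_epoch(self):
        p = hs.ScenarioParams(nu1=4.0, nu2=0.5, Ts=1.0)
        sched = hs.compile_two_pop("SIG", p).schedules[0][0]
        assert sched.sizes.shape[0] > 3  # sliced exponential trajectory
        # most recent slice near nu_i, oldest pre-split slice near ancestral 1
        assert sched.sizes[0, 0] > 3.0
        assert 0.9 < sched.sizes[-2, 0] < 1.6


class TestCompileThreePop:
    def test_chronology_guard(self):
        p = hs.ScenarioParams(nu1=1, nu2=1, nu3=1, Ts=1.0, Th=1.5, f=0.5)
        with pytest.raises(ChronologyError):
            hs.compile_three_pop("HS", p)

    def test_hs2p_zero_migration_equals_hs(self):
        base = dict(nu1=1, nu2=1, nu3=1, Ts=1.0, Th=0.4, f=0.3)
        hs_comp = hs.compile_three_pop("HS", hs.ScenarioParams(**base))
        hs2p = hs.compile_three_pop(
            "HS2p", hs.ScenarioParams(**base, m13=0.0, m31=0.0, m23=0.0, m32=0.0)
        )
        a = hs.expected_jafs(hs_comp, (6, 6, 6), n_reps=300, seed=4)
        b = hs.expected_jafs(hs2p, (6, 6, 6), n_reps=300, seed=4)
        np.testing.assert_allclose(a.entries, b.entries)

    def test_hs_f_one_equals_split_from_parent1(self):
        p_hs = hs.ScenarioParams(nu1=1, nu2=1, nu3=1, Ts=1.0, Th=0.4, f=1.0)
        p_sgf = hs.ScenarioParams(
            nu1=1, nu2=1, nu3=1, Ts=1.0, Th=0.4, m13=0.0, m31=0.0, m23=0.0, m32=0.0
        )
        a = hs.expected_jafs(hs.compile_three_pop("HS", p_hs), (6, 6, 6), n_reps=2000, seed=5)
        b = hs.expected_jafs(hs.compile_three_pop("SGF1", p_sgf), (6, 6, 6), n_reps=2000, seed=5)
        np.testing.assert_allclose(a.entries, b.entries)

    def test_sgf1_vs_sgf2_parental_axis_swap(self):
        kw = dict(nu1=1, nu2=1, nu3=1, Ts=2.0, Th=0.5, m13=1.0, m31=1.0, m23=1.0, m32=1.0)
        s1 = hs.expected_jafs(
            hs.compile_three_pop("SGF1", hs.ScenarioParams(**kw)), (8, 8, 4), n_reps=30000, seed=6
        )
        s2 = hs.expected_jafs(
            hs.compile_three_pop("SGF2", hs.ScenarioParams(**kw)), (8, 8, 4), n_reps=30000, seed=7
        )
        swapped = np.swapaxes(s2.entries, 0, 1)
        # aggregate comparison: per-axis marginals within Monte-Carlo noise
        for ax in range(3):
            a = s1.marginal(ax)[1:-1]
            b = hs.JointSFS(swapped, (8, 8, 4)).marginal(ax)[1:-1]
            np.testing.assert_allclose(a, b, rtol=0.12, atol=0.02)


class TestExpectedJafs:
    def test_neutral_single_population_theta_over_i(self, single_deme_schedule):
        s = hs.expected_jafs(single_deme_schedule, (20,), n_reps=50000, seed=1)
        i = np.arange(1, 20)
        np.testing.assert_allclose(s.entries[1:20], 1.0 / i, rtol=0.05)

    def test_bit_reproducible(self, single_deme_schedule):
        a = hs.expected_jafs(single_deme_schedule, (12,), n_reps=500, seed=3)
        b = hs.expected_jafs(single_deme_schedule, (12,), n_reps=500, seed=3)
        assert np.array_equal(a.entries, b.entries)

    def test_old_split_no_migration_no_shared_polymorphism(self):
        p = hs.ScenarioParams(nu1=1, nu2=1, Ts=15.0)
        s = hs.expected_jafs(hs.compile_two_pop("SI", p), (8, 8), n_reps=3000, seed=8)
        interior = s.entries[1:-1, 1:-1].sum()
        assert interior / s.unmasked_sum() < 0.01

    def test_symmetric_island_fst_closed_form(self):
        # equilibrium two-deme island model: Hudson Fst = 1/(1+2M)
        for M in (1.0, 5.0):
            p = hs.ScenarioParams(nu1=1, nu2=1, M12=M, M21=M, Ts=20.0)
            s = hs.expected_jafs(hs.compile_two_pop("IM", p), (20, 20), n_reps=30000, seed=10)
            assert hudson_fst_from_sfs(s) == pytest.approx(1 / (1 + 2 * M), rel=0.1)

    def test_symmetric_relabeling_invariance(self):
        p = hs.ScenarioParams(nu1=1, nu2=1, M12=2.0, M21=2.0, Ts=1.0)
        s = hs.expected_jafs(hs.compile_two_pop("IM", p), (10, 10), n_reps=40000, seed=11)
        np.testing.assert_allclose(s.entries[1:-1, 1:-1], s.entries.T[1:-1, 1:-1], rtol=0.25, atol=0.01)

    def test_matches_msprime_branch_spectrum(self):
        # independent coalescent oracle for a two-deme IM history
        msprime = pytest.importorskip("msprime")
        M12, M21, Ts, nu1, nu2 = 2.0, 1.0, 1.0, 1.0, 0.5
        N = 10_000
        dem = msprime.Demography()
        dem.add_population(name="p1", initial_size=nu1 * N)
        dem.add_population(name="p2", initial_size=nu2 * N)
        dem.add_population(name="anc", initial_size=N)
        # backward per-generation rates: lineage in p2 -> p1 at M12/(4N)
        dem.set_migration_rate("p2", "p1", M12 / (4 * N))
        dem.set_migration_rate("p1", "p2", M21 / (4 * N))
        dem.add_population_split(time=Ts * 2 * N, derived=["p1", "p2"], ancestral="anc")
        n1 = n2 = 8
        reps, n_batches = 3000, 10
        batches = np.zeros((n_batches, n1 + 1, n2 + 1))
        for i, ts in enumerate(
            msprime.sim_ancestry(
                samples={"p1": n1 // 2, "p2": n2 // 2},
                demography=dem,
                ploidy=2,
                num_replicates=reps,
                random_seed=99,
            )
        ):
            batches[i % n_batches] += ts.allele_frequency_spectrum(
                sample_sets=[ts.samples(0), ts.samples(1)],
                mode="branch",
                polarised=True,
                span_normalise=True,
            )
        batches /= (reps / n_batches) * (2 * N) * 2.0  # per unit theta, our scaling
        oracle = batches.mean(axis=0)
        se = batches.std(axis=0, ddof=1) / np.sqrt(n_batches)
        p = hs.ScenarioParams(nu1=nu1, nu2=nu2, M12=M12, M21=M21, Ts=Ts)
        ours = hs.expected_jafs(hs.compile_two_pop("IM", p), (n1, n2), n_reps=30000, seed=12)
        keep = ~ours.mask & (oracle > 0.01)
        z = (ours.entries[keep] - oracle[keep]) / se[keep]
        assert np.abs(z).max() < 4.5  # joint bound over ~75 cells
        # and no systematic bias in the total spectrum mass
        assert ours.entries[keep].sum() == pytest.approx(oracle[keep].sum(), rel=0.03)


class TestNesting:
    def test_im2m_at_equal_rates_matches_im_distribution(self):
        # with me == M the two locus classes are the same process
        p2m = hs.ScenarioParams(
            nu1=1, nu2=1, M12=1.0, M21=1.0, me12=1.0, me21=1.0, Ts=1.0, P=0.5, O=1.0
        )
        pim = hs.ScenarioParams(nu1=1, nu2=1, M12=1.0, M21=1.0, Ts=1.0)
        a = hs.expected_jafs(hs.compile_two_pop("IM2m", p2m), (8, 8), n_reps=40000, seed=13)
        b = hs.expected_jafs(hs.compile_two_pop("IM", pim), (8, 8), n_reps=40000, seed=14)
        np.testing.assert_allclose(a.unmasked_sum(), b.unmasked_sum(), rtol=0.05)
        big = b.entries > 0.05
        np.testing.assert_allclose(a.entries[big], b.entries[big], rtol=0.15)
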