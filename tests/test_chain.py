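"""Origin-fixation chain: fixation probabilities, rate matrices, stationary
distributions, propagation, convergence and hitting times."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import binom

import tfbsevol as tv
from tfbsevol.chain import MismatchDistribution, RateMatrix


def two_state_chain(r: float) -> RateMatrix:
    R = np.array([[-r, r], [r, -r]])
    return RateMatrix(R, 1)


@pytest.fixture(scope="module")
def baseline_chain(request):
    m = tv.BindingModel(n=7, epsilon=2.0, mu=4.0)
    pop = tv.PopulationParams.from_ns(100.0)
    mut = tv.MutationModel(theta=0.0)
    R = tv.build_rate_matrix(m, tv.FitnessSpec(s=pop.s), mut, pop)
    return m, pop, mut, R


class TestFixationProbability:
    def test_neutral_limit(self):
        assert tv.fixation_probability(100, 0.0) == pytest.approx(1.0 / 200.0)
        # series branch continuous with the exact formula
        assert tv.fixation_probability(100, 1e-10) == pytest.approx(
            tv.fixation_probability(100, 1e-6), rel=1e-3
        )

    def test_known_value(self):
        got = tv.fixation_probability(100, 0.01)
        assert got == pytest.approx((1 - np.exp(-0.02)) / (1 - np.exp(-4.0)))
        assert round(got, 5) == 0.02017

    def test_strong_selection_approaches_2df(self):
        ratios = [tv.fixation_probability(10_000, df) / (2 * df) for df in (0.01, 0.05, 0.1)]
        assert ratios[0] == pytest.approx(1.0, rel=0.02)

    def test_limits_and_deleterious_underflow(self):
        assert tv.fixation_probability(100, np.inf) == 1.0
        assert tv.fixation_probability(100, -np.inf) == 0.0
        assert tv.fixation_probability(1000, -0.5) == pytest.approx(0.0, abs=1e-300)

    @given(st.floats(-0.2, 0.2), st.integers(10, 10_000))
    def test_monotone_in_delta_f(self, df, N):
        assert tv.fixation_probability(N, df + 0.01) > tv.fixation_probability(N, df)


class TestRateMatrix:
    def test_neutral_reduction_exact(self):
        m = tv.BindingModel(n=7, epsilon=2.0, mu=4.0)
        mut = tv.MutationModel(theta=0.15)
        R = tv.build_rate_matrix(m, tv.FitnessSpec(s=0.0), mut, tv.PopulationParams(1000, 0.0))
        U = tv.combined_rate_matrix(7, mut).matrix
        assert np.array_equal(R.R, U)

    @given(
        st.integers(3, 12),
        st.floats(1.0, 3.0),
        st.floats(2.0, 6.0),
        st.floats(-300.0, 300.0),
        st.sampled_from([0.0, 0.15]),
    )
    def test_generator_property(self, n, eps, mu, ns, theta):
        m = tv.BindingModel(n=n, epsilon=eps, mu=mu)
        pop = tv.PopulationParams.from_ns(ns)
        R = tv.build_rate_matrix(m, tv.FitnessSpec(s=pop.s), tv.MutationModel(theta=theta), pop).R
        off = R - np.diag(np.diag(R))
        assert (off >= 0).all()
        assert np.abs(R.sum(axis=0)).max() < 1e-8 * max(1.0, np.abs(R).max())

    def test_selection_asymmetry(self, baseline_chain):
        _, _, _, R = baseline_chain
        assert R.R[1, 2] > 50 * R.R[2, 1]  # beneficial 2->1 vastly faster than 1->2


class TestStationary:
    def test_neutral_point_mutation_stationary_is_binomial(self):
        m = tv.BindingModel(n=7, epsilon=2.0, mu=4.0)
        R = tv.build_rate_matrix(
            m, tv.FitnessSpec(s=0.0), tv.MutationModel(theta=0.0), tv.PopulationParams(1000, 0.0)
        )
        psi = tv.stationary_distribution(R).psi
        assert np.allclose(psi, binom.pmf(np.arange(8), 7, 0.75), atol=1e-10)

    def test_matches_closed_form_under_selection(self, baseline_chain):
        m, pop, mut, R = baseline_chain
        psi = tv.stationary_distribution(R).psi
        cf = tv.closed_form_stationary(m, tv.FitnessSpec(s=pop.s), pop).psi
        assert np.abs(psi - cf).max() < 1e-8

    def test_bimodal_below_threshold(self):
        """Slightly below the strong-selection threshold the stationary
        distribution keeps both the adapted and the entropy-rich mode."""
        m = tv.BindingModel(n=7, epsilon=2.0, mu=4.0)
        pop = tv.PopulationParams.from_ns(2.0)  # threshold ~ 2.16-2.43
        R = tv.build_rate_matrix(m, tv.FitnessSpec(s=pop.s), tv.MutationModel(theta=0.0), pop)
        psi = tv.stationary_distribution(R).psi
        maxima = [
            k
            for k in range(8)
            if (k == 0 or psi[k] > psi[k - 1]) and (k == 7 or psi[k] > psi[k + 1])
        ]
        assert len(maxima) == 2
        assert maxima[0] <= 2  # near the fittest class
        assert abs(maxima[1] - round(0.75 * 7)) <= 1  # near 3n/4


class TestPropagate:
    def test_zero_time_is_identity(self, baseline_chain):
        _, _, _, R = baseline_chain
        d = MismatchDistribution.delta(5, 7)
        assert np.allclose(tv.propagate(R, d, 0.0).psi, d.psi)

    def test_negative_time_rejected(self, baseline_chain):
        _, _, _, R = baseline_chain
        with pytest.raises(ValueError):
            tv.propagate(R, MismatchDistribution.delta(5, 7), -1.0)

    def test_converges_to_stationary(self, baseline_chain):
        _, _, _, R = baseline_chain
        psi_inf = tv.propagate(R, MismatchDistribution.delta(5, 7), 1e3)
        psi_hat = tv.stationary_distribution(R)
        assert np.abs(psi_inf.psi - psi_hat.psi).sum() < 1e-6

    def test_kl_divergence_nonincreasing(self, baseline_chain):
        _, _, _, R = baseline_chain
        psi_hat = tv.stationary_distribution(R)
        kls = [
            tv.kl_divergence(tv.propagate(R, MismatchDistribution.delta(5, 7), t), psi_hat)
            for t in np.geomspace(1e-4, 1.0, 12)
        ]
        assert np.all(np.diff(kls) <= 1e-12)

    def test_probability_conserved(self, baseline_chain):
        _, _, _, R = baseline_chain
        p = tv.propagate(R, MismatchDistribution.background(7), 0.37)
        assert p.psi.sum() == pytest.approx(1.0)


class TestConvergenceRate:
    def test_two_state_closed_form(self):
        assert tv.convergence_rate(two_state_chain(3.5)) == pytest.approx(7.0)

    def test_slows_with_site_length(self):
        pop = tv.PopulationParams.from_ns(100.0)
        mut = tv.MutationModel(theta=0.15)
        lams = [
            tv.convergence_rate(
                tv.build_rate_matrix(
                    tv.BindingModel(n=n, epsilon=2.0, mu=4.0), tv.FitnessSpec(s=pop.s), mut, pop
                )
            )
            for n in range(6, 13)
        ]
        assert np.all(np.diff(lams) < 0)


class TestHittingTimes:
    def test_target_classes_have_zero_time(self, baseline_chain):
        _, _, _, R = baseline_chain
        ht = tv.hitting_times(R, [0, 1])
        assert ht.times[0] == 0 and ht.times[1] == 0
        assert np.all(ht.times[2:] > 0)

    def test_two_state_exponential_waiting(self):
        ht = tv.hitting_times(two_state_chain(4.0), [0])
        assert ht.times[1] == pytest.approx(0.25)

    def test_exact_matches_tridiagonal_gain_and_loss(self):
        m = tv.BindingModel(n=7, epsilon=2.0, mu=4.0)
        mut = tv.MutationModel(theta=0.0)
        for ns, target in [(100.0, (0, 1)), (-100.0, (3, 4, 5, 6, 7)), (0.0, (0, 1))]:
            pop = tv.PopulationParams.from_ns(ns)
            R = tv.build_rate_matrix(m, tv.FitnessSpec(s=pop.s), mut, pop)
            psi = tv.stationary_distribution(R)
            exact = tv.hitting_times(R, target).times
            tri = tv.hitting_times_tridiagonal(R, psi, target).times
            scale = np.where(exact > 0, exact, 1.0)
            assert np.abs(exact - tri).max() / scale.max() < 1e-8

    def test_single_class_target(self, baseline_chain):
        """Hitting an arbitrary class, e.g. consensus from one mismatch."""
        _, _, _, R = baseline_chain
        ht = tv.hitting_times(R, [0])
        # from k=1 the strong-selection chain is nearly a one-step race
        assert ht.times[1] < ht.times[2] < ht.times[5]
        assert ht.times[1] > 1.0 / R.R[0, 1]  # at least the direct-step wait

    def test_shortest_path_approaches_exact_at_strong_selection(self):
        m = tv.BindingModel(n=7, epsilon=2.0, mu=4.0)
        mut = tv.MutationModel(theta=0.0)
        pop = tv.PopulationParams.from_ns(1e4, N=100_000)
        R = tv.build_rate_matrix(m, tv.FitnessSpec(s=pop.s), mut, pop)
        exact = tv.hitting_times(R, (0, 1)).times
        sp = tv.hitting_times_shortest_path(R, (0, 1)).times
        assert np.allclose(sp[2:] / exact[2:], 1.0, atol=0.01)

    def test_shortest_path_loss_uses_downhill_rates(self):
        m = tv.BindingModel(n=7, epsilon=2.0, mu=4.0)
        pop = tv.PopulationParams.from_ns(-1e4, N=100_000)
        R = tv.build_rate_matrix(m, tv.FitnessSpec(s=pop.s), tv.MutationModel(theta=0.0), pop)
        exact = tv.hitting_times(R, (3, 4, 5, 6, 7)).times
        sp = tv.hitting_times_shortest_path(R, (3, 4, 5, 6, 7)).times
        assert np.allclose(sp[:3] / exact[:3], 1.0, atol=0.01)

    def test_ill_conditioned_loss_flagged(self, baseline_chain):
        """Loss under strong positive selection overflows and must raise,
        not return garbage."""
        _, _, _, R = baseline_chain
        with pytest.raises(ArithmeticError):
            tv.hitting_times(R, (3, 4, 5, 6, 7))

    def test_detailed_balance(self, baseline_chain):
        _, _, _, R = baseline_chain
        psi = tv.stationary_distribution(R).psi
        lhs = np.diag(R.R, -1) * psi[:-1]
        rhs = np.diag(R.R, 1) * psi[1:]
        assert np.abs(lhs - rhs).max() < 1e-8 * max(lhs.max(), rhs.max())


class TestSelectionThreshold:
    def test_closed_form_values(self):
        th = tv.ns_strong_selection_threshold(7)
        assert th["linear"] == pytest.approx(7 * np.log(2) / 2)
        assert round(th["linear"], 3) == 2.426
        assert round(th["full"], 3) == 2.162

    def test_linear_term_dominates_at_large_n(self):
        th = tv.ns_strong_selection_threshold(500)
        assert th["full"] / th["linear"] == pytest.approx(1.0, abs=0.01)

    def test_two_class_toy_threshold_by_hand(self):
        """n=1 step landscape: non-strong mass = 3 e^{-4 Ns pi0} / (1 + ...),
        solvable in closed form."""
        m = tv.BindingModel(n=1, epsilon=3.0, mu=1.0)
        pi0 = tv.occupancy(0, m)
        expected = np.log(3 * 0.95 / 0.05) / (4 * pi0)
        got = tv.bimodality_threshold(
            m, tv.MutationModel(theta=0.0), np.linspace(0.5, 4.0, 8), gamma=np.inf
        )
        assert got == pytest.approx(expected, rel=1e-3)

    def test_threshold_scales_linearly_with_n(self):
        mut = tv.MutationModel(theta=0.0)
        ns_grid = np.linspace(0.5, 12.0, 10)
        ths = [
            tv.bimodality_threshold(tv.BindingModel(n=n, epsilon=2.0, mu=4.0), mut, ns_grid)
            for n in range(5, 16)
        ]
        slope = np.polyfit(np.arange(5, 16), ths, 1)[0]
        assert abs(slope - np.log(2) / 2) / (np.log(2) / 2) < 0.30

    def test_above_threshold_mass_concentrates(self):
        m = tv.BindingModel(n=7, epsilon=2.0, mu=4.0)
        mut = tv.MutationModel(theta=0.0)
        th = tv.bimodality_threshold(m, mut, np.linspace(0.5, 12.0, 10))
        pop = tv.PopulationParams.from_ns(2 * th)
        R = tv.build_rate_matrix(m, tv.FitnessSpec(s=pop.s), mut, pop)
        psi = tv.stationary_distribution(R).psi
        assert psi[2:].sum() < 0.05


class TestValidityCheck:
    def test_fixed_state_warning_at_high_supply(self):
        pop = tv.PopulationParams(N=100_000, s=0.1)
        with pytest.warns(UserWarning, match="fixed-state"):
            pop.fixed_state_ok(u_beneficial=1e-3, delta_f=0.05)

    def test_quiet_at_low_beneficial_supply(self, recwarn):
        # presite at Nu = 0.01: beneficial supply u*k/3 ~ 7e-6 per individual
        pop = tv.PopulationParams(N=1000, s=0.1)
        assert pop.fixed_state_ok(u_beneficial=7e-6, delta_f=0.04)
        assert not recwarn.list
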