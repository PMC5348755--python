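import numpy as np
import pytest
from hypothesis import given, strategies as st

from cocompare.core import DegenerateStatisticsError
from cocompare.fluid import (
    classify_responder,
    fisher_compare,
    fluid_analysis,
    percent_change,
    responder_agreement,
    spearman_rho,
)
from cocompare.simulate import DeviceModel, SimulationConfig, simulate_study

from oracles import spearman_rho_longhand


class TestPercentChange:
    @pytest.mark.parametrize("pre,post,expected", [
        (60, 70, 100 * 10 / 60),
        (50, 45, -10.0),
        (60, 60, 0.0),
    ])
    def test_arithmetic(self, pre, post, expected):
        assert percent_change(pre, post) == pytest.approx(expected)

    def test_nonpositive_pre_rejected(self):
        with pytest.raises(DegenerateStatisticsError):
            percent_change(0.0, 50.0)


class TestClassifyResponder:
    def test_clear_responder(self):
        assert classify_responder(16.7)

    def test_exactly_at_threshold_is_nonresponder(self):
        assert not classify_responder(10.0)

    def test_decrease_is_nonresponder(self):
        assert not classify_responder(-5.0)

    @given(a=st.floats(-50, 50), b=st.floats(-50, 50))
    def test_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert classify_responder(lo) <= classify_responder(hi)


class TestResponderAgreement:
    def test_identical_lists(self):
        assert responder_agreement([True] * 22, [True] * 22) == (22, 22)

    def test_counting(self):
        ref = [True, False, False, True]
        test = [True, False, True, True]
        assert responder_agreement(ref, test) == (3, 4)

    def test_empty(self):
        assert responder_agreement([], []) == (0, 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            responder_agreement([True], [True, False])

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), max_size=20))
    def test_symmetric(self, flags):
        ref = [a for a, _ in flags]
        test = [b for _, b in flags]
        assert responder_agreement(ref, test) == responder_agreement(test, ref)


class TestSpearman:
    def test_monotone_increasing(self):
        rho, p = spearman_rho([1, 2, 3, 4, 5], [10, 20, 25, 30, 50])
        assert rho == pytest.approx(1.0)
        assert p is not None

    def test_reversed(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_four_point_example_with_exact_p(self):
        x, y = [1, 2, 3, 4], [2, 1, 4, 3]
        rho, p = spearman_rho(x, y)
        assert rho == pytest.approx(0.6)
        assert rho == pytest.approx(spearman_rho_longhand(x, y))
        # exact permutation two-sided p at n=4: 10/24 permutations have |rho| >= 0.6
        assert p == pytest.approx(10 / 24)

    def test_constant_vector_undefined(self):
        rho, p = spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
        assert rho is None and p is None

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.5, size=30)
        rho, p = spearman_rho(x, y)
        from scipy import stats

        rho_ref, p_ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(rho_ref)
        assert p == pytest.approx(p_ref)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateStatisticsError):
            spearman_rho([1, 2], [1, 2])


class TestFisherCompare:
    def test_equal_correlations(self):
        z, p = fisher_compare(0.5, 20, 0.5, 20)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_radial_vs_femoral_correlations_not_different(self):
        # r = 0.57 vs 0.60 at n = 22 each: closed form gives z ~ -0.14
        z, p = fisher_compare(0.57, 22, 0.60, 22)
        assert z == pytest.approx(-0.1407, abs=1e-3)
        assert p == pytest.approx(0.888, abs=2e-3)

    def test_clearly_different_correlations(self):
        z, p = fisher_compare(0.9, 100, 0.0, 100)
        assert abs(z) > 3
        assert p < 0.001

    def test_degenerate_r_rejected(self):
        with pytest.raises(DegenerateStatisticsError):
            fisher_compare(1.0, 20, 0.5, 20)
        with pytest.raises(DegenerateStatisticsError):
            fisher_compare(0.5, 3, 0.5, 20)

    @given(
        r1=st.floats(-0.95, 0.95), r2=st.floats(-0.95, 0.95),
        n1=st.integers(5, 100), n2=st.integers(5, 100),
    )
    def test_antisymmetric_under_swap(self, r1, r2, n1, n2):
        z1, p1 = fisher_compare(r1, n1, r2, n2)
        z2, p2 = fisher_compare(r2, n2, r1, n1)
        assert z2 == pytest.approx(-z1, abs=1e-12)
        assert p2 == pytest.approx(p1, abs=1e-12)


class TestFluidAnalysis:
    def test_noise_free_device_agrees_everywhere(self):
        # responders drawn far above, non-responders far below the threshold
        dev = DeviceModel("p", subject_sd=0.0, noise_sd=0.0, residual_sd=0.0)
        cfg = SimulationConfig(
            n_subjects=20, devices=(dev,), td_noise_sd=0.0, gedv_cv=0.0,
            responder_dsv_mean=25.0, responder_dsv_sd=1.0,
            nonresponder_dsv_mean=0.0, nonresponder_dsv_sd=1.0, seed=2,
        )
        ds, truth = simulate_study(cfg)
        fr = fluid_analysis(ds, "td", "p")
        assert fr.n_total == 20
        assert fr.n_agree == 20
        assert fr.responder_ref == tuple(bool(r) for r in truth.responder)

    def test_agreement_degrades_with_device_noise(self):
        def mean_agreement(noise_sd, reps=10):
            vals = []
            for seed in range(reps):
                dev = DeviceModel("p", noise_sd=noise_sd, residual_sd=noise_sd)
                cfg = SimulationConfig(
                    n_subjects=25, devices=(dev,), td_noise_sd=0.0, gedv_cv=0.0,
                    seed=seed,
                )
                ds, _ = simulate_study(cfg)
                fr = fluid_analysis(ds, "td", "p")
                vals.append(fr.n_agree / fr.n_total)
            return np.mean(vals)

        assert mean_agreement(0.1) > mean_agreement(1.5)

    def test_pairing_modes(self, simulated_study):
        ds, _ = simulated_study
        a = fluid_analysis(ds, "td", "pR", pairing_mode="postcal-postcal")
        b = fluid_analysis(ds, "td", "pR", pairing_mode="postcal-precal")
        assert a.n_total == b.n_total
        assert a.pairing_mode != b.pairing_mode
        with pytest.raises(ValueError):
            fluid_analysis(ds, "td", "pR", pairing_mode="precal-precal")
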