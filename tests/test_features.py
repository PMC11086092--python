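"""Non-linear feature estimators: embeddings, exact values, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eegcomplexity as ec
from eegcomplexity.errors import DegenerateSeriesError, ParameterError
from eegcomplexity.features import FEATURE_NAMES, UnreliableResultWarning


class TestEmbedding:
    def test_state_count_follows_m_tau_identity(self):
        att = ec.embed(np.arange(10.0), ec.EmbeddingParams(tau=2, m=3))
        assert att.n_states == 6  # M = N - (m-1)*tau = 10 - 4
        assert np.array_equal(att.states[0], [0.0, 2.0, 4.0])
        assert np.array_equal(att.states[5], [5.0, 7.0, 9.0])

    def test_trivial_embedding_is_the_series(self):
        x = np.random.default_rng(0).standard_normal(50)
        att = ec.embed(x, ec.EmbeddingParams(tau=1, m=1))
        assert np.array_equal(att.states[:, 0], x)

    def test_impossible_embedding_rejected(self):
        with pytest.raises(ParameterError):
            ec.embed(np.arange(5.0), ec.EmbeddingParams(tau=3, m=3))

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            ec.EmbeddingParams(tau=0, m=2)


class TestDelayAndDimension:
    def test_sine_delay_is_quarter_period(self):
        x = np.sin(2 * np.pi * np.arange(1280) / 20.0)
        assert ec.estimate_delay(x) == 5

    def test_iid_noise_collapses_to_smallest_lags(self):
        taus = [ec.estimate_delay(np.random.default_rng(s).standard_normal(1024))
                for s in range(10)]
        assert all(t <= 4 for t in taus)
        assert np.median(taus) <= 2

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            ec.estimate_delay(np.ones(256))

    def test_noiseless_sine_unfolds_in_two_dimensions(self):
        x = np.sin(2 * np.pi * np.arange(1280) / 20.0)
        assert ec.estimate_dimension(x, tau=5) == 2

    def test_iid_noise_never_settles(self):
        x = np.random.default_rng(3).standard_normal(1024)
        with pytest.warns(UnreliableResultWarning):
            assert ec.estimate_dimension(x, tau=1) == 10

    def test_series_too_short_for_cap_rejected(self):
        with pytest.raises(ParameterError):
            ec.estimate_dimension(np.random.default_rng(0).standard_normal(80), tau=10)


class TestCorrelationDimension:
    def test_line_segment_has_dimension_one(self):
        att = ec.embed(np.linspace(0.0, 1.0, 600), ec.EmbeddingParams(tau=1, m=2))
        assert abs(ec.correlation_dimension(att) - 1.0) <= 0.1

    def test_repeated_state_rejected(self):
        att = ec.embed(np.zeros(300), ec.EmbeddingParams(tau=1, m=2))
        with pytest.raises(DegenerateSeriesError):
            ec.correlation_dimension(att)

    def test_too_few_states_rejected(self):
        att = ec.embed(np.random.default_rng(0).standard_normal(60),
                       ec.EmbeddingParams(tau=1, m=2))
        with pytest.raises(ParameterError):
            ec.correlation_dimension(att)


class TestLyapunov:
    def test_periodic_orbit_has_no_divergence(self):
        x = np.sin(2 * np.pi * np.arange(1280) / 20.0)
        att = ec.embed(x, ec.EmbeddingParams(tau=5, m=2))
        assert ec.largest_lyapunov(att, ts=1.0) <= 0.05

    def test_small_attractor_rejected(self):
        att = ec.embed(np.random.default_rng(0).standard_normal(50),
                       ec.EmbeddingParams(tau=1, m=1))
        with pytest.raises(ParameterError):
            ec.largest_lyapunov(att, ts=1.0)


class TestApproximateEntropy:
    def test_constant_series_is_perfectly_regular(self):
        assert ec.approximate_entropy(np.ones(200)) == 0.0

    def test_amplitude_scale_invariance(self):
        x = np.random.default_rng(5).standard_normal(512)
        assert abs(ec.approximate_entropy(x) - ec.approximate_entropy(10 * x)) < 1e-12

    def test_noise_is_less_regular_than_a_sine(self):
        noise = np.random.default_rng(1).standard_normal(1024)
        sine = np.sin(2 * np.pi * np.arange(1024) / 64.0)
        assert ec.approximate_entropy(noise) > ec.approximate_entropy(sine)


class TestLongMemory:
    def test_white_noise_hurst_is_half(self):
        est = [ec.hurst_rs(np.random.default_rng(s).standard_normal(2048))
               for s in range(10)]
        assert abs(np.mean(est) - 0.5) <= 0.1

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            ec.hurst_rs(np.ones(512))
        with pytest.raises(DegenerateSeriesError):
            ec.dfa(np.ones(512))

    def test_dfa_tracks_fgn_exponent(self):
        est = [ec.dfa(ec.gen_fgn(0.8, 2048, seed=s)) for s in range(10)]
        assert abs(np.mean(est) - 0.8) <= 0.1


class TestFractalDimensions:
    def test_higuchi_line_is_one(self):
        assert abs(ec.higuchi_fd(np.arange(200.0)) - 1.0) <= 0.05

    def test_higuchi_sine_is_smooth(self):
        x = np.sin(2 * np.pi * np.arange(1280) / 128.0)
        assert ec.higuchi_fd(x) <= 1.1

    def test_higuchi_kmax_validation(self):
        with pytest.raises(ParameterError):
            ec.higuchi_fd(np.arange(200.0), kmax=1)

    def test_katz_line_is_exactly_one(self):
        assert ec.katz_fd(np.arange(100.0) * 2 + 3) == pytest.approx(1.0, abs=1e-12)

    def test_katz_zigzag_matches_hand_computation(self):
        # [0,1,0,1,0]: L = 4*sqrt(2), a = sqrt(2), d = 4
        # => log(L/a)/log(d/a) = log(4)/log(2*sqrt(2)) = 4/3
        assert ec.katz_fd([0, 1, 0, 1, 0]) == pytest.approx(4.0 / 3.0, abs=1e-12)

    def test_katz_constant_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            ec.katz_fd(np.ones(10))


class TestEnergyAndEntropy:
    def test_energy_direct_sum(self):
        assert ec.energy([1.0, 2.0, 2.0]) == 9.0
        assert ec.energy(np.zeros(16)) == 0.0

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(c=st.floats(min_value=0.01, max_value=50.0))
    def test_energy_homogeneity(self, c):
        x = np.random.default_rng(2).standard_normal(64)
        assert ec.energy(c * x) == pytest.approx(c**2 * ec.energy(x), rel=1e-12)

    def test_unit_samples_have_zero_entropy(self):
        assert ec.shannon_entropy([1.0, 1.0]) == 0.0
        assert ec.log_energy_entropy([1.0, 1.0]) == 0.0

    def test_shannon_single_sample_closed_form(self):
        assert ec.shannon_entropy([0.5]) == pytest.approx(-0.25 * np.log(0.25), abs=1e-12)

    def test_log_energy_sign_convention(self):
        assert ec.log_energy_entropy([np.sqrt(np.e)]) == pytest.approx(-1.0, abs=1e-12)


class TestExtractAll:
    def test_identical_input_gives_identical_vector(self):
        x = ec.gen_fgn(0.7, 1280, seed=9)
        a = ec.extract_all(x, fs=256.0)
        b = ec.extract_all(x, fs=256.0)
        assert a.values == b.values and a.status == b.status
        assert set(a.values) == set(FEATURE_NAMES)

    def test_constant_window_contract(self):
        fv = ec.extract_all(np.zeros(1280), fs=256.0)
        assert fv.values["EN"] == 0.0
        assert fv.values["ApEn"] == 0.0
        for name in ("D2", "LLE", "H", "DFA", "FDk"):
            assert fv.status[name].startswith("degenerate"), name
            assert np.isnan(fv.values[name])

    def test_alpha_tone_energy_dominates_its_band(self):
        t = np.arange(1280) / 256.0
        x = np.sin(2 * np.pi * 11.0 * t) + 0.01 * np.random.default_rng(0).standard_normal(1280)
        pyr = ec.dwt_decompose(x)
        en_alpha = ec.extract_all(ec.reconstruct_subband(pyr, "alpha"), 256.0).values["EN"]
        en_delta = ec.extract_all(ec.reconstruct_subband(pyr, "delta"), 256.0).values["EN"]
        assert en_alpha >= 10 * en_delta
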