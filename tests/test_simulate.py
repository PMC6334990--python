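"""Montage construction, predictor table, epoch synthesis, and filtering."""

import numpy as np
import pytest
from scipy import signal

from surpeeg.montage import make_montage
from surpeeg.ngram import train_ngram
from surpeeg.simulate import (
    Effect,
    EpochSet,
    build_predictor_table,
    epoch_times,
    lowpass_epochs,
    reject_trials,
    simulate_epochs,
)
from surpeeg.surprisal import ngram_surprisal


@pytest.fixture(scope="module")
def montage16():
    return make_montage(16, 4, seed=0)


@pytest.fixture(scope="module")
def table(small_corpus):
    ng = ngram_surprisal(train_ngram(small_corpus), small_corpus)
    return build_predictor_table(small_corpus, [ng], seed=3)


class TestMontage:
    def test_two_electrodes_one_pair(self):
        m = make_montage(2, 1, seed=0)
        assert m.adjacency[0, 1] and m.adjacency[1, 0]
        assert not m.adjacency[0, 0]

    def test_61_electrode_reference_layout(self):
        m = make_montage(61, 4, seed=0)
        assert m.n_electrodes == 61
        assert (m.adjacency == m.adjacency.T).all()
        assert not m.adjacency.diagonal().any()
        assert m.is_connected()
        assert all(m.neighbors(e).size >= 1 for e in range(61))

    def test_seed_determinism(self):
        a = make_montage(16, 4, seed=5)
        b = make_montage(16, 4, seed=5)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)

    @pytest.mark.parametrize("n_e,k", [(1, 1), (4, 4), (4, 0)])
    def test_invalid_parameters(self, n_e, k):
        with pytest.raises(ValueError):
            make_montage(n_e, k, seed=0)


class TestPredictorTable:
    def test_orders_restart_per_sentence(self, small_corpus, table):
        lens = [len(s) for s in small_corpus.sentences]
        assert list(table["word_order"][: lens[0]]) == list(range(1, lens[0] + 1))
        assert (table.groupby("sentence_order")["word_order"].min() == 1).all()
        sizes = table.groupby("sentence_order").size()
        assert list(sizes) == lens

    def test_frq_prev_is_shifted_frq(self, table):
        # within a sentence, frq_prev of word i equals frq of word i-1
        inner = table["word_order"] > 1
        np.testing.assert_allclose(
            table.loc[inner, "frq_prev"].to_numpy(),
            table["frq"].shift(1)[inner].to_numpy(),
        )
        inner_next = table["frq_next"].shift(1)[inner]
        np.testing.assert_allclose(
            inner_next.to_numpy(), table.loc[inner, "frq"].to_numpy()
        )

    def test_function_words_more_frequent(self, table):
        means = table.groupby("word_class")["frq"].mean()
        assert means["function"] > means["content"]

    def test_no_missing_values(self, table):
        assert not table.isna().any().any()

    def test_correlation_between_models_reported(self, small_corpus, fixture_grammar):
        from surpeeg.surprisal import cfg_surprisal

        ng = ngram_surprisal(train_ngram(small_corpus), small_corpus)
        cfg = cfg_surprisal(fixture_grammar, small_corpus)
        t = build_predictor_table(small_corpus, [ng, cfg], seed=0)
        r = np.corrcoef(t["surprisal_Ngram"], t["surprisal_CFG"])[0, 1]
        # the sequential and hierarchical series share variance but are not
        # interchangeable (qualitative check only)
        assert 0.2 < abs(r) < 0.99


class TestSimulateEpochs:
    def test_zero_effects_zero_noise(self, table, montage16):
        ep = simulate_epochs(table, [], montage16, 3, fs=100, noise_sd=0.0, seed=0)
        assert np.all(ep.data == 0)

    def test_sample_count_at_500hz(self, table, montage16):
        ep = simulate_epochs(
            table[:5], [], montage16, 1, fs=500, noise_sd=0.0, seed=0
        )
        assert ep.data.shape[-1] == 651
        assert len(epoch_times(500.0)) == 651
        assert ep.time_index(0.0) == 150  # word onset at t = 0

    def test_noiseless_injection_recovered_by_ols(self, table, montage16):
        """Per-timepoint OLS on noiseless data recovers spatial x kernel."""
        spatial = np.linspace(0.2, 1.0, 16)
        eff = Effect("surprisal_Ngram", spatial, 0.3, 0.05, 2.0)
        ep = simulate_epochs(
            table, [eff], montage16, 1, fs=100, noise_sd=0.0,
            subject_gain_sd=0.0, seed=0,
        )
        x = table["surprisal_Ngram"].to_numpy()
        X = np.column_stack([np.ones(len(x)), x - x.mean()])
        Y = ep.data[0].reshape(len(x), -1)
        beta = np.linalg.lstsq(X, Y, rcond=None)[0][1].reshape(16, -1)
        expect = spatial[:, None] * eff.kernel(ep.times)[None, :]
        np.testing.assert_allclose(beta, expect, atol=1e-9)

    def test_linear_in_predictor(self, table, montage16):
        spatial = np.ones(16)
        args = dict(fs=100, noise_sd=0.0, subject_gain_sd=0.0, seed=0)
        e1 = Effect("surprisal_Ngram", spatial, 0.3, 0.05, 1.0)
        e2 = Effect("surprisal_Ngram", spatial, 0.3, 0.05, 2.0)
        ep1 = simulate_epochs(table, [e1], montage16, 1, **args)
        ep2 = simulate_epochs(table, [e2], montage16, 1, **args)
        np.testing.assert_allclose(ep2.data, 2.0 * ep1.data, atol=1e-12)

    def test_word_class_restriction(self, table, montage16):
        eff = Effect("surprisal_Ngram", np.ones(16), 0.3, 0.05, 1.0, "content")
        ep = simulate_epochs(
            table, [eff], montage16, 1, fs=100, noise_sd=0.0,
            subject_gain_sd=0.0, seed=0,
        )
        func = (table["word_class"] == "function").to_numpy()
        assert np.all(ep.data[0][func] == 0)
        assert np.any(ep.data[0][~func] != 0)

    def test_kernel_outside_window_errors(self, table, montage16):
        eff = Effect("surprisal_Ngram", np.ones(16), 2.0, 0.05, 1.0)
        with pytest.raises(ValueError, match="window"):
            simulate_epochs(table, [eff], montage16, 1, fs=100, seed=0)

    def test_seed_determinism(self, table, montage16):
        a = simulate_epochs(table, [], montage16, 2, fs=100, seed=9)
        b = simulate_epochs(table, [], montage16, 2, fs=100, seed=9)
        np.testing.assert_array_equal(a.data, b.data)


class TestFiltering:
    def test_constant_signal_unchanged(self, table, montage16):
        ep = simulate_epochs(table[:10], [], montage16, 1, fs=100, noise_sd=0.0, seed=0)
        ep.data[:] = 3.25
        out = lowpass_epochs(ep, 40.0)
        np.testing.assert_allclose(out.data, 3.25, atol=1e-9)

    def test_single_pass_gain_at_cutoff(self):
        sos = signal.butter(4, 40.0, btype="low", fs=500.0, output="sos")
        w, h = signal.sosfreqz(sos, worN=[40.0], fs=500.0)
        assert abs(h[0]) == pytest.approx(1.0 / np.sqrt(2.0), abs=1e-6)

    def test_stopband_attenuation(self, montage16, table):
        """A 100 Hz sinusoid at fs=500 is crushed by the 40 Hz filter."""
        ep = simulate_epochs(table[:8], [], montage16, 1, fs=500, noise_sd=0.0, seed=0)
        tone = np.sin(2 * np.pi * 100.0 * ep.times)
        ep.data[:] = tone
        out = lowpass_epochs(ep, 40.0)
        # ignore filtfilt edge transients
        core = slice(50, -50)
        rms_in = np.sqrt(np.mean(tone[core] ** 2))
        rms_out = np.sqrt(np.mean(out.data[0, 0, 0, core] ** 2))
        assert rms_out < 0.01 * rms_in

    def test_passband_preserved(self, montage16, table):
        ep = simulate_epochs(table[:8], [], montage16, 1, fs=500, noise_sd=0.0, seed=0)
        tone = np.sin(2 * np.pi * 5.0 * ep.times)
        ep.data[:] = tone
        out = lowpass_epochs(ep, 40.0)
        core = slice(100, -100)
        gain = np.sqrt(
            np.mean(out.data[0, 0, 0, core] ** 2) / np.mean(tone[core] ** 2)
        )
        assert 0.99 <= gain <= 1.01

    def test_cutoff_at_nyquist_errors(self, table, montage16):
        ep = simulate_epochs(table[:5], [], montage16, 1, fs=100, noise_sd=0.0, seed=0)
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_epochs(ep, 50.0)


class TestRejection:
    def test_zero_fraction_keeps_everything(self, table, montage16):
        ep = simulate_epochs(table, [], montage16, 3, fs=100, seed=0)
        out = reject_trials(ep, 0.0, seed=1)
        assert out.mask.all()

    def test_binomial_rate(self, table, montage16):
        ep = simulate_epochs(table, [], montage16, 5, fs=100, noise_sd=0.0, seed=0)
        out = reject_trials(ep, 0.135, seed=2)
        n = out.mask.size
        expect = n * (1 - 0.135)
        sd = np.sqrt(n * 0.135 * (1 - 0.135))
        assert abs(out.mask.sum() - expect) <= 3 * sd

    def test_masks_differ_across_subjects(self, table, montage16):
        ep = simulate_epochs(table, [], montage16, 4, fs=100, noise_sd=0.0, seed=0)
        out = reject_trials(ep, 0.3, seed=3)
        assert not all(
            np.array_equal(out.mask[0], out.mask[s]) for s in range(1, 4)
        )

    def test_invalid_fraction(self, table, montage16):
        ep = simulate_epochs(table[:5], [], montage16, 1, fs=100, seed=0)
        with pytest.raises(ValueError):
            reject_trials(ep, 1.0, seed=0)


class TestPersistence:
    def test_h5_roundtrip(self, table, montage16, tmp_path):
        ep = simulate_epochs(table[:10], [], montage16, 2, fs=100, seed=4)
        ep.save(tmp_path / "ep.h5")
        back = EpochSet.load(tmp_path / "ep.h5")
        np.testing.assert_array_equal(back.data, ep.data)
        np.testing.assert_array_equal(back.mask, ep.mask)
        assert back.fs == ep.fs
        np.testing.assert_array_equal(back.montage.adjacency, montage16.adjacency)
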