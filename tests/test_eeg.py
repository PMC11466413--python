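"""EEG pipeline: pattern binning, condition-mode labels, LORO decoding,
ERP interaction contrast, and cluster statistics."""

import numpy as np
import pandas as pd
import pytest

from numbci import (
    Condition,
    ModelSpec,
    ObserverParams,
    SimulationState,
    bin_patterns,
    cluster_permutation,
    condition_mode_labels,
    decode_estimates,
    erp_av_interaction,
)
from numbci.eeg import EEGEpochs, deconcatenate
from numbci.synth import (
    EstimateEmbedding,
    ForwardEEGSpec,
    default_channels,
    make_design,
    simulate_subject,
    synth_eeg,
)


def _noise_epochs(n_trials=24, n_ch=64, n_samp=171, seed=0, sfreq=200.0):
    rng = np.random.default_rng(seed)
    return EEGEpochs(
        data=rng.standard_normal((n_trials, n_ch, n_samp)),
        time_ms=-100.0 + 1000.0 * np.arange(n_samp) / sfreq,
        sfreq=sfreq,
        run=1 + (np.arange(n_trials) % 4),
        n_aud=rng.integers(1, 5, n_trials),
        n_vis=rng.integers(1, 5, n_trials),
        task=np.array(["A", "V"] * ((n_trials + 1) // 2))[:n_trials],
        channels=default_channels(n_ch),
    )


class TestBinPatterns:
    def test_dimensions_at_200hz(self):
        """A 171-sample epoch yields 40 windows of 64*12 = 768 features."""
        win = bin_patterns(_noise_epochs())
        assert win.X.shape == (40, 24, 768)
        assert win.times_ms[0] == pytest.approx(-100.0)
        # 20-ms step = 4 samples
        assert win.times_ms[1] - win.times_ms[0] == pytest.approx(20.0)

    def test_adjacent_windows_share_eight_samples(self):
        epochs = _noise_epochs(n_trials=4)
        win = bin_patterns(epochs)
        a = deconcatenate(win.X[0, 0], 64, 12)
        b = deconcatenate(win.X[1, 0], 64, 12)
        np.testing.assert_array_equal(a[:, 4:], b[:, :8])

    def test_features_deconcatenate_exactly(self):
        epochs = _noise_epochs(n_trials=2)
        win = bin_patterns(epochs)
        block = deconcatenate(win.X[3, 1], 64, 12)
        np.testing.assert_array_equal(block, epochs.data[1, :, 12:24])

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError):
            bin_patterns(_noise_epochs(n_samp=8))


class TestConditionModeLabels:
    def test_low_noise_congruent_modes_equal_truth(self):
        p = ObserverParams(
            p_common=0.9, mu_p=2.5, sigma_p=8.0, sigma_a=0.05, sigma_v=0.05, lapse=0.0
        )
        conds = [Condition(n, n, "A") for n in (1, 3)]
        out = condition_mode_labels(
            p, ModelSpec("MA", "constant"), SimulationState(0), conditions=conds, n_sim=3000
        )
        for _, row in out.iterrows():
            for name in ("v_seg", "a_seg", "fusion", "final"):
                assert row[name] == pytest.approx(row["n_aud"], abs=0.1)

    def test_fusion_mode_between_segregation_modes(self):
        p = ObserverParams(
            p_common=0.5, mu_p=2.5, sigma_p=2.0, sigma_a=0.4, sigma_v=0.8, lapse=0.0
        )
        out = condition_mode_labels(
            p,
            ModelSpec("MA", "constant"),
            SimulationState(1),
            conditions=[Condition(1, 4, "V"), Condition(4, 1, "A")],
            n_sim=4000,
        )
        for _, row in out.iterrows():
            lo, hi = sorted([row["a_seg"], row["v_seg"]])
            assert lo - 0.15 <= row["fusion"] <= hi + 0.15

    def test_deterministic_under_seed(self):
        p = ObserverParams(p_common=0.5, sigma_a=0.5, sigma_v=0.8)
        conds = [Condition(2, 3, "A")]
        a = condition_mode_labels(p, ModelSpec("MA", "constant"), SimulationState(3), conditions=conds, n_sim=2000)
        b = condition_mode_labels(p, ModelSpec("MA", "constant"), SimulationState(3), conditions=conds, n_sim=2000)
        pd.testing.assert_frame_equal(a, b)


def _embedded_setup(gain=4.0, latency=150.0, n_reps=3, seed=5, noise=1.0):
    params = ObserverParams(
        p_common=0.5, mu_p=2.5, sigma_p=1.5, sigma_a=0.4, sigma_v=1.0, lapse=0.0
    )
    spec = ModelSpec("MA", "constant")
    design = make_design(n_av_runs=4, n_uni_runs=0, state=SimulationState(seed))
    # thin the design for speed
    table = (
        design.trials.groupby(["run", "n_aud", "n_vis"], as_index=False)
        .head(n_reps)
        .reset_index(drop=True)
    )
    design.trials = table
    rng = np.random.default_rng(seed)
    trials = simulate_subject(design, params, spec, rng)
    trials["subject"] = "S1"
    fwd = ForwardEEGSpec(
        embeddings={
            "v_seg": EstimateEmbedding(latency_ms=latency, width_ms=30.0, gain=gain)
        },
        noise_std=noise,
        one_over_f_exponent=1.0,
        tmax_ms=400.0,
    )
    state = SimulationState(seed, n_sim=3000)
    epochs, labels = synth_eeg(trials, params, spec, fwd, state)
    return epochs, labels


class TestDecoding:
    def test_embedded_estimate_recovered_in_window(self):
        """Strongly embedded visual-segregation signal at 150 ms: decoding
        accuracy is high inside and near zero far outside the embedding."""
        epochs, labels = _embedded_setup()
        windows = bin_patterns(epochs)
        inside = np.where((windows.times_ms >= 100) & (windows.times_ms <= 160))[0][:2]
        outside = np.where(windows.times_ms <= -60)[0][:2]
        sel = np.concatenate([inside, outside])
        from numbci.eeg import PatternWindows

        sub = PatternWindows(
            times_ms=windows.times_ms[sel], X=windows.X[sel],
            n_channels=64, win_samples=12,
        )
        trace, fold_log = decode_estimates(
            sub, {"v_seg": labels["v_seg"].to_numpy()}, epochs.run,
            c_grid=(1.0,), nu_grid=(0.5,),
        )
        z_in = trace[trace["time_ms"] >= 100]["z"].mean()
        z_out = trace[trace["time_ms"] <= -60]["z"].mean()
        assert z_in > 0.3
        assert abs(z_out) < 0.15

    def test_no_leakage_between_runs(self):
        epochs, labels = _embedded_setup()
        windows = bin_patterns(epochs)
        from numbci.eeg import PatternWindows

        sub = PatternWindows(
            times_ms=windows.times_ms[:1], X=windows.X[:1], n_channels=64, win_samples=12
        )
        _, fold_log = decode_estimates(
            sub, {"v_seg": labels["v_seg"].to_numpy()}, epochs.run,
            c_grid=(1.0,), nu_grid=(0.5,),
        )
        for entry in fold_log:
            assert entry["test_run"] not in entry["train_runs"]

    def test_shuffled_labels_give_chance_accuracy(self):
        epochs, labels = _embedded_setup()
        windows = bin_patterns(epochs)
        from numbci.eeg import PatternWindows

        sel = [5, 12]
        sub = PatternWindows(
            times_ms=windows.times_ms[sel], X=windows.X[sel], n_channels=64, win_samples=12
        )
        rng = np.random.default_rng(0)
        zs = []
        for _ in range(3):
            y = rng.permutation(labels["v_seg"].to_numpy())
            trace, _ = decode_estimates(
                sub, {"v_seg": y}, epochs.run, c_grid=(1.0,), nu_grid=(0.5,)
            )
            zs.append(trace["z"].mean())
        assert abs(np.mean(zs)) < 0.1

    def test_single_run_rejected(self):
        epochs, labels = _embedded_setup()
        windows = bin_patterns(epochs)
        with pytest.raises(ValueError):
            decode_estimates(
                windows, {"v_seg": labels["v_seg"].to_numpy()},
                np.ones_like(epochs.run),
            )


class TestErpInteraction:
    def _epochs_with_classes(self, av_wave, a_wave, v_wave, seed=0, n_per=10):
        n_samp = 171
        time = -100.0 + 5.0 * np.arange(n_samp)
        chans = default_channels(64)
        data, na, nv = [], [], []
        for wave, (a, v) in (
            (av_wave, (2, 2)),
            (a_wave, (2, 0)),
            (v_wave, (0, 2)),
        ):
            for _ in range(n_per):
                ep = np.zeros((64, n_samp))
                ep[:, :] = wave[None, :]
                data.append(ep)
                na.append(a)
                nv.append(v)
        n = len(data)
        return EEGEpochs(
            data=np.array(data),
            time_ms=time,
            sfreq=200.0,
            run=np.ones(n, dtype=int),
            n_aud=np.array(na),
            n_vis=np.array(nv),
            task=np.array(["V"] * n),
            channels=chans,
        )

    def test_additive_data_gives_null_difference(self):
        n_samp = 171
        t = np.arange(n_samp)
        a = np.sin(t / 7.0)
        v = np.cos(t / 11.0)
        epochs = self._epochs_with_classes(a + v, a, v)
        _, diff = erp_av_interaction(epochs, baseline=False)
        np.testing.assert_allclose(diff, 0.0, atol=1e-12)

    def test_superadditive_bump_recovered_at_latency(self):
        n_samp = 171
        time = -100.0 + 5.0 * np.arange(n_samp)
        a = np.zeros(n_samp)
        v = np.zeros(n_samp)
        bump = 2.0 * np.exp(-0.5 * ((time - 180.0) / 25.0) ** 2)
        epochs = self._epochs_with_classes(a + v + bump, a, v)
        t_ms, diff = erp_av_interaction(epochs, baseline=True)
        assert t_ms[np.argmax(diff)] == pytest.approx(180.0, abs=10.0)
        pre = diff[t_ms < 0]
        assert np.abs(pre.mean()) < 1e-6

    def test_missing_occipital_channel_rejected(self):
        epochs = _noise_epochs()
        epochs.channels[epochs.channels.index("Oz")] = "XX"
        with pytest.raises(ValueError):
            erp_av_interaction(epochs)


class TestClusterPermutation:
    def test_no_suprathreshold_points_yields_empty_list(self):
        # demeaning across subjects pins every time point's t at 0 < thresh
        rng = np.random.default_rng(1)
        data = rng.standard_normal((10, 50))
        data -= data.mean(axis=0)
        assert cluster_permutation(data, n_perm=100, seed=0) == []

    def test_sustained_effect_detected_with_correct_extent(self):
        """d=2 effect over 100-300 ms at 200 Hz: one significant cluster
        spanning >= 150 ms."""
        rng = np.random.default_rng(2)
        n_sub, n_t = 20, 120
        time = -100.0 + 5.0 * np.arange(n_t)
        data = rng.standard_normal((n_sub, n_t))
        effect = (time >= 100) & (time <= 300)
        data[:, effect] += 2.0
        clusters = cluster_permutation(data, n_perm=500, seed=3)
        sig = [c for c in clusters if c["p"] < 0.01]
        assert len(sig) >= 1
        best = max(sig, key=lambda c: abs(c["mass"]))
        span_ms = (best["end"] - best["start"]) * 5.0
        assert span_ms >= 150.0

    def test_agrees_with_mne_reference_implementation(self):
        """One-sample cluster p-values match MNE's permutation cluster test
        on the same data (independent implementation, same statistic)."""
        from mne.stats import permutation_cluster_1samp_test

        rng = np.random.default_rng(2)
        data = rng.standard_normal((15, 60))
        data[:, 20:30] += 1.2
        _, _, mne_p, _ = permutation_cluster_1samp_test(
            data, threshold=2.0, n_permutations=1024, tail=0,
            rng=np.random.default_rng(1), out_type="mask", verbose=False,
        )
        mine = cluster_permutation(data, n_perm=1000, seed=3)
        assert len(mine) == len(mne_p)
        np.testing.assert_allclose(
            sorted(c["p"] for c in mine), sorted(mne_p), atol=0.05
        )
        # the injected 20:30 effect is the uniquely significant cluster in both
        sig = [c for c in mine if c["p"] < 0.01]
        assert len(sig) == 1 and (sig[0]["start"], sig[0]["end"]) == (20, 29)
        assert (np.asarray(mne_p) < 0.01).sum() == 1

    def test_two_sample_mode_and_sorting(self):
        rng = np.random.default_rng(4)
        g1 = rng.standard_normal((12, 60))
        g2 = rng.standard_normal((12, 60))
        g1[:, 10:20] += 1.5
        g1[:, 40:45] += 1.5
        clusters = cluster_permutation(g1, g2, test="two-sample", n_perm=300, seed=5)
        starts = [c["start"] for c in clusters]
        assert starts == sorted(starts)
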