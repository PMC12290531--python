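"""Continuous-EEG cleaning chain: detrend, filter, resample, epoch, repair."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from oddtag import preprocess as pp


def make_rec(data, rate=200.0, events=(), montage=None):
    n_ch = np.atleast_2d(data).shape[0]
    return pp.EEGRecording(
        data=data,
        rate=rate,
        ch_names=[f"E{i}" for i in range(n_ch)],
        montage=montage,
        events=list(events),
    )


class TestDetrend:
    def test_constant_removed(self):
        out = pp.detrend_dc(make_rec(np.full((1, 100), 5.0)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_ramp_removed(self):
        t = np.arange(200.0)
        out = pp.detrend_dc(make_rec(3.0 * t[None, :]))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-9)

    def test_sinusoid_survives_ramp_removal(self):
        # oracle: least-squares line fit removed from the composite
        n, rate = 2000, 200.0
        t = np.arange(n) / rate
        sine = np.sin(2 * np.pi * 8 * t)
        comp = sine + 2.5 * t + 1.0
        out = pp.detrend_dc(make_rec(comp[None, :], rate)).data[0]
        X = np.column_stack([np.ones(n), t])
        beta, *_ = np.linalg.lstsq(X, comp, rcond=None)
        oracle = comp - X @ beta
        assert np.sqrt(np.mean((out - oracle) ** 2)) < 1e-9 * np.std(sine)


class TestBandpass:
    def test_passband_tone_preserved(self):
        rate, n = 2000.0, 40000
        t = np.arange(n) / rate
        x = np.sin(2 * np.pi * 8 * t)
        y = pp.bandpass_filter(make_rec(x[None, :], rate)).data[0]
        interior = slice(4000, -4000)
        atten = np.std(y[interior]) / np.std(x[interior])
        assert abs(1 - atten) < 0.02

    @pytest.mark.parametrize("freq,max_gain", [(0.01, 0.10), (100.0, 0.01)])
    def test_stopband_attenuation(self, freq, max_gain):
        # oracle: squared design magnitude response (forward-backward pass)
        sos = signal.butter(4, (0.1, 40), btype="bandpass", fs=2000, output="sos")
        w, h = signal.sosfreqz(sos, worN=[freq], fs=2000)
        assert np.abs(h[0]) ** 2 < max_gain

    def test_invalid_corners_rejected(self):
        rec = make_rec(np.zeros((1, 100)), rate=100.0)
        with pytest.raises(ValueError):
            pp.bandpass_filter(rec, 40.0, 0.1)
        with pytest.raises(ValueError):
            pp.bandpass_filter(rec, 0.1, 60.0)


class TestResample:
    def test_sample_count_divided(self):
        rec = make_rec(np.zeros((2, 8000)), rate=2000.0)
        out = pp.resample(rec, 500.0)
        assert out.data.shape == (2, 2000)
        assert out.rate == 500.0

    def test_tone_amplitude_preserved(self):
        rate, n = 2000.0, 80000
        t = np.arange(n) / rate
        x = np.sin(2 * np.pi * 8 * t)
        out = pp.resample(make_rec(x[None, :], rate), 500.0).data[0]
        t2 = np.arange(out.size) / 500.0
        oracle = np.sin(2 * np.pi * 8 * t2)
        interior = slice(500, -500)
        amp_err = np.std(out[interior]) / np.std(oracle[interior]) - 1
        assert abs(amp_err) < 0.01

    def test_event_remapped_to_same_time(self):
        rec = make_rec(np.zeros((1, 8000)), rate=2000.0, events=[(4000, "t")])
        out = pp.resample(rec, 500.0)
        assert abs(out.events[0][0] - 1000) <= 1

    def test_upsampling_rejected(self):
        rec = make_rec(np.zeros((1, 100)), rate=100.0)
        with pytest.raises(ValueError):
            pp.resample(rec, 200.0)


class TestEpoching:
    def test_full_windows_kept(self, rng):
        data = rng.standard_normal((3, 1000))
        rec = make_rec(data, rate=100.0, events=[(0, "a"), (100, "b"), (500, "c")])
        ep = pp.epoch_trials(rec, window=(0.0, 2.0))
        assert ep.data.shape == (3, 3, 200)
        np.testing.assert_array_equal(ep.data[1], data[:, 100:300])

    def test_truncated_trigger_dropped(self, caplog):
        rec = make_rec(np.zeros((1, 300)), rate=100.0, events=[(0, "a"), (250, "b")])
        with caplog.at_level("WARNING", logger="oddtag.preprocess"):
            ep = pp.epoch_trials(rec, window=(0.0, 2.0))
        assert ep.n_trials == 1
        assert any("truncated" in r.message for r in caplog.records)

    def test_meta_subset_to_kept_trials(self):
        rec = make_rec(np.zeros((1, 300)), rate=100.0, events=[(0, "a"), (250, "b")])
        meta = pd.DataFrame({"site": ["hand", "foot"]})
        ep = pp.epoch_trials(rec, window=(0.0, 2.0), meta=meta)
        assert ep.meta["site"].tolist() == ["hand"]


class TestInterpolation:
    def test_channel_equal_to_neighbor_mean_unchanged(self, toy_montage, rng):
        labels, coords = toy_montage
        data = rng.standard_normal((8, 500))
        # E1's nearest three good neighbors on the line are E0, E2, E3
        data[1] = data[[0, 2, 3]].mean(axis=0)
        rec = pp.EEGRecording(data, 100.0, labels, montage=coords)
        out = pp.interpolate_bad_channels(rec, ["E1"])
        np.testing.assert_allclose(out.data[1], data[1])

    def test_empty_bad_list_is_identity(self, toy_recording):
        out = pp.interpolate_bad_channels(toy_recording, [])
        np.testing.assert_array_equal(out.data, toy_recording.data)

    def test_neighbor_choice_matches_brute_force(self, rng):
        # scattered 3-D montage; oracle = exhaustive nearest-3 search
        coords = rng.standard_normal((10, 3))
        labels = [f"E{i}" for i in range(10)]
        data = rng.standard_normal((10, 50))
        rec = pp.EEGRecording(data, 100.0, labels, montage=coords)
        bad = "E4"
        out = pp.interpolate_bad_channels(rec, [bad])
        dists = [
            (np.linalg.norm(coords[i] - coords[4]), i) for i in range(10) if i != 4
        ]
        nearest = [i for _, i in sorted(dists)[:3]]
        np.testing.assert_allclose(out.data[4], data[nearest].mean(axis=0))

    def test_unknown_label_rejected(self, toy_recording):
        with pytest.raises(ValueError):
            pp.interpolate_bad_channels(toy_recording, ["nope"])

    def test_needs_three_good_channels(self, rng):
        rec = pp.EEGRecording(
            rng.standard_normal((3, 10)),
            100.0,
            ["a", "b", "c"],
            montage=rng.standard_normal((3, 3)),
        )
        with pytest.raises(ValueError):
            pp.interpolate_bad_channels(rec, ["a"])


class TestArtifactRejection:
    def test_planted_artifacts_removed_exactly(self, rng):
        data = rng.standard_normal((10, 2, 100)) * 10
        planted = [1, 4, 7]
        for i in planted:
            data[i, 0, 50] = 600.0
        ep = pp.EpochSet(data=data, rate=100.0, ch_names=["a", "b"], window=(0.0, 1.0))
        out = pp.reject_artifact_trials(ep, criterion=500.0)
        assert out.n_trials == 7
        assert np.max(np.abs(out.data)) < 500.0

    def test_zero_trial_kept(self):
        ep = pp.EpochSet(np.zeros((1, 2, 10)), 100.0, ["a", "b"], window=(0.0, 0.1))
        assert pp.reject_artifact_trials(ep).n_trials == 1


class TestRereference:
    def test_antisymmetric_pair_unchanged(self):
        ep = pp.EpochSet(
            np.stack([np.vstack([np.ones(5), -np.ones(5)])]),
            100.0,
            ["a", "b"],
            window=(0.0, 0.05),
        )
        np.testing.assert_array_equal(pp.rereference_average(ep).data, ep.data)

    def test_two_channel_example(self):
        ep = pp.EpochSet(
            np.stack([np.vstack([2 * np.ones(4), np.zeros(4)])]),
            100.0,
            ["a", "b"],
            window=(0.0, 0.04),
        )
        out = pp.rereference_average(ep)
        np.testing.assert_allclose(out.data[0, 0], 1.0)
        np.testing.assert_allclose(out.data[0, 1], -1.0)

    def test_channel_mean_is_zero(self, rng):
        ep = pp.EpochSet(
            rng.standard_normal((4, 6, 100)), 100.0, [f"c{i}" for i in range(6)],
            window=(0.0, 1.0),
        )
        out = pp.rereference_average(ep)
        assert np.max(np.abs(out.data.mean(axis=1))) < 1e-10


def test_interpolation_and_rereference_do_not_commute(toy_montage, rng):
    """With a bad channel present, repairing before vs after average
    referencing gives different data, so the chain order matters."""
    labels, coords = toy_montage
    data = rng.standard_normal((8, 200))
    data[2] += 40.0  # corrupted channel
    rec = pp.EEGRecording(data, 100.0, labels, montage=coords)

    interp_first = pp.rereference_average(pp.interpolate_bad_channels(rec, ["E2"]))
    reref_first = pp.interpolate_bad_channels(pp.rereference_average(rec), ["E2"])
    assert not np.allclose(interp_first.data, reref_first.data)


def test_pipeline_runs_ordered_chain(toy_montage, rng):
    labels, coords = toy_montage
    rate, n = 200.0, 200 * 30
    t = np.arange(n) / rate
    data = rng.standard_normal((8, n)) + 5.0 + 0.2 * t
    # sustained in-band artifact inside the second epoch (survives filtering)
    data[3, 1300:2300] += 900.0 * np.sin(2 * np.pi * 8 * t[1300:2300])
    events = [(0, "t"), (1200, "t"), (2400, "t"), (5900, "t")]  # last truncated
    rec = pp.EEGRecording(data, rate, labels, montage=coords, events=events)
    ep = pp.preprocess_pipeline(
        rec, bad_channels=["E7"], resample_to=100.0, window=(0.0, 4.0), criterion=500.0
    )
    assert ep.rate == 100.0
    assert ep.n_trials == 2  # one truncated, one rejected
    assert np.max(np.abs(ep.data.mean(axis=1))) < 1e-9


def test_epochset_roundtrip(tmp_path, rng):
    meta = pd.DataFrame({"site": ["hand", "foot"], "detected": [True, False]})
    ep = pp.EpochSet(
        rng.standard_normal((2, 3, 50)), 100.0, ["a", "b", "c"],
        montage=rng.standard_normal((3, 3)), window=(0.0, 0.5), meta=meta,
    )
    path = tmp_path / "ep.npz"
    ep.save(path)
    back = pp.EpochSet.load(path)
    np.testing.assert_array_equal(back.data, ep.data)
    assert back.rate == ep.rate
    assert list(back.ch_names) == ep.ch_names
    assert back.meta["site"].tolist() == ["hand", "foot"]
    assert back.meta["detected"].tolist() == [True, False]


def test_matrix_and_marker_reader(tmp_path, rng):
    data = rng.standard_normal((100, 3))
    df = pd.DataFrame(data, columns=["Cz", "C3", "C4"])
    mat = tmp_path / "eeg.tsv"
    df.to_csv(mat, sep="\t", index=False)
    mrk = tmp_path / "markers.tsv"
    pd.DataFrame({"onset_s": [0.1, 0.5], "code": ["a", "b"]}).to_csv(
        mrk, sep="\t", index=False
    )
    rec = pp.read_matrix(mat, rate=100.0, markers=mrk)
    assert rec.ch_names == ["Cz", "C3", "C4"]
    np.testing.assert_allclose(rec.data, data.T)
    assert rec.events == [(10, "a"), (50, "b")]
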