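"""Trial containers, windowing, channel dropping, and the synthetic generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal, stats

from edgemi.channels import ChannelMask
from edgemi.data import (MontageInfo, SyntheticProfile, TrialSet,
                         default_profile, drop_channels, extract_window,
                         generate_subject, load_cohort, make_cohort,
                         save_cohort)


def _bandpower(x, fs, lo, hi):
    f, p = signal.periodogram(x, fs=fs, axis=-1)
    sel = (f >= lo) & (f <= hi)
    return p[..., sel].mean(axis=-1)


class TestMontageAndTrials:
    def test_standard_montage_has_22_named_channels(self):
        m = MontageInfo.standard_2a()
        assert m.n_channels == 22
        assert m.channel_names[m.channel_ids.index(8)] == "C3"
        assert m.channel_names[m.channel_ids.index(12)] == "C4"

    def test_trialset_rejects_bad_labels_and_shapes(self):
        m = MontageInfo.standard_2a(fs=10)
        data = np.zeros((4, 22, 10))
        with pytest.raises(ValueError, match="labels"):
            TrialSet(data, np.array([0, 1, 2, 3]), m, window=(0, 1))
        with pytest.raises(ValueError, match="implies"):
            TrialSet(data, np.array([1, 2, 3, 4]), m, window=(0, 2))


class TestWindowing:
    @settings(max_examples=60, deadline=None)
    @given(fs=st.sampled_from([50, 64, 100, 128, 250]),
           start=st.floats(0.0, 2.0),
           dur=st.floats(0.2, 4.0))
    def test_sample_count_formula(self, fs, start, dur):
        trial_s = 7.0
        if round(start * fs) + round(dur * fs) > round(trial_s * fs):
            return
        m = MontageInfo(tuple(range(1, 4)), ("a", "b", "c"), fs)
        n = int(round(trial_s * fs))
        ts = TrialSet(np.zeros((2, 3, n)), np.array([1, 2]), m,
                      window=(0.0, n / fs))
        out = extract_window(ts, start, dur)
        assert out.n_samples == int(round(dur * fs))
        assert np.array_equal(out.labels, ts.labels)

    def test_4p5s_at_250hz_gives_1125_samples(self):
        prof = default_profile()
        ts = generate_subject(prof, 4, fs=250.0, trial_s=7.0, seed=0)
        out = extract_window(ts, 2.0, 4.5)
        assert out.n_samples == 1125

    def test_full_window_is_identity(self, windowed_trials):
        out = extract_window(windowed_trials, 0.0,
                             windowed_trials.n_samples / windowed_trials.fs)
        assert np.array_equal(out.data, windowed_trials.data)

    def test_window_outside_trial_raises(self, windowed_trials):
        with pytest.raises(ValueError, match="outside"):
            extract_window(windowed_trials, 10.0, 1.0)


class TestDropChannels:
    def test_printed_mask_keeps_12_channels(self, windowed_trials):
        mask = ChannelMask.from_string("3,8,10,11,13,15,16,18-22")
        out = drop_channels(windowed_trials, mask)
        assert out.n_channels == 12
        assert out.montage.channel_ids == mask.ids

    def test_all_ones_is_identity(self, windowed_trials):
        out = drop_channels(windowed_trials, ChannelMask.all_ones(22))
        assert np.array_equal(out.data, windowed_trials.data)

    def test_single_channel(self, windowed_trials):
        out = drop_channels(windowed_trials, ChannelMask.from_ids([1]))
        assert out.n_channels == 1
        assert np.array_equal(out.data[:, 0], windowed_trials.data[:, 0])

    def test_empty_mask_rejected(self, windowed_trials):
        with pytest.raises(ValueError):
            drop_channels(windowed_trials, np.zeros(22, dtype=int))

    @settings(max_examples=25, deadline=None)
    @given(bits_a=st.lists(st.booleans(), min_size=22, max_size=22),
           bits_b=st.lists(st.booleans(), min_size=22, max_size=22))
    def test_composition_equals_intersection(self, windowed_trials,
                                             bits_a, bits_b):
        a = np.array(bits_a)
        both = a & np.array(bits_b)
        if not (a.any() and both.any()):
            return
        once = drop_channels(windowed_trials, both.astype(int))
        first = drop_channels(windowed_trials, a.astype(int))
        # re-index the second mask onto the surviving channels
        second_ids = [cid for cid, keep in zip(range(1, 23), both) if keep]
        twice = drop_channels(first, second_ids)
        assert np.array_equal(once.data, twice.data)
        assert once.montage.channel_ids == twice.montage.channel_ids


class TestGenerator:
    def test_deterministic_for_fixed_seed(self, strong_profile):
        a = generate_subject(strong_profile, 12, fs=64, trial_s=7.0, seed=5)
        b = generate_subject(strong_profile, 12, fs=64, trial_s=7.0, seed=5)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.labels, b.labels)

    def test_labels_balanced(self, strong_profile):
        ts = generate_subject(strong_profile, 40, fs=64, trial_s=7.0, seed=1)
        counts = np.bincount(ts.labels, minlength=5)[1:]
        assert counts.min() == counts.max() == 10

    def test_zero_depth_is_class_indistinguishable(self):
        """ERD depth 0: imagery-interval band power does not separate classes
        (Welch two-sample test on an informative channel, alpha = 0.01)."""
        prof = default_profile(erd_depth=0.0, snr_db=10.0, mixing_strength=0.0,
                               depth_jitter=0.0)
        ts = generate_subject(prof, 200, fs=128, trial_s=7.0, seed=42)
        imagery = ts.data[:, :, int(2.5 * 128):int(5.5 * 128)]
        row = ts.montage.channel_ids.index(12)  # C4, informative for class 1
        bp = _bandpower(imagery[:, row], 128, 9, 13)
        _, p = stats.ttest_ind(bp[ts.labels == 1], bp[ts.labels != 1],
                               equal_var=False)
        assert p > 0.01

    def test_erd_suppresses_imagery_bandpower(self):
        """Depth 0.6 at 10 dB: imagery/baseline band-power ratio < 1 on the
        informative channels in at least 95% of that class's trials."""
        prof = default_profile(erd_depth=0.6, snr_db=10.0, mixing_strength=0.0,
                               depth_jitter=0.0)
        fs = 128
        ts = generate_subject(prof, 200, fs=fs, trial_s=7.0, seed=7)
        rows = [ts.montage.channel_ids.index(i)
                for i in prof.class_channel_map[1]]
        baseline = ts.data[:, rows, 0:int(1.9 * fs)]
        imagery = ts.data[:, rows, int(2.5 * fs):int(4.4 * fs)]
        lo, hi = 9, 13
        ratio = (_bandpower(imagery, fs, lo, hi).mean(axis=1)
                 / _bandpower(baseline, fs, lo, hi).mean(axis=1))
        frac = (ratio[ts.labels == 1] < 1.0).mean()
        assert frac >= 0.95

    def test_information_only_on_declared_channels(self):
        """With no mixing, class separation (one-way ANOVA on mu-band power)
        shows on informative channels but not on unused ones."""
        prof = default_profile(erd_depth=0.6, snr_db=10.0, mixing_strength=0.0,
                               depth_jitter=0.0)
        fs = 128
        ts = generate_subject(prof, 240, fs=fs, trial_s=7.0, seed=9)
        imagery = ts.data[:, :, int(2.5 * fs):int(5.5 * fs)]

        def anova_p(channel_id, lo, hi):
            row = ts.montage.channel_ids.index(channel_id)
            bp = _bandpower(imagery[:, row], fs, lo, hi)
            groups = [bp[ts.labels == c] for c in (1, 2, 3, 4)]
            return stats.f_oneway(*groups).pvalue

        assert anova_p(12, 9, 13) < 1e-4    # C4: left-hand ERD
        assert anova_p(8, 9, 13) < 1e-4     # C3: right-hand ERD
        for unused in (19, 21, 22):         # P1, P2, POz: in no class map
            assert anova_p(unused, 9, 13) > 0.01

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            SyntheticProfile(class_channel_map={1: (1,), 2: (2,), 3: (3,)},
                             band_specs={})
        with pytest.raises(ValueError, match="depth"):
            default_profile(erd_depth=1.5)


class TestCohort:
    def test_roles_and_ids_mirror_benchmark_grouping(self, strong_profile):
        src, tgt = make_cohort(6, 3, strong_profile, seed=0, n_trials=4,
                               n_sessions=1, fs=32)
        assert src.role == "source" and tgt.role == "target"
        assert src.subject_ids == [1, 2, 3, 4, 5, 6]
        assert tgt.subject_ids == [7, 8, 9]

    def test_reproducible(self, strong_profile):
        a = make_cohort(2, 1, strong_profile, seed=3, n_trials=4, fs=32)
        b = make_cohort(2, 1, strong_profile, seed=3, n_trials=4, fs=32)
        assert np.array_equal(a[0].combined(1).data, b[0].combined(1).data)

    def test_subjects_differ_by_mixing(self):
        prof = default_profile(mixing_strength=0.5)
        src, _ = make_cohort(2, 1, prof, seed=3, n_trials=4, fs=32)
        s1, s2 = src.combined(1), src.combined(2)
        assert not np.allclose(s1.data, s2.data)

    def test_hdf5_round_trip(self, tmp_path, small_cohort):
        src, tgt = small_cohort
        path = tmp_path / "cohort.h5"
        save_cohort(path, {"source": src, "target": tgt})
        back = load_cohort(path)
        assert back["source"].subject_ids == src.subject_ids
        orig = src.sessions(1)[0]
        loaded = back["source"].sessions(1)[0]
        assert np.array_equal(orig.data, loaded.data)
        assert np.array_equal(orig.labels, loaded.labels)
        assert loaded.window == orig.window


class TestGDF:
    fs = 250

    def _write(self, path, n_trials=8, n_ch=22):
        from gdf_fixture import write_gdf

        rng = np.random.default_rng(0)
        trial_gap = 8 * self.fs
        n_samp = (n_trials + 1) * trial_gap
        data = (rng.standard_normal((n_ch, n_samp)) * 10).astype(np.float32)
        events, labels = [], []
        for k in range(n_trials):
            onset = trial_gap * (k + 1)   # cue onset, 2 s after trial start
            events.append((onset, 769 + k % 4))
            labels.append(1 + k % 4)
        write_gdf(path, data, self.fs, events)
        return labels

    def test_round_trip_counts_and_labels(self, tmp_path):
        pytest.importorskip("mne")
        from edgemi.data import load_gdf_session

        path = tmp_path / "s.gdf"
        labels = self._write(path)
        ts = load_gdf_session(path)
        assert ts.n_trials == len(labels)
        assert ts.n_channels == 22
        assert ts.n_samples == int(7.0 * self.fs)
        assert np.array_equal(ts.labels, labels)

    def test_no_annotations_is_an_error(self, tmp_path):
        pytest.importorskip("mne")
        from gdf_fixture import write_gdf
        from edgemi.data import load_gdf_session

        path = tmp_path / "empty.gdf"
        write_gdf(path, np.zeros((22, 2500), np.float32), self.fs, [])
        with pytest.raises(ValueError, match="no trials"):
            load_gdf_session(path)

    def test_wrong_channel_count_is_an_error(self, tmp_path):
        pytest.importorskip("mne")
        from edgemi.data import load_gdf_session

        path = tmp_path / "c.gdf"
        self._write(path, n_ch=5)
        with pytest.raises(ValueError, match="channels"):
            load_gdf_session(path)

    def test_unreadable_file_is_an_error(self, tmp_path):
        pytest.importorskip("mne")
        from edgemi.data import load_gdf_session

        path = tmp_path / "bad.gdf"
        path.write_bytes(b"not a gdf file at all")
        with pytest.raises(ValueError, match="unreadable"):
            load_gdf_session(path)
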