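"""Model construction, registry/freeze semantics, MAC accounting, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgemi import nn
from edgemi.data import TrialSet, default_profile, extract_window, generate_subject
from edgemi.models import (FCNNA, LFCNN, XFCNN, FREEZE_LEVELS, StageSpec,
                           TrainConfig, build_model, count_total_params,
                           count_trainable_params, get_variant, load_checkpoint,
                           mac_conv2d, mac_depthwise_conv2d,
                           mac_separable_conv2d, predict, save_checkpoint,
                           set_freeze_level, total_mac, train)
from conftest import TEST_FS, tiny_variant


class TestVariants:
    @pytest.mark.parametrize("variant,s1,s2", [
        (FCNNA, (96, 60, 2, 16), (16, 64, 1, 16)),
        (XFCNN, (16, 60, 2, 16), (16, 64, 1, 16)),
        (LFCNN, (8, 48, 2, 16), (16, 64, 1, 16)),
    ])
    def test_stage_dimensions(self, variant, s1, s2):
        assert variant.stage1 == StageSpec(*s1)
        assert variant.stage2 == StageSpec(*s2)
        assert variant.n_classes == 4

    def test_lookup_and_cs_flag(self):
        assert get_variant("fcnna") is FCNNA
        cs = FCNNA.with_channel_selection(True)
        assert cs.uses_channel_selection and not FCNNA.uses_channel_selection

    def test_invalid_stage_rejected(self):
        with pytest.raises(ValueError):
            StageSpec(0, 60, 2, 16)


class TestRegistry:
    def test_indices_contiguous_and_cover_freeze_levels(self, tiny):
        m = build_model(tiny, 22, 288, seed=0)
        assert [e.index for e in m.registry] == list(range(1, len(m.registry) + 1))
        assert len(m.registry) >= max(FREEZE_LEVELS)

    def test_param_counts_sum_to_total(self, tiny):
        m = build_model(tiny, 22, 288, seed=0)
        assert sum(e.param_count for e in m.registry) == count_total_params(m)
        assert count_total_params(m) == sum(p.size for p in m.all_params)

    def test_channel_dependent_params_confined_to_prefix_16(self, tiny):
        """Only electrode-facing spatial filters (registry index <= 16) may
        change when the montage is reduced from 22 to 12 channels."""
        m22 = build_model(tiny, 22, 288, seed=0)
        m12 = build_model(tiny, 12, 288, seed=0)
        for e22, e12 in zip(m22.registry, m12.registry):
            if e22.index > 16:
                assert e22.param_count == e12.param_count

    def test_freeze_boundaries_have_expected_sections(self, tiny):
        m = build_model(tiny, 22, 288, seed=0)
        kinds = {e.index: e.kind for e in m.registry}
        assert kinds[2] == "temporal_conv"
        assert kinds[7] == "spatial_depthwise_conv"
        assert kinds[12] == "spatial_depthwise_conv"
        assert kinds[17] == "separable_conv"
        assert all(kinds[i] in ("attention_sub", "activation", "batch_norm",
                                "marker") for i in range(27, 45))


class TestBuild:
    def test_same_seed_identical_weights(self, tiny):
        a = build_model(tiny, 22, 288, seed=5)
        b = build_model(tiny, 22, 288, seed=5)
        for pa, pb in zip(a.all_params, b.all_params):
            assert np.array_equal(pa.value, pb.value)

    def test_kernel_wider_than_input_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            build_model(FCNNA, 22, 32, seed=0)

    def test_published_footprints(self):
        """Built architectures reproduce their published size budgets."""
        m = build_model(FCNNA, 22, 1125, seed=0)
        assert count_total_params(m) == 358_622
        assert total_mac(m) == 192_819_260
        set_freeze_level(m, 44)
        assert count_trainable_params(m) == 110_774
        ml = build_model(LFCNN, 22, 1125, seed=0)
        assert count_total_params(ml) == 30_550
        assert total_mac(ml) == 39_539_100


class TestFreezing:
    def test_level_0_all_trainable_full_length_none(self, tiny):
        m = build_model(tiny, 22, 288, seed=0)
        set_freeze_level(m, 0)
        assert count_trainable_params(m) == count_total_params(m)
        set_freeze_level(m, len(m.registry))
        assert count_trainable_params(m) == 0

    def test_trainable_count_non_increasing(self, tiny):
        m = build_model(tiny, 22, 288, seed=0)
        counts = []
        for level in FREEZE_LEVELS:
            set_freeze_level(m, level)
            counts.append(count_trainable_params(m))
        assert counts == sorted(counts, reverse=True)

    def test_invalid_level_rejected(self, tiny):
        m = build_model(tiny, 22, 288, seed=0)
        with pytest.raises(ValueError):
            set_freeze_level(m, len(m.registry) + 1)

    def test_frozen_prefix_bit_identical_after_training(self, tiny,
                                                        windowed_trials):
        m = build_model(tiny, 22, windowed_trials.n_samples, seed=0)
        set_freeze_level(m, 26)
        before = {p.name: p.value.copy()
                  for e in m.registry if e.frozen for p in e.params}
        train(m, windowed_trials,
              TrainConfig(learning_rate=0.002, epochs=2, batch_size=32, seed=0))
        for e in m.registry:
            if e.frozen:
                for p in e.params:
                    assert np.array_equal(p.value, before[p.name]), p.name

    def test_full_freeze_training_is_identity(self, tiny, windowed_trials):
        m = build_model(tiny, 22, windowed_trials.n_samples, seed=0)
        set_freeze_level(m, len(m.registry))
        before = m.get_weights()
        train(m, windowed_trials,
              TrainConfig(learning_rate=0.01, epochs=1, batch_size=32, seed=0))
        after = m.get_weights()
        for k in before:
            if not k.endswith(("_running_mean", "_running_var")):
                assert np.array_equal(before[k], after[k]), k


class TestMacFormulas:
    def test_printed_examples(self):
        assert mac_conv2d(1, 1, 1, 1, 1, 1) == 1
        assert mac_conv2d(1, 60, 1, 96, 22, 1125) == 142_560_000
        assert mac_separable_conv2d(1, 1, 1, 1, 1, 1) == 2
        assert mac_separable_conv2d(1, 16, 96, 192, 22, 281) == 123_442_176
        assert mac_depthwise_conv2d(1, 1, 1, 1, 1, 1) == 1
        assert mac_depthwise_conv2d(22, 1, 96, 2, 1, 1125) == 4_752_000

    def test_non_positive_arguments_rejected(self):
        for fn in (mac_conv2d, mac_separable_conv2d):
            with pytest.raises(ValueError):
                fn(1, 0, 1, 1, 1, 1)
        with pytest.raises(ValueError):
            mac_depthwise_conv2d(1, 1, -2, 1, 1, 1)

    @settings(max_examples=40, deadline=None)
    @given(dims=st.tuples(*[st.integers(1, 3)] * 6))
    def test_formulas_match_loop_counters(self, dims):
        k1, k2, cin, cm, ho, wo = dims
        conv = sep = dw = 0
        for _ in range(k1):
            for _ in range(k2):
                for _ in range(cin):
                    for _ in range(cm):
                        for _ in range(ho):
                            for _ in range(wo):
                                conv += 1
                                dw += 1
        for c_in in range(cin):
            for _ in range(ho):
                for _ in range(wo):
                    for _ in range(k1 * k2):   # depthwise pass
                        sep += 1
                    for _ in range(cm):        # pointwise pass
                        sep += 1
        assert mac_conv2d(k1, k2, cin, cm, ho, wo) == conv
        assert mac_depthwise_conv2d(k1, k2, cin, cm, ho, wo) == dw
        assert mac_separable_conv2d(k1, k2, cin, cm, ho, wo) == sep

    def test_total_mac_sums_conv_entries(self, tiny):
        m = build_model(tiny, 22, 288, seed=0)
        manual = 0
        for e in m.registry:
            if e.meta is None:
                continue
            f = {"conv": mac_conv2d, "separable": mac_separable_conv2d}.get(
                e.meta["op"])
            if f is not None:
                manual += f(e.meta["K1"], e.meta["K2"], e.meta["Cin"],
                            e.meta["Cout"], e.meta["Hout"], e.meta["Wout"])
            else:
                manual += mac_depthwise_conv2d(
                    e.meta["K1"], e.meta["K2"], e.meta["Cin"], e.meta["D"],
                    e.meta["Hout"], e.meta["Wout"])
        assert total_mac(m) == manual


class TestEngine:
    def test_backprop_matches_directional_derivative(self):
        """Analytic gradients agree with a central finite difference along a
        random direction (the full network graph, eval mode)."""
        rng = np.random.default_rng(0)
        var = tiny_variant(f1=4, bank=8)
        m = build_model(var, 5, 64, seed=1)
        x = rng.standard_normal((3, 1, 5, 64)).astype(np.float32)
        y = np.array([0, 2, 3])
        for p in m.all_params:
            p.grad[...] = 0.0
        probs = nn.softmax(m.forward(x))
        g = probs.copy()
        g[np.arange(3), y] -= 1.0
        m.backward(g / 3)
        dirs = {id(p): rng.standard_normal(p.value.shape).astype(np.float32)
                for p in m.all_params}
        norm = np.sqrt(sum(float((d ** 2).sum()) for d in dirs.values()))
        analytic = sum(float((p.grad * dirs[id(p)]).sum())
                       for p in m.all_params) / norm
        base = {id(p): p.value.copy() for p in m.all_params}
        eps = 1e-2

        def loss_at(sign):
            for p in m.all_params:
                p.value = base[id(p)] + sign * eps * dirs[id(p)] / norm
            return nn.cross_entropy(nn.softmax(m.forward(x)), y)

        numeric = (loss_at(+1) - loss_at(-1)) / (2 * eps)
        assert abs(numeric - analytic) / abs(analytic) < 0.01

    def test_adam_skips_frozen_params(self):
        p1 = nn.Param("a", np.ones(3))
        p2 = nn.Param("b", np.ones(3))
        p2.frozen = True
        opt = nn.Adam([p1, p2], lr=0.1)
        p1.grad[...] = 1.0
        p2.grad[...] = 1.0
        opt.step()
        assert not np.array_equal(p1.value, np.ones(3))
        assert np.array_equal(p2.value, np.ones(3))


class TestTrainPredict:
    def test_zero_epochs_is_a_no_op(self, tiny, windowed_trials):
        m = build_model(tiny, 22, windowed_trials.n_samples, seed=0)
        before = m.get_weights()
        report = train(m, windowed_trials, TrainConfig(epochs=0))
        after = m.get_weights()
        assert report.losses == [] and report.monitored_accuracy == []
        for k in before:
            assert np.array_equal(before[k], after[k])

    def test_learns_separable_classes(self, tiny, windowed_trials):
        m = build_model(tiny, 22, windowed_trials.n_samples, seed=0)
        report = train(m, windowed_trials,
                       TrainConfig(learning_rate=0.002, epochs=20,
                                   batch_size=32, seed=0))
        assert report.best_accuracy > 0.9

    def test_training_is_deterministic(self, tiny, windowed_trials):
        results = []
        for _ in range(2):
            m = build_model(tiny, 22, windowed_trials.n_samples, seed=0)
            rep = train(m, windowed_trials,
                        TrainConfig(learning_rate=0.002, epochs=2,
                                    batch_size=32, seed=3))
            results.append((rep.losses, rep.monitored_accuracy, m.get_weights()))
        assert results[0][0] == results[1][0]
        assert results[0][1] == results[1][1]
        for k in results[0][2]:
            assert np.array_equal(results[0][2][k], results[1][2][k])

    def test_single_class_warns(self, tiny, strong_profile):
        ts = generate_subject(strong_profile, 16, fs=TEST_FS, trial_s=7.0, seed=2)
        ts = extract_window(ts, 2.0, 4.5)
        one = ts.subset_trials(np.where(ts.labels == 1)[0])
        m = build_model(tiny, 22, ts.n_samples, seed=0)
        with pytest.warns(UserWarning, match="single class"):
            train(m, one, TrainConfig(epochs=1, batch_size=4))

    def test_probabilities_sum_to_one(self, tiny, windowed_trials):
        m = build_model(tiny, 22, windowed_trials.n_samples, seed=0)
        labels, probs = predict(m, windowed_trials)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.array_equal(labels, np.argmax(probs, axis=1) + 1)
        assert set(labels) <= {1, 2, 3, 4}

    def test_untrained_model_is_at_chance(self, tiny):
        """Balanced random data, untrained net: accuracy within the binomial
        band around chance (0.25) for 1000 trials."""
        prof = default_profile(erd_depth=0.0, snr_db=0.0, mixing_strength=0.0)
        ts = generate_subject(prof, 1000, fs=32, trial_s=7.0, seed=77)
        ts = extract_window(ts, 2.0, 4.5)
        m = build_model(tiny, 22, ts.n_samples, seed=1)
        labels, _ = predict(m, ts)
        acc = (labels == ts.labels).mean()
        assert 0.15 <= acc <= 0.35

    def test_label_permutation_destroys_skill(self, tiny, windowed_trials):
        """Training on permuted labels yields chance-level accuracy on a
        fresh draw from the same distribution."""
        rng = np.random.default_rng(0)
        permuted = TrialSet(windowed_trials.data,
                            rng.permutation(windowed_trials.labels),
                            windowed_trials.montage,
                            window=windowed_trials.window)
        m = build_model(tiny, 22, permuted.n_samples, seed=0)
        train(m, permuted, TrainConfig(learning_rate=0.002, epochs=8,
                                       batch_size=32, seed=0))
        prof = default_profile(erd_depth=0.8, snr_db=10.0, mixing_strength=0.0)
        fresh = extract_window(
            generate_subject(prof, 200, fs=TEST_FS, trial_s=7.0, seed=123),
            2.0, 4.5)
        labels, _ = predict(m, fresh)
        acc = (labels == fresh.labels).mean()
        assert acc < 0.40  # binomial upper bound around chance for n=200

    def test_shape_mismatch_rejected(self, tiny, windowed_trials):
        m = build_model(tiny, 21, windowed_trials.n_samples, seed=0)
        with pytest.raises(ValueError, match="match"):
            predict(m, windowed_trials)


class TestCheckpoint:
    def test_round_trip(self, tiny, tmp_path):
        m = build_model(tiny, 22, 288, seed=4)
        set_freeze_level(m, 16)
        save_checkpoint(m, tmp_path / "ck")
        back = load_checkpoint(tmp_path / "ck")
        assert back.variant == m.variant
        assert back.freeze_level == 16
        wa, wb = m.get_weights(), back.get_weights()
        assert set(wa) == set(wb)
        for k in wa:
            assert np.array_equal(wa[k], wb[k])
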