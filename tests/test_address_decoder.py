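import numpy as np
import pytest

from bitbrain import address_decoder as adm
from bitbrain import sampling as sp
from bitbrain.io_encoding import SignedImage, center_pixels


def _flat_target(shape=(28, 28), seed=0):
    rng = np.random.default_rng(seed)
    mass = rng.integers(1, 100, size=shape[0] * shape[1])
    return sp.sqrt_transform(sp.PixelMassVector(mass.astype(np.int64), shape))


def _signed(raw):
    return center_pixels(np.asarray(raw, dtype=np.uint8))


class TestBuild:
    def test_shapes_locality_and_no_multapses(self):
        target = _flat_target()
        ad = adm.build_address_decoder(target, w=64, n=6, locality_radius=2, seed=1)
        assert ad.pixels.shape == (64, 6)
        for j in range(64):
            assert len(set(ad.pixels[j].tolist())) == 6
            cr, cc = divmod(int(ad.centroids[j]), 28)
            for p in ad.pixels[j]:
                r, c = divmod(int(p), 28)
                assert abs(r - cr) <= 2 and abs(c - cc) <= 2

    def test_minimal_decoder(self):
        ad = adm.build_address_decoder(_flat_target(), w=1, n=1, seed=0)
        assert ad.w == 1 and ad.width_n == 1

    def test_deterministic_given_seed(self):
        target = _flat_target()
        a = adm.build_address_decoder(target, w=16, n=4, locality_radius=3, seed=9)
        b = adm.build_address_decoder(target, w=16, n=4, locality_radius=3, seed=9)
        assert np.array_equal(a.pixels, b.pixels)
        assert np.array_equal(a.weights, b.weights)

    def test_int8_weights_span_full_range_and_exclude_zero(self):
        ad = adm.build_address_decoder(
            _flat_target(), w=64, n=8, synapse_type="int8", seed=2
        )
        assert (ad.weights != 0).all()
        assert ad.weights.min() >= -127 and ad.weights.max() <= 127


class TestActivation:
    def test_binary_hand_example(self):
        """All-zero raw image binarises to -1 everywhere; weights (+1, +1, -1)
        give activation -1 - 1 + 1 = -1."""
        ade = adm.ADE(
            pixels=np.array([0, 1, 2]),
            weights=np.array([1, 1, -1], dtype=np.int16),
            longevities=np.full(3, 16, dtype=np.int16),
            threshold=0,
            centroid=None,
            synapse_type="binary",
        )
        assert adm.ade_activation(ade, _signed(np.zeros((2, 2)))) == -1

    def test_int8_dot_product(self):
        ade = adm.ADE(
            pixels=np.array([0, 1]),
            weights=np.array([3, -2], dtype=np.int16),
            longevities=np.full(2, 16, dtype=np.int16),
            threshold=0,
            centroid=None,
            synapse_type="int8",
        )
        img = SignedImage(np.array([[10, 5]], dtype=np.int16))
        assert adm.ade_activation(ade, img) == 30 - 10

    def test_int8_activation_is_linear(self):
        ade = adm.ADE(
            pixels=np.array([0, 1, 2]),
            weights=np.array([5, -3, 2], dtype=np.int16),
            longevities=np.full(3, 16, dtype=np.int16),
            threshold=0,
            centroid=None,
            synapse_type="int8",
        )
        a1 = adm.ade_activation(ade, SignedImage(np.array([[7, 11, -4]], dtype=np.int16)))
        a2 = adm.ade_activation(ade, SignedImage(np.array([[14, 22, -8]], dtype=np.int16)))
        assert a2 == 2 * a1


class TestFiring:
    @pytest.fixture()
    def decoder(self):
        return adm.build_address_decoder(_flat_target(), w=32, n=6, seed=4)

    def test_max_threshold_silences_all(self, decoder):
        decoder.thresholds[:] = np.iinfo(np.int32).max
        img = _signed(np.random.default_rng(0).integers(0, 256, (28, 28)))
        assert len(adm.decoder_firing_pattern(decoder, img)) == 0

    def test_min_threshold_fires_all(self, decoder):
        decoder.thresholds[:] = np.iinfo(np.int32).min
        img = _signed(np.random.default_rng(0).integers(0, 256, (28, 28)))
        assert len(adm.decoder_firing_pattern(decoder, img)) == 32

    def test_threshold_equality_fires(self, decoder):
        img = _signed(np.random.default_rng(1).integers(0, 256, (28, 28)))
        acts = [adm.ade_activation(decoder.ade(j), img) for j in range(decoder.w)]
        decoder.thresholds[:] = acts  # every activation exactly at threshold
        assert len(adm.decoder_firing_pattern(decoder, img)) == 32

    def test_matches_per_synapse_loop_oracle(self):
        """Vectorised firing equals a naive per-ADE evaluation."""
        rng = np.random.default_rng(7)
        for st in ("binary", "int8"):
            ad = adm.build_address_decoder(
                _flat_target(seed=3), w=32, n=5, synapse_type=st, seed=11
            )
            ad.thresholds[:] = rng.integers(-50, 50, size=32)
            img = _signed(rng.integers(0, 256, (28, 28)))
            expected = [
                j
                for j in range(ad.w)
                if adm.ade_activation(ad.ade(j), img) >= ad.thresholds[j]
            ]
            got = adm.decoder_firing_pattern(ad, img).active.tolist()
            assert got == expected

    def test_raising_threshold_never_adds_firing(self):
        ad = adm.build_address_decoder(_flat_target(), w=32, n=6, seed=5)
        img = _signed(np.random.default_rng(2).integers(0, 256, (28, 28)))
        before = set(adm.decoder_firing_pattern(ad, img).active.tolist())
        ad.thresholds[::2] += 3
        after = set(adm.decoder_firing_pattern(ad, img).active.tolist())
        assert after <= before


class TestThresholdAdaptation:
    def test_constant_stream_parks_near_activation_value(self):
        """On one repeated input the only achievable rates are 0 and 1;
        the threshold must end within one step of the activation value."""
        ad = adm.build_address_decoder(_flat_target(), w=4, n=6, seed=6)
        img = np.random.default_rng(3).integers(0, 256, (1, 28, 28)).astype(np.uint8)
        acts = adm._batch_activations(ad, adm.prepare_inputs(img, ad.synapse_type))[0]
        adm.adapt_thresholds(ad, img, target_rate=0.01, interval_t=50,
                             n_presentations=500, seed=1)
        assert (np.abs(ad.thresholds - acts) <= 1).all()

    def test_zero_step_leaves_thresholds_unchanged(self):
        ad = adm.build_address_decoder(_flat_target(), w=8, n=6, seed=7)
        before = ad.thresholds.copy()
        img = np.random.default_rng(4).integers(0, 256, (20, 28, 28)).astype(np.uint8)
        adm.adapt_thresholds(ad, img, step=0, interval_t=10, n_presentations=100)
        assert np.array_equal(ad.thresholds, before)

    def test_empty_stream_rejected(self):
        ad = adm.build_address_decoder(_flat_target(), w=4, n=4, seed=8)
        with pytest.raises(ValueError):
            adm.adapt_thresholds(ad, np.zeros((0, 28, 28), dtype=np.uint8))

    def test_mean_rate_within_factor_two_of_target(self, small_benchmark, ink_target):
        """Homeostasis at a 1% target lands the sweep-average rate in
        [0.5%, 2%] for weighted greyscale synapses."""
        train, _ = small_benchmark
        ad = adm.build_address_decoder(
            ink_target, w=256, n=10, synapse_type="int8", locality_radius=3, seed=12
        )
        adm.adapt_thresholds(ad, train.images, target_rate=0.01, interval_t=500,
                             n_presentations=2000, seed=2)
        rate = adm.batch_firing(ad, adm.prepare_inputs(train.images, "int8")).mean()
        assert 0.005 <= rate <= 0.02

    def test_binary_rate_order_of_magnitude(self, small_benchmark, ink_target):
        """Binary ADEs have only n+1 activation levels on hard-edged disc
        data, so per-element rates park at coarse achievable values; the
        mean still lands within half an order of magnitude of the target."""
        train, _ = small_benchmark
        ad = adm.build_address_decoder(
            ink_target, w=256, n=6, synapse_type="binary", locality_radius=2, seed=13
        )
        adm.adapt_thresholds(ad, train.images, target_rate=0.01, interval_t=500,
                             n_presentations=2000, seed=3)
        rate = adm.batch_firing(ad, adm.prepare_inputs(train.images, "binary")).mean()
        assert 0.001 <= rate <= 0.05


class TestPlasticity:
    def _ade(self, weights, threshold=0):
        n = len(weights)
        return adm.ADE(
            pixels=np.arange(n),
            weights=np.asarray(weights, dtype=np.int16),
            longevities=np.full(n, 16, dtype=np.int16),
            threshold=threshold,
            centroid=None,
            synapse_type="int8",
        )

    def test_argmin_decremented_argmax_incremented(self):
        ade = self._ade([5, 3, 9])  # contributions = inputs 1,1,1 times weights
        img = SignedImage(np.array([[1, 1, 1]], dtype=np.int16))
        adm.plasticity_step(ade, img)
        assert ade.longevities.tolist() == [16, 15, 17]

    def test_degenerate_tie_is_no_op(self):
        ade = self._ade([4, 4])
        img = SignedImage(np.array([[1, 1]], dtype=np.int16))
        adm.plasticity_step(ade, img)
        assert ade.longevities.tolist() == [16, 16]

    def test_longevity_floor_at_zero(self):
        ade = self._ade([1, 9])
        ade.longevities[:] = [0, 16]
        img = SignedImage(np.array([[1, 1]], dtype=np.int16))
        adm.plasticity_step(ade, img)
        assert ade.longevities.tolist() == [0, 17]

    def test_non_firing_ade_is_contract_violation(self):
        ade = self._ade([1, 1], threshold=1000)
        img = SignedImage(np.array([[1, 1]], dtype=np.int16))
        with pytest.raises(ValueError, match="did not fire"):
            adm.plasticity_step(ade, img)


class TestReplacement:
    def test_healthy_synapses_untouched(self):
        target = _flat_target()
        ad = adm.build_address_decoder(target, w=16, n=6, locality_radius=2, seed=1)
        before = ad.pixels.copy()
        adm.replace_weak_synapses(ad, target, critical=1, seed=5)
        assert np.array_equal(ad.pixels, before)

    def test_exactly_the_weak_synapse_replaced(self):
        target = _flat_target()
        ad = adm.build_address_decoder(target, w=16, n=6, locality_radius=2, seed=2)
        before = ad.pixels.copy()
        ad.longevities[3, 2] = 0
        adm.replace_weak_synapses(ad, target, critical=1, seed=6)
        changed = np.argwhere(ad.pixels != before)
        assert changed.tolist() == [[3, 2]]
        assert ad.longevities[3, 2] == adm.LONGEVITY_DEFAULT
        # new pixel is distinct from the ADE's other pixels and in the box
        row = ad.pixels[3]
        assert len(set(row.tolist())) == 6
        cr, cc = divmod(int(ad.centroids[3]), 28)
        r, c = divmod(int(row[2]), 28)
        assert abs(r - cr) <= 2 and abs(c - cc) <= 2


class TestUnsupervisedLearn:
    def test_zero_presentations_is_identity(self, ink_target, small_benchmark):
        train, _ = small_benchmark
        ad = adm.build_address_decoder(ink_target, w=16, n=6, seed=3)
        before = (ad.pixels.copy(), ad.thresholds.copy(), ad.longevities.copy())
        sched = adm.UnsupervisedSchedule(n_presentations=0)
        adm.unsupervised_learn([ad], train.images, ink_target, sched)
        assert np.array_equal(ad.pixels, before[0])
        assert np.array_equal(ad.thresholds, before[1])
        assert np.array_equal(ad.longevities, before[2])

    def test_plasticity_disabled_changes_only_thresholds(
        self, ink_target, small_benchmark
    ):
        train, _ = small_benchmark
        ad = adm.build_address_decoder(ink_target, w=32, n=6, seed=4)
        pixels, longevities = ad.pixels.copy(), ad.longevities.copy()
        sched = adm.UnsupervisedSchedule(
            n_presentations=600, interval_t=200, plasticity=False, replacement=False
        )
        adm.unsupervised_learn([ad], train.images, ink_target, sched)
        assert np.array_equal(ad.pixels, pixels)
        assert np.array_equal(ad.longevities, longevities)

    def test_full_defaults_keep_no_multapses(self, ink_target, small_benchmark):
        train, _ = small_benchmark
        ad = adm.build_address_decoder(
            ink_target, w=64, n=6, locality_radius=2, seed=5
        )
        sched = adm.UnsupervisedSchedule(n_presentations=1000, interval_t=250, seed=9)
        adm.unsupervised_learn([ad], train.images, ink_target, sched)
        for j in range(ad.w):
            assert len(set(ad.pixels[j].tolist())) == ad.width_n
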