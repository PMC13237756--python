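"""Preprocessing: re-referencing, segmentation, artifact rules, interpolation."""

import numpy as np
import pytest

from restalpha.geometry import ElectrodeLayout, nearest_neighbors, recorded_labels
from restalpha.preprocessing import (
    ArtifactMask,
    EpochSet,
    RawRecording,
    apply_channel_rule,
    apply_segment_rule,
    detect_artifacts,
    eog_regress,
    hjorth_interpolate,
    rereference_average,
    segment,
)

FS = 500.0


def make_recording(layout, data=None, n_samples=45000, with_ref=False):
    labels = tuple(layout.labels) if with_ref else tuple(recorded_labels(layout))
    if data is None:
        data = np.zeros((len(labels), n_samples))
    return RawRecording("p1", "closed", labels, data, FS)


class TestRereference:
    def test_recovers_reference_and_zeroes_mean(self, layout, rng):
        rec = make_recording(layout, rng.normal(size=(64, 2000)))
        out = rereference_average(rec, layout)
        assert out.samples.shape[0] == 65
        assert "FCz" in out.channel_labels
        np.testing.assert_allclose(out.samples.mean(axis=0), 0.0, atol=1e-10)

    def test_identical_signals_cancel(self, layout):
        sig = np.sin(np.linspace(0, 10, 1500))
        rec = make_recording(layout, np.tile(sig, (65, 1)), n_samples=1500, with_ref=True)
        out = rereference_average(rec, layout)
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_idempotent(self, layout, rng):
        rec = make_recording(layout, rng.normal(size=(64, 1000)))
        once = rereference_average(rec, layout)
        twice = rereference_average(once, layout)
        np.testing.assert_allclose(once.samples, twice.samples, atol=1e-10)

    def test_unknown_channel_rejected(self, layout, rng):
        rec = RawRecording(
            "p1", "closed", ("Qz",), rng.normal(size=(1, 100)), FS
        )
        with pytest.raises(ValueError, match="Qz"):
            rereference_average(rec, layout)


class TestSegment:
    def test_90s_gives_45_epochs(self, layout):
        ep = segment(make_recording(layout, with_ref=True))
        assert ep.epochs.shape == (45, 65, 1000)

    def test_trailing_remainder_discarded(self, layout):
        rec = make_recording(layout, n_samples=45500, with_ref=True)  # 91 s
        ep = segment(rec)
        assert ep.n_epochs == 45

    def test_too_short_rejected(self, layout):
        rec = make_recording(layout, n_samples=500, with_ref=True)  # 1 s
        with pytest.raises(ValueError, match="shorter"):
            segment(rec)


class TestDetectArtifacts:
    def epochs(self, layout, data):
        return EpochSet("p1", "closed", tuple(layout.labels), data, FS)

    def test_clean_input_empty_mask(self, layout):
        mask = detect_artifacts(self.epochs(layout, np.zeros((10, 65, 1000))))
        assert not mask.flags.any()

    def test_single_exceedance_flags_single_cell(self, layout):
        data = np.zeros((10, 65, 1000))
        data[7, 3, 500] = 150.0
        mask = detect_artifacts(self.epochs(layout, data))
        # the 150 µV spike also violates the step criterion only in that cell
        assert mask.flags[3, 7]
        assert mask.flags.sum() == 1

    def test_step_criterion(self, layout):
        data = np.zeros((2, 65, 1000))
        data[0, 5, 100:] = 60.0  # 60 µV jump, below 100 µV absolute
        mask = detect_artifacts(self.epochs(layout, data))
        assert mask.flags[5, 0] and mask.flags.sum() == 1

    def test_bad_fraction_bookkeeping(self, layout):
        data = np.zeros((10, 65, 1000))
        data[:5, 2, 0] = 200.0  # channel 2 bad in 5 of 10 epochs
        mask = detect_artifacts(self.epochs(layout, data))
        assert mask.channel_bad_fraction[2] == pytest.approx(0.5)
        assert mask.epoch_bad_fraction[0] == pytest.approx(1 / 65)

    def test_nonpositive_thresholds_rejected(self, layout):
        with pytest.raises(ValueError, match="positive"):
            detect_artifacts(self.epochs(layout, np.zeros((2, 65, 10))), 0.0)


class TestChannelRule:
    def setup_epochs(self, layout, rng, bad_channel=0, bad_count=0, n_epochs=100):
        data = rng.normal(size=(n_epochs, 65, 100))
        flags = np.zeros((65, n_epochs), dtype=bool)
        flags[bad_channel, :bad_count] = True
        ep = EpochSet("p1", "closed", tuple(layout.labels), data, FS)
        return ep, ArtifactMask(flags)

    def test_41_percent_interpolated(self, layout, graph, rng):
        ep, mask = self.setup_epochs(layout, rng, bad_count=41)
        out, new_mask, interp = apply_channel_rule(ep, mask, graph)
        assert interp == (0,)
        assert not new_mask.flags[0].any()
        assert not np.allclose(out.epochs[:, 0], ep.epochs[:, 0])

    def test_40_percent_kept(self, layout, graph, rng):
        ep, mask = self.setup_epochs(layout, rng, bad_count=40)
        out, new_mask, interp = apply_channel_rule(ep, mask, graph)
        assert interp == ()
        np.testing.assert_array_equal(out.epochs, ep.epochs)
        assert new_mask.flags[0].sum() == 40

    def test_non_target_channels_untouched(self, layout, graph, rng):
        ep, mask = self.setup_epochs(layout, rng, bad_channel=3, bad_count=50)
        out, _, _ = apply_channel_rule(ep, mask, graph)
        untouched = [c for c in range(65) if c != 3]
        np.testing.assert_array_equal(out.epochs[:, untouched], ep.epochs[:, untouched])

    def test_all_channels_bad_rejected(self, layout, graph, rng):
        ep, mask = self.setup_epochs(layout, rng)
        mask.flags[:, :] = True
        with pytest.raises(ValueError, match="unrecoverable"):
            apply_channel_rule(ep, mask, graph)


class TestSegmentRule:
    def make(self, layout, flags):
        n_epochs = flags.shape[1]
        ep = EpochSet(
            "p1", "closed", tuple(layout.labels), np.zeros((n_epochs, 65, 100)), FS
        )
        return ep, ArtifactMask(flags)

    def test_7_of_65_dropped(self, layout):
        flags = np.zeros((65, 10), dtype=bool)
        flags[:7, 4] = True  # 10.8% of sensors
        ep, mask = self.make(layout, flags)
        clean = apply_segment_rule(ep, mask)
        assert clean.dropped_epochs == (4,)
        assert len(clean.retained_indices) == 9

    def test_6_of_65_retained(self, layout):
        flags = np.zeros((65, 10), dtype=bool)
        flags[:6, 4] = True  # 9.2%
        ep, mask = self.make(layout, flags)
        clean = apply_segment_rule(ep, mask)
        assert clean.dropped_epochs == ()
        assert len(clean.retained_indices) == 10

    def test_clean_input_retains_everything(self, layout):
        ep, mask = self.make(layout, np.zeros((65, 45), dtype=bool))
        clean = apply_segment_rule(ep, mask)
        assert len(clean.retained_indices) == 45
        assert clean.retained_seconds == pytest.approx(45 * 100 / FS)

    def test_all_epochs_bad_rejected(self, layout):
        ep, mask = self.make(layout, np.ones((65, 5), dtype=bool))
        with pytest.raises(ValueError, match="unrecoverable"):
            apply_segment_rule(ep, mask)


class TestHjorthInterpolation:
    def test_constant_neighbors_give_constant(self, layout, graph):
        epoch = np.full((65, 100), 3.7)
        out = hjorth_interpolate(epoch, layout.index("Cz"), graph)
        np.testing.assert_allclose(out, 3.7, atol=1e-12)

    def test_single_usable_neighbor_is_copied(self, layout, graph, rng):
        epoch = rng.normal(size=(65, 50))
        ch = layout.index("Cz")
        bad = np.ones(65, dtype=bool)
        keep = graph.neighbors[ch][0]
        bad[keep] = False
        out = hjorth_interpolate(epoch, ch, graph, bad)
        np.testing.assert_array_equal(out, epoch[keep])

    def test_linear_field_exact_at_symmetric_site(self, layout, graph):
        # potential linear in ML; Cz's neighbor set is ML-symmetric
        field = 2.5 * layout.ml + 0.7
        epoch = np.tile(field[:, None], (1, 10))
        ch = layout.index("Cz")
        out = hjorth_interpolate(epoch, ch, graph)
        np.testing.assert_allclose(out, field[ch], atol=1e-9)

    def test_no_usable_neighbors_rejected(self, layout, graph):
        epoch = np.zeros((65, 10))
        with pytest.raises(ValueError, match="neighbor"):
            hjorth_interpolate(epoch, 0, graph, np.ones(65, dtype=bool))


class TestEOGRegression:
    def test_proportional_channel_nulled(self, layout, rng):
        eog = rng.normal(size=2000)
        data = np.tile(2.0 * eog, (64, 1))
        rec = make_recording(layout, data, n_samples=2000)
        out = eog_regress(rec, eog)
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-10)

    def test_orthogonal_channel_unchanged(self, layout):
        t = np.arange(1000)
        eog = np.sin(2 * np.pi * t / 100)
        sig = np.cos(2 * np.pi * t / 100)  # orthogonal over whole cycles
        data = np.tile(sig, (64, 1))
        rec = make_recording(layout, data, n_samples=1000)
        out = eog_regress(rec, eog)
        np.testing.assert_allclose(out.samples, data, atol=1e-10)

    def test_matches_hand_computed_least_squares(self, layout):
        eog = np.array([1.0, 2.0, 3.0])
        chan = np.array([2.0, 3.0, 5.0])
        # centred eog g=(-1,0,1); beta = <x,g>/<g,g> = 3/2; intercept 10/3
        data = np.zeros((64, 3))
        data[0] = chan
        rec = make_recording(layout, data, n_samples=3)
        out = eog_regress(rec, eog)
        expected = chan - 10.0 / 3.0 - 1.5 * np.array([-1.0, 0.0, 1.0])
        np.testing.assert_allclose(out.samples[0], expected, atol=1e-12)

    def test_zero_variance_eog_rejected(self, layout):
        rec = make_recording(layout, n_samples=100)
        with pytest.raises(ValueError, match="variance"):
            eog_regress(rec, np.ones(100))
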