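"""Artifact interpolation, filtering, epoching, rejection, averaging."""

import numpy as np
import pytest

from delphi_tep.containers import EpochSet, RawTEPRecording, StimulationEvent
from delphi_tep.preprocess import (
    ConditionSelector,
    SelectionError,
    average_evoked,
    epoch_and_baseline,
    filter_recording,
    reject_trials,
    remove_pulse_artifact,
)

from conftest import events_at, flat_recording


class TestArtifactRemoval:
    def test_impulse_on_flat_background_is_erased(self, montage):
        rec = flat_recording(montage, events=events_at([5.0]))
        rec.data[:, 5000] = 5000.0
        out = remove_pulse_artifact(rec)
        assert np.abs(out.data).max() < 1e-6

    def test_samples_outside_windows_bit_exact(self, montage):
        rng = np.random.default_rng(0)
        rec = flat_recording(montage, events=events_at([5.0]))
        rec.data[:] = rng.normal(0, 10, rec.data.shape)
        out = remove_pulse_artifact(rec, window_ms=(-2, 10))
        fs = rec.sampling_rate_hz
        lo = int(5.0 * fs) - 2
        hi = int(5.0 * fs) + 10 + 1
        assert np.array_equal(out.data[:, :lo - 2], rec.data[:, :lo - 2])
        assert np.array_equal(out.data[:, hi + 2:], rec.data[:, hi + 2:])

    def test_linear_ramp_is_reproduced(self, montage):
        rec = flat_recording(montage, events=events_at([5.0]))
        ramp = np.linspace(0.0, 100.0, rec.n_samples)
        rec.data[:] = ramp
        rec.data[:, 4998:5011] += 4000.0  # artifact burst
        out = remove_pulse_artifact(rec)
        assert np.abs(out.data - ramp).max() < 1e-6

    def test_idempotent_on_clean_windows(self, montage):
        rec = flat_recording(montage, events=events_at([5.0]))
        rec.data[:] = np.linspace(0.0, 50.0, rec.n_samples)
        once = remove_pulse_artifact(rec)
        twice = remove_pulse_artifact(once)
        assert np.array_equal(once.data, twice.data)

    def test_overlapping_windows_merge_with_warning(self, montage, caplog):
        rec = flat_recording(montage, events=events_at([5.0, 5.005]))
        rec.data[:, 5000] = 3000.0
        rec.data[:, 5005] = 3000.0
        with caplog.at_level("WARNING"):
            out = remove_pulse_artifact(rec)
        assert np.abs(out.data).max() < 1e-6
        assert any("merged" in r.message for r in caplog.records)


class TestFiltering:
    def test_notch_kills_line_frequency(self, montage):
        fs = 1000.0
        t = np.arange(int(20 * fs)) / fs
        rec = flat_recording(montage, fs=fs, dur_s=20.0)
        rec.data[:] = 50.0 * np.sin(2 * np.pi * 50.0 * t)
        out = filter_recording(rec, band_hz=(1, 80), notch_hz=50.0, resample_hz=fs)
        mid = slice(2000, 18000)  # avoid filter edges
        assert np.sqrt((out.data[:, mid] ** 2).mean()) < 0.05 * 50.0 / np.sqrt(2)

    def test_dc_offset_removed(self, montage):
        rec = flat_recording(montage, value=100.0)
        out = filter_recording(rec, resample_hz=1000.0)
        assert abs(out.data[:, 2000:-2000].mean()) < 1.0

    def test_resampling_keeps_event_alignment(self, montage):
        rec = flat_recording(montage, fs=5000.0, dur_s=4.0, events=events_at([1.0]))
        out = filter_recording(rec, resample_hz=1000.0)
        assert out.sampling_rate_hz == 1000.0
        assert int(round(out.events[0].onset_time * 1000.0)) == 1000

    def test_band_above_nyquist_rejected(self, montage):
        rec = flat_recording(montage)
        with pytest.raises(ValueError, match="Nyquist"):
            filter_recording(rec, band_hz=(1, 600), resample_hz=1000.0)


class TestEpoching:
    def test_one_trial_per_event_and_zero_in_axis(self, montage):
        rec = flat_recording(montage, events=events_at([2.0, 5.0, 8.0]))
        ep = epoch_and_baseline(rec)
        assert ep.n_trials == 3
        assert 0.0 in ep.time_axis_ms

    def test_constant_channel_zeroed_by_baseline(self, montage):
        rec = flat_recording(montage, value=7.0, events=events_at([5.0]))
        ep = epoch_and_baseline(rec)
        assert np.abs(ep.data).max() < 1e-9

    def test_edge_event_dropped_others_intact(self, montage):
        rec = flat_recording(montage, dur_s=10.0, events=events_at([5.0, 9.9]))
        ep = epoch_and_baseline(rec)
        assert ep.n_trials == 1
        assert ep.dropped_event_indices == [1]

    def test_baseline_shift_invariance(self, montage):
        """Baseline correction removes any per-trial offset without touching
        post-stimulus differences."""
        rng = np.random.default_rng(1)
        rec = flat_recording(montage, events=events_at([3.0, 7.0]))
        rec.data[:] = rng.normal(0, 5, rec.data.shape)
        shifted = rec.copy_with(data=rec.data + 42.0)
        a = epoch_and_baseline(rec)
        b = epoch_and_baseline(shifted)
        assert np.allclose(a.data, b.data, atol=1e-9)


class TestRejection:
    def _epochs(self, montage, n_trials=40, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(-500.0, 500.0, 1.0)
        data = rng.normal(0, 5, (n_trials, montage.n_channels, t.size))
        meta = [dict(intensity_pct=40, train_frequency_hz=0.1, block_id=0, sham=False)
                for _ in range(n_trials)]
        return EpochSet(data, t, meta, (-300.0, -50.0), montage)

    def test_large_excursion_rejected(self, montage):
        ep = self._epochs(montage)
        ep.data[7, 3, 700] = 400.0  # +200 ms
        kept, report = reject_trials(ep)
        assert report.n_trials_kept == 39
        assert report.rejected_indices == [7]

    def test_all_clean_keeps_everything(self, montage):
        kept, report = reject_trials(self._epochs(montage))
        assert report.n_trials_kept == report.n_trials_in

    def test_flat_channel_rejected(self, montage):
        ep = self._epochs(montage)
        ep.data[3, 5, :] = 0.0
        kept, report = reject_trials(ep)
        assert 3 in report.rejected_indices
        assert "flat_channel_trials" in report.flags

    def test_all_rejected_is_hard_error(self, montage):
        ep = self._epochs(montage)
        ep.data[:, 0, 700] = 900.0
        with pytest.raises(RuntimeError, match="threshold"):
            reject_trials(ep)

    def test_contaminated_fraction_recovered(self, montage):
        """10% of trials carry a blink-like 200 µV excursion; the rejected
        fraction tracks the contamination rate across seeded runs."""
        fracs = []
        t = np.arange(-500.0, 500.0, 1.0)
        blink = 200.0 * np.exp(-0.5 * ((t - 150.0) / 80.0) ** 2)
        for seed in range(50):
            rng = np.random.default_rng(seed)
            ep = self._epochs(montage, n_trials=40, seed=seed)
            bad = rng.random(40) < 0.10
            ep.data[bad, 2, :] += blink
            _, report = reject_trials(ep)
            fracs.append(len(report.rejected_indices) / 40.0)
        assert abs(np.mean(fracs) - 0.10) < 0.03


class TestAveraging:
    def _two_trial_epochs(self, montage):
        t = np.arange(-500.0, 500.0, 1.0)
        data = np.stack([np.ones((20, t.size)), -np.ones((20, t.size))])
        meta = [dict(intensity_pct=40, train_frequency_hz=0.1, block_id=0, sham=False),
                dict(intensity_pct=40, train_frequency_hz=0.1, block_id=0, sham=False)]
        return EpochSet(data, t, meta, (-300.0, -50.0), montage)

    def test_opposite_trials_cancel(self, montage):
        ev = average_evoked(self._two_trial_epochs(montage))
        assert np.abs(ev.data).max() == 0.0
        assert ev.n_trials == 2

    def test_empty_selection_raises_with_description(self, montage):
        with pytest.raises(SelectionError, match="excitatory"):
            average_evoked(
                self._two_trial_epochs(montage),
                ConditionSelector(frequency_class="excitatory"),
            )

    def test_single_pulse_selector_counts_low_freq_trials(self, small_recording):
        from delphi_tep.preprocess import epoch_and_baseline

        ep = epoch_and_baseline(small_recording)
        n_low = sum(
            1 for m in ep.trial_meta if m["train_frequency_hz"] <= 0.5
        )
        ev = average_evoked(ep, ConditionSelector(frequency_class="baseline"))
        assert ev.n_trials == n_low

    @pytest.mark.parametrize("n", [4, 16, 64])
    def test_noise_scales_as_inverse_sqrt_n(self, montage, n):
        t = np.arange(-500.0, 500.0, 1.0)
        rms = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = rng.normal(0, 10.0, (n, montage.n_channels, t.size))
            meta = [dict(intensity_pct=40, train_frequency_hz=0.1, block_id=0,
                         sham=False) for _ in range(n)]
            ep = EpochSet(data, t, meta, (-300.0, -50.0), montage)
            rms.append(np.sqrt((average_evoked(ep).data ** 2).mean()))
        assert np.mean(rms) == pytest.approx(10.0 / np.sqrt(n), rel=0.2)

    def test_averaging_identical_trials_is_identity(self, montage):
        t = np.arange(-500.0, 500.0, 1.0)
        rng = np.random.default_rng(5)
        trial = rng.normal(0, 3, (montage.n_channels, t.size))
        data = np.stack([trial] * 8)
        meta = [dict(intensity_pct=40, train_frequency_hz=0.1, block_id=0,
                     sham=False) for _ in range(8)]
        ep = EpochSet(data, t, meta, (-300.0, -50.0), montage)
        assert np.allclose(average_evoked(ep).data, trial, atol=1e-12)
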