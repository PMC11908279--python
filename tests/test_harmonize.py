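"""Conditional high-pass, LOESS peak flattening, amplitude matching."""

import numpy as np
import pytest

import ecgkit as ek
from ecgkit.records import ECGRecord
from tests.conftest import band_power


def sinusoid_record(freq, amp=1.0, fs=500.0, duration=10.0):
    t = np.arange(int(fs * duration)) / fs
    return ECGRecord(waveform=amp * np.sin(2 * np.pi * freq * t), fs=fs)


class TestHighpass:
    def test_stopband_attenuation_at_least_20db(self):
        rec = sinusoid_record(0.3)
        out = ek.apply_highpass(rec, 1.0)
        attenuation_db = 20 * np.log10(
            rec.waveform.std() / max(out.waveform.std(), 1e-300)
        )
        assert attenuation_db >= 20

    def test_passband_amplitude_preserved_within_1pct(self):
        rec = sinusoid_record(10.0)
        out = ek.apply_highpass(rec, 1.0)
        assert out.waveform.std() == pytest.approx(rec.waveform.std(), rel=0.01)

    def test_zero_input_zero_output(self):
        rec = ECGRecord(waveform=np.zeros((2, 5000)), fs=500.0)
        out = ek.apply_highpass(rec, 1.0)
        assert np.all(out.waveform == 0.0)

    def test_dc_offset_removed(self):
        rec = sinusoid_record(10.0)
        offset = rec.copy(waveform=rec.waveform + 5.0)
        out = ek.apply_highpass(offset, 1.0)
        # 5 mV offset suppressed by > 3 orders of magnitude
        assert abs(out.waveform.mean()) < 5e-3
        assert out.waveform.std() == pytest.approx(rec.waveform.std(), rel=0.01)

    def test_cutoff_at_nyquist_rejected(self, clean_record):
        with pytest.raises(ValueError):
            ek.apply_highpass(clean_record, 250.0)

    def test_lead_subset_only_touches_those_leads(self, clean_record):
        out = ek.apply_highpass(clean_record, 1.0, leads=[0, 2])
        assert np.array_equal(out.waveform[1], clean_record.waveform[1])
        assert not np.array_equal(out.waveform[0], clean_record.waveform[0])


class TestFlattenPeaks:
    def test_empty_peak_list_is_identity(self, clean_record):
        out = ek.flatten_peaks(clean_record, [])
        assert np.array_equal(out.waveform, clean_record.waveform)

    def test_flattened_tone_no_longer_detected(self, clean_record):
        contam = ek.inject_mains(clean_record, 50.0, 1, 0.5)
        peaks = ek.detect_artifact_peaks(ek.power_spectrum(contam))
        assert peaks
        flat = ek.flatten_peaks(contam, peaks)
        assert ek.detect_artifact_peaks(ek.power_spectrum(flat)) == []

    def test_clean_signal_distortion_below_5pct(self, clean_record):
        contam = ek.inject_mains(clean_record, 50.0, 1, 0.5)
        peaks = ek.detect_artifact_peaks(ek.power_spectrum(contam))
        flat = ek.flatten_peaks(contam, peaks)
        rms_err = (flat.waveform - clean_record.waveform).std()
        assert rms_err < 0.05 * clean_record.waveform.std()

    def test_peak_near_dc_rejected(self, clean_record):
        peak = ek.ArtifactPeak(center_hz=0.5, excess_sd=5.0)
        with pytest.raises(ValueError):
            ek.flatten_peaks(clean_record, [peak])

    def test_peak_near_nyquist_rejected(self, clean_record):
        peak = ek.ArtifactPeak(center_hz=249.5, excess_sd=5.0)
        with pytest.raises(ValueError):
            ek.flatten_peaks(clean_record, [peak])


class TestReferenceProfile:
    def test_constant_record_rejected_as_degenerate(self):
        rec = ECGRecord(waveform=np.full((2, 5000), 3.0), fs=500.0)
        with pytest.raises(ValueError, match="degenerate"):
            ek.build_reference_profile([rec])

    def test_scaling_equivariance(self, clean_record):
        base = ek.build_reference_profile([clean_record])
        doubled = ek.build_reference_profile(
            [clean_record.copy(waveform=2.0 * clean_record.waveform)]
        )
        assert np.allclose(doubled.span, 2.0 * base.span, rtol=1e-9)

    def test_pooling_identical_records_matches_single(self, clean_record):
        one = ek.build_reference_profile([clean_record])
        two = ek.build_reference_profile([clean_record, clean_record])
        assert np.allclose(one.span, two.span, rtol=1e-9)

    def test_inconsistent_lead_counts_rejected(self, clean_record, small_record):
        with pytest.raises(ValueError, match="lead"):
            ek.build_reference_profile([clean_record, small_record])


class TestAmplitudeMatch:
    def test_already_matching_record_gets_unit_factors(self, clean_record):
        ref = ek.build_reference_profile([clean_record])
        factors, skipped = ek.harmonize.amplitude_scale_factors(clean_record, ref)
        assert skipped == []
        assert np.allclose(factors, 1.0, atol=1e-9)

    def test_half_scale_record_gets_factor_two(self, clean_record):
        ref = ek.build_reference_profile([clean_record])
        half = clean_record.copy(waveform=0.5 * clean_record.waveform)
        factors, _ = ek.harmonize.amplitude_scale_factors(half, ref)
        assert np.allclose(factors, 2.0, rtol=1e-6)

    def test_idempotent(self, clean_record):
        ref = ek.build_reference_profile([clean_record])
        once = ek.amplitude_match(
            clean_record.copy(waveform=0.3 * clean_record.waveform), ref
        )
        twice = ek.amplitude_match(once, ref)
        assert np.allclose(once.waveform, twice.waveform, rtol=1e-9)

    def test_scale_equivariant(self, clean_record):
        ref = ek.build_reference_profile([clean_record])
        a = ek.amplitude_match(clean_record, ref)
        b = ek.amplitude_match(
            clean_record.copy(waveform=13.0 * clean_record.waveform), ref
        )
        assert np.allclose(a.waveform, b.waveform, rtol=1e-7)

    def test_zero_span_lead_skipped_and_flagged(self, clean_record):
        ref = ek.build_reference_profile([clean_record])
        wf = clean_record.waveform.copy()
        wf[3] = 0.0
        rec = clean_record.copy(waveform=wf)
        factors, skipped = ek.harmonize.amplitude_scale_factors(rec, ref)
        assert skipped == [3]
        assert factors[3] == 1.0


class TestHarmonizeRecord:
    def test_conforming_record_is_a_noop(self, clean_record):
        ref = ek.build_reference_profile([clean_record])
        out, log = ek.harmonize_record(clean_record, ref)
        assert not log.any_highpass()
        assert log.peaks_removed == []
        assert np.allclose(log.scale_factors, 1.0, atol=1e-6)
        assert np.allclose(out.waveform, clean_record.waveform, atol=1e-6)

    def test_full_contamination_fires_all_stages(self, contaminated_pair):
        clean, contam = contaminated_pair(11)
        ref = ek.build_reference_profile([clean])
        out, log = ek.harmonize_record(contam, ref)
        assert log.any_highpass()
        assert len(log.peaks_removed) >= 1
        assert np.median(log.scale_factors) == pytest.approx(2.0, rel=0.05)
        spec = ek.power_spectrum(out)
        assert np.all(ek.lowfreq_excess(spec) <= 1.0)
        assert ek.detect_artifact_peaks(spec) == []

    def test_clinical_band_preserved(self, contaminated_pair):
        clean, contam = contaminated_pair(12)
        ref = ek.build_reference_profile([clean])
        out, _ = ek.harmonize_record(contam, ref)
        rel = np.abs(band_power(out) - band_power(clean)) / band_power(clean)
        assert rel.max() < 0.05

    def test_second_pass_triggers_nothing(self, contaminated_pair):
        clean, contam = contaminated_pair(13)
        ref = ek.build_reference_profile([clean])
        once, _ = ek.harmonize_record(contam, ref)
        twice, log2 = ek.harmonize_record(once, ref)
        assert not log2.any_highpass()
        assert log2.peaks_removed == []
        assert np.allclose(log2.scale_factors, 1.0, atol=0.01)

    def test_replay_reproduces_output_bit_exactly(self, contaminated_pair):
        clean, contam = contaminated_pair(14)
        ref = ek.build_reference_profile([clean])
        out, log = ek.harmonize_record(contam, ref)
        assert np.array_equal(ek.replay(contam, log).waveform, out.waveform)

    def test_record_scope_filters_all_leads(self, clean_record):
        rms = clean_record.waveform.std()
        # wander on the waveform of one lead only
        wf = clean_record.waveform.copy()
        t = np.arange(clean_record.n_samples) / clean_record.fs
        wf[0] += 100 * rms * np.sin(2 * np.pi * 0.3 * t)
        rec = clean_record.copy(waveform=wf)
        ref = ek.build_reference_profile([clean_record])
        _, log_lead = ek.harmonize_record(rec, ref, ek.HarmonizeConfig())
        _, log_rec = ek.harmonize_record(
            rec, ref, ek.HarmonizeConfig(trigger_scope="record")
        )
        assert sum(log_lead.highpass_applied) == 1
        assert all(log_rec.highpass_applied)

    def test_stage_disable_switches(self, contaminated_pair):
        clean, contam = contaminated_pair(15)
        ref = ek.build_reference_profile([clean])
        cfg = ek.HarmonizeConfig(
            enable_highpass=False, enable_flatten=False, enable_scaling=False
        )
        out, log = ek.harmonize_record(contam, ref, cfg)
        assert np.array_equal(out.waveform, contam.waveform)
        assert not log.any_highpass() and log.peaks_removed == []
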