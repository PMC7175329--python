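"""Denoising and augmentation: invariants and worked examples."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrrecg.io import ECGRecord, LabelVector, CANONICAL_LEADS
from mrrecg.preprocess import (
    AugmentConfig,
    DenoiseConfig,
    augment_mask,
    augment_scale,
    augment_shift,
    denoise,
    denoise_record,
)
from mrrecg.synth import RHYTHM_LIBRARY, generate_record


def make_record(n_samples=500, fs=100.0, seed=0):
    rng = np.random.default_rng(seed)
    return ECGRecord(
        "r",
        rng.normal(size=(8, n_samples)),
        fs,
        CANONICAL_LEADS,
        40,
        "male",
        LabelVector.from_names(("A",), ("A", "B")),
    )


class TestDenoise:
    def test_zero_in_zero_out(self):
        out = denoise(np.zeros(1024))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_constant_preserved(self):
        out = denoise(np.full(1024, 3.7))
        np.testing.assert_allclose(out, 3.7, atol=1e-8)

    def test_snr_strictly_improves_on_noisy_beat_train(self):
        rec = generate_record(
            RHYTHM_LIBRARY["Normal sinus rhythm"],
            fs=500.0, duration_s=10.0, seed=2, snr_db=10.0,
        )
        # reconstruct the clean component from a noise-free twin
        clean = generate_record(
            RHYTHM_LIBRARY["Normal sinus rhythm"],
            fs=500.0, duration_s=10.0, seed=2, snr_db=200.0,
        ).lead("II")
        noisy = rec.lead("II")
        den = denoise(noisy)

        def snr(x):
            return 10 * np.log10(
                np.mean(clean**2) / np.mean((x - clean) ** 2)
            )

        assert snr(den) > snr(noisy)

    def test_infeasible_level_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            denoise(np.zeros(64), DenoiseConfig(level=12))

    def test_idempotent_within_tolerance(self):
        rec = generate_record(
            RHYTHM_LIBRARY["Normal sinus rhythm"],
            fs=250.0, duration_s=10.0, seed=4, snr_db=15.0,
        )
        once = denoise(rec.lead("II"))
        twice = denoise(once)
        resid = np.sqrt(np.mean((twice - once) ** 2))
        scale = np.sqrt(np.mean(once**2))
        assert resid < 0.1 * scale

    def test_record_denoise_keeps_shape_and_labels(self):
        rec = make_record()
        out = denoise_record(rec)
        assert out.signal.shape == rec.signal.shape
        assert out.labels is rec.labels


class TestScale:
    def test_tau_zero_is_identity(self):
        rec = make_record()
        np.testing.assert_array_equal(augment_scale(rec, 0.0).signal, rec.signal)

    def test_direct_multiplication(self):
        rec = make_record()
        rec = rec.with_signal(np.tile([1.0, 2.0, 3.0], (8, 1)))
        np.testing.assert_allclose(
            augment_scale(rec, 0.1).signal[0], [1.1, 2.2, 3.3]
        )

    def test_extrema_scale_exactly(self):
        rec = make_record()
        out = augment_scale(rec, 0.23)
        assert np.isclose(
            np.abs(out.signal).max(), 1.23 * np.abs(rec.signal).max()
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        tau1=st.floats(-0.5, 0.5),
        tau2=st.floats(-0.5, 0.5),
    )
    def test_composition_is_single_scale(self, tau1, tau2):
        rec = make_record(n_samples=64)
        double = augment_scale(augment_scale(rec, tau1), tau2)
        single = augment_scale(rec, (1 + tau1) * (1 + tau2) - 1)
        np.testing.assert_allclose(double.signal, single.signal, rtol=1e-12)


class TestShift:
    def test_zero_and_full_rotation_are_identity(self):
        rec = make_record()
        np.testing.assert_array_equal(augment_shift(rec, 0).signal, rec.signal)
        wrapped = augment_shift(augment_shift(rec, 250), 250)
        np.testing.assert_array_equal(wrapped.signal, rec.signal)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.integers(-499, 499))
    def test_sample_multiset_invariant(self, shift):
        rec = make_record()
        out = augment_shift(rec, shift)
        np.testing.assert_array_equal(
            np.sort(out.signal, axis=1), np.sort(rec.signal, axis=1)
        )

    def test_zero_padding_mode_drops_samples(self):
        rec = make_record()
        out = augment_shift(rec, 100, mode="zero")
        assert (out.signal[:, :100] == 0).all()
        np.testing.assert_array_equal(out.signal[:, 100:], rec.signal[:, :-100])


class TestMask:
    def test_mask_length_within_one_second(self):
        rec = make_record(n_samples=5000, fs=500.0)
        cfg = AugmentConfig(max_mask_s=1.0)
        out = augment_mask(rec, seed=8, cfg=cfg)
        newly_zero = (out.signal == 0) & (rec.signal != 0)
        run = newly_zero[0].sum()
        assert 0 < run <= 500  # (0, 1) s at 500 Hz

    def test_same_seed_same_mask(self):
        rec = make_record()
        a = augment_mask(rec, seed=3)
        b = augment_mask(rec, seed=3)
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_zeroed_count_is_length_times_leads(self):
        rec = make_record()
        out = augment_mask(rec, seed=5)
        diff = out.signal != rec.signal
        # same contiguous run on every lead
        per_lead = diff.sum(axis=1)
        assert (per_lead == per_lead[0]).all()
        assert diff.sum() == per_lead[0] * rec.n_leads
        changed = np.where(diff[0])[0]
        assert (np.diff(changed) == 1).all()


class TestCommonInvariants:
    @pytest.mark.parametrize(
        "aug",
        [
            lambda r: augment_scale(r, 0.3),
            lambda r: augment_shift(r, 37),
            lambda r: augment_mask(r, seed=1),
        ],
        ids=["scale", "shift", "mask"],
    )
    def test_shape_fs_labels_preserved(self, aug):
        rec = make_record()
        out = aug(rec)
        assert out.signal.shape == rec.signal.shape
        assert out.fs == rec.fs
        assert out.labels is rec.labels
        assert out.lead_names == rec.lead_names
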