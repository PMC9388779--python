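"""QC/denoising contracts: scrubbing, exclusion rule, aCompCor, filtering,
smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdcsfc.preprocess import (
    ExclusionReason,
    QCThresholds,
    acompcor_regress,
    apply_exclusion_rule,
    bandpass_detrend_despike,
    detect_outlier_volumes,
    make_qc_report,
    smooth_gaussian,
)
from tdcsfc.types import BoldSeries


def _bold_from_array(data, tr=2.0, motion=None):
    return BoldSeries(
        data=np.asarray(data, dtype=np.float32),
        affine=np.diag([4.0, 4.0, 4.0, 1.0]),
        tr_s=tr,
        motion=motion,
    )


TH = QCThresholds()


class TestDetectOutlierVolumes:
    def test_constant_series_zero_motion_censors_nothing(self):
        bold = _bold_from_array(np.ones((4, 4, 4, 50)), motion=np.zeros((50, 6)))
        assert not detect_outlier_volumes(bold, TH).any()

    def test_single_large_spike_censored(self, rng):
        data = np.tile(rng.normal(size=(4, 4, 4, 1)), (1, 1, 1, 100)) + rng.normal(
            0, 0.1, size=(4, 4, 4, 100)
        )
        data[..., 40] += 50.0  # global-signal jump, difference z >> 9
        bold = _bold_from_array(data)
        censor = detect_outlier_volumes(bold, TH)
        assert censor[40]
        assert censor.sum() <= 3  # the spike and its shoulder at most

    def test_motion_threshold_censors_regardless_of_signal(self):
        motion = np.zeros((50, 6))
        motion[20:, 0] = 2.5  # 2.5 mm translation step at volume 20
        bold = _bold_from_array(np.ones((4, 4, 4, 50)), motion=motion)
        censor = detect_outlier_volumes(bold, TH)
        assert censor[20] and censor.sum() == 1

    def test_motion_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="motion"):
            _bold_from_array(np.ones((4, 4, 4, 50)), motion=np.zeros((49, 6)))


class TestExclusionRule:
    @pytest.mark.parametrize(
        "fraction,reg_ok,excluded,reason",
        [
            (0.30, True, True, ExclusionReason.CENSORING),  # inclusive boundary
            (0.29, True, False, ExclusionReason.NONE),
            (0.0, False, True, ExclusionReason.REGISTRATION),
            (0.9, False, True, ExclusionReason.REGISTRATION),
        ],
    )
    def test_rule(self, fraction, reg_ok, excluded, reason):
        report = make_qc_report(np.zeros(100, dtype=bool))
        report.censored_fraction = fraction
        report = apply_exclusion_rule(report, reg_ok, TH)
        assert report.excluded is excluded
        assert report.exclusion_reason is reason

    @given(st.floats(0.0, 1.0), st.floats(0.01, 1.0))
    @settings(max_examples=50, derandomize=True)
    def test_exclusion_monotone_in_threshold(self, fraction, cutoff):
        """Raising the allowed censored fraction never excludes a previously
        retained subject."""
        report = make_qc_report(np.zeros(10, dtype=bool))
        report.censored_fraction = fraction
        lo = apply_exclusion_rule(report, True, QCThresholds(max_censored_fraction=cutoff))
        retained_lo = not lo.excluded
        hi_cut = min(1.0, cutoff + 0.2)
        hi = apply_exclusion_rule(report, True, QCThresholds(max_censored_fraction=hi_cut))
        if retained_lo:
            assert not hi.excluded


@pytest.fixture(scope="module")
def masks():
    wm = np.zeros((6, 6, 6), dtype=bool)
    csf = np.zeros((6, 6, 6), dtype=bool)
    wm[:2], csf[4:] = True, True
    return wm, csf


class TestACompCor:
    def test_voxel_equal_to_csf_pc_is_annihilated(self, masks, rng):
        wm, csf = masks
        T = 80
        comp = np.sin(np.linspace(0, 20, T))
        data = rng.normal(size=(6, 6, 6, T)).astype(np.float32)
        data[csf] = comp + 0.01 * rng.normal(size=(csf.sum(), T))
        data[2, 2, 2] = comp  # gray voxel = CSF component
        bold = _bold_from_array(data)
        resid = acompcor_regress(bold, wm, csf, n_components=2)
        assert resid.data[2, 2, 2].var() < 1e-4 * data[2, 2, 2].var()

    def test_zero_confounds_returns_centered_input(self, masks):
        wm, csf = masks
        T = 40
        data = np.zeros((6, 6, 6, T), dtype=np.float32)
        data[wm] = 0.0
        data[csf] = 0.0
        data[3, 3, 3] = np.linspace(1, 5, T)
        bold = _bold_from_array(data)
        resid = acompcor_regress(bold, wm, csf, n_components=1)
        expected = data[3, 3, 3] - data[3, 3, 3].mean()
        np.testing.assert_allclose(resid.data[3, 3, 3], expected, atol=1e-4)

    def test_planted_nuisance_removed(self, masks, rng):
        wm, csf = masks
        T = 120
        nuis = rng.normal(size=T)
        data = rng.normal(size=(6, 6, 6, T))
        data += 0.5 * nuis  # nuisance mixed into every voxel
        data[wm] = nuis + 0.05 * rng.normal(size=(wm.sum(), T))
        data[csf] = rng.normal(size=(csf.sum(), T))
        bold = _bold_from_array(data)
        resid = acompcor_regress(bold, wm, csf, n_components=3)
        gray = ~(wm | csf)
        cors = [
            abs(np.corrcoef(resid.data[tuple(v)], nuis)[0, 1])
            for v in np.argwhere(gray)[::7]
        ]
        assert np.mean(cors) < 0.05

    def test_residuals_orthogonal_to_confounds(self, masks, rng):
        wm, csf = masks
        T = 60
        data = rng.normal(size=(6, 6, 6, T)).astype(np.float32)
        motion = rng.normal(size=(T, 6)) * 0.1
        censor = np.zeros(T, dtype=bool)
        censor[[5, 17]] = True
        bold = _bold_from_array(data, motion=motion)
        resid = acompcor_regress(bold, wm, csf, n_components=3, censor_mask=censor)
        keep = ~censor
        r = resid.data.reshape(-1, T)[::11, keep].astype(float)
        r -= r.mean(axis=1, keepdims=True)
        for conf in list(motion.T):
            c = conf[keep] - conf[keep].mean()
            denom = np.sqrt((r**2).sum(axis=1) * (c**2).sum())
            ok = denom > 1e-12
            assert np.all(np.abs(r[ok] @ c) / denom[ok] < 1e-8)

    def test_empty_mask_raises(self, masks):
        _, csf = masks
        bold = _bold_from_array(np.ones((6, 6, 6, 20)))
        with pytest.raises(ValueError, match="mask"):
            acompcor_regress(bold, np.zeros((6, 6, 6), bool), csf)


class TestBandpass:
    def _sine(self, freq_hz, T=300, tr=2.0):
        t = np.arange(T) * tr
        vol = np.zeros((3, 3, 3, T))
        vol[...] = np.sin(2 * np.pi * freq_hz * t)
        return _bold_from_array(vol, tr=tr)

    def test_passband_sine_preserved(self):
        bold = self._sine(0.03)
        out = bandpass_detrend_despike(bold, TH)
        amp_in = np.abs(np.fft.rfft(bold.data[0, 0, 0].astype(float)))
        amp_out = np.abs(np.fft.rfft(out.data[0, 0, 0].astype(float)))
        k = amp_in.argmax()
        assert abs(amp_out[k] - amp_in[k]) / amp_in[k] < 0.05

    def test_stopband_sine_attenuated(self):
        bold = self._sine(0.15)
        out = bandpass_detrend_despike(bold, TH)
        assert np.abs(out.data).max() < 0.10 * np.abs(bold.data).max()

    def test_linear_ramp_removed(self):
        T = 200
        vol = np.zeros((3, 3, 3, T))
        vol[...] = np.linspace(0, 10, T)
        out = bandpass_detrend_despike(_bold_from_array(vol), TH)
        assert np.abs(out.data).max() < 1e-4

    def test_idempotent_in_band(self):
        bold = self._sine(0.03)
        once = bandpass_detrend_despike(bold, TH)
        twice = bandpass_detrend_despike(once, TH)
        a1 = np.abs(np.fft.rfft(once.data[0, 0, 0].astype(float))).max()
        a2 = np.abs(np.fft.rfft(twice.data[0, 0, 0].astype(float))).max()
        assert abs(a2 - a1) / a1 < 0.05

    def test_band_above_nyquist_rejected(self):
        bold = self._sine(0.03, tr=10.0)  # Nyquist 0.05 < band_high 0.09
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_detrend_despike(bold, TH)


class TestSmoothing:
    def test_tiny_fwhm_is_identity(self, rng):
        data = rng.normal(size=(8, 8, 8, 3))
        bold = _bold_from_array(data)
        out = smooth_gaussian(bold, fwhm_mm=1.0)  # below half the 4 mm voxel
        np.testing.assert_array_equal(out.data, bold.data)

    def test_impulse_peak_and_symmetry(self):
        data = np.zeros((9, 9, 9, 1))
        data[4, 4, 4, 0] = 1.0
        out = smooth_gaussian(_bold_from_array(data), fwhm_mm=8.0).data[..., 0]
        assert np.unravel_index(out.argmax(), out.shape) == (4, 4, 4)
        np.testing.assert_allclose(out[3, 4, 4], out[5, 4, 4], atol=1e-10)
        np.testing.assert_allclose(out[4, 3, 4], out[4, 4, 5], atol=1e-10)

    def test_constant_volume_unchanged(self):
        data = np.full((8, 8, 8, 2), 3.5)
        out = smooth_gaussian(_bold_from_array(data), fwhm_mm=4.0)
        np.testing.assert_allclose(out.data, data, atol=1e-5)

    def test_nonpositive_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_gaussian(_bold_from_array(np.ones((8, 8, 8, 1))), 0.0)
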