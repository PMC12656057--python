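"""Feature extraction against brute-force and spectral oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import ictalnet as ic
from ictalnet.features import (
    BANDS,
    FEATURE_NAMES,
    FeatureMatrix,
    band_power,
    temporal_features,
    welch_psd,
    welch_window_length,
)
from ictalnet.recording import Segment
from ictalnet.seizures import SeizureClass


def _brute_force_temporal(x):
    """Direct-summation oracle for the nine statistics."""
    xs = sorted(x)
    n = len(x)

    def perc(q):
        idx = q / 100 * (n - 1)
        lo, hi = int(np.floor(idx)), int(np.ceil(idx))
        return xs[lo] + (idx - lo) * (xs[hi] - xs[lo])

    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    return [
        mean, var ** 0.5, max(x), min(x), perc(75) - perc(25), perc(50), var,
        sum(abs(v) for v in x) / n,
        sum(abs(x[i + 1] - x[i]) for i in range(n - 1)),
    ]


class TestTemporalFeatures:
    def test_constant_signal(self):
        got = temporal_features(np.full(100, 5.0))
        np.testing.assert_allclose(got, [5, 0, 5, 5, 0, 5, 0, 5, 0])

    def test_alternating_signal(self):
        got = temporal_features(np.array([0.0, 1.0, 0.0, 1.0]))
        assert got[8] == 3.0 and got[2] == 1.0 and got[3] == 0.0 and got[0] == 0.5

    def test_ramp_line_length(self):
        n = 57
        got = temporal_features(np.arange(n + 1, dtype=float))
        assert got[8] == n

    @given(
        x=hnp.arrays(
            float, st.integers(min_value=2, max_value=60),
            elements=st.floats(min_value=-1e3, max_value=1e3),
        )
    )
    def test_matches_brute_force(self, x):
        np.testing.assert_allclose(
            temporal_features(x), _brute_force_temporal(list(x)), rtol=1e-9, atol=1e-9
        )

    def test_rejects_singleton(self):
        with pytest.raises(ValueError):
            temporal_features(np.array([1.0]))


class TestWelch:
    @pytest.mark.parametrize("fs,expected", [(250, 256), (400, 410)])
    def test_window_length_rule(self, fs, expected):
        assert welch_window_length(fs) == expected
        x = np.random.default_rng(0).standard_normal(10 * fs)
        f, p = welch_psd(x, fs)
        assert np.all(p >= 0)

    def test_tone_peak_location(self):
        t = np.arange(2500) / 250.0
        f, p = welch_psd(np.sin(2 * np.pi * 10.0 * t), 250.0)
        assert abs(f[p.argmax()] - 10.0) <= 0.5

    def test_signal_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100), 250.0)

    def test_parseval_consistency(self):
        """Integrated PSD approximates the variance within 10% (density scaling)."""
        rng = np.random.default_rng(21)
        x = rng.standard_normal(2500) * 20
        x -= x.mean()
        f, p = welch_psd(x, 250.0)
        assert abs(np.trapezoid(p, f) - x.var()) / x.var() < 0.10


class TestBandPower:
    def test_flat_psd_gives_constant(self):
        f = np.linspace(0, 125, 500)
        p = np.full_like(f, 3.7)
        for b in BANDS:
            assert band_power(f, p, b) == pytest.approx(3.7)

    def test_tone_lands_in_alpha(self):
        t = np.arange(2500) / 250.0
        f, p = welch_psd(np.sin(2 * np.pi * 10.0 * t), 250.0)
        powers = [band_power(f, p, b) for b in BANDS]
        assert np.argmax(powers) == 2  # alpha

    def test_zero_psd(self):
        f = np.linspace(0, 125, 500)
        assert band_power(f, np.zeros_like(f), BANDS[0]) == 0.0

    def test_band_without_bins_named_in_error(self):
        f = np.array([0.0, 50.0, 100.0])
        with pytest.raises(ValueError, match="theta"):
            band_power(f, np.ones_like(f), BANDS[1])

    def test_band_edges_partition_passband(self):
        """Adjacent band interiors do not overlap and cover 0.5-40 Hz."""
        f = np.arange(0.5, 40.01, 0.25)
        hit = np.zeros(len(f), dtype=int)
        for b in BANDS:
            if b.closed_high:
                hit += ((f >= b.low_hz) & (f <= b.high_hz)).astype(int)
            else:
                hit += ((f >= b.low_hz) & (f < b.high_hz)).astype(int)
        assert np.all(hit == 1)


class TestExtract:
    def test_flattened_length_280(self, seizure_segment):
        fm = ic.extract(seizure_segment)
        assert fm.values.shape == (20, 14)
        assert fm.flatten().shape == (280,)
        assert len(FEATURE_NAMES) == 14

    def test_all_zero_segment(self):
        seg = Segment(np.zeros((20, 2500)), 250.0, SeizureClass.ABSZ)
        assert np.all(ic.extract(seg).values == 0)

    def test_channel_permutation_permutes_rows(self, seizure_segment):
        base = ic.extract(seizure_segment).values
        data = seizure_segment.data.copy()
        data[[2, 9]] = data[[9, 2]]
        swapped = ic.extract(
            Segment(data, 250.0, seizure_segment.label, seizure_segment.patient_id)
        ).values
        np.testing.assert_allclose(swapped[2], base[9])
        np.testing.assert_allclose(swapped[9], base[2])
        others = [i for i in range(20) if i not in (2, 9)]
        np.testing.assert_allclose(swapped[others], base[others])

    def test_internal_consistency(self, seizure_segment):
        fm = ic.extract(seizure_segment).values
        np.testing.assert_allclose(fm[:, 1] ** 2, fm[:, 6], rtol=1e-6)  # SD^2 = var
        assert np.all(fm[:, 2] >= fm[:, 5]) and np.all(fm[:, 5] >= fm[:, 3])
        assert np.all(fm[:, 4] >= 0) and np.all(fm[:, 8] >= 0)
        assert np.all(fm[:, 9:] >= 0)

    def test_matrix_shape_enforced(self):
        with pytest.raises(ValueError):
            FeatureMatrix(np.zeros((20, 13)))


def test_absence_low_frequency_power_dominates(synth_config):
    """Generalized spike-and-wave: delta+theta power exceeds beta power."""
    rec = ic.preprocess(ic.generate_seizure("ABSZ", synth_config, 10.0, seed=31))
    fm = ic.extract(ic.segment_events(rec)[0]).values
    low = fm[:, 9] + fm[:, 10]
    assert np.all(low > fm[:, 12])
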