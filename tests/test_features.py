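"""Feature definitions vs independent brute-force oracles and closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from affectemg.features import (
    DegenerateInputError,
    EntropyParams,
    amplitude_features,
    approximate_entropy,
    extract_feature_table,
    feature_vector,
    frequency_features,
    fuzzy_entropy,
    spectrum,
    variability_features,
    zero_crossings,
)

FS = 512.0


# ---------------------------------------------------------------------------
# Brute-force oracles, written independently of the implementation
# ---------------------------------------------------------------------------

def apen_oracle(u, m, r_frac):
    u = list(map(float, u))
    N = len(u)
    r = r_frac * math.sqrt(sum((v - sum(u) / N) ** 2 for v in u) / N)
    def phi(mm):
        vecs = [u[i:i + mm] for i in range(N - mm + 1)]
        total = 0.0
        for vj in vecs:
            count = 0
            for vi in vecs:
                if max(abs(a - b) for a, b in zip(vi, vj)) <= r:
                    count += 1
            total += math.log(count / len(vecs))
        return total / len(vecs)
    return phi(m) - phi(m + 1)


def fuzzyen_oracle(u, m, r_frac, n):
    u = list(map(float, u))
    N = len(u)
    r = r_frac * math.sqrt(sum((v - sum(u) / N) ** 2 for v in u) / N)
    def phi(mm):
        vecs = []
        for i in range(N - m):  # same template count for both lengths
            v = u[i:i + mm]
            mean = sum(v) / mm
            vecs.append([a - mean for a in v])
        total = 0.0
        for j, vj in enumerate(vecs):
            for i, vi in enumerate(vecs):
                if i == j:
                    continue
                d = max(abs(a - b) for a, b in zip(vi, vj))
                total += math.exp(-((d / r) ** n))
        return total / (len(vecs) * (len(vecs) - 1))
    return math.log(phi(m) / phi(m + 1))


def features_oracle(x):
    """One-line formulas for the 14 non-entropy features."""
    x = np.asarray(x, dtype=float)
    N = len(x)
    X = np.abs(np.fft.rfft(x))
    f = np.fft.rfftfreq(N, 1 / FS)
    P = X**2
    cum = np.cumsum(P)
    half_peak = P.max() / 2
    band = f[P >= half_peak]
    s = np.sign(x)
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    return {
        "mav": np.mean(np.abs(x)),
        "mavfd": np.mean(np.abs(x[1:] - x[:-1])),
        "mavsd": np.mean(np.abs(x[2:] - 2 * x[1:-1] + x[:-2])),
        "peak": x.max(),
        "rms": math.sqrt(np.mean(x**2)),
        "zc": float(np.sum((s[:-1] * s[1:]) < 0)),
        "fmed": f[np.argmax(cum >= 0.5 * P.sum())],
        "fmode": f[np.argmax(X)],
        "fmean": np.sum(X * f) / np.sum(X),
        "cf": (band[-1] - band[0]) / 2,
        "var": np.sum((x - x.mean()) ** 2) / (N - 1),
        "std": math.sqrt(np.sum((x - x.mean()) ** 2) / (N - 1)),
        "range": x.max() - x.min(),
        "intrange": (np.percentile(x, 75) - np.percentile(x, 25)) / 2,
    }


# ---------------------------------------------------------------------------
# Closed-form examples
# ---------------------------------------------------------------------------

class TestClosedForms:
    def test_amplitude_constant_signal(self):
        assert amplitude_features(np.array([2.0, 2, 2, 2])) == (2, 0, 0, 2, 2)

    def test_amplitude_alternating_signal(self):
        mav, mavfd, mavsd, peak, rms = amplitude_features(np.array([1.0, -1, 1, -1]))
        assert (mav, mavfd, mavsd, peak, rms) == (1, 2, 4, 1, 1)

    def test_variability_small_case(self):
        var, std, rng_, intr = variability_features(np.array([1.0, 2, 3, 4, 5]))
        assert var == pytest.approx(2.5)
        assert std == pytest.approx(math.sqrt(2.5))
        assert rng_ == 4
        assert intr == pytest.approx(1.0)

    def test_variability_constant(self):
        assert variability_features(np.full(10, 3.0)) == (0, 0, 0, 0)

    @pytest.mark.parametrize(
        "x,expected",
        [
            ([1.0, -1, 1, -1], 3),
            ([1.0, 1, 1, 1], 0),
            ([1.0, 0.0, -1.0], 1),  # zero carries previous (positive) sign
        ],
    )
    def test_zero_crossings(self, x, expected):
        assert zero_crossings(np.array(x)) == expected

    def test_zero_crossings_sinusoid(self):
        t = np.arange(int(FS)) / FS
        x = np.sin(2 * np.pi * 10 * t)  # 10 full periods
        assert abs(zero_crossings(x) - 20) <= 1

    def test_spectrum_peak_at_integer_tone(self):
        t = np.arange(512) / FS
        sp = spectrum(np.sin(2 * np.pi * 64 * t), FS)
        assert sp.frequencies[np.argmax(sp.magnitudes)] == 64.0

    def test_parseval(self, rng):
        x = rng.standard_normal(512)
        sp = spectrum(x, FS)
        two_sided = sp.power.copy()
        two_sided[1:-1] *= 2  # fold back the negative frequencies
        assert np.sum(two_sided) == pytest.approx(512 * np.sum(x**2), rel=1e-6)

    def test_pure_tone_frequency_features(self):
        t = np.arange(1024) / FS
        sp = spectrum(np.sin(2 * np.pi * 100 * t), FS)
        fmed, fmode, fmean, _cf = frequency_features(sp)
        assert fmed == pytest.approx(100, abs=0.5)
        assert fmode == pytest.approx(100, abs=0.5)
        assert fmean == pytest.approx(100, abs=2.0)

    def test_two_tone_mean_and_tie_rule(self):
        t = np.arange(1024) / FS
        x = np.sin(2 * np.pi * 60 * t) + np.sin(2 * np.pi * 140 * t)
        fmed, fmode, fmean, _ = frequency_features(spectrum(x, FS))
        assert fmean == pytest.approx(100, abs=2.0)
        assert fmode == pytest.approx(60, abs=0.5)  # equal peaks: lowest wins

    def test_flat_band_median_and_cf(self, rng):
        # construct an exactly band-limited 80-120 Hz signal
        n = 2048
        spec = np.zeros(n // 2 + 1, dtype=complex)
        f = np.fft.rfftfreq(n, 1 / FS)
        sel = (f >= 80) & (f <= 120)
        phases = rng.uniform(0, 2 * np.pi, sel.sum())
        spec[sel] = np.exp(1j * phases)
        x = np.fft.irfft(spec, n=n)
        fmed, _, _, cf = frequency_features(spectrum(x, FS))
        assert fmed == pytest.approx(100, abs=2.0)
        assert cf == pytest.approx(20, abs=1.0)

    def test_all_zero_spectrum_rejected(self):
        with pytest.raises(DegenerateInputError):
            frequency_features(spectrum(np.zeros(64), FS))


class TestEntropies:
    def test_constant_series_zero(self):
        x = np.full(50, 7.0)
        assert approximate_entropy(x) == 0.0
        assert fuzzy_entropy(x) == 0.0

    def test_apen_matches_oracle_periodic(self):
        x = np.array([1.0, 2.0] * 25)
        p = EntropyParams(m=2, r=0.5)
        assert approximate_entropy(x, p) == pytest.approx(
            apen_oracle(x, 2, 0.5), abs=1e-12
        )

    def test_apen_matches_oracle_random_and_ordering(self, rng):
        x = rng.uniform(size=300)
        p = EntropyParams(m=2, r=0.2)
        val = approximate_entropy(x, p)
        assert val == pytest.approx(apen_oracle(x, 2, 0.2), abs=1e-12)
        periodic = approximate_entropy(np.array([1.0, 2.0] * 150), p)
        assert val > periodic

    def test_fuzzyen_matches_oracle(self, rng):
        x = rng.standard_normal(120)
        p = EntropyParams(m=2, r=0.2, n=2)
        assert fuzzy_entropy(x, p) == pytest.approx(
            fuzzyen_oracle(x, 2, 0.2, 2), abs=1e-12
        )

    def test_fuzzyen_monotone_in_tolerance(self, rng):
        x = rng.standard_normal(200)
        vals = [fuzzy_entropy(x, EntropyParams(m=2, r=r)) for r in (0.1, 0.2, 0.4, 0.8)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            approximate_entropy(np.array([1.0, 2.0, 3.0]), EntropyParams(m=2))


class TestOracleSweep:
    def test_all_features_match_oracles_on_random_segments(self, rng):
        p = EntropyParams()
        for _ in range(50):
            x = rng.standard_normal(128) * rng.uniform(0.5, 50)
            got = feature_vector(x, FS, p)
            want = features_oracle(x)
            for name, val in want.items():
                assert got[name] == pytest.approx(val, rel=1e-9, abs=1e-12), name
            assert got["ap_en"] == pytest.approx(apen_oracle(x, p.m, p.r), abs=1e-12)
            assert got["fuzzy_en"] == pytest.approx(
                fuzzyen_oracle(x, p.m, p.r, p.n), abs=1e-12
            )


class TestScaleEquivariance:
    @settings(max_examples=20, deadline=None)
    @given(st.floats(min_value=0.1, max_value=100.0),
           st.integers(min_value=0, max_value=2**31 - 1))
    def test_scaling_laws(self, c, seed):
        x = np.random.default_rng(seed).standard_normal(96)
        a, b = feature_vector(x, FS), feature_vector(c * x, FS)
        for name in ("mav", "mavfd", "mavsd", "rms", "std", "range", "intrange", "peak"):
            assert b[name] == pytest.approx(c * a[name], rel=1e-9)
        assert b["var"] == pytest.approx(c**2 * a["var"], rel=1e-9)
        for name in ("zc", "fmed", "fmode", "fmean", "cf", "ap_en", "fuzzy_en"):
            assert b[name] == pytest.approx(a[name], rel=1e-7, abs=1e-9)


class TestFeatureTable:
    def test_row_and_column_counts(self, schedule, recording):
        from affectemg.windowing import WINDOW_CONDITIONS, extract_segments
        rec, _ = recording
        segs = extract_segments(rec, schedule, WINDOW_CONDITIONS["1-1"])
        both = extract_feature_table(segs, FS, channel_set="both")
        assert both.shape[0] == 20
        assert sum(c.startswith(("corr_", "zyg_")) for c in both.columns) == 32
        single = extract_feature_table(segs, FS, channel_set="corrugator")
        assert sum(c.startswith("corr_") for c in single.columns) == 16
        assert not any(c.startswith("zyg_") for c in single.columns)

    def test_input_order_invariance(self, schedule, recording):
        from affectemg.windowing import WINDOW_CONDITIONS, extract_segments
        rec, _ = recording
        segs = extract_segments(rec, schedule, WINDOW_CONDITIONS["1-1"])
        a = extract_feature_table(segs, FS)
        b = extract_feature_table(list(reversed(segs)), FS)
        import pandas as pd
        pd.testing.assert_frame_equal(a, b)

    def test_missing_channel_rejected(self, schedule, recording):
        from affectemg.windowing import WINDOW_CONDITIONS, extract_segments
        rec, _ = recording
        segs = [s for s in extract_segments(rec, schedule, WINDOW_CONDITIONS["1-1"])
                if s.channel == "corrugator"]
        with pytest.raises(ValueError):
            extract_feature_table(segs, FS, channel_set="both")
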