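"""Front-end tests: loading/resampling, framing, deltas, and a full
cross-check of the Rasta-PLP chain against an independently coded oracle."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.io import wavfile
from scipy.linalg import solve_toeplitz

from phonogroup import FrontEndConfig, append_deltas, extract_rasta_plp
from phonogroup.features import (
    bark_band_centers_hz,
    bark_filterbank,
    equal_loudness,
    frame_signal,
    frame_times,
    hz_to_bark,
    load_and_normalize,
    normalize_waveform,
    rasta_filter,
)


# ---------------------------------------------------------------------------
# loading / normalisation
# ---------------------------------------------------------------------------

def _write_wav(path, x, sr):
    wavfile.write(str(path), sr, (np.clip(x, -1, 1) * 32767).astype(np.int16))


class TestLoad:
    def test_downsample_and_peak_normalize(self, tmp_path):
        sr = 44100
        t = np.arange(sr) / sr
        _write_wav(tmp_path / "a.wav", 0.5 * np.sin(2 * np.pi * 440 * t), sr)
        y = load_and_normalize(tmp_path / "a.wav")
        assert y.shape[0] == 16000
        assert np.max(np.abs(y)) == pytest.approx(1.0, abs=1e-3)

    def test_all_zero_stays_zero(self, tmp_path):
        _write_wav(tmp_path / "z.wav", np.zeros(16000), 16000)
        y = load_and_normalize(tmp_path / "z.wav")
        assert np.all(y == 0.0)

    def test_identity_resample_preserves_count(self, tmp_path):
        x = np.sin(np.linspace(0, 20, 12345))
        _write_wav(tmp_path / "b.wav", x, 16000)
        assert load_and_normalize(tmp_path / "b.wav").shape[0] == 12345

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="below target"):
            normalize_waveform(np.zeros(8000), 8000)

    def test_multichannel_needs_explicit_channel(self, tmp_path):
        stereo = np.zeros((1000, 2), dtype=np.int16)
        wavfile.write(str(tmp_path / "s.wav"), 16000, stereo)
        with pytest.raises(ValueError, match="channel"):
            load_and_normalize(tmp_path / "s.wav")
        assert load_and_normalize(tmp_path / "s.wav", channel=0).shape[0] == 1000


# ---------------------------------------------------------------------------
# framing and deltas
# ---------------------------------------------------------------------------

class TestFraming:
    def test_frame_count_one_second(self):
        cfg = FrontEndConfig(F=10)
        frames = frame_signal(np.zeros(16000), cfg)
        assert frames.shape == (132, 240)  # floor((16000-240)/120)+1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            frame_signal(np.zeros(100), FrontEndConfig(F=10))

    def test_frame_times_centres(self):
        cfg = FrontEndConfig(F=10)
        t = frame_times(3, cfg)
        np.testing.assert_allclose(t, [0.0075, 0.015, 0.0225])

    def test_shift_tied_to_length(self):
        with pytest.raises(ValueError, match="frame_shift"):
            FrontEndConfig(F=10, frame_shift=0.01)


class TestDeltas:
    def test_constant_gives_zero(self):
        out = append_deltas(np.ones((20, 4)))
        np.testing.assert_array_equal(out[:, 4:], 0.0)

    def test_linear_ramp_slope_one(self):
        ramp = np.arange(30.0)[:, None]
        out = append_deltas(ramp)
        np.testing.assert_allclose(out[2:-2, 1], 1.0)   # interior delta
        np.testing.assert_allclose(out[4:-4, 2], 0.0, atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_convolution_oracle(self, seed):
        """Edge-replicated regression filter equals a hand-rolled loop."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(10, 3))

        def oracle_delta(m):
            n = m.shape[0]
            out = np.zeros_like(m)
            for t in range(n):
                for k in range(-2, 3):
                    out[t] += k * m[min(max(t + k, 0), n - 1)]
            return out / 10.0

        got = append_deltas(x)
        np.testing.assert_allclose(got[:, 3:6], oracle_delta(x), atol=1e-12)
        np.testing.assert_allclose(got[:, 6:9], oracle_delta(oracle_delta(x)), atol=1e-12)

    def test_width_is_three_f(self):
        for f in (10, 12, 14, 16, 18, 20):
            cfg = FrontEndConfig(F=f)
            x = np.random.default_rng(0).normal(size=8000)
            assert extract_rasta_plp(x, cfg).dim == 3 * f


# ---------------------------------------------------------------------------
# Rasta-PLP chain
# ---------------------------------------------------------------------------

def _oracle_plp(x, cfg):
    """Independently coded reference of the same published recipe: explicit
    loops, Toeplitz solve instead of Levinson, FFT-of-log-spectrum cepstrum
    instead of the recursion."""
    flen, hop = cfg.frame_samples, cfg.hop_samples
    n = (len(x) - flen) // hop + 1
    win = np.hamming(flen)
    nfft = int(2 ** np.ceil(np.log2(flen)))
    nfreqs = nfft // 2 + 1
    max_bark = 6.0 * np.arcsinh((cfg.sample_rate / 2) / 600.0)
    n_bands = int(np.ceil(max_bark)) + 1
    step = max_bark / (n_bands - 1)
    freqs = np.arange(nfreqs) * cfg.sample_rate / nfft
    binbark = 6.0 * np.arcsinh(freqs / 600.0)
    fb = np.zeros((n_bands, nfreqs))
    for b in range(n_bands):
        for j in range(nfreqs):
            lo = binbark[j] - b * step - 0.5
            hi = binbark[j] - b * step + 0.5
            fb[b, j] = 10.0 ** min(0.0, min(hi, -2.5 * lo))
    aspec = np.zeros((n, n_bands))
    for i in range(n):
        frame = x[i * hop : i * hop + flen] * win
        ps = np.abs(np.fft.rfft(frame, nfft)) ** 2
        aspec[i] = fb @ ps
    if cfg.rasta:
        logb = np.log(aspec + 1e-20)
        filt = np.zeros_like(logb)
        numer = np.array([0.2, 0.1, 0.0, -0.1, -0.2])
        for b in range(n_bands):
            xb = logb[:, b]
            yb = np.zeros(n)
            # FIR warm-up on the first 4 samples (output forced to 0), pole after
            for t in range(n):
                acc = 0.0
                for k in range(5):
                    if t - k >= 0:
                        acc += numer[k] * xb[t - k]
                if t < 4:
                    yb[t] = 0.0
                else:
                    acc += 0.94 * yb[t - 1]
                    yb[t] = acc
            filt[:, b] = yb
        aspec = np.exp(filt)
    cf = 600.0 * np.sinh(np.arange(n_bands) * step / 6.0)
    fsq = cf**2
    eql = (fsq / (fsq + 1.6e5)) ** 2 * ((fsq + 1.44e6) / (fsq + 9.61e6))
    static = np.zeros((n, cfg.F))
    for i in range(n):
        z = (aspec[i] * eql) ** 0.33
        z[0], z[-1] = z[1], z[-2]
        sym = np.concatenate([z, z[-2:0:-1]])
        r = np.fft.ifft(sym).real[: cfg.F + 1]
        a_tail = solve_toeplitz(r[: cfg.F], -r[1 : cfg.F + 1])
        a = np.concatenate([[1.0], a_tail])
        # cepstrum of the minimum-phase AR model via a dense log-spectrum IDFT
        m = 4096
        aw = np.fft.rfft(a, m)
        c = np.fft.irfft(-2.0 * np.log(np.abs(aw)), m)
        static[i] = c[1 : cfg.F + 1]
    return static


class TestRastaPlp:
    def test_matches_independent_oracle(self):
        """Production chain equals the independently coded reference
        implementation of the same recipe on seeded noise."""
        cfg = FrontEndConfig(F=10)
        x = np.random.default_rng(7).normal(size=4000)
        x /= np.max(np.abs(x))
        got = extract_rasta_plp(x, cfg)
        want = _oracle_plp(x, cfg)
        np.testing.assert_allclose(got.values[:, : cfg.F], want, atol=1e-6)

    def test_matches_oracle_without_rasta(self):
        cfg = FrontEndConfig(F=12, rasta=False)
        x = np.random.default_rng(8).normal(size=3000)
        got = extract_rasta_plp(x, cfg)
        np.testing.assert_allclose(got.values[:, : cfg.F], _oracle_plp(x, cfg), atol=1e-6)

    def test_deterministic(self):
        cfg = FrontEndConfig(F=12)
        x = np.random.default_rng(3).normal(size=5000)
        a = extract_rasta_plp(x, cfg)
        b = extract_rasta_plp(x, cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_rasta_gain_invariance_steady_state(self):
        """A constant gain shifts the log spectrum by a constant, which the
        RASTA band-pass removes once the filter has settled."""
        cfg = FrontEndConfig(F=10)
        x = np.random.default_rng(11).normal(size=16000)
        a = extract_rasta_plp(x, cfg).values
        b = extract_rasta_plp(20.0 * x, cfg).values
        assert np.max(np.abs(a[30:] - b[30:])) < 1e-6

    def test_stationary_input_settles_input_independent(self):
        """After settling, a stationary tone yields time-constant static
        coefficients that do not depend on the input level or frequency
        content's scale (the RASTA filter removes the constant log offset)."""
        cfg = FrontEndConfig(F=10)
        t = np.arange(16000) / 16000.0
        tone = np.sin(2 * np.pi * 1000 * t)
        a = extract_rasta_plp(tone, cfg).values[:, : cfg.F]
        b = extract_rasta_plp(0.01 * tone, cfg).values[:, : cfg.F]
        steady = a[60:]
        assert np.max(np.abs(steady - steady[0])) < 1e-6   # time-constant
        assert np.max(np.abs(a[60:] - b[60:])) < 1e-6      # level-invariant

    def test_rasta_changes_modulation_content(self):
        """RASTA must actually do something: on amplitude-modulated noise the
        filtered and unfiltered chains disagree."""
        rng = np.random.default_rng(11)
        x = rng.normal(size=8000) * (1.0 + 0.8 * np.sin(np.arange(8000) / 300.0))
        a = extract_rasta_plp(x, FrontEndConfig(F=10, rasta=True)).values
        b = extract_rasta_plp(x, FrontEndConfig(F=10, rasta=False)).values
        assert np.max(np.abs(a[:, :10] - b[:, :10])) > 0.01

    def test_filterbank_partition_like(self):
        fb = bark_filterbank(256, 16000)
        assert fb.shape[0] == int(np.ceil(hz_to_bark(8000))) + 1
        assert np.all(fb >= 0) and np.all(fb <= 1.0 + 1e-12)
        centers = bark_band_centers_hz(256, 16000, fb.shape[0])
        assert centers[0] == pytest.approx(0.0, abs=1e-9)
        assert centers[-1] == pytest.approx(8000.0, rel=1e-6)
        assert np.all(np.diff(equal_loudness(centers[1:])) != 0)

    def test_rasta_filter_removes_dc(self):
        x = np.full((200, 5), 3.7)
        y = rasta_filter(x)
        assert np.max(np.abs(y[50:])) < 1e-9
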