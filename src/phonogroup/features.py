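"""Acoustic front-end: 16 kHz waveform -> Rasta-PLP cepstra + Δ + ΔΔ.

The representation follows the classic perceptual linear prediction recipe
(Hermansky) with optional RASTA filtering of the log critical-band
trajectories:

  power spectrum -> Bark-scale critical-band integration -> RASTA band-pass
  of the log band energies -> equal-loudness pre-emphasis -> cube-root
  intensity-loudness compression -> order-F autoregressive fit (Levinson) ->
  cepstral recursion keeping c1..cF.

The static vector is c1..cF (c0, the energy term, is excluded so that the
feature dimension is exactly 3F after appending first and second
derivatives).  Frames are 15 ms with 50 % overlap and a Hamming window;
derivatives use a 5-tap linear-regression FIR with edge replication.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import lfilter, resample_poly

from .store import FrameMatrix

TARGET_SR = 16000

_F_GRID = (10, 12, 14, 16, 18, 20)


@dataclass(frozen=True)
class FrontEndConfig:
    """Front-end parameters.

    F is the PLP model order / number of static cepstral coefficients,
    restricted to the even grid {10, 12, ..., 20}.  The frame shift is tied
    to half the frame length (50 % overlap).
    """

    F: int = 12
    frame_length: float = 0.015
    frame_shift: float = 0.0075
    delta_filter_len: int = 5
    rasta: bool = True
    sample_rate: int = TARGET_SR

    def __post_init__(self) -> None:
        if self.F not in _F_GRID:
            raise ValueError(f"F must be one of {_F_GRID}, got {self.F}")
        if abs(self.frame_shift - self.frame_length / 2) > 1e-12:
            raise ValueError("frame_shift must be frame_length / 2")
        if self.delta_filter_len != 5 and self.delta_filter_len % 2 == 0:
            raise ValueError("delta_filter_len must be odd")

    @property
    def frame_samples(self) -> int:
        return int(round(self.frame_length * self.sample_rate))

    @property
    def hop_samples(self) -> int:
        return int(round(self.frame_shift * self.sample_rate))


# ---------------------------------------------------------------------------
# audio loading
# ---------------------------------------------------------------------------

def load_and_normalize(
    path: str | Path, target_sr: int = TARGET_SR, channel: int | None = None
) -> np.ndarray:
    """Load a WAV file, resample to ``target_sr`` and peak-normalise.

    Sources above the target rate are anti-alias filtered and polyphase
    resampled down; sources below it are rejected (upsampling clinical
    recordings is undefined behaviour).  Multi-channel audio requires an
    explicit ``channel``.  An all-zero signal is returned as zeros.
    """
    sr, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim == 2:
        if channel is None:
            raise ValueError(
                f"{path}: {data.shape[1]}-channel audio; pass channel= explicitly"
            )
        data = data[:, channel]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return normalize_waveform(data, sr, target_sr)


def normalize_waveform(
    x: np.ndarray, sr: int, target_sr: int = TARGET_SR
) -> np.ndarray:
    """Resample (down only) and peak-normalise an in-memory waveform."""
    if sr < target_sr:
        raise ValueError(f"source rate {sr} Hz below target {target_sr} Hz")
    if sr > target_sr:
        g = np.gcd(int(sr), int(target_sr))
        x = resample_poly(x, target_sr // g, sr // g)
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak > 0:
        x = x / peak
    return np.asarray(x, dtype=np.float64)


# ---------------------------------------------------------------------------
# PLP internals
# ---------------------------------------------------------------------------

def hz_to_bark(f):
    return 6.0 * np.arcsinh(np.asarray(f, dtype=np.float64) / 600.0)


def bark_filterbank(nfft: int, sr: int, n_bands: int | None = None) -> np.ndarray:
    """Trapezoidal (in log-magnitude) critical-band filterbank on the Bark
    scale, rows = bands, columns = FFT bins up to Nyquist."""
    n_freqs = nfft // 2 + 1
    max_bark = float(hz_to_bark(sr / 2))
    if n_bands is None:
        n_bands = int(np.ceil(max_bark)) + 1
    bin_bark = hz_to_bark(np.arange(n_freqs) * sr / nfft)
    step = max_bark / (n_bands - 1)
    centers = np.arange(n_bands) * step
    lo = bin_bark[None, :] - centers[:, None] - 0.5
    hi = bin_bark[None, :] - centers[:, None] + 0.5
    return 10.0 ** np.minimum(0.0, np.minimum(hi, -2.5 * lo))


def bark_band_centers_hz(nfft: int, sr: int, n_bands: int) -> np.ndarray:
    max_bark = float(hz_to_bark(sr / 2))
    centers = np.arange(n_bands) * max_bark / (n_bands - 1)
    return 600.0 * np.sinh(centers / 6.0)


def rasta_filter(log_bands: np.ndarray) -> np.ndarray:
    """RASTA band-pass along time (axis 0) of log band energies.

    Numerator 0.1*(2,1,0,-1,-2), pole at 0.94.  The first four output frames
    are zeroed: the filter is warmed up FIR-only on them (standard start-up
    handling), so early frames carry a transient.
    """
    numer = -np.arange(-2, 3, dtype=np.float64)
    numer /= np.sum(numer**2)
    denom = np.array([1.0, -0.94])
    x = log_bands
    n = min(4, x.shape[0])
    zi = np.zeros((numer.size - 1, x.shape[1]))
    y1, z = lfilter(numer, np.array([1.0]), x[:n], axis=0, zi=zi)
    y1 = 0.0 * y1
    if x.shape[0] > n:
        y2, _ = lfilter(numer, denom, x[n:], axis=0, zi=z)
    else:
        y2 = np.empty((0, x.shape[1]))
    return np.vstack([y1, y2])


def equal_loudness(f_hz: np.ndarray) -> np.ndarray:
    """Equal-loudness weighting at the band centre frequencies."""
    fsq = np.asarray(f_hz, dtype=np.float64) ** 2
    ftmp = fsq / (fsq + 1.6e5)
    return ftmp**2 * ((fsq + 1.44e6) / (fsq + 9.61e6))


def _levinson(r: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Levinson-Durbin: autocorrelation r[0..order] -> AR coefficients
    a[1..order] (prediction polynomial 1 + a1 z^-1 + ...) and residual."""
    a = np.zeros(order + 1)
    a[0] = 1.0
    err = float(r[0])
    floor = max(abs(err), 1.0) * 1e-14
    for i in range(1, order + 1):
        acc = r[i] + np.dot(a[1:i], r[i - 1 : 0 : -1])
        k = -acc / max(err, floor)
        a[1 : i + 1] = a[1 : i + 1] + k * a[i - 1 :: -1][: i]
        err *= 1.0 - k * k
        if err < floor:
            err = floor
    return a, float(err)


def _lpc_to_cepstrum(a: np.ndarray, n_cep: int) -> np.ndarray:
    """Cepstrum c1..c_ncep of the minimum-phase AR model 1/A(z)."""
    p = len(a) - 1
    c = np.zeros(n_cep + 1)
    for n in range(1, n_cep + 1):
        acc = -a[n] if n <= p else 0.0
        for k in range(1, n):
            if n - k <= p:
                acc -= (k / n) * c[k] * a[n - k]
        c[n] = acc
    return c[1:]


def frame_signal(x: np.ndarray, config: FrontEndConfig) -> np.ndarray:
    """Slice a waveform into overlapping Hamming-windowed frames.

    N = floor((samples - frame_length*sr) / (frame_shift*sr)) + 1.
    """
    flen, hop = config.frame_samples, config.hop_samples
    if x.shape[0] < flen:
        raise ValueError(f"waveform of {x.shape[0]} samples shorter than one frame")
    n = (x.shape[0] - flen) // hop + 1
    idx = np.arange(flen)[None, :] + hop * np.arange(n)[:, None]
    return x[idx] * np.hamming(flen)[None, :]


def extract_rasta_plp(x: np.ndarray, config: FrontEndConfig) -> FrameMatrix:
    """Full front-end: waveform -> N x 3F Rasta-PLP + Δ + ΔΔ matrix."""
    frames = frame_signal(x, config)
    nfft = int(2 ** np.ceil(np.log2(config.frame_samples)))
    spec = np.abs(np.fft.rfft(frames, nfft, axis=1)) ** 2
    fb = bark_filterbank(nfft, config.sample_rate)
    aspec = spec @ fb.T
    if config.rasta:
        aspec = np.exp(rasta_filter(np.log(aspec + 1e-20)))
    n_bands = aspec.shape[1]
    eql = equal_loudness(bark_band_centers_hz(nfft, config.sample_rate, n_bands))
    z = (aspec * eql[None, :]) ** 0.33
    # edge bands replicate their neighbours (the filterbank's edge bands are
    # half-filters and would otherwise bias the AR fit)
    z[:, 0] = z[:, 1]
    z[:, -1] = z[:, -2]
    # inverse DFT of the symmetrised auditory spectrum -> autocorrelation
    sym = np.concatenate([z, z[:, -2:0:-1]], axis=1)
    r = np.fft.ifft(sym, axis=1).real[:, : config.F + 1]
    static = np.empty((frames.shape[0], config.F))
    for i in range(frames.shape[0]):
        a, _ = _levinson(r[i], config.F)
        static[i] = _lpc_to_cepstrum(a, config.F)
    values = append_deltas(static, config.delta_filter_len)
    times = frame_times(frames.shape[0], config)
    return FrameMatrix(values, times)


def frame_times(n: int, config: FrontEndConfig) -> np.ndarray:
    """Frame-centre times: i*shift + length/2."""
    return np.arange(n) * config.frame_shift + config.frame_length / 2


def append_deltas(static: np.ndarray, filter_len: int = 5) -> np.ndarray:
    """Append Δ and ΔΔ: antisymmetric linear-regression FIR, taps
    proportional to (-h..h) normalised by Σk², with edge replication."""
    static = np.asarray(static, dtype=np.float64)
    if static.ndim != 2 or static.shape[0] < 1:
        raise ValueError("static must be a non-empty N x F matrix")
    h = filter_len // 2
    norm = 2.0 * sum(k * k for k in range(1, h + 1))

    def one_delta(m: np.ndarray) -> np.ndarray:
        pad = np.pad(m, ((h, h), (0, 0)), mode="edge")
        n = m.shape[0]
        out = np.zeros_like(m)
        for k in range(-h, h + 1):
            out += k * pad[h + k : h + k + n]
        return out / norm

    d = one_delta(static)
    dd = one_delta(d)
    return np.hstack([static, d, dd])
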