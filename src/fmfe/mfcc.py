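"""Mel-frequency cepstral coefficients and fusion with matching features.

Standard speech-processing pipeline: 25 ms Hamming-windowed frames with a
10 ms hop, one-sided magnitude spectrum per frame, a 26-filter triangular Mel
filterbank spanning 0..sample_rate/2, natural-log filterbank energies, a
type-II DCT, coefficients 1..n_coeff kept and averaged across frames.

The Mel scale is ``mel_constant * log10(1 + f/700)``; the conventional
constant 2595 is the default, with 2585 available as a configuration switch
for literal reproducibility of sources that print that value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct

from .core import FmfeFeatureVector
from .errors import ValidationError
from .signal_io import PcgSignal

MEL_CONSTANT_STANDARD = 2595.0
MEL_CONSTANT_PRINTED = 2585.0


@dataclass
class MfccConfig:
    frame_ms: float = 25.0
    hop_ms: float = 10.0
    n_filters: int = 26
    n_coeff: int = 13
    mel_constant: float = MEL_CONSTANT_STANDARD
    log_floor: float = 1e-10          # floor for silent filter outputs
    aggregate: str = "mean"           # mean | mean+std

    def validate(self) -> None:
        if self.frame_ms <= 0 or self.hop_ms <= 0:
            raise ValidationError("frame and hop must be positive")
        if self.n_filters < 1:
            raise ValidationError("need at least one Mel filter")
        if not 1 <= self.n_coeff <= self.n_filters - 1:
            raise ValidationError(
                "n_coeff must be in 1..n_filters-1 (coefficient 0 is dropped)")
        if self.aggregate not in ("mean", "mean+std"):
            raise ValidationError(f"unknown aggregate {self.aggregate!r}")


@dataclass
class MfccFeatures:
    coefficients: np.ndarray
    names: list[str] = field(default_factory=list)
    signal_id: str = ""

    def __len__(self) -> int:
        return self.coefficients.size


def mel_scale(frequency_hz, mel_constant: float = MEL_CONSTANT_STANDARD):
    """Mel value of a frequency: mel_constant * log10(1 + f/700)."""
    f = np.asarray(frequency_hz, dtype=np.float64)
    if np.any(f < 0):
        raise ValidationError("frequency must be nonnegative")
    out = mel_constant * np.log10(1.0 + f / 700.0)
    return float(out) if np.isscalar(frequency_hz) else out


def mel_inverse(mel_value, mel_constant: float = MEL_CONSTANT_STANDARD):
    m = np.asarray(mel_value, dtype=np.float64)
    out = 700.0 * (10.0 ** (m / mel_constant) - 1.0)
    return float(out) if np.isscalar(mel_value) else out


def mel_filterbank(n_filters: int, n_fft: int, sample_rate: float,
                   mel_constant: float = MEL_CONSTANT_STANDARD) -> np.ndarray:
    """Triangular filters evaluated at the one-sided FFT bin frequencies.

    Centre frequencies are uniformly spaced on the configured Mel scale
    between 0 and sample_rate/2; each filter rises linearly (in Hz) from its
    lower edge to its centre and falls to its upper edge, peak amplitude 1.
    """
    edges_mel = np.linspace(0.0, mel_scale(sample_rate / 2.0, mel_constant),
                            n_filters + 2)
    edges_hz = mel_inverse(edges_mel, mel_constant)
    bin_freqs = np.arange(n_fft // 2 + 1) * (sample_rate / n_fft)
    bank = np.zeros((n_filters, bin_freqs.size))
    for m in range(n_filters):
        lo, mid, hi = edges_hz[m], edges_hz[m + 1], edges_hz[m + 2]
        rising = (bin_freqs - lo) / (mid - lo)
        falling = (hi - bin_freqs) / (hi - mid)
        bank[m] = np.clip(np.minimum(rising, falling), 0.0, None)
    return bank


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def compute_mfcc(signal: PcgSignal, config: MfccConfig | None = None) -> MfccFeatures:
    """Frame-aggregated MFCC vector of one signal.

    Silent frames are handled by flooring the filterbank energies at
    ``log_floor`` before the log, so no exception is raised.
    """
    config = config or MfccConfig()
    config.validate()
    sr = signal.sample_rate
    frame_len = int(round(config.frame_ms * sr / 1000.0))
    hop = int(round(config.hop_ms * sr / 1000.0))
    if frame_len < 1 or hop < 1:
        raise ValidationError("frame/hop shorter than one sample")
    x = signal.samples
    if x.size < frame_len:
        raise ValidationError("signal shorter than one analysis frame")
    n_frames = 1 + (x.size - frame_len) // hop
    window = np.hamming(frame_len)
    n_fft = _next_pow2(frame_len)
    bank = mel_filterbank(config.n_filters, n_fft, sr, config.mel_constant)
    coeffs = np.empty((n_frames, config.n_coeff))
    for t in range(n_frames):
        frame = x[t * hop:t * hop + frame_len] * window
        magnitude = np.abs(np.fft.rfft(frame, n_fft))
        energies = np.maximum(bank @ magnitude, config.log_floor)
        cepstrum = dct(np.log(energies), type=2, norm="ortho")
        coeffs[t] = cepstrum[1:config.n_coeff + 1]
    if config.aggregate == "mean":
        values = coeffs.mean(axis=0)
        names = [f"MFCC.{i + 1}" for i in range(config.n_coeff)]
    else:
        values = np.concatenate([coeffs.mean(axis=0), coeffs.std(axis=0)])
        names = ([f"MFCC.{i + 1}" for i in range(config.n_coeff)]
                 + [f"MFCC.sd.{i + 1}" for i in range(config.n_coeff)])
    return MfccFeatures(values, names, signal_id=signal.id)


def fuse_features(fmfe: FmfeFeatureVector,
                  mfcc: MfccFeatures) -> tuple[np.ndarray, list[str]]:
    """Concatenate matching features with MFCCs (matching block first)."""
    if fmfe.signal_id and mfcc.signal_id and fmfe.signal_id != mfcc.signal_id:
        raise ValidationError(
            f"feature id mismatch: {fmfe.signal_id!r} vs {mfcc.signal_id!r}")
    values = np.concatenate([fmfe.values, mfcc.coefficients])
    names = fmfe.names + list(mfcc.names)
    return values, names
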