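"""Seeded synthetic five-class phonocardiogram generator.

Each signal is three concatenated cardiac cycles at 8 kHz (0.8 s nominal
cycle, 2.4 s total, matching the 2-3 s three-cycle recordings the method
targets).  A cycle is built from:

* an S1 burst: a 40 Hz tone under a Gaussian envelope near the cycle start,
* an S2 burst: a 60 Hz tone under a narrower envelope at 35% of the cycle,
* a class-specific murmur: band-pass filtered noise in the auscultatory
  timing window of the pathology (AR: diastolic decrescendo 80-250 Hz;
  MR: holosystolic 100-400 Hz; MS: diastolic rumble 40-150 Hz; MVP:
  mid-systolic click plus late-systolic murmur 120-350 Hz; NHS: none),
* broadband measurement noise.

Murmur and noise levels are set relative to the S1+S2 energy
(``murmur_snr_db`` = 10 dB and ``noise_snr_db`` = 20 dB by default).  Cycle
lengths are jittered by +/-2% and padded/truncated back to nominal length,
which is exactly the cycle-to-cycle inconsistency fuzzy matching is meant to
tolerate.  A fixed seed reproduces the dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import ValidationError
from .signal_io import LABELS, PcgSignal

#: per-class auscultatory signature: murmur pass-band (Hz), timing window
#: (fractions of the cycle), murmur envelope shape, and the textbook changes
#: to the heart sounds themselves (accentuated S1 in mitral stenosis, soft S1
#: in mitral regurgitation, soft S2 in aortic regurgitation, the mid-systolic
#: click of mitral valve prolapse)
MURMUR_SPECS: dict[str, dict] = {
    "NHS": {},
    "AR": {"band": (80.0, 250.0), "window": (0.42, 0.92), "shape": "decrescendo",
           "s2_gain": 0.65},
    "MR": {"band": (100.0, 400.0), "window": (0.11, 0.31), "shape": "flat",
           "s1_gain": 0.6},
    "MS": {"band": (40.0, 150.0), "window": (0.50, 0.95), "shape": "crescendo",
           "s1_gain": 1.4},
    "MVP": {"band": (120.0, 350.0), "window": (0.22, 0.31), "shape": "crescendo",
            "click_fraction": 0.20, "click_freq_hz": 300.0},
}


@dataclass
class SyntheticConfig:
    sample_rate: int = 8000
    cycle_seconds: float = 0.8
    n_cycles: int = 3
    s1_freq_hz: float = 40.0
    s2_freq_hz: float = 60.0
    s2_offset_fraction: float = 0.35
    s1_amp: float = 1.0
    s2_amp: float = 0.7
    s1_width_s: float = 0.012        # Gaussian envelope sigma
    s2_width_s: float = 0.010
    amp_jitter: float = 0.05         # relative sd of burst amplitudes
    murmur_snr_db: float = 10.0      # S1+S2 energy over murmur energy
    noise_snr_db: float = 20.0       # S1+S2 energy over broadband noise
    cycle_jitter_fraction: float = 0.02
    output_gain: float = 0.5         # headroom for 16-bit WAV export
    murmur_specs: dict = field(default_factory=lambda: dict(MURMUR_SPECS))

    def validate(self) -> None:
        nyquist = self.sample_rate / 2.0
        for cls, spec in self.murmur_specs.items():
            band = spec.get("band")
            if band and not (0 < band[0] < band[1] < nyquist):
                raise ValidationError(f"murmur band for {cls} exceeds Nyquist")
        for f in (self.s1_freq_hz, self.s2_freq_hz):
            if not 0 < f < nyquist:
                raise ValidationError("burst frequency exceeds Nyquist")
        if not 0 <= self.s2_offset_fraction < 1:
            raise ValidationError("s2_offset_fraction must be in [0, 1)")
        if not 0 <= self.cycle_jitter_fraction < 1:
            raise ValidationError("cycle_jitter_fraction must be in [0, 1)")
        if self.cycle_seconds * self.sample_rate < 3:
            raise ValidationError("cycle too short")

    @property
    def cycle_samples(self) -> int:
        return int(round(self.cycle_seconds * self.sample_rate))


def _gaussian_burst(t: np.ndarray, center: float, sigma: float,
                    freq: float, amp: float) -> np.ndarray:
    envelope = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return amp * envelope * np.sin(2.0 * np.pi * freq * (t - center))


def _murmur_envelope(n: int, start: int, stop: int, shape: str) -> np.ndarray:
    env = np.zeros(n)
    width = max(stop - start, 1)
    ramp = np.linspace(0.0, 1.0, width)
    if shape == "flat":
        body = np.ones(width)
        edge = max(width // 8, 1)
        body[:edge] = np.linspace(0.0, 1.0, edge)
        body[-edge:] = np.linspace(1.0, 0.0, edge)
    elif shape == "decrescendo":
        body = np.exp(-3.0 * ramp)
    elif shape == "crescendo":
        body = 0.3 + 0.7 * ramp
    else:
        raise ValidationError(f"unknown murmur shape {shape!r}")
    env[start:stop] = body
    return env


def generate_cycle(cls: str, config: SyntheticConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """One synthetic cardiac cycle of nominal length ``config.cycle_samples``.

    The cycle is laid out on a jittered grid, then padded with zeros or
    truncated back to the nominal length; broadband noise covers the full
    nominal duration.
    """
    if cls not in LABELS:
        raise ValidationError(f"unknown class {cls!r}")
    config.validate()
    sr = config.sample_rate
    n_nom = config.cycle_samples
    jitter = rng.uniform(-config.cycle_jitter_fraction,
                         config.cycle_jitter_fraction)
    n = max(int(round(n_nom * (1.0 + jitter))), 3)
    t = np.arange(n) / sr
    duration = n / sr

    spec = config.murmur_specs.get(cls, {})
    s1_amp = (config.s1_amp * spec.get("s1_gain", 1.0)
              * (1.0 + config.amp_jitter * rng.standard_normal()))
    s2_amp = (config.s2_amp * spec.get("s2_gain", 1.0)
              * (1.0 + config.amp_jitter * rng.standard_normal()))
    base = _gaussian_burst(t, 0.07 * duration, config.s1_width_s,
                           config.s1_freq_hz, s1_amp)
    base += _gaussian_burst(t, config.s2_offset_fraction * duration,
                            config.s2_width_s, config.s2_freq_hz, s2_amp)
    base_energy = float(np.sum(base * base))

    cycle = base.copy()
    if spec.get("band") and np.isfinite(config.murmur_snr_db):
        lo, hi = spec["band"]
        sos = butter(4, [lo, hi], btype="bandpass", fs=sr, output="sos")
        murmur = sosfiltfilt(sos, rng.standard_normal(n))
        start, stop = (int(round(frac * n)) for frac in spec["window"])
        murmur *= _murmur_envelope(n, start, stop, spec["shape"])
        energy = float(np.sum(murmur * murmur))
        if energy > 0:
            target = base_energy * 10.0 ** (-config.murmur_snr_db / 10.0)
            cycle += murmur * np.sqrt(target / energy)
        if "click_fraction" in spec:
            click_amp = 0.8 * s1_amp
            cycle += _gaussian_burst(t, spec["click_fraction"] * duration,
                                     0.004, spec["click_freq_hz"], click_amp)

    if n >= n_nom:
        out = cycle[:n_nom]
    else:
        out = np.concatenate([cycle, np.zeros(n_nom - n)])
    if np.isfinite(config.noise_snr_db):
        noise_power = (base_energy / n_nom) * 10.0 ** (-config.noise_snr_db / 10.0)
        out = out + np.sqrt(noise_power) * rng.standard_normal(n_nom)
    return config.output_gain * out


def generate_signal(cls: str, config: SyntheticConfig,
                    rng: np.random.Generator, signal_id: str = "") -> PcgSignal:
    """Three jittered cycles concatenated into one labeled recording."""
    cycles = [generate_cycle(cls, config, rng) for _ in range(config.n_cycles)]
    return PcgSignal(np.concatenate(cycles), config.sample_rate,
                     label=cls, id=signal_id or cls)


def generate_dataset(n_per_class: int, config: SyntheticConfig | None = None,
                     seed: int = 0) -> tuple[list[PcgSignal], PcgSignal]:
    """A balanced labeled dataset plus a dedicated normal reference signal.

    The reference (id ``NHS-reference``) plays the role of the designated
    normal recording used to build the shared mutual-matching template.
    Deterministic given ``seed``.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    signals: list[PcgSignal] = []
    for cls in LABELS:
        for i in range(n_per_class):
            signals.append(generate_signal(cls, config, rng,
                                           signal_id=f"{cls}-{i:04d}"))
    reference = generate_signal("NHS", config, rng, signal_id="NHS-reference")
    return signals, reference
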