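"""Cycle splitting and template construction.

Each recording holds exactly three cardiac cycles; no beat detection is
performed (the method's point is that it needs no heart-sound segmentation),
so a signal is cut into three consecutive equal-length thirds.  Templates
average the three cycles elementwise:

* time domain (self):      m = (h1 + h2 + h3) / 3
* frequency domain (self): m = (|FFT(h1)| + |FFT(h2)| + |FFT(h3)|) / 3
* frequency domain (mutual): the same frequency template, built once from a
  designated normal reference recording and shared by every test signal.

Spectra are one-sided moduli (bins 0 .. floor(n/2)), so matching does not
double-count the symmetric half of the DFT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .signal_io import PcgSignal

N_CYCLES = 3


@dataclass
class CycleSet:
    """The three cycles h1, h2, h3 of one recording (equal lengths)."""

    h1: np.ndarray
    h2: np.ndarray
    h3: np.ndarray
    domain_tag: str = "time"

    def __post_init__(self) -> None:
        self.h1 = np.asarray(self.h1, dtype=np.float64)
        self.h2 = np.asarray(self.h2, dtype=np.float64)
        self.h3 = np.asarray(self.h3, dtype=np.float64)
        lengths = {self.h1.size, self.h2.size, self.h3.size}
        if lengths == {0}:
            raise ValidationError("cycles are empty")
        if len(lengths) != 1:
            raise ValidationError("cycles must have equal lengths")
        if self.domain_tag not in ("time", "frequency"):
            raise ValidationError(f"unknown domain tag {self.domain_tag!r}")

    @property
    def cycles(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.h1, self.h2, self.h3

    @property
    def cycle_length(self) -> int:
        return self.h1.size


@dataclass
class Template:
    """A one-cycle reference ``m`` in the time or frequency domain."""

    values: np.ndarray
    domain_tag: str
    source_tag: str = "self"       # self | mutual
    origin_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size == 0:
            raise ValidationError("template is empty")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("template contains non-finite values")
        if self.domain_tag == "frequency" and np.any(self.values < 0):
            raise ValidationError("frequency template must be nonnegative moduli")

    def __len__(self) -> int:
        return self.values.size


def split_cycles(signal: PcgSignal) -> CycleSet:
    """Cut a signal into three consecutive equal thirds of floor(n/3) samples.

    Up to two trailing samples are discarded.
    """
    n = signal.samples.size
    if n < N_CYCLES:
        raise ValidationError("signal too short to split into three cycles")
    third = n // N_CYCLES
    x = signal.samples
    return CycleSet(x[:third], x[third:2 * third], x[2 * third:3 * third],
                    domain_tag="time")


def time_template(cycles: CycleSet, origin_id: str = "") -> Template:
    """Average the three time-domain cycles elementwise."""
    if cycles.domain_tag != "time":
        raise ValidationError("time_template expects time-domain cycles")
    values = (cycles.h1 + cycles.h2 + cycles.h3) / 3.0
    return Template(values, "time", "self", origin_id)


def magnitude_spectrum(cycle: np.ndarray) -> np.ndarray:
    """One-sided DFT modulus: |FFT(x)[k]| for k = 0 .. floor(n/2)."""
    cycle = np.asarray(cycle, dtype=np.float64)
    if cycle.size == 0:
        raise ValidationError("empty cycle")
    return np.abs(np.fft.rfft(cycle))


def freq_template(cycles: CycleSet, origin_id: str = "",
                  source_tag: str = "self") -> Template:
    """Average the one-sided magnitude spectra of the three cycles."""
    if cycles.domain_tag != "time":
        raise ValidationError("freq_template expects time-domain cycles")
    spectra = [magnitude_spectrum(h) for h in cycles.cycles]
    values = (spectra[0] + spectra[1] + spectra[2]) / 3.0
    return Template(values, "frequency", source_tag, origin_id)


def mutual_template(reference: PcgSignal) -> Template:
    """Frequency template of the designated normal reference recording.

    Every signal is matched against this one template in the mutual
    dimension; cycle spectra of test signals are resampled to its length
    before matching.
    """
    if reference is None:
        raise ValidationError("mutual matching requires a reference signal")
    return freq_template(split_cycles(reference), origin_id=reference.id,
                         source_tag="mutual")


def resample_spectrum(spectrum: np.ndarray, target_length: int) -> np.ndarray:
    """Linearly resample a one-sided spectrum onto ``target_length`` bins."""
    spectrum = np.asarray(spectrum, dtype=np.float64)
    if target_length < 1:
        raise ValidationError("target_length must be >= 1")
    if spectrum.size == target_length:
        return spectrum.copy()
    src = np.linspace(0.0, 1.0, spectrum.size)
    dst = np.linspace(0.0, 1.0, target_length)
    return np.interp(dst, src, spectrum)
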