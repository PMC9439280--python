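"""Audio and tabular I/O for phonocardiogram (PCG) work.

A recording is held as a :class:`PcgSignal`: a mono float array, its sample
rate (8000 Hz canonical for this dataset), a diagnostic label and an id.
Feature tables are plain :class:`pandas.DataFrame` objects written as CSV
with 12 significant digits, which round-trips through :func:`read_feature_table`
to better than 1e-10.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import ValidationError

#: The five diagnostic classes: normal heart sound, aortic regurgitation,
#: mitral regurgitation, mitral stenosis, mitral valve prolapse.
LABELS = ("NHS", "AR", "MR", "MS", "MVP")
UNKNOWN = "UNKNOWN"

_PCM_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31}


@dataclass
class PcgSignal:
    """A labeled, sampled heart-sound recording (the target signal ``s``)."""

    samples: np.ndarray
    sample_rate: int = 8000
    label: str = UNKNOWN
    id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValidationError("PcgSignal samples must be one-dimensional")
        if self.samples.size < 3:
            raise ValidationError(
                "PcgSignal needs at least 3 samples (three nonempty cycles)"
            )
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")
        if self.label not in LABELS and self.label != UNKNOWN:
            raise ValidationError(f"unknown label {self.label!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def scaled(self, factor: float) -> "PcgSignal":
        return PcgSignal(self.samples * factor, self.sample_rate, self.label, self.id)


def read_wav(path: str | os.PathLike, target_rate: int | None = 8000,
             label: str = UNKNOWN, signal_id: str | None = None) -> PcgSignal:
    """Read a PCM WAV file as a mono :class:`PcgSignal`.

    Multi-channel audio is averaged to mono.  If the header rate differs from
    ``target_rate`` the signal is resampled by polyphase rational resampling
    (deterministic, no external state).  Pass ``target_rate=None`` to keep the
    header rate.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / non-PCM
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValidationError(f"empty audio in {path}")
    if data.dtype in _PCM_SCALE:
        x = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    else:
        x = data.astype(np.float64)
    if x.ndim == 2:
        x = x.mean(axis=1)
    if target_rate is not None and rate != target_rate:
        frac = Fraction(int(target_rate), int(rate))
        x = resample_poly(x, frac.numerator, frac.denominator)
        rate = int(target_rate)
    return PcgSignal(x, int(rate), label=label,
                     id=signal_id if signal_id is not None else path.stem)


def write_wav(signal: PcgSignal, path: str | os.PathLike) -> None:
    """Write a signal as 16-bit PCM WAV (amplitudes clipped to [-1, 1])."""
    x = np.clip(signal.samples, -1.0, 1.0)
    pcm = np.clip(np.round(x * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(Path(path), signal.sample_rate, pcm)


def write_feature_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a feature table as CSV (header row, 12 significant digits)."""
    if table is None or len(table) == 0:
        raise ValidationError("feature table is empty")
    numeric = table.select_dtypes(include=[np.number])
    if numeric.isna().any().any() or not np.all(np.isfinite(numeric.to_numpy())):
        raise ValidationError("feature table contains undefined values")
    try:
        table.to_csv(Path(path), index=False, float_format="%.12g")
    except OSError as exc:
        raise IOError(f"cannot write feature table to {path}: {exc}") from exc


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    try:
        return pd.read_csv(Path(path))
    except OSError as exc:
        raise IOError(f"cannot read feature table from {path}: {exc}") from exc


@dataclass
class ManifestEntry:
    id: str
    path: str
    label: str


def build_manifest(directory: str | os.PathLike) -> pd.DataFrame:
    """List WAV files under ``directory`` with labels parsed from subdirectory names.

    Layout: one directory per class (``NHS/``, ``AR/`` ...); files directly in
    ``directory`` get label UNKNOWN.  Returns a DataFrame with columns
    ``id, path, label`` sorted by id.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise IOError(f"not a directory: {directory}")
    rows: list[ManifestEntry] = []
    for wav in sorted(directory.rglob("*.wav")):
        parent = wav.parent.name
        label = parent if parent in LABELS else UNKNOWN
        rows.append(ManifestEntry(wav.stem, str(wav), label))
    return pd.DataFrame([r.__dict__ for r in rows], columns=["id", "path", "label"])


def load_manifest(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = {"id", "path", "label"} - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    return df


def read_manifest_signals(manifest: pd.DataFrame,
                          target_rate: int | None = 8000) -> list[PcgSignal]:
    """Read every WAV listed in a manifest into memory."""
    return [read_wav(row.path, target_rate=target_rate, label=row.label,
                     signal_id=str(row.id))
            for row in manifest.itertuples(index=False)]
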