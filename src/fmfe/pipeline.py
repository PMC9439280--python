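"""End-to-end feature extraction over a collection of signals."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import FmfeConfig, extract_fmfe
from .errors import ValidationError
from .mfcc import MfccConfig, compute_mfcc, fuse_features
from .signal_io import PcgSignal
from .templating import Template, mutual_template


def extract_feature_table(signals: list[PcgSignal],
                          reference: PcgSignal | Template | None = None,
                          config: FmfeConfig | None = None,
                          with_mfcc: bool = False,
                          mfcc_config: MfccConfig | None = None) -> pd.DataFrame:
    """One feature row per signal: id, label, then the named feature columns.

    ``reference`` supplies the shared normal template for mutual matching
    (either a signal, split and averaged here, or a ready-made frequency
    template).  With ``with_mfcc`` the MFCC block is appended after the
    matching features.
    """
    if not signals:
        raise ValidationError("no signals to extract features from")
    config = config or FmfeConfig()
    if isinstance(reference, PcgSignal):
        mutual = mutual_template(reference)
    else:
        mutual = reference
    rows = []
    columns: list[str] | None = None
    for signal in signals:
        vector = extract_fmfe(signal, config, mutual=mutual)
        if with_mfcc:
            values, names = fuse_features(vector, compute_mfcc(signal, mfcc_config))
        else:
            values, names = vector.values, vector.names
        if columns is None:
            columns = names
        elif names != columns:
            raise ValidationError("inconsistent feature columns across signals")
        rows.append([signal.id, signal.label, *values.tolist()])
    frame = pd.DataFrame(rows, columns=["id", "label", *columns])
    if not np.all(np.isfinite(frame[columns].to_numpy(float))):
        raise ValidationError("non-finite feature values produced")
    return frame
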