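"""Positional and length features: relative position i/L and log-length."""

from __future__ import annotations

import numpy as np
import pandas as pd


def positional_and_length(seq: str) -> pd.DataFrame:
    """Per-residue table with relative position i/L (1-based, in (0, 1])
    and the natural-log sequence length (constant across residues)."""
    length = len(seq)
    if length < 1:
        raise ValueError("empty sequence")
    positions = np.arange(1, length + 1)
    return pd.DataFrame(
        {
            "relative_position": positions / length,
            "log_length": np.full(length, np.log(length)),
        },
        index=pd.RangeIndex(1, length + 1, name="position"),
    )
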