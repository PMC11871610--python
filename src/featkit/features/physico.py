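"""Per-residue physicochemical property features.

The packaged table ships 25 published scales (hydropathy, polarity,
bulkiness, polarizability, volume, flexibility, secondary-structure
propensities, charge, ...), each covering all 20 standard residues; scale
names carry a literature tag and live in a versioned JSON data file.
"""

from __future__ import annotations

import pandas as pd

from ..sequence_io import STANDARD_AA
from ._data import physico_scales


def available_scales() -> list[str]:
    return sorted(physico_scales())


def get_scale(name: str) -> dict[str, float]:
    scales = physico_scales()
    if name not in scales:
        raise KeyError(f"unknown scale {name!r}; see available_scales()")
    return dict(scales[name])


def physico_features(seq: str, selection: list[str] | None = None,
                     normalize: bool = False) -> pd.DataFrame:
    """len(seq) x n_scales table of physicochemical values.

    ``normalize=True`` min-max rescales each scale to [0, 1] using the
    scale's own range over the 20 standard residues, so the mapping does not
    depend on the particular sequence.
    """
    scales = physico_scales()
    names = sorted(scales) if selection is None else list(selection)
    for name in names:
        if name not in scales:
            raise KeyError(f"unknown scale {name!r}")
    seq = seq.upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in STANDARD_AA:
            raise ValueError(f"non-standard residue {ch!r} at position {pos}")
    data = {}
    for name in names:
        table = scales[name]
        if normalize:
            lo = min(table.values())
            hi = max(table.values())
            span = hi - lo or 1.0
            data[name] = [(table[ch] - lo) / span for ch in seq]
        else:
            data[name] = [table[ch] for ch in seq]
    return pd.DataFrame(data, index=pd.RangeIndex(1, len(seq) + 1, name="position"))
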