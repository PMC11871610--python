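"""Secondary-structure one-hot features (3-state H/E/C)."""

from __future__ import annotations

import numpy as np

from .rsa import parse_dssp

#: DSSP 8-state to 3-state collapse: helices (H, G, I) -> H,
#: strands/bridges (E, B) -> E, everything else (coil, turn, bend) -> C.
SS8_TO_SS3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C", "-": "C", " ": "C", "P": "C",
}

SS3_ORDER = "HEC"


def collapse_ss8(ss: str) -> str:
    """Collapse a string of DSSP 8-state letters to 3 states."""
    out = []
    for ch in ss:
        up = ch.upper() if ch != " " else ch
        if up not in SS8_TO_SS3:
            raise ValueError(f"unknown secondary-structure letter {ch!r}")
        out.append(SS8_TO_SS3[up])
    return "".join(out)


def ss_onehot(ss: str | None = None, dssp_path=None) -> np.ndarray:
    """(L, 3) one-hot matrix over H/E/C from an SS string or a DSSP file.

    Accepts 8-state or 3-state letters; every row sums to 1.
    """
    if (ss is None) == (dssp_path is None):
        raise ValueError("provide exactly one of ss or dssp_path")
    if dssp_path is not None:
        ss = "".join(row.ss for row in parse_dssp(dssp_path))
    ss3 = collapse_ss8(ss)
    mat = np.zeros((len(ss3), 3))
    for i, ch in enumerate(ss3):
        mat[i, SS3_ORDER.index(ch)] = 1.0
    return mat
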