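"""One-hot encoding of pre-computed 3di structural-alphabet sequences.

3di is a 20-letter alphabet describing local backbone geometry, emitted by
structure-search tools; featkit consumes the strings, it does not generate
them.
"""

from __future__ import annotations

import numpy as np

#: The 3di alphabet reuses the 20 amino-acid letters.
THREEDI_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def threedi_onehot(seq_3di: str) -> np.ndarray:
    """(L, 20) one-hot matrix over the 3di alphabet; input case-insensitive."""
    seq = seq_3di.upper()
    mat = np.zeros((len(seq), len(THREEDI_ALPHABET)))
    for i, ch in enumerate(seq):
        idx = THREEDI_ALPHABET.find(ch)
        if idx < 0:
            raise ValueError(f"letter {ch!r} at position {i + 1} outside the 3di alphabet")
        mat[i, idx] = 1.0
    return mat


def threedi_decode(mat: np.ndarray) -> str:
    """Argmax decode back to a 3di string (inverse of :func:`threedi_onehot`)."""
    return "".join(THREEDI_ALPHABET[i] for i in np.asarray(mat).argmax(axis=1))
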