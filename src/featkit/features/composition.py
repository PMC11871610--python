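"""k-mer amino-acid composition: monopeptide (20), dipeptide (400) and
tripeptide (8000) frequency vectors.

Vectors are serialised in fixed lexicographic k-mer order over the 20-letter
standard alphabet so feature columns are stable across proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from ..sequence_io import STANDARD_AA


@dataclass
class CompositionVector:
    k: int
    kmers: tuple[str, ...]
    values: np.ndarray

    @property
    def dimension(self) -> int:
        return len(self.kmers)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.kmers, self.values.tolist()))


def kmer_order(k: int) -> tuple[str, ...]:
    """All 20**k k-mers in lexicographic order over the standard alphabet."""
    return tuple("".join(p) for p in product(sorted(STANDARD_AA), repeat=k))


def kmer_composition(seq: str, k: int, skip_nonstandard: bool = False) -> CompositionVector:
    """Frequency of every k-mer: count / number of k-length windows.

    Non-standard letters raise by default, naming the offending position;
    with ``skip_nonstandard=True`` windows containing them are dropped and
    frequencies renormalised over the remaining windows.
    """
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    seq = seq.upper()
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    standard = set(STANDARD_AA)
    if not skip_nonstandard:
        for pos, ch in enumerate(seq, start=1):
            if ch not in standard:
                raise ValueError(
                    f"non-standard residue {ch!r} at position {pos}; "
                    "pass skip_nonstandard=True to drop affected windows"
                )
    kmers = kmer_order(k)
    index = {m: i for i, m in enumerate(kmers)}
    counts = np.zeros(len(kmers))
    n_windows = 0
    for i in range(len(seq) - k + 1):
        window = seq[i:i + k]
        if window in index:
            counts[index[window]] += 1
            n_windows += 1
    if n_windows == 0:
        raise ValueError("no valid k-mer windows after skipping non-standard residues")
    return CompositionVector(k=k, kmers=kmers, values=counts / n_windows)
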