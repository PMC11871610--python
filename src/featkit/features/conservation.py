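"""Column-wise conservation scoring of an MSA by Jensen-Shannon divergence.

Each column's observed amino-acid distribution p is compared with a
background distribution q (BLOSUM62 marginal frequencies by default) using

    JSD(p, q) = H(lam*p + (1-lam)*q) - lam*H(p) - (1-lam)*H(q)

with Shannon entropy H in bits and lam = 0.5, which bounds the score to
[0, 1].  Gaps are excluded from p but tracked as the column gap fraction g:
the raw divergence is down-weighted by (1 - g), columns with g > 0.5 score
0, and a sliding mean over +/- `window` columns (clipped at the alignment
ends) incorporates sequence context, following common practice in
conservation scoring of functional sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..sequence_io import STANDARD_AA, Alignment
from ._data import background_freqs

_AA_INDEX = {aa: i for i, aa in enumerate(sorted(STANDARD_AA))}


@dataclass
class ConservationProfile:
    scores: np.ndarray          # final windowed scores, one per column
    raw_scores: np.ndarray      # gap-penalised, un-windowed scores
    gap_fractions: np.ndarray
    background: np.ndarray
    lam: float
    window: int

    def __len__(self):
        return len(self.scores)


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _background_vector(background) -> np.ndarray:
    if background is None or isinstance(background, str):
        table = background_freqs(background or "blosum62")
        vec = np.array([table[aa] for aa in sorted(STANDARD_AA)])
    elif isinstance(background, dict):
        vec = np.array([background[aa] for aa in sorted(STANDARD_AA)])
    else:
        vec = np.asarray(background, dtype=float)
        if vec.shape != (20,):
            raise ValueError("background vector must have 20 entries")
    if (vec < 0).any() or vec.sum() <= 0:
        raise ValueError("background must be a non-negative distribution")
    return vec / vec.sum()


def column_distribution(column: str) -> tuple[np.ndarray, float]:
    """Observed AA distribution of one column (gaps excluded) and its gap
    fraction.  Letters outside the 20-letter alphabet (X, B, ...) are
    ignored for both."""
    counts = np.zeros(20)
    gaps = 0
    considered = 0
    for ch in column.upper():
        if ch == "-":
            gaps += 1
            considered += 1
        elif ch in _AA_INDEX:
            counts[_AA_INDEX[ch]] += 1
            considered += 1
    gap_fraction = gaps / considered if considered else 1.0
    total = counts.sum()
    p = counts / total if total > 0 else counts
    return p, gap_fraction


def jsd_score(p: np.ndarray, q: np.ndarray, lam: float = 0.5) -> float:
    """Jensen-Shannon divergence (bits) between a column distribution and
    the background; 0 when the distributions coincide, 1 at maximum."""
    m = lam * p + (1.0 - lam) * q
    return _entropy_bits(m) - lam * _entropy_bits(p) - (1.0 - lam) * _entropy_bits(q)


def jsd_conservation(aln: Alignment, background=None, lam: float = 0.5,
                     window: int = 3) -> ConservationProfile:
    """Per-column conservation profile of an alignment.

    Returns a :class:`ConservationProfile` whose ``scores`` are the
    window-averaged, gap-penalised divergences in [0, 1] bits.
    """
    if not len(aln):
        raise ValueError("empty alignment")
    if not 0.0 < lam < 1.0:
        raise ValueError("lam must lie in (0, 1)")
    if window < 0:
        raise ValueError("window must be >= 0")
    q = _background_vector(background)
    width = aln.width
    raw = np.zeros(width)
    gaps = np.zeros(width)
    for c in range(width):
        column = "".join(rec.seq[c] for rec in aln)
        p, g = column_distribution(column)
        gaps[c] = g
        if p.sum() == 0:
            warnings.warn(f"column {c + 1}: no non-gap residues; score 0")
            raw[c] = 0.0
        elif g > 0.5:
            raw[c] = 0.0
        else:
            raw[c] = (1.0 - g) * jsd_score(p, q, lam)
    if window == 0:
        scores = raw.copy()
    else:
        scores = np.empty(width)
        for c in range(width):
            lo = max(0, c - window)
            hi = min(width, c + window + 1)
            scores[c] = raw[lo:hi].mean()
    return ConservationProfile(scores=scores, raw_scores=raw, gap_fractions=gaps,
                               background=q, lam=lam, window=window)
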