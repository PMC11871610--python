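"""Evolutionary profile features from PSI-BLAST ASCII PSSM files.

The classic ASCII layout has a two-line header naming the 20 score columns
followed by one body row per query residue: position, residue letter, 20
log-odds scores, 20 weighted observed percentages (and, in full files, two
trailing statistics that are ignored here).  Only parsing is done; running
PSI-BLAST is the user's job.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..errors import FormatError


@dataclass
class PSSMProfile:
    letters: str                 # query residue per row
    scores: np.ndarray           # (L, 20) log-odds
    percentages: np.ndarray      # (L, 20) observed percentages
    columns: tuple[str, ...]     # AA order of the 20 score columns


def parse_pssm(path, transform: str = "raw", query: str | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM into per-residue 20-vectors.

    transform: ``raw`` keeps log-odds; ``sigmoid`` squashes each score
    through 1/(1+exp(-x)) into (0, 1) for ML use.  When *query* is given the
    body residue letters must match it; a mismatch names the first bad row.
    """
    if transform not in ("raw", "sigmoid"):
        raise ValueError(f"unknown transform {transform!r}")
    lines = Path(path).read_text().splitlines()
    columns: tuple[str, ...] | None = None
    letters: list[str] = []
    scores: list[list[float]] = []
    pcts: list[list[float]] = []
    for lineno, line in enumerate(lines, start=1):
        fields = line.split()
        if not fields:
            continue
        if columns is None:
            # header line: 40 single-letter column labels (or 20 repeated twice)
            if all(len(f) == 1 and f.isalpha() for f in fields) and len(fields) in (20, 40):
                columns = tuple(fields[:20])
            continue
        if not fields[0].isdigit():
            continue  # trailing statistics block
        if len(fields) < 2 or not fields[1].isalpha():
            raise FormatError(f"{path}:{lineno}: expected 'pos letter ...' body row")
        numbers = fields[2:]
        if len(numbers) not in (40, 42):
            raise FormatError(
                f"{path}:{lineno}: expected 40 profile columns, found {len(numbers)}"
            )
        try:
            values = [float(v) for v in numbers[:40]]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric profile value") from exc
        letters.append(fields[1].upper())
        scores.append(values[:20])
        pcts.append(values[20:40])
    if columns is None or not letters:
        raise FormatError(f"{path}: not a PSI-BLAST ASCII PSSM")
    letter_str = "".join(letters)
    if query is not None:
        qnorm = query.upper()
        if len(qnorm) != len(letter_str):
            raise FormatError(
                f"{path}: PSSM has {len(letter_str)} rows but query has {len(qnorm)}"
            )
        for i, (a, b) in enumerate(zip(letter_str, qnorm), start=1):
            if a != b:
                raise FormatError(
                    f"{path}: row {i}: PSSM residue {a!r} does not match query {b!r}"
                )
    score_mat = np.asarray(scores, dtype=float)
    if transform == "sigmoid":
        score_mat = 1.0 / (1.0 + np.exp(-score_mat))
    return PSSMProfile(letters=letter_str, scores=score_mat,
                       percentages=np.asarray(pcts, dtype=float), columns=columns)
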