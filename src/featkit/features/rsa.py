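"""Relative solvent accessibility from classic DSSP output.

DSSP reports the absolute accessible surface area (ACC, A^2) per residue;
dividing by the residue type's maximum reference area and clamping to [0, 1]
gives the relative solvent accessibility (RSA).  The packaged reference
table uses theoretical Gly-X-Gly maxima by default; an empirical table is
available by flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from ..errors import FormatError
from ._data import max_asa_table


@dataclass
class DSSPRow:
    chain: str
    number: int
    icode: str
    aa: str
    ss: str
    acc: float


@dataclass
class RSARecord:
    chain: str
    number: int
    aa: str
    asa: float
    max_asa: float
    rsa: float
    clamped: bool = False


def parse_dssp(path) -> list[DSSPRow]:
    """Parse the fixed-column residue table of a classic DSSP file.

    Chain-break rows (AA '!') are skipped.
    """
    lines = Path(path).read_text().splitlines()
    rows: list[DSSPRow] = []
    in_body = False
    for line in lines:
        if line.lstrip().startswith("#  RESIDUE"):
            in_body = True
            continue
        if not in_body or len(line) < 38:
            continue
        aa = line[13]
        if aa == "!":
            continue
        try:
            number = int(line[5:10])
            acc = float(line[34:38])
        except ValueError as exc:
            raise FormatError(f"malformed DSSP row: {line!r}") from exc
        rows.append(DSSPRow(chain=line[11].strip() or " ", number=number,
                            icode=line[10].strip(), aa=aa.upper(),
                            ss=line[16], acc=acc))
    if not rows:
        raise FormatError(f"{path}: no DSSP residue rows found")
    return rows


def rsa_from_dssp(path, max_asa: str | dict = "theoretical",
                  permissive: bool = False) -> list[RSARecord]:
    """RSA records for every residue row of a DSSP file.

    rsa = min(ACC / maxASA[residue], 1.0).  ACC above the reference maximum
    is clamped and flagged.  Residue letters absent from the reference table
    (e.g. 'X') raise unless ``permissive``, which skips them with a warning.
    """
    table = max_asa_table(max_asa) if isinstance(max_asa, str) else dict(max_asa)
    out: list[RSARecord] = []
    for row in parse_dssp(path):
        if row.aa not in table:
            if permissive:
                warnings.warn(f"residue {row.aa!r} at {row.chain}/{row.number} "
                              "absent from max ASA table; skipped")
                continue
            raise KeyError(f"residue {row.aa!r} at {row.chain}/{row.number} "
                           "absent from max ASA table")
        ratio = row.acc / table[row.aa]
        out.append(RSARecord(chain=row.chain, number=row.number, aa=row.aa,
                             asa=row.acc, max_asa=table[row.aa],
                             rsa=min(ratio, 1.0), clamped=ratio > 1.0))
    return out
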