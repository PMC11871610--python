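"""Synthetic inputs with analytically known ground truth.

Every generator is deterministic under its seed and computes its truth
tables at generation time from the coordinates/columns it writes, using
plain arithmetic — never the analysis modules whose outputs the fixtures are
meant to check.  Geometry is deliberately unphysical (poly-alanine blocks on
a lattice): the point is controlled distances and labels, not plausible
conformations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import STANDARD_AA, Alignment, SequenceRecord, write_fasta

# Alanine-like residue template: (atom name, element, dx, dy, dz).  CB is
# present so heavy-atom and CA metrics differ measurably.
_RESIDUE_TEMPLATE = (
    ("N", "N", -1.2, 0.6, 0.0),
    ("CA", "C", 0.0, 0.0, 0.0),
    ("C", "C", 1.2, 0.6, 0.0),
    ("O", "O", 1.2, 1.8, 0.0),
    ("CB", "C", 0.0, -1.5, 0.5),
)
_TEMPLATE_MAX_Y = max(a[3] for a in _RESIDUE_TEMPLATE)   # 1.8 (the O atom)
_RES_SPACING = 3.8


@dataclass
class ComplexFixture:
    pdb_path: Path
    #: analytic cross-chain distances: chain_i num_i chain_j num_j
    #: heavy_distance ca_distance
    truth: pd.DataFrame
    interface_distance: float
    n_interface: int
    chain_lengths: dict[str, int] = field(default_factory=dict)


def _pdb_line(rec: str, serial: int, name: str, res: str, chain: str,
              resseq: int, x: float, y: float, z: float, element: str,
              altloc: str = " ", occ: float = 1.0) -> str:
    name_field = f" {name:<3}" if len(name) < 4 else name[:4]
    return (f"{rec:<6}{serial:>5} {name_field}{altloc}{res:>3} {chain}"
            f"{resseq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
            f"          {element:>2}")


def make_pdb_complex(out_dir, seed: int = 0, chain_length: int = 10,
                     n_interface: int = 3, interface_distance: float = 4.0,
                     far_offset: float = 20.0, jitter: float = 0.0,
                     add_waters: int = 0, add_unk: bool = False,
                     add_mse: bool = False, add_altloc: bool = False,
                     name: str = "complex") -> ComplexFixture:
    """Two poly-alanine chains with a designed interface.

    The first *n_interface* residues of chains A and B face each other so
    the closest heavy-atom pair of each aligned residue pair sits at exactly
    *interface_distance* Angstrom (chain B is the mirror image of chain A,
    so the two O atoms are vertically aligned); the remaining chain-B
    residues are displaced a further *far_offset* away.  Optional defects
    (waters, an UNK residue, an MSE HETATM, alternate locations) exercise
    structure QC.  With ``jitter > 0`` coordinates get uniform noise and the
    truth table simply reflects the perturbed geometry.
    """
    if interface_distance <= 0:
        raise ValueError("interface_distance must be positive")
    if n_interface > chain_length:
        raise ValueError("n_interface cannot exceed chain_length")
    rng = np.random.default_rng(seed)
    shift = interface_distance + 2 * _TEMPLATE_MAX_Y
    atoms = []  # (chain, resseq, resname, [(name, elem, x, y, z)], hetatm)

    def residue_atoms(base_x, base_y, mirror):
        out = []
        for aname, elem, dx, dy, dz in _RESIDUE_TEMPLATE:
            y = base_y - dy if mirror else base_y + dy
            z = -dz if mirror else dz
            x = base_x + dx
            if jitter > 0:
                x += rng.uniform(-jitter, jitter)
                y += rng.uniform(-jitter, jitter)
                z += rng.uniform(-jitter, jitter)
            # round to the PDB file's 3-decimal precision so the analytic
            # truth table and the written coordinates are the same numbers
            out.append((aname, elem, round(x, 3), round(y, 3), round(z, 3)))
        return out

    for i in range(chain_length):
        atoms.append(("A", i + 1, "ALA",
                      residue_atoms(i * _RES_SPACING, 0.0, mirror=False), False))
    for i in range(chain_length):
        extra = 0.0 if i < n_interface else far_offset
        atoms.append(("B", i + 1, "ALA",
                      residue_atoms(i * _RES_SPACING, shift + extra, mirror=True),
                      False))
    if add_unk:
        atoms.append(("A", chain_length + 1, "UNK",
                      residue_atoms(chain_length * _RES_SPACING, 0.0, False), False))
    if add_mse:
        atoms.append(("B", chain_length + 1, "MSE",
                      residue_atoms(chain_length * _RES_SPACING,
                                    shift + far_offset, True), True))

    lines = []
    serial = 1
    for chain, resseq, resname, atom_list, het in atoms:
        rec = "HETATM" if het else "ATOM"
        for aname, elem, x, y, z in atom_list:
            if add_altloc and aname == "CB" and chain == "A" and resseq == 1:
                lines.append(_pdb_line(rec, serial, aname, resname, chain,
                                       resseq, x, y, z, elem, altloc="A",
                                       occ=0.4))
                serial += 1
                lines.append(_pdb_line(rec, serial, aname, resname, chain,
                                       resseq, x + 0.3, y, z, elem,
                                       altloc="B", occ=0.6))
                serial += 1
            else:
                lines.append(_pdb_line(rec, serial, aname, resname, chain,
                                       resseq, x, y, z, elem))
                serial += 1
    for w in range(add_waters):
        lines.append(_pdb_line("HETATM", serial, "O", "HOH", "W", w + 1,
                               -10.0 - 5 * w, -10.0, 0.0, "O"))
        serial += 1
    lines.append("END")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_path = out_dir / f"{name}.pdb"
    pdb_path.write_text("\n".join(lines) + "\n")

    # Analytic truth: plain double loop over the written coordinates.
    by_res: dict[tuple[str, int], list[tuple[str, float, float, float]]] = {}
    for chain, resseq, resname, atom_list, het in atoms:
        if het or resname == "UNK":
            continue  # truth covers the QC-clean complex
        coords = atom_list
        if add_altloc and chain == "A" and resseq == 1:
            # altloc collapse keeps the higher-occupancy B conformer
            coords = [(an, el, x + (0.3 if an == "CB" else 0.0), y, z)
                      for an, el, x, y, z in atom_list]
        by_res[(chain, resseq)] = [(an, x, y, z) for an, el, x, y, z in coords]
    rows = []
    a_keys = sorted(k for k in by_res if k[0] == "A")
    b_keys = sorted(k for k in by_res if k[0] == "B")
    for ka in a_keys:
        for kb in b_keys:
            heavy = min(
                math.dist(pa[1:], pb[1:])
                for pa in by_res[ka] for pb in by_res[kb]
            )
            ca_a = next(p for p in by_res[ka] if p[0] == "CA")
            ca_b = next(p for p in by_res[kb] if p[0] == "CA")
            rows.append((ka[0], ka[1], kb[0], kb[1], heavy,
                         math.dist(ca_a[1:], ca_b[1:])))
    truth = pd.DataFrame(rows, columns=["chain_i", "num_i", "chain_j",
                                        "num_j", "heavy_distance",
                                        "ca_distance"])
    return ComplexFixture(pdb_path=pdb_path, truth=truth,
                          interface_distance=interface_distance,
                          n_interface=n_interface,
                          chain_lengths={"A": chain_length, "B": chain_length})


@dataclass
class MSAFixture:
    alignment: Alignment
    #: per-column class: 'conserved' | 'background' | 'gappy'
    column_classes: list[str]
    fasta_path: Path | None = None


def make_msa(seed: int = 0, depth: int = 20, n_conserved: int = 5,
             n_background: int = 10, n_gappy: int = 3,
             background: dict[str, float] | None = None,
             out_path=None, shuffle: bool = True) -> MSAFixture:
    """Alignment whose columns are drawn from known conservation classes.

    conserved: one residue repeated down the column; background: i.i.d.
    draws from the background distribution (BLOSUM62 marginals by default);
    gappy: >50% gaps with background draws elsewhere.
    """
    if depth < 2:
        raise ValueError("depth must be >= 2")
    from .features._data import background_freqs

    rng = np.random.default_rng(seed)
    bg = background or background_freqs("blosum62")
    letters = sorted(STANDARD_AA)
    probs = np.array([bg[aa] for aa in letters], dtype=float)
    probs = probs / probs.sum()

    classes = (["conserved"] * n_conserved + ["background"] * n_background
               + ["gappy"] * n_gappy)
    if shuffle:
        rng.shuffle(classes)
    columns = []
    for cls in classes:
        if cls == "conserved":
            aa = letters[rng.integers(len(letters))]
            columns.append([aa] * depth)
        elif cls == "background":
            columns.append(list(rng.choice(letters, size=depth, p=probs)))
        else:
            n_gaps = int(math.ceil(depth * rng.uniform(0.6, 0.9)))
            col = list(rng.choice(letters, size=depth, p=probs))
            gap_rows = rng.choice(depth, size=n_gaps, replace=False)
            for r in gap_rows:
                col[r] = "-"
            columns.append(col)
    records = []
    for r in range(depth):
        seq = "".join(col[r] for col in columns)
        records.append(SequenceRecord(id=f"seq{r + 1}", seq=seq))
    aln = Alignment(records=records)
    fasta_path = None
    if out_path is not None:
        fasta_path = Path(out_path)
        write_fasta(records, fasta_path)
    return MSAFixture(alignment=aln, column_classes=classes,
                      fasta_path=fasta_path)


@dataclass
class UniProtFixture:
    dat_path: Path
    #: accession -> {"entry_name", "taxon", "secondary", "length",
    #:               "TRANSMEM": [(s,e)...], "BINDING": [...], "pdb": [...]}
    truth: dict[str, dict]


def _sq_lines(seq: str) -> list[str]:
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i:i + 60]
        groups = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append("     " + groups)
    return lines


def make_uniprot_dat(out_dir, seed: int = 0, n_entries: int = 3,
                     length_range: tuple[int, int] = (80, 160),
                     with_fuzzy: bool = False, taxa: tuple[str, ...] = ("9606",),
                     name: str = "synthetic_sprot") -> UniProtFixture:
    """UniProtKB flat-text file with known TRANSMEM/BINDING features,
    secondary accessions and PDB cross-references."""
    rng = np.random.default_rng(seed)
    letters = sorted(STANDARD_AA)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blocks = []
    truth: dict[str, dict] = {}
    for k in range(n_entries):
        acc = f"P{(10000 + 97 * seed + k) % 90000 + 10000}"
        secondary = f"Q{(20000 + 31 * seed + k) % 90000 + 10000}"
        entry_name = f"SYN{k + 1}_HUMAN"
        taxon = taxa[k % len(taxa)]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(letters, size=length))
        tm1 = (int(rng.integers(5, 15)), 0)
        tm1 = (tm1[0], tm1[0] + int(rng.integers(15, 25)))
        tm2_start = tm1[1] + int(rng.integers(10, 20))
        tm2 = (tm2_start, min(tm2_start + int(rng.integers(15, 25)), length))
        binding = int(rng.integers(tm1[1] + 1, tm2[0]))
        pdb_id = f"{rng.integers(1, 9)}SY{chr(65 + k % 26)}"
        lines = [
            f"ID   {entry_name:<24}Reviewed;{length:>12} AA.",
            f"AC   {acc}; {secondary};",
            "DT   01-JAN-2024, integrated into UniProtKB/Swiss-Prot.",
            f"DE   RecName: Full=Synthetic test protein {k + 1};",
            "OS   Homo sapiens (Human).",
            f"OX   NCBI_TaxID={taxon};",
            f"DR   PDB; {pdb_id}; X-ray; 2.00 A; A=1-{length}.",
            f"FT   TRANSMEM        {tm1[0]}..{tm1[1]}",
            "FT                   /note=\"Helical\"",
            f"FT   TRANSMEM        {tm2[0]}..{tm2[1]}",
            "FT                   /note=\"Helical\"",
            f"FT   BINDING         {binding}",
        ]
        if with_fuzzy:
            lines.append("FT   TRANSMEM        <1..5")
        lines.append(f"SQ   SEQUENCE   {length} AA;  {length * 110} MW;"
                     "  0000000000000000 CRC64;")
        lines.extend(_sq_lines(seq))
        lines.append("//")
        blocks.append("\n".join(lines))
        truth[acc] = {
            "entry_name": entry_name, "taxon": taxon, "secondary": secondary,
            "length": length, "TRANSMEM": [tm1, tm2],
            "BINDING": [(binding, binding)], "pdb": [pdb_id],
        }
    dat_path = out_dir / f"{name}.dat"
    dat_path.write_text("\n".join(blocks) + "\n")
    return UniProtFixture(dat_path=dat_path, truth=truth)
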