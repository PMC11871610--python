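"""PDB structure parsing, quality control, and chain-sequence extraction.

Parsing is fixed-column (PDB format columns 13-16 atom name, 18-20 residue
name, 22 chain id, 23-26 residue number, 27 insertion code, 31-54
coordinates): insertion codes and negative residue numbers make whitespace
splitting unsafe.  Alternate locations are collapsed to the highest-occupancy
conformer (ties broken by altloc letter) so a parse is deterministic.

Quality control follows the common machine-learning dataset rules: HETATM
atoms are excluded (with a configurable allowlist for modified residues such
as selenomethionine, MSE -> M), and unknown residues (UNK) either fail the
structure (strict) or are dropped with a report entry (permissive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import FormatError, QCError
from .sequence_io import SequenceRecord

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: HETATM residues accepted by default and their one-letter mapping.
DEFAULT_HET_ALLOWLIST = {"MSE": "M"}


@dataclass
class Atom:
    name: str
    element: str
    coords: tuple[float, float, float]
    is_hetatm: bool = False
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    author_number: int
    insertion_code: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.author_number, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class QCReport:
    had_hetatm: bool = False
    unk_positions: list[tuple[str, int]] = field(default_factory=list)
    nonstandard_mapped: list[tuple[str, str]] = field(default_factory=list)
    altloc_collapsed: int = 0

    @property
    def passed(self) -> bool:
        return not self.unk_positions

    def rows(self, pdb_id: str):
        """QC report as (pdb_id, chain, rule, detail) rows for TSV output."""
        out = []
        if self.had_hetatm:
            out.append((pdb_id, "*", "hetatm_removed", "yes"))
        for chain, num in self.unk_positions:
            out.append((pdb_id, chain, "unk_residue", str(num)))
        for name, letter in self.nonstandard_mapped:
            out.append((pdb_id, "*", "nonstandard_mapped", f"{name}->{letter}"))
        if self.altloc_collapsed:
            out.append((pdb_id, "*", "altloc_collapsed", str(self.altloc_collapsed)))
        return out


@dataclass
class StructureModel:
    pdb_id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    qc_report: QCReport | None = None
    altloc_collapsed: int = 0

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise KeyError(f"chain {chain_id!r} not in structure "
                           f"(has {sorted(self.chains)})")
        return self.chains[chain_id]

    def residues(self):
        for residues in self.chains.values():
            yield from residues


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else ""


def parse_pdb(path, model_index: int = 1) -> StructureModel:
    """Parse ATOM/HETATM records of one MODEL from a fixed-column PDB file."""
    path = Path(path)
    current_model = 1
    in_wanted_model = True
    # (chain, resseq, icode) -> residue; atom name -> list of altloc candidates
    residues: dict[tuple, Residue] = {}
    candidates: dict[tuple, dict[str, list[Atom]]] = {}
    order: list[tuple] = []
    n_atom_lines = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            fields = line.split()
            current_model = int(fields[1]) if len(fields) > 1 else current_model + 1
            in_wanted_model = current_model == model_index
            continue
        if rec.startswith("ENDMDL"):
            in_wanted_model = False
            continue
        if rec not in ("ATOM  ", "HETATM") or not in_wanted_model:
            continue
        n_atom_lines += 1
        try:
            name = line[12:16].strip()
            altloc = line[16].strip()
            res_name = line[17:20].strip()
            chain_id = line[21].strip() or " "
            resseq = int(line[22:26])
            icode = line[26].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}:{lineno}: malformed PDB record: {exc}") from exc
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _guess_element(name)
        atom = Atom(name=name, element=element, coords=(x, y, z),
                    is_hetatm=rec == "HETATM", occupancy=occupancy, altloc=altloc)
        key = (chain_id, resseq, icode)
        if key not in residues:
            residues[key] = Residue(chain_id=chain_id, author_number=resseq,
                                    insertion_code=icode, res_name=res_name)
            candidates[key] = {}
            order.append(key)
        candidates[key].setdefault(name, []).append(atom)
    if n_atom_lines == 0:
        raise FormatError(f"{path}: no ATOM/HETATM records in model {model_index}")

    collapsed = 0
    for key in order:
        res = residues[key]
        for name, alts in candidates[key].items():
            if len(alts) > 1:
                collapsed += len(alts) - 1
                alts = sorted(alts, key=lambda a: (-a.occupancy, a.altloc))
            res.atoms.append(alts[0])

    chains: dict[str, list[Residue]] = {}
    for key in order:
        res = residues[key]
        chains.setdefault(res.chain_id, []).append(res)
    return StructureModel(pdb_id=path.stem, chains=chains,
                          altloc_collapsed=collapsed)


def qc_structure(model: StructureModel, mode: str = "strict",
                 het_allowlist: dict[str, str] | None = None
                 ) -> tuple[StructureModel, QCReport]:
    """Apply HETATM exclusion and unknown-residue (UNK) rules.

    strict: allowlisted HETATM residues are kept (converted to ATOM and
    recorded in ``nonstandard_mapped``), every other HETATM atom is removed,
    and any UNK residue raises :class:`QCError` carrying its positions.
    permissive: UNK residues are dropped with a report entry instead.

    Idempotent: running QC on an already-clean model changes nothing.
    """
    if mode not in ("strict", "permissive"):
        raise ValueError(f"unknown QC mode {mode!r}")
    allow = DEFAULT_HET_ALLOWLIST if het_allowlist is None else het_allowlist
    report = QCReport(altloc_collapsed=model.altloc_collapsed)
    chains: dict[str, list[Residue]] = {}
    for chain_id, residues in model.chains.items():
        kept: list[Residue] = []
        for res in residues:
            if res.res_name == "UNK":
                report.unk_positions.append((chain_id, res.author_number))
                continue
            atoms = []
            for atom in res.atoms:
                if atom.is_hetatm:
                    report.had_hetatm = True
                    if res.res_name in allow:
                        atom = Atom(name=atom.name, element=atom.element,
                                    coords=atom.coords, is_hetatm=False,
                                    occupancy=atom.occupancy, altloc=atom.altloc)
                    else:
                        continue
                atoms.append(atom)
            if not atoms:
                continue
            if res.res_name in allow and res.res_name not in THREE_TO_ONE:
                pair = (res.res_name, allow[res.res_name])
                if pair not in report.nonstandard_mapped:
                    report.nonstandard_mapped.append(pair)
            kept.append(Residue(chain_id=res.chain_id,
                                author_number=res.author_number,
                                insertion_code=res.insertion_code,
                                res_name=res.res_name, atoms=atoms))
        if kept:
            chains[chain_id] = kept
    if mode == "strict" and report.unk_positions:
        raise QCError(
            f"{model.pdb_id}: unknown residues at {report.unk_positions}",
            unk_positions=report.unk_positions,
        )
    clean = StructureModel(pdb_id=model.pdb_id, chains=chains,
                           qc_report=report, altloc_collapsed=0)
    return clean, report


def extract_sequence(model: StructureModel, chain_id: str, strict: bool = True,
                     het_allowlist: dict[str, str] | None = None
                     ) -> tuple[SequenceRecord, list[int]]:
    """One-letter sequence of a chain plus the author number of each position.

    ``numbering[i]`` is the author residue number of 1-based sequence
    position ``i+1``; gaps in author numbering do not affect the sequence.
    """
    allow = DEFAULT_HET_ALLOWLIST if het_allowlist is None else het_allowlist
    table = {**THREE_TO_ONE, **allow}
    letters = []
    numbering = []
    for res in model.chain(chain_id):
        letter = table.get(res.res_name)
        if letter is None:
            if strict:
                raise QCError(f"residue {res.res_name} at {chain_id}/"
                              f"{res.author_number} has no one-letter mapping")
            letter = "X"
        letters.append(letter)
        numbering.append(res.author_number)
    record = SequenceRecord(id=f"{model.pdb_id}_{chain_id}", seq="".join(letters))
    return record, numbering


def write_qc_report(report: QCReport, pdb_id: str, path) -> None:
    """Write the QC report as a pdb_id/chain/rule/detail TSV."""
    with open(path, "w") as fh:
        fh.write("pdb_id\tchain\trule\tdetail\n")
        for row in report.rows(pdb_id):
            fh.write("\t".join(row) + "\n")
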