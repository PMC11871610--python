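"""Residue-residue distances and cutoff-based interaction labeling.

Two metrics are supported: the minimum Euclidean distance over all
heavy-atom (non-hydrogen, non-deuterium) pairs, and the C-alpha/C-alpha
distance.  Applying a cutoff to inter-chain distances labels residues as
interacting (interface) or not; intra-chain runs support a sequence
separation filter |i-j| >= s as used in contact prediction.

Default cutoffs (6.0 A heavy-atom, 8.0 A C-alpha) follow common literature
conventions and are plain parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import DistanceUndefinedError
from .structure import Residue, StructureModel

DEFAULT_CUTOFFS = {"heavy": 6.0, "ca": 8.0}


@dataclass
class ContactParams:
    metric: str = "heavy"
    cutoff: float | None = None
    level: str = "inter"
    seq_separation: int = 0  # intra-chain |i-j| >= s filter

    def __post_init__(self):
        if self.metric not in ("heavy", "ca"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.level not in ("intra", "inter"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.cutoff is None:
            self.cutoff = DEFAULT_CUTOFFS[self.metric]
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class ContactTable:
    params: ContactParams
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: all residues seen per chain, as (chain, number) -> res_name
    residues: dict[tuple[str, int], str] = field(default_factory=dict)

    def __len__(self):
        return len(self.rows)


def _metric_coords(res: Residue, metric: str) -> np.ndarray:
    if metric == "ca":
        ca = res.atom("CA")
        if ca is None:
            raise DistanceUndefinedError(
                f"residue {res.res_name} {res.chain_id}/{res.author_number} has no CA atom"
            )
        return np.asarray([ca.coords], dtype=float)
    coords = [a.coords for a in res.atoms if a.is_heavy]
    if not coords:
        raise DistanceUndefinedError(
            f"residue {res.res_name} {res.chain_id}/{res.author_number} has no heavy atoms"
        )
    return np.asarray(coords, dtype=float)


def residue_distance(r1: Residue, r2: Residue, metric: str = "heavy") -> float:
    """Distance between two residues: heavy-atom minimum or CA-CA."""
    c1 = _metric_coords(r1, metric)
    c2 = _metric_coords(r2, metric)
    return float(cdist(c1, c2).min())


def _pairwise_min(res_a: list[Residue], res_b: list[Residue], metric: str) -> np.ndarray:
    """(len(a), len(b)) matrix of residue distances, vectorised over atoms."""
    coords_a = [_metric_coords(r, metric) for r in res_a]
    coords_b = [_metric_coords(r, metric) for r in res_b]
    idx_a = np.repeat(np.arange(len(res_a)), [len(c) for c in coords_a])
    idx_b = np.repeat(np.arange(len(res_b)), [len(c) for c in coords_b])
    atom_d = cdist(np.vstack(coords_a), np.vstack(coords_b))
    out = np.full((len(res_a), len(res_b)), np.inf)
    np.minimum.at(out, (idx_a[:, None], idx_b[None, :]), atom_d)
    return out


def contact_table(model: StructureModel, params: ContactParams,
                  chains: str | tuple[str, str]) -> ContactTable:
    """All residue-pair distances for a chain pair (inter) or one chain (intra).

    Rows are ordered so residue i precedes j in (chain, number, icode) order
    and no (i,j)/(j,i) duplicate appears.
    """
    if isinstance(chains, str):
        chains = (chains,) if params.level == "intra" else tuple(chains.split(","))
    if params.level == "inter":
        if len(chains) != 2:
            raise ValueError("inter level needs exactly two chains")
        res_a = model.chain(chains[0])
        res_b = model.chain(chains[1])
        if not res_a or not res_b:
            raise ValueError("empty chain")
        dmat = _pairwise_min(res_a, res_b, params.metric)
        records = []
        for i, ri in enumerate(res_a):
            for j, rj in enumerate(res_b):
                records.append((ri.chain_id, ri.author_number, ri.res_name,
                                rj.chain_id, rj.author_number, rj.res_name,
                                dmat[i, j]))
        pool = res_a + res_b
    else:
        if len(chains) != 1:
            raise ValueError("intra level needs exactly one chain")
        res_a = model.chain(chains[0])
        if not res_a:
            raise ValueError("empty chain")
        dmat = _pairwise_min(res_a, res_a, params.metric)
        records = []
        for i, ri in enumerate(res_a):
            for j in range(i + 1, len(res_a)):
                rj = res_a[j]
                if abs(ri.author_number - rj.author_number) < params.seq_separation:
                    continue
                records.append((ri.chain_id, ri.author_number, ri.res_name,
                                rj.chain_id, rj.author_number, rj.res_name,
                                dmat[i, j]))
        pool = res_a
    df = pd.DataFrame(records, columns=["chain_i", "num_i", "res_i",
                                        "chain_j", "num_j", "res_j", "distance"])
    df["is_contact"] = df["distance"] <= params.cutoff
    residues = {(r.chain_id, r.author_number): r.res_name for r in pool}
    return ContactTable(params=params, rows=df, residues=residues)


def interface_residues(table: ContactTable) -> pd.DataFrame:
    """Per-residue interface labels from an inter-chain contact table.

    label = 1 iff the residue appears in at least one contact row;
    min_distance is its smallest cross-chain distance (reported for
    non-interface residues too).
    """
    if table.params.level != "inter":
        raise ValueError("interface labels require an inter-level contact table")
    df = table.rows
    best: dict[tuple[str, int], float] = {k: np.inf for k in table.residues}
    hit: dict[tuple[str, int], bool] = {k: False for k in table.residues}
    for row in df.itertuples(index=False):
        for key in ((row.chain_i, row.num_i), (row.chain_j, row.num_j)):
            if row.distance < best[key]:
                best[key] = row.distance
            if row.is_contact:
                hit[key] = True
    out = pd.DataFrame(
        [(c, n, int(hit[(c, n)]), best[(c, n)]) for (c, n) in sorted(best)],
        columns=["chain", "number", "label", "min_distance"],
    )
    return out


def write_contacts_tsv(table: ContactTable, path) -> None:
    """Write the contact table as TSV with distances to 3 decimals."""
    df = table.rows.copy()
    df["distance"] = df["distance"].map(lambda d: f"{d:.3f}")
    df["is_contact"] = df["is_contact"].astype(int)
    df.to_csv(path, sep="\t", index=False)
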