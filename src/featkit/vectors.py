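"""Assembly of ML-ready feature vectors from per-residue feature tables.

A :class:`FeatureBundle` holds named feature groups for one protein: ordered
per-residue tables (rows are 1-based positions) plus optional whole-protein
groups such as composition vectors.  Site vectors concatenate the selected
groups over a sliding window centred on each site; positions outside the
sequence are padded with a configurable value and marked by a per-offset
in-bounds mask, so every row has fixed width and edges remain learnable.
Pair vectors concatenate two site blocks; protein vectors reduce per-residue
groups by the mean and pass whole-protein groups through.

Every matrix ships with a schema (one entry per column: offset, group,
feature) so downstream ML can audit column provenance.  Column names follow
``off{+k}.{group}.{feature}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FeatureBundle:
    protein_id: str
    length: int
    groups: dict[str, pd.DataFrame] = field(default_factory=dict)
    #: whole-protein feature groups (e.g. k-mer composition), one row each
    protein_groups: dict[str, pd.Series] = field(default_factory=dict)

    def add_group(self, name: str, table) -> "FeatureBundle":
        """Add a per-residue group; rows must equal the protein length."""
        df = pd.DataFrame(table)
        if len(df) != self.length:
            raise ValueError(
                f"group {name!r} has {len(df)} rows, expected {self.length}"
            )
        df = df.reset_index(drop=True)
        df.index = pd.RangeIndex(1, self.length + 1, name="position")
        self.groups[name] = df
        return self

    def add_protein_group(self, name: str, values) -> "FeatureBundle":
        """Add a whole-protein group (a single vector, e.g. composition)."""
        if isinstance(values, dict):
            series = pd.Series(values)
        else:
            series = pd.Series(np.asarray(values, dtype=float))
            series.index = [f"f{i}" for i in range(len(series))]
        self.protein_groups[name] = series
        return self

    def group_width(self, name: str) -> int:
        return self.groups[name].shape[1]


@dataclass
class WindowSpec:
    half_width: int = 0
    pad_value: float = 0.0
    emit_mask: bool = True

    def __post_init__(self):
        if self.half_width < 0:
            raise ValueError("half_width must be >= 0")

    @property
    def size(self) -> int:
        return 2 * self.half_width + 1


def _check_include(bundle: FeatureBundle, include: list[str]) -> list[str]:
    if not include:
        raise ValueError("include must name at least one feature group")
    missing = [g for g in include if g not in bundle.groups]
    if missing:
        raise KeyError(f"groups {missing} not in bundle {bundle.protein_id!r}")
    return list(include)


def _site_block(bundle: FeatureBundle, site: int, window: WindowSpec,
                include: list[str]) -> tuple[list[float], list[dict]]:
    """Feature values and schema entries for one site's window block."""
    values: list[float] = []
    schema: list[dict] = []
    for off in range(-window.half_width, window.half_width + 1):
        pos = site + off
        in_bounds = 1 <= pos <= bundle.length
        tag = f"off{off:+d}"
        for group in include:
            table = bundle.groups[group]
            for feat in table.columns:
                schema.append({"name": f"{tag}.{group}.{feat}",
                               "offset": off, "group": group, "feature": str(feat)})
                values.append(float(table.at[pos, feat]) if in_bounds
                              else window.pad_value)
        if window.emit_mask:
            schema.append({"name": f"{tag}.mask", "offset": off,
                           "group": "mask", "feature": "in_bounds"})
            values.append(1.0 if in_bounds else 0.0)
    return values, schema


def assemble_site_vectors(bundle: FeatureBundle, sites, window: WindowSpec,
                          include: list[str]) -> tuple[pd.DataFrame, list[dict]]:
    """One fixed-width feature row per site.

    Row width = (2w+1) * (sum of selected group widths) + (2w+1) mask
    columns when the mask is emitted.
    """
    include = _check_include(bundle, include)
    sites = list(sites)
    for s in sites:
        if not 1 <= s <= bundle.length:
            raise ValueError(f"site {s} outside [1, {bundle.length}]")
    _, schema = _site_block(bundle, 1, window, include)
    rows = []
    for s in sites:
        values, _ = _site_block(bundle, s, window, include)
        rows.append(values)
    columns = [entry["name"] for entry in schema]
    df = pd.DataFrame(rows, columns=columns,
                      index=pd.Index(sites, name="position"))
    return df, schema


def assemble_pair_vectors(bundles, pairs, window: WindowSpec,
                          include: list[str], symmetric: bool = True,
                          allow_self: bool = False) -> tuple[pd.DataFrame, list[dict]]:
    """One row per site pair: the concatenation of both sites' window blocks.

    *bundles* is a single bundle (intra-protein pairs) or a (bundle_i,
    bundle_j) tuple for cross-protein pairs.  With ``symmetric=True``
    intra-protein pairs are canonicalised so (i, j) and (j, i) yield
    identical rows.
    """
    if isinstance(bundles, FeatureBundle):
        bundle_i = bundle_j = bundles
        same = True
    else:
        bundle_i, bundle_j = bundles
        same = bundle_i is bundle_j
    _check_include(bundle_i, include)
    _check_include(bundle_j, include)
    _, schema_i = _site_block(bundle_i, 1, window, include)
    _, schema_j = _site_block(bundle_j, 1, window, include)
    rows = []
    index = []
    for i, j in pairs:
        if same:
            if i == j and not allow_self:
                raise ValueError(f"self-pair ({i}, {i}); pass allow_self=True to keep")
            if symmetric and j < i:
                i, j = j, i
        vi, _ = _site_block(bundle_i, i, window, include)
        vj, _ = _site_block(bundle_j, j, window, include)
        rows.append(vi + vj)
        index.append((i, j))
    schema = (
        [{**e, "name": f"site_i.{e['name']}", "site": "i"} for e in schema_i]
        + [{**e, "name": f"site_j.{e['name']}", "site": "j"} for e in schema_j]
    )
    df = pd.DataFrame(rows, columns=[e["name"] for e in schema],
                      index=pd.MultiIndex.from_tuples(index, names=["i", "j"]))
    return df, schema


def assemble_protein_vector(bundle: FeatureBundle, include: list[str],
                            ) -> tuple[pd.Series, list[dict]]:
    """Single fixed-width row per protein, length-independent.

    *include* may name per-residue groups (reduced by the mean over
    positions) and whole-protein groups (passed through unchanged).
    """
    if not include:
        raise ValueError("include must name at least one feature group")
    values: list[float] = []
    schema: list[dict] = []
    for group in include:
        if group in bundle.groups:
            means = bundle.groups[group].mean(axis=0)
            for feat, val in means.items():
                schema.append({"name": f"mean.{group}.{feat}", "group": group,
                               "feature": str(feat), "reducer": "mean"})
                values.append(float(val))
        elif group in bundle.protein_groups:
            for feat, val in bundle.protein_groups[group].items():
                schema.append({"name": f"{group}.{feat}", "group": group,
                               "feature": str(feat), "reducer": "passthrough"})
                values.append(float(val))
        else:
            raise KeyError(f"group {group!r} not in bundle {bundle.protein_id!r}")
    series = pd.Series(values, index=[e["name"] for e in schema],
                       name=bundle.protein_id)
    return series, schema


def restrict_to_region(regions, length: int) -> list[int]:
    """Union of 1-based inclusive (start, end) regions as a sorted,
    deduplicated position list (e.g. transmembrane segments)."""
    positions: set[int] = set()
    for start, end in regions:
        if start > end:
            raise ValueError(f"inverted region ({start}, {end})")
        if start < 1 or end > length:
            raise ValueError(f"region ({start}, {end}) outside [1, {length}]")
        positions.update(range(start, end + 1))
    return sorted(positions)


def write_matrix(df: pd.DataFrame, schema: list[dict], path, sep: str = "\t") -> None:
    """Write a feature matrix with header plus a JSON-lines sidecar schema."""
    df.to_csv(path, sep=sep)
    with open(str(path) + ".schema.jsonl", "w") as fh:
        for entry in schema:
            fh.write(json.dumps(entry) + "\n")
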