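"""Residue distances, contact tables and interface labels vs brute force."""

import math

import numpy as np
import pytest

from featkit.contacts import (ContactParams, contact_table, interface_residues,
                              residue_distance)
from featkit.errors import DistanceUndefinedError
from featkit.structure import Atom, Residue, parse_pdb, qc_structure


def _res(chain, num, atoms):
    return Residue(chain_id=chain, author_number=num, insertion_code="",
                   res_name="ALA",
                   atoms=[Atom(name=n, element=e, coords=c) for n, e, c in atoms])


def test_single_atom_three_four_five_triangle():
    r1 = _res("A", 1, [("CA", "C", (0.0, 0.0, 0.0))])
    r2 = _res("B", 1, [("CA", "C", (3.0, 4.0, 0.0))])
    assert residue_distance(r1, r2, "heavy") == pytest.approx(5.0)
    assert residue_distance(r1, r2, "ca") == pytest.approx(5.0)
    assert residue_distance(r1, r1, "heavy") == 0.0


def test_heavy_metric_takes_minimum_over_atom_pairs():
    r1 = _res("A", 1, [("CA", "C", (0.0, 0.0, 0.0)),
                       ("CB", "C", (10.0, 0.0, 0.0))])
    r2 = _res("B", 1, [("CA", "C", (0.0, 4.0, 3.0))])
    # brute force over the two pairs: 5.0 and sqrt(125)
    assert residue_distance(r1, r2, "heavy") == pytest.approx(5.0)
    assert residue_distance(r1, r2, "heavy") == pytest.approx(
        min(math.dist((0, 0, 0), (0, 4, 3)), math.dist((10, 0, 0), (0, 4, 3))))


def test_hydrogens_excluded_and_missing_ca_raises():
    r1 = _res("A", 1, [("CB", "C", (0.0, 0.0, 0.0)),
                       ("H", "H", (0.0, 0.0, 4.9))])
    r2 = _res("B", 1, [("CB", "C", (0.0, 0.0, 5.0))])
    assert residue_distance(r1, r2, "heavy") == pytest.approx(5.0)
    with pytest.raises(DistanceUndefinedError, match="no CA"):
        residue_distance(r1, r2, "ca")


def test_threshold_flip_around_cutoff(tmp_path):
    from featkit.fixtures import make_pdb_complex
    fix = make_pdb_complex(tmp_path, seed=0, chain_length=1, n_interface=1,
                           interface_distance=4.0)
    model, _ = qc_structure(parse_pdb(fix.pdb_path))
    at6 = contact_table(model, ContactParams(metric="heavy", cutoff=6.0), ("A", "B"))
    at3 = contact_table(model, ContactParams(metric="heavy", cutoff=3.0), ("A", "B"))
    assert len(at6) == 1
    assert bool(at6.rows["is_contact"].iloc[0]) is True
    assert bool(at3.rows["is_contact"].iloc[0]) is False
    assert at6.rows["distance"].iloc[0] == pytest.approx(4.0, abs=1e-9)


def _brute_force(res_a, res_b, metric):
    out = {}
    for ri in res_a:
        for rj in res_b:
            out[(ri.author_number, rj.author_number)] = residue_distance(ri, rj, metric)
    return out


@pytest.mark.parametrize("metric", ["heavy", "ca"])
def test_contact_table_matches_exhaustive_oracle(complex_fixture, metric):
    model, _ = qc_structure(parse_pdb(complex_fixture.pdb_path))
    params = ContactParams(metric=metric, level="inter")
    table = contact_table(model, params, ("A", "B"))
    oracle = _brute_force(model.chain("A"), model.chain("B"), metric)
    assert len(table) == len(oracle)
    for row in table.rows.itertuples(index=False):
        assert row.distance == pytest.approx(oracle[(row.num_i, row.num_j)],
                                             abs=1e-6)
        assert row.is_contact == (row.distance <= params.cutoff)


def test_heavy_min_distance_never_exceeds_ca_distance(complex_fixture):
    """CA is itself a heavy atom, so the heavy-atom minimum bounds it below."""
    model, _ = qc_structure(parse_pdb(complex_fixture.pdb_path))
    heavy = contact_table(model, ContactParams(metric="heavy"), ("A", "B"))
    ca = contact_table(model, ContactParams(metric="ca"), ("A", "B"))
    merged = heavy.rows.merge(ca.rows, on=["chain_i", "num_i", "chain_j", "num_j"],
                              suffixes=("_heavy", "_ca"))
    assert (merged["distance_heavy"] <= merged["distance_ca"] + 1e-9).all()


def test_contact_monotonicity_in_cutoff(complex_fixture):
    model, _ = qc_structure(parse_pdb(complex_fixture.pdb_path))
    small = contact_table(model, ContactParams(cutoff=6.0), ("A", "B"))
    large = contact_table(model, ContactParams(cutoff=8.0), ("A", "B"))
    keys = ["chain_i", "num_i", "chain_j", "num_j"]
    small_set = set(map(tuple, small.rows[small.rows.is_contact][keys].to_numpy()))
    large_set = set(map(tuple, large.rows[large.rows.is_contact][keys].to_numpy()))
    assert small_set <= large_set


def test_intra_level_sequence_separation_and_ordering(complex_fixture):
    model, _ = qc_structure(parse_pdb(complex_fixture.pdb_path))
    n = len(model.chain("A"))
    all_pairs = contact_table(model, ContactParams(level="intra"), "A")
    assert len(all_pairs) == n * (n - 1) // 2
    assert (all_pairs.rows["num_i"] < all_pairs.rows["num_j"]).all()
    sep = contact_table(
        model, ContactParams(level="intra", seq_separation=6), "A")
    assert (sep.rows["num_j"] - sep.rows["num_i"] >= 6).all()


def test_interface_labels_on_constructed_geometry(complex_fixture):
    """Interface block at 5.0 A: residues 1-3 of both chains label 1 at a
    6 A cutoff, everything else labels 0 but still reports min_distance."""
    model, _ = qc_structure(parse_pdb(complex_fixture.pdb_path))
    table = contact_table(model, ContactParams(metric="heavy", cutoff=6.0),
                          ("A", "B"))
    labels = interface_residues(table)
    by_key = {(r.chain, r.number): r.label for r in labels.itertuples(index=False)}
    for chain in "AB":
        for num in range(1, 11):
            expected = 1 if num <= 3 else 0
            assert by_key[(chain, num)] == expected, (chain, num)
    assert np.isfinite(labels["min_distance"]).all()
    # truth table agrees with the labels it implies
    truth = complex_fixture.truth
    tmin = truth.groupby(["chain_i", "num_i"])["heavy_distance"].min()
    for (chain, num), dist in tmin.items():
        assert (dist <= 6.0) == (by_key[(chain, num)] == 1)


def test_interface_label_monotonicity_over_seeded_fixtures(tmp_path):
    from featkit.fixtures import make_pdb_complex
    for seed in range(20):
        fix = make_pdb_complex(tmp_path / f"s{seed}", seed=seed,
                               chain_length=6, n_interface=2,
                               interface_distance=4.0 + 0.2 * seed,
                               jitter=0.1)
        model, _ = qc_structure(parse_pdb(fix.pdb_path))
        lab6 = interface_residues(contact_table(
            model, ContactParams(cutoff=6.0), ("A", "B")))
        lab8 = interface_residues(contact_table(
            model, ContactParams(cutoff=8.0), ("A", "B")))
        pos6 = set(map(tuple, lab6[lab6.label == 1][["chain", "number"]].to_numpy()))
        pos8 = set(map(tuple, lab8[lab8.label == 1][["chain", "number"]].to_numpy()))
        assert pos6 <= pos8


def test_fixture_truth_equals_contact_table(complex_fixture):
    model, _ = qc_structure(parse_pdb(complex_fixture.pdb_path))
    table = contact_table(model, ContactParams(metric="heavy"), ("A", "B"))
    merged = table.rows.merge(complex_fixture.truth,
                              on=["chain_i", "num_i", "chain_j", "num_j"])
    assert len(merged) == len(complex_fixture.truth)
    assert (merged["distance"] - merged["heavy_distance"]).abs().max() < 1e-6
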