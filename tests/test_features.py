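"""Composition, physicochemical, conservation, and positional features."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from featkit.features import (available_scales, get_scale, jsd_conservation,
                              jsd_score, kmer_composition, kmer_order,
                              physico_features, positional_and_length)
from featkit.features._data import background_freqs
from featkit.fixtures import make_msa
from featkit.sequence_io import Alignment, SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# k-mer composition

def test_monopeptide_composition_of_acde():
    vec = kmer_composition("ACDE", 1)
    assert vec.dimension == 20
    d = vec.as_dict()
    for aa in "ACDE":
        assert d[aa] == pytest.approx(0.25)
    assert sum(1 for v in d.values() if v == 0) == 16


def test_dipeptide_composition_of_homopolymer():
    vec = kmer_composition("AAA", 2)
    assert vec.dimension == 400
    d = vec.as_dict()
    assert d["AA"] == pytest.approx(1.0)
    assert vec.values.sum() == pytest.approx(1.0)


@pytest.mark.parametrize("k,dim", [(1, 20), (2, 400), (3, 8000)])
def test_composition_dimensions_are_exact(k, dim):
    vec = kmer_composition(AA * 2, k)
    assert vec.dimension == dim
    assert len(kmer_order(k)) == dim
    assert list(vec.kmers) == sorted(vec.kmers)


@settings(max_examples=30, deadline=None)
@given(st.text(alphabet=AA, min_size=3, max_size=200),
       st.sampled_from([1, 2, 3]))
def test_composition_matches_counting_oracle(seq, k):
    """Frequencies equal an independent count-and-divide loop and sum to 1."""
    vec = kmer_composition(seq, k)
    n_windows = len(seq) - k + 1
    counts: dict[str, int] = {}
    for i in range(n_windows):
        counts[seq[i:i + k]] = counts.get(seq[i:i + k], 0) + 1
    d = vec.as_dict()
    for kmer, count in counts.items():
        assert d[kmer] == pytest.approx(count / n_windows)
    assert vec.values.sum() == pytest.approx(1.0)


def test_composition_error_paths():
    with pytest.raises(ValueError, match="length"):
        kmer_composition("AC", 3)
    with pytest.raises(ValueError, match="position 2"):
        kmer_composition("AXDE", 1)
    vec = kmer_composition("AXAA", 2, skip_nonstandard=True)
    assert vec.as_dict()["AA"] == pytest.approx(1.0)  # only window 3-4 counts
    assert vec.values.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# physicochemical scales

def test_at_least_23_complete_scales_packaged():
    names = available_scales()
    assert len(names) >= 23
    for name in names:
        scale = get_scale(name)
        assert set(scale) == set(AA), name
        assert all(isinstance(v, float) for v in scale.values())


def test_single_residue_feature_reads_packaged_value():
    kd = get_scale("hydropathy_kyte_doolittle_1982")
    table = physico_features("A", selection=["hydropathy_kyte_doolittle_1982"])
    assert table.shape == (1, 1)
    assert table.iloc[0, 0] == kd["A"] == 1.8


def test_constant_sequence_gives_constant_column():
    table = physico_features("GGGG")
    assert table.shape == (4, len(available_scales()))
    assert (table.nunique() == 1).all()


def test_normalization_maps_scale_extremes_to_unit_interval():
    kd = get_scale("hydropathy_kyte_doolittle_1982")
    lo = min(kd, key=kd.get)
    hi = max(kd, key=kd.get)
    table = physico_features(lo + hi, selection=["hydropathy_kyte_doolittle_1982"],
                             normalize=True)
    assert table.iloc[0, 0] == pytest.approx(0.0)
    assert table.iloc[1, 0] == pytest.approx(1.0)
    full = physico_features(AA, normalize=True)
    assert (full.to_numpy() >= 0).all() and (full.to_numpy() <= 1).all()
    with pytest.raises(KeyError):
        physico_features("ACD", selection=["no_such_scale"])


# ---------------------------------------------------------------------------
# Jensen-Shannon conservation

def _single_column_aln(column):
    return Alignment(records=[SequenceRecord(id=f"s{i}", seq=ch)
                              for i, ch in enumerate(column)])


def test_background_column_scores_zero():
    """A column whose distribution equals the background has JSD 0."""
    q = np.full(20, 0.05)
    assert jsd_score(q, q) == pytest.approx(0.0, abs=1e-12)
    bg = background_freqs("blosum62")
    qv = np.array([bg[a] for a in sorted(AA)])
    qv = qv / qv.sum()
    assert jsd_score(qv, qv) == pytest.approx(0.0, abs=1e-12)


def test_fully_conserved_column_equals_direct_formula():
    """Uniform background, lam=0.5, no window: evaluate the entropy-based
    expression by hand for a delta distribution p = e_A."""
    aln = _single_column_aln("AAAAA")
    prof = jsd_conservation(aln, background="uniform", lam=0.5, window=0)
    # direct evaluation: H(m) with m = 0.5*e_A + 0.5*q, H(p)=0, H(q)=log2(20)
    q = 0.05
    m_a = 0.5 + 0.5 * q
    m_other = 0.5 * q
    h_m = -(m_a * math.log2(m_a) + 19 * m_other * math.log2(m_other))
    expected = h_m - 0.5 * 0.0 - 0.5 * math.log2(20)
    assert prof.scores[0] == pytest.approx(expected, abs=1e-12)
    assert 0.0 < expected < 1.0


def test_conserved_columns_outrank_background_columns(msa_fixture):
    prof = jsd_conservation(msa_fixture.alignment, window=0)
    classes = np.array(msa_fixture.column_classes)
    conserved = prof.scores[classes == "conserved"]
    background = prof.scores[classes == "background"]
    assert conserved.min() > background.max()


def test_gap_rich_columns_score_zero(msa_fixture):
    prof = jsd_conservation(msa_fixture.alignment, window=0)
    classes = np.array(msa_fixture.column_classes)
    assert (prof.scores[classes == "gappy"] == 0.0).all()
    assert (prof.gap_fractions[classes == "gappy"] > 0.5).all()


def test_all_gap_column_scores_zero_with_warning():
    aln = Alignment(records=[SequenceRecord(id="a", seq="-A"),
                             SequenceRecord(id="b", seq="-A")])
    with pytest.warns(UserWarning, match="no non-gap"):
        prof = jsd_conservation(aln, window=0)
    assert prof.scores[0] == 0.0


def test_windowing_averages_neighbouring_columns():
    aln = Alignment(records=[SequenceRecord(id=f"s{i}", seq="AAA")
                             for i in range(4)])
    raw = jsd_conservation(aln, window=0).scores
    win = jsd_conservation(aln, window=1).scores
    assert win[0] == pytest.approx(raw[:2].mean())   # clipped at the edge
    assert win[1] == pytest.approx(raw.mean())


def test_jsd_scores_bounded_on_random_alignments():
    rng = np.random.default_rng(42)
    for trial in range(100):
        depth = int(rng.integers(2, 12))
        width = int(rng.integers(1, 15))
        letters = list(AA + "-")
        records = [
            SequenceRecord(id=f"s{i}",
                           seq="".join(rng.choice(letters, size=width)))
            for i in range(depth)
        ]
        with np.errstate(all="ignore"):
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                prof = jsd_conservation(Alignment(records=records),
                                        window=int(rng.integers(0, 4)))
        assert (prof.scores >= 0.0).all() and (prof.scores <= 1.0).all()


# ---------------------------------------------------------------------------
# positional / length

def test_positional_and_length_features():
    table = positional_and_length("ACDE")
    assert list(table["relative_position"]) == [0.25, 0.5, 0.75, 1.0]
    assert (table["log_length"] == math.log(4)).all()
    single = positional_and_length("A")
    assert list(single["relative_position"]) == [1.0]
    assert (np.diff(positional_and_length(AA)["relative_position"]) > 0).all()
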