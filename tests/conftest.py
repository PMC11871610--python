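import pytest

from featkit import fixtures as fx


@pytest.fixture(scope="session")
def complex_fixture(tmp_path_factory):
    """Clean two-chain complex: 10 residues/chain, first 3 pairs at 5.0 A."""
    out = tmp_path_factory.mktemp("complex")
    return fx.make_pdb_complex(out, seed=11, chain_length=10, n_interface=3,
                               interface_distance=5.0)


@pytest.fixture(scope="session")
def dirty_complex_fixture(tmp_path_factory):
    """Complex with waters, an MSE HETATM residue and alternate locations."""
    out = tmp_path_factory.mktemp("dirty")
    return fx.make_pdb_complex(out, seed=12, chain_length=6, n_interface=2,
                               interface_distance=4.0, add_waters=3,
                               add_mse=True, add_altloc=True)


@pytest.fixture(scope="session")
def msa_fixture():
    return fx.make_msa(seed=5, depth=20, n_conserved=5, n_background=10,
                       n_gappy=3)


@pytest.fixture(scope="session")
def uniprot_fixture(tmp_path_factory):
    out = tmp_path_factory.mktemp("uniprot")
    return fx.make_uniprot_dat(out, seed=3, n_entries=3)
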