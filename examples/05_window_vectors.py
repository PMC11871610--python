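"""Assemble sliding-window site vectors and a whole-protein vector."""

from featkit.features import kmer_composition, physico_features
from featkit.vectors import (FeatureBundle, WindowSpec, assemble_pair_vectors,
                             assemble_protein_vector, assemble_site_vectors,
                             restrict_to_region)

seq = "MKTAYIAKQRQISFVKSHFS"
bundle = FeatureBundle(protein_id="P1", length=len(seq))
bundle.add_group("physico", physico_features(seq, normalize=True))
bundle.add_protein_group("aac", kmer_composition(seq, 1).as_dict())

sites = restrict_to_region([(3, 6), (10, 12)], len(seq))
print(f"sites from regions (3-6) u (10-12): {sites}")

window = WindowSpec(half_width=2, pad_value=0.0, emit_mask=True)
X, schema = assemble_site_vectors(bundle, sites, window, include=["physico"])
print(f"site matrix: {X.shape[0]} sites x {X.shape[1]} columns "
      f"(= 5 offsets x 25 scales + 5 masks)")
print(f"first columns: {list(X.columns[:2])} ... {list(X.columns[-2:])}")

pairs, _ = assemble_pair_vectors(bundle, [(3, 10)], WindowSpec(1),
                                 include=["physico"])
print(f"pair vector width: {pairs.shape[1]} (= 2 x one site block)")

protein_row, _ = assemble_protein_vector(bundle, include=["physico", "aac"])
print(f"protein vector width: {len(protein_row)} "
      "(25 per-residue means + 20 composition entries, length-independent)")
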