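"""Generate the intrinsic feature families for one sequence and one MSA."""

from featkit.features import (available_scales, jsd_conservation,
                              kmer_composition, physico_features,
                              positional_and_length, ss_onehot, threedi_onehot)
from featkit.fixtures import make_msa

seq = "MKTAYIAKQRQISFVKSHFS"

aac = kmer_composition(seq, 1)
dpc = kmer_composition(seq, 2)
tpc = kmer_composition(seq, 3)
print(f"composition dimensions: {aac.dimension}/{dpc.dimension}/{tpc.dimension}")
print(f"AAC of K: {aac.as_dict()['K']:.3f} (3 of 20 residues are K)")

phys = physico_features(seq, normalize=True)
print(f"physicochemical table: {phys.shape[0]} residues x {phys.shape[1]} scales "
      f"({len(available_scales())} packaged)")

pos = positional_and_length(seq)
print(f"relative position of residue 5: {pos.loc[5, 'relative_position']:.2f}")

msa = make_msa(seed=4, depth=20, n_conserved=5, n_background=10, n_gappy=3)
prof = jsd_conservation(msa.alignment, window=3)
print(f"JSD conservation over {len(prof)} columns: "
      f"min {prof.scores.min():.3f}, max {prof.scores.max():.3f} bits")
# conserved columns score high, background-like columns low, and columns
# with >50% gaps are forced to zero before windowing

ss = ss_onehot("HHHGEEC")
print(f"secondary-structure one-hot shape: {ss.shape} (8-state collapsed to H/E/C)")
tdi = threedi_onehot("ACDDV")
print(f"3di one-hot shape: {tdi.shape}")
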