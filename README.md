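# featkit

Pre-processing, residue-level feature generation and site-wise evaluation
for protein machine learning.

Training a model to predict residue-level properties — protein–protein
interaction sites, disordered residues, variant effects — requires a long
chain of unglamorous steps before and after the model itself: cleaning
structures, converting alignment formats, deriving ground-truth labels from
residue geometry, generating per-residue features from heterogeneous
sources, assembling them into fixed-width vectors, and scoring predictions
site by site. featkit covers that chain as a single Python library with a
thin `featkit` command-line wrapper.

## What it does

- **Sequence I/O** (`featkit.sequence_io`): FASTA read/write with duplicate
  handling, MSA interconversion between aligned FASTA, A3M, Clustal and
  Stockholm (A3M lowercase insertions are removed relative to the query),
  and hash-based diffing of large identifier lists.
- **Structure QC** (`featkit.structure`): fixed-column PDB parsing,
  alternate-location collapse by occupancy, HETATM exclusion with a
  configurable allowlist (MSE → M by default), UNK handling in strict or
  permissive mode, and chain-sequence extraction with author-number
  tracking.
- **Contacts** (`featkit.contacts`): intra-/inter-chain residue distances —
  minimum over heavy-atom pairs, min<sub>a∈i, b∈j</sub>‖x<sub>a</sub> −
  x<sub>b</sub>‖, or Cα–Cα — and cutoff-based interface labeling
  (label<sub>i</sub> = 1 iff min cross-chain distance ≤ c, defaults 6.0 Å
  heavy / 8.0 Å Cα).
- **Features** (`featkit.features`): k-mer composition (20/400/8000
  dimensions for k = 1/2/3), 25 packaged physicochemical scales,
  Jensen–Shannon conservation of MSA columns,
  JSD(p, q) = H(λp + (1−λ)q) − λH(p) − (1−λ)H(q) in bits with λ = ½,
  gap penalty (1−g) and a ±3-column window, positional/length features,
  PSI-BLAST PSSM parsing, RSA = min(ACC/maxASA, 1) from DSSP output,
  secondary-structure and 3di one-hots.
- **Vectors** (`featkit.vectors`): sliding-window assembly of site, pair and
  whole-protein vectors with pad+mask edge handling and an auditable column
  schema.
- **Evaluation** (`featkit.evaluate`): confusion counts, precision, recall,
  specificity, F1, MCC, rank-based AUROC, trapezoidal AUPRC, and pooled or
  macro aggregation across proteins.
- **Annotations** (`featkit.annotations`): streaming UniProt flat-text
  parsing (TRANSMEM/BINDING features, accession lists, PDB cross-references)
  with fuzzy-position flagging.
- **Fixtures** (`featkit.fixtures`): seeded synthetic complexes, MSAs and
  UniProt files with analytically known ground truth, used by the test suite
  and the examples.

## Worked example

`examples/03_contacts_and_interface.py` builds a two-chain complex whose
first three residue pairs sit at exactly 5.0 Å and labels its interface:

```
100 cross-chain residue pairs, 3 within 6.0 A
closest pair distance: 5.000 A (designed to be exactly 5.000)
interface residues (label=1):
chain  number  label  min_distance
    A       1      1           5.0
    A       2      1           5.0
    A       3      1           5.0
    B       1      1           5.0
    B       2      1           5.0
    B       3      1           5.0
```

The three designed residue pairs (and only those) fall under the 6 Å
heavy-atom cutoff, so they are the interface; all other residues keep
label 0 while still reporting their minimum cross-chain distance, which is
exactly what a site-wise classifier needs as ground truth. The other
examples (`examples/01…07`) walk through sequence I/O, structure QC,
feature families, window vectors, evaluation and UniProt extraction the
same way; each prints the numbers it computes.

## Command line

```
featkit convert --in msa.a3m --from a3m --to clustal --out msa.aln
featkit qc --pdb in.pdb --mode strict --report qc.tsv --fasta out.fa
featkit contacts --pdb cplx.pdb --chains A,B --metric heavy --cutoff 6.0 --out contacts.tsv
featkit interface --contacts contacts.tsv --out labels.tsv
featkit features --fasta in.fa --k 3 --out tpc.tsv
featkit conserve --msa aln.fa --out jsd.tsv
featkit eval --pred preds.tsv --mode pooled --out report.tsv
featkit uniprot --dat sprot.dat --ids ids.txt --feature TRANSMEM --out tm.tsv
featkit fixtures --kind complex --seed 7 --out dir/
```

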