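# Methods

This note documents the models and procedures implemented in featkit, the
parameters that matter, the numerical choices, and what the synthetic
fixtures do and do not demonstrate.

## Sequence handling

Sequences are normalised on input: letters upper-cased, `.` mapped to `-`,
and any character outside the configured alphabet (the 20 standard amino
acids plus X, B, Z, U, O and `-`) rejected, or mapped to `X` under the
`loose` flag. Explicit rejection is the default because silent character
coercion corrupts downstream feature tables. Duplicate FASTA identifiers
are an error by default; `dedup=True` appends `_1`, `_2`, … with a warning,
since silently overwriting a record would corrupt (protein, position)
feature joins.

Four MSA dialects form the interchange set: aligned FASTA, A3M, Clustal and
Stockholm. Clustal and Stockholm go through Biopython's `AlignIO`;
annotation lines (`#=GC` …) are not preserved. A3M follows standard
semantics: lowercase letters and `.` placeholders are insertion states
relative to the query and are deleted when converting to columnar formats;
upper-case letters and `-` are match states. Converting *into* A3M emits
plain upper-case rows — no insertions are invented. A row whose match-state
width differs from the query's is a format error naming the record.

Identifier diffing is hash-set based (build two sets, intersect and
subtract), so it is linear in input size and comfortably handles millions
of identifiers; the unit tests check the partition laws against a naive
membership-scan oracle.

## Structure parsing and quality control

PDB files are parsed by fixed column positions (atom name 13–16, residue
name 18–20, chain 22, residue number 23–26, insertion code 27, coordinates
31–54) rather than whitespace splitting, because insertion codes and
negative residue numbers make token-based parsing ambiguous. Only one MODEL
is read (the first by default). Alternate locations for the same atom name
within a residue are collapsed to the highest-occupancy conformer, ties
broken by altloc letter, so parses are deterministic. mmCIF is out of
scope.

QC implements the rules commonly applied when building structure-derived ML
datasets: HETATM atoms are removed, except residues on an allowlist
(default MSE → M, because selenomethionine is deposited as HETATM in many
structures) which are converted to ATOM and recorded; residues named UNK
either fail the structure (strict mode, error carrying the positions) or
are dropped with a report entry (permissive mode). Both behaviours are
exposed because either can be the right call depending on whether a dataset
prefers completeness or purity. QC is idempotent, and hydrogens are kept in
the model — the contacts module excludes them via its heavy-atom filter —
so RSA- or geometry-oriented consumers can still see them.

Sequence extraction emits one letter per retained residue through the
standard 3→1 table plus the allowlist, together with a parallel list of
author residue numbers, which is the join key back to structure-derived
labels.

## Residue distances and interface labels

Two metrics: `heavy` is the minimum Euclidean distance over all pairs of
non-hydrogen, non-deuterium atoms; `ca` is the Cα–Cα distance. Since Cα is
itself a heavy atom, heavy ≤ ca always — a property test. Distance matrices
are computed by one atom-level `cdist` per chain pair followed by a
min-reduction onto residue indices; the exhaustive per-pair scan
(`residue_distance` in a double loop) is the reference path the tests
compare against at 1e-6 Å.

Contacts are labeled by `distance ≤ cutoff`. Default cutoffs are 6.0 Å
(heavy) and 8.0 Å (Cα), common literature conventions; both are plain
parameters because no single value suits every labeling task. Intra-chain
runs support a sequence-separation filter |i−j| ≥ s (default 0; contact
prediction often uses 6). Interface labels mark a residue 1 iff it has at
least one cross-chain contact; its minimum cross-chain distance is reported
either way so thresholds can be revisited after the fact. Distances in
output files are printed to 3 decimals; all comparisons use full precision.

## Feature families

**Composition.** k-mer frequencies, count/(L−k+1), serialised in
lexicographic order over the 20-letter alphabet for stable ML joins; the
dimensionalities are exactly 20, 400 and 8000 for k = 1, 2, 3. Non-standard
letters raise by default; `skip_nonstandard` drops affected windows and
renormalises over the remaining ones.

**Physicochemical scales.** 25 published per-residue scales (hydropathy
by Kyte–Doolittle, Hopp–Woods and Parker hydrophilicities, Eisenberg
consensus, Fauchère–Pliška, Black–Mould and Miyazawa–Jernigan
hydrophobicities, Engelman GES transfer energy, Wimley–White interface
scale, Janin buriedness, Rose fractional buried area, Grantham and
Zimmerman polarities, Zimmerman bulkiness, Charton polarizability, Jones
refractivity, Zamyatnin volume, normalised van der Waals volume, molecular
weight, isoelectric point, net charge at pH 7, Bhaskaran–Ponnuswamy
flexibility, and the three Chou–Fasman propensities) live in a versioned
JSON data file keyed by scale name with a literature tag. The completeness
invariant (every scale covers all 20 residues, ≥ 23 scales) is tested
against the file, not a hard-coded list, so adding scales cannot silently
break it. Optional min–max normalisation maps each scale to [0, 1] using
the scale's own range over the 20 residues — sequence-independent, so
feature values are comparable across proteins.

**Conservation.** Per-column Jensen–Shannon divergence between the
observed residue distribution p (gaps excluded) and a background q:
`JSD = H(λp + (1−λ)q) − λH(p) − (1−λ)H(q)` with entropies in bits and
λ = 0.5, which bounds scores to [0, 1]. The packaged default background is
the BLOSUM62 marginal frequency set; a uniform background and arbitrary
user distributions are accepted. Columns are down-weighted by (1 − gap
fraction), forced to 0 above 50% gaps, and averaged over a ±3-column window
clipped at the ends — the standard choices in divergence-based conservation
scoring of functional sites; all are exposed as parameters. Letters outside
the 20-letter alphabet are ignored in both p and the gap fraction.

**Profile.** PSI-BLAST ASCII PSSMs are parsed into per-residue 20-vectors
(log-odds block; the percentage block is also kept). Bodies with 40 or 42
numeric columns are accepted (full files append per-row information and
weight statistics); anything else is a format error. An optional query
sequence is checked row-by-row, failing at the first mismatch. The
`sigmoid` transform squashes scores through 1/(1+e^(−x)) into (0, 1).

**RSA.** rsa = min(ACC/maxASA[res], 1). The packaged maxASA reference is
the theoretical Gly-X-Gly set of Tien et al. (2013); the empirical set is
available by flag. Values above the maximum are clamped and flagged rather
than rejected, since DSSP ACC can exceed tripeptide references for exposed
termini. Chain-break rows (`!`) are skipped.

**Secondary structure.** DSSP's 8 states collapse to 3 by the usual rule
{H,G,I}→H, {E,B}→E, else→C, then one-hot. **3di.** Pre-computed 20-letter
structural-alphabet strings are one-hot encoded; generating 3di from
structures is out of scope.

**Positional/length.** Relative position i/L (1-based) and ln L. The
natural log is this package's choice for the length feature; any monotone
transform would serve, and the value is constant across residues.

## Vector assembly

Feature groups are per-residue tables keyed 1-based, consistent with PDB
author numbering; whole-protein groups (composition) are single vectors.
Site vectors concatenate the selected groups over window offsets −w…+w;
out-of-range offsets are filled with a configurable pad value and flagged
by a per-offset in-bounds mask column. Pad+mask was chosen over truncation
because ML consumers need fixed-width rows, and the mask lets a model learn
edge effects instead of confusing padding with signal. Row width is exactly
(2w+1)·Σ(group widths) + (2w+1) mask columns — tested arithmetic. Pair
vectors concatenate two site blocks; intra-protein pairs are canonicalised
(i ≤ j) under the symmetric flag so (i,j) and (j,i) produce identical rows.
Protein vectors reduce per-residue groups by the mean and pass
whole-protein groups through, making row width independent of sequence
length. Every matrix carries a JSON-lines schema (offset, group, feature
per column, names `off{+k}.{group}.{feature}`) so column provenance is
auditable, and labels should be joined on (protein, position) keys, never
row order.

## Evaluation

Prediction is positive when score ≥ threshold (closed on the left).
Ratio metrics with zero denominators are reported as `None` rather than 0,
so macro-averaging can skip them (the skip count is reported) instead of
biasing the mean toward zero; MCC uses the convention that a zero factor
under the root yields 0. AUROC is the Mann–Whitney formulation on average
ranks — exactly the probability that a random positive outranks a random
negative, with ties counted half — and is tested against an O(n²)
pair-counting oracle. AUPRC is the trapezoidal area under the
precision–recall staircase evaluated at distinct thresholds, and is
therefore an approximation to the step-function area. Pooled aggregation
sums confusion counts (equivalent to concatenating sites); macro averages
per-protein metrics. Plot helpers (metric bars, conservation profiles) are
smoke-tested only.

## UniProt annotations

The flat-text (Swiss-Prot) dialect is the primary format — simpler to
stream than XML and identical in information content for the fields in
scope; parsing is delegated to Biopython's SwissProt reader and normalised
to 1-based inclusive coordinates. Fuzzy positions (`<`, `>`, `?`) are
flagged and excluded from ML regions by default to avoid off-by-one label
noise; `include_fuzzy` clamps them to the sequence instead. Species-level
extraction is the same streaming parser plus a taxon filter; entries are
yielded one at a time, and a test bounds peak allocation while streaming a
1000-entry file. XML and live API access are out of scope.

## Synthetic fixtures — what they show and what they don't

The generators produce inputs whose ground truth is computed analytically
at generation time with plain arithmetic, independent of the modules under
test. Complexes are poly-alanine chains (N, CA, C, O, CB atoms) on a
lattice: chain B is chain A's mirror image shifted so the closest
heavy-atom pair of each aligned interface residue pair sits at exactly the
prescribed distance (the shift is distance + 2·1.8 Å, twice the O-atom
offset in the template), while non-interface residues are displaced 20 Å
further. This exercises the full parse → QC → distance → label path with
exact expected values, and optional defects (waters, UNK, MSE, altlocs)
exercise every QC rule. MSA fixtures draw columns from three known classes
(conserved, background-sampled, gap-rich); UniProt fixtures write entries
with known feature spans. Default fixture sizes (10-residue chains,
depth-20 alignments, 3-entry flat files; 20 seeded replicates where
variability matters) keep the whole suite and the acceptance script fast
while covering every code path.

What passing these tests does *not* show: behaviour on real deposited
structures (multiple conformers, missing atoms, non-standard chemistry
beyond MSE), on deep real alignments with phylogenetic correlation (the
JSD background is a crude model of real residue frequencies), or on real
DSSP/PSSM output quirks beyond the documented layouts. The fixtures
validate the computations, not the biology.

## Known limitations

- mmCIF, bioassembly expansion and structure retrieval are out of scope;
  inputs are local files.
- Running DSSP, PSI-BLAST or Foldseek is out of scope; featkit parses
  their outputs.
- The A3M reader requires insertion gaps to be written as `.` (or omitted,
  the common convention); writers that pad insertions with `-` are
  ambiguous and unsupported.
- AUPRC is trapezoidal, which can differ slightly from average-precision
  implementations on heavily tied scores.
- Spatial indexing is not used for contact maps; the dense atom-distance
  route is exact and fast at complex sizes typical for interface labeling,
  but very large assemblies would benefit from a grid.
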