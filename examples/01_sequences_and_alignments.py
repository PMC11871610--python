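"""Read, write and convert sequence files, and diff identifier lists.

Builds a small FASTA file and an A3M alignment in a temp directory, converts
between formats, and partitions two identifier sets.
"""

import tempfile
from pathlib import Path

from featkit.sequence_io import (SequenceRecord, convert_msa, diff_identifiers,
                                 read_alignment, read_fasta, write_fasta)

tmp = Path(tempfile.mkdtemp())

records = [SequenceRecord(id="P1", seq="MKTAYIAKQR"),
           SequenceRecord(id="P2", seq="MKTA-IAKQR"),
           SequenceRecord(id="P3", seq="MKSAYIAK-R")]
fasta = tmp / "aln.fa"
write_fasta(records, fasta)
print(f"wrote {len(read_fasta(fasta))} records to {fasta.name}")

clustal = tmp / "aln.aln"
aln = convert_msa(fasta, "fasta", "clustal", clustal)
print(f"converted to Clustal: {len(aln)} sequences x {aln.width} columns")

a3m = tmp / "hits.a3m"
a3m.write_text(">query\nMKTAY\n>hit\nMKta-AY\n")
parsed = read_alignment(a3m, "a3m")
# lowercase letters are insertions relative to the query and are removed
print(f"A3M hit row after insertion removal: {parsed.records[1].seq}")

only_a, only_b, shared = diff_identifiers(["P1", "P2", "P4"], ["P2", "P3"])
print(f"identifier diff: only_a={sorted(only_a)} only_b={sorted(only_b)} "
      f"shared={sorted(shared)}")
# the three sets partition the union: every id lands in exactly one bucket
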