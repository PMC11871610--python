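"""Stream UniProt flat-text entries and pull residue-level evidence.

Generates a small synthetic Swiss-Prot-style file, then extracts
transmembrane segments and binding sites and turns them into ML-ready
position lists.
"""

import tempfile
from pathlib import Path

from featkit.annotations import (features_to_regions, filter_entries,
                                 parse_uniprot_text)
from featkit.fixtures import make_uniprot_dat
from featkit.vectors import restrict_to_region

tmp = Path(tempfile.mkdtemp())
fix = make_uniprot_dat(tmp, seed=3, n_entries=3)

entries = list(parse_uniprot_text(fix.dat_path))
print(f"parsed {len(entries)} entries from {fix.dat_path.name}")

entry = entries[0]
print(f"entry {entry.primary_accession} ({entry.entry_name}), "
      f"{len(entry.sequence)} aa, taxon {entry.taxon_id}, "
      f"PDB xrefs {entry.pdb_ids()}")

tm = features_to_regions(entry, "TRANSMEM")
binding = features_to_regions(entry, "BINDING")
print(f"TRANSMEM regions: {tm}; BINDING sites: {binding}")

positions = restrict_to_region(tm, len(entry.sequence))
print(f"{len(positions)} transmembrane positions ready for window assembly")

subset, missing = filter_entries(parse_uniprot_text(fix.dat_path),
                                 accessions=[entry.accessions[1]])
print(f"filtering by the secondary accession still finds the entry: "
      f"{subset[0].primary_accession}; missing={missing}")
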