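# Column maps from search-engine result tables onto normalized fields.
# Editing this file (or pointing the readers at a copy) adapts the package
# to a new tool version without code changes.
#
# Cell encodings:
#   shifts (top-down):       "mass:start-end[:score]" entries joined by ";"
#                            (start/end in protein coordinates, 1-based closed)
#   variable_ptms:           "Name:site" entries joined by ";" (protein coords)
#   fragments:               comma-separated matched-fragment positions
#   shifts (bottom-up):      ";"-joined delta masses (blank = unmodified PSM)
#   assigned (bottom-up):    "pos:Name" entries joined by ";" (peptide coords);
#                            a bare "Name" is accepted for protein-N-terminal
#                            modifications (position 1 of the peptide)
topdown:
  toppic:
    record_id: "Prsm ID"
    protein: "Protein accession"
    first: "First residue"
    last: "Last residue"
    shifts: "Unexpected modifications"
    variable_ptms: "Variable PTMs"
    fragments: "Matched fragment positions"
  mspathfinder:
    record_id: "Scan"
    protein: "ProteinName"
    first: "Start"
    last: "End"
    variable_ptms: "Modifications"
bottomup:
  msfragger:
    record_id: "Spectrum"
    peptide: "Peptide"
    protein: "Protein ID"
    start: "Protein Start"
    shifts: "Delta Mass"
    assigned: "Assigned Modifications"
  metamorpheus:
    record_id: "Scan Number"
    peptide: "Base Sequence"
    protein: "Protein Accession"
    start: "Start Residue In Protein"
    assigned: "Modifications"
  maxquant:
    record_id: "id"
    peptide: "Sequence"
    protein: "Proteins"
    start: "Start position"
    assigned: "Modifications"
annotations:
  uniprot:
    protein: "Accession"
    site: "Position"
    ptm: "Description"
  dbptm:
    protein: "Accession"
    site: "Site"
    ptm: "PTM"
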