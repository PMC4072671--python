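"""Shared vocabulary: the residue alphabet and the eight dataset classes.

All feature vectors, PSSM column layouts and class orderings in the package
derive from the two tuples below; they are declared once and never reordered.
"""

# Fixed alphabetical residue order used for every vector component and for
# PSSM columns after parsing (PSI-BLAST files are re-mapped on read).
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Residue letters that are legal in FASTA but outside the 20-letter alphabet.
AMBIGUOUS_RESIDUES: frozenset = frozenset("BJOUXZ*")

# Seven substrate-specific transporter classes plus the non-transporter
# control class. The order is fixed: it is the tie-break order for
# multi-class prediction and the row order of every report.
CLASS_LABELS: tuple = (
    "amino_acid",
    "anion",
    "cation",
    "electron",
    "protein_mrna",
    "sugar",
    "other",
    "non_transporter",
)

# PSI-BLAST's native column order in ASCII PSSM files.
PSIBLAST_COLUMN_ORDER: str = "ARNDCQEGHILKMFPSTWYV"
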