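"""Residue and atom dictionaries shared across the package.

Heavy-atom inventories for the 20 standard amino acids and the four
deoxyribonucleotides define the residue-specific atom-type catalogue used by
the knowledge-based potential (167 protein types, 82 DNA types) and the
base-moiety definitions used by contact detection and base replacement.
"""

from __future__ import annotations

# Heavy atoms per standard amino acid, PDB v3 names.  167 in total.
AMINO_ACID_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("N", "CA", "C", "O", "CB"),
    "ARG": ("N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"),
    "ASP": ("N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"),
    "CYS": ("N", "CA", "C", "O", "CB", "SG"),
    "GLN": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"),
    "GLY": ("N", "CA", "C", "O"),
    "HIS": ("N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"),
    "LEU": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"),
    "LYS": ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"),
    "MET": ("N", "CA", "C", "O", "CB", "CG", "SD", "CE"),
    "PHE": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("N", "CA", "C", "O", "CB", "CG", "CD"),
    "SER": ("N", "CA", "C", "O", "CB", "OG"),
    "THR": ("N", "CA", "C", "O", "CB", "OG1", "CG2"),
    "TRP": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1",
            "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2",
            "CZ", "OH"),
    "VAL": ("N", "CA", "C", "O", "CB", "CG1", "CG2"),
}

# Base-moiety heavy atoms per nucleotide (sugar and phosphate excluded).
# Counts: A=10, G=11, C=8, T=9.
BASE_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "T": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6"),
}

# Sugar-phosphate heavy atoms shared by all four nucleotides (11 atoms).
SUGAR_PHOSPHATE_ATOMS: tuple[str, ...] = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'",
)

#: Ring atoms defining the base plane (all ring atoms; 9 purine, 6 pyrimidine).
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"),
    "G": ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

#: Glycosidic nitrogen (template anchor): N9 for purines, N1 for pyrimidines.
ANCHOR_ATOM: dict[str, str] = {"A": "N9", "G": "N9", "C": "N1", "T": "N1"}

#: Atoms (p, anchor, q) whose interior angle bisector orients the template.
BISECTOR_ATOMS: dict[str, tuple[str, str, str]] = {
    "A": ("C4", "N9", "C8"),
    "G": ("C4", "N9", "C8"),
    "C": ("C2", "N1", "C6"),
    "T": ("C2", "N1", "C6"),
}

#: Watson-Crick hydrogen-bond atom used for pairing detection.
WC_ATOM: dict[str, str] = {"A": "N1", "G": "N1", "C": "N3", "T": "N3"}

PURINES = frozenset({"A", "G"})
PYRIMIDINES = frozenset({"C", "T"})

COMPLEMENT: dict[str, str] = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Residue-name dialects: remediated (DA) and legacy (A) deoxyribonucleotides.
_NUCLEOTIDE_NAMES = {
    "DA": "A", "DT": "T", "DC": "C", "DG": "G",
    "A": "A", "T": "T", "C": "C", "G": "G",
}

# Selenomethionine is scored as methionine.
_PROTEIN_ALIASES = {"MSE": "MET"}

# Atom-name drift across PDB remediation eras.
ATOM_NAME_ALIASES: dict[str, str] = {
    "O1P": "OP1", "O2P": "OP2", "C5M": "C7",
    "O5*": "O5'", "C5*": "C5'", "C4*": "C4'", "O4*": "O4'",
    "C3*": "C3'", "O3*": "O3'", "C2*": "C2'", "C1*": "C1'",
}


def normalize_atom_name(name: str) -> str:
    name = name.strip()
    return ATOM_NAME_ALIASES.get(name, name)


def nucleotide_letter(residue_name: str) -> str | None:
    """Return the one-letter base code, or None for non-standard residues."""
    return _NUCLEOTIDE_NAMES.get(residue_name.strip().upper())


def protein_residue(residue_name: str) -> str | None:
    """Return the canonical 3-letter amino-acid code, or None."""
    name = residue_name.strip().upper()
    name = _PROTEIN_ALIASES.get(name, name)
    return name if name in AMINO_ACID_ATOMS else None


def complement_sequence(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in seq)


def reverse_complement(seq: str) -> str:
    return complement_sequence(seq)[::-1]
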