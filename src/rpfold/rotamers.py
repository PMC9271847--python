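"""Side-chain internal-coordinate templates and amino-acid tables.

Each side chain is described as a Z-matrix rooted at CB: every atom is
placed from three previously available atoms (backbone or side chain) by a
bond length (A), a bond angle (deg) and a dihedral. Dihedrals are either
fixed or bound to a sampled torsion: chi1 and chi2 take discrete values
from ``CHI_CHOICES`` during repacking; deeper torsions are frozen at 180
(extended). Geometry uses standard peptide-chemistry values; aromatic and
heteroaromatic rings are closed to within a few hundredths of an Angstrom,
which is ample for 4.5-A heavy-atom contact analysis.
"""
from __future__ import annotations

from typing import NamedTuple

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: common modified residues mapped to their parent amino acid
MODIFIED_PARENT = {
    "MSE": "MET", "SEC": "CYS", "CSO": "CYS", "SEP": "SER",
    "TPO": "THR", "PTR": "TYR", "MLY": "LYS", "HYP": "PRO",
}

CHI_CHOICES = (-60.0, 60.0, 180.0)

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class ZEntry(NamedTuple):
    name: str
    element: str
    refs: tuple[str, str, str]   # A, B, C; new atom bonds to C
    bond: float                  # C-D distance, A
    angle: float                 # B-C-D angle, deg
    dihedral: tuple              # ("fixed", value) | ("chi", k, offset)


def _chi(k, offset=0.0):
    return ("chi", k, float(offset))


def _fx(value):
    return ("fixed", float(value))


# CB placement shared by all non-glycine residues.  The dihedral
# C-N-CA-CB = -122 deg yields the L-configuration.
_CB = ZEntry("CB", "C", ("C", "N", "CA"), 1.53, 110.4, _fx(-122.0))

SIDECHAIN_ZMATRIX: dict[str, list[ZEntry]] = {
    "G": [],
    "A": [_CB],
    "S": [_CB, ZEntry("OG", "O", ("N", "CA", "CB"), 1.42, 110.8, _chi(1))],
    "C": [_CB, ZEntry("SG", "S", ("N", "CA", "CB"), 1.81, 113.8, _chi(1))],
    "V": [_CB,
          ZEntry("CG1", "C", ("N", "CA", "CB"), 1.52, 110.5, _chi(1)),
          ZEntry("CG2", "C", ("N", "CA", "CB"), 1.52, 110.5, _chi(1, 122.0))],
    "T": [_CB,
          ZEntry("OG1", "O", ("N", "CA", "CB"), 1.43, 109.5, _chi(1)),
          ZEntry("CG2", "C", ("N", "CA", "CB"), 1.52, 110.5, _chi(1, -122.0))],
    "I": [_CB,
          ZEntry("CG1", "C", ("N", "CA", "CB"), 1.53, 110.4, _chi(1)),
          ZEntry("CG2", "C", ("N", "CA", "CB"), 1.53, 110.5, _chi(1, -122.0)),
          ZEntry("CD1", "C", ("CA", "CB", "CG1"), 1.52, 113.9, _chi(2))],
    "L": [_CB,
          ZEntry("CG", "C", ("N", "CA", "CB"), 1.53, 116.3, _chi(1)),
          ZEntry("CD1", "C", ("CA", "CB", "CG"), 1.52, 110.5, _chi(2)),
          ZEntry("CD2", "C", ("CA", "CB", "CG"), 1.52, 110.5, _chi(2, 122.0))],
    "N": [_CB,
          ZEntry("CG", "C", ("N", "CA", "CB"), 1.52, 112.6, _chi(1)),
          ZEntry("OD1", "O", ("CA", "CB", "CG"), 1.23, 120.8, _chi(2)),
          ZEntry("ND2", "N", ("CA", "CB", "CG"), 1.33, 116.4, _chi(2, 180.0))],
    "D": [_CB,
          ZEntry("CG", "C", ("N", "CA", "CB"), 1.52, 112.6, _chi(1)),
          ZEntry("OD1", "O", ("CA", "CB", "CG"), 1.25, 118.4, _chi(2)),
          ZEntry("OD2", "O", ("CA", "CB", "CG"), 1.25, 118.4, _chi(2, 180.0))],
    "Q": [_CB,
          ZEntry("CG", "C", ("N", "CA", "CB"), 1.52, 114.1, _chi(1)),
          ZEntry("CD", "C", ("CA", "CB", "CG"), 1.52, 112.6, _chi(2)),
          ZEntry("OE1", "O", ("CB", "CG", "CD"), 1.23, 120.8, _fx(180.0)),
          ZEntry("NE2", "N", ("CB", "CG", "CD"), 1.33, 116.4, _fx(0.0))],
    "E": [_CB,
          ZEntry("CG", "C", ("N", "CA", "CB"), 1.52, 114.1, _chi(1)),
          ZEntry("CD", "C", ("CA", "CB", "CG"), 1.52, 112.6, _chi(2)),
          ZEntry("OE1", "O", ("CB", "CG", "CD"), 1.25, 118.4, _fx(180.0)),
          ZEntry("OE2", "O", ("CB", "CG", "CD"), 1.25, 118.4, _fx(0.0))],
    "M": [_CB,
          ZEntry("CG", "C", ("N", "CA", "CB"), 1.52, 114.1, _chi(1)),
          ZEntry("SD", "S", ("CA", "CB", "CG"), 1.80, 112.7, _chi(2)),
          ZEntry("CE", "C", ("CB", "CG", "SD"), 1.79, 100.2, _fx(180.0))],
    "K": [_CB,
          ZEntry("CG", "C", ("N", "CA", "CB"), 1.52, 114.1, _chi(1)),
          ZEntry("CD", "C", ("CA", "CB", "CG"), 1.52, 111.3, _chi(2)),
          ZEntry("CE", "C", ("CB", "CG", "CD"), 1.52, 111.3, _fx(180.0)),
          ZEntry("NZ", "N", ("CG", "CD", "CE"), 1.49, 111.9, _fx(180.0))],
    "R": [_CB,
          ZEntry("CG", "C", ("N", "CA", "CB"), 1.52, 114.1, _chi(1)),
          ZEntry("CD", "C", ("CA", "CB", "CG"), 1.52, 111.3, _chi(2)),
          ZEntry("NE", "N", ("CB", "CG", "CD"), 1.46, 112.0, _fx(180.0)),
          ZEntry("CZ", "C", ("CG", "CD", "NE"), 1.33, 124.2, _fx(180.0)),
          ZEntry("NH1", "N", ("CD", "NE", "CZ"), 1.33, 120.0, _fx(0.0)),
          ZEntry("NH2", "N", ("CD", "NE", "CZ"), 1.33, 120.0, _fx(180.0))],
    "F": [_CB,
          ZEntry("CG", "C", ("N", "CA", "CB"), 1.51, 113.8, _chi(1)),
          ZEntry("CD1", "C", ("CA", "CB", "CG"), 1.39, 120.7, _chi(2)),
          ZEntry("CD2", "C", ("CA", "CB", "CG"), 1.39, 120.7, _chi(2, 180.0)),
          ZEntry("CE1", "C", ("CB", "CG", "CD1"), 1.39, 120.7, _fx(180.0)),
          ZEntry("CE2", "C", ("CB", "CG", "CD2"), 1.39, 120.7, _fx(180.0)),
          ZEntry("CZ", "C", ("CG", "CD1", "CE1"), 1.39, 120.0, _fx(0.0))],
    "Y": [_CB,
          ZEntry("CG", "C", ("N", "CA", "CB"), 1.51, 113.8, _chi(1)),
          ZEntry("CD1", "C", ("CA", "CB", "CG"), 1.39, 120.7, _chi(2)),
          ZEntry("CD2", "C", ("CA", "CB", "CG"), 1.39, 120.7, _chi(2, 180.0)),
          ZEntry("CE1", "C", ("CB", "CG", "CD1"), 1.39, 120.7, _fx(180.0)),
          ZEntry("CE2", "C", ("CB", "CG", "CD2"), 1.39, 120.7, _fx(180.0)),
          ZEntry("CZ", "C", ("CG", "CD1", "CE1"), 1.39, 120.0, _fx(0.0)),
          ZEntry("OH", "O", ("CD1", "CE1", "CZ"), 1.38, 119.9, _fx(180.0))],
    "H": [_CB,
          ZEntry("CG", "C", ("N", "CA", "CB"), 1.50, 113.8, _chi(1)),
          ZEntry("ND1", "N", ("CA", "CB", "CG"), 1.38, 122.7, _chi(2)),
          ZEntry("CD2", "C", ("CA", "CB", "CG"), 1.36, 131.1, _chi(2, 180.0)),
          ZEntry("CE1", "C", ("CB", "CG", "ND1"), 1.32, 109.0, _fx(180.0)),
          ZEntry("NE2", "N", ("CB", "CG", "CD2"), 1.37, 107.2, _fx(180.0))],
    "W": [_CB,
          ZEntry("CG", "C", ("N", "CA", "CB"), 1.50, 113.6, _chi(1)),
          ZEntry("CD1", "C", ("CA", "CB", "CG"), 1.37, 126.9, _chi(2)),
          ZEntry("CD2", "C", ("CA", "CB", "CG"), 1.43, 126.6, _chi(2, 180.0)),
          ZEntry("NE1", "N", ("CB", "CG", "CD1"), 1.38, 110.2, _fx(180.0)),
          ZEntry("CE2", "C", ("CB", "CG", "CD2"), 1.41, 107.2, _fx(180.0)),
          ZEntry("CE3", "C", ("CB", "CG", "CD2"), 1.40, 133.9, _fx(0.0)),
          ZEntry("CZ2", "C", ("CG", "CD2", "CE2"), 1.40, 122.4, _fx(180.0)),
          ZEntry("CZ3", "C", ("CG", "CD2", "CE3"), 1.39, 118.7, _fx(180.0)),
          ZEntry("CH2", "C", ("CD2", "CE2", "CZ2"), 1.37, 117.5, _fx(0.0))],
    # proline's ring is built from a fixed pucker; no chi sampling
    "P": [ZEntry("CB", "C", ("C", "N", "CA"), 1.53, 103.2, _fx(-120.0)),
          ZEntry("CG", "C", ("N", "CA", "CB"), 1.50, 104.5, _fx(30.0)),
          ZEntry("CD", "C", ("CA", "CB", "CG"), 1.51, 105.5, _fx(-35.0))],
}

#: number of sampled torsions per residue type (chi1/chi2 only)
N_CHI = {
    aa: max([e.dihedral[1] for e in entries if e.dihedral[0] == "chi"], default=0)
    for aa, entries in SIDECHAIN_ZMATRIX.items()
}

#: heavy side-chain atom names per residue type
SIDECHAIN_ATOMS = {aa: tuple(e.name for e in entries)
                   for aa, entries in SIDECHAIN_ZMATRIX.items()}

#: side-chain heavy-atom count, used for greedy big-first placement order
SIDECHAIN_SIZE = {aa: len(names) for aa, names in SIDECHAIN_ATOMS.items()}
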