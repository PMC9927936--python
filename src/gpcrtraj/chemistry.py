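"""Static donor/acceptor chemistry for standard amino acids and water.

Heavy-atom hydrogen-bond chemistry of the twenty standard residues:
side-chain donors are listed with the hydrogen names conventionally
attached to them (PDB v3 naming), acceptors as bare heavy atoms.  Backbone
amide N (donor, hydrogen "H") and carbonyl O (acceptor) are added for every
amino acid.  Ligand or modified-residue atoms are not guessed; they must be
annotated explicitly by the caller.
"""

from __future__ import annotations

from .structure_io import WATER_RESNAMES

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

# residue -> list of (heavy donor atom, hydrogen names on it)
_SIDECHAIN_DONORS: dict[str, list[tuple[str, tuple[str, ...]]]] = {
    "ARG": [("NE", ("HE",)), ("NH1", ("HH11", "HH12")), ("NH2", ("HH21", "HH22"))],
    "ASN": [("ND2", ("HD21", "HD22"))],
    "GLN": [("NE2", ("HE21", "HE22"))],
    "HIS": [("ND1", ("HD1",)), ("NE2", ("HE2",))],
    "LYS": [("NZ", ("HZ1", "HZ2", "HZ3"))],
    "SER": [("OG", ("HG",))],
    "THR": [("OG1", ("HG1",))],
    "TRP": [("NE1", ("HE1",))],
    "TYR": [("OH", ("HH",))],
    "CYS": [("SG", ("HG",))],
}

# residue -> list of acceptor heavy atoms
_SIDECHAIN_ACCEPTORS: dict[str, list[str]] = {
    "ASN": ["OD1"],
    "ASP": ["OD1", "OD2"],
    "GLN": ["OE1"],
    "GLU": ["OE1", "OE2"],
    "HIS": ["ND1", "NE2"],
    "SER": ["OG"],
    "THR": ["OG1"],
    "TYR": ["OH"],
    "MET": ["SD"],
}

_BACKBONE_DONOR = ("N", ("H",))
_BACKBONE_ACCEPTOR = "O"

_WATER_DONOR = ("O", ("H1", "H2"))
_WATER_ACCEPTOR = "O"


def donors_for(residue_name: str) -> list[tuple[str, tuple[str, ...]]]:
    """Donor heavy atoms (with their hydrogens) for one residue type."""
    if residue_name in WATER_RESNAMES:
        return [_WATER_DONOR]
    if residue_name not in STANDARD_AMINO_ACIDS:
        return []
    out = [_BACKBONE_DONOR]
    out.extend(_SIDECHAIN_DONORS.get(residue_name, []))
    return out


def acceptors_for(residue_name: str) -> list[str]:
    """Acceptor heavy atoms for one residue type."""
    if residue_name in WATER_RESNAMES:
        return [_WATER_ACCEPTOR]
    if residue_name not in STANDARD_AMINO_ACIDS:
        return []
    out = [_BACKBONE_ACCEPTOR]
    out.extend(_SIDECHAIN_ACCEPTORS.get(residue_name, []))
    return out
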