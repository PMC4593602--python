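"""Ideal-geometry side-chain construction.

Each side chain is described as a small internal-coordinate table: every
atom is placed from three previously known atoms by bond length, bond angle
and torsion (NeRF).  Rotatable torsions reference a packaged table of the
single most common backbone-independent rotamer; ring geometries use fixed
torsions.  Bond lengths and angles follow standard stereochemical
dictionaries to ~0.01 A / 1 degree, which is sufficient for contact
detection — no energy minimisation is attempted, and steric clashes are
reported rather than resolved.
"""

from __future__ import annotations

import numpy as np

from .geometry import place_atom
from .model import Residue

__all__ = [
    "SIDECHAIN_ATOMS",
    "DEFAULT_CHI",
    "build_cb",
    "build_side_chain",
    "sidechain_atom_names",
]

# most common backbone-independent rotamer, degrees
DEFAULT_CHI: dict[str, tuple[float, ...]] = {
    "ARG": (-67.0, 180.0, 180.0, 180.0),
    "ASN": (-65.0, -65.0),
    "ASP": (-70.0, -15.0),
    "CYS": (-65.0,),
    "GLN": (-65.0, 180.0, 0.0),
    "GLU": (-65.0, 180.0, 0.0),
    "HIS": (-65.0, -75.0),
    "ILE": (-65.0, 170.0),
    "LEU": (-65.0, 175.0),
    "LYS": (-65.0, 180.0, 180.0, 180.0),
    "MET": (-65.0, 180.0, 75.0),
    "PHE": (-65.0, 90.0),
    "PRO": (30.0, -35.0),
    "SER": (65.0,),
    "THR": (65.0,),
    "TRP": (-65.0, 95.0),
    "TYR": (-65.0, 90.0),
    "VAL": (175.0,),
}

# (atom, (a, b, c), bond, angle, torsion) with torsion either a float or
# ("chi", k, offset) meaning chi_k + offset.
_Z = dict[str, list]
SIDECHAIN_ATOMS: dict[str, list[tuple]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.42, 111.1, ("chi", 1, 0.0))],
    "CYS": [("SG", ("N", "CA", "CB"), 1.81, 114.0, ("chi", 1, 0.0))],
    "THR": [
        ("OG1", ("N", "CA", "CB"), 1.43, 109.6, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, -120.0)),
    ],
    "VAL": [
        ("CG1", ("N", "CA", "CB"), 1.53, 110.5, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.53, 110.5, ("chi", 1, -122.0)),
    ],
    "ILE": [
        ("CG1", ("N", "CA", "CB"), 1.53, 110.4, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.53, 110.5, ("chi", 1, -122.0)),
        ("CD1", ("CA", "CB", "CG1"), 1.52, 113.8, ("chi", 2, 0.0)),
    ],
    "LEU": [
        ("CG", ("N", "CA", "CB"), 1.53, 116.3, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.52, 110.7, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.52, 110.7, ("chi", 2, 122.0)),
    ],
    "ASP": [
        ("CG", ("N", "CA", "CB"), 1.52, 112.6, ("chi", 1, 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.25, 118.4, ("chi", 2, 0.0)),
        ("OD2", ("CA", "CB", "CG"), 1.25, 118.4, ("chi", 2, 180.0)),
    ],
    "ASN": [
        ("CG", ("N", "CA", "CB"), 1.52, 112.6, ("chi", 1, 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.23, 120.8, ("chi", 2, 0.0)),
        ("ND2", ("CA", "CB", "CG"), 1.33, 116.4, ("chi", 2, 180.0)),
    ],
    "GLU": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2, 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.25, 118.4, ("chi", 3, 0.0)),
        ("OE2", ("CB", "CG", "CD"), 1.25, 118.4, ("chi", 3, 180.0)),
    ],
    "GLN": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2, 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.23, 120.8, ("chi", 3, 0.0)),
        ("NE2", ("CB", "CG", "CD"), 1.33, 116.4, ("chi", 3, 180.0)),
    ],
    "MET": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
        ("SD", ("CA", "CB", "CG"), 1.80, 112.7, ("chi", 2, 0.0)),
        ("CE", ("CB", "CG", "SD"), 1.79, 100.9, ("chi", 3, 0.0)),
    ],
    "LYS": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2, 0.0)),
        ("CE", ("CB", "CG", "CD"), 1.52, 111.7, ("chi", 3, 0.0)),
        ("NZ", ("CG", "CD", "CE"), 1.49, 111.9, ("chi", 4, 0.0)),
    ],
    "ARG": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2, 0.0)),
        ("NE", ("CB", "CG", "CD"), 1.46, 112.0, ("chi", 3, 0.0)),
        ("CZ", ("CG", "CD", "NE"), 1.33, 124.2, ("chi", 4, 0.0)),
        ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
        ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0),
    ],
    "HIS": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0.0)),
        ("ND1", ("CA", "CB", "CG"), 1.38, 122.7, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.36, 131.0, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "ND1"), 1.32, 109.3, 180.0),
        ("NE2", ("CB", "CG", "CD2"), 1.37, 107.2, 180.0),
    ],
    "PHE": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
    ],
    "TYR": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
        ("OH", ("CD1", "CE1", "CZ"), 1.38, 120.0, 180.0),
    ],
    "TRP": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.37, 127.0, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.43, 126.6, ("chi", 2, 180.0)),
        ("NE1", ("CB", "CG", "CD1"), 1.38, 110.2, 180.0),
        ("CE2", ("CG", "CD1", "NE1"), 1.37, 109.0, 0.0),
        ("CE3", ("CB", "CG", "CD2"), 1.40, 133.9, 0.0),
        ("CZ2", ("CD1", "NE1", "CE2"), 1.40, 130.4, 180.0),
        ("CZ3", ("CG", "CD2", "CE3"), 1.39, 118.8, 180.0),
        ("CH2", ("CD2", "CE2", "CZ2"), 1.37, 117.5, 0.0),
    ],
    "PRO": [
        ("CG", ("N", "CA", "CB"), 1.49, 104.5, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.50, 106.1, ("chi", 2, 0.0)),
    ],
}


def sidechain_atom_names(resname: str) -> list[str]:
    """All heavy side-chain atom names (CB included) for a residue type."""
    if resname == "GLY":
        return []
    return ["CB"] + [row[0] for row in SIDECHAIN_ATOMS.get(resname, [])]


def build_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral C-beta from backbone N, CA, C.

    The improper torsion N-C-CA-CB of +123.2 deg fixes L-chirality.
    """
    return place_atom(n, c, ca, 1.53, 111.1, 123.2)


def build_side_chain(
    residue: Residue,
    target: str,
    chi: tuple[float, ...] | None = None,
) -> dict[str, np.ndarray]:
    """Coordinates for the side chain of ``target`` on ``residue``'s backbone.

    Uses the residue's own CB when present, otherwise constructs one.
    Returns a name -> coordinate mapping (CB included for non-Gly targets).
    """
    if target not in SIDECHAIN_ATOMS:
        raise ValueError(f"unknown residue type {target!r}")
    if not residue.has_backbone():
        raise ValueError(f"residue {residue.label} lacks backbone atoms")
    coords: dict[str, np.ndarray] = {
        "N": residue.coord("N"),
        "CA": residue.coord("CA"),
        "C": residue.coord("C"),
    }
    if target == "GLY":
        return {}
    if "CB" in residue.atoms:
        coords["CB"] = residue.coord("CB")
    else:
        coords["CB"] = build_cb(coords["N"], coords["CA"], coords["C"])
    chis = chi if chi is not None else DEFAULT_CHI.get(target, ())
    out: dict[str, np.ndarray] = {"CB": coords["CB"]}
    for name, (a, b, c), bond, ang, tor in SIDECHAIN_ATOMS[target]:
        if isinstance(tor, tuple):
            _, k, offset = tor
            if k > len(chis):
                raise ValueError(f"{target} needs chi{k} but only {len(chis)} given")
            tor_val = chis[k - 1] + offset
        else:
            tor_val = tor
        pos = place_atom(coords[a], coords[b], coords[c], bond, ang, tor_val)
        coords[name] = pos
        out[name] = pos
    return out
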