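"""Synthetic test structures with controlled geometry.

Peptides are grown residue-by-residue from ideal bond lengths and angles at
requested phi/psi (NeRF construction), so canonical secondary structures
(alpha helix at -57/-47, extended strand at 180/180, beta turns at
literature phi/psi) can be produced exactly.  ``residue_pair`` fixtures
place two fully built residues so that two named atoms sit at an exact
distance, and ``metal_site`` fixtures arrange coordinating residues around
a central ion.  Every fixture re-parses losslessly through the PDB reader.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import place_atom, unit
from .model import Atom, Chain, Residue, Structure
from .sidechains import DEFAULT_CHI, build_cb, build_side_chain

__all__ = ["FixtureSpec", "make_fixture", "build_peptide"]

# ideal backbone geometry
_N_CA, _CA_C, _C_N, _C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA = 111.2, 116.2, 121.7
_ANG_CA_C_O = 120.8
_OMEGA = 180.0

_ELEMENT = {"N": "N", "C": "C", "O": "O", "S": "S"}


def _element_of(atom_name: str) -> str:
    # peptide heavy atoms only; metal elements are set explicitly
    return _ELEMENT.get(atom_name[0], atom_name[0])


@dataclasses.dataclass
class FixtureSpec:
    """Recipe for a synthetic structure.

    kind:
        one of ``ideal_helix``, ``extended_strand``, ``beta_turn``,
        ``residue_pair``, ``left_handed_site``, ``metal_site``.
    length:
        number of residues (where meaningful).
    phi, psi:
        backbone dihedrals in degrees for uniform-conformation kinds.
    sequence:
        optional 1- or 3-letter residue names; defaults to polyalanine.
    pair_residues, pair_atoms, pair_distance:
        for ``residue_pair``: two 3-letter codes, the two atom names to
        separate, and the exact distance in Angstrom.
    turn_type:
        for ``beta_turn``: one of I, I', II, II', VIII.
    metal:
        element symbol for ``metal_site`` (default ZN).
    """

    kind: str
    length: int = 12
    phi: float = -57.0
    psi: float = -47.0
    sequence: list[str] | str | None = None
    pair_residues: tuple[str, str] = ("ASP", "LYS")
    pair_atoms: tuple[str, str] = ("OD1", "NZ")
    pair_distance: float = 3.0
    turn_type: str = "I"
    metal: str = "ZN"


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# canonical (phi,psi) at positions 2 and 3 of the four-residue turn
TURN_ANGLES = {
    "I": ((-60.0, -30.0), (-90.0, 0.0)),
    "I'": ((60.0, 30.0), (90.0, 0.0)),
    "II": ((-60.0, 120.0), (80.0, 0.0)),
    "II'": ((60.0, -120.0), (-80.0, 0.0)),
    "VIII": ((-60.0, -30.0), (-120.0, 120.0)),
}


def _normalize_sequence(sequence, length: int) -> list[str]:
    if sequence is None:
        return ["ALA"] * length
    if isinstance(sequence, str):
        names = [_ONE_TO_THREE.get(c.upper(), "ALA") for c in sequence]
    else:
        names = [s.upper() for s in sequence]
    if len(names) != length:
        raise ValueError(f"sequence length {len(names)} != requested length {length}")
    return names


def build_peptide(
    sequence,
    phi_psi: list[tuple[float, float]],
    chain_id: str = "A",
    start_number: int = 1,
    with_side_chains: bool = True,
) -> Structure:
    """Build a continuous peptide at per-residue (phi, psi).

    phi of the first residue and psi of the last are ignored (undefined).
    """
    names = _normalize_sequence(sequence, len(phi_psi))
    n_res = len(names)
    if n_res < 1:
        raise ValueError("need at least one residue")

    # backbone trace: seed residue, then extend C->N->CA->C using
    # omega (trans), phi, psi torsions
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_N_CA, 0.0, 0.0])
    # arbitrary rotation about the N-CA axis; only the N-CA-C angle matters
    c0 = place_atom(np.array([0.0, 1.0, 0.0]), n0, ca0, _CA_C, _ANG_N_CA_C, 57.0)
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = coords[-1]
        psi_prev = phi_psi[i - 1][1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], _C_N, _ANG_CA_C_N, psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i, _N_CA, _ANG_C_N_CA, _OMEGA)
        phi_i = phi_psi[i][0]
        c_i = place_atom(prev["C"], n_i, ca_i, _CA_C, _ANG_N_CA_C, phi_i)
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl oxygens: O anti to the next N (torsion psi+180); for the
    # last residue use its nominal psi
    for i in range(n_res):
        psi_i = phi_psi[i][1]
        coords[i]["O"] = place_atom(
            coords[i]["N"], coords[i]["CA"], coords[i]["C"], _C_O, _ANG_CA_C_O,
            psi_i + 180.0,
        )

    chain = Chain(id=chain_id)
    for i, name in enumerate(names):
        res = Residue(chain_id=chain_id, number=start_number + i, name=name)
        for an in ("N", "CA", "C", "O"):
            res.atoms[an] = Atom(an, _element_of(an), coords[i][an])
        if with_side_chains and name != "GLY":
            res.atoms["CB"] = Atom(
                "CB", "C", build_cb(coords[i]["N"], coords[i]["CA"], coords[i]["C"])
            )
            for an, pos in build_side_chain(res, name).items():
                if an not in res.atoms:
                    res.atoms[an] = Atom(an, _element_of(an), pos)
        chain.residues.append(res)
    return Structure(id="fixture", chains=[chain])


def _uniform(spec: FixtureSpec, phi: float, psi: float) -> Structure:
    if spec.length < 1:
        raise ValueError("length must be >= 1")
    return build_peptide(
        _normalize_sequence(spec.sequence, spec.length),
        [(phi, psi)] * spec.length,
    )


def _beta_turn(spec: FixtureSpec) -> Structure:
    if spec.turn_type not in TURN_ANGLES:
        raise ValueError(f"unknown turn type {spec.turn_type!r}")
    (phi2, psi2), (phi3, psi3) = TURN_ANGLES[spec.turn_type]
    length = max(spec.length, 6)
    names = _normalize_sequence(spec.sequence, length) if spec.sequence else ["ALA"] * length
    # turn occupies positions 2..5 of the chain (start residue = index 1)
    phi_psi = [(180.0, 180.0)] * length
    phi_psi[2] = (phi2, psi2)
    phi_psi[3] = (phi3, psi3)
    return build_peptide(names, phi_psi)


def _left_handed(spec: FixtureSpec) -> Structure:
    length = max(spec.length, 5)
    names = _normalize_sequence(spec.sequence, length) if spec.sequence else ["ALA"] * length
    mid = length // 2
    phi_psi = [(-140.0, 140.0)] * length
    phi_psi[mid] = (60.0, 40.0)
    return build_peptide(names, phi_psi)


def _residue_pair(spec: FixtureSpec) -> Structure:
    if spec.pair_distance <= 0:
        raise ValueError("pair_distance must be positive")
    name_a, name_b = (n.upper() for n in spec.pair_residues)
    atom_a, atom_b = spec.pair_atoms
    sa = build_peptide([name_a], [(180.0, 180.0)])
    sb = build_peptide([name_b], [(180.0, 180.0)])
    res_a = sa.chains[0].residues[0]
    res_b = sb.chains[0].residues[0]
    if atom_a not in res_a.atoms:
        raise ValueError(f"{name_a} has no atom {atom_a!r}")
    if atom_b not in res_b.atoms:
        raise ValueError(f"{name_b} has no atom {atom_b!r}")
    # shift B far away, then approach along the inter-atom axis to the
    # exact requested separation
    for atom in res_b.atoms.values():
        atom.coord = atom.coord + np.array([50.0, 0.0, 0.0])
    d = res_b.coord(atom_b) - res_a.coord(atom_a)
    shift = (spec.pair_distance - np.linalg.norm(d)) * unit(d)
    for atom in res_b.atoms.values():
        atom.coord = atom.coord + shift
    res_b.number = res_a.number + 9
    res_b.chain_id = res_a.chain_id
    sa.chains[0].residues.append(res_b)
    sa.id = "fixture"
    return sa


def _metal_site(spec: FixtureSpec) -> Structure:
    """Four CYS arranged tetrahedrally, SG at 2.3 A from a central ion."""
    vertices = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    vertices /= np.linalg.norm(vertices[0])
    chain = Chain(id="A")
    for i, v in enumerate(vertices):
        s = build_peptide(["CYS"], [(180.0, 180.0)])
        res = s.chains[0].residues[0]
        res.number = 1 + i * 10
        # put SG on the vertex, push the rest of the residue outward
        sg = res.coord("SG")
        target_sg = 2.3 * v
        shift = target_sg - sg
        outward = 3.0 * v
        for atom in res.atoms.values():
            atom.coord = atom.coord + shift + (0 if atom.name == "SG" else 1) * outward
        res.atoms["SG"].coord = target_sg
        chain.residues.append(res)
    metal = Residue(chain_id="A", number=99, name=spec.metal.upper(), is_hetero=True)
    metal.atoms[spec.metal.upper()] = Atom(
        spec.metal.upper(), spec.metal.upper(), np.zeros(3), hetero=True
    )
    chain.residues.append(metal)
    return Structure(id="fixture", chains=[chain])


def make_fixture(spec: FixtureSpec) -> Structure:
    """Build the structure described by ``spec``."""
    if spec.kind == "ideal_helix":
        return _uniform(spec, spec.phi, spec.psi)
    if spec.kind == "extended_strand":
        return _uniform(spec, 180.0, 180.0)
    if spec.kind == "beta_turn":
        return _beta_turn(spec)
    if spec.kind == "left_handed_site":
        return _left_handed(spec)
    if spec.kind == "residue_pair":
        return _residue_pair(spec)
    if spec.kind == "metal_site":
        return _metal_site(spec)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
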