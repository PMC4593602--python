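"""Coordinate model: Structure / Chain / Residue / Atom plus PDB I/O.

The reader is backed by :mod:`gemmi` and collapses the file to a single
model with one conformer per residue (highest occupancy altloc, ties broken
toward 'A').  Author residue numbering, including insertion codes, is kept
throughout because all downstream reports cite author numbers.  Waters are
dropped; other HETATM groups are retained as hetero residues so that metal
sites remain analysable.  Selenomethionine (MSE) is mapped to MET.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "ParseError",
    "load_structure",
    "write_structure",
    "structure_to_pdb_string",
    "extract_sequence",
    "THREE_TO_ONE",
    "STANDARD_AA",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
STANDARD_AA = frozenset(THREE_TO_ONE)
_WATERS = {"HOH", "WAT", "DOD", "H2O"}

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")


class ParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


@dataclasses.dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    hetero: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)


@dataclasses.dataclass
class Residue:
    chain_id: str
    number: int
    name: str
    icode: str = ""
    atoms: dict[str, Atom] = dataclasses.field(default_factory=dict)
    is_hetero: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    @property
    def is_standard_aa(self) -> bool:
        return self.name in STANDARD_AA

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C", "O"))

    def get(self, atom_name: str) -> Atom | None:
        return self.atoms.get(atom_name)

    def coord(self, atom_name: str) -> np.ndarray:
        try:
            return self.atoms[atom_name].coord
        except KeyError:
            raise KeyError(f"residue {self.label} has no atom {atom_name!r}") from None

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.name}{self.number}{self.icode}"


@dataclasses.dataclass
class Chain:
    id: str
    residues: list[Residue] = dataclasses.field(default_factory=list)

    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_standard_aa and not r.is_hetero]


@dataclasses.dataclass
class Structure:
    id: str
    chains: list[Chain] = dataclasses.field(default_factory=list)
    model_index: int = 1
    source_path: str = ""

    def residues(self, protein_only: bool = False) -> Iterator[Residue]:
        for chain in self.chains:
            for res in chain.residues:
                if protein_only and (res.is_hetero or not res.is_standard_aa):
                    continue
                yield res

    def hetero_residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            for res in chain.residues:
                if res.is_hetero:
                    yield res

    def get_chain(self, chain_id: str) -> Chain:
        for chain in self.chains:
            if chain.id == chain_id:
                return chain
        raise KeyError(f"no chain {chain_id!r} in structure {self.id}")

    def get_residue(self, key: tuple[str, int, str]) -> Residue:
        chain = self.get_chain(key[0])
        for res in chain.residues:
            if res.number == key[1] and res.icode == (key[2] or ""):
                return res
        raise KeyError(f"no residue {key} in structure {self.id}")

    def n_protein_residues(self) -> int:
        return sum(1 for _ in self.residues(protein_only=True))

    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def copy(self) -> "Structure":
        new_chains = []
        for chain in self.chains:
            new_res = []
            for res in chain.residues:
                atoms = {
                    n: Atom(a.name, a.element, a.coord.copy(), a.occupancy,
                            a.b_factor, a.hetero)
                    for n, a in res.atoms.items()
                }
                new_res.append(Residue(res.chain_id, res.number, res.name,
                                       res.icode, atoms, res.is_hetero))
            new_chains.append(Chain(chain.id, new_res))
        return Structure(self.id, new_chains, self.model_index, self.source_path)


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties resolve to the alphabetically first
    altloc, so 'A' beats 'B' and a blank altloc beats everything."""
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def load_structure(path: str | Path, model: int | None = None) -> Structure:
    """Read a PDB (or mmCIF) file into a :class:`Structure`.

    Parameters
    ----------
    path:
        Coordinate file with at least one ATOM record.
    model:
        1-based model number to keep for multi-model (NMR/ensemble) files.
        Default: the first model in the file.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    try:
        gst = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(gst) == 0:
        raise ParseError(f"{path}: no coordinate models found")

    if model is None:
        gmodel = gst[0]
    else:
        available = [m.num for m in gst]
        matches = [m for m in gst if m.num == model]
        if not matches:
            raise ParseError(
                f"{path}: model {model} not present; available models: {available}"
            )
        gmodel = matches[0]

    st = Structure(id=gst.name or path.stem, model_index=gmodel.num,
                   source_path=str(path))
    for gchain in gmodel:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            name = gres.name.strip()
            if name in _WATERS:
                continue
            hetero = gres.het_flag == "H"
            if name == "MSE":
                name, hetero = "MET", False
            res = Residue(
                chain_id=gchain.name,
                number=gres.seqid.num,
                name=name,
                icode=(gres.seqid.icode or "").strip(),
                is_hetero=hetero and name not in STANDARD_AA,
            )
            by_name: dict[str, list[gemmi.Atom]] = {}
            for gatom in gres:
                by_name.setdefault(gatom.name, []).append(gatom)
            for atom_name, group in by_name.items():
                g = _pick_altloc(group)
                out_name = "SD" if (gres.name == "MSE" and atom_name == "SE") else atom_name
                element = g.element.name.upper()
                if gres.name == "MSE" and atom_name == "SE":
                    element = "S"
                res.atoms[out_name] = Atom(
                    name=out_name,
                    element=element,
                    coord=np.array([g.pos.x, g.pos.y, g.pos.z]),
                    occupancy=g.occ,
                    b_factor=g.b_iso,
                    hetero=res.is_hetero,
                )
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            st.chains.append(chain)

    if st.n_protein_residues() == 0:
        raise ParseError(f"{path}: no protein residues")
    return st


def _format_atom_line(serial: int, atom: Atom, res: Residue) -> str:
    record = "HETATM" if res.is_hetero else "ATOM  "
    name = atom.name
    if len(name) < 4:
        # element symbols of one letter are right-justified into column 14
        name = (" " + name) if len(atom.element) == 1 else name
    x, y, z = atom.coord
    return (
        f"{record}{serial:5d} {name:<4s}{'':1s}{res.name:>3s} "
        f"{res.chain_id[:1]:1s}{res.number:4d}{res.icode or '':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
        f"          {atom.element:>2s}"
    )


def structure_to_pdb_string(structure: Structure) -> str:
    if structure.atom_count() == 0:
        raise ValueError("refusing to write a structure with no atoms")
    lines: list[str] = []
    serial = 0
    for chain in structure.chains:
        last_protein = None
        for res in chain.residues:
            for atom in res.atoms.values():
                serial += 1
                lines.append(_format_atom_line(serial, atom, res))
            if not res.is_hetero:
                last_protein = res
        if last_protein is not None:
            serial += 1
            lines.append(
                f"TER   {serial:5d}      {last_protein.name:>3s} "
                f"{chain.id[:1]:1s}{last_protein.number:4d}{last_protein.icode or '':1s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write standard PDB ATOM/HETATM records; round-trips through
    :func:`load_structure` at 3-decimal coordinate precision."""
    Path(path).write_text(structure_to_pdb_string(structure))


def extract_sequence(structure: Structure, chain: str | None = None) -> dict[str, str]:
    """One-letter sequence per chain in author-number order.

    Nonstandard residues map to ``X``; hetero residues are skipped.  With
    ``chain`` given, the result contains that single chain (KeyError if it
    does not exist).
    """
    chains = [structure.get_chain(chain)] if chain is not None else structure.chains
    out: dict[str, str] = {}
    for ch in chains:
        seq = "".join(
            res.one_letter for res in ch.residues if not res.is_hetero
        )
        if seq:
            out[ch.id] = seq
    return out
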