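"""Non-covalent interaction detection and interaction networks.

Seven contact classes are detected between residues of a structure:

========  =============================================================
IP        ion pair / salt bridge: charged side-chain N/O of Arg/Lys/His
          against carboxylate O of Asp/Glu within 6.0 A
AAI       aromatic-aromatic: Phe/Tyr/Trp ring-centroid distance in
          [4.5, 7.0] A
ASI       aromatic-sulphur: Cys SG or Met SD within 5.3 A of a ring
          centroid
CPI       cation-pi: Lys NZ or the Arg guanidinium centroid within
          6.0 A of a ring centroid
HB        hydrogen bond: donor-acceptor heavy atoms within 3.5 A (plus
          H geometry when an amide H can be constructed), classed
          MM/MS/SS by main-chain/side-chain membership
HP        hydrophobic: side-chain carbon contact (< 5.0 A) between
          residues of {Ala,Val,Leu,Ile,Met,Phe,Trp,Tyr}, counted once
          per residue pair
DISULFIDE Cys SG-SG within [1.8, 2.5] A
========  =============================================================

All cutoffs are parameters; the defaults above follow the standard
protein-interaction-calculator conventions.  Interactions of one type
sharing residues form networks (connected components with at least two
member interactions), which the comparative analysis treats as more
stabilizing than isolated contacts.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .geometry import angle, distance
from .model import Residue, Structure
from .secstruct import SSAssignment, chain_fragments

__all__ = [
    "Interaction",
    "InteractionNetwork",
    "DisulfideRecord",
    "INTERACTION_TYPES",
    "DEFAULT_CUTOFFS",
    "find_interactions",
    "find_all_interactions",
    "build_networks",
    "disulfide_report",
]

INTERACTION_TYPES = ("IP", "AAI", "ASI", "CPI", "HB", "HP", "DISULFIDE")

DEFAULT_CUTOFFS = {
    "ip_distance": 6.0,
    "aai_min": 4.5,
    "aai_max": 7.0,
    "asi_distance": 5.3,
    "cpi_distance": 6.0,
    "hb_distance": 3.5,
    "hb_h_acceptor_max": 2.5,
    "hb_angle_min": 90.0,
    "hp_distance": 5.0,
    "disulfide_min": 1.8,
    "disulfide_max": 2.5,
}

_POSITIVE = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
_NEGATIVE = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
_SULPHUR = {"CYS": "SG", "MET": "SD"}
_HYDROPHOBIC = frozenset({"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "TYR"})

# side-chain H-bond donors/acceptors (heavy atoms)
_SC_DONORS = {
    "ARG": ("NE", "NH1", "NH2"), "ASN": ("ND2",), "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"), "LYS": ("NZ",), "SER": ("OG",), "THR": ("OG1",),
    "TRP": ("NE1",), "TYR": ("OH",),
}
_SC_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "HIS": ("ND1", "NE2"), "SER": ("OG",), "THR": ("OG1",),
    "TYR": ("OH",),
}
_MAIN_CHAIN_POLAR = ("N", "O", "OXT")


@dataclasses.dataclass
class Interaction:
    type: str
    residue_a: Residue
    residue_b: Residue
    atoms: tuple[str, str]  # atom names or group descriptions
    distance: float
    angle: float | None = None
    hb_class: str | None = None  # MM / MS / SS
    burial: str | None = None  # buried-buried / buried-exposed / exposed-exposed

    @property
    def key_pair(self) -> tuple[tuple, tuple]:
        return (self.residue_a.key, self.residue_b.key)


@dataclasses.dataclass
class InteractionNetwork:
    type: str
    residues: list[Residue]
    interactions: list[Interaction]

    @property
    def size(self) -> int:
        return len(self.interactions)


@dataclasses.dataclass
class DisulfideRecord:
    cys_a: Residue
    cys_b: Residue
    sg_distance: float
    loop_size: int | None  # sequence separation; None across chains
    exposure: tuple[str, str] | None = None
    ss_labels: tuple[str, str] | None = None


def _canonical(a: Residue, b: Residue) -> tuple[Residue, Residue]:
    return (a, b) if a.key <= b.key else (b, a)


def _seq_sep(a: Residue, b: Residue) -> int | None:
    if a.chain_id != b.chain_id:
        return None
    return abs(a.number - b.number)


def _ring_centroid(res: Residue) -> np.ndarray | None:
    names = _RING_ATOMS.get(res.name)
    if not names:
        return None
    coords = [res.atoms[n].coord for n in names if n in res.atoms]
    if len(coords) < 4:
        return None
    return np.mean(coords, axis=0)


def _pairs_within(
    entries: list[tuple[Residue, np.ndarray]], cutoff: float
) -> Iterable[tuple[int, int]]:
    if len(entries) < 2:
        return []
    tree = cKDTree(np.array([c for _, c in entries]))
    return sorted(tree.query_pairs(cutoff))


def _min_separation_ok(a: Residue, b: Residue, minimum: int = 2) -> bool:
    sep = _seq_sep(a, b)
    return sep is None or sep >= minimum


def find_interactions(
    structure: Structure,
    interaction_type: str,
    params: dict | None = None,
    exposure: dict[tuple, str] | None = None,
) -> list[Interaction]:
    """Deduplicated list of one interaction class, default criteria above.

    ``params`` overrides entries of :data:`DEFAULT_CUTOFFS`; unknown keys
    raise.  With ``exposure`` given (from the SASA module) each contact is
    annotated buried-buried / buried-exposed / exposed-exposed.
    """
    if interaction_type not in INTERACTION_TYPES:
        raise ValueError(
            f"unknown interaction type {interaction_type!r}; "
            f"expected one of {INTERACTION_TYPES}"
        )
    cut = dict(DEFAULT_CUTOFFS)
    if params:
        bad = set(params) - set(cut)
        if bad:
            raise ValueError(f"unknown interaction parameters: {sorted(bad)}")
        cut.update(params)
        if any(v <= 0 for v in params.values()):
            raise ValueError("interaction cutoffs must be positive")

    finder = {
        "IP": _find_ion_pairs,
        "AAI": _find_aromatic,
        "ASI": _find_aromatic_sulphur,
        "CPI": _find_cation_pi,
        "HB": _find_hbonds,
        "HP": _find_hydrophobic,
        "DISULFIDE": _find_disulfides,
    }[interaction_type]
    found = finder(structure, cut)
    if exposure is not None:
        for it in found:
            ea = exposure.get(it.residue_a.key, "exposed")
            eb = exposure.get(it.residue_b.key, "exposed")
            it.burial = f"{min(ea, eb)}-{max(ea, eb)}"
    return found


def find_all_interactions(
    structure: Structure, params: dict | None = None
) -> dict[str, list[Interaction]]:
    return {
        t: find_interactions(structure, t, params) for t in INTERACTION_TYPES
    }


def _charged_entries(structure: Structure, table) -> list[tuple[Residue, str, np.ndarray]]:
    out = []
    for res in structure.residues(protein_only=True):
        for name in table.get(res.name, ()):
            if name in res.atoms:
                out.append((res, name, res.atoms[name].coord))
    return out


def _find_ion_pairs(structure: Structure, cut: dict) -> list[Interaction]:
    pos = _charged_entries(structure, _POSITIVE)
    neg = _charged_entries(structure, _NEGATIVE)
    best: dict[tuple, Interaction] = {}
    if pos and neg:
        tree = cKDTree(np.array([c for _, _, c in neg]))
        for res_p, name_p, coord_p in pos:
            for j in tree.query_ball_point(coord_p, cut["ip_distance"]):
                res_n, name_n, coord_n = neg[j]
                if not _min_separation_ok(res_p, res_n):
                    continue
                a, b = _canonical(res_p, res_n)
                d = distance(coord_p, coord_n)
                key = (a.key, b.key)
                if key not in best or d < best[key].distance:
                    atoms = (name_p, name_n) if a is res_p else (name_n, name_p)
                    best[key] = Interaction("IP", a, b, atoms, d)
    return [best[k] for k in sorted(best)]


def _find_aromatic(structure: Structure, cut: dict) -> list[Interaction]:
    rings = []
    for res in structure.residues(protein_only=True):
        if res.name in ("PHE", "TYR", "TRP"):
            c = _ring_centroid(res)
            if c is not None:
                rings.append((res, c))
    out = []
    for i, j in _pairs_within(rings, cut["aai_max"]):
        res_a, ca = rings[i]
        res_b, cb = rings[j]
        d = distance(ca, cb)
        if d < cut["aai_min"] or not _min_separation_ok(res_a, res_b):
            continue
        a, b = _canonical(res_a, res_b)
        out.append(Interaction("AAI", a, b, ("ring", "ring"), d))
    return out


def _find_aromatic_sulphur(structure: Structure, cut: dict) -> list[Interaction]:
    rings = []
    sulphurs = []
    for res in structure.residues(protein_only=True):
        if res.name in ("PHE", "TYR", "TRP"):
            c = _ring_centroid(res)
            if c is not None:
                rings.append((res, c))
        s_name = _SULPHUR.get(res.name)
        if s_name and s_name in res.atoms:
            sulphurs.append((res, s_name, res.atoms[s_name].coord))
    out = []
    for res_s, s_name, coord_s in sulphurs:
        for res_r, centroid in rings:
            d = distance(coord_s, centroid)
            if d > cut["asi_distance"] or not _min_separation_ok(res_s, res_r):
                continue
            a, b = _canonical(res_s, res_r)
            atoms = (s_name, "ring") if a is res_s else ("ring", s_name)
            out.append(Interaction("ASI", a, b, atoms, d))
    return sorted(out, key=lambda it: it.key_pair)


def _find_cation_pi(structure: Structure, cut: dict) -> list[Interaction]:
    cations = []
    for res in structure.residues(protein_only=True):
        if res.name == "LYS" and "NZ" in res.atoms:
            cations.append((res, "NZ", res.atoms["NZ"].coord))
        elif res.name == "ARG":
            names = [n for n in ("NE", "CZ", "NH1", "NH2") if n in res.atoms]
            if len(names) >= 3:
                cations.append(
                    (res, "guan", np.mean([res.atoms[n].coord for n in names], axis=0))
                )
    rings = []
    for res in structure.residues(protein_only=True):
        if res.name in ("PHE", "TYR", "TRP"):
            c = _ring_centroid(res)
            if c is not None:
                rings.append((res, c))
    out = []
    for res_c, label, coord_c in cations:
        for res_r, centroid in rings:
            d = distance(coord_c, centroid)
            if d > cut["cpi_distance"] or not _min_separation_ok(res_c, res_r):
                continue
            a, b = _canonical(res_c, res_r)
            atoms = (label, "ring") if a is res_c else ("ring", label)
            out.append(Interaction("CPI", a, b, atoms, d))
    return sorted(out, key=lambda it: it.key_pair)


def _donor_entries(structure: Structure) -> list[tuple[Residue, str, bool]]:
    """(residue, atom name, is_main_chain) for every H-bond donor atom."""
    out = []
    for res in structure.residues(protein_only=True):
        if res.name != "PRO" and "N" in res.atoms:
            out.append((res, "N", True))
        for name in _SC_DONORS.get(res.name, ()):
            if name in res.atoms:
                out.append((res, name, False))
    return out


def _acceptor_entries(structure: Structure) -> list[tuple[Residue, str, bool]]:
    out = []
    for res in structure.residues(protein_only=True):
        for name in ("O", "OXT"):
            if name in res.atoms:
                out.append((res, name, True))
        for name in _SC_ACCEPTORS.get(res.name, ()):
            if name in res.atoms:
                out.append((res, name, False))
    return out


def _find_hbonds(structure: Structure, cut: dict) -> list[Interaction]:
    from .secstruct import _amide_hydrogens  # shared construction

    fragments = chain_fragments(structure)
    h_pos = _amide_hydrogens(fragments)
    donors = _donor_entries(structure)
    acceptors = _acceptor_entries(structure)
    if not donors or not acceptors:
        return []
    tree = cKDTree(np.array([r.atoms[n].coord for r, n, _ in acceptors]))
    best: dict[tuple, Interaction] = {}
    for res_d, name_d, mc_d in donors:
        coord_d = res_d.atoms[name_d].coord
        for j in tree.query_ball_point(coord_d, cut["hb_distance"]):
            res_a, name_a, mc_a = acceptors[j]
            if res_a.key == res_d.key:
                continue
            sep = _seq_sep(res_d, res_a)
            if mc_d and mc_a and sep is not None and sep <= 1:
                continue  # the peptide bond itself is not a hydrogen bond
            coord_a = res_a.atoms[name_a].coord
            d = distance(coord_d, coord_a)
            ang = None
            if name_d == "N":
                h = h_pos.get(res_d.key)
                if h is not None:
                    if distance(h, coord_a) > cut["hb_h_acceptor_max"]:
                        continue
                    ang = angle(coord_d, h, coord_a)
                    if ang < cut["hb_angle_min"]:
                        continue
            klass = "MM" if (mc_d and mc_a) else ("SS" if not (mc_d or mc_a) else "MS")
            a, b = _canonical(res_d, res_a)
            # direction-sensitive dedup: reciprocal bonds (as in antiparallel
            # sheets) are distinct contacts, re-reporting the same donor ->
            # acceptor pair is not
            pair_key = (a.key, b.key, klass, a is res_d)
            if pair_key not in best or d < best[pair_key].distance:
                atoms = (name_d, name_a) if a is res_d else (name_a, name_d)
                best[pair_key] = Interaction("HB", a, b, atoms, d, ang, klass)
    return [best[k] for k in sorted(best)]


def _find_hydrophobic(structure: Structure, cut: dict) -> list[Interaction]:
    residues = [
        r for r in structure.residues(protein_only=True) if r.name in _HYDROPHOBIC
    ]
    coords = []
    owner = []
    for idx, res in enumerate(residues):
        for atom in res.atoms.values():
            # side-chain carbons only (CB and beyond)
            if atom.element.upper() != "C" or atom.name in ("CA", "C"):
                continue
            coords.append(atom.coord)
            owner.append(idx)
    if not coords:
        return []
    coords = np.array(coords)
    tree = cKDTree(coords)
    best: dict[tuple, Interaction] = {}
    for i, j in tree.query_pairs(cut["hp_distance"]):
        ra, rb = residues[owner[i]], residues[owner[j]]
        if ra.key == rb.key:
            continue
        sep = _seq_sep(ra, rb)
        if sep is not None and sep < 2:
            continue
        a, b = _canonical(ra, rb)
        d = distance(coords[i], coords[j])
        key = (a.key, b.key)
        if key not in best or d < best[key].distance:
            best[key] = Interaction("HP", a, b, ("sidechain C", "sidechain C"), d)
    return [best[k] for k in sorted(best)]


def _find_disulfides(structure: Structure, cut: dict) -> list[Interaction]:
    cys = [
        r for r in structure.residues(protein_only=True)
        if r.name == "CYS" and "SG" in r.atoms
    ]
    out = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = distance(cys[i].coord("SG"), cys[j].coord("SG"))
            if cut["disulfide_min"] <= d <= cut["disulfide_max"]:
                a, b = _canonical(cys[i], cys[j])
                out.append(Interaction("DISULFIDE", a, b, ("SG", "SG"), d))
    return sorted(out, key=lambda it: it.key_pair)


def build_networks(interactions: list[Interaction]) -> list[InteractionNetwork]:
    """Connected components of the same-type interaction graph with >= 2
    member interactions, sorted by size (interaction count) descending."""
    if not interactions:
        return []
    types = {it.type for it in interactions}
    if len(types) > 1:
        raise ValueError(f"mixed interaction types in one network call: {sorted(types)}")
    itype = types.pop()
    graph = nx.Graph()
    residue_by_key = {}
    for it in interactions:
        residue_by_key[it.residue_a.key] = it.residue_a
        residue_by_key[it.residue_b.key] = it.residue_b
        graph.add_edge(it.residue_a.key, it.residue_b.key)
    networks = []
    for component in nx.connected_components(graph):
        members = [
            it for it in interactions
            if it.residue_a.key in component and it.residue_b.key in component
        ]
        if len(members) >= 2:
            networks.append(
                InteractionNetwork(
                    itype,
                    [residue_by_key[k] for k in sorted(component)],
                    members,
                )
            )
    networks.sort(key=lambda nw: (-nw.size, nw.residues[0].key))
    return networks


def disulfide_report(
    structure: Structure,
    ss: SSAssignment | None = None,
    exposure: dict[tuple, str] | None = None,
) -> list[DisulfideRecord]:
    """Disulfide bridges with the enclosed loop size (the entropic-effect
    proxy), plus exposure and secondary-structure context when given."""
    records = []
    for it in find_interactions(structure, "DISULFIDE"):
        a, b = it.residue_a, it.residue_b
        rec = DisulfideRecord(a, b, it.distance, _seq_sep(a, b))
        if ss is not None:
            rec.ss_labels = (ss.label(a), ss.label(b))
        if exposure is not None:
            rec.exposure = (
                exposure.get(a.key, "exposed"), exposure.get(b.key, "exposed")
            )
        records.append(rec)
    return records
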