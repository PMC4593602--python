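"""Secondary structure from backbone hydrogen bonding (Kabsch-Sander).

The assignment follows the classic electrostatic H-bond model: the amide
hydrogen is constructed 1.0 A from N along the carbonyl C->O direction of
the preceding residue, and a hydrogen bond is accepted when

    E = 0.084 * 332 * (1/rON + 1/rCH - 1/rOH - 1/rCN)  <  -0.5 kcal/mol.

Helices come from consecutive n-turns (n = 4 -> H, 3 -> G, 5 -> I),
strands from bridge ladders, turns from otherwise-unused n-turns and bends
from backbone curvature.  Beta turns (four-residue chain reversals with
CA(i)-CA(i+3) <= 7 A) are detected and typed from the phi/psi of the two
central residues; helix segments are inventoried together with their cap
positions for the N-cap and helix-dipole analyses.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .geometry import angle, dihedral, distance
from .model import Residue, Structure

__all__ = [
    "SSAssignment",
    "BetaTurn",
    "HelixSegment",
    "assign_ss",
    "detect_beta_turns",
    "helix_inventory",
    "ss_composition",
    "backbone_dihedrals",
    "chain_fragments",
    "HB_ENERGY_CUTOFF",
]

HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_Q = 0.084 * 332  # = 27.888, kcal/mol * A
PEPTIDE_BOND_MAX = 2.5  # A, C(i)-N(i+1) continuity test

HELIX_LABELS = frozenset("HGI")
STRAND_LABELS = frozenset("EB")


@dataclasses.dataclass
class SSAssignment:
    """Per-residue label in {H,G,I,E,B,T,S,C} keyed by residue key."""

    labels: dict[tuple, str]

    def label(self, res: Residue) -> str:
        return self.labels.get(res.key, "C")

    def simplified(self, res: Residue) -> str:
        return simplify_label(self.label(res))


def simplify_label(label: str) -> str:
    if label in HELIX_LABELS:
        return "Helix"
    if label in STRAND_LABELS:
        return "Strand"
    if label == "T":
        return "Turn"
    return "Coil"


@dataclasses.dataclass
class BetaTurn:
    residues: tuple[Residue, Residue, Residue, Residue]
    turn_type: str  # I, I', II, II', VIII or IV

    @property
    def start(self) -> Residue:
        return self.residues[0]

    @property
    def position2(self) -> Residue:
        """Residue i+1 — the classic proline-insertion position."""
        return self.residues[1]


@dataclasses.dataclass
class HelixSegment:
    residues: list[Residue]  # H-labelled run, length >= 4
    ncap: Residue | None  # residue immediately preceding the first H
    ccap: Residue | None  # residue immediately following the last H

    @property
    def first(self) -> Residue:
        return self.residues[0]

    @property
    def last(self) -> Residue:
        return self.residues[-1]

    def n_positions(self) -> dict[str, Residue]:
        """Position tags Ncap/N1/N2/N3 where defined."""
        out = {}
        if self.ncap is not None:
            out["Ncap"] = self.ncap
        for k in range(min(3, len(self.residues))):
            out[f"N{k + 1}"] = self.residues[k]
        return out

    def c_positions(self) -> dict[str, Residue]:
        out = {}
        if self.ccap is not None:
            out["Ccap"] = self.ccap
        for k in range(min(3, len(self.residues))):
            out[f"C{k + 1}"] = self.residues[-(k + 1)]
        return out


def chain_fragments(structure: Structure) -> list[list[Residue]]:
    """Covalently continuous runs of standard residues with backbone atoms.

    Continuity requires C(i)-N(i+1) <= 2.5 A; dihedrals, turns and H-bond
    patterns are never evaluated across a break.
    """
    fragments: list[list[Residue]] = []
    for chain in structure.chains:
        current: list[Residue] = []
        for res in chain.residues:
            if res.is_hetero or not res.is_standard_aa or not res.has_backbone():
                if current:
                    fragments.append(current)
                    current = []
                continue
            if current:
                prev = current[-1]
                if distance(prev.coord("C"), res.coord("N")) > PEPTIDE_BOND_MAX:
                    fragments.append(current)
                    current = []
            current.append(res)
        if current:
            fragments.append(current)
    return fragments


def backbone_dihedrals(structure: Structure) -> dict[tuple, tuple[float | None, float | None]]:
    """(phi, psi) per residue key; None at fragment ends."""
    out: dict[tuple, tuple[float | None, float | None]] = {}
    for frag in chain_fragments(structure):
        for i, res in enumerate(frag):
            phi = psi = None
            if i > 0:
                phi = dihedral(
                    frag[i - 1].coord("C"), res.coord("N"),
                    res.coord("CA"), res.coord("C"),
                )
            if i < len(frag) - 1:
                psi = dihedral(
                    res.coord("N"), res.coord("CA"),
                    res.coord("C"), frag[i + 1].coord("N"),
                )
            out[res.key] = (phi, psi)
    return out


def _amide_hydrogens(fragments: list[list[Residue]]) -> dict[tuple, np.ndarray | None]:
    """Backbone H per residue: file hydrogen if present, else constructed
    1.0 A from N along the previous residue's C->O direction (reversed).
    First residues of fragments and prolines have no amide H."""
    h: dict[tuple, np.ndarray | None] = {}
    for frag in fragments:
        for i, res in enumerate(frag):
            if res.name == "PRO":
                h[res.key] = None
                continue
            if "H" in res.atoms:
                h[res.key] = res.coord("H")
                continue
            if i == 0:
                h[res.key] = None
                continue
            prev = frag[i - 1]
            co = prev.coord("C") - prev.coord("O")
            n = np.linalg.norm(co)
            h[res.key] = res.coord("N") + co / n if n > 1e-6 else None
    return h


def hbond_energy(
    donor: Residue, acceptor: Residue, h_pos: np.ndarray | None
) -> float:
    """Kabsch-Sander electrostatic energy of N-H(donor) ... O=C(acceptor)."""
    if h_pos is None:
        return 0.0
    n = donor.coord("N")
    o = acceptor.coord("O")
    c = acceptor.coord("C")
    r_on = distance(o, n)
    r_ch = distance(c, h_pos)
    r_oh = distance(o, h_pos)
    r_cn = distance(c, n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9  # clash; treat as bonded, as the reference algorithm does
    return _Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _hbond_map(fragments: list[list[Residue]]):
    """acceptor_index -> set of donor indices over a flat residue list.

    Only pairs with sequence separation >= 2 within a fragment (or any
    inter-fragment pair) are evaluated, with a CA-CA 9 A prefilter.
    """
    flat: list[Residue] = [r for frag in fragments for r in frag]
    frag_id: list[int] = []
    pos_in_frag: list[int] = []
    for fi, frag in enumerate(fragments):
        frag_id.extend([fi] * len(frag))
        pos_in_frag.extend(range(len(frag)))
    h_pos = _amide_hydrogens(fragments)

    ca = np.array([r.coord("CA") for r in flat]) if flat else np.empty((0, 3))
    accepts: dict[int, set[int]] = {i: set() for i in range(len(flat))}
    if len(flat) < 2:
        return flat, frag_id, pos_in_frag, accepts
    from scipy.spatial import cKDTree

    tree = cKDTree(ca)
    pairs = tree.query_pairs(9.0)
    for i, j in pairs:
        for a, d in ((i, j), (j, i)):
            if frag_id[a] == frag_id[d] and abs(pos_in_frag[a] - pos_in_frag[d]) < 2:
                continue
            if "O" not in flat[a].atoms or "C" not in flat[a].atoms:
                continue
            e = hbond_energy(flat[d], flat[a], h_pos.get(flat[d].key))
            if e < HB_ENERGY_CUTOFF:
                accepts[a].add(d)
    return flat, frag_id, pos_in_frag, accepts


def assign_ss(structure: Structure) -> SSAssignment:
    """Assign {H,G,I,E,B,T,S,C} per residue from backbone H-bonding."""
    fragments = chain_fragments(structure)
    labels: dict[tuple, str] = {
        r.key: "C" for r in structure.residues(protein_only=True)
    }
    if not fragments or all(len(f) < 4 for f in fragments):
        warnings.warn("chain too short for secondary structure; all-coil")
        return SSAssignment(labels)

    flat, frag_id, pos, accepts = _hbond_map(fragments)
    n = len(flat)
    index_of = {r.key: i for i, r in enumerate(flat)}

    def same_frag_offset(i: int, k: int) -> int | None:
        j = i + k
        if 0 <= j < n and frag_id[j] == frag_id[i] and pos[j] - pos[i] == k:
            return j
        return None

    def hb(acc: int | None, don: int | None) -> bool:
        # H-bond CO(acc) <- NH(don)
        return acc is not None and don is not None and don in accepts[acc]

    # n-turns: turn_n[i] true if CO(i) accepts from NH(i+n)
    turns = {3: [False] * n, 4: [False] * n, 5: [False] * n}
    for i in range(n):
        for k in (3, 4, 5):
            turns[k][i] = hb(i, same_frag_offset(i, k))

    out = ["C"] * n

    def mark(i: int, count: int, label: str) -> None:
        for j in range(i, i + count):
            jj = same_frag_offset(i, j - i)
            if jj is not None and out[jj] == "C":
                out[jj] = label

    # alpha helices: two consecutive 4-turns
    for i in range(1, n):
        if turns[4][i] and turns[4][i - 1] and frag_id[i] == frag_id[i - 1] \
                and pos[i] - pos[i - 1] == 1:
            mark(i, 4, "H")

    # bridges and ladders
    par: set[tuple[int, int]] = set()
    anti: set[tuple[int, int]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            if frag_id[i] == frag_id[j] and abs(pos[i] - pos[j]) < 3:
                continue
            im1, ip1 = same_frag_offset(i, -1), same_frag_offset(i, 1)
            jm1, jp1 = same_frag_offset(j, -1), same_frag_offset(j, 1)
            if hb(im1, j) and hb(j, ip1) or hb(jm1, i) and hb(i, jp1):
                par.add((i, j))
            if hb(i, j) and hb(j, i) or hb(im1, jp1) and hb(jm1, ip1):
                anti.add((i, j))
    for i, j in par | anti:
        in_ladder = False
        if (i, j) in par:
            in_ladder |= (i + 1, j + 1) in par or (i - 1, j - 1) in par
        if (i, j) in anti:
            # pairs are stored with i < j, so the neighbouring rung of an
            # antiparallel ladder is (i+1, j-1) or (i-1, j+1)
            in_ladder |= (i + 1, j - 1) in anti or (i - 1, j + 1) in anti
        label = "E" if in_ladder else "B"
        for k in (i, j):
            if out[k] == "C" or (out[k] == "B" and label == "E"):
                out[k] = label

    # 3-10 and pi helices after H and E
    for helix_n, label in ((3, "G"), (5, "I")):
        for i in range(1, n):
            if turns[helix_n][i] and turns[helix_n][i - 1] \
                    and frag_id[i] == frag_id[i - 1] and pos[i] - pos[i - 1] == 1:
                span = [same_frag_offset(i, k) for k in range(helix_n)]
                if all(s is not None and out[s] in ("C", "T", "S") for s in span):
                    for s in span:
                        out[s] = label

    # hydrogen-bonded turns
    for k in (3, 4, 5):
        for i in range(n):
            if turns[k][i]:
                for d in range(1, k):
                    j = same_frag_offset(i, d)
                    if j is not None and out[j] == "C":
                        out[j] = "T"

    # bends from backbone curvature
    for i in range(n):
        a = same_frag_offset(i, -2)
        b = same_frag_offset(i, 2)
        if a is not None and b is not None and out[i] == "C":
            kappa = angle(flat[a].coord("CA"), flat[i].coord("CA"), flat[b].coord("CA"))
            # kappa is the supplement of the bend angle used by the
            # reference algorithm (bend if > 70 deg)
            if 180.0 - kappa > 70.0:
                out[i] = "S"

    for res, lab in zip(flat, out):
        labels[res.key] = lab
    return SSAssignment(labels)


# canonical (phi2, psi2, phi3, psi3) for turn types
_TURN_TYPES = {
    "I": (-60.0, -30.0, -90.0, 0.0),
    "I'": (60.0, 30.0, 90.0, 0.0),
    "II": (-60.0, 120.0, 80.0, 0.0),
    "II'": (60.0, -120.0, -80.0, 0.0),
    "VIII": (-60.0, -30.0, -120.0, 120.0),
}


def _angdiff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def _classify_turn(phi2, psi2, phi3, psi3) -> str:
    """Promotif convention: all four angles within +/-30 deg of the
    canonical values, one of them allowed +/-45 deg."""
    if None in (phi2, psi2, phi3, psi3):
        return "IV"
    for name, (c1, c2, c3, c4) in _TURN_TYPES.items():
        devs = [
            _angdiff(phi2, c1), _angdiff(psi2, c2),
            _angdiff(phi3, c3), _angdiff(psi3, c4),
        ]
        within30 = sum(d <= 30.0 for d in devs)
        if within30 == 4 or (within30 == 3 and max(devs) <= 45.0):
            return name
    return "IV"


def detect_beta_turns(
    structure: Structure,
    ss: SSAssignment | None = None,
    max_ca_distance: float = 7.0,
) -> list[BetaTurn]:
    """All four-residue chain reversals i..i+3.

    Requirements: covalent continuity, CA(i)-CA(i+3) <= ``max_ca_distance``
    and neither central residue helical.  Overlapping turns are all
    reported.
    """
    if ss is None:
        ss = assign_ss(structure)
    dihedrals = backbone_dihedrals(structure)
    turns: list[BetaTurn] = []
    for frag in chain_fragments(structure):
        for i in range(len(frag) - 3):
            quad = tuple(frag[i:i + 4])
            if distance(quad[0].coord("CA"), quad[3].coord("CA")) > max_ca_distance:
                continue
            if any(ss.label(r) in HELIX_LABELS for r in quad[1:3]):
                continue
            phi2, psi2 = dihedrals[quad[1].key]
            phi3, psi3 = dihedrals[quad[2].key]
            turns.append(BetaTurn(quad, _classify_turn(phi2, psi2, phi3, psi3)))
    return turns


def helix_inventory(
    ss: SSAssignment, structure: Structure, min_length: int = 4
) -> list[HelixSegment]:
    """Maximal runs of H of length >= ``min_length`` with cap residues."""
    segments: list[HelixSegment] = []
    for frag in chain_fragments(structure):
        run: list[Residue] = []
        for idx, res in enumerate(frag + [None]):
            if res is not None and ss.label(res) == "H":
                run.append(res)
                continue
            if len(run) >= min_length:
                first_idx = frag.index(run[0])
                last_idx = frag.index(run[-1])
                ncap = frag[first_idx - 1] if first_idx > 0 else None
                ccap = frag[last_idx + 1] if last_idx + 1 < len(frag) else None
                segments.append(HelixSegment(run, ncap, ccap))
            run = []
    return segments


def ss_composition(
    ss: SSAssignment, count_310_as_helix: bool = True
) -> dict[str, float]:
    """Fractions of Helix/Strand/Turn/Coil plus the loop fraction.

    Loop = 1 - (Helix + Strand); fractions always sum to 1.
    """
    labels = list(ss.labels.values())
    n = len(labels)
    if n == 0:
        raise ValueError("empty assignment")
    helix_set = HELIX_LABELS if count_310_as_helix else frozenset("H")
    helix = sum(1 for l in labels if l in helix_set) / n
    strand = sum(1 for l in labels if l in STRAND_LABELS) / n
    turn = sum(1 for l in labels if l == "T") / n
    coil = 1.0 - helix - strand - turn
    return {
        "Helix": helix,
        "Strand": strand,
        "Turn": turn,
        "Coil": coil,
        "Loop": 1.0 - helix - strand,
    }
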