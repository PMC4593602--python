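"""Per-structure thermostability feature profiles and the feature vector.

Nineteen comparative parameters are computed per structure: residue-class
contents (Aro, UP, Pro, ALI, CHG and the R/K ratio), the six non-covalent
interaction totals (IP, AAI, ASI, CPI, HB, HP), proline placement counts
(Bt2P: prolines at the second position of beta turns; NCap: prolines at
helix N-caps), the dipole-stabilized helix fraction (Hdip), thermolabile
Asn/Gln bonds (TL), conformationally strained residues (CS), the
nonpolar/polar accessible-area ratio (NP/P) and the loop fraction (Loop).

Raw counts are normalized by the denominator appropriate to each
parameter: sequence length for residue classes, interactions, CS and Loop;
the proline count for Bt2P and NCap; the helix count for Hdip; the
Asn+Gln count for TL; R/K and NP/P are used as raw ratios.  A parameter
whose raw count and denominator vanish carries an absence marker (None)
that the comparison engine renders with the '#'/'~' codes.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .geometry import distance
from .interactions import (
    DEFAULT_CUTOFFS,
    find_interactions,
)
from .model import Residue, Structure, extract_sequence
from .sasa import SasaResult, classify_exposure, compute_sasa
from .secstruct import (
    BetaTurn,
    HelixSegment,
    SSAssignment,
    assign_ss,
    backbone_dihedrals,
    detect_beta_turns,
    helix_inventory,
    ss_composition,
)

__all__ = [
    "FeatureVector",
    "StrainedResidue",
    "ThermolabileSite",
    "DipoleHelix",
    "MetalSite",
    "composition_profile",
    "proline_profile",
    "thermolabile_profile",
    "strain_profile",
    "dipole_profile",
    "metal_profile",
    "feature_vector",
    "FEATURE_NAMES",
    "STRAIN_PHI_RANGE",
]

AROMATIC = set("FWY")
UNCHARGED_POLAR = set("NQST")
ALIPHATIC = set("VILM")
CHARGED = set("DERKH")

STRAIN_PHI_RANGE = (10.0, 140.0)  # left-handed region for non-Gly residues

# common biologically relevant metals seen as mono-/di-atomic HETATM groups
METALS = frozenset({
    "LI", "NA", "K", "RB", "CS", "MG", "CA", "SR", "BA", "MN", "FE", "CO",
    "NI", "CU", "ZN", "CD", "HG", "MO", "W", "V", "AL",
})
METAL_COORDINATION_CUTOFF = 3.0  # A, protein N/O/S to metal

FEATURE_NAMES = (
    "Aro", "UP", "Pro", "ALI", "CHG", "R/K", "IP", "AAI", "ASI", "CPI",
    "HB", "HP", "Bt2P", "NCap", "Hdip", "TL", "CS", "NP/P", "Loop",
)


@dataclasses.dataclass
class StrainedResidue:
    residue: Residue
    phi: float
    psi: float | None
    strain_distance: float | None  # CB to same-residue carbonyl O
    ss_label: str
    exposure: str | None = None


@dataclasses.dataclass
class ThermolabileSite:
    residue: Residue  # Asn or Gln
    next_residue: Residue | None
    hotspot: bool  # Asn-Gly or Asn-Ser sequence neighbours
    ss_label: str
    exposure: str | None = None


@dataclasses.dataclass
class DipoleHelix:
    helix: HelixSegment
    stabilizers: list[tuple[str, Residue]]  # (position tag, residue)
    stabilized: bool


@dataclasses.dataclass
class MetalSite:
    metal: Residue
    element: str
    coordinating: list[tuple[Residue, str, float]]  # residue, atom, distance

    @property
    def coordination_number(self) -> int:
        return len(self.coordinating)


@dataclasses.dataclass
class FeatureVector:
    """Raw counts, normalized values and denominators of all parameters.

    ``normalized[name]`` is None when the parameter is absent (zero raw
    count with zero/undefined denominator, or an undefined ratio).
    """

    structure_id: str
    raw: dict[str, float]
    normalized: dict[str, float | None]
    denominators: dict[str, float]

    def as_row(self) -> dict:
        row = {"structure": self.structure_id}
        for name in FEATURE_NAMES:
            row[f"{name}_raw"] = self.raw.get(name)
            row[f"{name}_norm"] = self.normalized.get(name)
        return row


def composition_profile(sequences: dict[str, str]) -> dict[str, float | None]:
    """Residue-class fractions and the Arg/Lys ratio over all chains."""
    seq = "".join(sequences.values())
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    counts = {c: seq.count(c) for c in set(seq)}

    def frac(members: set[str]) -> float:
        return sum(counts.get(c, 0) for c in members) / n

    n_arg = counts.get("R", 0)
    n_lys = counts.get("K", 0)
    # no lysines -> the ratio is undefined and propagates as an absence code
    rk: float | None = (n_arg / n_lys) if n_lys else None
    return {
        "Aro": frac(AROMATIC),
        "UP": frac(UNCHARGED_POLAR),
        "Pro": counts.get("P", 0) / n,
        "ALI": frac(ALIPHATIC),
        "CHG": frac(CHARGED),
        "R/K": rk,
        "length": n,
        "n_arg": n_arg,
        "n_lys": n_lys,
    }


def proline_profile(
    structure: Structure,
    ss: SSAssignment,
    turns: list[BetaTurn],
    helices: list[HelixSegment],
) -> dict:
    """Proline placement: per-SS-class distribution, Bt2P and NCap counts."""
    per_ss: dict[str, int] = {"Helix": 0, "Strand": 0, "Turn": 0, "Coil": 0}
    n_pro = 0
    for res in structure.residues(protein_only=True):
        if res.name == "PRO":
            n_pro += 1
            per_ss[ss.simplified(res)] += 1
    bt2p_keys = {t.position2.key for t in turns if t.position2.name == "PRO"}
    ncap_keys = {
        h.ncap.key for h in helices if h.ncap is not None and h.ncap.name == "PRO"
    }
    return {
        "n_pro": n_pro,
        "per_ss": per_ss,
        "Bt2P": len(bt2p_keys),
        "NCap": len(ncap_keys),
    }


def thermolabile_profile(
    structure: Structure,
    ss: SSAssignment,
    exposure: dict[tuple, str] | None = None,
) -> list[ThermolabileSite]:
    """Every Asn/Gln with its C-terminal neighbour; deamidation hotspots
    (Asn-Gly, Asn-Ser) flagged."""
    sites = []
    for chain in structure.chains:
        protein = [r for r in chain.residues if r.is_standard_aa and not r.is_hetero]
        for i, res in enumerate(protein):
            if res.name not in ("ASN", "GLN"):
                continue
            nxt = protein[i + 1] if i + 1 < len(protein) else None
            hotspot = (
                res.name == "ASN"
                and nxt is not None
                and nxt.number - res.number == 1
                and nxt.name in ("GLY", "SER")
            )
            sites.append(
                ThermolabileSite(
                    res, nxt, hotspot, ss.label(res),
                    exposure.get(res.key) if exposure else None,
                )
            )
    return sites


def strain_profile(
    structure: Structure,
    ss: SSAssignment,
    exposure: dict[tuple, str] | None = None,
    phi_range: tuple[float, float] = STRAIN_PHI_RANGE,
) -> list[StrainedResidue]:
    """Non-Gly residues in the left-handed (positive-phi) region.

    The strain distance — CB to the residue's own carbonyl O — quantifies
    the steric conflict released by mutation to glycine.
    """
    lo, hi = phi_range
    dihedrals = backbone_dihedrals(structure)
    out = []
    for res in structure.residues(protein_only=True):
        if res.name == "GLY":
            continue
        phi, psi = dihedrals.get(res.key, (None, None))
        if phi is None or not lo < phi < hi:
            continue
        strain_d = None
        if "CB" in res.atoms and "O" in res.atoms:
            strain_d = distance(res.coord("CB"), res.coord("O"))
        out.append(
            StrainedResidue(
                res, phi, psi, strain_d, ss.label(res),
                exposure.get(res.key) if exposure else None,
            )
        )
    return out


_NEG = ("ASP", "GLU")
_POS = ("LYS", "ARG", "HIS")


def dipole_profile(
    helices: list[HelixSegment], structure: Structure | None = None
) -> tuple[list[DipoleHelix], float | None]:
    """Helix-dipole stabilization: Asp/Glu at Ncap..N3 or Lys/Arg/His at
    C3..Ccap mark a helix as dipole-stabilized.  Returns the per-helix
    records and the stabilized fraction (None without helices)."""
    records = []
    for helix in helices:
        stabilizers: list[tuple[str, Residue]] = []
        for tag, res in helix.n_positions().items():
            if res.name in _NEG:
                stabilizers.append((tag, res))
        for tag, res in helix.c_positions().items():
            if res.name in _POS:
                stabilizers.append((tag, res))
        records.append(DipoleHelix(helix, stabilizers, bool(stabilizers)))
    if not records:
        return [], None
    frac = sum(r.stabilized for r in records) / len(records)
    return records, frac


def metal_profile(structure: Structure) -> list[MetalSite]:
    """Coordination listing per metal HETATM: protein N/O/S atoms within
    3.0 A.  No geometry classification is attempted."""
    protein_atoms = []
    for res in structure.residues(protein_only=True):
        for atom in res.atoms.values():
            if atom.element.upper() in ("N", "O", "S"):
                protein_atoms.append((res, atom))
    sites = []
    for het in structure.hetero_residues():
        if len(het.atoms) > 2:
            continue
        for atom in het.atoms.values():
            if atom.element.upper() not in METALS:
                continue
            coordinating = []
            for res, patom in protein_atoms:
                d = distance(atom.coord, patom.coord)
                if d <= METAL_COORDINATION_CUTOFF:
                    coordinating.append((res, patom.name, d))
            sites.append(MetalSite(het, atom.element.upper(), coordinating))
    return sites


def _norm(raw: float, denom: float) -> float | None:
    """raw/denom with the absence convention: zero raw over zero denominator
    (or any zero denominator) is 'absent', not 0."""
    if denom == 0:
        return None
    return raw / denom


def feature_vector(
    structure: Structure,
    params: dict | None = None,
    asa_threshold: float = 10.0,
    sasa_points: int = 960,
) -> FeatureVector:
    """Assemble the full per-structure feature vector."""
    sequences = extract_sequence(structure)
    comp = composition_profile(sequences)
    length = comp["length"]

    ss = assign_ss(structure)
    turns = detect_beta_turns(structure, ss)
    helices = helix_inventory(ss, structure)
    sasa = compute_sasa(structure, points=sasa_points)
    exposure = classify_exposure(sasa, asa_threshold)
    comp_ss = ss_composition(ss)

    counts = {
        t: len(find_interactions(structure, t, params))
        for t in ("IP", "AAI", "ASI", "CPI", "HB", "HP")
    }
    pro = proline_profile(structure, ss, turns, helices)
    tl_sites = thermolabile_profile(structure, ss, exposure)
    tl_hotspots = sum(1 for s in tl_sites if s.hotspot)
    strained = strain_profile(structure, ss, exposure)
    _, hdip = dipole_profile(helices, structure)

    n_nq = len(tl_sites)
    raw = {
        "Aro": comp["Aro"] * length,
        "UP": comp["UP"] * length,
        "Pro": comp["Pro"] * length,
        "ALI": comp["ALI"] * length,
        "CHG": comp["CHG"] * length,
        "R/K": comp["R/K"],
        **{k: float(v) for k, v in counts.items()},
        "Bt2P": pro["Bt2P"],
        "NCap": pro["NCap"],
        "Hdip": (hdip * len(helices)) if hdip is not None else 0.0,
        "TL": tl_hotspots,
        "CS": len(strained),
        "NP/P": sasa.np_over_p,
        "Loop": comp_ss["Loop"] * length,
    }
    normalized: dict[str, float | None] = {
        "Aro": comp["Aro"],
        "UP": comp["UP"],
        "Pro": comp["Pro"],
        "ALI": comp["ALI"],
        "CHG": comp["CHG"],
        "R/K": comp["R/K"],
        "IP": _norm(counts["IP"], length),
        "AAI": _norm(counts["AAI"], length),
        "ASI": _norm(counts["ASI"], length),
        "CPI": _norm(counts["CPI"], length),
        "HB": _norm(counts["HB"], length),
        "HP": _norm(counts["HP"], length),
        "Bt2P": _norm(pro["Bt2P"], pro["n_pro"]),
        "NCap": _norm(pro["NCap"], pro["n_pro"]),
        "Hdip": hdip,
        "TL": _norm(tl_hotspots, n_nq),
        "CS": _norm(len(strained), length),
        "NP/P": sasa.np_over_p,
        "Loop": comp_ss["Loop"],
    }
    denominators = {
        "length": length,
        "n_pro": pro["n_pro"],
        "n_helices": len(helices),
        "n_asn_gln": n_nq,
    }
    return FeatureVector(structure.id, raw, normalized, denominators)
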