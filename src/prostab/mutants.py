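"""Deterministic mutant building and local interaction profiling.

Mutants are built without any minimization so that results are exactly
reproducible: a mutation to a residue whose heavy atoms are a subset of
the wild side chain (X -> Ala, X -> Gly, Glu -> Asp, ...) simply truncates
the side chain in place, and a mutation to a larger residue grows an
ideal-geometry side chain at the most common rotamer on the unchanged
backbone.  Every atom of every unmutated residue is left bit-identical.

The local interaction profile of a residue counts, per interaction class,
the contacts incident to it and the same-type networks containing it —
the quantitative readout used to rationalize mutant stability changes.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .interactions import (
    INTERACTION_TYPES,
    build_networks,
    find_interactions,
)
from .model import Atom, Residue, Structure, THREE_TO_ONE
from .sidechains import build_side_chain, sidechain_atom_names
from .strategies import MutationSpec
from .geometry import distance

__all__ = [
    "InteractionProfile",
    "ProfileDiff",
    "build_mutant",
    "local_interaction_profile",
    "diff_profiles",
    "PROFILE_COLUMNS",
]

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

PROFILE_COLUMNS = (
    "IP", "IPNet", "AP", "APNet", "AS", "ASNet", "HB", "Disul",
    "Catpi", "CatpiNet", "Hphob",
)

# profile column -> (interaction type, networks?)
_COLUMN_SOURCE = {
    "IP": ("IP", False),
    "IPNet": ("IP", True),
    "AP": ("AAI", False),
    "APNet": ("AAI", True),
    "AS": ("ASI", False),
    "ASNet": ("ASI", True),
    "HB": ("HB", False),
    "Disul": ("DISULFIDE", False),
    "Catpi": ("CPI", False),
    "CatpiNet": ("CPI", True),
    "Hphob": ("HP", False),
}

_BACKBONE_KEEP = ("N", "CA", "C", "O", "OXT", "H")


@dataclasses.dataclass
class InteractionProfile:
    residue_key: tuple
    residue_name: str
    counts: dict[str, int]

    def display(self) -> dict[str, str]:
        """Counts with zeros rendered as '-' (no interaction detected)."""
        return {c: (str(v) if v else "-") for c, v in self.counts.items()}


@dataclasses.dataclass
class ProfileDiff:
    site: tuple
    wild: InteractionProfile
    mutant: InteractionProfile

    @property
    def delta(self) -> dict[str, int]:
        return {
            c: self.mutant.counts[c] - self.wild.counts[c] for c in PROFILE_COLUMNS
        }


@dataclasses.dataclass
class MutantBuild:
    structure: Structure
    clashes: list[tuple[tuple, tuple, float]]  # (site key, other key, distance)


def _apply_mutation(structure: Structure, spec: MutationSpec) -> list:
    chain_id = spec.chain or structure.chains[0].id
    res = structure.get_residue((chain_id, spec.number, spec.icode))
    if res.one_letter != spec.wild.upper():
        raise ValueError(
            f"wild-type mismatch at {chain_id}/{spec.number}{spec.icode}: "
            f"structure has {res.name} ({res.one_letter}), mutation says {spec.wild}"
        )
    target = ONE_TO_THREE.get(spec.target.upper())
    if target is None:
        raise ValueError(f"unknown target residue {spec.target!r}")

    target_atoms = set(sidechain_atom_names(target))
    current_sidechain = {n for n in res.atoms if n not in _BACKBONE_KEEP}
    clash_atoms = []
    if target_atoms <= current_sidechain:
        # pure truncation: keep backbone plus the shared side-chain subset
        for name in current_sidechain - target_atoms:
            del res.atoms[name]
    else:
        for name in current_sidechain:
            del res.atoms[name]
        element = {"S": "S", "O": "O", "N": "N"}
        for name, coord in build_side_chain(res, target).items():
            res.atoms[name] = Atom(name, element.get(name[0], "C"), coord)
            clash_atoms.append(name)
    res.name = target
    return [(res, clash_atoms)]


def build_mutant(
    structure: Structure, mutations: list[MutationSpec] | MutationSpec
) -> MutantBuild:
    """Apply one or more point mutations; returns the mutant plus a list of
    steric clashes (grown side-chain atoms within 2.0 A of another
    residue's heavy atom).  Clashes are reported, never resolved."""
    if isinstance(mutations, MutationSpec):
        mutations = [mutations]
    if not mutations:
        raise ValueError("no mutations supplied")
    mutant = structure.copy()
    grown = []
    for spec in mutations:
        grown.extend(_apply_mutation(mutant, spec))
    clashes = []
    for res, atom_names in grown:
        for name in atom_names:
            coord = res.coord(name)
            for other in mutant.residues():
                if other.key == res.key:
                    continue
                for atom in other.atoms.values():
                    d = distance(coord, atom.coord)
                    if d < 2.0:
                        clashes.append((res.key, other.key, d))
    return MutantBuild(mutant, clashes)


def local_interaction_profile(
    structure: Structure,
    site: tuple | Residue,
    params: dict | None = None,
) -> InteractionProfile:
    """Counts of each interaction class incident to ``site`` plus the
    same-type networks containing it (one row of the profile table)."""
    if isinstance(site, Residue):
        res = site
    else:
        res = structure.get_residue(tuple(site))
    counts: dict[str, int] = {}
    interactions_by_type = {
        t: find_interactions(structure, t, params) for t in INTERACTION_TYPES
    }
    for column, (itype, is_network) in _COLUMN_SOURCE.items():
        interactions = interactions_by_type[itype]
        if is_network:
            networks = build_networks(interactions)
            counts[column] = sum(
                1 for nw in networks if any(r.key == res.key for r in nw.residues)
            )
        else:
            counts[column] = sum(
                1 for it in interactions
                if res.key in (it.residue_a.key, it.residue_b.key)
            )
    return InteractionProfile(res.key, res.name, counts)


def diff_profiles(
    wild: Structure,
    mutant: Structure,
    sites: list[tuple],
    params: dict | None = None,
) -> list[ProfileDiff]:
    """Paired wild/mutant interaction profiles at each site.

    The two structures must share residue keys (they may differ in residue
    identity only at the mutated sites)."""
    wild_keys = {r.key for r in wild.residues()}
    mut_keys = {r.key for r in mutant.residues()}
    if wild_keys != mut_keys:
        raise ValueError(
            "wild and mutant structures have different residue keys: "
            f"{sorted(wild_keys ^ mut_keys)[:5]} ..."
        )
    out = []
    for site in sites:
        out.append(
            ProfileDiff(
                tuple(site),
                local_interaction_profile(wild, site, params),
                local_interaction_profile(mutant, site, params),
            )
        )
    return out


def profile_table(diffs: list[ProfileDiff]) -> pd.DataFrame:
    """Wild/mut row pairs in the standard profile layout."""
    rows = []
    for i, diff in enumerate(diffs, start=1):
        for kind, profile in (("wild", diff.wild), ("mut", diff.mutant)):
            chain, number, icode = profile.residue_key
            rows.append(
                {
                    "MutNo": i,
                    "Type": kind,
                    "Chain": chain,
                    "ResNo": f"{number}{icode}",
                    "ResID": THREE_TO_ONE.get(profile.residue_name, "X"),
                    **profile.display(),
                }
            )
    return pd.DataFrame(rows)
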