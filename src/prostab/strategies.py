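"""Strategy-based scanning for candidate stabilizing mutations.

Four established thermostabilization strategies are implemented as
structure scans:

* proline at the second position of beta turns (entropic rigidification),
* proline at helix N-caps,
* glycine at conformationally strained (left-handed, positive-phi)
  residues to release backbone strain,
* engineered disulfide bridges, found geometrically from CB-CB/CA-CA
  windows and ranked by the size of the loop they would close (larger
  loop, larger unfolded-state entropy reduction).

Candidates can be annotated with a 1-9 conservation score derived from a
user-supplied multiple sequence alignment (9 = fully conserved) and scored
with a pluggable stability predictor.  The built-in predictor is a simple
interaction-count delta heuristic — a coarse screen, not a physics-based
energy function — and external tools can be registered as plugins.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

from .geometry import distance
from .interactions import find_all_interactions, find_interactions
from .model import Residue, Structure, extract_sequence
from .profiles import StrainedResidue, strain_profile
from .secstruct import (
    SSAssignment,
    assign_ss,
    backbone_dihedrals,
    detect_beta_turns,
    helix_inventory,
)
from .sidechains import build_cb

__all__ = [
    "MutationSpec",
    "CandidateSite",
    "ConservationScore",
    "scan_bt2p",
    "scan_ncap",
    "scan_strain",
    "scan_disulfide",
    "conservation_from_msa",
    "predict_stability",
    "register_predictor",
    "parse_mutation_file",
    "DISULFIDE_GEOMETRY",
]

DISULFIDE_GEOMETRY = {
    "cb_min": 3.4,
    "cb_max": 4.6,
    "ca_min": 4.0,
    "ca_max": 7.5,
    "min_separation": 4,
}

# weights of the built-in interaction-delta stability heuristic
HEURISTIC_WEIGHTS = {
    "IP": 1.0,
    "HB": 0.5,
    "AAI": 0.5,
    "ASI": 0.3,
    "CPI": 0.5,
    "HP": 0.3,
    "DISULFIDE": 2.0,
}


@dataclasses.dataclass(frozen=True)
class MutationSpec:
    chain: str
    number: int
    wild: str  # 1-letter
    target: str  # 1-letter
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.chain}/{self.wild}{self.number}{self.icode}{self.target}"


@dataclasses.dataclass
class CandidateSite:
    strategy: str  # BT2P / NCAP_PRO / STRAIN_GLY / DISULFIDE / CUSTOM
    mutations: tuple[MutationSpec, ...]
    annotations: dict = dataclasses.field(default_factory=dict)
    conservation: int | None = None
    score: float | None = None
    predicted: str | None = None  # I / D


@dataclasses.dataclass
class ConservationScore:
    residue_key: tuple
    score: int  # 1 (variable) .. 9 (conserved)

    def __post_init__(self) -> None:
        if not 1 <= self.score <= 9:
            raise ValueError("conservation score must be within 1..9")


def _spec_for(res: Residue, target_one: str) -> MutationSpec:
    return MutationSpec(res.chain_id, res.number, res.one_letter, target_one, res.icode)


def scan_bt2p(
    structure: Structure, ss: SSAssignment | None = None
) -> list[CandidateSite]:
    """X -> Pro candidates at the second position of every beta turn.

    The phi-compatibility flag marks sites whose backbone phi already sits
    in the proline-friendly window (-60 +/- 30 deg)."""
    if ss is None:
        ss = assign_ss(structure)
    dihedrals = backbone_dihedrals(structure)
    seen = set()
    out = []
    for turn in detect_beta_turns(structure, ss):
        res = turn.position2
        if res.name == "PRO" or res.key in seen:
            continue
        seen.add(res.key)
        phi, _ = dihedrals.get(res.key, (None, None))
        out.append(
            CandidateSite(
                "BT2P",
                (_spec_for(res, "P"),),
                {
                    "turn_start": turn.start.key,
                    "turn_type": turn.turn_type,
                    "phi": phi,
                    "phi_compatible": phi is not None and -90.0 <= phi <= -30.0,
                },
            )
        )
    return out


def scan_ncap(
    structure: Structure, ss: SSAssignment | None = None
) -> list[CandidateSite]:
    """X -> Pro candidates at the N-cap residue of every helix."""
    if ss is None:
        ss = assign_ss(structure)
    out = []
    for helix in helix_inventory(ss, structure):
        ncap = helix.ncap
        if ncap is None or ncap.name == "PRO":
            continue
        out.append(
            CandidateSite(
                "NCAP_PRO",
                (_spec_for(ncap, "P"),),
                {"helix_first": helix.first.key, "helix_last": helix.last.key},
            )
        )
    return out


def scan_strain(
    structure: Structure, ss: SSAssignment | None = None
) -> list[CandidateSite]:
    """X -> Gly candidates at conformationally strained residues."""
    if ss is None:
        ss = assign_ss(structure)
    out = []
    for sr in strain_profile(structure, ss):
        out.append(
            CandidateSite(
                "STRAIN_GLY",
                (_spec_for(sr.residue, "G"),),
                {
                    "phi": sr.phi,
                    "psi": sr.psi,
                    "strain_distance": sr.strain_distance,
                    "ss": sr.ss_label,
                },
            )
        )
    return out


def _cb_coord(res: Residue):
    if "CB" in res.atoms:
        return res.coord("CB")
    if res.has_backbone():
        return build_cb(res.coord("N"), res.coord("CA"), res.coord("C"))
    return None


def scan_disulfide(
    structure: Structure, geometry: dict | None = None
) -> list[CandidateSite]:
    """Residue pairs that could form a disulfide if both were cysteine.

    CB-CB within [3.4, 4.6] A and CA-CA within [4.0, 7.5] A, sequence
    separation >= 4 (or inter-chain), neither residue already in a
    disulfide; ranked by enclosed loop size, largest first."""
    geo = dict(DISULFIDE_GEOMETRY)
    if geometry:
        geo.update(geometry)
    existing = set()
    for it in find_interactions(structure, "DISULFIDE"):
        existing.add(it.residue_a.key)
        existing.add(it.residue_b.key)
    residues = [
        r for r in structure.residues(protein_only=True)
        if r.has_backbone() and r.key not in existing
    ]
    cbs = {r.key: _cb_coord(r) for r in residues}
    out = []
    for i, ra in enumerate(residues):
        for rb in residues[i + 1:]:
            if ra.chain_id == rb.chain_id:
                sep = abs(ra.number - rb.number)
                if sep < geo["min_separation"]:
                    continue
                loop = sep
            else:
                loop = None
            cb_a, cb_b = cbs[ra.key], cbs[rb.key]
            if cb_a is None or cb_b is None:
                continue
            d_cb = distance(cb_a, cb_b)
            if not geo["cb_min"] <= d_cb <= geo["cb_max"]:
                continue
            d_ca = distance(ra.coord("CA"), rb.coord("CA"))
            if not geo["ca_min"] <= d_ca <= geo["ca_max"]:
                continue
            out.append(
                CandidateSite(
                    "DISULFIDE",
                    (_spec_for(ra, "C"), _spec_for(rb, "C")),
                    {"cb_distance": d_cb, "ca_distance": d_ca, "loop_size": loop},
                )
            )
    out.sort(
        key=lambda c: (
            -(c.annotations["loop_size"] or 10 ** 6),
            c.mutations[0].chain,
            c.mutations[0].number,
        )
    )
    return out


def conservation_from_msa(
    msa: str | Path | list[tuple[str, str]],
    chain_sequence: str,
    min_identity: float = 0.95,
) -> dict[int, ConservationScore]:
    """Per-residue conservation (1-9) from an aligned FASTA.

    The alignment row whose ungapped sequence matches ``chain_sequence``
    (identity >= ``min_identity``) anchors columns to residue indices
    (0-based into the chain sequence).  The score is ceil(9p) clamped to
    >= 1 where p is the column frequency of the wild-type residue over all
    alignment rows.
    """
    if isinstance(msa, (str, Path)):
        from Bio import SeqIO

        rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(msa), "fasta")]
    else:
        rows = [(rid, seq.upper()) for rid, seq in msa]
    if not rows:
        raise ValueError("empty alignment")
    lengths = {len(seq) for _, seq in rows}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")

    chain_sequence = chain_sequence.upper()
    anchor = None
    for rid, seq in rows:
        ungapped = seq.replace("-", "").replace(".", "")
        if len(ungapped) != len(chain_sequence):
            continue
        matches = sum(a == b for a, b in zip(ungapped, chain_sequence))
        if matches / len(chain_sequence) >= min_identity:
            anchor = seq
            break
    if anchor is None:
        raise ValueError(
            "no alignment row matches the chain sequence at >= "
            f"{min_identity:.0%} ungapped identity"
        )

    n_rows = len(rows)
    scores: dict[int, ConservationScore] = {}
    seq_index = 0
    for col, aa in enumerate(anchor):
        if aa in ("-", "."):
            continue
        count = sum(1 for _, seq in rows if seq[col] == aa)
        p = count / n_rows
        score = max(1, math.ceil(9 * p))
        scores[seq_index] = ConservationScore(("column", col), min(9, score))
        seq_index += 1
    return scores


# ---------------------------------------------------------------------------
# stability predictors

def _builtin_heuristic(wild: Structure, mutant: Structure) -> float:
    """Weighted change in whole-structure interaction counts (mutant minus
    wild).  Positive = predicted stabilizing.  A screening heuristic only:
    it knows nothing about strain, packing energetics or solvation."""
    wild_counts = {t: len(v) for t, v in find_all_interactions(wild).items()}
    mut_counts = {t: len(v) for t, v in find_all_interactions(mutant).items()}
    return sum(
        w * (mut_counts[t] - wild_counts[t]) for t, w in HEURISTIC_WEIGHTS.items()
    )


_PREDICTORS = {"builtin": _builtin_heuristic}


def register_predictor(name: str, fn) -> None:
    """Register an external stability predictor plugin.

    The callable receives (wild, mutant) structures and returns a float
    score whose sign convention must be 'positive = more stable'."""
    _PREDICTORS[name] = fn


def predict_stability(
    wild: Structure, mutant: Structure, predictor: str = "builtin"
) -> tuple[float, str]:
    """Score a mutant against its wild-type; returns (score, 'I'|'D').

    Class is 'I' iff score > 0; the boundary (score == 0, e.g. a mutant
    identical to wild) is conservatively reported 'D'.
    """
    try:
        fn = _PREDICTORS[predictor]
    except KeyError:
        raise ValueError(
            f"stability predictor {predictor!r} is not available; "
            f"registered: {sorted(_PREDICTORS)}"
        ) from None
    score = float(fn(wild, mutant))
    return score, ("I" if score > 0 else "D")


# ---------------------------------------------------------------------------
# user mutation lists

def parse_mutation_file(
    path: str | Path, default_chain: str | None = None
) -> list[tuple[MutationSpec, ...]]:
    """Read a mutation list: one mutation per line, comma-separated entries
    on one line for multi-mutants.  Entries look like ``V22A`` (first/
    default chain) or ``A/V22A`` / ``A:V22A`` with an explicit chain."""
    lines = Path(path).read_text().splitlines()
    out = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        specs = []
        for token in line.split(","):
            token = token.strip()
            try:
                specs.append(_parse_token(token, default_chain))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
        out.append(tuple(specs))
    if not out:
        raise ValueError(f"{path}: no mutations found")
    return out


def _parse_token(token: str, default_chain: str | None) -> MutationSpec:
    chain = default_chain
    body = token
    for sep in ("/", ":"):
        if sep in token:
            chain_part, body = token.split(sep, 1)
            chain = chain_part.strip()
            break
    body = body.strip().upper()
    if len(body) < 3 or not body[0].isalpha() or not body[-1].isalpha():
        raise ValueError(f"malformed mutation {token!r} (expected e.g. V22A)")
    wild, target = body[0], body[-1]
    middle = body[1:-1]
    icode = ""
    if middle and middle[-1].isalpha():
        icode = middle[-1]
        middle = middle[:-1]
    if not middle.lstrip("-").isdigit():
        raise ValueError(f"malformed residue number in {token!r}")
    return MutationSpec(chain or "", int(middle), wild, target, icode)
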