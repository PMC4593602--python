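import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prostab.fixtures import FixtureSpec, build_peptide, make_fixture
from prostab.geometry import distance
from prostab.interactions import (
    DEFAULT_CUTOFFS,
    INTERACTION_TYPES,
    build_networks,
    disulfide_report,
    find_all_interactions,
    find_interactions,
)
from prostab.model import Structure

# independent atom tables for the brute-force oracle
_ORACLE_POS = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
_ORACLE_NEG = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_ORACLE_HYDROPHOBIC = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "TYR"}


def _pair_structure(res_a, res_b, atom_a, atom_b, d):
    return make_fixture(
        FixtureSpec(
            kind="residue_pair",
            pair_residues=(res_a, res_b),
            pair_atoms=(atom_a, atom_b),
            pair_distance=d,
        )
    )


def test_ion_pair_inside_and_outside_cutoff():
    inside = _pair_structure("ASP", "LYS", "OD1", "NZ", 3.0)
    assert len(find_interactions(inside, "IP")) == 1
    outside = _pair_structure("ASP", "LYS", "OD1", "NZ", 8.0)
    assert find_interactions(outside, "IP") == []


def test_ion_pair_counted_once_per_residue_pair():
    # both carboxylate oxygens near NZ still give one ion pair
    st_ = _pair_structure("GLU", "ARG", "OE1", "NH1", 2.8)
    found = find_interactions(st_, "IP")
    assert len(found) == 1
    assert found[0].distance <= 2.8 + 1e-6


def test_aromatic_ring_centroid_window():
    close = _pair_structure("PHE", "TRP", "CZ", "CZ2", 1.0)
    rings_close = find_interactions(close, "AAI")
    far = _pair_structure("PHE", "TRP", "CZ", "CZ2", 30.0)
    assert find_interactions(far, "AAI") == []
    mid = _pair_structure("PHE", "PHE", "CZ", "CZ", 5.0)
    centroid_d = [it.distance for it in find_interactions(mid, "AAI")]
    for d in centroid_d:
        assert 4.5 <= d <= 7.0
    # rings fused at 1 A centroids are below the lower window edge
    for it in rings_close:
        assert 4.5 <= it.distance <= 7.0


def test_aromatic_sulphur():
    st_ = _pair_structure("CYS", "PHE", "SG", "CZ", 3.5)
    found = find_interactions(st_, "ASI")
    assert len(found) == 1
    assert found[0].distance <= 5.3


def test_cation_pi_lys():
    st_ = _pair_structure("LYS", "TYR", "NZ", "CZ", 4.0)
    found = find_interactions(st_, "CPI")
    assert len(found) == 1


def test_disulfide_window_and_report():
    st_ = _pair_structure("CYS", "CYS", "SG", "SG", 2.05)
    found = find_interactions(st_, "DISULFIDE")
    assert len(found) == 1
    assert found[0].distance == pytest.approx(2.05)
    report = disulfide_report(st_)
    assert report[0].loop_size == 9
    too_long = _pair_structure("CYS", "CYS", "SG", "SG", 3.2)
    assert find_interactions(too_long, "DISULFIDE") == []


def test_helix_backbone_hbonds(helix18):
    found = find_interactions(helix18, "HB")
    mm = [it for it in found if it.hb_class == "MM"]
    # an 18-residue ideal helix supports the i -> i+4 ladder
    assert len(mm) == 14
    for it in mm:
        assert abs(it.residue_a.number - it.residue_b.number) == 4


def test_hydrophobic_excludes_backbone_carbons():
    # backbone-only contact must not register as hydrophobic
    st_ = _pair_structure("ALA", "ALA", "CB", "CB", 4.0)
    found = find_interactions(st_, "HP")
    assert len(found) == 1
    for it in found:
        assert it.atoms == ("sidechain C", "sidechain C")


def test_unknown_type_and_params_rejected(helix18):
    with pytest.raises(ValueError, match="unknown interaction type"):
        find_interactions(helix18, "XX")
    with pytest.raises(ValueError, match="unknown interaction parameters"):
        find_interactions(helix18, "IP", {"bogus": 1.0})
    with pytest.raises(ValueError, match="positive"):
        find_interactions(helix18, "IP", {"ip_distance": -2.0})


# ---------------------------------------------------------------------------
# brute-force oracle equivalence on random structures

def _random_structure(seed: int) -> Structure:
    """A couple of short random-conformation peptides thrown together."""
    rng = np.random.default_rng(seed)
    alphabet = "ARNDCQEGHILKMFPSTWYV"
    chain = None
    out = None
    number = 1
    for frag in range(rng.integers(2, 4)):
        n = int(rng.integers(3, 7))
        seq = "".join(rng.choice(list(alphabet), n))
        phi_psi = [
            (float(rng.uniform(-180, 180)), float(rng.uniform(-180, 180)))
            for _ in range(n)
        ]
        piece = build_peptide(seq, phi_psi, start_number=number)
        number += n + 1
        shift = rng.uniform(-8, 8, size=3)
        for res in piece.chains[0].residues:
            for atom in res.atoms.values():
                atom.coord = atom.coord + shift
        if out is None:
            out = piece
            chain = out.chains[0]
        else:
            chain.residues.extend(piece.chains[0].residues)
    return out


def _oracle_ion_pairs(structure):
    pairs = set()
    residues = list(structure.residues(protein_only=True))
    for ra, rb in itertools.combinations(residues, 2):
        if ra.chain_id == rb.chain_id and abs(ra.number - rb.number) < 2:
            continue
        for pa, na in ((ra, rb), (rb, ra)):
            for ap in _ORACLE_POS.get(pa.name, ()):
                for an in _ORACLE_NEG.get(na.name, ()):
                    if ap in pa.atoms and an in na.atoms:
                        if distance(pa.coord(ap), na.coord(an)) <= 6.0:
                            pairs.add(frozenset((ra.key, rb.key)))
    return pairs


def _oracle_hydrophobic(structure):
    pairs = set()
    residues = [
        r for r in structure.residues(protein_only=True)
        if r.name in _ORACLE_HYDROPHOBIC
    ]
    for ra, rb in itertools.combinations(residues, 2):
        if ra.chain_id == rb.chain_id and abs(ra.number - rb.number) < 2:
            continue
        for aa, ab in itertools.product(ra.atoms.values(), rb.atoms.values()):
            if aa.element != "C" or aa.name in ("CA", "C"):
                continue
            if ab.element != "C" or ab.name in ("CA", "C"):
                continue
            if distance(aa.coord, ab.coord) < 5.0:
                pairs.add(frozenset((ra.key, rb.key)))
                break
        else:
            continue
    return pairs


def _oracle_disulfides(structure):
    pairs = set()
    cys = [
        r for r in structure.residues(protein_only=True)
        if r.name == "CYS" and "SG" in r.atoms
    ]
    for ra, rb in itertools.combinations(cys, 2):
        if 1.8 <= distance(ra.coord("SG"), rb.coord("SG")) <= 2.5:
            pairs.add(frozenset((ra.key, rb.key)))
    return pairs


@pytest.mark.parametrize("seed", range(100))
def test_detectors_match_brute_force_oracle(seed):
    structure = _random_structure(seed)
    found_ip = {
        frozenset(it.key_pair) for it in find_interactions(structure, "IP")
    }
    assert found_ip == _oracle_ion_pairs(structure)
    found_hp = {
        frozenset(it.key_pair) for it in find_interactions(structure, "HP")
    }
    assert found_hp == _oracle_hydrophobic(structure)
    found_ss = {
        frozenset(it.key_pair)
        for it in find_interactions(structure, "DISULFIDE")
    }
    assert found_ss == _oracle_disulfides(structure)


@given(seed=st.integers(0, 10_000), scale=st.floats(0.5, 1.5))
@settings(max_examples=25)
def test_cutoff_monotonicity(seed, scale):
    """Widening a distance cutoff can only add interactions."""
    structure = _random_structure(seed)
    base = {
        frozenset(it.key_pair)
        for it in find_interactions(structure, "IP", {"ip_distance": 6.0 * scale})
    }
    wider = {
        frozenset(it.key_pair)
        for it in find_interactions(
            structure, "IP", {"ip_distance": 6.0 * scale + 1.0}
        )
    }
    assert base <= wider


# ---------------------------------------------------------------------------
# networks

def test_networks_require_two_interactions(salt_bridge):
    found = find_interactions(salt_bridge, "IP")
    assert len(found) == 1
    assert build_networks(found) == []


def test_networks_reject_mixed_types(helix18, salt_bridge):
    hb = find_interactions(helix18, "HB")
    ip = find_interactions(salt_bridge, "IP")
    with pytest.raises(ValueError, match="mixed"):
        build_networks(hb + ip)


@pytest.mark.parametrize("seed", range(20))
def test_network_partition_conserves_interactions(seed):
    """Every interaction belongs to exactly one component; components of
    size >= 2 are exactly the reported networks, sorted by size."""
    structure = _random_structure(seed)
    for itype in INTERACTION_TYPES:
        interactions = find_interactions(structure, itype)
        networks = build_networks(interactions)
        seen = []
        for nw in networks:
            assert nw.size >= 2
            member_keys = {r.key for r in nw.residues}
            for it in nw.interactions:
                assert it.residue_a.key in member_keys
                assert it.residue_b.key in member_keys
            seen.extend(id(it) for it in nw.interactions)
        assert len(seen) == len(set(seen))
        sizes = [nw.size for nw in networks]
        assert sizes == sorted(sizes, reverse=True)
        # interactions outside all networks are in components of size 1
        in_networks = set(seen)
        leftovers = [it for it in interactions if id(it) not in in_networks]
        assert len(leftovers) + len(in_networks) == len(interactions)


def test_find_all_covers_every_type(helix18):
    result = find_all_interactions(helix18)
    assert set(result) == set(INTERACTION_TYPES)


def test_exposure_annotation(salt_bridge):
    keys = [r.key for r in salt_bridge.residues()]
    exposure = {keys[0]: "buried", keys[1]: "exposed"}
    found = find_interactions(salt_bridge, "IP", exposure=exposure)
    assert found[0].burial == "buried-exposed"
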