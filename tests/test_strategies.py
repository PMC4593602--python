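import numpy as np
import pytest

from prostab.fixtures import FixtureSpec, build_peptide, make_fixture
from prostab.geometry import distance
from prostab.model import Structure
from prostab.strategies import (
    MutationSpec,
    conservation_from_msa,
    parse_mutation_file,
    predict_stability,
    register_predictor,
    scan_bt2p,
    scan_disulfide,
    scan_ncap,
    scan_strain,
)


def test_scan_bt2p_targets_position_two(turn_fixture):
    candidates = scan_bt2p(turn_fixture)
    numbers = {c.mutations[0].number for c in candidates}
    assert 3 in numbers  # second position of the 2..5 turn
    for c in candidates:
        assert c.strategy == "BT2P"
        assert c.mutations[0].target == "P"
        assert "turn_type" in c.annotations


def test_scan_bt2p_skips_existing_proline():
    st = make_fixture(
        FixtureSpec(kind="beta_turn", length=12, sequence="AAPAAAAAAAAA")
    )
    numbers = {c.mutations[0].number for c in scan_bt2p(st)}
    assert 3 not in numbers


def test_scan_ncap(helix18):
    candidates = scan_ncap(helix18)
    assert len(candidates) == 1
    cand = candidates[0]
    assert cand.strategy == "NCAP_PRO"
    assert cand.mutations[0].target == "P"
    # the N-cap precedes the first helical residue
    assert cand.mutations[0].number == cand.annotations["helix_first"][1] - 1


def test_scan_strain(left_handed):
    candidates = scan_strain(left_handed)
    assert [c.mutations[0].number for c in candidates] == [5]
    cand = candidates[0]
    assert cand.strategy == "STRAIN_GLY"
    assert cand.mutations[0].target == "G"
    assert 10.0 < cand.annotations["phi"] < 140.0


def _disulfide_scan_structure():
    """Two alanines placed so CB-CB and CA-CA sit inside the scan windows."""
    st = build_peptide(["ALA"], [(180.0, 180.0)])
    chain = st.chains[0]
    res_b = build_peptide(["ALA"], [(180.0, 180.0)]).chains[0].residues[0]
    res_b.number = 10
    shift = 4.2 * np.array([0.0, 0.0, 1.0])
    for atom in res_b.atoms.values():
        atom.coord = atom.coord + shift
    chain.residues.append(res_b)
    return st


def test_scan_disulfide_geometry():
    st = _disulfide_scan_structure()
    a, b = list(st.residues())
    assert distance(a.coord("CB"), b.coord("CB")) == pytest.approx(4.2)
    candidates = scan_disulfide(st)
    assert len(candidates) == 1
    cand = candidates[0]
    assert cand.strategy == "DISULFIDE"
    assert {m.target for m in cand.mutations} == {"C"}
    assert cand.annotations["loop_size"] == 9


def test_scan_disulfide_respects_separation():
    st = _disulfide_scan_structure()
    st.chains[0].residues[1].number = 3  # separation below the minimum
    assert scan_disulfide(st) == []


def test_scan_disulfide_skips_existing(salt_bridge):
    bonded = make_fixture(
        FixtureSpec(
            kind="residue_pair",
            pair_residues=("CYS", "CYS"),
            pair_atoms=("SG", "SG"),
            pair_distance=2.05,
        )
    )
    for cand in scan_disulfide(bonded):
        keys = {(m.chain, m.number, m.icode) for m in cand.mutations}
        assert ("A", 1, "") not in keys and ("A", 10, "") not in keys


def test_scan_disulfide_ranks_by_loop_size():
    st = _disulfide_scan_structure()
    chain = st.chains[0]
    far = build_peptide(["ALA", "ALA"], [(180.0, 180.0)] * 2).chains[0].residues
    for i, res in enumerate(far):
        res.number = 30 + i
        for atom in res.atoms.values():
            atom.coord = atom.coord + np.array([40.0, 0.0, 4.2 * (1 - i) - 2.1])
    # place a second candidate pair with a larger enclosed loop
    chain.residues.extend(far)
    # not guaranteed to pair; only assert ordering when several exist
    candidates = scan_disulfide(st)
    loops = [c.annotations["loop_size"] for c in candidates]
    assert loops == sorted(loops, reverse=True)


# ---------------------------------------------------------------------------
# conservation

def test_conservation_scores():
    msa = [
        ("anchor", "AKLV-"),
        ("h1", "AKIV-"),
        ("h2", "AKLL-"),
        ("h3", "GKLV-"),
    ]
    scores = conservation_from_msa(msa, "AKLV")
    assert set(scores) == {0, 1, 2, 3}
    # column fully conserved -> 9
    assert scores[1].score == 9
    # 3/4 conserved -> ceil(9 * 0.75) = 7
    assert scores[0].score == 7
    assert scores[2].score == 7
    assert scores[3].score == 7


def test_conservation_needs_anchor():
    with pytest.raises(ValueError, match="identity"):
        conservation_from_msa([("x", "WWWW")], "AKLV")
    with pytest.raises(ValueError, match="unequal"):
        conservation_from_msa([("x", "AKLV"), ("y", "AKL")], "AKLV")
    with pytest.raises(ValueError, match="empty"):
        conservation_from_msa([], "AKLV")


def test_conservation_from_fasta(tmp_path):
    path = tmp_path / "aln.fasta"
    path.write_text(">a\nAKLV\n>b\nAKLI\n")
    scores = conservation_from_msa(path, "AKLV")
    assert scores[0].score == 9
    assert scores[3].score == 5  # ceil(9 * 0.5)


# ---------------------------------------------------------------------------
# predictors

def test_builtin_predictor_self_is_neutral(helix18):
    score, klass = predict_stability(helix18, helix18.copy())
    assert score == 0.0
    assert klass == "D"


def test_predictor_registry(helix18):
    register_predictor("always_up", lambda wild, mut: 1.5)
    score, klass = predict_stability(helix18, helix18, "always_up")
    assert (score, klass) == (1.5, "I")
    with pytest.raises(ValueError, match="not available"):
        predict_stability(helix18, helix18, "nonexistent")


# ---------------------------------------------------------------------------
# mutation files

def test_parse_mutation_file(tmp_path):
    path = tmp_path / "muts.txt"
    path.write_text(
        "# comment line\n"
        "V22A\n"
        "B/K10C, B/E50C\n"
        "A:N3aG\n"
    )
    parsed = parse_mutation_file(path, default_chain="A")
    assert parsed[0] == (MutationSpec("A", 22, "V", "A"),)
    assert parsed[1] == (
        MutationSpec("B", 10, "K", "C"), MutationSpec("B", 50, "E", "C"),
    )
    assert parsed[2] == (MutationSpec("A", 3, "N", "G", icode="A"),)


def test_parse_mutation_file_errors(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text("V22A\nnot-a-mutation!\n")
    with pytest.raises(ValueError, match="line 2"):
        parse_mutation_file(path)
    empty = tmp_path / "empty.txt"
    empty.write_text("# nothing\n")
    with pytest.raises(ValueError, match="no mutations"):
        parse_mutation_file(empty)
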