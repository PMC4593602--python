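import numpy as np
import pytest

from prostab.model import Atom, Chain, Residue, Structure, write_structure
from prostab.sasa import (
    GXG_REFERENCE,
    VDW_RADII,
    classify_exposure,
    compute_sasa,
    sasa_table,
    sphere_points,
)


def _single_atom_structure(element="C", name="CA"):
    res = Residue(chain_id="A", number=1, name="ALA")
    res.atoms[name] = Atom(name, element, np.zeros(3))
    return Structure(id="one", chains=[Chain("A", [res])])


def test_sphere_points_unit_and_count():
    pts = sphere_points(500)
    assert pts.shape == (500, 3)
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)


def test_isolated_atom_analytic_sphere():
    """An isolated atom's SASA is exactly 4*pi*(r+probe)^2; the sampled
    value must match within 1%."""
    for element in ("C", "N", "O", "S"):
        st = _single_atom_structure(element)
        result = compute_sasa(st, probe=1.4, points=960)
        r = VDW_RADII[element] + 1.4
        exact = 4.0 * np.pi * r ** 2
        assert result.total == pytest.approx(exact, rel=0.01)


def test_disjoint_atoms_are_additive():
    res = Residue(chain_id="A", number=1, name="ALA")
    res.atoms["C1"] = Atom("C1", "C", np.array([0.0, 0.0, 0.0]))
    res.atoms["C2"] = Atom("C2", "C", np.array([50.0, 0.0, 0.0]))
    st = Structure(id="two", chains=[Chain("A", [res])])
    result = compute_sasa(st, points=960)
    single = compute_sasa(_single_atom_structure("C"), points=960)
    assert result.total == pytest.approx(2 * single.total, rel=1e-9)


def test_engulfed_atom_has_zero_area():
    res = Residue(chain_id="A", number=1, name="ALA")
    res.atoms["O1"] = Atom("O1", "O", np.zeros(3))
    # a shell of large atoms fully surrounding the centre
    shell = 2.2 * sphere_points(60)
    for i, p in enumerate(shell):
        res.atoms[f"S{i}"] = Atom(f"S{i}", "S", p)
    st = Structure(id="shell", chains=[Chain("A", [res])])
    result = compute_sasa(st, points=960)
    assert result.atom_area[("A", 1, "")]["O1"] == 0.0


def test_refinement_convergence(helix18):
    """The default lattice must agree with a 10x denser one within 2%."""
    coarse = compute_sasa(helix18, points=960)
    fine = compute_sasa(helix18, points=9600)
    assert coarse.total == pytest.approx(fine.total, rel=0.02)


def test_agrees_with_independent_implementation(tmp_path, helix18):
    """Cross-check against an established Shrake-Rupley implementation on
    the same coordinates and radii."""
    biotite_pdb = pytest.importorskip("biotite.structure.io.pdb")
    biotite_structure = pytest.importorskip("biotite.structure")

    path = tmp_path / "helix.pdb"
    write_structure(helix18, path)
    arr = biotite_pdb.PDBFile.read(str(path)).get_structure(model=1)
    arr = arr[arr.element != "H"]
    radii = np.array([VDW_RADII[e] for e in arr.element])
    ref_atom = biotite_structure.sasa(
        arr, probe_radius=1.4, vdw_radii=radii, point_number=960
    )
    ours = compute_sasa(helix18, points=960)
    assert ours.total == pytest.approx(float(np.nansum(ref_atom)), rel=0.02)


def test_polar_nonpolar_partition(helix18):
    result = compute_sasa(helix18)
    assert result.total == pytest.approx(
        result.total_polar + result.total_nonpolar, rel=1e-9
    )
    assert result.np_over_p == pytest.approx(
        result.total_nonpolar / result.total_polar
    )


def test_relative_asa_and_exposure(helix18):
    result = compute_sasa(helix18)
    exposure = classify_exposure(result, threshold=10.0)
    # a short isolated helix is entirely solvent exposed
    assert set(exposure.values()) == {"exposed"}
    for key, rs in result.residue.items():
        assert rs.relative == pytest.approx(
            100.0 * rs.total / GXG_REFERENCE["ALA"]
        )
    # threshold 100 with any buried residue classes everything buried
    all_buried = classify_exposure(result, threshold=100.0)
    assert all(
        v == "buried" for k, v in all_buried.items()
        if result.residue[k].relative < 100.0
    )


def test_exposure_threshold_validated(helix18):
    result = compute_sasa(helix18)
    with pytest.raises(ValueError):
        classify_exposure(result, threshold=-5.0)
    with pytest.raises(ValueError):
        classify_exposure(result, threshold=150.0)


def test_sasa_table_shape(helix18):
    frame = sasa_table(helix18, compute_sasa(helix18))
    assert len(frame) == 18
    assert {"chain", "resnum", "abs", "rel", "mc", "sc"} <= set(frame.columns)


def test_unknown_element_warns():
    st = _single_atom_structure(element="ZN", name="ZN")
    with pytest.warns(UserWarning, match="radius"):
        compute_sasa(st)
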