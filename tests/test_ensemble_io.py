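"""I/O, heavy-atom selection, alignment, scaling and trajectory splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import idpgen as ig
from idpgen.ensemble import EnsembleFormatError

from oracles import quaternion_rmsd


def _toy_ensemble(n_frames=2, n_atoms=5, seed=0):
    rng = np.random.default_rng(seed)
    atoms = ig.AtomTable(
        residue_index=np.arange(1, n_atoms + 1),
        residue_name=["GLY"] * n_atoms,
        atom_name=["CA"] * n_atoms,
    )
    return ig.ConformationEnsemble(rng.normal(size=(n_frames, n_atoms, 3)) * 5, atoms)


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fmt,tol", [("pdb", 1e-3), ("table", 1e-5)])
def test_write_load_round_trip(tmp_path, fmt, tol):
    ens = _toy_ensemble(n_frames=3)
    path = tmp_path / f"ens.{fmt}"
    ig.write_ensemble(ens, path, fmt=fmt)
    back = ig.load_ensemble(path, fmt=fmt)
    assert back.n_frames == 3 and back.n_atoms == 5
    assert back.atoms == ens.atoms
    np.testing.assert_allclose(back.coordinates, ens.coordinates, atol=tol)


def test_load_two_model_pdb(tmp_path):
    ens = _toy_ensemble(n_frames=2)
    path = tmp_path / "two.pdb"
    ig.write_ensemble(ens, path)
    back = ig.load_ensemble(path)
    assert back.n_frames == 2 and back.n_atoms == 5


def test_single_frame_pdb_has_one_model(tmp_path, chain_template):
    path = tmp_path / "one.pdb"
    ig.write_ensemble(chain_template, path)
    text = path.read_text()
    assert text.count("MODEL") - text.count("ENDMDL") == 0
    back = ig.load_ensemble(path)
    assert back.n_frames == 1


def test_inconsistent_model_atom_count_rejected(tmp_path):
    ens5 = _toy_ensemble(n_frames=1, n_atoms=5)
    ens4 = _toy_ensemble(n_frames=1, n_atoms=4)
    p5, p4 = tmp_path / "a.pdb", tmp_path / "b.pdb"
    ig.write_ensemble(ens5, p5)
    ig.write_ensemble(ens4, p4)
    lines5 = [l for l in p5.read_text().splitlines() if l.startswith(("ATOM", "HETATM"))]
    lines4 = [l for l in p4.read_text().splitlines() if l.startswith(("ATOM", "HETATM"))]
    bad = ["MODEL     1", *lines5, "ENDMDL", "MODEL     2", *lines4, "ENDMDL", "END"]
    badpath = tmp_path / "bad.pdb"
    badpath.write_text("\n".join(bad) + "\n")
    with pytest.raises((EnsembleFormatError, Exception)):
        ig.load_ensemble(badpath)


def test_write_empty_ensemble_rejected(tmp_path):
    ens = _toy_ensemble(n_frames=1)
    empty = ig.ConformationEnsemble.__new__(ig.ConformationEnsemble)
    empty.coordinates = ens.coordinates[:0]
    empty.atoms = ens.atoms
    empty.frame_sources = None
    with pytest.raises(ValueError):
        ig.write_ensemble(empty, tmp_path / "x.pdb")


# ---------------------------------------------------------------------------
# Heavy-atom selection
# ---------------------------------------------------------------------------

def test_capped_glutamine_chain_keeps_140_atoms(chain_template):
    sel = ig.select_heavy_atoms(chain_template)
    assert sel.n_atoms == 140


def test_uncapped_polyglycine_keeps_backbone_only():
    gly = ig.make_chain_template(5, caps=False, seed=1, residue_name="GLY")
    sel = ig.select_heavy_atoms(gly)
    assert sel.n_atoms == 20


def test_full_atom_side_chains_are_truncated():
    # lysine-like residue: CE/NZ are beyond the retained side-chain set
    names = ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ", "HA", "HB2"]
    atoms = ig.AtomTable([1] * len(names), ["LYS"] * len(names), names)
    ens = ig.ConformationEnsemble(np.zeros((1, len(names), 3)), atoms)
    sel = ig.select_heavy_atoms(ens)
    assert list(sel.atoms.atom_name) == ["N", "CA", "C", "O", "CB", "CG", "CD"]


def test_empty_selection_rejected():
    atoms = ig.AtomTable([1, 1], ["LIG", "LIG"], ["ZN", "FE"])
    ens = ig.ConformationEnsemble(np.zeros((1, 2, 3)), atoms)
    with pytest.raises(ValueError):
        ig.select_heavy_atoms(ens)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def test_align_identical_frames_is_identity():
    ens = _toy_ensemble(n_frames=1)
    stacked = ens.with_coordinates(np.repeat(ens.coordinates, 4, axis=0))
    aligned = ig.align_frames(stacked)
    np.testing.assert_allclose(aligned.coordinates, stacked.coordinates, atol=1e-12)


def test_align_removes_rigid_motion():
    ens = _toy_ensemble(n_frames=1, n_atoms=8, seed=2)
    theta = 0.8
    rot = np.array(
        [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
    )
    moved = ens.coordinates[0] @ rot.T + np.array([3.0, -2.0, 7.0])
    pair = ens.with_coordinates(np.stack([ens.coordinates[0], moved]))
    aligned = ig.align_frames(pair)
    diff = aligned.coordinates[1] - aligned.coordinates[0]
    assert np.sqrt((diff**2).sum() / 8) < 1e-6


def test_alignment_matches_quaternion_oracle():
    rng = np.random.default_rng(7)
    coords = rng.normal(size=(10, 12, 3)) * 4
    atoms = ig.AtomTable(np.arange(1, 13), ["GLY"] * 12, ["CA"] * 12)
    ens = ig.ConformationEnsemble(coords, atoms)
    aligned = ig.align_frames(ens)
    ref = aligned.coordinates[0]
    for k in range(1, 10):
        achieved = np.sqrt(((aligned.coordinates[k] - ref) ** 2).sum() / 12)
        optimal = quaternion_rmsd(coords[k], coords[0])
        assert abs(achieved - optimal) < 1e-6


def test_degenerate_collinear_coordinates_fall_back_to_identity():
    line = np.zeros((4, 3))
    line[:, 0] = np.arange(4.0)
    rot = ig.ensemble.kabsch_rotation(line - line.mean(0), line - line.mean(0))
    np.testing.assert_allclose(rot, np.eye(3))


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

def test_scaling_span_and_unit_interval():
    coords = np.array([[[-3.0, 2.0, 7.0], [0.0, -3.0, 4.0], [7.0, 1.0, -1.0]]])
    atoms = ig.AtomTable([1, 1, 1], ["GLY"] * 3, ["N", "CA", "C"])
    ens = ig.ConformationEnsemble(coords, atoms)
    tr = ig.fit_scaling(ens)
    scaled = tr.apply(coords)
    assert tr.scale == pytest.approx(10.0)
    assert scaled.min() == pytest.approx(0.0)
    assert scaled.max() == pytest.approx(1.0)


def test_scaling_round_trip_exact():
    ens = _toy_ensemble(n_frames=4, seed=3)
    tr = ig.fit_scaling(ens)
    back = tr.invert(tr.apply(ens.coordinates))
    assert np.abs(back - ens.coordinates).max() < 1e-9


def test_scaling_of_out_of_range_test_values_exceeds_one():
    train = _toy_ensemble(n_frames=4, seed=3)
    tr = ig.fit_scaling(train)
    beyond = train.coordinates.max() + 5.0
    assert tr.apply(np.array([beyond])) > 1.0


def test_zero_range_rejected():
    atoms = ig.AtomTable([1], ["GLY"], ["CA"])
    flat = ig.ConformationEnsemble(np.full((2, 1, 3), 1.5), atoms)
    with pytest.raises(ValueError):
        ig.fit_scaling(flat)


def test_scaling_json_round_trip(tmp_path):
    tr = ig.ScalingTransform(shift=4.25, scale=31.5)
    tr.to_json(tmp_path / "s.json")
    back = ig.ScalingTransform.from_json(tmp_path / "s.json")
    assert back == tr


# ---------------------------------------------------------------------------
# Split and dilution
# ---------------------------------------------------------------------------

def _frames_only(n):
    atoms = ig.AtomTable([1], ["GLY"], ["CA"])
    coords = np.zeros((n, 1, 3))
    coords[:, 0, 0] = np.arange(n)  # frame index encoded in x
    return ig.ConformationEnsemble(coords, atoms)


@pytest.mark.parametrize(
    "n,frac,n_train,n_test",
    [(95_000, 0.1, 9_500, 85_500), (140_000, 0.2, 28_000, 112_000), (100, 0.5, 50, 50)],
)
def test_split_sizes(n, frac, n_train, n_test):
    tr, te = ig.split_trajectory(_frames_only(n), ig.SplitSpec(train_fraction=frac))
    assert (tr.n_frames, te.n_frames) == (n_train, n_test)
    # the training portion is the *initial* portion
    assert tr.coordinates[0, 0, 0] == 0
    assert te.coordinates[0, 0, 0] == n_train


@pytest.mark.parametrize("n,factor,expected", [(1_218_000, 1000, 1_218), (1_218_000, 100, 12_180)])
def test_dilution_counts(n, factor, expected):
    assert ig.dilute(_frames_only(n), factor).n_frames == expected


def test_dilution_identity_and_composition():
    ens = _frames_only(600)
    assert ig.dilute(ens, 1) is ens
    ab = ig.dilute(ig.dilute(ens, 2), 3)
    np.testing.assert_array_equal(ab.coordinates, ig.dilute(ens, 6).coordinates)
    with pytest.raises(ValueError):
        ig.dilute(ens, 0)


@given(
    n=st.integers(10, 3000),
    burn=st.integers(0, 50),
    frac=st.floats(0.05, 0.95),
)
@settings(max_examples=60, derandomize=True, deadline=None)
def test_split_conserves_frames(n, burn, frac):
    ens = _frames_only(n)
    spec = ig.SplitSpec(burn_in_frames=burn, train_fraction=frac)
    try:
        tr, te = ig.split_trajectory(ens, spec)
    except ValueError:
        return  # empty train or test: rejected, nothing to conserve
    assert burn + tr.n_frames + te.n_frames == n


def test_split_burn_in_too_large_rejected():
    with pytest.raises(ValueError):
        ig.split_trajectory(_frames_only(10), ig.SplitSpec(burn_in_frames=9))
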