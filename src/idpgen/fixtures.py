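"""Synthetic multi-basin "trajectories" of a disordered polymer chain.

Real inputs to the generative autoencoder are MD trajectories of an IDP.
These fixtures emulate their statistical structure without any physics:

* a heavy-atom chain with ideal bond geometry, capped with acetyl (ACE) and
  N-methylamide (NME) groups, carrying CB/CG/CD/OE1/NE2 side-chain stubs so
  the heavy-atom selection rule applies (a 15-residue capped glutamine-like
  chain has exactly 140 selectable heavy atoms);
* several conformational basins (template conformations with different
  backbone/side-chain torsions), visited by a Markov chain with a small
  per-frame switch probability, giving the temporal autocorrelation that
  makes an initial-portion training split meaningful;
* within-basin AR(1) Cartesian noise plus a random rigid jitter per frame,
  so preprocessing has genuine alignment work to do;
* replicate runs whose basin sets partially overlap, to emulate independent
  MD runs mining overlapping regions of conformational space.

Everything is deterministic given the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import AtomTable, ConformationEnsemble, kabsch_rotation
from .templates import (
    ANGLE_C_N_CA,
    ANGLE_CA_C_N,
    ANGLE_O_C_N,
    BOND_IDEALS,
    PEPTIDE_BOND,
    ANGLE_IDEALS,
    internal_terms,
    place_nerf,
    place_two_angles,
)

__all__ = ["FixtureSpec", "make_chain_template", "make_run", "make_replicates", "default_fixture_spec"]

# torsion basins a residue can adopt (phi, psi), degrees
_TORSION_LIBRARY = np.array(
    [(-140.0, 135.0), (-70.0, -40.0), (-60.0, 140.0), (-120.0, 60.0)]
)

_SIDECHAIN_NAMES = ("CB", "CG", "CD", "OE1", "NE2")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic replicate run."""

    n_res: int = 15
    caps: bool = True
    n_frames: int = 5000
    n_basins: int = 3
    basin_occupancy: np.ndarray | None = None  # default uniform
    within_basin_sd: float = 1.0  # A, per-coordinate noise scale
    switch_probability: float = 0.02  # per-frame basin switch rate
    noise_rho: float = 0.9  # AR(1) coefficient of within-basin noise
    rigid_jitter: bool = True  # random per-frame rotation + translation
    run_overlap: float = 1.0  # fraction of basins shared across replicates
    seed: int = 0
    basin_centers: list[np.ndarray] | None = None  # precomputed (n_atoms, 3)

    def __post_init__(self):
        if self.n_basins < 1:
            raise ValueError("n_basins must be >= 1")
        if not 0.0 <= self.switch_probability <= 1.0:
            raise ValueError("switch_probability must be in [0, 1]")
        if self.within_basin_sd <= 0:
            raise ValueError("within_basin_sd must be > 0")
        if self.basin_occupancy is not None:
            occ = np.asarray(self.basin_occupancy, dtype=float)
            if occ.shape != (self.n_basins,) or not np.isclose(occ.sum(), 1.0):
                raise ValueError("basin_occupancy must be n_basins probabilities summing to 1")
            self.basin_occupancy = occ

    @property
    def occupancy(self) -> np.ndarray:
        if self.basin_occupancy is None:
            return np.full(self.n_basins, 1.0 / self.n_basins)
        return self.basin_occupancy


def default_fixture_spec(seed: int = 0) -> FixtureSpec:
    """The standard small fixture: 15 capped residues, 5,000 frames, 3 basins,
    1.0 A within-basin noise, 2% switch rate."""
    return FixtureSpec(seed=seed)


# ---------------------------------------------------------------------------
# Template chain construction
# ---------------------------------------------------------------------------

def _atom_layout(n_res: int, caps: bool, residue_name: str) -> AtomTable:
    res_idx, res_name, atom_name = [], [], []
    rid = 0
    if caps:
        rid += 1
        for nm in ("CH3", "C", "O"):
            res_idx.append(rid)
            res_name.append("ACE")
            atom_name.append(nm)
    side = () if residue_name == "GLY" else _SIDECHAIN_NAMES
    for _ in range(n_res):
        rid += 1
        for nm in ("N", "CA", "C", "O") + side:
            res_idx.append(rid)
            res_name.append(residue_name)
            atom_name.append(nm)
    if caps:
        rid += 1
        for nm in ("N", "CH3"):
            res_idx.append(rid)
            res_name.append("NME")
            atom_name.append(nm)
    return AtomTable(res_idx, res_name, atom_name)


def make_chain_template(
    n_res: int,
    caps: bool = True,
    seed: int = 0,
    residue_name: str = "GLN",
    torsion_jitter: float = 8.0,
    max_retries: int = 60,
) -> ConformationEnsemble:
    """Build one chain conformation with exactly ideal bonds and angles.

    Backbone and side-chain torsions are drawn per residue from a small
    rotamer-like library plus seeded jitter; a draw whose nonbonded atoms
    clash (closer than 2.0 A) is rejected and redrawn.  Torsions do not
    affect bond lengths or angles, so the result always passes the geometry
    check with zero violations.
    """
    if n_res < 2:
        raise ValueError("n_res must be >= 2")
    atoms = _atom_layout(n_res, caps, residue_name)
    rng = np.random.default_rng(seed)
    for _attempt in range(max_retries):
        coords = _build_chain(atoms, n_res, caps, residue_name, rng, torsion_jitter)
        if _self_avoiding(coords, atoms):
            return ConformationEnsemble(coords[np.newaxis], atoms, f"template-{seed}")
    raise RuntimeError(f"failed to build a clash-free chain in {max_retries} attempts")


def _build_chain(atoms, n_res, caps, residue_name, rng, jitter) -> np.ndarray:
    aa_bonds = BOND_IDEALS["AA"]
    aa_angles = ANGLE_IDEALS["AA"]
    pos: dict[tuple[int, str], np.ndarray] = {}
    picks = rng.integers(0, len(_TORSION_LIBRARY), size=n_res)
    phi = _TORSION_LIBRARY[picks, 0] + rng.normal(0, jitter, n_res)
    psi = _TORSION_LIBRARY[picks, 1] + rng.normal(0, jitter, n_res)
    chi1 = -65.0 + rng.normal(0, jitter, n_res)
    chi2 = 180.0 + rng.normal(0, jitter, n_res)
    chi3 = -30.0 + rng.normal(0, jitter, n_res)

    first = 1 if caps else 0  # residue_index of first amino acid is first+? (1-based)
    if caps:
        # ACE: CH3 at origin, C along x, N of residue 1 in the xy-plane
        pos[(1, "CH3")] = np.array([0.0, 0.0, 0.0])
        pos[(1, "C")] = np.array([BOND_IDEALS["ACE"][("CH3", "C")], 0.0, 0.0])
        ang = np.deg2rad(180.0 - ANGLE_CA_C_N)
        pos[(2, "N")] = pos[(1, "C")] + PEPTIDE_BOND * np.array([np.cos(ang), np.sin(ang), 0.0])
        pos[(2, "CA")] = place_nerf(
            pos[(1, "CH3")], pos[(1, "C")], pos[(2, "N")],
            aa_bonds[("N", "CA")], ANGLE_C_N_CA, 180.0,
        )
        pos[(1, "O")] = place_two_angles(
            pos[(1, "C")], pos[(1, "CH3")], pos[(2, "N")],
            BOND_IDEALS["ACE"][("C", "O")], ANGLE_IDEALS["ACE"][("CH3", "C", "O")], ANGLE_O_C_N,
        )
        prev = (pos[(1, "CH3")], pos[(1, "C")], pos[(2, "N")], pos[(2, "CA")])
    else:
        pos[(1, "N")] = np.array([0.0, 0.0, 0.0])
        pos[(1, "CA")] = np.array([aa_bonds[("N", "CA")], 0.0, 0.0])
        prev = (None, None, pos[(1, "N")], pos[(1, "CA")])

    for r in range(n_res):
        rid = r + (2 if caps else 1)
        a_prev, b_prev, n_pos, ca_pos = prev
        # C(i) by phi about N-CA; for the very first uncapped residue there is
        # no predecessor, so place C in the initial plane instead.
        if b_prev is None:
            ang = np.deg2rad(180.0 - aa_angles[("N", "CA", "C")])
            c_pos = ca_pos + aa_bonds[("CA", "C")] * np.array([np.cos(ang), np.sin(ang), 0.0])
        else:
            c_pos = place_nerf(b_prev, n_pos, ca_pos, aa_bonds[("CA", "C")],
                               aa_angles[("N", "CA", "C")], phi[r])
        pos[(rid, "C")] = c_pos
        # next backbone nitrogen (or NME nitrogen), by psi about CA-C
        has_next = r < n_res - 1 or caps
        if has_next:
            next_rid = rid + 1
            n_next = place_nerf(n_pos, ca_pos, c_pos, PEPTIDE_BOND, ANGLE_CA_C_N, psi[r])
            pos[(next_rid, "N")] = n_next
            pos[(rid, "O")] = place_two_angles(
                c_pos, ca_pos, n_next, aa_bonds[("C", "O")],
                aa_angles[("CA", "C", "O")], ANGLE_O_C_N,
            )
        else:
            pos[(rid, "O")] = place_nerf(n_pos, ca_pos, c_pos, aa_bonds[("C", "O")],
                                         aa_angles[("CA", "C", "O")], psi[r] + 180.0)
        # side chain
        if residue_name != "GLY":
            cb = place_two_angles(ca_pos, n_pos, c_pos, aa_bonds[("CA", "CB")],
                                  aa_angles[("N", "CA", "CB")], aa_angles[("CB", "CA", "C")],
                                  sign=-1.0)
            cg = place_nerf(n_pos, ca_pos, cb, aa_bonds[("CB", "CG")],
                            aa_angles[("CA", "CB", "CG")], chi1[r])
            cd = place_nerf(ca_pos, cb, cg, aa_bonds[("CG", "CD")],
                            aa_angles[("CB", "CG", "CD")], chi2[r])
            oe1 = place_nerf(cb, cg, cd, aa_bonds[("CD", "OE1")],
                             aa_angles[("CG", "CD", "OE1")], chi3[r])
            ne2 = place_two_angles(cd, cg, oe1, aa_bonds[("CD", "NE2")],
                                   aa_angles[("CG", "CD", "NE2")],
                                   aa_angles[("OE1", "CD", "NE2")])
            pos[(rid, "CB")], pos[(rid, "CG")] = cb, cg
            pos[(rid, "CD")], pos[(rid, "OE1")], pos[(rid, "NE2")] = cd, oe1, ne2
        # advance: CA of the next residue via the omega = 180 peptide torsion
        if has_next:
            next_rid = rid + 1
            follower_bond = (
                BOND_IDEALS["NME"][("N", "CH3")] if (caps and r == n_res - 1)
                else aa_bonds[("N", "CA")]
            )
            follower_name = "CH3" if (caps and r == n_res - 1) else "CA"
            follower = place_nerf(ca_pos, c_pos, pos[(next_rid, "N")],
                                  follower_bond, ANGLE_C_N_CA, 180.0)
            pos[(next_rid, follower_name)] = follower
            prev = (ca_pos, c_pos, pos[(next_rid, "N")], follower)

    coords = np.empty((len(atoms), 3))
    for i in range(len(atoms)):
        coords[i] = pos[(int(atoms.residue_index[i]), str(atoms.atom_name[i]))]
    return coords


def _self_avoiding(coords: np.ndarray, atoms, min_dist: float = 1.7) -> bool:
    bonds, angles, _ = internal_terms(atoms)
    excluded = {frozenset((i, j)) for i, j, _ in bonds}
    excluded |= {frozenset((i, k)) for i, _, k, _ in angles}
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    n = len(coords)
    iu = np.triu_indices(n, 1)
    for i, j in zip(*iu):
        if dist[i, j] < min_dist and frozenset((int(i), int(j))) not in excluded:
            return False
    return True


# ---------------------------------------------------------------------------
# Runs and replicates
# ---------------------------------------------------------------------------

def _build_centers(spec: FixtureSpec, seeds: list[int]) -> list[np.ndarray]:
    centers = []
    for s in seeds:
        ens = make_chain_template(spec.n_res, spec.caps, seed=s)
        centers.append(ens.coordinates[0])
    # superpose all centers on the first for a stable common frame
    ref = centers[0] - centers[0].mean(axis=0)
    out = [ref]
    for c in centers[1:]:
        cc = c - c.mean(axis=0)
        rot = kabsch_rotation(cc, ref)
        out.append(cc @ rot.T)
    return out


def make_run(spec: FixtureSpec, return_details: bool = False):
    """Simulate one replicate run.

    The basin index follows a Markov chain (switch with probability
    ``switch_probability``, new basin drawn from the occupancy), each frame is
    the basin template plus AR(1) Cartesian noise of stationary standard
    deviation ``within_basin_sd``, and an optional random rigid motion is
    applied per frame.  With ``return_details`` the realized basin centers
    and per-frame basin states are also returned.
    """
    ss = np.random.SeedSequence(spec.seed)
    center_seed_rng, traj_ss = ss.spawn(2)
    rng_centers = np.random.default_rng(center_seed_rng)
    rng = np.random.default_rng(traj_ss)

    if spec.basin_centers is not None:
        centers = [np.asarray(c, dtype=float) for c in spec.basin_centers]
        if len(centers) != spec.n_basins:
            raise ValueError("basin_centers length must equal n_basins")
    else:
        seeds = [int(rng_centers.integers(0, 2**31 - 1)) for _ in range(spec.n_basins)]
        centers = _build_centers(spec, seeds)

    n_atoms = centers[0].shape[0]
    occ = spec.occupancy
    states = np.empty(spec.n_frames, dtype=int)
    state = rng.choice(spec.n_basins, p=occ)
    sd, rho = spec.within_basin_sd, spec.noise_rho
    noise = rng.normal(0.0, sd, size=(n_atoms, 3))
    coords = np.empty((spec.n_frames, n_atoms, 3))
    for t in range(spec.n_frames):
        if t > 0 and rng.random() < spec.switch_probability:
            state = rng.choice(spec.n_basins, p=occ)
            noise = rng.normal(0.0, sd, size=(n_atoms, 3))
        states[t] = state
        frame = centers[state] + noise
        if spec.rigid_jitter:
            frame = frame @ _small_rotation(rng).T + rng.normal(0.0, 1.0, size=3)
        coords[t] = frame
        noise = rho * noise + np.sqrt(1.0 - rho**2) * rng.normal(0.0, sd, size=(n_atoms, 3))

    atoms = _atom_layout(spec.n_res, spec.caps, "GLN")
    ens = ConformationEnsemble(coords, atoms, f"run-{spec.seed}")
    if return_details:
        return ens, centers, states
    return ens


def _small_rotation(rng: np.random.Generator, sigma_rad: float = 0.15) -> np.ndarray:
    """Random rotation matrix with small rotation angle (Rodrigues form)."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    theta = rng.normal(0.0, sigma_rad)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)


def make_replicates(
    spec: FixtureSpec, n_runs: int, run_overlap: float | None = None
) -> list[ConformationEnsemble]:
    """Replicate runs whose basin sets partially overlap.

    A fraction ``run_overlap`` of each run's ``n_basins`` basins (rounded) is
    shared by all runs; the rest are private to each run.  Per-run seeds are
    derived from the master seed, so the whole collection is deterministic.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    overlap = spec.run_overlap if run_overlap is None else run_overlap
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("run_overlap must be in [0, 1]")
    n_shared = int(round(overlap * spec.n_basins))
    ss = np.random.SeedSequence(spec.seed)
    seed_rng = np.random.default_rng(ss)
    shared_seeds = [int(seed_rng.integers(0, 2**31 - 1)) for _ in range(n_shared)]
    runs = []
    for r in range(n_runs):
        private_seeds = [
            int(seed_rng.integers(0, 2**31 - 1)) for _ in range(spec.n_basins - n_shared)
        ]
        centers = _build_centers(spec, shared_seeds + private_seeds) if (shared_seeds or private_seeds) else []
        run_spec = FixtureSpec(
            n_res=spec.n_res,
            caps=spec.caps,
            n_frames=spec.n_frames,
            n_basins=spec.n_basins,
            basin_occupancy=spec.basin_occupancy,
            within_basin_sd=spec.within_basin_sd,
            switch_probability=spec.switch_probability,
            noise_rho=spec.noise_rho,
            rigid_jitter=spec.rigid_jitter,
            run_overlap=overlap,
            seed=int(seed_rng.integers(0, 2**31 - 1)),
            basin_centers=centers,
        )
        ens = make_run(run_spec)
        ens.source_label = f"run{r}"
        runs.append(ens)
    return runs
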