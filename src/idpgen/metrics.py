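"""Evaluation statistics for conformational ensembles.

All RMSDs are minimal RMSDs: each pair of conformations is re-superposed by
the optimal rigid rotation and translation (Kabsch) before the deviation is
computed, so values are invariant to how either ensemble happens to be
oriented.  The coverage measure is the best-match RMSD: for each conformation
of a (diluted) test set, the minimum RMSD to any member of a reference or
generated set; its average over the test set summarises how completely the
reference set covers the test ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autoencoder import AutoencoderModel, reconstruct
from .ensemble import ConformationEnsemble, ScalingTransform, dilute, kabsch_rotation
from .templates import internal_terms

__all__ = [
    "EvaluationReport",
    "GeometryReport",
    "rmsd",
    "rmsd_matrix",
    "mean_reconstruction_rmsd",
    "best_match_rmsd",
    "pairwise_diversity",
    "within_set_best_match",
    "mape",
    "rmse",
    "geometry_check",
]


@dataclass
class EvaluationReport:
    """Summary of a best-match evaluation."""

    best_match_mean: float
    best_match_per_conformation: list[tuple[int, int, float]]  # (test idx, match idx, A)
    mean_reconstruction_rmsd: float | None = None
    pairwise_diversity_mean: float | None = None
    metadata: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "best_match_mean": self.best_match_mean,
            "mean_reconstruction_rmsd": self.mean_reconstruction_rmsd,
            "pairwise_diversity_mean": self.pairwise_diversity_mean,
            "best_match_per_conformation": [
                [int(i), int(j), float(r)] for i, j, r in self.best_match_per_conformation
            ],
            "metadata": self.metadata,
        }

    def matches_to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("test_index\tref_index\trmsd\n")
            for i, j, r in self.best_match_per_conformation:
                fh.write(f"{i}\t{j}\t{r:.6f}\n")


@dataclass
class GeometryReport:
    """Bond and angle deviations of one conformation from ideal geometry."""

    bond_violations: list[tuple[int, int, float, float]]  # (i, j, length, ideal)
    angle_violations: list[tuple[int, int, int, float, float]]  # (i, j, k, deg, ideal)
    bond_tol: float
    angle_tol: float
    n_bonds_checked: int = 0
    n_angles_checked: int = 0

    @property
    def n_bond_violations(self) -> int:
        return len(self.bond_violations)

    @property
    def n_angle_violations(self) -> int:
        return len(self.angle_violations)

    @property
    def total_violations(self) -> int:
        return self.n_bond_violations + self.n_angle_violations


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def rmsd(conf_a: np.ndarray, conf_b: np.ndarray) -> float:
    """Minimal RMSD between two conformations after optimal superposition."""
    a = np.asarray(conf_a, dtype=float)
    b = np.asarray(conf_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("conformations must both be (N, 3) with equal N")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms for superposition")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    rot = kabsch_rotation(ac, bc)
    diff = ac @ rot.T - bc
    return float(np.sqrt((diff**2).sum() / n))


def _det3(h: np.ndarray) -> np.ndarray:
    """Determinants of a stack of 3x3 matrices."""
    return (
        h[:, 0, 0] * (h[:, 1, 1] * h[:, 2, 2] - h[:, 1, 2] * h[:, 2, 1])
        - h[:, 0, 1] * (h[:, 1, 0] * h[:, 2, 2] - h[:, 1, 2] * h[:, 2, 0])
        + h[:, 0, 2] * (h[:, 1, 0] * h[:, 2, 1] - h[:, 1, 1] * h[:, 2, 0])
    )


def rmsd_matrix(
    coords_a: np.ndarray, coords_b: np.ndarray, chunk_a: int = 32, chunk_b: int = 65536
) -> np.ndarray:
    """Matrix of minimal RMSDs between every frame of A and every frame of B.

    Equivalent to superposing every pair explicitly, but the 3x3
    cross-covariances of a whole block of pairs are formed in one matrix
    product and only batched 3x3 symmetric eigenproblems are solved (the
    singular values of the cross-covariance, with the usual det-sign
    correction, give the optimally superposed deviation).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.ndim != 3 or b.ndim != 3 or a.shape[1:] != b.shape[1:]:
        raise ValueError("coordinate stacks must be (K, N, 3) with matching atoms")
    n = a.shape[1]
    ka, kb = a.shape[0], b.shape[0]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    ta = (ac**2).sum(axis=(1, 2))  # (Ka,)
    tb = (bc**2).sum(axis=(1, 2))  # (Kb,)
    out = np.empty((ka, kb))
    for i0 in range(0, ka, chunk_a):
        at = ac[i0 : i0 + chunk_a].transpose(0, 2, 1)  # (T, 3, N)
        t = at.shape[0]
        for j0 in range(0, kb, chunk_b):
            bs = bc[j0 : j0 + chunk_b]
            nb = bs.shape[0]
            # cross-covariances for all T x nb pairs in one GEMM
            h = np.tensordot(at, bs, axes=([2], [1]))  # (T, 3, nb, 3)
            h = h.transpose(0, 2, 1, 3).reshape(t * nb, 3, 3)
            g = h.transpose(0, 2, 1) @ h  # h^T h, symmetric PSD
            s = np.sqrt(np.clip(np.linalg.eigvalsh(g), 0.0, None))  # ascending
            d = s[:, 1] + s[:, 2] + np.where(_det3(h) < 0, -s[:, 0], s[:, 0])
            sq = (ta[i0 : i0 + chunk_a, None] + tb[None, j0 : j0 + chunk_b]
                  - 2.0 * d.reshape(t, nb)) / n
            out[i0 : i0 + chunk_a, j0 : j0 + chunk_b] = np.sqrt(np.clip(sq, 0.0, None))
    return out


# ---------------------------------------------------------------------------
# Ensemble-level statistics
# ---------------------------------------------------------------------------

def mean_reconstruction_rmsd(
    model: AutoencoderModel,
    test: ConformationEnsemble,
    scaling: ScalingTransform,
    dilution: int = 1,
) -> float:
    """Average minimal RMSD between diluted test conformations and their
    encode->decode reconstructions (mapped back to real coordinates with the
    training scaling)."""
    diluted = dilute(test, dilution)
    if diluted.n_frames < 1:
        raise ValueError("diluted test set is empty")
    scaled = scaling.apply(diluted.flat())
    recon = scaling.invert(reconstruct(model, scaled))
    recon = recon.reshape(diluted.n_frames, diluted.n_atoms, 3)
    vals = [rmsd(diluted.coordinates[k], recon[k]) for k in range(diluted.n_frames)]
    return float(np.mean(vals))


def best_match_rmsd(
    test: ConformationEnsemble, reference: ConformationEnsemble
) -> EvaluationReport:
    """Best-match (lowest-RMSD) partner in ``reference`` for every test
    conformation, and the average of those minima.

    Exhaustive over all test x reference pairs; ties broken by the lowest
    reference index.
    """
    if test.n_atoms != reference.n_atoms or not (test.atoms == reference.atoms):
        raise ValueError("test and reference ensembles have different atoms")
    if test.n_frames < 1 or reference.n_frames < 1:
        raise ValueError("both ensembles must be non-empty")
    mat = rmsd_matrix(test.coordinates, reference.coordinates)
    match_idx = mat.argmin(axis=1)  # argmin takes the first (lowest) index on ties
    minima = mat[np.arange(test.n_frames), match_idx]
    per_conf = [(int(i), int(match_idx[i]), float(minima[i])) for i in range(test.n_frames)]
    return EvaluationReport(
        best_match_mean=float(minima.mean()),
        best_match_per_conformation=per_conf,
        metadata={"n_test": test.n_frames, "n_reference": reference.n_frames},
    )


def pairwise_diversity(ensemble: ConformationEnsemble) -> float:
    """Mean minimal RMSD over all K(K-1)/2 distinct pairs within a set."""
    k = ensemble.n_frames
    if k < 2:
        raise ValueError("need at least two conformations")
    mat = rmsd_matrix(ensemble.coordinates, ensemble.coordinates)
    iu = np.triu_indices(k, 1)
    return float(mat[iu].mean())


def within_set_best_match(ensemble: ConformationEnsemble) -> float:
    """Mean over conformations of the minimal RMSD to any *other* member.

    A self-coverage benchmark: a generated set covers the test set well when
    test-vs-generated best-match RMSDs are comparable to this quantity.
    Always <= pairwise_diversity of the same set.
    """
    k = ensemble.n_frames
    if k < 2:
        raise ValueError("need at least two conformations")
    mat = rmsd_matrix(ensemble.coordinates, ensemble.coordinates)
    np.fill_diagonal(mat, np.inf)
    return float(mat.min(axis=1).mean())


# ---------------------------------------------------------------------------
# Generic series metrics
# ---------------------------------------------------------------------------

def mape(observed, expected) -> float:
    """Mean absolute percentage error, <|O - E| / E> * 100."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape:
        raise ValueError("series length mismatch")
    if np.any(e == 0):
        raise ValueError("expected values must be nonzero for MAPE")
    return float(np.mean(np.abs(o - e) / np.abs(e)) * 100.0)


def rmse(observed, expected) -> float:
    """Root-mean-square error, sqrt(<(O - E)^2>)."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape:
        raise ValueError("series length mismatch")
    return float(np.sqrt(np.mean((o - e) ** 2)))


# ---------------------------------------------------------------------------
# Geometry checking
# ---------------------------------------------------------------------------

def geometry_check(
    coordinates: np.ndarray,
    atoms,
    bond_tol: float = 0.15,
    angle_tol: float = 15.0,
) -> GeometryReport:
    """Flag bonds and angles deviating from ideal residue-template geometry.

    Decoded conformations are raw network output and can carry sizeable
    bond-length and bond-angle distortions; this reports them (no refinement
    is attempted).  Bonds deviating more than ``bond_tol`` as a fraction of
    the ideal length, and angles more than ``angle_tol`` degrees from ideal,
    are listed.  Residues matching no template are skipped with a warning.
    """
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coordinates must be a single (N, 3) conformation")
    bonds, angles, skipped = internal_terms(atoms)
    if skipped:
        warnings.warn(f"unknown residues skipped in geometry check: {sorted(set(skipped))}")
    bond_viol = []
    for i, j, ideal in bonds:
        length = float(np.linalg.norm(coords[i] - coords[j]))
        if abs(length - ideal) > bond_tol * ideal:
            bond_viol.append((i, j, length, ideal))
    angle_viol = []
    for i, j, k, ideal in angles:
        u = coords[i] - coords[j]
        v = coords[k] - coords[j]
        cosang = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
        ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        if abs(ang - ideal) > angle_tol:
            angle_viol.append((i, j, k, ang, ideal))
    return GeometryReport(
        bond_violations=bond_viol,
        angle_violations=angle_viol,
        bond_tol=bond_tol,
        angle_tol=angle_tol,
        n_bonds_checked=len(bonds),
        n_angles_checked=len(angles),
    )
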