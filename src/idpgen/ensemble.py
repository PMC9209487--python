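"""Conformational ensembles: containers, I/O, preprocessing and splitting.

An ensemble is a stack of conformations (frames) of the same molecule,
stored as an ``(n_frames, n_atoms, 3)`` coordinate array in Angstroms plus a
per-atom table (residue index, residue name, atom name).  The preprocessing
chain used before autoencoder training is:

1. select heavy atoms (all backbone plus the CB/CG/CD/OE1/NE2 side-chain set),
2. superpose every frame on a reference frame (minimum-RMSD rigid fit),
3. shift coordinates to be non-negative and divide by the maximum value so
   that every training coordinate lies in [0, 1].

The shift and scale are fit on the training portion only and reused verbatim
for test and generated coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from biotite.structure import AtomArrayStack, array as _atom_array
from biotite.structure import Atom as _Atom
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomTable",
    "ConformationEnsemble",
    "ScalingTransform",
    "SplitSpec",
    "load_ensemble",
    "write_ensemble",
    "select_heavy_atoms",
    "align_frames",
    "fit_scaling",
    "split_trajectory",
    "dilute",
    "kabsch_rotation",
]

#: Side-chain heavy-atom names retained by the reduced representation.
SIDECHAIN_KEEP = frozenset({"CB", "CG", "CD", "OE1", "NE2"})

#: Backbone heavy atoms of a standard amino-acid residue.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

#: Heavy atoms of the acetyl / N-methylamide capping groups, treated as backbone.
CAP_RESIDUES = {"ACE": frozenset({"CH3", "C", "O"}), "NME": frozenset({"N", "CH3"})}


class EnsembleFormatError(ValueError):
    """Raised for structurally inconsistent ensemble files."""


@dataclass(frozen=True)
class AtomTable:
    """Per-atom metadata shared by every frame of an ensemble."""

    residue_index: np.ndarray  # 1-based int
    residue_name: np.ndarray  # str
    atom_name: np.ndarray  # str

    def __post_init__(self):
        object.__setattr__(self, "residue_index", np.asarray(self.residue_index, dtype=int))
        object.__setattr__(self, "residue_name", np.asarray(self.residue_name, dtype="U4"))
        object.__setattr__(self, "atom_name", np.asarray(self.atom_name, dtype="U4"))
        n = len(self.residue_index)
        if not (len(self.residue_name) == len(self.atom_name) == n):
            raise ValueError("atom table columns have unequal lengths")

    def __len__(self) -> int:
        return len(self.residue_index)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AtomTable):
            return NotImplemented
        return (
            np.array_equal(self.residue_index, other.residue_index)
            and np.array_equal(self.residue_name, other.residue_name)
            and np.array_equal(self.atom_name, other.atom_name)
        )

    def subset(self, mask: np.ndarray) -> "AtomTable":
        return AtomTable(
            self.residue_index[mask], self.residue_name[mask], self.atom_name[mask]
        )


@dataclass
class ConformationEnsemble:
    """A set of conformations of one molecule.

    Parameters
    ----------
    coordinates : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in Angstroms.
    atoms : AtomTable
        Atom metadata, identical across frames.
    source_label : str
        Identifier of the originating run (useful when pooling).
    """

    coordinates: np.ndarray
    atoms: AtomTable
    source_label: str = ""
    frame_sources: np.ndarray | None = None  # per-frame run labels (pooled sets)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.n_frames < 1:
            raise ValueError("ensemble must contain at least one frame")
        if self.coordinates.shape[1] != len(self.atoms):
            raise ValueError(
                f"atom table length ({len(self.atoms)}) does not match "
                f"coordinate atom count ({self.coordinates.shape[1]})"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")
        if self.frame_sources is not None:
            self.frame_sources = np.asarray(self.frame_sources)
            if len(self.frame_sources) != self.n_frames:
                raise ValueError("frame_sources length must equal n_frames")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def with_coordinates(self, coords: np.ndarray) -> "ConformationEnsemble":
        return ConformationEnsemble(coords, self.atoms, self.source_label)

    def frames(self, indices) -> "ConformationEnsemble":
        sources = None if self.frame_sources is None else self.frame_sources[indices]
        return ConformationEnsemble(
            self.coordinates[indices], self.atoms, self.source_label, sources
        )

    def flat(self) -> np.ndarray:
        """Frame-major view of shape (n_frames, 3 * n_atoms)."""
        return self.coordinates.reshape(self.n_frames, -1)


@dataclass(frozen=True)
class ScalingTransform:
    """Affine map between real coordinates and the unit interval.

    ``scaled = (x + shift) / scale`` with a single scalar shift (minus the
    minimum training coordinate over all axes and frames) and a single scalar
    scale (the maximum shifted training coordinate), so every training value
    lies in [0, 1].  Test or generated coordinates outside the training range
    map outside [0, 1]; that is allowed.
    """

    shift: float
    scale: float
    reference_frame_index: int = 0

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords, dtype=float) + self.shift) / self.scale

    def invert(self, scaled: np.ndarray) -> np.ndarray:
        return np.asarray(scaled, dtype=float) * self.scale - self.shift

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "shift": self.shift,
                    "scale": self.scale,
                    "reference_frame_index": self.reference_frame_index,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "ScalingTransform":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


@dataclass(frozen=True)
class SplitSpec:
    """How to carve a trajectory into burn-in, training and test portions.

    ``burn_in_frames`` are discarded; of the remainder the first
    ``train_fraction`` becomes training data and the rest test data.
    Dilutions (keep every k-th frame) are applied after the split.
    """

    burn_in_frames: int = 0
    train_fraction: float = 0.1
    train_dilution: int = 1
    test_dilution: int = 1

    def __post_init__(self):
        if self.burn_in_frames < 0:
            raise ValueError("burn_in_frames must be >= 0")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.train_dilution < 1 or self.test_dilution < 1:
            raise ValueError("dilution factors must be >= 1")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_ensemble(path, fmt: str = "pdb", source_label: str | None = None) -> ConformationEnsemble:
    """Read an ensemble from a multi-model PDB file or a frame-major table.

    The table format has comment lines ``# atom <residue_index> <residue_name>
    <atom_name>`` followed by one whitespace-separated row of 3N coordinates
    per frame.
    """
    label = source_label if source_label is not None else str(path)
    if fmt == "pdb":
        return _load_pdb(path, label)
    if fmt == "table":
        return _load_table(path, label)
    raise ValueError(f"unknown format {fmt!r}")


def _load_pdb(path, label: str) -> ConformationEnsemble:
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises on per-model atom-count mismatch
        raise EnsembleFormatError(f"inconsistent or unreadable PDB models: {exc}") from exc
    if not isinstance(stack, AtomArrayStack):
        stack = stack[np.newaxis]
    atoms = AtomTable(stack.res_id, stack.res_name, stack.atom_name)
    return ConformationEnsemble(np.asarray(stack.coord, dtype=float), atoms, label)


def _load_table(path, label: str) -> ConformationEnsemble:
    res_idx, res_name, atom_name = [], [], []
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "atom":
                    res_idx.append(int(parts[1]))
                    res_name.append(parts[2])
                    atom_name.append(parts[3])
                continue
            try:
                rows.append(np.array(line.split(), dtype=float))
            except ValueError as exc:
                raise EnsembleFormatError(f"unreadable coordinate row: {exc}") from exc
    if not rows:
        raise EnsembleFormatError("table contains no coordinate rows")
    n_atoms = len(res_idx)
    coords = np.vstack(rows)
    if coords.shape[1] != 3 * n_atoms:
        raise EnsembleFormatError(
            f"rows have {coords.shape[1]} columns, expected {3 * n_atoms}"
        )
    atoms = AtomTable(res_idx, res_name, atom_name)
    return ConformationEnsemble(coords.reshape(len(rows), n_atoms, 3), atoms, label)


def write_ensemble(ensemble: ConformationEnsemble, path, fmt: str = "pdb") -> None:
    """Write an ensemble as a multi-model PDB or a frame-major table.

    PDB output is lossless to the format's 1e-3 A coordinate precision.
    """
    if ensemble.n_frames < 1:
        raise ValueError("cannot write an empty ensemble")
    if fmt == "pdb":
        _write_pdb(ensemble, path)
    elif fmt == "table":
        _write_table(ensemble, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _write_pdb(ensemble: ConformationEnsemble, path) -> None:
    t = ensemble.atoms
    template = _atom_array(
        [
            _Atom(
                [0.0, 0.0, 0.0],
                chain_id="A",
                res_id=int(t.residue_index[i]),
                res_name=str(t.residue_name[i]),
                atom_name=str(t.atom_name[i]),
                element=_guess_element(str(t.atom_name[i])),
                hetero=str(t.residue_name[i]) in CAP_RESIDUES,
            )
            for i in range(len(t))
        ]
    )
    stack = AtomArrayStack(ensemble.n_frames, len(t))
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = np.asarray(ensemble.coordinates, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def _guess_element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch
    return "C"


def _write_table(ensemble: ConformationEnsemble, path) -> None:
    t = ensemble.atoms
    with open(path, "w") as fh:
        for i in range(len(t)):
            fh.write(f"# atom {t.residue_index[i]} {t.residue_name[i]} {t.atom_name[i]}\n")
        np.savetxt(fh, ensemble.flat(), fmt="%.6f")


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

def heavy_atom_mask(atoms: AtomTable) -> np.ndarray:
    """Boolean mask of the reduced heavy-atom representation.

    Keeps every backbone heavy atom (N, CA, C, O and terminal OXT), the heavy
    atoms of ACE/NME capping groups, and side-chain atoms named CB, CG, CD,
    OE1 or NE2.  Hydrogens and other side-chain heavy atoms are dropped,
    truncating long side chains.
    """
    mask = np.zeros(len(atoms), dtype=bool)
    for i in range(len(atoms)):
        res = str(atoms.residue_name[i])
        name = str(atoms.atom_name[i])
        if name.startswith("H") or name.startswith(("1H", "2H", "3H")):
            continue
        if res in CAP_RESIDUES:
            mask[i] = name in CAP_RESIDUES[res]
        else:
            mask[i] = name in BACKBONE_NAMES or name in SIDECHAIN_KEEP
    return mask


def select_heavy_atoms(ensemble: ConformationEnsemble) -> ConformationEnsemble:
    """Restrict an ensemble to the reduced heavy-atom representation."""
    mask = heavy_atom_mask(ensemble.atoms)
    if not mask.any():
        raise ValueError("heavy-atom selection is empty")
    return ConformationEnsemble(
        ensemble.coordinates[:, mask, :], ensemble.atoms.subset(mask), ensemble.source_label
    )


# ---------------------------------------------------------------------------
# Superposition / alignment
# ---------------------------------------------------------------------------

def kabsch_rotation(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix superposing centered ``moving`` onto centered
    ``target`` (Kabsch algorithm via SVD, with the reflection guard).

    Falls back to the identity when the covariance is numerically degenerate
    (e.g. all-collinear coordinates).
    """
    h = moving.T @ target
    try:
        u, s, vt = np.linalg.svd(h)
    except np.linalg.LinAlgError:
        return np.eye(3)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        # rank <= 1 covariance (collinear coordinates): rotation ill-determined
        return np.eye(3)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def align_frames(ensemble: ConformationEnsemble, reference_index: int = 0) -> ConformationEnsemble:
    """Superpose every frame on the reference frame by minimum-RMSD rigid fit.

    The reference frame itself is returned unchanged.
    """
    coords = ensemble.coordinates
    ref = coords[reference_index]
    ref_center = ref.mean(axis=0)
    ref_c = ref - ref_center
    out = np.empty_like(coords)
    for k in range(ensemble.n_frames):
        if k == reference_index:
            out[k] = ref
            continue
        frame = coords[k]
        frame_c = frame - frame.mean(axis=0)
        rot = kabsch_rotation(frame_c, ref_c)
        out[k] = frame_c @ rot.T + ref_center
    return ensemble.with_coordinates(out)


# ---------------------------------------------------------------------------
# Scaling, split, dilution
# ---------------------------------------------------------------------------

def fit_scaling(ensemble: ConformationEnsemble, reference_frame_index: int = 0) -> ScalingTransform:
    """Fit the shift-and-scale map on (training) coordinates.

    Shift is minus the global minimum coordinate; scale is the maximum shifted
    value, so training coordinates map into [0, 1].
    """
    cmin = float(ensemble.coordinates.min())
    cmax = float(ensemble.coordinates.max())
    span = cmax - cmin
    if span <= 0:
        raise ValueError("zero coordinate range; cannot fit scaling")
    return ScalingTransform(shift=-cmin, scale=span, reference_frame_index=reference_frame_index)


def split_trajectory(
    ensemble: ConformationEnsemble, spec: SplitSpec
) -> tuple[ConformationEnsemble, ConformationEnsemble]:
    """Discard burn-in, split the remainder into training and test portions,
    then apply the per-portion dilutions.

    Returns ``(train, test)``.  Before dilution the frame counts satisfy
    ``burn_in + n_train + n_test == n_frames``.
    """
    n = ensemble.n_frames
    if spec.burn_in_frames + 1 >= n:
        raise ValueError("burn-in leaves fewer than two frames")
    remaining = n - spec.burn_in_frames
    n_train = int(np.floor(spec.train_fraction * remaining))
    n_test = remaining - n_train
    if n_train < 1 or n_test < 1:
        raise ValueError("split produces an empty training or test set")
    start = spec.burn_in_frames
    train = ensemble.frames(slice(start, start + n_train))
    test = ensemble.frames(slice(start + n_train, n))
    return dilute(train, spec.train_dilution), dilute(test, spec.test_dilution)


def dilute(ensemble: ConformationEnsemble, factor: int) -> ConformationEnsemble:
    """Keep every ``factor``-th frame starting at index 0."""
    if factor < 1:
        raise ValueError("dilution factor must be >= 1")
    if factor == 1:
        return ensemble
    return ensemble.frames(slice(None, None, factor))
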