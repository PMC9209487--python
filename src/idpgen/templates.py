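"""Ideal residue geometry: bond/angle templates and coordinate placement.

One table of ideal bond lengths and angles serves two purposes: the geometry
checker flags deviations from it in decoded conformations, and the synthetic
chain builder constructs template conformations that satisfy it exactly.
Values are conventional amino-acid equilibrium geometries (Engh/Huber-style);
side chains are restricted to the CB/CG/CD/OE1/NE2 stubs of the reduced
heavy-atom representation.  ACE (CH3, C, O) and NME (N, CH3) caps are
treated as backbone.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BOND_IDEALS", "ANGLE_IDEALS", "internal_terms", "place_nerf", "place_two_angles"]

# Intra-residue bonds (atom name pairs) for amino-acid-like residues.
_AA_BONDS = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "O"): 1.229,
    ("CA", "CB"): 1.530,
    ("CB", "CG"): 1.520,
    ("CG", "CD"): 1.520,
    ("CD", "OE1"): 1.229,
    ("CD", "NE2"): 1.328,
}
_ACE_BONDS = {("CH3", "C"): 1.508, ("C", "O"): 1.229}
_NME_BONDS = {("N", "CH3"): 1.455}
#: Peptide bond between consecutive residues (previous C to next N).
PEPTIDE_BOND = 1.329

BOND_IDEALS = {"AA": _AA_BONDS, "ACE": _ACE_BONDS, "NME": _NME_BONDS}

# Intra-residue angles, degrees.  The three angles around a planar center
# always sum to 360 so that templates built from them are self-consistent.
_AA_ANGLES = {
    ("N", "CA", "C"): 111.0,
    ("CA", "C", "O"): 120.8,
    ("N", "CA", "CB"): 110.5,
    ("CB", "CA", "C"): 110.1,
    ("CA", "CB", "CG"): 114.1,
    ("CB", "CG", "CD"): 112.6,
    ("CG", "CD", "OE1"): 120.8,
    ("CG", "CD", "NE2"): 116.4,
    ("OE1", "CD", "NE2"): 122.8,
}
_ACE_ANGLES = {("CH3", "C", "O"): 120.8}
# Cross-residue angles: (prev-residue atom | atoms)  handled in internal_terms.
ANGLE_CA_C_N = 116.2  # CA(i)-C(i)-N(i+1)
ANGLE_O_C_N = 123.0  # O(i)-C(i)-N(i+1); 360 - 120.8 - 116.2
ANGLE_C_N_CA = 121.7  # C(i-1)-N(i)-CA(i), also C(i-1)-N-CH3 for NME

ANGLE_IDEALS = {"AA": _AA_ANGLES, "ACE": _ACE_ANGLES}


def _residue_groups(atoms) -> list[tuple[int, str, dict[str, int]]]:
    """Group an AtomTable into (residue_index, residue_name, name->atom index)."""
    groups: list[tuple[int, str, dict[str, int]]] = []
    current = None
    for i in range(len(atoms)):
        rid = int(atoms.residue_index[i])
        rname = str(atoms.residue_name[i])
        if current is None or current[0] != rid:
            current = (rid, rname, {})
            groups.append(current)
        current[2][str(atoms.atom_name[i])] = i
    return groups


def internal_terms(atoms):
    """Bond and angle terms implied by an atom table.

    Returns ``(bonds, angles, skipped)`` where bonds are ``(i, j, ideal_A)``,
    angles are ``(i, j, k, ideal_deg)`` with j the vertex, and skipped is the
    list of residue names that matched no template.
    """
    groups = _residue_groups(atoms)
    bonds: list[tuple[int, int, float]] = []
    angles: list[tuple[int, int, int, float]] = []
    skipped: list[str] = []

    def kind(rname: str, names: dict) -> str | None:
        if rname == "ACE":
            return "ACE"
        if rname == "NME":
            return "NME"
        if {"N", "CA", "C"} <= names.keys():
            return "AA"
        return None

    kinds = [kind(rname, names) for _, rname, names in groups]
    for g, (rid, rname, names) in enumerate(groups):
        k = kinds[g]
        if k is None:
            skipped.append(rname)
            continue
        for (a, b), ideal in BOND_IDEALS[k].items():
            if a in names and b in names:
                bonds.append((names[a], names[b], ideal))
        for (a, b, c), ideal in ANGLE_IDEALS.get(k, {}).items():
            if a in names and b in names and c in names:
                angles.append((names[a], names[b], names[c], ideal))

    # peptide links between consecutive template-known residues
    for g in range(len(groups) - 1):
        if kinds[g] is None or kinds[g + 1] is None:
            continue
        prev_names, next_names = groups[g][2], groups[g + 1][2]
        c_prev = prev_names.get("C")
        n_next = next_names.get("N")
        if c_prev is None or n_next is None:
            continue
        bonds.append((c_prev, n_next, PEPTIDE_BOND))
        if "CA" in prev_names:
            angles.append((prev_names["CA"], c_prev, n_next, ANGLE_CA_C_N))
        elif "CH3" in prev_names:  # ACE
            angles.append((prev_names["CH3"], c_prev, n_next, ANGLE_CA_C_N))
        if "O" in prev_names:
            angles.append((prev_names["O"], c_prev, n_next, ANGLE_O_C_N))
        follower = next_names.get("CA", next_names.get("CH3"))
        if follower is not None:
            angles.append((c_prev, n_next, follower, ANGLE_C_N_CA))
    return bonds, angles, skipped


# ---------------------------------------------------------------------------
# Placement primitives for building template conformations
# ---------------------------------------------------------------------------

def place_nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given chain A-B-C, the C-D bond length, the B-C-D angle
    and the A-B-C-D torsion (natural-extension reference frame)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion), np.sin(angle) * np.sin(torsion)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def place_two_angles(
    center: np.ndarray,
    u_atom: np.ndarray,
    v_atom: np.ndarray,
    bond: float,
    angle_u_deg: float,
    angle_v_deg: float,
    sign: float = 1.0,
) -> np.ndarray:
    """Place an atom at distance ``bond`` from ``center`` forming exact angles
    with the directions to ``u_atom`` and ``v_atom``.

    When the three angles around the center sum to 360 deg the solution is
    coplanar; otherwise ``sign`` selects one of the two mirror positions.
    """
    u = u_atom - center
    u /= np.linalg.norm(u)
    v = v_atom - center
    v /= np.linalg.norm(v)
    cu = np.cos(np.deg2rad(angle_u_deg))
    cv = np.cos(np.deg2rad(angle_v_deg))
    uv = float(u @ v)
    det = 1.0 - uv**2
    if det < 1e-12:
        raise ValueError("reference directions are collinear")
    a = (cu - cv * uv) / det
    b = (cv - cu * uv) / det
    c2 = 1.0 - (a**2 + b**2 + 2.0 * a * b * uv)
    c = np.sqrt(max(c2, 0.0))
    n = np.cross(u, v)
    n /= np.linalg.norm(n)
    w = a * u + b * v + sign * c * n
    w /= np.linalg.norm(w)
    return center + bond * w
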