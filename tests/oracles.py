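"""Independent reference implementations used only to check the package.

The superposition oracle uses Horn's quaternion method (largest eigenvalue
of the 4x4 key matrix), a different algorithm from the SVD-based Kabsch
solution in the package.
"""

import numpy as np


def quaternion_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal RMSD between two conformations via Horn's quaternion method."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.shape[0]
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    m = ac.T @ bc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(key)[-1]
    sq = ((ac**2).sum() + (bc**2).sum() - 2.0 * lam) / n
    return float(np.sqrt(max(sq, 0.0)))


def gaussian_kl_closed_form(mu_p, cov_p, mu_q, cov_q) -> float:
    """KL divergence between two multivariate normals, closed form."""
    mu_p = np.asarray(mu_p, dtype=float)
    mu_q = np.asarray(mu_q, dtype=float)
    cov_p = np.asarray(cov_p, dtype=float)
    cov_q = np.asarray(cov_q, dtype=float)
    n = mu_p.size
    inv_q = np.linalg.inv(cov_q)
    diff = mu_q - mu_p
    return 0.5 * float(
        np.trace(inv_q @ cov_p)
        + diff @ inv_q @ diff
        - n
        + np.log(np.linalg.det(cov_q) / np.linalg.det(cov_p))
    )
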