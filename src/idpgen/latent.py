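"""Multivariate Gaussian modelling of the latent space.

Training conformations are encoded into latent vectors z; their population
mean mu_l = <z_l> and covariance sigma_lm = <(z_l - mu_l)(z_m - mu_m)> define
a multivariate normal from which new latent vectors are drawn and decoded.
Because the latent layer is rectified-linear, a sizeable fraction of latent
dimensions is typically dead (identically zero across the data); the
covariance is then singular, and sampling uses the eigendecomposition with
negative eigenvalues clipped to zero, which pins dead dimensions exactly at
their (zero) mean.

Latent distributions are compared through 2-D histograms on a shared grid
and the discrete Kullback-Leibler divergence

    D_KL(p|q) = sum_bins p * ln(p / q)

where any bin with p = 0 or q = 0 contributes nothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture as _SkGaussianMixture

__all__ = [
    "LatentSet",
    "GaussianLatentModel",
    "Histogram2D",
    "fit_gaussian",
    "sample_gaussian",
    "active_dimensions",
    "gaussian_density",
    "histogram2d",
    "shared_edges",
    "kl_divergence",
    "GaussianMixtureLatentModel",
    "fit_gaussian_mixture",
]


@dataclass
class LatentSet:
    """A batch of latent vectors with a provenance label."""

    vectors: np.ndarray  # (K, n)
    label: str = "train"

    def __post_init__(self):
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.vectors.shape[0] < 1:
            raise ValueError("latent set must contain at least one vector")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("latent vectors contain non-finite values")

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass
class GaussianLatentModel:
    """Mean vector and (possibly singular) covariance of training latents."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.covariance = np.asarray(self.covariance, dtype=float)
        n = self.mean.size
        if self.covariance.shape != (n, n):
            raise ValueError("covariance shape does not match mean dimension")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance is not symmetric")
        evals = np.linalg.eigvalsh(self.covariance)
        if evals.min() < -1e-8:
            raise ValueError(f"covariance has eigenvalue {evals.min():.3e} < -1e-8")

    @property
    def dim(self) -> int:
        return self.mean.size

    def to_json(self, path, provenance: str = "") -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "dim": self.dim,
                    "mean": self.mean.tolist(),
                    "covariance": self.covariance.tolist(),
                    "provenance": provenance,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "GaussianLatentModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(mean=np.array(d["mean"]), covariance=np.array(d["covariance"]))


def fit_gaussian(latent: LatentSet | np.ndarray) -> GaussianLatentModel:
    """Population (1/K) mean and covariance of a latent set; requires K >= 2."""
    vectors = latent.vectors if isinstance(latent, LatentSet) else np.atleast_2d(latent)
    if vectors.shape[0] < 2:
        raise ValueError("need at least two latent vectors to fit a Gaussian")
    mean = vectors.mean(axis=0)
    dev = vectors - mean
    cov = dev.T @ dev / vectors.shape[0]
    cov = (cov + cov.T) / 2.0
    return GaussianLatentModel(mean=mean, covariance=cov)


def sample_gaussian(model: GaussianLatentModel, m: int, seed: int) -> LatentSet:
    """Draw ``m`` latent vectors from the fitted Gaussian, reproducibly.

    Sampling goes through the eigendecomposition; eigenvalues in [-1e-8, 0)
    are clipped to zero so that degenerate directions (dead ReLU dimensions)
    are sampled exactly at their mean.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    evals, evecs = np.linalg.eigh(model.covariance)
    if evals.min() < -1e-8:
        raise ValueError("covariance is not positive semi-definite")
    evals = np.clip(evals, 0.0, None)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((m, model.dim))
    samples = model.mean + (white * np.sqrt(evals)) @ evecs.T
    return LatentSet(vectors=samples, label="generated")


def active_dimensions(latent: LatentSet | np.ndarray, tol: float = 1e-3) -> list[int]:
    """Indices of latent dimensions that are not uniformly at/near zero.

    A dimension is active when max |z_l| over the set exceeds ``tol``;
    rectified-linear latent units leave roughly half the dimensions dead in
    practice.
    """
    vectors = latent.vectors if isinstance(latent, LatentSet) else np.atleast_2d(latent)
    return [int(i) for i in np.nonzero(np.abs(vectors).max(axis=0) > tol)[0]]


def gaussian_density(
    model: GaussianLatentModel, z: np.ndarray, dims: list[int] | None = None
) -> float:
    """Multivariate normal density at ``z``.

    With ``dims`` given, the density is evaluated on that subspace (mean and
    covariance restricted to those dimensions) — the usual way to handle a
    covariance that is singular because of dead latent dimensions.  A
    singular covariance without such a restriction is an error.
    """
    z = np.asarray(z, dtype=float).ravel()
    if dims is not None:
        idx = np.asarray(dims, dtype=int)
        mean = model.mean[idx]
        cov = model.covariance[np.ix_(idx, idx)]
        z = z[idx] if z.size == model.dim else z
    else:
        mean, cov = model.mean, model.covariance
    n = mean.size
    if z.size != n:
        raise ValueError(f"expected vector of dim {n}, got {z.size}")
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ValueError("covariance is singular on the requested subspace")
    diff = z - mean
    expo = -0.5 * diff @ np.linalg.solve(cov, diff)
    lognorm = -0.5 * (n * np.log(2.0 * np.pi) + logdet)
    return float(np.exp(lognorm + expo))


# ---------------------------------------------------------------------------
# 2-D histograms and KL divergence
# ---------------------------------------------------------------------------

@dataclass
class Histogram2D:
    """2-D histogram of a latent-dimension pair on an explicit grid."""

    dims: tuple[int, int]
    edges: tuple[np.ndarray, np.ndarray]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.edges[0]) - 1, len(self.edges[1]) - 1):
            raise ValueError("counts shape inconsistent with bin edges")

    @property
    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("histogram is empty")
        return self.counts / total

    def same_grid(self, other: "Histogram2D") -> bool:
        return (
            self.counts.shape == other.counts.shape
            and np.allclose(self.edges[0], other.edges[0])
            and np.allclose(self.edges[1], other.edges[1])
        )

    def to_tsv(self, path) -> None:
        np.savetxt(path, self.counts, delimiter="\t", fmt="%g")


def shared_edges(
    sets: list[LatentSet], pair: tuple[int, int], bins: int = 50, pad: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Common bin edges spanning the union of the sets' ranges, padded 1%."""
    l, m = pair
    edges = []
    for axis_dim in (l, m):
        vals = np.concatenate([s.vectors[:, axis_dim] for s in sets])
        lo, hi = vals.min(), vals.max()
        span = hi - lo if hi > lo else max(abs(hi), 1.0)
        edges.append(np.linspace(lo - pad * span, hi + pad * span, bins + 1))
    return edges[0], edges[1]


def histogram2d(
    latent: LatentSet,
    pair: tuple[int, int],
    bins: int = 50,
    range_: tuple[np.ndarray, np.ndarray] | None = None,
) -> Histogram2D:
    """Histogram of a latent set over dimensions ``pair = (l, m)``.

    When comparing distributions, pass the same explicit edges (from
    ``shared_edges``) for every set.
    """
    l, m = pair
    if l == m:
        raise ValueError("histogram pair must be two distinct dimensions")
    if latent.n_vectors < 1:
        raise ValueError("cannot histogram an empty latent set")
    x = latent.vectors[:, l]
    y = latent.vectors[:, m]
    if range_ is None:
        ex, ey = shared_edges([latent], pair, bins)
    else:
        ex, ey = range_
    counts, ex, ey = np.histogram2d(x, y, bins=[ex, ey])
    return Histogram2D(dims=(l, m), edges=(ex, ey), counts=counts.astype(int))


def kl_divergence(p: Histogram2D, q: Histogram2D) -> float:
    """Discrete KL divergence between two normalized histograms.

    Grids must match exactly.  Bins where either distribution is zero
    contribute nothing (the zero-bin rule), so disjoint supports give 0;
    the value is therefore not guaranteed non-negative for distant
    distributions, but is exactly 0 for p = q.
    """
    if not p.same_grid(q):
        raise ValueError("histograms are on different grids")
    pn = p.normalized
    qn = q.normalized
    mask = (pn > 0) & (qn > 0)
    if not mask.any():
        return 0.0
    return float(np.sum(pn[mask] * np.log(pn[mask] / qn[mask])))


# ---------------------------------------------------------------------------
# Optional: mixture of Gaussians in latent space
# ---------------------------------------------------------------------------

@dataclass
class GaussianMixtureLatentModel:
    """Weighted mixture of Gaussian latent models."""

    weights: np.ndarray
    components: list[GaussianLatentModel]
    converged: bool = True

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-12):
            raise ValueError("mixture weights must sum to 1")

    def sample(self, m: int, seed: int) -> LatentSet:
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(m, self.weights)
        parts = []
        for k, (cnt, comp) in enumerate(zip(counts, self.components)):
            if cnt > 0:
                sub_seed = int(rng.integers(0, 2**31 - 1))
                parts.append(sample_gaussian(comp, cnt, sub_seed).vectors)
        return LatentSet(np.vstack(parts), label="generated")


def fit_gaussian_mixture(
    latent: LatentSet, k: int, seed: int, max_iter: int = 200, tol: float = 1e-6
) -> GaussianMixtureLatentModel:
    """Fit a k-component Gaussian mixture to a latent set by EM.

    Uses expectation-maximisation with k-means initialisation (via
    scikit-learn); k = 1 reduces to the single-Gaussian moment fit.  If EM
    does not converge within ``max_iter`` iterations the best model found is
    returned with ``converged=False``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if latent.n_vectors < k:
        raise ValueError("need at least k latent vectors")
    gm = _SkGaussianMixture(
        n_components=k,
        covariance_type="full",
        max_iter=max_iter,
        tol=tol,
        reg_covar=1e-10,
        init_params="k-means++",
        random_state=seed % (2**31 - 1),
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence surfaced via the flag
        gm.fit(latent.vectors)
    comps = [
        GaussianLatentModel(mean=gm.means_[i], covariance=_symmetrize(gm.covariances_[i]))
        for i in range(k)
    ]
    return GaussianMixtureLatentModel(
        weights=gm.weights_ / gm.weights_.sum(), components=comps, converged=bool(gm.converged_)
    )


def _symmetrize(cov: np.ndarray) -> np.ndarray:
    return (cov + cov.T) / 2.0
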