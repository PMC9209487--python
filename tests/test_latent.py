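"""Gaussian latent model: fitting, sampling, histograms, KL, mixtures."""

import numpy as np
import pytest
from scipy import stats

import idpgen as ig
import idpgen.autoencoder as ae
from idpgen.latent import (
    GaussianLatentModel,
    Histogram2D,
    LatentSet,
    active_dimensions,
    fit_gaussian,
    fit_gaussian_mixture,
    gaussian_density,
    histogram2d,
    kl_divergence,
    sample_gaussian,
    shared_edges,
)

from oracles import gaussian_kl_closed_form


# ---------------------------------------------------------------------------
# Moment fitting
# ---------------------------------------------------------------------------

def test_fit_gaussian_two_point_example():
    model = fit_gaussian(LatentSet(np.array([[0.0, 0.0], [2.0, 2.0]])))
    np.testing.assert_allclose(model.mean, [1.0, 1.0])
    np.testing.assert_allclose(model.covariance, [[1.0, 1.0], [1.0, 1.0]])


def test_fit_gaussian_identical_vectors_gives_zero_covariance():
    model = fit_gaussian(LatentSet(np.tile([3.0, -1.0, 2.0], (10, 1))))
    np.testing.assert_allclose(model.covariance, np.zeros((3, 3)), atol=1e-12)


def test_fit_gaussian_needs_two_vectors():
    with pytest.raises(ValueError):
        fit_gaussian(LatentSet(np.array([[1.0, 2.0]])))


def test_fit_uses_population_normalization():
    vectors = np.array([[0.0], [1.0], [2.0]])
    model = fit_gaussian(LatentSet(vectors))
    assert model.covariance[0, 0] == pytest.approx(np.var(vectors))  # 1/K, not 1/(K-1)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def test_zero_covariance_samples_equal_mean():
    model = GaussianLatentModel(mean=[1.5, -2.0], covariance=np.zeros((2, 2)))
    s = sample_gaussian(model, 7, seed=0)
    np.testing.assert_allclose(s.vectors, np.tile([1.5, -2.0], (7, 1)))


def test_sampling_is_seed_reproducible():
    model = GaussianLatentModel(mean=[0.0, 1.0], covariance=np.eye(2))
    np.testing.assert_array_equal(
        sample_gaussian(model, 100, seed=3).vectors,
        sample_gaussian(model, 100, seed=3).vectors,
    )


def test_sample_moments_converge():
    cov = np.array([[2.0, 0.6], [0.6, 1.0]])
    model = GaussianLatentModel(mean=[1.0, -1.0], covariance=cov)
    s = sample_gaussian(model, 20_000, seed=5)
    se = np.sqrt(np.diag(cov) / 20_000)
    assert np.all(np.abs(s.vectors.mean(axis=0) - model.mean) < 4 * se)
    refit = fit_gaussian(s)
    np.testing.assert_allclose(refit.covariance, cov, rtol=0.05)


def test_dead_dimensions_sampled_exactly_at_zero_mean():
    # dimension 1 is dead (zero mean, zero variance), as after a dead ReLU unit
    cov = np.diag([1.0, 0.0, 0.5])
    model = GaussianLatentModel(mean=[0.3, 0.0, -0.2], covariance=cov)
    s = sample_gaussian(model, 500, seed=11)
    assert np.abs(s.vectors[:, 1]).max() < 1e-12


# ---------------------------------------------------------------------------
# Active dimensions
# ---------------------------------------------------------------------------

def test_active_dimensions_thresholding():
    vectors = np.zeros((100, 4))
    vectors[:, 0] = 1.0
    vectors[:, 2] = 5e-4  # below the 1e-3 default tolerance
    assert active_dimensions(LatentSet(vectors)) == [0]
    assert active_dimensions(LatentSet(np.zeros((10, 3)))) == []


def test_trained_encoder_leaves_some_dimensions_dead(default_pipeline):
    """Rectified-linear latent units leave a sizeable fraction of the latent
    space at exactly zero on real training data."""
    res = default_pipeline
    z = ae.encode(res.model, res.scaling.apply(res.train.flat()))
    active = active_dimensions(LatentSet(z))
    assert 1 <= len(active) < z.shape[1]


# ---------------------------------------------------------------------------
# Density
# ---------------------------------------------------------------------------

def test_density_closed_form_at_mean():
    model = GaussianLatentModel(mean=[0.0, 0.0], covariance=np.eye(2))
    assert gaussian_density(model, [0.0, 0.0]) == pytest.approx(1.0 / (2 * np.pi), rel=1e-12)


def test_density_integrates_to_one():
    cov = np.array([[1.0, 0.3], [0.3, 0.8]])
    model = GaussianLatentModel(mean=[0.5, -0.5], covariance=cov)
    grid = np.linspace(-6, 6, 241)
    step = grid[1] - grid[0]
    xx, yy = np.meshgrid(grid + 0.5, grid - 0.5, indexing="ij")
    vals = np.array(
        [gaussian_density(model, [x, y]) for x, y in zip(xx.ravel(), yy.ravel())]
    )
    assert vals.sum() * step**2 == pytest.approx(1.0, abs=1e-3)


def test_density_mode_is_at_mean():
    rng = np.random.default_rng(4)
    a = rng.normal(size=(3, 3))
    model = GaussianLatentModel(mean=rng.normal(size=3), covariance=a @ a.T + np.eye(3))
    at_mean = gaussian_density(model, model.mean)
    for _ in range(20):
        z = model.mean + rng.normal(size=3)
        assert gaussian_density(model, z) <= at_mean


def test_density_singular_covariance_needs_subspace():
    cov = np.diag([1.0, 0.0])
    model = GaussianLatentModel(mean=[0.0, 0.0], covariance=cov)
    with pytest.raises(ValueError):
        gaussian_density(model, [0.0, 0.0])
    assert gaussian_density(model, [0.0, 0.0], dims=[0]) == pytest.approx(
        stats.norm.pdf(0.0), rel=1e-9
    )


# ---------------------------------------------------------------------------
# Histograms and KL
# ---------------------------------------------------------------------------

def test_histogram_quadrants_and_total():
    vectors = np.array([[-1.0, -1.0], [-1.0, 1.0], [1.0, -1.0], [1.0, 1.0]])
    edges = (np.array([-2.0, 0.0, 2.0]), np.array([-2.0, 0.0, 2.0]))
    h = histogram2d(LatentSet(vectors), (0, 1), bins=2, range_=edges)
    np.testing.assert_array_equal(h.counts, np.ones((2, 2)))
    assert h.counts.sum() == 4
    assert h.normalized.sum() == pytest.approx(1.0, abs=1e-12)


def test_histogram_mode_is_near_origin_for_standard_normal():
    # near the mode the density is almost flat across bins, so Poisson noise
    # can move the argmax by a bin or two; require the mode within 2 widths
    rng = np.random.default_rng(8)
    h = histogram2d(LatentSet(rng.standard_normal((100_000, 2))), (0, 1), bins=50)
    i, j = np.unravel_index(h.counts.argmax(), h.counts.shape)
    cx = (h.edges[0][i] + h.edges[0][i + 1]) / 2
    cy = (h.edges[1][j] + h.edges[1][j + 1]) / 2
    width = h.edges[0][1] - h.edges[0][0]
    assert abs(cx) < 2 * width and abs(cy) < 2 * width


def test_histogram_same_dimension_pair_rejected():
    with pytest.raises(ValueError):
        histogram2d(LatentSet(np.zeros((5, 3))), (1, 1))


def test_kl_of_identical_histograms_is_exactly_zero():
    rng = np.random.default_rng(9)
    h = histogram2d(LatentSet(rng.standard_normal((500, 2))), (0, 1), bins=20)
    assert kl_divergence(h, h) == 0.0


def test_kl_zero_rule_on_disjoint_supports():
    edges = (np.linspace(0, 4, 5), np.linspace(0, 4, 5))
    left = histogram2d(LatentSet(np.full((10, 2), 0.5)), (0, 1), range_=edges)
    right = histogram2d(LatentSet(np.full((10, 2), 3.5)), (0, 1), range_=edges)
    assert kl_divergence(left, right) == 0.0


def test_kl_mismatched_grids_rejected():
    a = histogram2d(LatentSet(np.random.default_rng(1).normal(size=(50, 2))), (0, 1), bins=10)
    b = histogram2d(LatentSet(np.random.default_rng(2).normal(size=(50, 2))), (0, 1), bins=12)
    with pytest.raises(ValueError):
        kl_divergence(a, b)


def test_kl_matches_gaussian_closed_form():
    """Discretized-Gaussian KL agrees with the analytic value within 5%."""
    mu_p, cov_p = np.zeros(2), np.eye(2)
    mu_q = np.array([0.5, 0.3])
    cov_q = np.array([[1.2, 0.2], [0.2, 0.9]])
    grid = np.linspace(-6.0, 6.0, 201)
    centers = (grid[:-1] + grid[1:]) / 2
    xx, yy = np.meshgrid(centers, centers, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    dens_p = stats.multivariate_normal(mu_p, cov_p).pdf(pts).reshape(200, 200)
    dens_q = stats.multivariate_normal(mu_q, cov_q).pdf(pts).reshape(200, 200)
    hp = Histogram2D(dims=(0, 1), edges=(grid, grid), counts=dens_p)
    hq = Histogram2D(dims=(0, 1), edges=(grid, grid), counts=dens_q)
    expected = gaussian_kl_closed_form(mu_p, cov_p, mu_q, cov_q)
    assert kl_divergence(hp, hq) == pytest.approx(expected, rel=0.05)


def test_shared_edges_cover_both_sets():
    a = LatentSet(np.random.default_rng(3).normal(0, 1, (100, 2)))
    b = LatentSet(np.random.default_rng(4).normal(5, 1, (100, 2)))
    ex, ey = shared_edges([a, b], (0, 1), bins=30)
    allvals = np.vstack([a.vectors, b.vectors])
    assert ex[0] < allvals[:, 0].min() and ex[-1] > allvals[:, 0].max()
    assert ey[0] < allvals[:, 1].min() and ey[-1] > allvals[:, 1].max()


# ---------------------------------------------------------------------------
# Mixture model
# ---------------------------------------------------------------------------

def test_mixture_with_one_component_reduces_to_single_gaussian():
    rng = np.random.default_rng(12)
    latent = LatentSet(rng.normal(size=(400, 3)))
    single = fit_gaussian(latent)
    mix = fit_gaussian_mixture(latent, k=1, seed=0)
    assert mix.weights == pytest.approx([1.0])
    np.testing.assert_allclose(mix.components[0].mean, single.mean, atol=1e-8)
    np.testing.assert_allclose(mix.components[0].covariance, single.covariance, atol=1e-8)


def test_mixture_recovers_two_separated_clusters():
    rng = np.random.default_rng(13)
    a = rng.normal(0.0, 0.3, size=(500, 2))
    b = rng.normal(0.0, 0.3, size=(500, 2)) + [6.0, 6.0]
    mix = fit_gaussian_mixture(LatentSet(np.vstack([a, b])), k=2, seed=1)
    assert mix.weights.sum() == pytest.approx(1.0, abs=1e-12)
    means = sorted(comp.mean[0] for comp in mix.components)
    assert abs(means[0] - 0.0) < 0.1 and abs(means[1] - 6.0) < 0.1


# ---------------------------------------------------------------------------
# Latent coverage of held-out data
# ---------------------------------------------------------------------------

def test_gaussian_covers_test_latents_at_least_as_well_as_training_hull(default_pipeline):
    """Held-out latent vectors fall inside the Gaussian's 99.9% Mahalanobis
    ellipsoid at least as often as inside the convex hull of the training
    latents: the smooth model generalises beyond the raw training cloud."""
    from scipy.optimize import linprog

    res = default_pipeline
    z_train = ae.encode(res.model, res.scaling.apply(res.train.flat()))
    z_test = ae.encode(res.model, res.scaling.apply(ig.dilute(res.test, 10).flat()))
    active = active_dimensions(LatentSet(z_train))
    zt, zs = z_train[:, active], z_test[:, active]
    model = fit_gaussian(LatentSet(zt))
    inv = np.linalg.pinv(model.covariance)
    d2 = np.einsum("ij,jk,ik->i", zs - model.mean, inv, zs - model.mean)
    rate_gauss = float(np.mean(d2 <= stats.chi2.ppf(0.999, df=len(active))))

    def in_hull(points, x):
        n = len(points)
        r = linprog(
            np.zeros(n),
            A_eq=np.vstack([points.T, np.ones(n)]),
            b_eq=np.append(x, 1.0),
            bounds=(0, None),
            method="highs",
        )
        return r.status == 0

    rate_hull = float(np.mean([in_hull(zt, z) for z in zs]))
    assert rate_gauss >= rate_hull
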