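"""Shared fixtures: synthetic runs and trained pipelines.

The expensive objects (the default 5,000-frame fixture run and the pipeline
trained on it) are session-scoped so that coverage, monotonicity and latent
-overlap tests all reuse one training under identical study conditions.
"""

import numpy as np
import pytest

import idpgen as ig
import idpgen.autoencoder as ae


@pytest.fixture(scope="session")
def chain_template():
    """Capped 15-residue glutamine-like chain with exactly ideal geometry."""
    return ig.make_chain_template(15, caps=True, seed=3)


@pytest.fixture(scope="session")
def default_run():
    """The standard acceptance fixture: 5,000 frames, 3 basins, 1.0 A noise,
    2% basin-switch rate."""
    return ig.make_run(ig.default_fixture_spec(seed=11))


@pytest.fixture(scope="session")
def default_pipeline(default_run):
    """Single-run pipeline (10% training, 100 epochs) on the default fixture."""
    config = ig.PipelineConfig(
        split=ig.SplitSpec(train_fraction=0.1),
        training=ae.TrainingConfig(seed=5),
        generated_multiple=1.0,
        eval_dilution=10,
    )
    return ig.run_single(default_run, config)


@pytest.fixture(scope="session")
def small_run():
    """A short 600-frame run for fast pipeline smoke tests."""
    return ig.make_run(ig.FixtureSpec(n_frames=600, seed=17))


@pytest.fixture(scope="session")
def memorized_model(chain_template):
    """Autoencoder trained on a single conformation repeated 400 times."""
    coords = np.repeat(chain_template.coordinates, 400, axis=0)
    ens = ig.ConformationEnsemble(coords, chain_template.atoms)
    scaling = ig.fit_scaling(ens)
    spec = ae.NetworkSpec(input_dim=3 * ens.n_atoms, latent_dim=13)
    model = ae.train(scaling.apply(ens.flat()), spec, ae.TrainingConfig(seed=0))
    return model, scaling, chain_template
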