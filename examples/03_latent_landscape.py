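"""Inspect the latent space: dead ReLU dimensions, the fitted Gaussian, and
2-D histogram comparisons via KL divergence.
"""

import numpy as np

import idpgen as ig
import idpgen.autoencoder as ae
from idpgen.latent import (
    LatentSet, active_dimensions, fit_gaussian, histogram2d, kl_divergence,
    sample_gaussian, shared_edges,
)

run = ig.make_run(ig.FixtureSpec(n_frames=2000, seed=31))
config = ig.PipelineConfig(split=ig.SplitSpec(train_fraction=0.2),
                           training=ae.TrainingConfig(seed=5))
res = ig.run_single(run, config)

z_train = ae.encode(res.model, res.scaling.apply(res.train.flat()))
z_test = ae.encode(res.model, res.scaling.apply(ig.dilute(res.test, 10).flat()))
active = active_dimensions(LatentSet(z_train))
print(f"{len(active)} of {z_train.shape[1]} latent dimensions are active "
      f"(rectified-linear units leave the rest at exactly zero)")

gauss = fit_gaussian(LatentSet(z_train))
z_gauss = sample_gaussian(gauss, 5000, seed=3).vectors

pair = (active[0], active[1])
sets = [LatentSet(z_train, "train"), LatentSet(z_test, "test"),
        LatentSet(z_gauss, "gaussian")]
edges = shared_edges(sets, pair, bins=40)
h_train, h_test, h_gauss = (histogram2d(s, pair, bins=40, range_=edges) for s in sets)
print(f"latent pair {pair}, 40x40 bins on a shared grid:")
print(f"  KL(train | test)     = {kl_divergence(h_train, h_test):.3f}")
print(f"  KL(train | gaussian) = {kl_divergence(h_train, h_gauss):.3f}")
print(f"  KL(test  | gaussian) = {kl_divergence(h_test, h_gauss):.3f}")
print("(zero-count bins contribute nothing; values are grid-dependent)")
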