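"""End-to-end generative pipeline.

``run_single`` reproduces the per-run protocol: split the trajectory into an
initial training portion and a test portion, align and scale, train the
autoencoder, fit the multivariate Gaussian to the training latent vectors,
sample and decode a generated set sized as a multiple of the test set, and
evaluate coverage by best-match RMSD on a diluted test set.  ``run_combined``
trains one model on the concatenated (then diluted) training portions of
several replicate runs and evaluates on their combined, further diluted test
set.  Generated sets drawn with one seed are prefix-nested: the first m
conformations of a larger draw equal the draw of size m, which makes
best-match RMSD exactly non-increasing in the generated-set size.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import autoencoder as ae
from .ensemble import (
    ConformationEnsemble,
    ScalingTransform,
    SplitSpec,
    align_frames,
    dilute,
    fit_scaling,
    select_heavy_atoms,
    split_trajectory,
    write_ensemble,
)
from .latent import GaussianLatentModel, LatentSet, fit_gaussian, sample_gaussian
from .metrics import (
    EvaluationReport,
    best_match_rmsd,
    geometry_check,
    mean_reconstruction_rmsd,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "generate_ensemble",
    "run_single",
    "run_combined",
    "pool_generated",
]


@dataclass
class PipelineConfig:
    """Settings for a single- or combined-run pipeline execution."""

    split: SplitSpec = field(default_factory=SplitSpec)
    latent_dim: int | None = None  # None -> 0.75 * n_res rule
    training: ae.TrainingConfig = field(default_factory=ae.TrainingConfig)
    generated_multiple: float = 1.0  # generated size as multiple of test size
    eval_dilution: int = 10  # dilution of the test set for evaluation
    generation_seed: int = 1234
    output_dir: str | None = None

    def __post_init__(self):
        if self.generated_multiple <= 0:
            raise ValueError("generated_multiple must be > 0")
        if self.eval_dilution < 1:
            raise ValueError("eval_dilution must be >= 1")


@dataclass
class PipelineResult:
    """Everything a pipeline run produces."""

    model: ae.AutoencoderModel
    gaussian: GaussianLatentModel
    scaling: ScalingTransform
    train: ConformationEnsemble
    test: ConformationEnsemble
    generated: ConformationEnsemble
    report: EvaluationReport
    geometry: object = None


def _n_residues(atoms) -> int:
    return len(np.unique(atoms.residue_index))


def generate_ensemble(
    model: ae.AutoencoderModel,
    gaussian: GaussianLatentModel,
    scaling: ScalingTransform,
    atoms,
    m: int,
    seed: int,
) -> ConformationEnsemble:
    """Sample ``m`` latent vectors from the Gaussian, decode them and map the
    outputs back to real coordinates with the training scaling.

    Deterministic given ``seed``; draws with the same seed are prefix-nested
    across sizes.
    """
    if gaussian.dim != model.spec.latent_dim:
        raise ValueError("Gaussian dimension does not match the model's latent dim")
    latents = sample_gaussian(gaussian, m, seed)
    scaled = ae.decode(model, latents.vectors)
    coords = scaling.invert(scaled).reshape(m, -1, 3)
    return ConformationEnsemble(coords, atoms, "generated")


def _stage(label: str):
    """Context wrapping a pipeline stage so failures carry the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{label}' failed: {exc}") from exc
            return False

    return _Ctx()


def _prepare(
    runs: list[ConformationEnsemble], config: PipelineConfig
) -> tuple[ConformationEnsemble, ConformationEnsemble, ScalingTransform]:
    """Heavy-atom selection, per-run split, concatenation, alignment, scaling.

    Returns aligned (train, test) ensembles and the training-only scaling.
    """
    with _stage("select/split"):
        trains, tests = [], []
        atoms = None
        for run in runs:
            heavy = select_heavy_atoms(run)
            if atoms is None:
                atoms = heavy.atoms
            elif not (heavy.atoms == atoms):
                raise ValueError("replicate runs have heterogeneous atom tables")
            # train_dilution is applied after concatenation (combined runs)
            per_run = SplitSpec(
                burn_in_frames=config.split.burn_in_frames,
                train_fraction=config.split.train_fraction,
                train_dilution=1,
                test_dilution=config.split.test_dilution,
            )
            tr, te = split_trajectory(heavy, per_run)
            trains.append(tr)
            tests.append(te)
        train = _concat(trains, atoms, "train")
        train = dilute(train, config.split.train_dilution)
        test = _concat(tests, atoms, "test")

    with _stage("align"):
        combined = ConformationEnsemble(
            np.concatenate([train.coordinates, test.coordinates]), atoms
        )
        combined = align_frames(combined, reference_index=0)
        train = ConformationEnsemble(
            combined.coordinates[: train.n_frames], atoms, "train", train.frame_sources
        )
        test = ConformationEnsemble(
            combined.coordinates[train.n_frames :], atoms, "test", test.frame_sources
        )

    with _stage("scale"):
        scaling = fit_scaling(train)
    return train, test, scaling


def _concat(parts, atoms, label) -> ConformationEnsemble:
    coords = np.concatenate([p.coordinates for p in parts])
    sources = np.concatenate(
        [np.full(p.n_frames, p.source_label, dtype=object) for p in parts]
    )
    return ConformationEnsemble(coords, atoms, label, sources)


def _execute(
    runs: list[ConformationEnsemble],
    config: PipelineConfig,
    test_size_unit: int | None = None,
) -> PipelineResult:
    train, test, scaling = _prepare(runs, config)

    with _stage("train-autoencoder"):
        n_res = _n_residues(train.atoms)
        latent_dim = config.latent_dim or ae.latent_dim_rule(n_res)
        spec = ae.NetworkSpec(input_dim=3 * train.n_atoms, latent_dim=latent_dim)
        model = ae.train(scaling.apply(train.flat()), spec, config.training)

    with _stage("fit-gaussian"):
        latents = LatentSet(ae.encode(model, scaling.apply(train.flat())), "train")
        gaussian = fit_gaussian(latents)

    with _stage("generate"):
        unit = test_size_unit if test_size_unit is not None else test.n_frames
        m = max(1, int(round(config.generated_multiple * unit)))
        generated = generate_ensemble(
            model, gaussian, scaling, train.atoms, m, config.generation_seed
        )

    with _stage("geometry-check"):
        geometry = geometry_check(generated.coordinates[0], generated.atoms)

    with _stage("evaluate"):
        test_eval = dilute(test, config.eval_dilution)
        report = best_match_rmsd(test_eval, generated)
        report.mean_reconstruction_rmsd = mean_reconstruction_rmsd(
            model, test, scaling, dilution=config.eval_dilution
        )
        report.metadata.update(
            {
                "n_runs": len(runs),
                "n_train": train.n_frames,
                "n_test": test.n_frames,
                "n_test_evaluated": test_eval.n_frames,
                "n_generated": generated.n_frames,
                "generated_multiple": config.generated_multiple,
                "eval_dilution": config.eval_dilution,
                "latent_dim": latent_dim,
                "generation_seed": config.generation_seed,
                "training_seed": config.training.seed,
                "geometry_bond_violations": geometry.n_bond_violations,
                "geometry_angle_violations": geometry.n_angle_violations,
            }
        )

    result = PipelineResult(
        model=model,
        gaussian=gaussian,
        scaling=scaling,
        train=train,
        test=test,
        generated=generated,
        report=report,
        geometry=geometry,
    )
    if config.output_dir is not None:
        _write_artifacts(result, config)
    return result


def run_single(run: ConformationEnsemble, config: PipelineConfig) -> PipelineResult:
    """Full single-run protocol: split, preprocess, train, model the latent
    distribution, generate and evaluate."""
    return _execute([run], config)


def run_combined(runs: list[ConformationEnsemble], config: PipelineConfig) -> PipelineResult:
    """Combined-run protocol for replicate trajectories.

    Each run is split with the same specification; the training portions are
    concatenated (in input order) and diluted by ``split.train_dilution``, a
    single autoencoder and Gaussian are fit to the combination, and the
    combined test set (diluted by ``eval_dilution``) is evaluated.  The
    generated-set multiple is measured against a single run's test size.
    """
    if len(runs) < 2:
        raise ValueError("run_combined needs at least two runs")
    heavy0 = select_heavy_atoms(runs[0])
    per_run = SplitSpec(
        burn_in_frames=config.split.burn_in_frames,
        train_fraction=config.split.train_fraction,
    )
    _, te0 = split_trajectory(heavy0, per_run)
    return _execute(runs, config, test_size_unit=te0.n_frames)


def pool_generated(sets: list[ConformationEnsemble]) -> ConformationEnsemble:
    """Concatenate generated sets from several models, keeping per-frame
    source labels."""
    if not sets:
        raise ValueError("nothing to pool")
    atoms = sets[0].atoms
    for s in sets[1:]:
        if not (s.atoms == atoms):
            raise ValueError("pooled ensembles have mismatched atom tables")
    if len(sets) == 1:
        return sets[0]
    return _concat(sets, atoms, "pooled")


def _write_artifacts(result: PipelineResult, config: PipelineConfig) -> None:
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    ae.save_model(result.model, os.path.join(out, "model"))
    result.gaussian.to_json(os.path.join(out, "gaussian.json"), provenance="training latents")
    result.scaling.to_json(os.path.join(out, "scaling.json"))
    write_ensemble(result.generated, os.path.join(out, "generated.pdb"), fmt="pdb")
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(result.report.to_json_dict(), fh, indent=1)
    result.report.matches_to_tsv(os.path.join(out, "best_matches.tsv"))
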