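"""Desk-scale end-to-end experiment driver.

Bundles the full workflow — phantom population, training, KDE fitting,
conditional generation, post-processing, evaluation — at a problem size
that runs in minutes on one CPU core: 32^3 1-mm grid, one arc bundle,
K = 32 points, latent dimension 8, 8 training / 2 validation subjects and
one held-out test subject, 100 epochs.  The reference-scale settings
(K = 128, latent 64, 1000 epochs, 3000 streamlines) are reachable through
the same configs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from atm.generation import (
    LatentDensity,
    embed_training_streamlines,
    fit_latent_kde,
    sample_bundle,
)
from atm.io import StreamlineSet, streamlines_to_occupancy
from atm.losses import LossWeights
from atm.metrics import BundleDefinition, evaluate_bundle
from atm.model import AtmModel, ModelConfig
from atm.phantom import BundleSpec, PhantomSubject, default_specs, make_population
from atm.postprocess import postprocess_bundle
from atm.training import TrainConfig, train


@dataclass
class DeskSettings:
    """Scaled-down study conditions for CPU experiments."""

    n_points: int = 32
    latent_dim: int = 8
    cond_dim: int = 16
    anat_channels: tuple[int, ...] = (8, 16, 24, 32)
    line_channels: int = 24
    n_train: int = 8
    n_val: int = 2
    n_test: int = 1
    variability_sd: float = 0.75
    epochs: int = 100
    learning_rate: float = 1e-3
    streamlines_per_step: int = 100
    n_generate: int = 300


@dataclass
class ExperimentResult:
    """Everything the desk experiment produced, for inspection and reuse."""

    seed: int
    metrics: dict
    seg_dice: float
    model: AtmModel
    density: LatentDensity
    test_subject: PhantomSubject
    train_subjects: list[PhantomSubject]
    generated: StreamlineSet
    processed: StreamlineSet
    filter_report: dict
    history_records: list[dict] = field(default_factory=list)


def segmentation_dice(model: AtmModel, subject: PhantomSubject, bundle: str,
                      threshold: float = 0.5) -> float:
    """Voxel Dice of the thresholded segmentation head vs ground truth."""
    a = model.encode_anatomy(subject.t1_like)
    pred = (model.decode_segmentation(a).data > threshold).astype(np.int64)
    gt = subject.gt_occupancy[bundle].data
    denom = pred.sum() + gt.sum()
    return float(2.0 * np.sum(pred * gt) / denom) if denom else 0.0


def run_desk_experiment(
    seed: int,
    settings: DeskSettings | None = None,
    specs: list[BundleSpec] | None = None,
) -> ExperimentResult:
    """Train on a phantom population and evaluate on the held-out subject.

    All randomness derives from ``seed``.  Network arithmetic runs in
    float32 for speed; evaluation is float64 throughout.
    """
    from atm.nn.tensor import get_default_dtype, set_default_dtype

    s = settings or DeskSettings()
    if specs is None:
        specs = [default_specs(n_points=s.n_points)[0]]  # the arc bundle
    bundle = specs[0].name

    prev_dtype = get_default_dtype()
    set_default_dtype(np.float32)
    try:
        n_total = s.n_train + s.n_val + s.n_test
        pop = make_population(n_total, specs, s.variability_sd, rng_seed=seed)
        train_subjects = pop[: s.n_train]
        val_subjects = pop[s.n_train : s.n_train + s.n_val]
        test_subject = pop[-1]

        model_config = ModelConfig(
            grid_shape=(32, 32, 32),
            latent_dim=s.latent_dim,
            cond_dim=s.cond_dim,
            n_points=s.n_points,
            anat_channels=s.anat_channels,
            line_channels=s.line_channels,
            seed=seed,
        )
        train_config = TrainConfig(
            learning_rate=s.learning_rate,
            epochs=s.epochs,
            streamlines_per_step=s.streamlines_per_step,
            seed=seed,
            weights=LossWeights(),
            bundle_name=bundle,
        )
        checkpoint, history = train(
            train_subjects, val_subjects, model_config, train_config
        )
        model = checkpoint.build_model()

        emb = embed_training_streamlines(
            model, train_subjects, bundle, max_per_subject=s.streamlines_per_step
        )
        density = fit_latent_kde(emb)
        generated = sample_bundle(
            model, density, test_subject.t1_like, s.n_generate, seed=seed
        )
        processed, filter_report = postprocess_bundle(
            generated,
            test_subject.brain_mask,
            test_subject.wm_mask,
            test_subject.parcellation,
            test_subject.exception_labels,
            min_length_mm=20.0,
        )

        gt_defs = {
            nm: BundleDefinition(
                mask=test_subject.gt_occupancy[nm],
                roi_a=test_subject.endpoint_rois[nm][0],
                roi_b=test_subject.endpoint_rois[nm][1],
            )
            for nm in test_subject.bundles
        }
        report = evaluate_bundle(
            processed,
            test_subject.bundles[bundle],
            test_subject.gt_occupancy[bundle],
            test_subject.t1_like,
            gt_defs=gt_defs,
            parcellation=test_subject.parcellation,
        )
        seg_dice = segmentation_dice(model, test_subject, bundle)
    finally:
        set_default_dtype(prev_dtype)

    return ExperimentResult(
        seed=seed,
        metrics=report.to_dict(),
        seg_dice=seg_dice,
        model=model,
        density=density,
        test_subject=test_subject,
        train_subjects=list(train_subjects),
        generated=generated,
        processed=processed,
        filter_report=filter_report,
        history_records=history.records,
    )


def occupancy_coverage(model: AtmModel, density: LatentDensity,
                       subject: PhantomSubject, n_small: int, n_large: int,
                       seed: int) -> float:
    """Fraction of the small-sample occupancy covered by the large sample."""
    small = sample_bundle(model, density, subject.t1_like, n_small, seed=seed)
    large = sample_bundle(model, density, subject.t1_like, n_large, seed=seed + 1)
    occ_s = streamlines_to_occupancy(small, subject.t1_like).data > 0
    occ_l = streamlines_to_occupancy(large, subject.t1_like).data > 0
    if occ_s.sum() == 0:
        return 1.0
    return float(np.sum(occ_s & occ_l) / occ_s.sum())
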