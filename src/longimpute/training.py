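"""Optimisation loop: alternating discriminator/generator Adam updates.

The schedule follows the published recipe: batch size 1, Adam with
``beta1=0.5, beta2=0.999`` (the usual GAN convention; the momentum terms
are not pinned by the recipe), learning rate 2e-4 for the first 44 epochs
then halved every 22 epochs for a further 176 (220 total, 8 halvings).
Each iteration performs one discriminator update (both discriminators
jointly in the dual-contrast configuration) followed by one generator
update; the perceptual feature extractor is never updated.

Ablation variants are configurations that switch loss terms on and off:

================  ==========================================
variant           active generator terms
================  ==========================================
``unet_lvr``      voxel-wise L1 only (no discriminator)
``unet_lvr_lp``   L1 + perceptual
``gan``           adversarial only
``gan_lvr``       adversarial + L1
``pgan``          all three, single contrast
``mpgan``         all three, dual contrast, shared encoder
================  ==========================================

Model selection keeps the epoch with the lowest validation L1; with no
validation split the final epoch is used.  Runs are deterministic in
(config, cohort, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import losses as L
from .errors import ConfigError, DataError, InputError, TrainingDivergenceError
from .networks import (
    DiscriminatorSpec,
    FeatureExtractorSpec,
    GeneratorSpec,
    ModelBundle,
    TABLE1_DECODER,
    TABLE1_DISCRIMINATOR,
    TABLE1_ENCODER,
    TABLE1_FEATURE_BLOCKS,
    make_bundle,
    scaled_channels,
)
from .nn import Adam
from .synthetic import AGES, Cohort, SubjectRecord
from .volume_io import Volume

__all__ = [
    "VARIANTS",
    "TrainConfig",
    "TrainHistory",
    "LongitudinalExample",
    "learning_rate",
    "build_bundle_for_config",
    "train_step",
    "TrainState",
    "fit",
    "predict",
    "impute_cohort",
    "evaluate_vr",
    "copy_input_baseline",
]

# variant -> (adversarial, voxel L1, perceptual)
VARIANTS = {
    "unet_lvr": (False, True, False),
    "unet_lvr_lp": (False, True, True),
    "gan": (True, False, False),
    "gan_lvr": (True, True, False),
    "pgan": (True, True, True),
    "mpgan": (True, True, True),
}

_DIRECTIONS = ("6to12", "12to6")


@dataclass(frozen=True)
class TrainConfig:
    """Everything that defines one training run.

    ``width_scale`` divides every Table-1 channel width by an integer
    factor for desk-scale runs; 1 reproduces the published widths.
    ``train_epochs`` limits how far into the 220-epoch schedule the run
    goes (defaults to the full schedule).
    """

    variant: str = "mpgan"
    direction: str = "6to12"
    contrast: str = "T1w"  # used by single-contrast variants
    weights: L.LossWeights = field(default_factory=L.LossWeights)
    lr0: float = 2e-4
    warm_epochs: int = 44
    decay_every: int = 22
    decay_base: float = 0.5
    extra_epochs: int = 176
    train_epochs: int | None = None
    batch_size: int = 1
    seed: int = 0
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    width_scale: int = 1
    literal_ascent: bool = False

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}; one of {sorted(VARIANTS)}")
        if self.direction not in _DIRECTIONS:
            raise ConfigError(f"direction must be one of {_DIRECTIONS}")
        if self.contrast not in ("T1w", "T2w"):
            raise ConfigError("contrast must be T1w or T2w")
        if self.batch_size != 1:
            raise ConfigError("batch size is fixed at 1")
        for name in ("lr0", "decay_base"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("warm_epochs", "decay_every", "extra_epochs"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.width_scale < 1:
            raise ConfigError("width_scale must be >= 1")
        if self.train_epochs is not None and not (
            1 <= self.train_epochs <= self.total_epochs
        ):
            raise ConfigError(
                f"train_epochs must be in 1..{self.total_epochs}")

    @property
    def total_epochs(self) -> int:
        return self.warm_epochs + self.extra_epochs

    @property
    def epochs_to_run(self) -> int:
        return self.train_epochs if self.train_epochs is not None else self.total_epochs

    @property
    def dual(self) -> bool:
        return self.variant == "mpgan"

    @property
    def active_terms(self):
        adv, vr, perc = VARIANTS[self.variant]
        return {"adv": adv, "vr": vr, "perceptual": perc}

    @property
    def ages(self) -> tuple[str, str]:
        return ("6m", "12m") if self.direction == "6to12" else ("12m", "6m")


def learning_rate(epoch: int, cfg: TrainConfig) -> float:
    """Piecewise-constant decayed learning rate at a 0-based epoch index.

    lr0 during the warm phase, then lr0 * base^(1 + floor((e - warm)/every)).
    """
    if not 0 <= epoch < cfg.total_epochs:
        raise InputError(
            f"epoch must be in 0..{cfg.total_epochs - 1}, got {epoch}")
    if epoch < cfg.warm_epochs:
        return cfg.lr0
    steps = 1 + (epoch - cfg.warm_epochs) // cfg.decay_every
    return cfg.lr0 * cfg.decay_base ** steps


@dataclass
class LongitudinalExample:
    """One subject's input-age and target-age volumes (1 or 2 contrasts)."""

    subject_id: str
    x: dict  # contrast -> Volume at the input age
    y: dict  # contrast -> Volume at the target age
    input_age: str
    target_age: str

    def contrasts(self):
        return tuple(self.x.keys())


def example_from_record(rec: SubjectRecord, cfg: TrainConfig) -> LongitudinalExample:
    a_in, a_out = cfg.ages
    contrasts = ("T1w", "T2w") if cfg.dual else (cfg.contrast,)
    for age in (a_in, a_out):
        if age not in rec.scans:
            raise DataError(f"{rec.subject_id}: missing timepoint {age}")
    return LongitudinalExample(
        rec.subject_id,
        {c: rec.scans[a_in][c] for c in contrasts},
        {c: rec.scans[a_out][c] for c in contrasts},
        a_in, a_out,
    )


def _stack_inputs(example: LongitudinalExample) -> np.ndarray:
    arrs = []
    for c, v in example.x.items():
        if not v.normalized:
            raise InputError(f"{example.subject_id}: input {c} is not normalized")
        arrs.append(np.asarray(v.data, dtype=np.float32))
    return np.stack(arrs, axis=0)


def _targets(example: LongitudinalExample) -> list:
    out = []
    for c, v in example.y.items():
        if not v.normalized:
            raise InputError(f"{example.subject_id}: target {c} is not normalized")
        out.append(np.asarray(v.data, dtype=np.float32))
    return out


def build_bundle_for_config(cfg: TrainConfig) -> ModelBundle:
    ws = cfg.width_scale
    dual = cfg.dual
    gen_spec = GeneratorSpec(
        in_contrasts=2 if dual else 1,
        out_decoders=2 if dual else 1,
        encoder_channels=scaled_channels(TABLE1_ENCODER, ws),
        decoder_channels=scaled_channels(TABLE1_DECODER, ws),
    )
    disc_spec = DiscriminatorSpec(channels=scaled_channels(TABLE1_DISCRIMINATOR, ws))
    feat_spec = FeatureExtractorSpec(
        block_channels=tuple(tuple(scaled_channels(b, ws)) for b in TABLE1_FEATURE_BLOCKS)
    )
    contrasts_out = ("T1w", "T2w") if dual else (cfg.contrast,)
    return make_bundle(gen_spec, disc_spec, feat_spec, seed=cfg.seed,
                       direction=cfg.direction, contrasts_out=contrasts_out)


class TrainState:
    """Persistent optimiser state across train steps."""

    def __init__(self, bundle: ModelBundle, cfg: TrainConfig):
        self.opt_G = Adam(bundle.generator_params(), cfg.adam_beta1, cfg.adam_beta2)
        self.opt_D = Adam(bundle.discriminator_params(), cfg.adam_beta1, cfg.adam_beta2)


def _check_finite(name: str, value: float):
    if not np.isfinite(value):
        raise TrainingDivergenceError(name, value)


def train_step(bundle: ModelBundle, batch: LongitudinalExample, cfg: TrainConfig,
               state: TrainState | None = None, lr: float | None = None) -> L.LossBreakdown:
    """One discriminator update (if adversarial) then one generator update.

    Returns the loss breakdown of the generator objective evaluated during
    its update.  The feature extractor's parameters are never touched.
    """
    if state is None:
        state = TrainState(bundle, cfg)
    if lr is None:
        lr = learning_rate(0, cfg)
    active = cfg.active_terms
    w = cfg.weights

    x = _stack_inputs(batch)
    ys = _targets(batch)
    preds = bundle.generator.forward(x)
    preds = list(preds) if isinstance(preds, tuple) else [preds]
    if len(preds) != len(ys):
        raise InputError("generator output arity does not match target contrasts")

    adv_D_total = 0.0
    if active["adv"]:
        state.opt_D.zero_grad()
        for d_net, pred, y in zip(bundle.discriminators, preds, ys):
            d_real = d_net.forward(y)
            g_real = (-2.0 * (1.0 - d_real) / d_real.size).astype(d_real.dtype)
            d_net.backward(g_real)
            d_fake = d_net.forward(pred[0])  # numpy arrays carry no graph: detached
            g_fake = (2.0 * d_fake / d_fake.size).astype(d_fake.dtype)
            d_net.backward(g_fake)
            _, adv_D = L.adversarial_terms(d_real, d_fake,
                                           literal_ascent=cfg.literal_ascent)
            adv_D_total += adv_D
        _check_finite("adv_D", adv_D_total)
        state.opt_D.step(lr)

    # generator update: accumulate d total / d prediction per contrast
    state.opt_G.zero_grad()
    for p in bundle.discriminator_params():
        p.zero_grad()  # gradients from the G pass through D are discarded
    g_preds = [np.zeros_like(p) for p in preds]
    adv_G_total = 0.0
    if active["adv"]:
        for i, (d_net, pred) in enumerate(zip(bundle.discriminators, preds)):
            d_fake = d_net.forward(pred[0])
            adv_G_total += float(np.mean((1.0 - d_fake) ** 2))
            g_preds[i] += d_net.backward(L.adversarial_generator_grad(d_fake))
        _check_finite("adv_G", adv_G_total)
    vr_total = 0.0
    if active["vr"]:
        vr_total = L.voxel_reconstruction_loss([p[0] for p in preds], ys)
        _check_finite("vr", vr_total)
        for i, (pred, y) in enumerate(zip(preds, ys)):
            g_preds[i] += np.float32(w.alpha) * L.l1_grad(pred[0], y)[None]
    perc_total = 0.0
    if active["perceptual"]:
        perc_total, grads = L.perceptual_grads(
            bundle.feature_extractor, [p[0] for p in preds], ys, w.feature_layer)
        _check_finite("perceptual", perc_total)
        for i, g in enumerate(grads):
            g_preds[i] += np.float32(w.beta) * g[None]
    if len(g_preds) == 1:
        bundle.generator.backward(g_preds[0])
    else:
        bundle.generator.backward(tuple(g_preds))
    state.opt_G.step(lr)

    return L.total_generator_objective(adv_G_total, vr_total, perc_total, w,
                                       adv_D=adv_D_total)


@dataclass
class TrainHistory:
    """Per-epoch mean losses, validation L1 and learning rate."""

    epochs: list = field(default_factory=list)
    best_epoch: int = -1

    def as_dict(self) -> dict:
        return {"epochs": self.epochs, "best_epoch": self.best_epoch}


def _snapshot(bundle: ModelBundle) -> list:
    return [p.value.copy() for p in
            bundle.generator_params() + bundle.discriminator_params()]


def _restore(bundle: ModelBundle, snap: list):
    for p, v in zip(bundle.generator_params() + bundle.discriminator_params(), snap):
        p.value[...] = v


def evaluate_vr(bundle: ModelBundle, records, cfg: TrainConfig) -> float:
    """Mean voxel-wise L1 of the generator's predictions over records."""
    vals = []
    for rec in records:
        ex = example_from_record(rec, cfg)
        preds = bundle.generator.forward(_stack_inputs(ex))
        preds = list(preds) if isinstance(preds, tuple) else [preds]
        vals.append(L.voxel_reconstruction_loss([p[0] for p in preds], _targets(ex)))
    return float(np.mean(vals))


def copy_input_baseline(records, cfg: TrainConfig) -> float:
    """Voxel-wise L1 of predicting the target image as the input image."""
    vals = []
    for rec in records:
        ex = example_from_record(rec, cfg)
        vals.append(L.voxel_reconstruction_loss(
            [v.data for v in ex.x.values()], [v.data for v in ex.y.values()]))
    return float(np.mean(vals))


def fit(cohort: Cohort, cfg: TrainConfig,
        bundle: ModelBundle | None = None) -> tuple[ModelBundle, TrainHistory]:
    """Train a model bundle on the cohort's training split.

    Iterates ``cfg.epochs_to_run`` epochs over the complete training
    subjects in a seed-deterministic shuffled order, computes the
    validation L1 each epoch, and returns the checkpoint with the lowest
    validation L1 (final epoch when the validation split is empty).
    """
    train_recs = [r for r in cohort.subjects("train") if r.is_complete()]
    if not train_recs:
        raise ConfigError("no complete training subjects for this direction")
    val_recs = [r for r in cohort.subjects("val") if r.is_complete()]
    if bundle is None:
        bundle = build_bundle_for_config(cfg)
    state = TrainState(bundle, cfg)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 31]))
    history = TrainHistory()
    best_vr = np.inf
    best_snap = None
    for epoch in range(cfg.epochs_to_run):
        lr = learning_rate(epoch, cfg)
        order = rng.permutation(len(train_recs))
        sums = dict.fromkeys(("adv_G", "adv_D", "vr", "perceptual", "total_G"), 0.0)
        for idx in order:
            bd = train_step(bundle, example_from_record(train_recs[idx], cfg),
                            cfg, state, lr)
            for k, v in bd.as_dict().items():
                sums[k] += v
        n = len(train_recs)
        entry = {"epoch": epoch, "lr": lr}
        entry.update({k: v / n for k, v in sums.items()})
        entry["val_vr"] = evaluate_vr(bundle, val_recs, cfg) if val_recs else None
        history.epochs.append(entry)
        if val_recs and entry["val_vr"] < best_vr:
            best_vr = entry["val_vr"]
            best_snap = _snapshot(bundle)
            history.best_epoch = epoch
    if best_snap is not None:
        _restore(bundle, best_snap)
    else:
        history.best_epoch = cfg.epochs_to_run - 1
    return bundle, history


def predict(bundle: ModelBundle, inputs):
    """Apply a trained bundle to one input (Volume or dual-contrast pair).

    Accepts a single :class:`Volume` for single-contrast bundles, or a
    (T1w, T2w) pair / {contrast: Volume} dict for dual-contrast bundles.
    Returns Volume(s) tagged with the bundle's target age.
    """
    n_in = bundle.generator_spec.in_contrasts
    if isinstance(inputs, Volume):
        vols = [inputs]
    elif isinstance(inputs, dict):
        vols = [inputs[c] for c in ("T1w", "T2w") if c in inputs]
    else:
        vols = list(inputs)
    if len(vols) != n_in:
        raise InputError(
            f"bundle expects {n_in} input contrast(s), got {len(vols)}")
    for v in vols:
        if not v.normalized:
            raise InputError("predict expects normalized input volumes")
    target_age = bundle.direction.split("to")[1] + "m"
    x = np.stack([np.asarray(v.data, dtype=np.float32) for v in vols], axis=0)
    preds = bundle.generator.forward(x)
    preds = list(preds) if isinstance(preds, tuple) else [preds]
    out = [
        Volume(p[0], vols[0].spacing, contrast=c, age_tag=target_age, normalized=True)
        for p, c in zip(preds, bundle.contrasts_out)
    ]
    return out[0] if len(out) == 1 else tuple(out)


def impute_cohort(cohort: Cohort, bundle_6to12: ModelBundle,
                  bundle_12to6: ModelBundle):
    """Complete every incomplete subject by predicting its missing timepoint.

    Predicted scans are flagged imputed and may later serve as training
    examples; subjects outside the training split are refused (imputed
    data must never enter validation or test data), and real scans are
    never overwritten.  Returns the completed cohort and an imputation
    manifest (one row per imputed scan).
    """
    import pandas as pd

    rows = []
    for rec in cohort.records:
        if rec.missing_tag is None:
            continue
        missing = rec.missing_tag
        present = [a for a in AGES if a != missing]
        if not present or present[0] not in rec.scans:
            raise DataError(f"{rec.subject_id}: no input timepoint available")
        if cohort.split.get(rec.subject_id) != "train":
            raise DataError(
                f"{rec.subject_id}: refusing to impute a "
                f"{cohort.split.get(rec.subject_id)!r}-split subject; imputed data "
                "is only admissible in the training split")
        if missing in rec.scans:
            raise DataError(f"{rec.subject_id}: timepoint {missing} already has real data")
        direction = "6to12" if missing == "12m" else "12to6"
        bundle = bundle_6to12 if direction == "6to12" else bundle_12to6
        if bundle.direction != direction:
            raise ConfigError(f"bundle direction {bundle.direction} cannot impute {missing}")
        src = rec.scans[present[0]]
        preds = predict(bundle, src)
        preds = preds if isinstance(preds, tuple) else (preds,)
        rec.scans[missing] = {v.contrast: v for v in preds}
        rec.imputed.add(missing)
        rec.missing_tag = None
        for v in preds:
            rows.append(dict(subject_id=rec.subject_id, age_tag=missing,
                             contrast=v.contrast, direction=direction, imputed=True))
    manifest = pd.DataFrame(rows, columns=["subject_id", "age_tag", "contrast",
                                           "direction", "imputed"])
    return cohort, manifest
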