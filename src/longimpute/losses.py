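"""Adversarial, voxel-wise reconstruction and perceptual loss terms.

The generator objective is the weighted combination

    L(G) = L_adv(G) + alpha * L_vr(G) + beta * L_p(G)

with L_vr the mean absolute voxel difference, L_p the mean absolute
difference between frozen deep features phi_m of prediction and target,
and the least-squares adversarial terms below.  In the dual-contrast
configuration each of L_adv, L_vr, L_p is the sum of the per-contrast
terms.

The printed minmax adversarial objective has the discriminator *ascending*
on (1 - D(G(x)))^2 + D(y)^2, whose optimum with a sigmoid-bounded D is
D(real) -> 1, D(fake) -> 0.  By default the equivalent descent losses are
used — adv_D = mean(1 - D(y))^2 + mean D(G(x))^2 and
adv_G = mean(1 - D(G(x)))^2 — which share those optima; ``literal_ascent``
restores the printed form (the D term is then reported with opposite
sign convention).

Expectations are realised as means over the current example (batch size 1)
and over spatial positions; L1 norms are likewise means, not sums, so the
weights alpha and beta are resolution-independent.  The default
alpha = beta = 25 and feature layer m = 1 are tied to that convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, InputError

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "adversarial_terms",
    "adversarial_generator_grad",
    "voxel_reconstruction_loss",
    "l1_grad",
    "perceptual_loss",
    "perceptual_grads",
    "total_generator_objective",
]


@dataclass(frozen=True)
class LossWeights:
    """alpha weights L_vr, beta weights L_p, m indexes the feature layer."""

    alpha: float = 25.0
    beta: float = 25.0
    feature_layer: int = 1

    def __post_init__(self):
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ConfigError(f"{name} must be finite and >= 0, got {v}")
        if self.feature_layer not in (1, 2, 3, 4):
            raise ConfigError(f"feature_layer must be in 1..4, got {self.feature_layer}")


@dataclass
class LossBreakdown:
    """Per-iteration loss components; total_G = adv_G + alpha*vr + beta*perceptual."""

    adv_G: float = 0.0
    adv_D: float = 0.0
    vr: float = 0.0
    perceptual: float = 0.0
    total_G: float = 0.0

    def as_dict(self) -> dict:
        return {
            "adv_G": self.adv_G,
            "adv_D": self.adv_D,
            "vr": self.vr,
            "perceptual": self.perceptual,
            "total_G": self.total_G,
        }


def _as_list(x):
    if isinstance(x, (list, tuple)):
        return list(x)
    return [x]


def _data(v):
    return v.data if hasattr(v, "data") and not isinstance(v, np.ndarray) else np.asarray(v)


def adversarial_terms(d_real, d_fake, literal_ascent: bool = False):
    """Least-squares adversarial losses from two discriminator score maps.

    Returns ``(adv_G, adv_D)``: the generator loss mean(1 - d_fake)^2 and
    the discriminator descent loss mean(1 - d_real)^2 + mean(d_fake)^2.
    With ``literal_ascent`` the second element is the printed ascent
    objective mean(1 - d_fake)^2 + mean(d_real)^2 instead (to be
    *maximised* by D).
    """
    d_real = np.asarray(d_real, dtype=np.float64)
    d_fake = np.asarray(d_fake, dtype=np.float64)
    if d_real.shape != d_fake.shape:
        raise InputError(f"score map shapes differ: {d_real.shape} vs {d_fake.shape}")
    if d_real.size == 0:
        raise InputError("empty score maps")
    adv_G = float(np.mean((1.0 - d_fake) ** 2))
    if literal_ascent:
        adv_D = float(np.mean((1.0 - d_fake) ** 2) + np.mean(d_real ** 2))
    else:
        adv_D = float(np.mean((1.0 - d_real) ** 2) + np.mean(d_fake ** 2))
    return adv_G, adv_D


def adversarial_generator_grad(d_fake):
    """d adv_G / d d_fake for adv_G = mean(1 - d_fake)^2."""
    d_fake = np.asarray(d_fake)
    return (-2.0 * (1.0 - d_fake) / d_fake.size).astype(d_fake.dtype)


def voxel_reconstruction_loss(predicted, target) -> float:
    """Mean absolute voxel difference per contrast, summed over contrasts."""
    preds, targs = _as_list(predicted), _as_list(target)
    if len(preds) != len(targs):
        raise InputError("predicted and target contrast counts differ")
    total = 0.0
    for p, t in zip(preds, targs):
        pa, ta = _data(p), _data(t)
        if pa.shape != ta.shape:
            raise InputError(f"shape mismatch: {pa.shape} vs {ta.shape}")
        total += float(np.mean(np.abs(pa.astype(np.float64) - ta.astype(np.float64))))
    return total


def l1_grad(predicted, target):
    """d/d predicted of mean |predicted - target| (one contrast)."""
    pa, ta = _data(predicted), _data(target)
    return (np.sign(pa - ta) / pa.size).astype(pa.dtype)


def perceptual_loss(phi, predicted, target, m: int = 1) -> float:
    """Mean absolute difference between phi_m features, summed over contrasts."""
    if not 1 <= int(m) <= 4:
        raise ConfigError(f"feature layer m must be in 1..4, got {m}")
    preds, targs = _as_list(predicted), _as_list(target)
    if len(preds) != len(targs):
        raise InputError("predicted and target contrast counts differ")
    total = 0.0
    for p, t in zip(preds, targs):
        fp = phi.features(_data(p), m)
        ft = phi.features(_data(t), m)
        total += float(np.mean(np.abs(fp.astype(np.float64) - ft.astype(np.float64))))
    return total


def perceptual_grads(phi, predicted, target, m: int = 1):
    """Loss value and per-contrast gradients w.r.t. the predictions.

    The target features are computed first, then for each prediction the
    feature-space L1 gradient sign(fp - ft)/n is pulled back through the
    frozen extractor.
    """
    preds, targs = _as_list(predicted), _as_list(target)
    total = 0.0
    grads = []
    for p, t in zip(preds, targs):
        ft = phi.features(_data(t), m)
        fp = phi.features(_data(p), m)  # trace now holds the prediction pass
        diff = fp.astype(np.float64) - ft.astype(np.float64)
        total += float(np.mean(np.abs(diff)))
        gfeat = (np.sign(diff) / diff.size).astype(fp.dtype)
        grads.append(phi.backward_input(gfeat))
    return total, grads


def total_generator_objective(adv_G: float, vr: float, perceptual: float,
                              weights: LossWeights, adv_D: float = 0.0) -> LossBreakdown:
    """Assemble the weighted generator objective into a breakdown record."""
    total = float(adv_G + weights.alpha * vr + weights.beta * perceptual)
    return LossBreakdown(adv_G=float(adv_G), adv_D=float(adv_D), vr=float(vr),
                         perceptual=float(perceptual), total_G=total)
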