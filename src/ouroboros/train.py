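"""Loss terms, adversarial optimization and the leave-one-patient-out protocol.

The composite objective is L = L_I + lambda1 * L_r + lambda2 * L_p +
lambda3 * L_GAN with

* ``L_I``  — mean absolute error between the real patch I and the patch
  generated from its expression vector,
* ``L_r``  — mean squared error between p and the expression the
  discriminator predicts from the *generated* patch (shapes the generator;
  the discriminator is frozen on this path),
* ``L_p``  — mean squared error between p and the expression predicted from
  the *real* patch (shapes the discriminator's prediction head),
* ``L_GAN`` — the standard min-max adversarial loss
  E[log D(I)] + E[log(1 - D(G(p, z)))].

Each training step performs one discriminator update minimizing
``lambda2 * L_p + lambda3 * L_GAN_d`` followed by one generator update
minimizing ``L_I + lambda1 * L_r + lambda3 * L_GAN_g`` (non-saturating
surrogate by default), with Adam (lr 1e-4, beta1 0.5) and fresh z per item.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from . import _nn as nn
from .config import RunConfig
from .data import SpotDataset, images_to_float
from .model import (ArchDescriptor, DiscriminatorParams, GeneratorParams,
                    init_discriminator, init_generator)
from .preprocess import BatchCorrector, apply_transform, fit_transform_expression

log = logging.getLogger(__name__)


class TrainingDiverged(RuntimeError):
    """A loss term became non-finite during optimization."""


# ---------------------------------------------------------------------------
# loss terms (public numpy forms + internal tensor forms)
# ---------------------------------------------------------------------------

def loss_image(real: np.ndarray, generated: np.ndarray) -> float:
    """Image reconstruction loss L_I: mean absolute error over all pixels."""
    real = np.asarray(real, dtype=np.float64)
    generated = np.asarray(generated, dtype=np.float64)
    if real.shape != generated.shape:
        raise ValueError(f"shape mismatch: {real.shape} vs {generated.shape}")
    return float(np.abs(real - generated).mean())


def loss_expr(p: np.ndarray, p_hat: np.ndarray) -> float:
    """Expression loss (L_r / L_p): mean squared error."""
    p = np.asarray(p, dtype=np.float64)
    p_hat = np.asarray(p_hat, dtype=np.float64)
    if p.shape != p_hat.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {p_hat.shape}")
    return float(((p - p_hat) ** 2).mean())


def _softplus64(x):
    x = np.asarray(x, dtype=np.float64)
    return np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))


def loss_adversarial(d_real, d_fake, saturating: bool = False):
    """Adversarial losses from realism logits.

    With s the logistic sigmoid, the discriminator maximizes
    ``log s(d_real) + log(1 - s(d_fake))``; we return its negative
    ``L_GAN_d`` (to be minimized). The generator part ``L_GAN_g`` is the
    non-saturating surrogate ``-log s(d_fake)`` by default, or the original
    ``log(1 - s(d_fake))`` when ``saturating=True``. Both are evaluated in
    overflow-safe log-sum-exp form.
    """
    d_real = np.asarray(d_real, dtype=np.float64)
    d_fake = np.asarray(d_fake, dtype=np.float64)
    l_d = float(_softplus64(-d_real).mean() + _softplus64(d_fake).mean())
    if saturating:
        l_g = float(-_softplus64(d_fake).mean())
    else:
        l_g = float(_softplus64(-d_fake).mean())
    return l_d, l_g


def _abs_mean(d: nn.Tensor) -> nn.Tensor:
    # |x| with subgradient sign(x): implemented as x * sign(x) with sign constant
    s = nn.Tensor(np.sign(d.data))
    return nn.mean(nn.mul(d, s))


def _mse_t(a: nn.Tensor, b: nn.Tensor) -> nn.Tensor:
    d = nn.sub(a, b)
    return nn.mean(nn.mul(d, d))


@dataclass
class LossBreakdown:
    """The loss terms of one training step and their weighted player totals."""

    L_I: float
    L_r: float
    L_p: float
    L_GAN_g: float
    L_GAN_d: float
    total_g: float
    total_d: float

    def check_finite(self):
        for k, v in self.__dict__.items():
            if not np.isfinite(v):
                raise TrainingDiverged(f"loss term {k} is non-finite: {v}; "
                                       f"full breakdown: {self}")

    def check_totals(self, cfg: RunConfig, tol: float = 1e-5):
        assert abs(self.total_g - (self.L_I + cfg.lambda1 * self.L_r
                                   + cfg.lambda3 * self.L_GAN_g)) < tol
        assert abs(self.total_d - (cfg.lambda2 * self.L_p
                                   + cfg.lambda3 * self.L_GAN_d)) < tol


@dataclass
class TrainHistory:
    """Per-step losses and per-epoch validation summary of one fit run."""

    steps: list = field(default_factory=list)
    val_pearson: list = field(default_factory=list)
    seed: int = 0
    best_epoch: int = -1


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

def train_step(p_batch: np.ndarray, img_batch: np.ndarray,
               G: GeneratorParams, D: DiscriminatorParams,
               opt_g: nn.Adam, opt_d: nn.Adam, cfg: RunConfig,
               rng: np.random.Generator, saturating: bool = False) -> LossBreakdown:
    """One discriminator update followed by one generator update.

    ``p_batch`` is transformed (and batch-corrected) expression, shape
    (b, m); ``img_batch`` is float images in [-1, 1], shape (b, P, P, 3).
    """
    b = p_batch.shape[0]
    p_t = nn.Tensor(p_batch)
    real_t = nn.Tensor(img_batch)

    # --- discriminator step: minimize lambda2 * L_p + lambda3 * L_GAN_d
    z = rng.standard_normal((b, G.arch.noise_dim)).astype(np.float32)
    with nn.no_grad():
        fake = G.forward(nn.Tensor(p_batch), nn.Tensor(z))
    fake_detached = nn.Tensor(fake.data)
    logit_real, pred_real = D.forward(real_t)
    logit_fake, _ = D.forward(fake_detached)
    l_p = _mse_t(pred_real, p_t)
    l_gan_d = nn.add(nn.mean(nn.softplus(nn.scale(logit_real, -1.0))),
                     nn.mean(nn.softplus(logit_fake)))
    total_d = nn.add(nn.scale(l_p, cfg.lambda2), nn.scale(l_gan_d, cfg.lambda3))
    opt_d.zero_grad()
    opt_g.zero_grad()
    total_d.backward()
    opt_d.step()

    # --- generator step: minimize L_I + lambda1 * L_r + lambda3 * L_GAN_g
    z2 = rng.standard_normal((b, G.arch.noise_dim)).astype(np.float32)
    fake2 = G.forward(nn.Tensor(p_batch), nn.Tensor(z2))
    l_i = _abs_mean(nn.sub(real_t, fake2))
    logit_fake2, pred_fake2 = D.forward(fake2)  # D frozen: grads unused
    l_r = _mse_t(pred_fake2, p_t)
    if saturating:
        l_gan_g = nn.scale(nn.mean(nn.softplus(logit_fake2)), -1.0)
    else:
        l_gan_g = nn.mean(nn.softplus(nn.scale(logit_fake2, -1.0)))
    total_g = nn.add(nn.add(l_i, nn.scale(l_r, cfg.lambda1)),
                     nn.scale(l_gan_g, cfg.lambda3))
    opt_d.zero_grad()
    opt_g.zero_grad()
    total_g.backward()
    opt_g.step()
    opt_d.zero_grad()
    opt_g.zero_grad()

    bd = LossBreakdown(
        L_I=l_i.item(), L_r=l_r.item(), L_p=l_p.item(),
        L_GAN_g=l_gan_g.item(), L_GAN_d=l_gan_d.item(),
        total_g=total_g.item(), total_d=total_d.item())
    bd.check_finite()
    bd.check_totals(cfg)
    return bd


def predict_expression(D: DiscriminatorParams, images: np.ndarray,
                       batch: int = 32) -> np.ndarray:
    """Prediction-head output for a stack of images (uint8 or [-1,1] float)."""
    if images.dtype == np.uint8:
        images = images_to_float(images)
    out = []
    with nn.no_grad():
        for i in range(0, len(images), batch):
            _, pred = D.forward(nn.Tensor(images[i:i + batch]))
            out.append(pred.data)
    return np.concatenate(out, axis=0)


def _mean_pearson(y: np.ndarray, yhat: np.ndarray) -> float:
    rs = []
    for j in range(y.shape[1]):
        if np.std(y[:, j]) == 0 or np.std(yhat[:, j]) == 0:
            continue
        rs.append(np.corrcoef(y[:, j], yhat[:, j])[0, 1])
    return float(np.mean(rs)) if rs else float("nan")


def fit(train_ds: SpotDataset, cfg: RunConfig,
        arch: ArchDescriptor | None = None,
        max_steps: int | None = None,
        val_ds: SpotDataset | None = None,
        saturating: bool = False):
    """Train the generator/discriminator pair on one training fold.

    ``train_ds.expression`` must already be transformed (and batch-corrected)
    with statistics fitted on this fold only. Runs ``cfg.epochs`` epochs of
    1:1 alternating updates, capped at ``max_steps`` total steps when given.
    When a validation set is supplied, the epoch with the best prediction-head
    mean Pearson r is checkpointed and restored at the end.

    Returns ``(G, D, TrainHistory)``.
    """
    if train_ds.n_spots == 0:
        raise ValueError("empty training fold")
    if not train_ds.transformed:
        log.warning("training on expression not flagged as transformed")
    if arch is None:
        arch = ArchDescriptor(patch_size_px=cfg.patch_size_px,
                              n_markers=len(train_ds.marker_names),
                              noise_dim=cfg.noise_dim)
    G = init_generator(arch, cfg.seed)
    D = init_discriminator(arch, cfg.seed)
    log.info("generator: %d parameters; discriminator: %d parameters",
             G.n_parameters, D.n_parameters)
    opt_g = nn.Adam(G.parameters(), lr=cfg.learning_rate, beta1=cfg.adam_beta1)
    opt_d = nn.Adam(D.parameters(), lr=cfg.learning_rate, beta1=cfg.adam_beta1)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7EA1]))
    hist = TrainHistory(seed=cfg.seed)
    expr = train_ds.expression.astype(np.float32)
    imgs = images_to_float(train_ds.images)
    n = train_ds.n_spots
    best = (-np.inf, None, None)
    steps_done = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if len(idx) < 2:
                continue
            bd = train_step(expr[idx], imgs[idx], G, D, opt_g, opt_d, cfg, rng,
                            saturating=saturating)
            hist.steps.append(bd)
            steps_done += 1
            if max_steps is not None and steps_done >= max_steps:
                break
        if val_ds is not None:
            pred = predict_expression(D, val_ds.images)
            r = _mean_pearson(val_ds.expression, pred)
            hist.val_pearson.append(r)
            log.info("epoch %d: val mean Pearson r = %.3f", epoch, r)
            if np.isfinite(r) and r > best[0]:
                best = (r, copy.deepcopy(G.state_arrays()),
                        copy.deepcopy(D.state_arrays()))
                hist.best_epoch = epoch
        if max_steps is not None and steps_done >= max_steps:
            break
    if val_ds is not None and best[1] is not None:
        G.load_state_arrays(best[1])
        D.load_state_arrays(best[2])
    return G, D, hist


# ---------------------------------------------------------------------------
# leave-one-patient-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    """Everything produced by one leave-one-patient-out fold."""

    held_out: object
    generator: GeneratorParams
    discriminator: DiscriminatorParams
    history: TrainHistory
    transform_state: object
    corrector: BatchCorrector
    test_expression: np.ndarray       # transformed+corrected truth
    test_prediction: np.ndarray       # prediction-head output
    metrics: dict


def prepare_fold(dataset: SpotDataset, held_out) -> tuple[SpotDataset, SpotDataset, object, BatchCorrector]:
    """Transform + batch-correct a raw-count dataset for one CV fold.

    All statistics (log-z transform, batch reference frame) are estimated on
    the training patients only and then applied to the held-out patient.
    Returns ``(train_ds, test_ds, transform_state, corrector)`` with
    transformed, corrected expression.
    """
    test_mask = dataset.patients == held_out
    if not test_mask.any():
        raise ValueError(f"held-out patient {held_out!r} has no spots")
    train = dataset.subset(~test_mask)
    test = dataset.subset(test_mask)
    z_train, state = fit_transform_expression(train.expression,
                                              marker_names=train.marker_names)
    corrector = BatchCorrector().fit(z_train, train.patients)
    z_train_c = corrector.apply(z_train, train.patients)
    z_test = apply_transform(test.expression, state, test.marker_names)
    z_test_c = corrector.apply(z_test, test.patients)
    return (train.with_expression(z_train_c, transformed=True),
            test.with_expression(z_test_c, transformed=True),
            state, corrector)


def loo_cv(dataset: SpotDataset, cfg: RunConfig,
           arch: ArchDescriptor | None = None,
           max_steps: int | None = None,
           folds: list | None = None,
           validate_during_fit: bool = False) -> list[FoldResult]:
    """Leave-one-patient-out cross-validation on a raw-count dataset.

    One fold per patient (or per entry of ``folds``): the model is fitted on
    the remaining patients and evaluated on the held-out one. Transform and
    batch-correction statistics never see the held-out patient.
    """
    from .evaluate import prediction_metrics

    patient_ids = dataset.patient_ids
    if len(patient_ids) < 2:
        raise ValueError("leave-one-patient-out needs at least 2 patients")
    results = []
    for held_out in (folds if folds is not None else patient_ids):
        n_spots = int((dataset.patients == held_out).sum())
        if n_spots == 0:
            log.warning("patient %r has zero spots; fold skipped", held_out)
            continue
        train_ds, test_ds, state, corrector = prepare_fold(dataset, held_out)
        G, D, hist = fit(train_ds, cfg, arch=arch, max_steps=max_steps,
                         val_ds=test_ds if validate_during_fit else None)
        pred = predict_expression(D, test_ds.images)
        metrics = prediction_metrics(test_ds.expression, pred)
        results.append(FoldResult(
            held_out=held_out, generator=G, discriminator=D, history=hist,
            transform_state=state, corrector=corrector,
            test_expression=test_ds.expression, test_prediction=pred,
            metrics=metrics))
    return results
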