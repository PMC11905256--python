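"""Self-ensembling mean-teacher (SE-MT) training engine.

Two networks of identical topology are maintained: the *student*, trained
by gradient descent, and the *teacher*, an exponential moving average
(EMA) of the student's parameters.  Each step draws a composite batch —
labeled source cases (SL), labeled target cases (TL), unlabeled target
cases (TU) — and minimizes

    L_total = L_sup + λ_eff(k) · L_un

where L_sup is a dice + cross-entropy compound over SL ∪ TL, L_un is the
mean-squared disagreement between student and teacher predictions on the
same TU inputs under independent noise, and λ_eff ramps from ≈0 to the
trade-off weight λ along a Gaussian warm-up so the consistency term only
bites once the student makes meaningful predictions.  The teacher never
receives gradients; the deliverable model is the student.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._tensor import Tensor, no_grad
from .nn import Module
from .optim import AdamW, clip_grad_norm, stepwise_exponential_lr
from .preprocess import LabelMap, Volume, augment
from .segnet import NetworkConfig, SegNet, build_network
from .synthetic import DomainSample, SplitDataset

__all__ = ["LossWeights", "TrainConfig", "TrainResult", "soft_dice_loss",
           "cross_entropy_loss", "supervised_loss", "consistency_loss",
           "consistency_weight", "effective_lambda", "total_loss", "ema_update",
           "train", "predict_labels", "evaluate_model"]

_EPS = 1e-7


# --------------------------------------------------------------------- losses

@dataclass
class LossWeights:
    """Loss trade-offs: λ (consistency), λ_dice/λ_ce (supervised mix), warm-up."""
    lam: float = 2.0
    lam_dice: float = 0.7
    lam_ce: float = 0.3
    ramp_amplitude: float = 0.1
    ramp_sharpness: float = 5.0

    def validate(self) -> None:
        if abs(self.lam_dice + self.lam_ce - 1.0) > 1e-9:
            raise ValueError("lam_dice + lam_ce must equal 1")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


def _one_hot(target: np.ndarray, n_classes: int) -> np.ndarray:
    if target.min() < 0 or target.max() >= n_classes:
        raise ValueError(
            f"target classes outside [0, {n_classes - 1}]: "
            f"[{target.min()}, {target.max()}]")
    oh = np.zeros((target.shape[0], n_classes) + target.shape[1:], dtype=np.float32)
    for c in range(n_classes):
        oh[:, c][target == c] = 1.0
    return oh


def soft_dice_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """1 - mean over classes of the batch-aggregated soft dice coefficient."""
    pred = Tensor._coerce(pred)
    n_classes = pred.shape[1]
    oh = _one_hot(np.asarray(target), n_classes)
    axes = (0, 2, 3, 4)
    inter = (pred * Tensor(oh)).sum(axis=axes)
    denom = pred.sum(axis=axes) + Tensor(oh.sum(axis=axes))
    dice = (inter * 2.0 + _EPS) / (denom + _EPS)
    return 1.0 - dice.mean()


def cross_entropy_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean per-voxel cross-entropy, computed on the probability output."""
    pred = Tensor._coerce(pred)
    oh = _one_hot(np.asarray(target), pred.shape[1])
    picked = (pred * Tensor(oh)).sum(axis=1)
    return -((picked + _EPS).log().mean())


def supervised_loss(pred: Tensor, target, w: LossWeights) -> Tensor:
    """Compound segmentation loss λ_dice·dice + λ_ce·CE over a labeled batch."""
    w.validate()
    pred = Tensor._coerce(pred)
    if pred.shape[0] == 0:
        raise ValueError("empty batch")
    t = target.labels[None] if isinstance(target, LabelMap) else np.asarray(target)
    return soft_dice_loss(pred, t) * w.lam_dice + cross_entropy_loss(pred, t) * w.lam_ce


def consistency_loss(student_pred: Tensor, teacher_pred) -> Tensor:
    """Mean squared error between student and teacher probability maps.

    The teacher prediction is treated as a constant — no gradient flows
    through it.
    """
    student_pred = Tensor._coerce(student_pred)
    t = teacher_pred.data if isinstance(teacher_pred, Tensor) else np.asarray(teacher_pred)
    if student_pred.shape != t.shape:
        raise ValueError(f"shape mismatch: {student_pred.shape} vs {t.shape}")
    diff = student_pred - Tensor(t)
    return (diff * diff).mean()


def consistency_weight(k: int, k_max: int, amplitude: float = 0.1,
                       sharpness: float = 5.0) -> float:
    """Gaussian warm-up  amplitude · exp(-sharpness · (1 - k/k_max)²).

    Monotone non-decreasing in k; equals ``amplitude`` at k = k_max and
    ``amplitude·e^(-sharpness)`` at k = 0.
    """
    if k_max <= 0:
        raise ValueError("k_max must be positive")
    if not 0 <= k <= k_max:
        raise ValueError(f"iteration k={k} outside [0, {k_max}]")
    return amplitude * math.exp(-sharpness * (1.0 - k / k_max) ** 2)


def effective_lambda(k: int, k_max: int, w: LossWeights) -> float:
    """Consistency weight actually applied at iteration k.

    The warm-up shape is normalized so its final value equals the tuned
    trade-off λ: λ_eff(k) = λ · ramp(k)/ramp(k_max).
    """
    ramp = consistency_weight(k, k_max, w.ramp_amplitude, w.ramp_sharpness)
    return w.lam * ramp / w.ramp_amplitude


def total_loss(sup, un, w: LossWeights, k: int, k_max: int):
    """L_total = L_sup + λ_eff(k) · L_un; returns (loss, λ_eff)."""
    lam_eff = effective_lambda(k, k_max, w)
    return sup + un * lam_eff, lam_eff


# ------------------------------------------------------------------ EMA update

def ema_update(student: Module, teacher: Module, eta: float) -> None:
    """In-place EMA: every teacher tensor t ← η·t + (1-η)·s.

    Applies to parameters and buffers alike (so DSBN running statistics track
    the student's the same way).  Topology mismatch raises.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError("EMA decay must lie in [0, 1]")
    s_params = dict(student.named_parameters())
    t_params = dict(teacher.named_parameters())
    if s_params.keys() != t_params.keys():
        raise ValueError("student/teacher topology mismatch (parameter names differ)")
    for name, sp in s_params.items():
        tp = t_params[name]
        if tp.data.shape != sp.data.shape:
            raise ValueError(f"shape mismatch for {name}")
        tp.data = eta * tp.data + (1.0 - eta) * sp.data
    s_mods = dict(student.named_modules())
    for mod_name, t_mod in teacher.named_modules():
        s_mod = s_mods[mod_name]
        for b_name in list(t_mod._buffers):
            t_mod.set_buffer(b_name, eta * t_mod._buffers[b_name]
                             + (1.0 - eta) * s_mod._buffers[b_name])


# -------------------------------------------------------------------- training

@dataclass
class TrainConfig:
    """Optimization recipe (defaults follow the standard training recipe of the method)."""
    steps: int = 500
    batch_sl: int = 4
    batch_tl: int = 2
    batch_tu: int = 2
    lr: float = 9e-4
    weight_decay: float = 5e-5
    lr_gamma: float = 0.95
    lr_step_every: int = 250
    ema_decay: float = 0.99
    grad_clip: float = 5.0
    noise_sd: float = 0.05
    augment: bool = True          # geometric+gamma augmentation of training draws
    use_source: bool = True       # False: supervised-only on TL
    use_semt: bool = True         # False: no teacher / no consistency term


@dataclass
class TrainResult:
    student: SegNet
    teacher: SegNet | None
    history: pd.DataFrame

    def __iter__(self):  # allow  model, history = train(...)
        return iter((self.student, self.history))


def _stack(samples: list[DomainSample], idx, rng_aug, do_augment,
           with_labels: bool):
    vols, labs = [], []
    for i in idx:
        s = samples[i]
        vol, lab = s.volume, s.label
        if do_augment:
            vol, lab = augment(vol, lab, seed=int(rng_aug.integers(2 ** 31)))
        vols.append(vol.values)
        if with_labels:
            labs.append(lab.labels)
    x = np.stack(vols)[:, None].astype(np.float32)
    y = np.stack(labs) if with_labels else None
    return x, y


def train(data: SplitDataset, net_cfg: NetworkConfig, w: LossWeights,
          opt_cfg: TrainConfig, seed: int) -> TrainResult:
    """Run the mean-teacher loop and return the trained student plus history.

    Per step: sample ``batch_sl`` SL + ``batch_tl`` TL + ``batch_tu`` TU cases
    (with replacement), forward source and target batches separately (the
    domain tag routes DSBN), apply the compound supervised loss on SL ∪ TL and
    the consistency loss on TU, backpropagate into the student only, clip the
    global gradient norm, take an AdamW step with the stepwise-exponential
    learning-rate schedule, and EMA-update the teacher.

    Determinism: all randomness derives from ``seed`` through separate
    streams (weight init, batch sampling, supervised augmentation,
    consistency noise), so a consistency-disabled run reproduces the exact
    supervised trajectory of a λ=0 run.
    """
    w.validate()
    if opt_cfg.use_source and not data.SL:
        raise ValueError("use_source=True but the dataset has no SL cases")
    if not data.TL:
        raise ValueError("dataset has no labeled target (TL) cases")
    use_cons = opt_cfg.use_semt and w.lam > 0 and len(data.TU) > 0
    if opt_cfg.use_semt and not data.TU:
        import warnings
        warnings.warn("TU is empty; consistency term disabled", stacklevel=2)

    ss = np.random.SeedSequence(seed)
    s_init, s_batch, s_aug, s_noise = ss.spawn(4)
    rng_batch = np.random.default_rng(s_batch)
    rng_aug = np.random.default_rng(s_aug)
    rng_noise = np.random.default_rng(s_noise)

    student = build_network(net_cfg, seed=int(s_init.generate_state(1)[0] % 2 ** 31))
    teacher = None
    if opt_cfg.use_semt:
        teacher = build_network(net_cfg, seed=0)
        teacher.load_state_dict(student.state_dict())
        teacher.train(True)   # teacher normalizes its batches like the student

    opt = AdamW(student.parameters(), lr=opt_cfg.lr,
                weight_decay=opt_cfg.weight_decay)
    k_max = max(opt_cfg.steps - 1, 1)
    rows = []
    for k in range(opt_cfg.steps):
        # batch indices are always drawn, in fixed order, so ablations that
        # drop a term keep an identical sampling stream
        idx_sl = rng_batch.integers(len(data.SL), size=opt_cfg.batch_sl) \
            if data.SL else np.empty(0, dtype=int)
        idx_tl = rng_batch.integers(len(data.TL), size=opt_cfg.batch_tl)
        idx_tu = rng_batch.integers(len(data.TU), size=opt_cfg.batch_tu) \
            if data.TU else np.empty(0, dtype=int)

        opt.lr = stepwise_exponential_lr(opt_cfg.lr, k, opt_cfg.lr_gamma,
                                         opt_cfg.lr_step_every)
        student.train(True)
        student.zero_grad()

        sup_terms = []
        n_labeled = 0
        if opt_cfg.use_source:
            x_sl, y_sl = _stack(data.SL, idx_sl, rng_aug, opt_cfg.augment, True)
            p_sl = student(Tensor(x_sl), "source")
            sup_terms.append((supervised_loss(p_sl, y_sl, w), len(idx_sl)))
            n_labeled += len(idx_sl)
        x_tl, y_tl = _stack(data.TL, idx_tl, rng_aug, opt_cfg.augment, True)

        p_stu_tu = None
        if use_cons:
            # one target-domain student forward over [TL | noised TU]: the
            # target mini-batch is normalized jointly, and it saves a pass
            x_tu, _ = _stack(data.TU, idx_tu, rng_noise, opt_cfg.augment, False)
            noise_s = rng_noise.normal(0, opt_cfg.noise_sd,
                                       size=x_tu.shape).astype(np.float32)
            noise_t = rng_noise.normal(0, opt_cfg.noise_sd,
                                       size=x_tu.shape).astype(np.float32)
            p_t = student(Tensor(np.concatenate([x_tl, x_tu + noise_s])), "target")
            p_tl = p_t[: len(idx_tl)]
            p_stu_tu = p_t[len(idx_tl):]
        else:
            p_tl = student(Tensor(x_tl), "target")
        sup_terms.append((supervised_loss(p_tl, y_tl, w), len(idx_tl)))
        n_labeled += len(idx_tl)
        sup = sup_terms[0][0] * (sup_terms[0][1] / n_labeled)
        for term, n in sup_terms[1:]:
            sup = sup + term * (n / n_labeled)

        if use_cons:
            with no_grad():
                p_tea = teacher(Tensor(x_tu + noise_t), "target")
            un = consistency_loss(p_stu_tu, p_tea)
            loss, lam_eff = total_loss(sup, un, w, k, k_max)
            un_val = un.item()
        else:
            lam_eff = effective_lambda(k, k_max, w) if opt_cfg.use_semt else 0.0
            loss = sup
            un_val = 0.0

        if not np.isfinite(loss.item()):
            raise RuntimeError(
                f"non-finite loss at step {k}: sup={sup.item()}, un={un_val} — "
                "training aborted")
        loss.backward()
        grad_norm = clip_grad_norm(student.parameters(), opt_cfg.grad_clip)
        opt.step()
        if opt_cfg.use_semt and teacher is not None:
            ema_update(student, teacher, opt_cfg.ema_decay)
        rows.append({"step": k, "lr": opt.lr, "loss_sup": sup.item(),
                     "loss_un": un_val, "lambda_eff": lam_eff,
                     "loss_total": loss.item(), "grad_norm": grad_norm})

    student.eval()
    if teacher is not None:
        teacher.eval()
    return TrainResult(student, teacher, pd.DataFrame(rows))


# ------------------------------------------------------------------ inference

def predict_labels(model: SegNet, volumes: list[Volume],
                   domain: str = "target") -> list[LabelMap]:
    """Argmax segmentation of each volume in eval mode."""
    model.eval()
    out = []
    for vol in volumes:
        x = vol.values[None, None].astype(np.float32)
        with no_grad():
            p = model(Tensor(x), domain)
        out.append(LabelMap(np.argmax(p.data[0], axis=0).astype(np.int16)))
    return out


def evaluate_model(model: SegNet, samples: list[DomainSample],
                   domain: str = "target"):
    """Per-case metrics of a model on labeled samples."""
    from .metrics import evaluate_case
    preds = predict_labels(model, [s.volume for s in samples], domain)
    return [evaluate_case(p, s.label, s.volume.spacing_mm, s.case_id)
            for p, s in zip(preds, samples)]
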