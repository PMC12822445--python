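"""Label handling, the dual-MSE objective, optimization, and patient-level
cross-validation.

The continuous risk score arrives on the assay's native [-1, 1] scale and is
mapped to [0, 1] by (x + 1) / 2; the high/low decision boundary is 0 on the
raw scale, hence 0.5 after normalization (boundary inclusive on the
high-risk side).  Training minimizes a dual mean-squared-error:

    L = (1/B) * sum_i [ lam1 * (Y_i - Yhat_i)^2
                        + lam2 * 1(Y_i > 0.5) * (Y_i - Yhat_i)^2 ]

i.e. samples on the low-risk side of the boundary (normalized score > 0.5)
receive an extra squared-error term, emphasizing the class whose correct
identification spares patients overtreatment.

Optimization is Adam (beta1 = 0.9) on bags processed one at a time with
gradient accumulation over ``accum_size`` bags, a linear learning-rate decay
from 1e-4 to 1e-5 across the first 500 epochs (constant after), and early
stopping once the validation loss has not strictly decreased for
``patience`` consecutive epochs; the parameters achieving the minimum
validation loss are returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor
from .data import TileBag
from .model import ModelConfig, forward_with_graph, init_params

__all__ = [
    "TrainConfig",
    "CVPlan",
    "CVExperiment",
    "EarlyStopper",
    "normalize_mp_score",
    "assign_risk_group",
    "dual_mse_loss",
    "learning_rate_at",
    "make_cv_plan",
    "train_model",
]


# ---------------------------------------------------------------------------
# Labels and risk groups
# ---------------------------------------------------------------------------

def normalize_mp_score(x: float) -> float:
    """Map a raw score in [-1, 1] to [0, 1] via (x + 1) / 2."""
    x = float(x)
    if not -1.0 <= x <= 1.0:
        raise ValueError(f"raw score {x} outside [-1, 1]")
    return (x + 1.0) / 2.0


def assign_risk_group(score: float, scale: str = "raw") -> str:
    """Binary risk group from a continuous score.

    ``raw`` scale: score <= 0 -> ``high``, > 0 -> ``low``.
    ``normalized`` scale: score <= 0.5 -> ``high``, > 0.5 -> ``low``.
    The boundary is inclusive on the high-risk side on both scales, and the
    two scales agree through :func:`normalize_mp_score`.
    """
    score = float(score)
    if scale == "raw":
        if not -1.0 <= score <= 1.0:
            raise ValueError(f"raw score {score} outside [-1, 1]")
        return "high" if score <= 0.0 else "low"
    if scale == "normalized":
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"normalized score {score} outside [0, 1]")
        return "high" if score <= 0.5 else "low"
    raise ValueError(f"unknown scale {scale!r}; use 'raw' or 'normalized'")


def dual_mse_loss(
    Y: Sequence[float],
    Yhat: Sequence[float],
    lambda1: float = 1.0,
    lambda2: float = 1.0,
) -> float:
    """Batch dual-MSE objective (see module docstring)."""
    Y = np.asarray(Y, dtype=float)
    Yhat = np.asarray(Yhat, dtype=float)
    if Y.shape != Yhat.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {Yhat.shape}")
    sq = (Y - Yhat) ** 2
    return float(np.mean(lambda1 * sq + lambda2 * (Y > 0.5) * sq))


def learning_rate_at(epoch: int, config: "TrainConfig") -> float:
    """Linear decay from lr_init to lr_floor over lr_decay_epochs epochs."""
    frac = min(epoch, config.lr_decay_epochs) / config.lr_decay_epochs
    return config.lr_init + (config.lr_floor - config.lr_init) * frac


# ---------------------------------------------------------------------------
# Configuration and CV plans
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    lr_init: float = 1e-4
    lr_floor: float = 1e-5
    lr_decay_epochs: int = 500
    max_epochs: int = 1000
    patience: int = 50
    accum_size: int = 32
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_floor > self.lr_init:
            raise ValueError("lr_floor must be <= lr_init")
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")
        if self.accum_size < 1 or self.lr_decay_epochs < 1 or self.max_epochs < 1:
            raise ValueError("counts must be positive")


@dataclass
class CVExperiment:
    test: list[str]
    folds: list[list[str]]


@dataclass
class CVPlan:
    experiments: list[CVExperiment] = field(default_factory=list)


def _chunk_sizes(n: int, k: int) -> np.ndarray:
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    return sizes


def make_cv_plan(
    patient_ids: Sequence[str],
    times: int = 5,
    folds: int = 5,
    test_frac: float = 0.2,
    seed: int = 0,
    risk_groups: Optional[dict[str, str]] = None,
) -> CVPlan:
    """Patient-level repeated CV: per experiment a held-out test set
    (``test_frac`` of patients, stratified by risk group when given) and a
    partition of the remainder into ``folds`` near-equal validation folds.
    """
    patients = list(dict.fromkeys(patient_ids))  # de-dup, keep order
    n = len(patients)
    n_test = int(round(test_frac * n))
    if n - n_test < folds or n_test < 1:
        raise ValueError(
            f"{n} patients cannot support test_frac={test_frac} with {folds} folds"
        )
    rng = np.random.default_rng(seed)
    plan = CVPlan()
    for _ in range(times):
        if risk_groups:
            test: list[str] = []
            by_group: dict[str, list[str]] = {}
            for p in patients:
                by_group.setdefault(risk_groups.get(p, "?"), []).append(p)
            # proportional allocation, remainder to the largest groups
            groups = sorted(by_group, key=lambda g: -len(by_group[g]))
            alloc = {g: int(np.floor(test_frac * len(by_group[g]))) for g in groups}
            gi = 0
            while sum(alloc.values()) < n_test:
                alloc[groups[gi % len(groups)]] += 1
                gi += 1
            for g in groups:
                members = np.array(by_group[g])
                take = min(alloc[g], len(members))
                test.extend(rng.choice(members, size=take, replace=False).tolist())
            test = test[:n_test]
        else:
            test = rng.choice(np.array(patients), size=n_test, replace=False).tolist()
        rest = np.array([p for p in patients if p not in set(test)])
        rng.shuffle(rest)
        sizes = _chunk_sizes(len(rest), folds)
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        fold_sets = [rest[a:b].tolist() for a, b in zip(offsets[:-1], offsets[1:])]
        plan.experiments.append(CVExperiment(test=sorted(test), folds=fold_sets))
    return plan


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _bag_loss_node(bag: TileBag, params, model_config: ModelConfig):
    if bag.label_normalized is None:
        raise ValueError(f"bag {bag.slide_id} has no label")
    pred_node, prediction = forward_with_graph(bag, params, model_config)
    y = bag.label_normalized
    weight = model_config.lambda1 + model_config.lambda2 * (y > 0.5)
    diff = pred_node - y
    return (diff * diff).sum() * weight, prediction


def _validation_loss(bags, params, model_config) -> float:
    losses = []
    for bag in bags:
        node, _ = _bag_loss_node(bag, params, model_config)
        losses.append(float(node.data))
    return float(np.mean(losses))


class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without strict improvement.

    Tracks the epoch index of the best (minimum) value seen so far;
    ``update`` returns True when training should stop.
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = np.inf
        self.best_epoch: Optional[int] = None
        self.stall = 0

    def update(self, epoch: int, value: float) -> bool:
        if value < self.best:
            self.best = value
            self.best_epoch = epoch
            self.stall = 0
            return False
        self.stall += 1
        return self.stall >= self.patience


class _Adam:
    def __init__(self, params: dict[str, Tensor], config: TrainConfig):
        self.params = params
        self.c = config
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self, lr: float, grad_scale: float) -> None:
        self.t += 1
        c = self.c
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad * grad_scale
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g**2
            mhat = self.m[k] / (1 - c.beta1**self.t)
            vhat = self.v[k] / (1 - c.beta2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + c.eps)
            p.grad = None


def train_model(
    train_bags: Sequence[TileBag],
    val_bags: Sequence[TileBag],
    model_config: ModelConfig,
    train_config: Optional[TrainConfig] = None,
    params: Optional[dict[str, Tensor]] = None,
) -> tuple[dict[str, Tensor], list[dict]]:
    """Train on labeled bags, early-stopping on validation loss.

    Returns the parameters achieving the minimum recorded validation loss
    and a per-epoch history of learning rate and train/validation losses.
    """
    tc = train_config or TrainConfig()
    for bag in list(train_bags) + list(val_bags):
        if bag.label_normalized is None:
            raise ValueError(f"bag {bag.slide_id} is unlabeled")
    rng = np.random.default_rng(tc.seed)
    if params is None:
        params = init_params(model_config, seed=tc.seed)
    opt = _Adam(params, tc)

    stopper = EarlyStopper(tc.patience)
    best_params: dict[str, np.ndarray] = {k: v.data.copy() for k, v in params.items()}
    history: list[dict] = []

    order = np.arange(len(train_bags))
    for epoch in range(tc.max_epochs):
        lr = learning_rate_at(epoch, tc)
        rng.shuffle(order)
        epoch_losses = []
        window = 0
        for idx in order:
            node, _ = _bag_loss_node(train_bags[idx], params, model_config)
            loss_val = float(node.data)
            if not np.isfinite(loss_val):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            epoch_losses.append(loss_val)
            node.backward()  # grads accumulate across bags in the window
            window += 1
            if window == tc.accum_size:
                opt.step(lr, grad_scale=1.0 / window)
                window = 0
        if window:  # partial final accumulation window still steps
            opt.step(lr, grad_scale=1.0 / window)

        val_loss = _validation_loss(val_bags, params, model_config)
        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
            }
        )
        improved = val_loss < stopper.best
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_params = {k: v.data.copy() for k, v in params.items()}
        if stop:
            break

    out = {k: Tensor(v, requires_grad=True) for k, v in best_params.items()}
    return out, history
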