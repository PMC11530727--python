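"""Losses and the concordance correlation coefficient (CCC).

The multitask objective follows the dynamic restrained uncertainty
weighting (DRUW) scheme: each task k carries a log-variance parameter
s_k = log sigma_k^2, its loss is weighted by w_k = exp(-s_k)/2 =
1/(2 sigma_k^2), a log-regularizer sum_k s_k/2 keeps the variances from
growing without bound, and a restraint lambda * (sum_k w_k - tau)^2
regulates the total weight so no trivial all-weights-to-zero solution
exists.  The same functional form is reused for the two-modality fusion
penalty in the model core.

CCC = 2 rho sigma_x sigma_y / (sigma_x^2 + sigma_y^2 + (mu_x - mu_y)^2)
with population (divisor n) moments throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Parameter, Tensor

__all__ = [
    "CccStats", "ccc", "ccc_values",
    "TaskUncertainty", "LossBreakdown", "druw_multitask_loss",
    "task_loss", "equal_weight_loss", "fixed_weight_loss", "summed_loss",
]


# -- concordance correlation coefficient --------------------------------------

@dataclass
class CccStats:
    ccc: float
    rho: float
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    degenerate: bool = False


def ccc(pred, true) -> CccStats:
    """Concordance correlation coefficient between predictions and targets.

    Uses population moments.  If either series is constant the coefficient
    is 0 (degenerate agreement); requires at least two points.
    """
    x = np.asarray(pred, dtype=float).ravel()
    y = np.asarray(true, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("CCC needs at least 2 points")
    mu_x, mu_y = x.mean(), y.mean()
    sigma_x, sigma_y = x.std(), y.std()
    cov = ((x - mu_x) * (y - mu_y)).mean()
    if sigma_x == 0.0 or sigma_y == 0.0:
        return CccStats(0.0, 0.0, mu_x, mu_y, sigma_x, sigma_y, degenerate=True)
    rho = cov / (sigma_x * sigma_y)
    value = 2.0 * cov / (sigma_x ** 2 + sigma_y ** 2 + (mu_x - mu_y) ** 2)
    return CccStats(float(value), float(rho), float(mu_x), float(mu_y),
                    float(sigma_x), float(sigma_y))


def ccc_values(pred: np.ndarray, true: np.ndarray) -> np.ndarray:
    """Column-wise CCC for (N, K) prediction/target matrices."""
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    true = np.atleast_2d(np.asarray(true, dtype=float))
    return np.array([ccc(pred[:, k], true[:, k]).ccc for k in range(pred.shape[1])])


def _ccc_tensor(pred_col: Tensor, true_col: np.ndarray) -> Tensor:
    """Differentiable CCC of one prediction column against fixed targets."""
    y = np.asarray(true_col, dtype=float)
    mu_y, var_y = y.mean(), y.var()
    mu_x = pred_col.mean()
    centered = pred_col - mu_x
    var_x = (centered ** 2).mean()
    cov = (centered * Tensor(y - mu_y)).mean()
    return 2.0 * cov / (var_x + var_y + (mu_x - mu_y) ** 2)


# -- per-task losses -----------------------------------------------------------

def task_loss(pred, true, kind: str = "mse") -> Tensor:
    """Per-task losses over a batch: (B, K) predictions and targets -> (K,).

    ``mse`` is the default training loss; ``one_minus_ccc`` optimizes
    agreement directly but needs batches of at least 2.
    """
    true = np.asarray(true.data if isinstance(true, Tensor) else true, dtype=float)
    if not isinstance(pred, Tensor):
        pred = Tensor(pred)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    if kind == "mse":
        return ((pred - Tensor(true)) ** 2).mean(axis=0)
    if kind == "one_minus_ccc":
        if pred.shape[0] < 2:
            raise ValueError("one_minus_ccc needs a batch of at least 2")
        from .nn import stack
        cols = [1.0 - _ccc_tensor(take_col(pred, k), true[:, k])
                for k in range(pred.shape[1])]
        return stack(cols)
    raise ValueError(f"unknown task loss kind {kind!r}")


def take_col(t: Tensor, k: int) -> Tensor:
    """Column k of a (B, K) tensor as a (B,) tensor."""
    b, width = t.shape
    picker = np.zeros((width, 1))
    picker[k, 0] = 1.0
    return (t @ Tensor(picker)).reshape(b)


# -- DRUW multitask weighting ---------------------------------------------------

class TaskUncertainty:
    """Learnable per-task log-variances s_k with restraint settings.

    Weights are w_k = exp(-s_k)/2; the restraint target tau defaults to
    K/2 so the symmetric initialization s = 0 (all sigma = 1) is
    penalty-free.
    """

    def __init__(self, n_tasks: int, restraint_coefficient: float = 0.1,
                 restraint_target: float | None = None):
        if restraint_coefficient < 0:
            raise ValueError("restraint coefficient must be >= 0")
        self.n_tasks = int(n_tasks)
        self.s = Parameter(np.zeros(self.n_tasks))
        self.lam = float(restraint_coefficient)
        self.tau = float(restraint_target if restraint_target is not None
                         else self.n_tasks / 2.0)

    def weights(self) -> Tensor:
        return (-self.s).exp() * 0.5

    def parameters(self) -> list[Parameter]:
        return [self.s]

    def state_dict(self):
        return {"s": self.s.data.copy()}

    def load_state_dict(self, state):
        self.s.data = np.asarray(state["s"], dtype=float).copy()


@dataclass
class LossBreakdown:
    per_task: np.ndarray
    weights: np.ndarray
    weighted_sum: float
    log_term: float
    restraint: float
    total: float
    total_tensor: Tensor  # differentiable total, for the training step

    def as_dict(self) -> dict:
        return {"per_task": self.per_task.tolist(),
                "weights": self.weights.tolist(),
                "weighted_sum": self.weighted_sum,
                "log_term": self.log_term,
                "restraint": self.restraint,
                "total": self.total}


def druw_multitask_loss(per_task, uncertainty: TaskUncertainty) -> LossBreakdown:
    """DRUW total: sum_k w_k L_k + sum_k s_k/2 + lambda (sum_k w_k - tau)^2."""
    losses = per_task if isinstance(per_task, Tensor) else Tensor(np.asarray(per_task, float))
    if losses.shape != (uncertainty.n_tasks,):
        raise ValueError(f"expected {uncertainty.n_tasks} per-task losses, got {losses.shape}")
    if not np.isfinite(losses.data).all():
        raise ValueError("non-finite per-task losses")
    w = uncertainty.weights()
    weighted = (w * losses).sum()
    log_term = uncertainty.s.sum() * 0.5
    restraint = (w.sum() - uncertainty.tau) ** 2 * uncertainty.lam
    total = weighted + log_term + restraint
    return LossBreakdown(per_task=losses.data.copy(), weights=w.data.copy(),
                         weighted_sum=float(weighted.data),
                         log_term=float(log_term.data),
                         restraint=float(restraint.data),
                         total=float(total.data), total_tensor=total)


# -- baseline multitask weightings ----------------------------------------------

def equal_weight_loss(per_task) -> Tensor:
    losses = per_task if isinstance(per_task, Tensor) else Tensor(np.asarray(per_task, float))
    return losses.mean()


def summed_loss(per_task) -> Tensor:
    losses = per_task if isinstance(per_task, Tensor) else Tensor(np.asarray(per_task, float))
    return losses.sum()


def fixed_weight_loss(per_task, weights) -> Tensor:
    losses = per_task if isinstance(per_task, Tensor) else Tensor(np.asarray(per_task, float))
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any():
        raise ValueError("fixed task weights must be >= 0")
    if weights.shape != losses.shape:
        raise ValueError("weights and losses must have the same length")
    return (losses * Tensor(weights)).sum()
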