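"""Training loop, model selection, CCC evaluation tables, and the
mixed-model within-individual validation.

The optimization schedule is the study's standard recipe: SGD with
Nesterov momentum 0.9, initial learning rate 0.001 decayed by 0.9
whenever the development-set mean CCC fails to improve for 5 consecutive
epochs, batch size 16, weight decay 1e-4 (applied to network weights
only, never to log-variance uncertainty parameters or the macro-micro
blending factor), up to 100 epochs, and selection of the epoch with the
best development mean CCC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import EMOTIONS, Dataset, SplitIndex
from .model import EmotionModel, druw_fuse
from .nn import SGD, Tensor
from .objectives import (TaskUncertainty, ccc, ccc_values, druw_multitask_loss,
                         equal_weight_loss, fixed_weight_loss, summed_loss,
                         task_loss)

MODALITY_MASKS = ("zcm", "pim", "speech", "all")


@dataclass
class TrainConfig:
    epochs: int = 100
    initial_lr: float = 0.001
    momentum: float = 0.9
    nesterov: bool = True
    lr_decay_factor: float = 0.9
    lr_patience: int = 5
    batch_size: int = 16
    weight_decay: float = 0.0001
    min_improvement: float = 1e-6   # strict-increase threshold for "improvement"
    mtl: str = "druw"               # equal | fixed_weighted | multioutput | druw
    task_loss: str = "mse"          # mse | one_minus_ccc
    fixed_task_weights: tuple | None = None
    task_restraint_coefficient: float = 0.1
    task_restraint_target: float | None = None
    modality_mask: str = "all"
    # frequency compensation for per-participant layers: each is updated by
    # ~1/P of the batches, so its learning rate is scaled by the number of
    # participants ("auto") or an explicit factor
    personal_lr_scale: float | str = "auto"
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.lr_patience) < 1:
            raise ValueError("epochs, batch_size and lr_patience must be >= 1")
        if min(self.initial_lr, self.lr_decay_factor) <= 0:
            raise ValueError("learning-rate settings must be positive")
        if self.modality_mask not in MODALITY_MASKS:
            raise ValueError(f"unknown modality mask {self.modality_mask!r}")


# -- learning-rate plateau schedule ---------------------------------------------

def lr_schedule_step(history, current_lr: float, patience: int = 5,
                     factor: float = 0.9, min_improvement: float = 1e-6) -> float:
    """Reduce the learning rate after ``patience`` consecutive epochs with
    no improvement of the development metric over the best seen before them.
    """
    history = list(history)
    if not history:
        raise ValueError("history must be non-empty")
    best = -np.inf
    bad = 0
    for value in history:
        if value > best + min_improvement:
            best = value
            bad = 0
        else:
            bad += 1
    return current_lr * factor if bad >= patience else current_lr


class PlateauScheduler:
    """Stateful plateau schedule: the patience counter resets on decay."""

    def __init__(self, lr: float, patience: int = 5, factor: float = 0.9,
                 min_improvement: float = 1e-6):
        self.lr = float(lr)
        self.patience = int(patience)
        self.factor = float(factor)
        self.min_improvement = float(min_improvement)
        self.best = -np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> float:
        if metric > self.best + self.min_improvement:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.lr *= self.factor
                self.bad_epochs = 0
        return self.lr


# -- checkpoints -----------------------------------------------------------------

@dataclass
class Checkpoint:
    model_state: dict
    task_state: dict | None
    participant_ids: list[str]
    speech_dim: int
    fusion: str
    personalization: str
    best_epoch: int
    best_dev_ccc: float
    config: dict = field(default_factory=dict)

    def save(self, prefix) -> None:
        """Write <prefix>.npz (parameters) and <prefix>.json (metadata)."""
        arrays = {f"model::{k}": v for k, v in self.model_state.items()}
        if self.task_state is not None:
            arrays.update({f"task::{k}": v for k, v in self.task_state.items()})
        np.savez(f"{prefix}.npz", **arrays)
        with open(f"{prefix}.json", "w") as fh:
            json.dump({"participant_ids": self.participant_ids,
                       "speech_dim": self.speech_dim,
                       "fusion": self.fusion,
                       "personalization": self.personalization,
                       "best_epoch": self.best_epoch,
                       "best_dev_ccc": self.best_dev_ccc,
                       "config": self.config}, fh, indent=1)

    @classmethod
    def load(cls, prefix) -> "Checkpoint":
        with open(f"{prefix}.json") as fh:
            meta = json.load(fh)
        blob = np.load(f"{prefix}.npz")
        model_state = {k[len("model::"):]: blob[k] for k in blob.files
                       if k.startswith("model::")}
        task_state = {k[len("task::"):]: blob[k] for k in blob.files
                      if k.startswith("task::")} or None
        return cls(model_state=model_state, task_state=task_state, **meta)

    def build_model(self, model_config=None) -> EmotionModel:
        from .model import ModelConfig
        cfg = ModelConfig(**self.config) if self.config else (model_config or ModelConfig())
        model = EmotionModel(self.participant_ids, self.speech_dim, config=cfg,
                             fusion=self.fusion,
                             personalization=self.personalization)
        model.load_state_dict(self.model_state)
        return model


# -- batching helpers -------------------------------------------------------------

def _masked_inputs(dataset: Dataset, index: np.ndarray, mask: str):
    zcm = dataset.zcm[index]
    pim = dataset.pim[index]
    speech = dataset.speech[index]
    if mask != "all":
        if mask != "zcm":
            zcm = np.zeros_like(zcm)
        if mask != "pim":
            pim = np.zeros_like(pim)
        if mask != "speech":
            speech = np.zeros_like(speech)
    return zcm, pim, speech


def predict_records(model: EmotionModel, dataset: Dataset, index: np.ndarray,
                    modality_mask: str = "all", batch_size: int = 256) -> np.ndarray:
    """Deterministic (dropout-off) predictions for the given rows."""
    was_training = model.training
    model.eval()
    preds = []
    for start in range(0, len(index), batch_size):
        rows = index[start:start + batch_size]
        zcm, pim, speech = _masked_inputs(dataset, rows, modality_mask)
        out, _ = model(zcm, pim, speech, dataset.participant_ids[rows])
        preds.append(out.data)
    if was_training:
        model.train()
    return np.concatenate(preds, axis=0) if preds else np.zeros((0, len(EMOTIONS)))


def _combine_loss(per_task: Tensor, config: TrainConfig,
                  uncertainty: TaskUncertainty | None):
    if config.mtl == "druw":
        breakdown = druw_multitask_loss(per_task, uncertainty)
        return breakdown.total_tensor, breakdown
    if config.mtl == "equal":
        return equal_weight_loss(per_task), None
    if config.mtl == "multioutput":
        return summed_loss(per_task), None
    if config.mtl == "fixed_weighted":
        weights = (np.asarray(config.fixed_task_weights, float)
                   if config.fixed_task_weights is not None
                   else np.full(len(EMOTIONS), 1.0 / len(EMOTIONS)))
        return fixed_weight_loss(per_task, weights), None
    raise ValueError(f"unknown mtl kind {config.mtl!r}")


# -- training ---------------------------------------------------------------------

def train(model: EmotionModel, dataset: Dataset, split: SplitIndex,
          config: TrainConfig) -> tuple[Checkpoint, list[dict]]:
    """Train and return (best checkpoint by dev mean CCC, per-epoch history).

    ``dataset`` must be cleaned, label-normalized, standardized, and
    consistent with ``split``.
    """
    if not dataset.labels_normalized:
        raise ValueError("labels must be normalized to [0, 1] before training")
    train_idx, dev_idx = split.train, split.dev
    if train_idx.size == 0 or dev_idx.size == 0:
        raise ValueError("train and dev splits must be non-empty")

    rng = np.random.default_rng(config.seed)
    uncertainty = (TaskUncertainty(len(EMOTIONS), config.task_restraint_coefficient,
                                   config.task_restraint_target)
                   if config.mtl == "druw" else None)
    groups = [{"params": model.decay_parameters(), "weight_decay": config.weight_decay},
              {"params": model.no_decay_parameters(), "weight_decay": 0.0}]
    personal = model.personal_parameters()
    if personal:
        scale = (float(len(model.participant_ids))
                 if config.personal_lr_scale == "auto"
                 else float(config.personal_lr_scale))
        groups.append({"params": personal, "weight_decay": config.weight_decay,
                       "lr_scale": scale})
    if uncertainty is not None:
        groups.append({"params": uncertainty.parameters(), "weight_decay": 0.0})
    optimizer = SGD(groups, lr=config.initial_lr, momentum=config.momentum,
                    nesterov=config.nesterov)
    scheduler = PlateauScheduler(config.initial_lr, config.lr_patience,
                                 config.lr_decay_factor, config.min_improvement)

    history: list[dict] = []
    best = {"dev_ccc": -np.inf, "epoch": -1, "model": None, "task": None}

    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        n_batches = 0
        last_breakdown = None
        for start in range(0, len(order), config.batch_size):
            rows = order[start:start + config.batch_size]
            zcm, pim, speech = _masked_inputs(dataset, rows, config.modality_mask)
            preds, fusion_penalty = model(zcm, pim, speech,
                                          dataset.participant_ids[rows])
            per_task = task_loss(preds, dataset.labels[rows], config.task_loss)
            total, breakdown = _combine_loss(per_task, config, uncertainty)
            total = total + fusion_penalty
            if not np.isfinite(total.data):
                raise RuntimeError(f"non-finite loss at epoch {epoch}, batch {n_batches}")
            optimizer.zero_grad()
            total.backward()
            optimizer.step()
            epoch_loss += float(total.data)
            n_batches += 1
            last_breakdown = breakdown

        dev_pred = predict_records(model, dataset, dev_idx, config.modality_mask)
        dev_ccc = float(ccc_values(dev_pred, dataset.labels[dev_idx]).mean())
        row = {"epoch": epoch, "lr": optimizer.lr,
               "train_loss": epoch_loss / max(n_batches, 1),
               "dev_mean_ccc": dev_ccc}
        if model.fusion_params is not None:
            row["fusion_weights"] = model.fusion_params.weights().data.tolist()
        if last_breakdown is not None:
            row["task_weights"] = last_breakdown.weights.tolist()
        history.append(row)

        if dev_ccc > best["dev_ccc"]:
            best.update(dev_ccc=dev_ccc, epoch=epoch,
                        model=model.state_dict(),
                        task=uncertainty.state_dict() if uncertainty else None)
        optimizer.lr = scheduler.step(dev_ccc)

    model.load_state_dict(best["model"])
    if uncertainty is not None and best["task"] is not None:
        uncertainty.load_state_dict(best["task"])
    checkpoint = Checkpoint(
        model_state=best["model"], task_state=best["task"],
        participant_ids=model.participant_ids, speech_dim=model.speech_dim,
        fusion=model.fusion_kind, personalization=model.personalization_kind,
        best_epoch=int(best["epoch"]), best_dev_ccc=float(best["dev_ccc"]),
        config={})
    return checkpoint, history


# -- evaluation -------------------------------------------------------------------

@dataclass
class EvalTable:
    """Per-emotion CCC over one split part, plus mean (SD) across emotions."""

    emotions: tuple[str, ...]
    ccc: np.ndarray
    part: str
    modality_mask: str = "all"

    @property
    def mean(self) -> float:
        return float(np.mean(self.ccc))

    @property
    def sd(self) -> float:
        return float(np.std(self.ccc))  # population SD, matching CCC moments

    def to_frame(self) -> pd.DataFrame:
        row = {e: v for e, v in zip(self.emotions, self.ccc)}
        row["mean"] = self.mean
        row["sd"] = self.sd
        return pd.DataFrame([row], index=[f"{self.part}/{self.modality_mask}"])

    def __str__(self) -> str:
        cells = "  ".join(f"{e}={v:.3f}" for e, v in zip(self.emotions, self.ccc))
        return f"[{self.part}/{self.modality_mask}] {cells}  mean={self.mean:.3f} (SD {self.sd:.3f})"


def evaluate(model: EmotionModel, dataset: Dataset, split: SplitIndex,
             part: str = "test", modality_mask: str = "all") -> EvalTable:
    """Pooled per-emotion CCC of model predictions on one split part."""
    if modality_mask not in MODALITY_MASKS:
        raise ValueError(f"unknown modality mask {modality_mask!r}")
    index = split.part(part)
    preds = predict_records(model, dataset, index, modality_mask)
    values = ccc_values(preds, dataset.labels[index])
    return EvalTable(emotions=EMOTIONS, ccc=values, part=part,
                     modality_mask=modality_mask)


# -- mixed-model within-individual validation ---------------------------------------

@dataclass
class MixedModelRow:
    emotion: str
    intercept: float
    coefficient: float
    se: float
    z_score: float
    p_value: float
    ci_low: float
    ci_high: float
    group_variance: float
    residual_variance: float
    flagged: bool = False


def within_individual_validation(predictions, observations, participant_ids
                                 ) -> list[MixedModelRow]:
    """Per emotion, regress observed on predicted with a participant-level
    random intercept (statsmodels MixedLM) and report the standard schema.

    Singular or non-converged fits are flagged per emotion, not fatal.
    """
    import statsmodels.api as sm

    predictions = np.asarray(predictions, dtype=float)
    observations = np.asarray(observations, dtype=float)
    pids = np.asarray(participant_ids).astype(str)
    if predictions.shape != observations.shape or predictions.shape[0] != pids.shape[0]:
        raise ValueError("predictions, observations and participant_ids must align")
    if len(np.unique(pids)) < 2:
        raise ValueError("mixed-model validation needs at least 2 participants")

    rows: list[MixedModelRow] = []
    for k, emotion in enumerate(EMOTIONS[:predictions.shape[1]]):
        x = sm.add_constant(predictions[:, k])
        y = observations[:, k]
        flagged = False
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fit = sm.MixedLM(y, x, groups=pids).fit(reml=True)
                flagged = any("converge" in str(w.message).lower()
                              or "singular" in str(w.message).lower()
                              or "boundary" in str(w.message).lower()
                              for w in caught)
            coef = float(fit.params[1])
            se = float(fit.bse[1])
            ci = fit.conf_int()
            rows.append(MixedModelRow(
                emotion=emotion,
                intercept=float(fit.params[0]),
                coefficient=coef, se=se,
                z_score=float(fit.tvalues[1]),
                p_value=float(fit.pvalues[1]),
                ci_low=float(np.asarray(ci)[1, 0]),
                ci_high=float(np.asarray(ci)[1, 1]),
                group_variance=float(np.asarray(fit.cov_re)[0, 0]),
                residual_variance=float(fit.scale),
                flagged=flagged or not np.isfinite(se),
            ))
        except (np.linalg.LinAlgError, ValueError):
            rows.append(MixedModelRow(emotion=emotion, intercept=np.nan,
                                      coefficient=np.nan, se=np.nan,
                                      z_score=np.nan, p_value=np.nan,
                                      ci_low=np.nan, ci_high=np.nan,
                                      group_variance=np.nan,
                                      residual_variance=np.nan, flagged=True))
    return rows


def mixed_model_frame(rows: list[MixedModelRow]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in rows]).set_index("emotion")
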