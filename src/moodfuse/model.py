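"""Forward path of the macro-micro multimodal model.

Pipeline per record:

1. ZCM, PIM, and speech feature vectors each pass through their own
   2-layer feed-forward encoder to a common width d.
2. The two actigraphy streams are merged into one physical-activity
   stream (concatenation + projection), because the fusion stage weights
   exactly two modalities: physical activity and speech.
3. DRUW fusion combines the streams with uncertainty-derived weights
   w_m = exp(-s_m)/2 and contributes a penalty
   sum_m s_m/2 + lambda_f (sum_m w_m - tau_f)^2 to the objective.
4. The macro stage (shared across participants) applies an emotional
   FFNN to the fused vector, then runs the triple (emotional, phys,
   speech) as a 3-token sequence with learned token-type embeddings
   through one transformer encoder layer and mean-pools into the macro
   embedding M.
5. The micro stage personalizes: P_i = alpha * M + (1 - alpha) * FFNN_i(M)
   with one small residual FFNN per participant (identity at
   initialization, so personalization grows out of the macro solution).
   Unknown participants fall back to M (alpha forced to 1).
6. Nine sigmoid heads map P_i to the emotion predictions in (0, 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import baselines
from .data import EMOTIONS, N_EPOCHS
from .nn import (FeedForward, Linear, Module, Parameter, Tensor,
                 TransformerEncoderLayer, concat, stack, take_rows)

logger = logging.getLogger(__name__)


@dataclass
class EncoderConfig:
    input_dim: int
    hidden_dim: int = 128
    output_dim: int = 128
    dropout: float = 0.1

    def __post_init__(self):
        if min(self.input_dim, self.hidden_dim, self.output_dim) < 1:
            raise ValueError("encoder dimensions must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    def build(self, rng: np.random.Generator) -> FeedForward:
        return FeedForward(self.input_dim, self.hidden_dim, self.output_dim,
                           rng, dropout=self.dropout)


@dataclass
class ModelConfig:
    embed_dim: int = 128
    hidden_dim: int = 128
    dropout: float = 0.1
    n_heads: int = 4
    ff_multiplier: int = 4
    alpha: float = 0.5
    alpha_learnable: bool = False
    fusion_restraint_coefficient: float = 0.1
    fusion_restraint_target: float | None = None  # default M/2 for M modalities
    three_way_fusion: bool = False  # fuse zcm/pim/speech as 3 streams

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


class FusionParameters(Module):
    """Per-modality log-variances s_m with the fusion restraint settings."""

    def __init__(self, n_modalities: int = 2, restraint_coefficient: float = 0.1,
                 restraint_target: float | None = None):
        super().__init__()
        if restraint_coefficient < 0:
            raise ValueError("restraint coefficient must be >= 0")
        self.n_modalities = int(n_modalities)
        self.s = Parameter(np.zeros(self.n_modalities))
        self.lam = float(restraint_coefficient)
        self.tau = float(restraint_target if restraint_target is not None
                         else self.n_modalities / 2.0)

    def weights(self) -> Tensor:
        return (-self.s).exp() * 0.5


def druw_fuse(streams, params: FusionParameters) -> tuple[Tensor, Tensor]:
    """Uncertainty-weighted sum of modality streams plus the fusion penalty.

    ``streams`` is a sequence of (B, d) tensors, one per modality, in the
    order matching ``params.s``.  Returns (fused, penalty) where penalty =
    sum_m s_m/2 + lambda (sum_m w_m - tau)^2.
    """
    if isinstance(streams, Tensor):
        raise TypeError("streams must be a sequence of modality tensors")
    streams = [Tensor._wrap(h) for h in streams]
    if len(streams) != params.n_modalities:
        raise ValueError(f"expected {params.n_modalities} streams, got {len(streams)}")
    if not np.isfinite(params.s.data).all():
        raise ValueError("non-finite fusion parameters")
    w = params.weights()
    fused = None
    for m, h in enumerate(streams):
        term = take_rows(w, [m]) * h
        fused = term if fused is None else fused + term
    penalty = params.s.sum() * 0.5 + (w.sum() - params.tau) ** 2 * params.lam
    return fused, penalty


class MicroLayerBank(Module):
    """Per-participant residual FFNN layers blended with the macro embedding.

    P_i = alpha * M + (1 - alpha) * (M + f_i(M)) where f_i is a 1-hidden-
    layer perturbation with zero-initialized output weights, so every
    micro layer starts as the identity.  alpha may be fixed or learned
    per participant through a logistic reparameterization.
    """

    def __init__(self, participant_ids, dim: int, rng: np.random.Generator,
                 alpha: float = 0.5, alpha_learnable: bool = False,
                 dropout: float = 0.0):
        super().__init__()
        self.dim = dim
        self.alpha_fixed = float(alpha)
        self.alpha_learnable = bool(alpha_learnable)
        self.registry = {str(p): i for i, p in enumerate(participant_ids)}
        self.layers = {str(p): FeedForward(dim, dim, dim, rng, dropout=dropout,
                                           zero_init_out=True)
                       for p in participant_ids}
        if alpha_learnable:
            # logit(alpha); logistic keeps alpha in (0, 1) during learning
            init = float(np.log(alpha / (1.0 - alpha))) if 0 < alpha < 1 else 0.0
            self.alpha_logits = {str(p): Parameter(np.array(init))
                                 for p in participant_ids}
        self._warned: set[str] = set()

    def alpha(self, pid: str) -> Tensor | float:
        if self.alpha_learnable:
            return self.alpha_logits[pid].sigmoid()
        return self.alpha_fixed

    def forward_one(self, M: Tensor, pid: str) -> Tensor:
        """Personalize a (B, d) macro embedding for a single participant."""
        if pid not in self.layers:
            if pid not in self._warned:
                logger.warning("unknown participant %s: macro passthrough (alpha=1)", pid)
                self._warned.add(pid)
            return M
        a = self.alpha(pid)
        micro = M + self.layers[pid](M)
        if isinstance(a, Tensor):
            return a * M + (1.0 - a) * micro
        return M * a + micro * (1.0 - a)

    def __call__(self, M: Tensor, pids: np.ndarray) -> Tensor:
        """Personalize a batch, grouping rows by participant."""
        pids = np.asarray(pids).astype(str)
        order: list[np.ndarray] = []
        chunks: list[Tensor] = []
        for pid in dict.fromkeys(pids):
            rows = np.flatnonzero(pids == pid)
            order.append(rows)
            chunks.append(self.forward_one(take_rows(M, rows), pid))
        perm = np.concatenate(order)
        inverse = np.argsort(perm)
        return take_rows(concat(chunks, axis=0), inverse)


class PredictionHeads(Module):
    """Nine linear heads (one per emotion) followed by the logistic map."""

    def __init__(self, dim: int, rng: np.random.Generator, n_tasks: int = len(EMOTIONS)):
        super().__init__()
        self.linear = Linear(dim, n_tasks, rng)

    def __call__(self, p: Tensor) -> Tensor:
        return self.linear(p).sigmoid()


class EmotionModel(Module):
    """Configurable macro-micro model covering the full comparison grid.

    ``fusion`` and ``personalization`` select a grid variant; the defaults
    build the proposed model (DRUW fusion + macro-micro personalization).
    """

    def __init__(self, participant_ids, speech_dim: int,
                 config: ModelConfig | None = None, fusion: str = "druw",
                 personalization: str = "macromicro", seed: int = 0):
        super().__init__()
        cfg = config or ModelConfig()
        self.config = cfg
        self.fusion_kind = fusion
        self.personalization_kind = personalization
        self.participant_ids = [str(p) for p in participant_ids]
        self.speech_dim = int(speech_dim)
        rng = np.random.default_rng(seed)
        d, h, drop = cfg.embed_dim, cfg.hidden_dim, cfg.dropout

        self.enc_zcm = EncoderConfig(N_EPOCHS, h, d, drop).build(rng)
        self.enc_pim = EncoderConfig(N_EPOCHS, h, d, drop).build(rng)
        self.enc_speech = EncoderConfig(speech_dim, h, d, drop).build(rng)
        self.phys_proj = Linear(2 * d, d, rng)

        n_streams = 3 if cfg.three_way_fusion else 2
        if fusion == "druw":
            self.fusion_params = FusionParameters(
                n_streams, cfg.fusion_restraint_coefficient,
                cfg.fusion_restraint_target)
            self.fusion_module = None
        else:
            if cfg.three_way_fusion:
                raise ValueError("three-way fusion is only available with DRUW fusion")
            self.fusion_params = None
            self.fusion_module = baselines.make_fusion(fusion, d, rng)

        self.use_emotional_ffnn = personalization != "transformer_only"
        self.emotional_ffnn = FeedForward(d, d, d, rng, dropout=drop)
        self.token_type = Parameter(rng.normal(0.0, 0.02, size=(3, d)))
        self.encoder_layer = TransformerEncoderLayer(
            d, cfg.n_heads, cfg.ff_multiplier * d, rng, dropout=drop)

        if personalization == "macromicro":
            self.micro = MicroLayerBank(self.participant_ids, d, rng,
                                        alpha=cfg.alpha,
                                        alpha_learnable=cfg.alpha_learnable)
            self.personal = None
        elif personalization == "adapter":
            self.micro = None
            self.personal = {pid: baselines.Adapter(d, rng)
                             for pid in self.participant_ids}
        elif personalization == "basic_ffnn":
            self.micro = None
            self.personal = baselines.SharedFFNN(d, rng, dropout=drop)
        elif personalization in ("none", "transformer_only"):
            self.micro = None
            self.personal = None
        else:
            raise ValueError(f"unknown personalization {personalization!r}")

        self.heads = PredictionHeads(d, rng)

    # -- stage-level operations ------------------------------------------------

    def encode_modalities(self, zcm, pim, speech) -> tuple[Tensor, Tensor, Tensor]:
        """Encode (B, 60) / (B, 60) / (B, D) standardized inputs to (B, d)."""
        zcm, pim, speech = Tensor._wrap(zcm), Tensor._wrap(pim), Tensor._wrap(speech)
        if speech.shape[-1] != self.speech_dim:
            raise ValueError(f"speech width {speech.shape[-1]} != {self.speech_dim}")
        return self.enc_zcm(zcm), self.enc_pim(pim), self.enc_speech(speech)

    def combine_physiological(self, h_zcm: Tensor, h_pim: Tensor) -> Tensor:
        return self.phys_proj(concat([h_zcm, h_pim], axis=-1))

    def macro_forward(self, fused: Tensor, h_phys: Tensor, h_speech: Tensor) -> Tensor:
        e = self.emotional_ffnn(fused) if self.use_emotional_ffnn else fused
        tokens = stack([e, h_phys, h_speech], axis=1) + self.token_type
        return self.encoder_layer(tokens).mean(axis=1)

    def personalize(self, M: Tensor, pids: np.ndarray) -> Tensor:
        if self.micro is not None:
            return self.micro(M, pids)
        if isinstance(self.personal, dict):  # per-participant adapters
            pids = np.asarray(pids).astype(str)
            order, chunks = [], []
            for pid in dict.fromkeys(pids):
                rows = np.flatnonzero(pids == pid)
                order.append(rows)
                chunk = take_rows(M, rows)
                chunks.append(self.personal[pid](chunk) if pid in self.personal else chunk)
            inverse = np.argsort(np.concatenate(order))
            return take_rows(concat(chunks, axis=0), inverse)
        if self.personal is not None:  # shared FFNN
            return self.personal(M)
        return M

    def predict_heads(self, p: Tensor) -> Tensor:
        return self.heads(p)

    # -- full forward -----------------------------------------------------------

    def forward(self, zcm, pim, speech, pids) -> tuple[Tensor, Tensor]:
        """Full forward pass; returns (predictions (B, 9), fusion penalty)."""
        h_zcm, h_pim, h_speech = self.encode_modalities(zcm, pim, speech)
        if self.config.three_way_fusion and self.fusion_params is not None:
            fused, penalty = druw_fuse([h_zcm, h_pim, h_speech], self.fusion_params)
            h_phys = self.combine_physiological(h_zcm, h_pim)
        else:
            h_phys = self.combine_physiological(h_zcm, h_pim)
            if self.fusion_params is not None:
                fused, penalty = druw_fuse([h_phys, h_speech], self.fusion_params)
            else:
                fused = self.fusion_module(h_phys, h_speech)
                penalty = Tensor(0.0)
        M = self.macro_forward(fused, h_phys, h_speech)
        P = self.personalize(M, pids)
        return self.predict_heads(P), penalty

    __call__ = forward

    def no_decay_parameters(self) -> list[Parameter]:
        """Uncertainty and blending parameters exempt from weight decay."""
        out: list[Parameter] = []
        if self.fusion_params is not None:
            out.append(self.fusion_params.s)
        if self.micro is not None and self.micro.alpha_learnable:
            out.extend(self.micro.alpha_logits.values())
        return out

    def personal_parameters(self) -> list[Parameter]:
        """Per-participant parameters (micro layers / adapters).

        Each participant's layer is touched only by that participant's
        records, i.e. roughly 1/P of the batches; the trainer compensates
        with a frequency-scaled learning rate for this group.
        """
        out: list[Parameter] = []
        if self.micro is not None:
            for layer in self.micro.layers.values():
                out.extend(p for _, p in layer.named_parameters())
        if isinstance(self.personal, dict):
            for adapter in self.personal.values():
                out.extend(p for _, p in adapter.named_parameters())
        return out

    def decay_parameters(self) -> list[Parameter]:
        skip = {id(p) for p in self.no_decay_parameters()}
        skip |= {id(p) for p in self.personal_parameters()}
        return [p for p in self.parameters() if id(p) not in skip]
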