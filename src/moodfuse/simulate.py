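"""Synthetic EMA data generator.

Emulates a two-week ecological-momentary-assessment study: each
participant is prompted five times a day (on waking, around 11 AM / 3 PM /
7 PM with a few minutes of jitter, and at bedtime) and each prompt yields
a 60-minute actigraphy window (ZCM counts and PIM intensities), a speech
feature vector, and nine 0-100 mood ratings.

The generative model is a per-participant latent AR(1) affect state
z_t in R^q (dimensions interpreted as valence, arousal, distress) with
unit stationary variance.  Mood labels are a logistic squash of a linear
read-out of the state plus participant-specific structure:

    labels = 100 * logistic(B_i z_t + c + u_i + eps),   B_i = B + dB_i

where u_i is a per-participant offset (between-subject heterogeneity),
dB_i a per-participant loading perturbation, and eps measurement noise.
ZCM windows are Poisson with a rate modulated by the arousal dimension,
PIM windows log-normal with a log-mean shifted by the same dimension, and
speech features are a linear encoding of the full state plus a
participant voiceprint and SNR-controlled noise.  Ground truth (latent
states, offsets, noiseless labels) is returned alongside the dataset so
recovery experiments can score models against the generative process.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data import EMOTIONS, N_EPOCHS, Dataset

LATENT_NAMES = ("valence", "arousal", "distress")
AROUSAL = 1  # index of the arousal dimension in the latent state

# Fixed read-out pattern: rows are emotions (canonical order), columns the
# latent dimensions (valence, arousal, distress).  Positive moods load on
# +valence, depressive moods on -valence/+distress, anxious moods on
# +distress.  Scaled so within-person label fluctuation is ~8 VAS points.
_B_PATTERN = np.array([
    [0.90,  0.60,  0.00],   # vigorous
    [-0.80, -0.30, 0.50],   # gloomy
    [-0.20, 0.20,  0.90],   # concerned
    [1.00,  0.20, -0.30],   # happy
    [-0.70, 0.10,  0.60],   # unpleasant
    [-0.20, 0.50,  0.90],   # anxious
    [0.95,  0.40, -0.20],   # cheerful
    [-0.90, -0.40, 0.60],   # depressed
    [-0.10, 0.30,  1.00],   # worried
])
DEFAULT_LOADING = 0.35 * _B_PATTERN


def _default_snr() -> dict[str, float]:
    return {"speech": 4.0, "zcm": 4.0, "pim": 4.0}


@dataclass
class SimulatorConfig:
    n_participants: int = 30          # paper-scale study: 298
    n_days: int = 14
    prompts_per_day: int = 5          # 3 fixed clock prompts + wake + bed
    jitter_minutes: float = 10.0
    speech_dim: int = 1024
    latent_dim: int = 3
    ar_coefficient: float = 0.6
    loading_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_LOADING.copy())
    label_intercept: np.ndarray = field(default_factory=lambda: np.zeros(len(EMOTIONS)))
    subject_offset_sd: float = 0.15   # tau_u, logit scale
    subject_loading_sd: float = 0.1
    label_noise_sd: float = 0.05      # logit scale
    zcm_base_rate: float = 30.0       # counts per 1-min epoch at neutral arousal
    pim_base_level: float = 200.0     # intensity units at neutral arousal
    zcm_gain: float = 0.5             # log-rate shift per unit arousal
    pim_gain: float = 0.4             # log-level shift per unit arousal
    pim_log_sd: float = 0.5
    voiceprint_sd: float = 0.5
    modality_snr: dict[str, float] = field(default_factory=_default_snr)
    speech_latent_mask: tuple[bool, ...] = (True, True, True)
    dropout_rate: float = 0.0         # optional uniform record missingness
    start_date: str = "2024-01-08"
    seed: int = 0

    def validate(self):
        if min(self.n_participants, self.n_days, self.prompts_per_day,
               self.speech_dim, self.latent_dim) < 1:
            raise ValueError("counts and dimensions must be positive")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must be in [0, 1)")
        for name in ("jitter_minutes", "subject_offset_sd", "subject_loading_sd",
                     "label_noise_sd", "pim_log_sd", "voiceprint_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.zcm_base_rate, self.pim_base_level) <= 0:
            raise ValueError("base activity levels must be positive")
        if any(v < 0 for v in self.modality_snr.values()):
            raise ValueError("modality SNRs must be >= 0")
        B = np.asarray(self.loading_matrix, dtype=float)
        if B.shape != (len(EMOTIONS), self.latent_dim) or not np.isfinite(B).all():
            raise ValueError(f"loading_matrix must be finite {len(EMOTIONS)}x{self.latent_dim}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if len(self.speech_latent_mask) != self.latent_dim:
            raise ValueError("speech_latent_mask length must equal latent_dim")


@dataclass
class GroundTruth:
    """Generative state aligned 1:1 with the dataset's (sorted) records."""

    participant_ids: np.ndarray           # (N,)
    latent: np.ndarray                    # (N, q)
    noiseless_labels: np.ndarray          # (N, 9) on [0, 1]
    subject_offsets: dict[str, list[float]]        # pid -> 9-vector (logit scale)
    loading_perturbations: dict[str, list[list[float]]]  # pid -> 9 x q

    def __eq__(self, other):
        if not isinstance(other, GroundTruth):
            return NotImplemented
        return (np.array_equal(self.participant_ids, other.participant_ids)
                and np.allclose(self.latent, other.latent)
                and np.allclose(self.noiseless_labels, other.noiseless_labels)
                and self.subject_offsets == other.subject_offsets
                and self.loading_perturbations == other.loading_perturbations)


def _snr_gain(snr: float) -> float:
    """Amplitude scale in [0, 1): 0 at SNR 0, -> 1 as SNR -> inf."""
    return float(np.sqrt(snr / (1.0 + snr)))


def zcm_window(rng: np.random.Generator, base_rate: float, gain: float,
               z_arousal: float, n: int = N_EPOCHS) -> np.ndarray:
    """Poisson counts with log-rate shifted by the arousal state."""
    return rng.poisson(base_rate * np.exp(gain * z_arousal), size=n).astype(float)


def pim_window(rng: np.random.Generator, base_level: float, gain: float,
               log_sd: float, z_arousal: float, n: int = N_EPOCHS) -> np.ndarray:
    """Log-normal intensities; log-mean offset keeps E[pim] = base_level at z=0."""
    mu = np.log(base_level) + gain * z_arousal - 0.5 * log_sd ** 2
    return np.exp(rng.normal(mu, log_sd, size=n))


def _prompt_times(rng: np.random.Generator, cfg: SimulatorConfig,
                  day_origin: np.datetime64) -> np.ndarray:
    jit = cfg.jitter_minutes
    if cfg.prompts_per_day == 5:
        # wake, three fixed clock prompts (11 AM / 3 PM / 7 PM), bed
        minutes = [7 * 60 + rng.uniform(-30, 30),
                   11 * 60 + rng.uniform(-jit, jit),
                   15 * 60 + rng.uniform(-jit, jit),
                   19 * 60 + rng.uniform(-jit, jit),
                   23 * 60 + rng.uniform(-30, 30)]
    else:
        anchors = np.linspace(8 * 60, 22 * 60, cfg.prompts_per_day)
        minutes = [a + rng.uniform(-jit, jit) for a in anchors]
    seconds = np.sort(np.asarray(minutes) * 60.0).astype(np.int64)
    seconds = np.maximum.accumulate(seconds + np.arange(len(seconds)))  # strict order
    return day_origin + seconds.astype("timedelta64[s]")


def simulate_dataset(config: SimulatorConfig) -> tuple[Dataset, GroundTruth]:
    """Generate a synthetic EMA dataset plus its generative ground truth.

    Labels in the returned dataset are on the raw 0-100 VAS scale, as a
    real study export would be; ``noiseless_labels`` in the ground truth
    are on [0, 1].
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    q = cfg.latent_dim
    B = np.asarray(cfg.loading_matrix, dtype=float)
    c = np.asarray(cfg.label_intercept, dtype=float)
    phi = cfg.ar_coefficient
    innov_sd = np.sqrt(1.0 - phi ** 2)

    # dataset-wide speech encoder: rows ~ N(0, 1/q) so each feature has
    # roughly unit signal variance; masked latent dims are silent
    W = rng.normal(0.0, 1.0 / np.sqrt(q), size=(cfg.speech_dim, q))
    W *= np.asarray(cfg.speech_latent_mask, dtype=float)
    a_speech = _snr_gain(cfg.modality_snr.get("speech", 0.0))
    noise_sd_speech = float(np.sqrt(1.0 / (1.0 + cfg.modality_snr.get("speech", 0.0))))
    g_zcm = cfg.zcm_gain * _snr_gain(cfg.modality_snr.get("zcm", 0.0))
    g_pim = cfg.pim_gain * _snr_gain(cfg.modality_snr.get("pim", 0.0))

    width = len(str(cfg.n_participants))
    origin = np.datetime64(cfg.start_date, "s")

    pids, times = [], []
    zcm_rows, pim_rows, speech_rows, label_rows = [], [], [], []
    latents, clean_rows = [], []
    offsets: dict[str, list[float]] = {}
    perturbs: dict[str, list[list[float]]] = {}

    for i in range(cfg.n_participants):
        pid = f"P{i + 1:0{width}d}"
        u_i = rng.normal(0.0, cfg.subject_offset_sd, size=len(EMOTIONS))
        dB_i = rng.normal(0.0, cfg.subject_loading_sd, size=B.shape)
        v_i = rng.normal(0.0, cfg.voiceprint_sd, size=cfg.speech_dim)
        offsets[pid] = u_i.tolist()
        perturbs[pid] = dB_i.tolist()
        B_i = B + dB_i
        z = rng.normal(0.0, 1.0, size=q)  # stationary start
        for day in range(cfg.n_days):
            day_times = _prompt_times(rng, cfg, origin + np.timedelta64(day, "D").astype("timedelta64[s]"))
            for t in day_times:
                z = phi * z + innov_sd * rng.normal(0.0, 1.0, size=q)
                logit_clean = B_i @ z + c + u_i
                eps = rng.normal(0.0, cfg.label_noise_sd, size=len(EMOTIONS))
                labels = np.clip(100.0 * expit(logit_clean + eps), 0.0, 100.0)
                zcm = zcm_window(rng, cfg.zcm_base_rate, g_zcm, z[AROUSAL])
                pim = pim_window(rng, cfg.pim_base_level, g_pim, cfg.pim_log_sd, z[AROUSAL])
                speech = (a_speech * (W @ z) + v_i
                          + noise_sd_speech * rng.normal(0.0, 1.0, size=cfg.speech_dim))
                pids.append(pid)
                times.append(t)
                zcm_rows.append(zcm)
                pim_rows.append(pim)
                speech_rows.append(speech)
                label_rows.append(labels)
                latents.append(z.copy())
                clean_rows.append(expit(logit_clean))

    keep = np.arange(len(pids))
    if cfg.dropout_rate > 0:
        keep = keep[rng.random(len(pids)) >= cfg.dropout_rate]

    pid_arr = np.asarray(pids, dtype=object)[keep]
    dataset = Dataset(pid_arr, np.asarray(times)[keep],
                      np.asarray(zcm_rows)[keep], np.asarray(pim_rows)[keep],
                      np.asarray(speech_rows)[keep], np.asarray(label_rows)[keep],
                      labels_normalized=False, sort=True)
    # generation order (participant, then time) matches the sorted order
    truth = GroundTruth(participant_ids=pid_arr,
                        latent=np.asarray(latents)[keep],
                        noiseless_labels=np.asarray(clean_rows)[keep],
                        subject_offsets=offsets,
                        loading_perturbations=perturbs)
    return dataset, truth


def export_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump({
            "participant_ids": [str(p) for p in truth.participant_ids],
            "latent": truth.latent.tolist(),
            "noiseless_labels": truth.noiseless_labels.tolist(),
            "subject_offsets": truth.subject_offsets,
            "loading_perturbations": truth.loading_perturbations,
        }, fh)


def load_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        blob = json.load(fh)
    return GroundTruth(
        participant_ids=np.asarray(blob["participant_ids"], dtype=object),
        latent=np.asarray(blob["latent"]),
        noiseless_labels=np.asarray(blob["noiseless_labels"]),
        subject_offsets={k: list(v) for k, v in blob["subject_offsets"].items()},
        loading_perturbations={k: [list(r) for r in v]
                               for k, v in blob["loading_perturbations"].items()},
    )
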