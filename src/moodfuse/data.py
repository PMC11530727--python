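"""EMA record tables: domain types, I/O, preprocessing, and time splits.

One record is a single ecological-momentary-assessment prompt: a 60-epoch
(1-minute) window of wrist actigraphy counts in zero-crossing mode (ZCM)
and proportional-integration mode (PIM) preceding the prompt, a
fixed-width speech feature vector extracted from the voice sample, and
nine self-rated emotion intensities on a 0-100 visual-analogue scale
(the DAMS items: vigorous, gloomy, concerned, happy, unpleasant, anxious,
cheerful, depressed, worried).

Preprocessing follows the standard EMA-regression recipe: drop corrupt
records, normalize labels to [0, 1], z-score the signal channels using
statistics fit on the training portion only, and split each participant's
records chronologically 70/15/15.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EMOTIONS: tuple[str, ...] = (
    "vigorous", "gloomy", "concerned", "happy", "unpleasant",
    "anxious", "cheerful", "depressed", "worried",
)
N_EMOTIONS = len(EMOTIONS)
N_EPOCHS = 60  # 1-minute actigraphy epochs per window (1 hour)

DEFAULT_FRACTIONS = (0.70, 0.15, 0.15)


@dataclass
class EmaRecord:
    """A single prompt's multimodal observation."""

    participant_id: str
    timestamp: np.datetime64
    zcm: np.ndarray          # (60,) zero-crossing counts per epoch
    pim: np.ndarray          # (60,) integrated acceleration per epoch
    speech_features: np.ndarray  # (D,)
    labels: np.ndarray       # (9,) canonical EMOTIONS order


class Dataset:
    """Column-oriented collection of EMA records, sorted by (participant, time).

    ``labels_normalized`` records whether labels are on the raw 0-100 VAS
    scale or the model's [0, 1] scale.
    """

    def __init__(self, participant_ids, timestamps, zcm, pim, speech, labels,
                 labels_normalized: bool = False, sort: bool = True):
        self.participant_ids = np.asarray(participant_ids, dtype=object)
        self.timestamps = np.asarray(timestamps, dtype="datetime64[s]")
        self.zcm = np.asarray(zcm, dtype=np.float64)
        self.pim = np.asarray(pim, dtype=np.float64)
        self.speech = np.asarray(speech, dtype=np.float64)
        self.labels = np.asarray(labels, dtype=np.float64)
        self.labels_normalized = labels_normalized
        n = len(self.participant_ids)
        for name, arr, width in (("zcm", self.zcm, N_EPOCHS), ("pim", self.pim, N_EPOCHS),
                                 ("labels", self.labels, N_EMOTIONS)):
            if arr.shape != (n, width):
                raise ValueError(f"{name} must have shape ({n}, {width}), got {arr.shape}")
        if self.speech.ndim != 2 or self.speech.shape[0] != n:
            raise ValueError("speech must be a (n_records, D) matrix")
        if sort and n:
            order = np.lexsort((np.arange(n), self.timestamps,
                                self.participant_ids.astype(str)))
            self._reorder(order)

    def _reorder(self, order):
        self.participant_ids = self.participant_ids[order]
        self.timestamps = self.timestamps[order]
        self.zcm = self.zcm[order]
        self.pim = self.pim[order]
        self.speech = self.speech[order]
        self.labels = self.labels[order]

    # -- basic protocol -----------------------------------------------------

    @property
    def speech_dim(self) -> int:
        return self.speech.shape[1]

    def __len__(self) -> int:
        return len(self.participant_ids)

    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for pid in self.participant_ids:
            seen.setdefault(str(pid))
        return list(seen)

    def record(self, i: int) -> EmaRecord:
        return EmaRecord(str(self.participant_ids[i]), self.timestamps[i],
                         self.zcm[i], self.pim[i], self.speech[i], self.labels[i])

    def records(self):
        return (self.record(i) for i in range(len(self)))

    def subset(self, index, sort: bool = False) -> "Dataset":
        index = np.asarray(index)
        return Dataset(self.participant_ids[index], self.timestamps[index],
                       self.zcm[index], self.pim[index], self.speech[index],
                       self.labels[index], self.labels_normalized, sort=sort)

    def copy(self) -> "Dataset":
        return Dataset(self.participant_ids.copy(), self.timestamps.copy(),
                       self.zcm.copy(), self.pim.copy(), self.speech.copy(),
                       self.labels.copy(), self.labels_normalized, sort=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (self.labels_normalized == other.labels_normalized
                and np.array_equal(self.participant_ids, other.participant_ids)
                and np.array_equal(self.timestamps, other.timestamps)
                and np.array_equal(self.zcm, other.zcm)
                and np.array_equal(self.pim, other.pim)
                and np.array_equal(self.speech, other.speech)
                and np.array_equal(self.labels, other.labels))

    def validate(self):
        """Check per-participant strictly increasing timestamps."""
        for pid in self.participants():
            ts = self.timestamps[self.participant_ids.astype(str) == pid]
            if len(ts) > 1 and not np.all(np.diff(ts).astype(np.int64) > 0):
                raise ValueError(f"timestamps not strictly increasing for {pid}")


# -- CSV dialect -------------------------------------------------------------

def _columns(speech_dim: int) -> list[str]:
    return (["participant_id", "timestamp"]
            + [f"zcm_{i:02d}" for i in range(N_EPOCHS)]
            + [f"pim_{i:02d}" for i in range(N_EPOCHS)]
            + [f"sf_{i:04d}" for i in range(speech_dim)]
            + [f"label_{e}" for e in EMOTIONS])


def write_ema_table(dataset: Dataset, path) -> None:
    cols = _columns(dataset.speech_dim)
    frame = pd.DataFrame(
        np.concatenate([dataset.zcm, dataset.pim, dataset.speech, dataset.labels], axis=1),
        columns=cols[2:])
    frame.insert(0, "participant_id", dataset.participant_ids.astype(str))
    frame.insert(1, "timestamp", np.datetime_as_string(dataset.timestamps, unit="s"))
    frame.to_csv(path, index=False)


def read_ema_table(path) -> Dataset:
    """Read an EMA CSV table; labels stay on the raw 0-100 VAS scale."""
    frame = pd.read_csv(path, dtype={"participant_id": str},
                        float_precision="round_trip")
    speech_cols = [c for c in frame.columns if c.startswith("sf_")]
    expected = _columns(len(speech_cols))
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise ValueError(f"EMA table {path} is missing columns: {missing[:8]}")
    try:
        timestamps = pd.to_datetime(frame["timestamp"], format="ISO8601").to_numpy()
    except (ValueError, TypeError) as exc:
        bad = pd.to_datetime(frame["timestamp"], format="ISO8601", errors="coerce")
        rows = list(frame.index[bad.isna()][:5])
        raise ValueError(f"unparseable timestamps at rows {rows} in {path}") from exc
    numeric = frame[expected[2:]]
    if numeric.isna().to_numpy().any():
        rows = list(frame.index[numeric.isna().any(axis=1)][:5])
        raise ValueError(f"ragged or non-numeric rows at {rows} in {path}")
    zcm = numeric[[f"zcm_{i:02d}" for i in range(N_EPOCHS)]].to_numpy(float)
    pim = numeric[[f"pim_{i:02d}" for i in range(N_EPOCHS)]].to_numpy(float)
    speech = numeric[speech_cols].to_numpy(float)
    labels = numeric[[f"label_{e}" for e in EMOTIONS]].to_numpy(float)
    return Dataset(frame["participant_id"].to_numpy(object), timestamps,
                   zcm, pim, speech, labels, labels_normalized=False)


# -- cleansing & normalization ------------------------------------------------

@dataclass
class CleanReport:
    n_input: int
    n_kept: int
    dropped_nonfinite: int = 0
    dropped_negative_counts: int = 0
    dropped_label_range: int = 0
    empty_output: bool = False

    @property
    def n_dropped(self) -> int:
        return self.n_input - self.n_kept


def clean_records(dataset: Dataset) -> tuple[Dataset, CleanReport]:
    """Drop corrupt records; each record is counted under its first violation.

    Violations, checked in order: any non-finite value in any channel; any
    negative zcm/pim entry; any label outside the 0-100 VAS range.
    """
    wide = np.concatenate([dataset.zcm, dataset.pim, dataset.speech, dataset.labels], axis=1)
    nonfinite = ~np.isfinite(wide).all(axis=1)
    with np.errstate(invalid="ignore"):
        negative = ((dataset.zcm < 0).any(axis=1) | (dataset.pim < 0).any(axis=1)) & ~nonfinite
        hi = 1.0 if dataset.labels_normalized else 100.0
        bad_label = (((dataset.labels < 0) | (dataset.labels > hi)).any(axis=1)
                     & ~nonfinite & ~negative)
    keep = ~(nonfinite | negative | bad_label)
    report = CleanReport(
        n_input=len(dataset), n_kept=int(keep.sum()),
        dropped_nonfinite=int(nonfinite.sum()),
        dropped_negative_counts=int(negative.sum()),
        dropped_label_range=int(bad_label.sum()),
        empty_output=not keep.any(),
    )
    return dataset.subset(np.flatnonzero(keep)), report


def normalize_labels(dataset: Dataset) -> Dataset:
    """Rescale 0-100 VAS labels to [0, 1]."""
    if dataset.labels_normalized:
        raise ValueError("labels are already normalized")
    if ((dataset.labels < 0) | (dataset.labels > 100)).any():
        raise ValueError("labels outside [0, 100]; run clean_records first")
    out = dataset.copy()
    out.labels = out.labels / 100.0
    out.labels_normalized = True
    return out


# -- time-based partitioning ---------------------------------------------------

@dataclass
class SplitIndex:
    """Per-participant chronological train/dev/test row assignment.

    Indices are 0-based positions into the (sorted) dataset.
    """

    per_participant: dict[str, dict[str, list[int]]]
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS

    def _gather(self, part: str) -> np.ndarray:
        idx: list[int] = []
        for pid in self.per_participant:
            idx.extend(self.per_participant[pid][part])
        return np.asarray(sorted(idx), dtype=np.intp)

    @property
    def train(self) -> np.ndarray:
        return self._gather("train")

    @property
    def dev(self) -> np.ndarray:
        return self._gather("dev")

    @property
    def test(self) -> np.ndarray:
        return self._gather("test")

    def part(self, name: str) -> np.ndarray:
        if name not in ("train", "dev", "test"):
            raise ValueError(f"unknown split part {name!r}")
        return self._gather(name)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"fractions": list(self.fractions),
                       "per_participant": self.per_participant}, fh, indent=1)

    @classmethod
    def load(cls, path) -> "SplitIndex":
        with open(path) as fh:
            blob = json.load(fh)
        return cls(per_participant=blob["per_participant"],
                   fractions=tuple(blob["fractions"]))


def partition_by_time(dataset: Dataset,
                      fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
                      ) -> SplitIndex:
    """Chronological per-participant split (default 70/15/15).

    Counts are floor(f_train*n) / floor(f_dev*n) with the remainder going
    to test; whenever a participant has at least 3 records, each split is
    topped up to at least one record (taking from the largest neighbour),
    so every participant appears in all three parts.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    counts = pd.Series(dataset.participant_ids.astype(str)).value_counts()
    offenders = sorted(counts.index[counts < 3])
    if offenders:
        raise ValueError(f"participants with fewer than 3 records: {offenders}")
    pids = dataset.participant_ids.astype(str)
    per: dict[str, dict[str, list[int]]] = {}
    for pid in dataset.participants():
        rows = np.flatnonzero(pids == pid)  # dataset is time-sorted per participant
        n = len(rows)
        n_train = int(np.floor(fractions[0] * n))
        n_dev = int(np.floor(fractions[1] * n))
        n_test = n - n_train - n_dev
        # minimum-occupancy adjustment: one record per split when n >= 3
        while n_dev < 1:
            if n_train >= n_test and n_train > 1:
                n_train -= 1
            else:
                n_test -= 1
            n_dev += 1
        while n_test < 1:
            if n_train > 1:
                n_train -= 1
            else:
                n_dev -= 1
            n_test += 1
        while n_train < 1:
            if n_dev >= n_test and n_dev > 1:
                n_dev -= 1
            else:
                n_test -= 1
            n_train += 1
        per[pid] = {
            "train": [int(r) for r in rows[:n_train]],
            "dev": [int(r) for r in rows[n_train:n_train + n_dev]],
            "test": [int(r) for r in rows[n_train + n_dev:]],
        }
    return SplitIndex(per_participant=per, fractions=tuple(fractions))


# -- standardization ------------------------------------------------------------

@dataclass
class StandardizationStats:
    """Train-split channel moments: scalar for zcm/pim, per-dim for speech.

    Population (divisor n) moments.  Channels with zero variance get SD 1
    and are listed in ``flagged``.
    """

    zcm_mean: float
    zcm_sd: float
    pim_mean: float
    pim_sd: float
    speech_mean: np.ndarray
    speech_sd: np.ndarray
    flagged: list[str] = field(default_factory=list)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"zcm_mean": self.zcm_mean, "zcm_sd": self.zcm_sd,
                       "pim_mean": self.pim_mean, "pim_sd": self.pim_sd,
                       "speech_mean": self.speech_mean.tolist(),
                       "speech_sd": self.speech_sd.tolist(),
                       "flagged": self.flagged}, fh)

    @classmethod
    def load(cls, path) -> "StandardizationStats":
        with open(path) as fh:
            blob = json.load(fh)
        return cls(zcm_mean=blob["zcm_mean"], zcm_sd=blob["zcm_sd"],
                   pim_mean=blob["pim_mean"], pim_sd=blob["pim_sd"],
                   speech_mean=np.asarray(blob["speech_mean"]),
                   speech_sd=np.asarray(blob["speech_sd"]),
                   flagged=list(blob["flagged"]))


def _moments(values: np.ndarray, axis=None):
    mean = values.mean(axis=axis)
    sd = values.std(axis=axis)  # population convention (divisor n)
    return mean, sd


def fit_standardization(dataset: Dataset, split: SplitIndex) -> StandardizationStats:
    """Fit channel moments on the training split only (no leakage)."""
    train = split.train
    if train.size == 0:
        raise ValueError("training split is empty")
    flagged: list[str] = []
    zm, zs = _moments(dataset.zcm[train])
    if zs == 0:
        zs = 1.0
        flagged.append("zcm")
    pm, ps = _moments(dataset.pim[train])
    if ps == 0:
        ps = 1.0
        flagged.append("pim")
    sm, ss = _moments(dataset.speech[train], axis=0)
    zero = ss == 0
    if zero.any():
        flagged.extend(f"sf_{i:04d}" for i in np.flatnonzero(zero))
        ss = np.where(zero, 1.0, ss)
    return StandardizationStats(float(zm), float(zs), float(pm), float(ps),
                                sm, ss, flagged)


def preprocess(dataset: Dataset,
               fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
               ) -> tuple["Dataset", SplitIndex, "StandardizationStats", CleanReport]:
    """Full preprocessing chain: clean, normalize labels, split by time,
    fit standardization on the training part, and apply it everywhere."""
    cleaned, report = clean_records(dataset)
    normalized = normalize_labels(cleaned)
    split = partition_by_time(normalized, fractions)
    stats = fit_standardization(normalized, split)
    return apply_standardization(normalized, stats), split, stats, report


def apply_standardization(dataset: Dataset, stats: StandardizationStats) -> Dataset:
    """Z-score zcm/pim/speech channels; labels are untouched."""
    if stats.speech_mean.shape[0] != dataset.speech_dim:
        raise ValueError("standardization stats were fit on a different speech width")
    out = dataset.copy()
    out.zcm = (out.zcm - stats.zcm_mean) / stats.zcm_sd
    out.pim = (out.pim - stats.pim_mean) / stats.pim_sd
    out.speech = (out.speech - stats.speech_mean) / stats.speech_sd
    return out
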