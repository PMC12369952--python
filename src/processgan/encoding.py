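"""Fixed-length numeric encodings of process cases for the adversarial models.

A case becomes: a padded one-hot activity matrix, a sequence of timestamp
differentials (gap to the preceding event divided by the case duration,
position 1 fixed at 0, zero-padded), a min-max normalized duration, and the
antisymmetric pairwise time-interval matrix built from cumulative scaled
timestamps.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .event_log_io import ActivityVocabulary, EventLog, ProcessCase, case_duration

__all__ = [
    "EncodedCase", "TimeIntervalMatrix", "normalize_duration",
    "compute_differentials", "pad_and_onehot", "build_time_interval_matrix",
    "encode_case", "encode_log",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class TimeIntervalMatrix:
    """Pairwise scaled time intervals M[i, j] = ts'_i - ts'_j (antisymmetric)."""

    M: np.ndarray

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=np.float64)
        if self.M.ndim != 2 or self.M.shape[0] != self.M.shape[1]:
            raise ValueError(f"time-interval matrix must be square, got {self.M.shape}")


@dataclasses.dataclass
class EncodedCase:
    activity_onehot: np.ndarray      # (max_length, vocab_size) one-hot rows
    differentials: np.ndarray        # (max_length,) in [0, 1], zero at pads
    duration_norm: float
    duration_real: float
    length: int                      # count of non-pad positions

    def interval_matrix(self) -> TimeIntervalMatrix:
        return build_time_interval_matrix(self.differentials)


def normalize_duration(t_real: float, bounds: tuple[float, float],
                       clamp: bool = False) -> float:
    """Min-max map of a case duration into [0, 1]; degenerate bounds give 0."""
    t_min, t_max = bounds
    if t_max == t_min:
        return 0.0
    if not clamp and not (t_min <= t_real <= t_max):
        raise ValueError(f"duration {t_real} outside bounds ({t_min}, {t_max})")
    return float(np.clip((t_real - t_min) / (t_max - t_min), 0.0, 1.0))


def denormalize_duration(t_norm: float, bounds: tuple[float, float]) -> float:
    t_min, t_max = bounds
    return t_norm * (t_max - t_min) + t_min


def compute_differentials(case: ProcessCase, max_length: int) -> np.ndarray:
    """Per-position timestamp differentials scaled by case duration.

    Position 1 is 0 by convention; non-pad differentials telescope to 1 for
    any case with a positive duration. Zero-duration cases encode as all
    zeros with a warning.
    """
    n = len(case)
    if n > max_length:
        raise ValueError(f"case {case.case_id!r} length {n} exceeds {max_length}")
    out = np.zeros(max_length, dtype=np.float64)
    t_real = case_duration(case)
    if t_real == 0.0:
        if n > 1:
            logger.warning("case %s has zero duration; all-zero differentials",
                           case.case_id)
        return out
    ts = case.timestamps
    out[1:n] = np.diff(ts) / t_real
    return out


def pad_and_onehot(case: ProcessCase, max_length: int,
                   vocab: ActivityVocabulary) -> np.ndarray:
    n = len(case)
    if n > max_length:
        raise ValueError(f"case {case.case_id!r} length {n} exceeds {max_length}")
    indices = [vocab.index(a) for a in case.activities]
    indices += [vocab.pad_index] * (max_length - n)
    onehot = np.zeros((max_length, vocab.size), dtype=np.float64)
    onehot[np.arange(max_length), indices] = 1.0
    return onehot


def build_time_interval_matrix(differentials: np.ndarray) -> TimeIntervalMatrix:
    diffs = np.asarray(differentials, dtype=np.float64)
    if not np.all(np.isfinite(diffs)):
        raise ValueError("differentials must be finite")
    ts = np.cumsum(diffs)
    return TimeIntervalMatrix(ts[:, None] - ts[None, :])


def encode_case(case: ProcessCase, max_length: int, vocab: ActivityVocabulary,
                bounds: tuple[float, float], clamp_duration: bool = False) -> EncodedCase:
    t_real = case_duration(case)
    return EncodedCase(
        activity_onehot=pad_and_onehot(case, max_length, vocab),
        differentials=compute_differentials(case, max_length),
        duration_norm=normalize_duration(t_real, bounds, clamp=clamp_duration),
        duration_real=t_real,
        length=len(case),
    )


def encode_log(log: EventLog, max_length: int | None = None) -> list[EncodedCase]:
    """Encode every case; max length defaults to the longest case in the log."""
    if max_length is None:
        max_length = log.max_length
    return [encode_case(c, max_length, log.vocabulary, log.duration_bounds)
            for c in log.cases]
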