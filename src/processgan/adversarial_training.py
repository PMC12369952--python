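"""Adversarial losses, auxiliary-weight calibration, the alternating training
schedule, equilibrium checkpoint selection, and decoding of generator output
back into an event log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ._autograd import Tensor, as_tensor
from ._nn import Adam, Module
from .encoding import denormalize_duration, encode_log
from .event_log_io import Event, EventLog, ProcessCase, build_event_log
from .generator import (Generator, GeneratorOutput, gumbel_straight_through,
                        sample_random_input)
__all__ = [
    "TrainingConfig", "LossReport", "Checkpoint",
    "generator_adversarial_loss", "discriminator_loss",
    "activity_divergence_loss", "timestamp_divergence_loss",
    "calibrate_aux_weights", "estimate_loss_expectations", "train", "select_equilibrium_checkpoint",
    "map_timestamps", "generate_log", "interval_matrix_batch",
    "save_checkpoint", "load_checkpoint",
]

logger = logging.getLogger(__name__)

LOG_EPS = 1e-8


@dataclasses.dataclass
class TrainingConfig:
    epochs: int
    batch_size: int = 32
    k: int = 2                       # generator epochs per discriminator epoch
    lr_g: float = 1e-3
    lr_d: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    checkpoint_interval: int = 50
    calibration_epochs: int = 3
    aux_weights: tuple[float, float] | str = "auto"
    max_aux_weight: float = 1e6
    holdout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.checkpoint_interval < 1:
            raise ValueError("checkpoint_interval must be >= 1")


@dataclasses.dataclass
class LossReport:
    epochs: list[int] = dataclasses.field(default_factory=list)
    loss_g: list[float] = dataclasses.field(default_factory=list)
    loss_d: list[float] = dataclasses.field(default_factory=list)
    loss_ga: list[float] = dataclasses.field(default_factory=list)
    loss_gt: list[float] = dataclasses.field(default_factory=list)
    d_accuracy: list[float] = dataclasses.field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": self.epochs, "loss_g": self.loss_g, "loss_d": self.loss_d,
            "loss_ga": self.loss_ga, "loss_gt": self.loss_gt,
            "d_accuracy": self.d_accuracy,
        })


@dataclasses.dataclass
class Checkpoint:
    epoch: int
    g_state: dict[str, np.ndarray]
    d_state: dict[str, np.ndarray]
    d_accuracy: float
    sample: EventLog | None = None
    sample_seed: int | None = None


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _safe_log(scores: Tensor) -> Tensor:
    if np.any(scores.data <= 0.0):
        logger.warning("discriminator score <= 0 clamped to %.0e", LOG_EPS)
    return scores.clip_min(LOG_EPS).log()


def generator_adversarial_loss(d_scores_synthetic) -> Tensor:
    """-mean(log D(G(z|T)))."""
    scores = as_tensor(d_scores_synthetic)
    return -_safe_log(scores).mean()


def discriminator_loss(d_authentic, d_synthetic) -> Tensor:
    """-mean(log D(x)) - mean(log(1 - D(G(z|T))))."""
    auth = as_tensor(d_authentic)
    syn = as_tensor(d_synthetic)
    return -_safe_log(auth).mean() - _safe_log(1.0 - syn).mean()


def activity_divergence_loss(authentic_onehot, synthetic_onehot,
                             n_real: int) -> Tensor:
    """MSE between within-batch activity frequency profiles.

    Frequencies are proportions over all batch x length positions (pad
    positions stay in the denominator); the squared-difference sum runs over
    the ``n_real`` non-pad activity types and is divided by m * n_real.
    """
    auth = as_tensor(authentic_onehot)
    syn = as_tensor(synthetic_onehot)
    m = auth.shape[0]
    if syn.shape[0] != m:
        raise ValueError("batch sizes differ")
    freq_auth = auth.mean(axis=0).mean(axis=0)      # (Nv,)
    freq_syn = syn.mean(axis=0).mean(axis=0)
    gap = (freq_auth - freq_syn)[:n_real]
    return (gap * gap).sum() / (m * n_real)


def timestamp_divergence_loss(authentic_onehot, authentic_diffs,
                              synthetic_onehot, synthetic_diffs,
                              n_real: int) -> Tensor:
    """MSE of the per-activity mean cumulative scaled timestamps.

    Occurrence-weighted means are pooled over the whole batch; an activity
    absent from a batch contributes a mean of 0 on that side.
    """
    def per_activity_mean(onehot: Tensor, diffs: Tensor) -> Tensor:
        ts = diffs.cumsum(axis=-1)                       # (m, l)
        weighted = onehot * ts.expand_dims(-1)           # (m, l, Nv)
        sums = weighted.sum(axis=0).sum(axis=0)          # (Nv,)
        counts = onehot.sum(axis=0).sum(axis=0)
        return sums / counts.clip_min(LOG_EPS)

    auth_oh, syn_oh = as_tensor(authentic_onehot), as_tensor(synthetic_onehot)
    auth_t, syn_t = as_tensor(authentic_diffs), as_tensor(synthetic_diffs)
    m = auth_oh.shape[0]
    if syn_oh.shape[0] != m:
        raise ValueError("batch sizes differ")
    gap = (per_activity_mean(auth_oh, auth_t)
           - per_activity_mean(syn_oh, syn_t))[:n_real]
    return (gap * gap).sum() / (m * n_real)


def interval_matrix_batch(diffs: Tensor) -> Tensor:
    """Batched antisymmetric time-interval matrices from differentials."""
    ts = diffs.cumsum(axis=-1)                           # (b, l)
    return ts.expand_dims(-1) - ts.expand_dims(1)        # (b, l, l)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _stack_batch(encoded, idx):
    onehot = np.stack([encoded[i].activity_onehot for i in idx])
    diffs = np.stack([encoded[i].differentials for i in idx])
    dur = np.array([encoded[i].duration_norm for i in idx])
    return onehot, diffs, dur


def _synthetic_forward(generator: Generator, z, t_norm,
                       rng: np.random.Generator) -> tuple[GeneratorOutput, Tensor]:
    out = generator(z, t_norm)
    st_onehot = gumbel_straight_through(out.activity_logits,
                                        generator.cfg.temperature, rng)
    return out, st_onehot


def estimate_loss_expectations(generator: Generator, discriminator: Module,
                               log: EventLog, calibration_epochs: int,
                               seed: int, batch_size: int = 32
                               ) -> tuple[float, float, float]:
    """Forward-only loss-scale estimates (E[L_G], E[L_Ga], E[L_Gt]).

    Accumulates, without any optimizer step, the cross-entropy of the
    discriminator on synthetic (label 0) and authentic (label 1) batches plus
    the two auxiliary divergences, averaged over all calibration batches.
    """
    if calibration_epochs < 1:
        raise ValueError("calibration_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    encoded = encode_log(log, generator.cfg.max_length)
    n = len(encoded)
    n_real = log.vocabulary.n_real
    # forward-only and repeatable: dropout off for the duration
    g_training, d_training = generator.training, discriminator.training
    generator.eval(), discriminator.eval()
    e_lg = e_lga = e_lgt = 0.0
    n_batches = 0
    for _ in range(calibration_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            onehot, diffs, dur = _stack_batch(encoded, idx)
            z = sample_random_input(log.vocabulary, generator.cfg.max_length,
                                    rng, batch=len(idx))
            out, st_onehot = _synthetic_forward(generator, z, dur, rng)
            syn_m = interval_matrix_batch(out.differentials)
            auth_m = interval_matrix_batch(Tensor(diffs))
            d_syn = discriminator(st_onehot, out.differentials, syn_m)
            d_auth = discriminator(Tensor(onehot), Tensor(diffs), auth_m)
            # Adversarial scale: CE(D(synthetic), 0) + CE(D(authentic), 1)
            ce = (-_safe_log(1.0 - d_syn).mean() - _safe_log(d_auth).mean())
            e_lg += ce.item()
            e_lga += activity_divergence_loss(onehot, st_onehot, n_real).item()
            e_lgt += timestamp_divergence_loss(onehot, diffs, st_onehot,
                                               out.differentials, n_real).item()
            n_batches += 1
    if g_training:
        generator.train()
    if d_training:
        discriminator.train()
    return tuple(v / n_batches for v in (e_lg, e_lga, e_lgt))


def calibrate_aux_weights(generator: Generator, discriminator: Module,
                          log: EventLog, calibration_epochs: int,
                          seed: int, batch_size: int = 32,
                          max_weight: float = 1e6) -> tuple[float, float]:
    """Weights that bring the auxiliary losses to the adversarial scale."""
    e_lg, e_lga, e_lgt = estimate_loss_expectations(
        generator, discriminator, log, calibration_epochs, seed, batch_size)

    def weight(aux: float) -> float:
        if aux <= 0.0:
            logger.warning("zero auxiliary expectation; weight capped at %g",
                           max_weight)
            return max_weight
        return min(e_lg / aux, max_weight)

    return weight(e_lga), weight(e_lgt)


def _holdout_accuracy(generator: Generator, discriminator: Module,
                      holdout, log: EventLog, rng: np.random.Generator) -> float:
    """D accuracy on held-out authentic cases vs an equal generated sample."""
    g_training, d_training = generator.training, discriminator.training
    generator.eval(), discriminator.eval()
    onehot, diffs, dur = holdout
    n = onehot.shape[0]
    z = sample_random_input(log.vocabulary, generator.cfg.max_length, rng, batch=n)
    out, st_onehot = _synthetic_forward(generator, z, dur, rng)
    d_auth = discriminator(Tensor(onehot), Tensor(diffs),
                           interval_matrix_batch(Tensor(diffs))).data
    d_syn = discriminator(st_onehot, out.differentials,
                          interval_matrix_batch(out.differentials)).data
    acc = 0.5 * (np.mean(d_auth > 0.5) + np.mean(d_syn <= 0.5))
    if g_training:
        generator.train()
    if d_training:
        discriminator.train()
    return float(acc)


def train(generator: Generator, discriminator: Module, log: EventLog,
          cfg: TrainingConfig) -> tuple[list[Checkpoint], LossReport]:
    """Alternating adversarial training, reproducible from ``cfg.seed``.

    The generator is updated every epoch; the discriminator only on epochs
    divisible by ``cfg.k``. A checkpoint (weights, held-out discriminator
    accuracy, a generated sample) is recorded at epoch 0 and every
    ``checkpoint_interval`` epochs thereafter.
    """
    rng = np.random.default_rng(cfg.seed)
    encoded = encode_log(log, generator.cfg.max_length)
    n = len(encoded)
    n_real = log.vocabulary.n_real

    n_hold = max(1, int(round(cfg.holdout_fraction * n)))
    perm = rng.permutation(n)
    hold_idx, train_idx = perm[:n_hold], perm[n_hold:]
    holdout = _stack_batch(encoded, hold_idx)

    if cfg.aux_weights == "auto":
        w_a, w_t = calibrate_aux_weights(
            generator, discriminator, log, cfg.calibration_epochs,
            seed=cfg.seed + 1, batch_size=cfg.batch_size,
            max_weight=cfg.max_aux_weight)
    else:
        w_a, w_t = cfg.aux_weights
    logger.info("auxiliary weights: w_a=%.4g w_t=%.4g", w_a, w_t)

    opt_g = Adam(generator.parameters(), lr=cfg.lr_g, betas=cfg.betas)
    opt_d = Adam(discriminator.parameters(), lr=cfg.lr_d, betas=cfg.betas)
    generator.train(), discriminator.train()

    report = LossReport()
    checkpoints: list[Checkpoint] = []

    def record_checkpoint(epoch: int, acc: float) -> None:
        sample_seed = int(rng.integers(0, 2**31 - 1))
        sample = generate_log(generator, min(64, n), log, seed=sample_seed)
        checkpoints.append(Checkpoint(
            epoch=epoch,
            g_state=generator.state_dict(),
            d_state=discriminator.state_dict(),
            d_accuracy=acc, sample=sample, sample_seed=sample_seed))

    record_checkpoint(0, _holdout_accuracy(generator, discriminator, holdout,
                                           log, np.random.default_rng(cfg.seed + 2)))

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(train_idx)
        ep_lg, ep_ld, ep_lga, ep_lgt, nb = 0.0, 0.0, 0.0, 0.0, 0
        d_epoch = epoch % cfg.k == 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            onehot, diffs, dur = _stack_batch(encoded, idx)

            # generator step (every epoch); durations matched to the batch
            z = sample_random_input(log.vocabulary, generator.cfg.max_length,
                                    rng, batch=len(idx))
            out, st_onehot = _synthetic_forward(generator, z, dur, rng)
            syn_m = interval_matrix_batch(out.differentials)
            d_syn = discriminator(st_onehot, out.differentials, syn_m)
            l_g = generator_adversarial_loss(d_syn)
            l_ga = activity_divergence_loss(onehot, st_onehot, n_real)
            l_gt = timestamp_divergence_loss(onehot, diffs, st_onehot,
                                             out.differentials, n_real)
            total = l_g + w_a * l_ga + w_t * l_gt
            if not np.isfinite(total.item()):
                raise RuntimeError(
                    f"non-finite generator loss at epoch {epoch}: "
                    f"L_G={l_g.item()} L_Ga={l_ga.item()} L_Gt={l_gt.item()}")
            opt_g.zero_grad(), opt_d.zero_grad()
            total.backward()
            opt_g.step()

            l_d_val = np.nan
            if d_epoch:
                z = sample_random_input(log.vocabulary, generator.cfg.max_length,
                                        rng, batch=len(idx))
                out_d, st_d = _synthetic_forward(generator, z, dur, rng)
                syn_oh = Tensor(st_d.data)           # detached from G
                syn_t = Tensor(out_d.differentials.data)
                d_syn2 = discriminator(syn_oh, syn_t, interval_matrix_batch(syn_t))
                d_auth = discriminator(Tensor(onehot), Tensor(diffs),
                                       interval_matrix_batch(Tensor(diffs)))
                l_d = discriminator_loss(d_auth, d_syn2)
                l_d_val = l_d.item()
                if not np.isfinite(l_d_val):
                    raise RuntimeError(f"non-finite discriminator loss at epoch {epoch}")
                opt_d.zero_grad(), opt_g.zero_grad()
                l_d.backward()
                opt_d.step()

            ep_lg += l_g.item()
            ep_ld += l_d_val if d_epoch else 0.0
            ep_lga += l_ga.item()
            ep_lgt += l_gt.item()
            nb += 1

        acc = _holdout_accuracy(generator, discriminator, holdout, log,
                                np.random.default_rng(cfg.seed + 2 + epoch))
        report.epochs.append(epoch)
        report.loss_g.append(ep_lg / nb)
        report.loss_d.append(ep_ld / nb if d_epoch else np.nan)
        report.loss_ga.append(ep_lga / nb)
        report.loss_gt.append(ep_lgt / nb)
        report.d_accuracy.append(acc)

        if epoch % cfg.checkpoint_interval == 0:
            record_checkpoint(epoch, acc)

    if checkpoints[-1].epoch != cfg.epochs:
        record_checkpoint(cfg.epochs, report.d_accuracy[-1])
    return checkpoints, report


def select_equilibrium_checkpoint(checkpoints: list[Checkpoint]) -> Checkpoint:
    """Checkpoint whose held-out D accuracy is nearest 0.5; ties -> later epoch."""
    if not checkpoints:
        raise ValueError("no checkpoints")
    # distances rounded to kill float artifacts in exact-decimal ties
    def dist(c: Checkpoint) -> float:
        return round(abs(c.d_accuracy - 0.5), 12)

    best = checkpoints[0]
    for ckpt in checkpoints[1:]:
        if dist(ckpt) <= dist(best):
            best = ckpt
    return best


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def map_timestamps(differentials: np.ndarray, duration_norm: float,
                   bounds: tuple[float, float]) -> np.ndarray:
    """Cumulative differentials scaled by the de-normalized case duration."""
    t_real = denormalize_duration(duration_norm, bounds)
    return t_real * np.cumsum(np.asarray(differentials, dtype=np.float64))


def generate_log(generator: Generator, n_cases: int, log: EventLog,
                 seed: int, max_retries: int = 20,
                 decode: str = "sample") -> EventLog:
    """Decode a trained generator into a synthetic event log.

    Per case: sample a random input and an authentic conditional duration,
    convert each position's probability row to an activity symbol, drop pad
    positions (and their differentials, renormalizing the remainder when the
    generator is configured to), then map differentials to timestamps.

    ``decode="sample"`` (default) draws each position by the Gumbel-max
    trick — the same discrete sampling the discriminator was trained
    against; ``decode="argmax"`` takes the deterministic per-position mode,
    which for a distribution-matched generator can be badly unrepresentative
    of its sampling distribution.
    """
    if decode not in ("sample", "argmax"):
        raise ValueError(f"unknown decode mode {decode!r}")
    rng = np.random.default_rng(seed)
    vocab = log.vocabulary
    was_training = generator.training
    generator.eval()
    durations = log.durations()
    bounds = log.duration_bounds
    cases: list[ProcessCase] = []
    for i in range(n_cases):
        for attempt in range(max_retries + 1):
            z = sample_random_input(vocab, generator.cfg.max_length, rng, batch=1)
            t_real = float(durations[rng.integers(0, len(durations))])
            t_norm = np.array([
                0.0 if bounds[1] == bounds[0]
                else (t_real - bounds[0]) / (bounds[1] - bounds[0])])
            out = generator(z, t_norm)
            logits = out.activity_logits.data[0]
            if decode == "sample":
                u = np.clip(rng.random(logits.shape), 1e-12, 1 - 1e-12)
                logits = logits - np.log(-np.log(u))
            labels_idx = np.argmax(logits, axis=-1)
            keep = labels_idx != vocab.pad_index
            if keep.any():
                break
            logger.warning("case %d decoded to all-pad (attempt %d); retrying",
                           i, attempt + 1)
        else:
            raise RuntimeError(f"case {i} decoded to all-pad after "
                               f"{max_retries} retries")
        diffs = out.differentials.data[0][keep].copy()
        diffs[0] = 0.0
        if generator.cfg.renormalize_differentials and diffs.sum() > 0:
            diffs = diffs / diffs.sum()
        ts = map_timestamps(diffs, float(t_norm[0]), bounds)
        events = [Event(vocab.labels[a], float(t))
                  for a, t in zip(labels_idx[keep], ts)]
        cases.append(ProcessCase(f"syn_{i:05d}", events))
    if was_training:
        generator.train()
    return build_event_log(cases, time_unit=log.time_unit, vocabulary=vocab)


# ---------------------------------------------------------------------------
# checkpoint serialization
# ---------------------------------------------------------------------------

def save_checkpoint(ckpt: Checkpoint, path, g_config=None, d_config=None) -> None:
    """Weights to .npz plus a JSON sidecar with configs and a content hash."""
    path = Path(path)
    arrays = {f"g::{k}": v for k, v in ckpt.g_state.items()}
    arrays |= {f"d::{k}": v for k, v in ckpt.d_state.items()}
    np.savez(path, **arrays)
    digest = hashlib.sha256()
    for k in sorted(arrays):
        digest.update(k.encode())
        digest.update(np.ascontiguousarray(arrays[k]).tobytes())
    sidecar = {
        "epoch": ckpt.epoch,
        "d_accuracy": ckpt.d_accuracy,
        "sample_seed": ckpt.sample_seed,
        "weights_sha256": digest.hexdigest(),
        "generator_config": dataclasses.asdict(g_config) if g_config else None,
        "discriminator_config": dataclasses.asdict(d_config) if d_config else None,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path) -> Checkpoint:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    data = np.load(path)
    g_state = {k[3:]: data[k] for k in data.files if k.startswith("g::")}
    d_state = {k[3:]: data[k] for k in data.files if k.startswith("d::")}
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    return Checkpoint(epoch=sidecar["epoch"], g_state=g_state, d_state=d_state,
                      d_accuracy=sidecar["d_accuracy"],
                      sample_seed=sidecar.get("sample_seed"))
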