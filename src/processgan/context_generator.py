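"""Multi-task context model: learns trace-to-context associations on
authentic cases and infers contexts for synthetic traces.

One shared transformer encoder feeds r task heads (two dense layers each);
task losses are combined with learnable homoscedastic-uncertainty weights
exp(-log_var) * L + log_var.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter

import numpy as np
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import KFold

from ._autograd import Tensor, cat
from ._nn import (Adam, Dropout, Linear, Module, Parameter, TransformerEncoder,
                  sinusoidal_positions)
from .encoding import compute_differentials, pad_and_onehot
from .event_log_io import EventLog, ProcessCase, ValidationError, build_event_log

__all__ = [
    "ContextTask", "ContextSchema", "ContextModelConfig", "ContextGenerator",
    "uncertainty_weighted_loss", "train_context_generator", "infer_contexts",
    "zero_r_f1", "uniform_random_f1",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ContextTask:
    name: str
    kind: str                        # categorical | numerical
    levels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("categorical", "numerical"):
            raise ValidationError(f"unknown task kind {self.kind!r}")
        if self.kind == "categorical" and len(self.levels) < 2:
            raise ValidationError(f"task {self.name!r} needs >= 2 levels")


@dataclasses.dataclass(frozen=True)
class ContextSchema:
    tasks: tuple[ContextTask, ...]

    def __post_init__(self):
        if not self.tasks:
            raise ValidationError("schema needs at least one task")

    @classmethod
    def from_dict(cls, spec: dict) -> "ContextSchema":
        tasks = tuple(
            ContextTask(t["name"], t["kind"], tuple(map(str, t.get("levels", ()))))
            for t in spec["tasks"])
        return cls(tasks)


@dataclasses.dataclass
class ContextModelConfig:
    hidden_size: int = 32
    n_heads: int = 2
    n_layers: int = 1
    dropout: float = 0.1
    head_width: int = 32
    batch_size: int = 16
    lr: float = 1e-2
    lr_decay_every: int = 10         # step decay schedule
    lr_decay_factor: float = 0.5
    betas: tuple[float, float] = (0.5, 0.99)
    patience: int = 20               # epochs without val-loss improvement
    folds: int = 5
    max_epochs: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def uncertainty_weighted_loss(task_losses, log_vars) -> Tensor:
    """Sum of exp(-log_var_i) * L_i + log_var_i over tasks."""
    total = None
    for loss, lv in zip(task_losses, log_vars):
        lv = lv if isinstance(lv, Tensor) else Tensor(lv)
        term = (-lv).exp() * loss + lv
        total = term if total is None else total + term
    return total.sum() if total.shape else total


class ContextGenerator(Module):
    def __init__(self, vocab_size: int, max_length: int, schema: ContextSchema,
                 cfg: ContextModelConfig):
        super().__init__()
        self.schema = schema
        self.cfg = cfg
        self.max_length = max_length
        self.vocab_size = vocab_size
        rng = np.random.default_rng(cfg.seed)
        h = cfg.hidden_size
        self.input_proj = Linear(vocab_size + 1, h, rng)
        self.pos_table = sinusoidal_positions(max_length, h)
        self.encoder = TransformerEncoder(h, cfg.n_heads, cfg.n_layers,
                                          cfg.dropout, rng)
        self.drop = Dropout(cfg.dropout, rng)
        feat = h + (vocab_size - 1) + 1
        self.heads = []
        for task in schema.tasks:
            out_dim = len(task.levels) if task.kind == "categorical" else 1
            self.heads.append([Linear(feat, cfg.head_width, rng),
                               Linear(cfg.head_width, out_dim, rng)])
        # one learnable log-variance per task (homoscedastic uncertainty)
        self.log_vars = [Parameter(np.zeros(())) for _ in schema.tasks]

    def featurize(self, onehot: np.ndarray, diffs: np.ndarray,
                  freqs: np.ndarray, lengths: np.ndarray) -> Tensor:
        """Pooled shared-encoder embedding ++ activity frequencies ++ length."""
        x = cat([Tensor(onehot), Tensor(diffs).expand_dims(-1)], axis=-1)
        x = self.input_proj(x) + Tensor(self.pos_table)
        x = self.encoder(self.drop(x))
        return cat([x.mean(axis=1), Tensor(freqs),
                    Tensor(lengths[:, None] / self.max_length)], axis=-1)

    def forward(self, onehot, diffs, freqs, lengths) -> list[Tensor]:
        feats = self.featurize(onehot, diffs, freqs, lengths)
        outputs = []
        for task, (fc1, fc2) in zip(self.schema.tasks, self.heads):
            y = fc2(fc1(feats).relu())
            if task.kind == "categorical":
                y = y.softmax(axis=-1)
            else:
                y = y.reshape(-1)
            outputs.append(y)
        return outputs


def _case_inputs(cases, vocab, max_length):
    onehot, diffs, freqs, lengths = [], [], [], []
    for c in cases:
        if len(c) > max_length:
            c = ProcessCase(c.case_id, c.events[:max_length], c.contexts)
        onehot.append(pad_and_onehot(c, max_length, vocab))
        diffs.append(compute_differentials(c, max_length))
        counts = Counter(c.activities)
        freqs.append([counts.get(a, 0) / len(c) for a in vocab.labels[:-1]])
        lengths.append(len(c))
    return (np.stack(onehot), np.stack(diffs),
            np.asarray(freqs, dtype=np.float64),
            np.asarray(lengths, dtype=np.float64))


def _task_targets(log: EventLog, schema: ContextSchema):
    """Integer label arrays for categorical tasks, float arrays for numerical."""
    targets = []
    for task in schema.tasks:
        vals = []
        for case in log.cases:
            if task.name not in case.contexts:
                raise ValidationError(
                    f"case {case.case_id!r} missing context {task.name!r}")
            raw = case.contexts[task.name]
            if task.kind == "categorical":
                label = str(raw)
                if label not in task.levels:
                    raise ValidationError(
                        f"case {case.case_id!r}: level {label!r} not in "
                        f"task {task.name!r} levels {task.levels}")
                vals.append(task.levels.index(label))
            else:
                vals.append(float(raw))
        targets.append(np.asarray(vals))
    return targets


def _batch_loss(model: ContextGenerator, inputs, targets, idx) -> Tensor:
    onehot, diffs, freqs, lengths = inputs
    outputs = model(onehot[idx], diffs[idx], freqs[idx], lengths[idx])
    losses = []
    for task, out, target in zip(model.schema.tasks, outputs, targets):
        y = target[idx]
        if task.kind == "categorical":
            picked = out[np.arange(len(idx)), y.astype(np.intp)]
            losses.append(-picked.clip_min(1e-12).log().mean())
        else:
            gap = out - Tensor(y)
            losses.append((gap * gap).mean())
    return uncertainty_weighted_loss(losses, model.log_vars)


def _fit(model: ContextGenerator, inputs, targets, train_idx, val_idx,
         rng: np.random.Generator) -> None:
    """Adam with step-decayed lr and early stopping on validation loss."""
    cfg = model.cfg
    opt = Adam(model.parameters(), lr=cfg.lr, betas=cfg.betas)
    best_val, best_state, since_best = np.inf, None, 0
    for epoch in range(cfg.max_epochs):
        opt.lr = cfg.lr * cfg.lr_decay_factor ** (epoch // cfg.lr_decay_every)
        model.train()
        order = rng.permutation(train_idx)
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss = _batch_loss(model, inputs, targets, idx)
            opt.zero_grad()
            loss.backward()
            opt.step()
        model.eval()
        val = _batch_loss(model, inputs, targets, val_idx).item()
        if val < best_val - 1e-9:
            best_val, best_state, since_best = val, model.state_dict(), 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()


def _predictions(model: ContextGenerator, inputs, idx):
    onehot, diffs, freqs, lengths = inputs
    model.eval()
    outputs = model(onehot[idx], diffs[idx], freqs[idx], lengths[idx])
    preds = []
    for task, out in zip(model.schema.tasks, outputs):
        if task.kind == "categorical":
            preds.append(np.argmax(out.data, axis=-1))
        else:
            preds.append(out.data)
    return preds


def train_context_generator(log: EventLog, schema: ContextSchema,
                            cfg: ContextModelConfig | None = None
                            ) -> tuple[ContextGenerator, dict]:
    """K-fold cross-validated training; returns (final model, metrics).

    Metrics per categorical task: support-weighted precision/recall/F1 per
    fold plus their means; numerical tasks report RMSE. The final model is
    refit on all cases (with a held-back validation slice for early
    stopping).
    """
    cfg = cfg or ContextModelConfig()
    vocab = log.vocabulary
    max_length = log.max_length
    inputs = _case_inputs(log.cases, vocab, max_length)
    targets = _task_targets(log, schema)
    n = len(log)

    metrics: dict[str, dict] = {
        t.name: {"precision": [], "recall": [], "f1": [], "rmse": []}
        for t in schema.tasks}
    kf = KFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    for fold, (tr, va) in enumerate(kf.split(np.arange(n))):
        model = ContextGenerator(vocab.size, max_length, schema,
                                 dataclasses.replace(cfg, seed=cfg.seed + fold))
        _fit(model, inputs, targets, tr, va,
             np.random.default_rng(cfg.seed + 100 + fold))
        preds = _predictions(model, inputs, va)
        for task, pred, target in zip(schema.tasks, preds, targets):
            m = metrics[task.name]
            if task.kind == "categorical":
                p, r, f1, _ = precision_recall_fscore_support(
                    target[va], pred, average="weighted", zero_division=0)
                m["precision"].append(float(p))
                m["recall"].append(float(r))
                m["f1"].append(float(f1))
            else:
                m["rmse"].append(float(np.sqrt(np.mean((pred - target[va]) ** 2))))
    for task in schema.tasks:
        m = metrics[task.name]
        for key in ("precision", "recall", "f1", "rmse"):
            m[f"mean_{key}"] = float(np.mean(m[key])) if m[key] else None

    # final model on all data; last 20% (shuffled) held back for early stop
    rng = np.random.default_rng(cfg.seed + 999)
    perm = rng.permutation(n)
    cut = max(1, int(round(0.2 * n)))
    final = ContextGenerator(vocab.size, max_length, schema, cfg)
    _fit(final, inputs, targets, perm[cut:], perm[:cut], rng)
    return final, metrics


def infer_contexts(model: ContextGenerator, synthetic: EventLog,
                   schema: ContextSchema | None = None
                   ) -> tuple[EventLog, dict[str, dict[str, float]]]:
    """Attach argmax/predicted contexts to every synthetic case.

    Also returns the aggregate predicted-level distribution per categorical
    task (sums to 1).
    """
    schema = schema or model.schema
    if model.vocab_size != synthetic.vocabulary.size:
        raise ValidationError("vocabulary mismatch between model and log")
    inputs = _case_inputs(synthetic.cases, synthetic.vocabulary, model.max_length)
    preds = _predictions(model, inputs, np.arange(len(synthetic)))
    new_cases = []
    for i, case in enumerate(synthetic.cases):
        contexts = dict(case.contexts)
        for task, pred in zip(schema.tasks, preds):
            if task.kind == "categorical":
                contexts[task.name] = task.levels[int(pred[i])]
            else:
                contexts[task.name] = float(pred[i])
        new_cases.append(ProcessCase(case.case_id, case.events, contexts))
    distributions: dict[str, dict[str, float]] = {}
    for task, pred in zip(schema.tasks, preds):
        if task.kind == "categorical":
            counts = Counter(int(p) for p in pred)
            distributions[task.name] = {
                lvl: counts.get(k, 0) / len(pred)
                for k, lvl in enumerate(task.levels)}
    out = build_event_log(new_cases, time_unit=synthetic.time_unit,
                          vocabulary=synthetic.vocabulary)
    return out, distributions


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def zero_r_f1(train_labels: np.ndarray, test_labels: np.ndarray) -> float:
    """Weighted F1 of always predicting the training majority class."""
    majority = Counter(train_labels.tolist()).most_common(1)[0][0]
    preds = np.full_like(test_labels, majority)
    _, _, f1, _ = precision_recall_fscore_support(
        test_labels, preds, average="weighted", zero_division=0)
    return float(f1)


def uniform_random_f1(test_labels: np.ndarray, n_levels: int,
                      rng: np.random.Generator) -> float:
    preds = rng.integers(0, n_levels, size=len(test_labels))
    _, _, f1, _ = precision_recall_fscore_support(
        test_labels, preds, average="weighted", zero_division=0)
    return float(f1)
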