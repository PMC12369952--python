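"""Three-part assessment of synthetic event logs.

Statistical measures (length stats, pairwise-edit-distance diversity,
activity-occurrence and timestamp errors), a supervised "off-the-shelf"
scorer trained on authentic-vs-corrupted traces whose false-positive rate on
synthetic data measures realism, and a simplified star-alignment consensus
workflow summary.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter

import numpy as np
from sklearn.metrics import precision_recall_fscore_support

from ._autograd import Tensor, cat
from ._nn import Adam, Dropout, Linear, Module, TransformerEncoder, sinusoidal_positions
from .encoding import compute_differentials, pad_and_onehot
from .event_log_io import (ActivityVocabulary, Event, EventLog, ProcessCase,
                           build_event_log, case_duration)

__all__ = [
    "EvaluationReport", "length_stats", "spe", "activity_occurrence_error",
    "timestamp_error", "make_negative_samples", "train_offshelf_classifier",
    "supervised_score", "consensus_workflow", "levenshtein", "align",
    "export_timestamp_densities",
    "OffShelfScorer", "ClassifierConfig", "evaluate",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# edit distance
# ---------------------------------------------------------------------------

def levenshtein(a, b) -> int:
    """Classic DP edit distance between two label sequences."""
    a, b = list(a), list(b)
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, 1):
        cur = [i]
        for j, y in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (x != y)))
        prev = cur
    return prev[-1]


def align(a, b) -> list[tuple[int | None, int | None]]:
    """Optimal edit alignment of ``a`` onto ``b`` as (i, j) pairs.

    ``None`` marks a gap. Traceback preference: diagonal, then deletion from
    ``a``, then insertion (deterministic).
    """
    a, b = list(a), list(b)
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1), dtype=np.int64)
    dp[:, 0] = np.arange(n + 1)
    dp[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            dp[i, j] = min(dp[i - 1, j - 1] + (a[i - 1] != b[j - 1]),
                           dp[i - 1, j] + 1, dp[i, j - 1] + 1)
    pairs: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dp[i, j] == dp[i - 1, j - 1] + (a[i - 1] != b[j - 1]):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and dp[i, j] == dp[i - 1, j] + 1:
            pairs.append((i - 1, None))
            i -= 1
        else:
            pairs.append((None, j - 1))
            j -= 1
    return pairs[::-1]


# ---------------------------------------------------------------------------
# statistical measures
# ---------------------------------------------------------------------------

def length_stats(log: EventLog) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of case lengths."""
    lengths = np.array([len(c) for c in log.cases], dtype=np.float64)
    if len(lengths) == 1:
        logger.warning("single-case log: standard deviation reported as 0")
        return float(lengths[0]), 0.0
    return float(lengths.mean()), float(lengths.std(ddof=1))


def spe(log: EventLog) -> float:
    """Sum of pairwise length-normalized edit distances over N^2."""
    seqs = [tuple(c.activities) for c in log.cases]
    n = len(seqs)
    if n < 2:
        raise ValueError("SPE needs at least 2 sequences")
    # cache distances between distinct trace types
    uniq = list(Counter(seqs).items())
    total = 0.0
    dist: dict[tuple[int, int], int] = {}
    index = {s: i for i, (s, _) in enumerate(uniq)}
    for i in range(n):
        for j in range(i + 1, n):
            ui, uj = index[seqs[i]], index[seqs[j]]
            key = (min(ui, uj), max(ui, uj))
            if key not in dist:
                dist[key] = levenshtein(seqs[i], seqs[j])
            total += dist[key] / (len(seqs[i]) + len(seqs[j]))
    return total / n ** 2


def _token_frequencies(log: EventLog) -> dict[str, float]:
    counts = Counter(a for c in log.cases for a in c.activities)
    n = sum(counts.values())
    return {a: v / n for a, v in counts.items()}


def activity_occurrence_error(authentic: EventLog, synthetic: EventLog) -> float:
    """L1 distance between per-activity token-frequency profiles."""
    fa = _token_frequencies(authentic)
    fs = _token_frequencies(synthetic)
    return float(sum(abs(fa.get(a, 0.0) - fs.get(a, 0.0))
                     for a in set(fa) | set(fs)))


def _scaled_timestamps_by_activity(log: EventLog) -> dict[str, list[float]]:
    """Per activity: timestamps as fraction of case duration, times 100."""
    out: dict[str, list[float]] = {}
    for c in log.cases:
        dur = case_duration(c)
        t0 = c.events[0].timestamp
        for ev in c.events:
            frac = 0.0 if dur == 0 else (ev.timestamp - t0) / dur
            out.setdefault(ev.activity, []).append(100.0 * frac)
    return out


def timestamp_error(authentic: EventLog, synthetic: EventLog,
                    statistic: str = "mean") -> float:
    """Sum over activities of |stat(scaled ts, authentic) - stat(..., synthetic)|.

    ``statistic`` is ``mean`` or ``p90`` (linear-interpolation percentile).
    Scaled timestamps are fractions of case duration times 100. Activities
    absent from one log compare against 0 with a warning.
    """
    if statistic not in ("mean", "p90"):
        raise ValueError(f"unknown statistic {statistic!r}")

    def stat(vals: list[float]) -> float:
        arr = np.asarray(vals)
        return float(arr.mean() if statistic == "mean"
                     else np.percentile(arr, 90, method="linear"))

    ta = _scaled_timestamps_by_activity(authentic)
    ts = _scaled_timestamps_by_activity(synthetic)
    total = 0.0
    for act in set(ta) | set(ts):
        if act not in ta or act not in ts:
            logger.warning("activity %r absent from one log; compared against 0", act)
        sa = stat(ta[act]) if act in ta else 0.0
        ss = stat(ts[act]) if act in ts else 0.0
        total += abs(sa - ss)
    return total


# ---------------------------------------------------------------------------
# negative sampling and the off-the-shelf scorer
# ---------------------------------------------------------------------------

def make_negative_samples(log: EventLog, noise_ratio: float,
                          rng: np.random.Generator) -> EventLog:
    """Corrupt a noise_ratio fraction of tokens per case.

    Operations are drawn uniformly from add / delete / switch (cases shorter
    than 2 tokens only allow add). Added activities get a uniform timestamp
    between their neighbors; switches swap two activities keeping timestamps
    in place. Each corrupted case's timestamps are re-scaled to [0, 1].
    """
    if not 0.0 <= noise_ratio <= 1.0:
        raise ValueError("noise_ratio must be in [0, 1]")
    real_labels = log.vocabulary.labels[:-1]
    cases: list[ProcessCase] = []
    for case in log.cases:
        acts = list(case.activities)
        ts = list(case.timestamps)
        n_ops = int(round(noise_ratio * len(acts)))
        for _ in range(n_ops):
            ops = ["add"] if len(acts) < 2 else ["add", "delete", "switch"]
            op = ops[rng.integers(0, len(ops))]
            if op == "add":
                pos = int(rng.integers(0, len(acts) + 1))
                lo = ts[pos - 1] if pos > 0 else ts[0]
                hi = ts[pos] if pos < len(acts) else ts[-1]
                acts.insert(pos, real_labels[rng.integers(0, len(real_labels))])
                ts.insert(pos, float(rng.uniform(lo, hi)))
            elif op == "delete":
                pos = int(rng.integers(0, len(acts)))
                del acts[pos], ts[pos]
            else:  # switch: activities swap, timestamps stay
                i, j = rng.choice(len(acts), size=2, replace=False)
                acts[i], acts[j] = acts[j], acts[i]
        arr = np.asarray(ts)
        span = arr.max() - arr.min()
        arr = (arr - arr.min()) / span if span > 0 else np.zeros_like(arr)
        cases.append(ProcessCase(f"neg_{case.case_id}",
                                 [Event(a, float(t)) for a, t in zip(acts, arr)]))
    return build_event_log(cases, time_unit=log.time_unit,
                           vocabulary=log.vocabulary)


@dataclasses.dataclass
class ClassifierConfig:
    hidden_size: int = 32
    n_heads: int = 2
    n_layers: int = 1
    dropout: float = 0.1
    dense_width: int = 32
    epochs: int = 60
    batch_size: int = 32
    lr: float = 1e-3
    seed: int = 0


class _TraceClassifier(Module):
    """Transformer encoder over (one-hot, differential) positions; the pooled
    embedding is concatenated with the activity frequency distribution and
    the sequence length before two dense layers and a sigmoid."""

    def __init__(self, vocab_size: int, max_length: int, cfg: ClassifierConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        h = cfg.hidden_size
        self.max_length = max_length
        self.input_proj = Linear(vocab_size + 1, h, rng)
        self.pos_table = sinusoidal_positions(max_length, h)
        self.encoder = TransformerEncoder(h, cfg.n_heads, cfg.n_layers,
                                          cfg.dropout, rng)
        self.drop = Dropout(cfg.dropout, rng)
        feat = h + (vocab_size - 1) + 1          # pooled + real-label freqs + length
        self.fc1 = Linear(feat, cfg.dense_width, rng)
        self.fc2 = Linear(cfg.dense_width, 1, rng)

    def forward(self, onehot: np.ndarray, diffs: np.ndarray,
                freqs: np.ndarray, lengths: np.ndarray) -> Tensor:
        x = cat([Tensor(onehot), Tensor(diffs).expand_dims(-1)], axis=-1)
        x = self.input_proj(x) + Tensor(self.pos_table)
        x = self.encoder(self.drop(x))
        feats = cat([x.mean(axis=1), Tensor(freqs),
                     Tensor(lengths[:, None] / self.max_length)], axis=-1)
        return self.fc2(self.fc1(feats).relu()).reshape(-1).sigmoid()


@dataclasses.dataclass
class OffShelfScorer:
    model: _TraceClassifier
    vocab: ActivityVocabulary
    max_length: int
    f1: float
    reliable: bool

    def scores(self, log: EventLog) -> np.ndarray:
        self.model.eval()
        onehot, diffs, freqs, lengths = _classifier_inputs(
            log.cases, self.vocab, self.max_length)
        return self.model(onehot, diffs, freqs, lengths).data


def _classifier_inputs(cases, vocab: ActivityVocabulary, max_length: int):
    onehot, diffs, freqs, lengths = [], [], [], []
    for c in cases:
        if len(c) > max_length:   # truncate over-long cases defensively
            c = ProcessCase(c.case_id, c.events[:max_length], c.contexts)
        onehot.append(pad_and_onehot(c, max_length, vocab))
        diffs.append(compute_differentials(c, max_length))
        counts = Counter(c.activities)
        freqs.append([counts.get(a, 0) / len(c) for a in vocab.labels[:-1]])
        lengths.append(len(c))
    return (np.stack(onehot), np.stack(diffs),
            np.asarray(freqs, dtype=np.float64),
            np.asarray(lengths, dtype=np.float64))


def train_offshelf_classifier(log: EventLog, noise_ratio: float = 0.2,
                              negatives_multiple: int = 5,
                              cfg: ClassifierConfig | None = None,
                              seed: int = 0) -> tuple[OffShelfScorer, float]:
    """Train the authentic-vs-corrupted scorer; returns (scorer, held-out F1).

    Negatives are generated ``negatives_multiple`` times over; training uses
    an 80/20 stratified split with class weights balancing the 5x negatives.
    The scorer is flagged unreliable (with a warning) if held-out weighted
    F1 <= 0.8.
    """
    if len(log) < 20:
        raise ValueError("need at least 20 cases to train the scorer")
    cfg = cfg or ClassifierConfig(seed=seed)
    rng = np.random.default_rng(seed)
    negatives: list[ProcessCase] = []
    for _ in range(negatives_multiple):
        negatives.extend(make_negative_samples(log, noise_ratio, rng).cases)
    positives = log.cases
    max_length = max(max(len(c) for c in positives),
                     max(len(c) for c in negatives))
    all_cases = list(positives) + negatives
    labels = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])

    # stratified 80/20 split
    train_idx, test_idx = [], []
    for lab in (0.0, 1.0):
        idx = np.flatnonzero(labels == lab)
        idx = rng.permutation(idx)
        cut = int(round(0.8 * len(idx)))
        train_idx.extend(idx[:cut])
        test_idx.extend(idx[cut:])
    train_idx, test_idx = np.array(train_idx), np.array(test_idx)

    onehot, diffs, freqs, lengths = _classifier_inputs(
        all_cases, log.vocabulary, max_length)
    model = _TraceClassifier(log.vocabulary.size, max_length, cfg)
    opt = Adam(model.parameters(), lr=cfg.lr)
    # per-class weights balance the negatives_multiple-to-1 imbalance
    n_pos = labels[train_idx].sum()
    n_neg = len(train_idx) - n_pos
    w_pos, w_neg = len(train_idx) / (2 * n_pos), len(train_idx) / (2 * n_neg)

    model.train()
    for _ in range(cfg.epochs):
        order = rng.permutation(train_idx)
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            y = labels[idx]
            w = np.where(y == 1.0, w_pos, w_neg)
            p = model(onehot[idx], diffs[idx], freqs[idx], lengths[idx])
            p = p.clip_min(1e-8)
            one_minus = (1.0 - p).clip_min(1e-8)
            loss = -(Tensor(w * y) * p.log()
                     + Tensor(w * (1 - y)) * one_minus.log()).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()

    model.eval()
    preds = (model(onehot[test_idx], diffs[test_idx], freqs[test_idx],
                   lengths[test_idx]).data > 0.5).astype(float)
    _, _, f1, _ = precision_recall_fscore_support(
        labels[test_idx], preds, average="weighted", zero_division=0)
    f1 = float(f1)
    reliable = f1 > 0.8
    if not reliable:
        logger.warning("off-the-shelf scorer held-out F1 %.3f <= 0.8; "
                       "flagged unreliable", f1)
    scorer = OffShelfScorer(model, log.vocabulary, max_length, f1, reliable)
    return scorer, f1


def supervised_score(scorer: OffShelfScorer, synthetic: EventLog) -> float:
    """FPR: fraction of synthetic cases the scorer classifies as authentic."""
    return float(np.mean(scorer.scores(synthetic) > 0.5))


def export_timestamp_densities(log: EventLog, path) -> None:
    """Per-activity scaled timestamps as long-format CSV (for density plots)."""
    import pandas as pd
    rows = [(act, val)
            for act, vals in _scaled_timestamps_by_activity(log).items()
            for val in vals]
    pd.DataFrame(rows, columns=["activity", "scaled_timestamp"]).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# consensus workflow (simplified star alignment; a summary view)
# ---------------------------------------------------------------------------

def _medoid_index(seqs: list[tuple]) -> int:
    """Trace with the minimum total edit distance to all others."""
    dist: dict[tuple, dict[tuple, int]] = {}
    uniq = sorted(set(seqs), key=seqs.index)
    for s in uniq:
        dist[s] = {t: levenshtein(s, t) for t in uniq}
    totals = [sum(dist[s][t] for t in seqs) for s in seqs]
    return int(np.argmin(totals))


def consensus_workflow(log: EventLog) -> tuple[list[str], dict[str, int]]:
    """Star-align all traces to the medoid trace and take column majorities.

    Returns the consensus sequence (column symbols present in more than half
    the traces) and the remaining activities as branches with counts.
    """
    seqs = [tuple(c.activities) for c in log.cases]
    n = len(seqs)
    medoid = seqs[_medoid_index(seqs)]
    columns: list[Counter] = [Counter() for _ in medoid]
    off_backbone: Counter = Counter()
    for s in seqs:
        pairs = align(s, medoid)
        for i, j in pairs:
            if j is not None:
                if i is not None:
                    columns[j][s[i]] += 1
            elif i is not None:
                off_backbone[s[i]] += 1
    consensus: list[str] = []
    branches: Counter = Counter(off_backbone)
    for col in columns:
        if col:
            symbol, count = col.most_common(1)[0]
            if count > n / 2:
                consensus.append(symbol)
                for sym, c in col.items():
                    if sym != symbol:
                        branches[sym] += c
                continue
        for sym, c in col.items():
            branches[sym] += c
    return consensus, dict(branches)


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EvaluationReport:
    authentic_length: tuple[float, float]
    synthetic_length: tuple[float, float]
    authentic_spe: float
    synthetic_spe: float
    act_error: float
    time_error_mean: float
    time_error_p90: float
    classifier_f1: float | None
    fpr: float | None
    consensus: list[str]
    branches: dict[str, int]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["authentic_length"] = {"mean": self.authentic_length[0],
                                 "sd": self.authentic_length[1]}
        d["synthetic_length"] = {"mean": self.synthetic_length[0],
                                 "sd": self.synthetic_length[1]}
        return d


def evaluate(authentic: EventLog, synthetic: EventLog,
             noise_ratio: float = 0.2, negatives_multiple: int = 5,
             classifier_cfg: ClassifierConfig | None = None,
             with_classifier: bool = True, seed: int = 0) -> EvaluationReport:
    f1 = fpr = None
    if with_classifier:
        scorer, f1 = train_offshelf_classifier(
            authentic, noise_ratio, negatives_multiple, classifier_cfg, seed)
        fpr = supervised_score(scorer, synthetic)
    consensus, branches = consensus_workflow(synthetic)
    return EvaluationReport(
        authentic_length=length_stats(authentic),
        synthetic_length=length_stats(synthetic),
        authentic_spe=spe(authentic),
        synthetic_spe=spe(synthetic),
        act_error=activity_occurrence_error(authentic, synthetic),
        time_error_mean=timestamp_error(authentic, synthetic, "mean"),
        time_error_p90=timestamp_error(authentic, synthetic, "p90"),
        classifier_f1=f1, fpr=fpr,
        consensus=consensus, branches=branches,
    )
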