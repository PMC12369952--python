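"""Ground-truth event-log simulator for testing the whole pipeline.

Workflows have a sequential backbone, optional branch activities inserted by
independent coin flips, one parallel block realized in uniformly random
order, and per-transition delay distributions. Context attributes are
attached per case by deterministic or stochastic rules of the trace.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

from .event_log_io import Event, EventLog, ProcessCase, ValidationError, build_event_log

__all__ = ["Branch", "DelayModel", "WorkflowSpec", "simulate_log",
           "degenerate_log", "clinic_small"]


@dataclasses.dataclass
class Branch:
    activity: str
    probability: float
    after: str                      # backbone activity the branch follows

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError(f"branch probability {self.probability} not in [0,1]")


@dataclasses.dataclass
class DelayModel:
    """Per-transition inter-activity delay distribution."""

    family: str = "exponential"     # exponential | lognormal
    mean: float = 10.0
    sigma: float = 0.5              # lognormal only

    def __post_init__(self):
        if self.family not in ("exponential", "lognormal"):
            raise ValidationError(f"unknown delay family {self.family!r}")
        if self.mean <= 0:
            raise ValidationError("delay mean must be positive")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "exponential":
            return rng.exponential(self.mean, size=size)
        mu = np.log(self.mean) - self.sigma ** 2 / 2
        return rng.lognormal(mu, self.sigma, size=size)


@dataclasses.dataclass
class WorkflowSpec:
    backbone: list[str]
    branches: list[Branch] = dataclasses.field(default_factory=list)
    parallel_block: list[str] = dataclasses.field(default_factory=list)
    parallel_after: str | None = None   # backbone activity the block follows
    delay_model: DelayModel = dataclasses.field(default_factory=DelayModel)
    context_rules: dict[str, Callable] = dataclasses.field(default_factory=dict)
    n_cases: int = 250
    seed: int = 0

    def __post_init__(self):
        if not self.backbone:
            raise ValidationError("backbone must be non-empty")


def _realize_trace(spec: WorkflowSpec, rng: np.random.Generator) -> list[str]:
    trace: list[str] = []
    for act in spec.backbone:
        trace.append(act)
        if spec.parallel_block and spec.parallel_after == act:
            block = list(spec.parallel_block)
            rng.shuffle(block)
            trace.extend(block)
        for br in spec.branches:
            if br.after == act and rng.random() < br.probability:
                trace.append(br.activity)
    return trace


def simulate_log(spec: WorkflowSpec) -> EventLog:
    """Simulate ``spec.n_cases`` cases; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    cases: list[ProcessCase] = []
    for i in range(spec.n_cases):
        trace = _realize_trace(spec, rng)
        delays = spec.delay_model.draw(rng, len(trace) - 1)
        ts = np.concatenate([[0.0], np.cumsum(delays)])
        events = [Event(a, float(t)) for a, t in zip(trace, ts)]
        contexts = {name: rule(trace, ts, rng)
                    for name, rule in spec.context_rules.items()}
        cases.append(ProcessCase(f"case_{i:05d}", events, contexts))
    return build_event_log(cases)


def degenerate_log(n_cases: int, trace: list[str],
                   delay: float = 1.0) -> EventLog:
    """``n_cases`` identical copies of ``trace`` with constant delays."""
    if not trace:
        raise ValidationError("trace must be non-empty")
    events = [Event(a, float(i * delay)) for i, a in enumerate(trace)]
    cases = [ProcessCase(f"case_{i:05d}", list(events)) for i in range(n_cases)]
    return build_event_log(cases)


def clinic_small(n_cases: int = 250, seed: int = 0) -> WorkflowSpec:
    """Default fixture: 6-activity backbone, 3-activity parallel block, two
    optional branches, exponential delays, three context rules (one
    deterministic, one noisily length-correlated, one independent coin).
    """
    backbone = ["arrive", "triage", "assess", "treat", "review", "discharge"]

    def ctx_branch_taken(trace, ts, rng):
        return "yes" if "specialist" in trace else "no"

    def ctx_long_case(trace, ts, rng):
        # noisy function of trace length: flips with probability 0.15
        val = len(trace) >= 10
        if rng.random() < 0.15:
            val = not val
        return "long" if val else "short"

    def ctx_coin(trace, ts, rng):
        return "heads" if rng.random() < 0.5 else "tails"

    return WorkflowSpec(
        backbone=backbone,
        branches=[Branch("specialist", 0.3, after="treat"),
                  Branch("labs_repeat", 0.6, after="assess")],
        parallel_block=["blood_draw", "imaging", "ecg"],
        parallel_after="assess",
        delay_model=DelayModel("exponential", mean=10.0),
        context_rules={
            "context_specialist": ctx_branch_taken,
            "context_long_case": ctx_long_case,
            "context_coin": ctx_coin,
        },
        n_cases=n_cases,
        seed=seed,
    )
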