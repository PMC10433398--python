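"""Generative engine for the two-stage Markov decision task.

The task: on each trial a first-stage choice between two options (the
"magic carpets") leads probabilistically to one of two second-stage
states (the "mountains"). Each option travels to its preferred state
with probability ``p_common`` (default 0.70) and to the other state
otherwise, and the two options prefer opposite states. At the second
stage a choice between two options (the "genie lamps") pays a unit
reward with a probability that drifts slowly across trials as a
Gaussian random walk reflected into ``[reward_low, reward_high]``
(default [0.25, 0.75]). A session is 250 trials in 5 contiguous blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Protocol

import numpy as np

__all__ = [
    "TaskConfig",
    "RewardWalk",
    "TrialRecord",
    "SessionLog",
    "Policy",
    "FixedPolicy",
    "init_walks",
    "step_walk",
    "reflect_into",
    "sample_transition",
    "run_session",
    "common_destination",
]

COMMON = "common"
RARE = "rare"


class TaskConfigError(ValueError):
    """Raised for invalid task configuration."""


class PolicyContractError(RuntimeError):
    """Raised when a policy returns an out-of-range action."""


@dataclass(frozen=True)
class TaskConfig:
    """Generative constants of the task.

    Parameters
    ----------
    p_common
        Probability that a first-stage choice transitions to its
        preferred second-stage state. Must satisfy 0.5 < p_common <= 1.
    n_trials
        Trials per session.
    n_blocks
        Number of contiguous blocks the session is divided into.
    reward_low, reward_high
        Floor and ceiling of the drifting reward probabilities.
    drift_sd
        Standard deviation of the per-trial Gaussian random-walk step.
    seed
        Default seed for session-level randomness (optional).
    """

    p_common: float = 0.70
    n_trials: int = 250
    n_blocks: int = 5
    reward_low: float = 0.25
    reward_high: float = 0.75
    drift_sd: float = 0.025
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.5 < self.p_common <= 1.0):
            raise TaskConfigError(f"p_common must be in (0.5, 1], got {self.p_common}")
        if self.n_trials < 1 or self.n_blocks < 1:
            raise TaskConfigError("n_trials and n_blocks must be positive")
        if self.n_trials % self.n_blocks != 0:
            raise TaskConfigError(
                f"n_trials ({self.n_trials}) must be divisible by n_blocks ({self.n_blocks})"
            )
        if not (0.0 <= self.reward_low < self.reward_high <= 1.0):
            raise TaskConfigError(
                f"need 0 <= reward_low < reward_high <= 1, got "
                f"[{self.reward_low}, {self.reward_high}]"
            )
        if self.drift_sd < 0:
            raise TaskConfigError("drift_sd must be non-negative")


@dataclass(frozen=True)
class RewardWalk:
    """The four drifting reward probabilities, indexed [state2, choice2]."""

    probs: np.ndarray  # shape (2, 2)
    trial_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        if self.probs.shape != (2, 2):
            raise TaskConfigError("reward walk must hold a 2x2 probability array")


@dataclass(frozen=True)
class TrialRecord:
    """One completed trial. Trials/blocks are 1-based; actions/states 0-based."""

    trial: int
    block: int
    choice1: int
    transition: str  # "common" | "rare"
    state2: int
    choice2: int
    reward: int
    reward_probs_snapshot: tuple[float, float, float, float]  # row-major (state2, choice2)


@dataclass
class SessionLog:
    """One subject-session's trial sequence plus design metadata."""

    subject_id: str
    group: str  # "control" | "PTSD"
    condition: str  # "light" | "moderate"
    delay: str  # "short" | "long"
    visit: int  # 1 | 2
    site: str  # "UW" | "UT"
    age: float
    iq: float
    records: list[TrialRecord] = field(default_factory=list)
    extras: dict = field(default_factory=dict)  # generator metadata; not serialized


class Policy(Protocol):
    """Interface a behaving agent must expose to :func:`run_session`."""

    def act(self, stage: int, state2: int | None = None) -> int: ...

    def learn(self, record: TrialRecord) -> None: ...


class FixedPolicy:
    """Degenerate policy taking the same actions every trial (for tests/QC)."""

    def __init__(self, choice1: int = 0, choice2: int = 0) -> None:
        self.choice1 = choice1
        self.choice2 = choice2

    def act(self, stage: int, state2: int | None = None) -> int:
        return self.choice1 if stage == 1 else self.choice2

    def learn(self, record: TrialRecord) -> None:  # pragma: no cover - no-op
        pass


def common_destination(choice1: int) -> int:
    """Second-stage state a first-stage action preferentially leads to.

    The mapping is the identity (action a commonly reaches state a) and is
    fixed for a session; the two actions prefer opposite states.
    """
    return choice1


def reflect_into(x: np.ndarray, low: float, high: float) -> np.ndarray:
    """Fold values into [low, high] by reflection at both boundaries."""
    span = high - low
    if span <= 0:
        raise TaskConfigError("reflecting interval must have positive length")
    y = np.mod(np.asarray(x, dtype=float) - low, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return low + y


def init_walks(config: TaskConfig, rng: np.random.Generator) -> RewardWalk:
    """Draw the four starting reward probabilities uniform on the bounds."""
    if config.reward_low == config.reward_high:
        # degenerate interval: all walks pinned
        probs = np.full((2, 2), config.reward_low)
    else:
        probs = rng.uniform(config.reward_low, config.reward_high, size=(2, 2))
    return RewardWalk(probs=probs, trial_index=0)


def step_walk(walk: RewardWalk, config: TaskConfig, rng: np.random.Generator) -> RewardWalk:
    """Advance each walk by an independent Gaussian step, reflected at the bounds."""
    steps = rng.normal(0.0, config.drift_sd, size=(2, 2)) if config.drift_sd > 0 else 0.0
    probs = reflect_into(walk.probs + steps, config.reward_low, config.reward_high)
    return replace(walk, probs=probs, trial_index=walk.trial_index + 1)


def sample_transition(
    choice1: int, config: TaskConfig, rng: np.random.Generator
) -> tuple[int, str]:
    """Sample the second-stage state reached by a first-stage action.

    Returns ``(state2, label)`` where the label is "common" iff the
    preferred destination was reached.
    """
    if choice1 not in (0, 1):
        raise PolicyContractError(f"first-stage action must be 0 or 1, got {choice1}")
    preferred = common_destination(choice1)
    if rng.random() < config.p_common:
        return preferred, COMMON
    return 1 - preferred, RARE


def run_session(
    policy: Policy,
    config: TaskConfig,
    seed: int | np.random.Generator | None = None,
    *,
    subject_id: str = "sim",
    group: str = "control",
    condition: str = "light",
    delay: str = "short",
    visit: int = 1,
    site: str = "UW",
    age: float = 30.0,
    iq: float = 114.0,
) -> SessionLog:
    """Run one session of ``config.n_trials`` trials under ``policy``.

    The walks are stepped once per trial (including the first) before the
    reward draw; rewards are Bernoulli in the current walk value for the
    visited (state2, choice2) cell. Blocks are contiguous runs of equal
    length. Identical (policy, config, seed) reproduce the log exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    walk = init_walks(config, rng)
    block_len = config.n_trials // config.n_blocks
    records: list[TrialRecord] = []
    for t in range(1, config.n_trials + 1):
        walk = step_walk(walk, config, rng)
        choice1 = policy.act(1)
        if choice1 not in (0, 1):
            raise PolicyContractError(f"first-stage action must be 0 or 1, got {choice1}")
        state2, label = sample_transition(choice1, config, rng)
        choice2 = policy.act(2, state2)
        if choice2 not in (0, 1):
            raise PolicyContractError(f"second-stage action must be 0 or 1, got {choice2}")
        p_reward = float(walk.probs[state2, choice2])
        reward = int(rng.random() < p_reward)
        record = TrialRecord(
            trial=t,
            block=(t - 1) // block_len + 1,
            choice1=choice1,
            transition=label,
            state2=state2,
            choice2=choice2,
            reward=reward,
            reward_probs_snapshot=tuple(walk.probs.ravel().tolist()),
        )
        policy.learn(record)
        records.append(record)
    return SessionLog(
        subject_id=subject_id,
        group=group,
        condition=condition,
        delay=delay,
        visit=visit,
        site=site,
        age=age,
        iq=iq,
        records=records,
    )


def walk_trajectory(
    config: TaskConfig, n_steps: int, seed: int | None = None
) -> np.ndarray:
    """Simulate the reward walks for ``n_steps`` trials; shape (n_steps, 2, 2).

    Convenience for diagnostics: iterates :func:`step_walk` from a fresh
    :func:`init_walks` draw and stacks the per-trial snapshots.
    """
    rng = np.random.default_rng(seed)
    walk = init_walks(config, rng)
    out = np.empty((n_steps, 2, 2))
    for i in range(n_steps):
        walk = step_walk(walk, config, rng)
        out[i] = walk.probs
    return out
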