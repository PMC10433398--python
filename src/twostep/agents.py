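"""Synthetic behaving agents and cohort assembly.

The generator produces trial logs from hybrid reinforcement-learning
agents that mix model-free SARSA(lambda) values with model-based planning
through the true transition structure, weighted by ``w`` in [0, 1]:
``w = 0`` is a pure model-free learner (stay behavior shows a main effect
of previous reward), ``w = 1`` a pure model-based planner (stay behavior
shows the previous-reward x previous-transition crossover). Cohorts mirror
a 2 (group: control vs PTSD, between) x 2 (delay: short vs long, between)
x 2 (condition: light vs moderate exercise, within) x 2 (visit, within)
design with counterbalanced condition order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .task import SessionLog, TaskConfig, TrialRecord, common_destination, run_session

__all__ = [
    "AgentParams",
    "HybridAgent",
    "CohortSpec",
    "generate_cohort",
    "fig2_w_pattern",
    "uniform_w_pattern",
]

GROUPS = ("control", "PTSD")
CONDITIONS = ("light", "moderate")
DELAYS = ("short", "long")
SITES = ("UW", "UT")


class CohortSpecError(ValueError):
    """Raised for invalid cohort specifications."""


@dataclass(frozen=True)
class AgentParams:
    """Knobs of the hybrid agent.

    alpha : learning rate in [0, 1] (shared across stages)
    lam   : eligibility-trace parameter in [0, 1]
    beta1 : first-stage softmax inverse temperature >= 0
    beta2 : second-stage softmax inverse temperature >= 0
    w     : model-based weight in [0, 1]
    persev: perseveration bonus added to repeating the previous
            first-stage choice (log-odds scale before beta1)
    """

    alpha: float = 0.4
    lam: float = 0.6
    beta1: float = 5.0
    beta2: float = 5.0
    w: float = 1.0
    persev: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise CohortSpecError(f"alpha must be in [0,1], got {self.alpha}")
        if not (0.0 <= self.lam <= 1.0):
            raise CohortSpecError(f"lam must be in [0,1], got {self.lam}")
        if self.beta1 < 0 or self.beta2 < 0:
            raise CohortSpecError("inverse temperatures must be non-negative")
        if not (0.0 <= self.w <= 1.0):
            raise CohortSpecError(f"w must be in [0,1], got {self.w}")


def _softmax2(v0: float, v1: float, beta: float) -> float:
    """P(action 1) under a two-option softmax with inverse temperature beta."""
    d = beta * (v1 - v0)
    if d > 35.0:
        return 1.0
    if d < -35.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-d))


class HybridAgent:
    """Hybrid model-based / model-free agent for the two-stage task.

    First-stage net values combine a planner using the true transition
    probabilities, Q_MB(a) = p_common * max_a' Q2(dest(a), a') +
    (1 - p_common) * max_a' Q2(other, a'), with SARSA(lambda) model-free
    values, plus a perseveration bonus for repeating the previous choice:

        net(a) = w * Q_MB(a) + (1 - w) * Q_MF(a) + persev * 1[a == prev]

    Actions are sampled softmax(beta1 * net) at stage 1 and
    softmax(beta2 * Q2(state2, .)) at stage 2. After each trial:

        Q2(s2, c2) += alpha * (r - Q2(s2, c2))
        Q_MF(c1)   += alpha * (Q2_pre - Q_MF(c1)) + lam * alpha * (r - Q2_pre)

    where Q2_pre is the second-stage value before its update. The agent
    knows the true transition probabilities (the task's instruction design
    ensures subjects do).
    """

    def __init__(
        self,
        params: AgentParams,
        p_common: float = 0.70,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.params = params
        self.p_common = p_common
        self.rng = rng if rng is not None else np.random.default_rng()
        # plain python floats: this loop runs millions of times in cohort sims
        self.q2 = [[0.0, 0.0], [0.0, 0.0]]
        self.q_mf = [0.0, 0.0]
        self.prev_choice1: int | None = None

    def action_probabilities(self, stage: int, state2: int | None = None) -> tuple[float, float]:
        """Return (P(action 0), P(action 1)) at the given stage."""
        p = self.params
        if stage == 2:
            if state2 not in (0, 1):
                raise ValueError("stage-2 probabilities need a valid state2")
            q = self.q2[state2]
            p1 = _softmax2(q[0], q[1], p.beta2)
            return 1.0 - p1, p1
        pc = self.p_common
        best0 = max(self.q2[0][0], self.q2[0][1])
        best1 = max(self.q2[1][0], self.q2[1][1])
        # identity action->destination mapping, matching the task engine
        q_mb0 = pc * best0 + (1.0 - pc) * best1
        q_mb1 = pc * best1 + (1.0 - pc) * best0
        net0 = p.w * q_mb0 + (1.0 - p.w) * self.q_mf[0]
        net1 = p.w * q_mb1 + (1.0 - p.w) * self.q_mf[1]
        if self.prev_choice1 == 0:
            net0 += p.persev
        elif self.prev_choice1 == 1:
            net1 += p.persev
        p1 = _softmax2(net0, net1, p.beta1)
        return 1.0 - p1, p1

    def act(self, stage: int, state2: int | None = None) -> int:
        _, p1 = self.action_probabilities(stage, state2)
        return int(self.rng.random() < p1)

    def learn(self, record: TrialRecord) -> None:
        p = self.params
        s2, c1, c2, r = record.state2, record.choice1, record.choice2, record.reward
        q2_pre = self.q2[s2][c2]
        self.q2[s2][c2] = q2_pre + p.alpha * (r - q2_pre)
        self.q_mf[c1] += p.alpha * (q2_pre - self.q_mf[c1]) + p.lam * p.alpha * (r - q2_pre)
        self.prev_choice1 = c1


def fig2_w_pattern() -> dict[tuple[str, str, str], float]:
    """Cell means of the model-based weight mirroring the study's effect pattern.

    Keys are (group, condition, delay). The pattern encodes: PTSD more
    model-based after moderate than light exercise at both delays (much
    more at the long delay); controls more model-based than PTSD except
    at moderate/long, where the ordering reverses; controls drop at
    moderate/long relative to moderate/short.
    """
    return {
        ("control", "light", "short"): 0.8,
        ("control", "light", "long"): 0.8,
        ("control", "moderate", "short"): 0.8,
        ("control", "moderate", "long"): 0.3,
        ("PTSD", "light", "short"): 0.2,
        ("PTSD", "light", "long"): 0.2,
        ("PTSD", "moderate", "short"): 0.5,
        ("PTSD", "moderate", "long"): 0.9,
    }


def uniform_w_pattern(w: float = 0.6) -> dict[tuple[str, str, str], float]:
    """A null pattern: the same model-based weight in every design cell."""
    return {
        (g, c, d): w for g in GROUPS for c in CONDITIONS for d in DELAYS
    }


@dataclass
class CohortSpec:
    """Cohort assembly: cell sizes, parameter distributions, covariates.

    ``n_per_cell`` subjects are generated in each of the four between-subject
    cells (group x delay). Each subject completes both conditions, one per
    visit, with condition order counterbalanced within the cell. The
    model-based weight mean per (group, condition, delay) cell comes from
    ``w_mean``; ``visit_w_increment`` is added at visit 2 (practice effect).
    All agent parameters are drawn truncated-normal per subject-session.
    Ages: control ~ N(29.6, 8.1), PTSD ~ N(37.1, 9.2), truncated to
    [21, 50]; IQ ~ N(114, 12). Sites alternate across subjects.
    """

    n_per_cell: int = 15
    w_mean: dict[tuple[str, str, str], float] = field(default_factory=fig2_w_pattern)
    w_sd: float = 0.1
    visit_w_increment: float = 0.05
    alpha_mean: float = 0.4
    alpha_sd: float = 0.1
    lam_mean: float = 0.6
    lam_sd: float = 0.1
    beta1_mean: float = 5.0
    beta1_sd: float = 1.0
    beta2_mean: float = 5.0
    beta2_sd: float = 1.0
    persev_mean: float = 0.1
    persev_sd: float = 0.05
    age_mean: dict[str, float] = field(
        default_factory=lambda: {"control": 29.6, "PTSD": 37.1}
    )
    age_sd: dict[str, float] = field(
        default_factory=lambda: {"control": 8.1, "PTSD": 9.2}
    )
    age_bounds: tuple[float, float] = (21.0, 50.0)
    iq_mean: float = 114.0
    iq_sd: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise CohortSpecError("n_per_cell must be >= 1")
        missing = [
            (g, c, d)
            for g in GROUPS
            for c in CONDITIONS
            for d in DELAYS
            if (g, c, d) not in self.w_mean
        ]
        if missing:
            raise CohortSpecError(f"w_mean missing cells: {missing}")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  low: float, high: float) -> float:
    if sd <= 0:
        return float(min(max(mean, low), high))
    a, b = (low - mean) / sd, (high - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _draw_params(rng: np.random.Generator, spec: CohortSpec, w_mean: float) -> AgentParams:
    return AgentParams(
        alpha=_trunc_normal(rng, spec.alpha_mean, spec.alpha_sd, 0.0, 1.0),
        lam=_trunc_normal(rng, spec.lam_mean, spec.lam_sd, 0.0, 1.0),
        beta1=_trunc_normal(rng, spec.beta1_mean, spec.beta1_sd, 0.0, 50.0),
        beta2=_trunc_normal(rng, spec.beta2_mean, spec.beta2_sd, 0.0, 50.0),
        w=_trunc_normal(rng, w_mean, spec.w_sd, 0.0, 1.0),
        persev=float(rng.normal(spec.persev_mean, spec.persev_sd))
        if spec.persev_sd > 0
        else spec.persev_mean,
    )


def generate_cohort(spec: CohortSpec, config: TaskConfig) -> list[SessionLog]:
    """Generate two SessionLogs per subject across the full design.

    Deterministic given ``spec.seed``: subject-level randomness is derived
    from a spawned seed sequence, so changing one subject's draw order
    never perturbs another's.
    """
    root = np.random.SeedSequence(spec.seed)
    logs: list[SessionLog] = []
    subject_index = 0
    prefix = {"control": "CON", "PTSD": "PTSD"}
    for group in GROUPS:
        for delay in DELAYS:
            for i in range(spec.n_per_cell):
                sub_seq = root.spawn(1)[0]
                rng = np.random.default_rng(sub_seq)
                subject_id = f"{prefix[group]}-{delay[0].upper()}{i + 1:02d}"
                age = _trunc_normal(
                    rng, spec.age_mean[group], spec.age_sd[group], *spec.age_bounds
                )
                iq = float(rng.normal(spec.iq_mean, spec.iq_sd))
                # site and condition order crossed within each cell so that
                # site is never confounded with the counterbalancing
                site = SITES[(i // 2) % 2]
                # counterbalance: even subjects do light first, odd moderate first
                order = CONDITIONS if i % 2 == 0 else CONDITIONS[::-1]
                for visit, condition in zip((1, 2), order):
                    w_mean = spec.w_mean[(group, condition, delay)]
                    w_mean += spec.visit_w_increment * (visit - 1)
                    w_mean = min(max(w_mean, 0.0), 1.0)
                    params = _draw_params(rng, spec, w_mean)
                    agent = HybridAgent(params, p_common=config.p_common, rng=rng)
                    log = run_session(
                        agent,
                        config,
                        seed=rng,
                        subject_id=subject_id,
                        group=group,
                        condition=condition,
                        delay=delay,
                        visit=visit,
                        site=site,
                        age=age,
                        iq=iq,
                    )
                    log.extras["params"] = params
                    logs.append(log)
                subject_index += 1
    return logs
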