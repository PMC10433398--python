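"""Stay/switch analysis frame, QC, descriptive stay tables, effect sizes.

The behavioral unit of analysis is whether the first-stage choice on
trial t repeats the choice on trial t-1 (stay = 1) as a function of the
previous trial's reward and transition type. Both predictors are effect
coded +/-0.5 (rewarded/common = +0.5) so the logistic interaction
coefficient is directly the log-odds crossover contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import SessionLog

__all__ = [
    "FEATURE_COLUMNS",
    "StayTable",
    "EffectSize",
    "build_lagged_features",
    "features_from_logs",
    "qc_invariant_responders",
    "stay_table",
    "subject_stay_probs",
    "cohens_d",
]

REWARD_CODE = {1: 0.5, 0: -0.5}
TRANSITION_CODE = {"common": 0.5, "rare": -0.5}

FEATURE_COLUMNS = [
    "subject_id", "group", "condition", "delay", "visit", "site",
    "age", "iq", "trial", "stay", "prev_reward", "prev_transition",
]


class DegenerateSampleError(ValueError):
    """Raised when an effect size is undefined (zero pooled SD)."""


@dataclass(frozen=True)
class EffectSize:
    cohens_d: float
    n1: int
    n2: int


@dataclass(frozen=True)
class StayTable:
    """2x2 stay probabilities by (previous reward) x (previous transition).

    ``probs``/``counts`` are indexed [reward][transition] with reward in
    {"rewarded", "unrewarded"} and transition in {"common", "rare"}.
    Empty bins carry probability NaN and are listed in ``empty_bins``.
    """

    probs: pd.DataFrame
    counts: pd.DataFrame

    @property
    def empty_bins(self) -> list[tuple[str, str]]:
        out = []
        for r in self.counts.index:
            for t in self.counts.columns:
                if self.counts.loc[r, t] == 0:
                    out.append((r, t))
        return out


def build_lagged_features(
    log: SessionLog, *, drop_block_starts: bool = False
) -> pd.DataFrame:
    """One row per trial >= 2: stay indicator plus lagged reward/transition.

    Lags cross block boundaries within the session (the 30-second rests are
    assumed not to reset behavior); pass ``drop_block_starts=True`` to drop
    rows whose trial opens a new block instead. Sessions with fewer than 2
    trials produce an empty frame.
    """
    n = len(log.records)
    if n < 2:
        import warnings

        warnings.warn(f"session {log.subject_id} has < 2 trials; no lagged rows")
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    choice1 = np.fromiter((r.choice1 for r in log.records), dtype=int, count=n)
    reward = np.fromiter((r.reward for r in log.records), dtype=int, count=n)
    common = np.fromiter(
        (r.transition == "common" for r in log.records), dtype=bool, count=n
    )
    trial = np.fromiter((r.trial for r in log.records), dtype=int, count=n)
    keep = np.ones(n - 1, dtype=bool)
    if drop_block_starts:
        block = np.fromiter((r.block for r in log.records), dtype=int, count=n)
        keep = block[1:] == block[:-1]
    frame = pd.DataFrame(
        {
            "subject_id": log.subject_id,
            "group": log.group,
            "condition": log.condition,
            "delay": log.delay,
            "visit": log.visit,
            "site": log.site,
            "age": log.age,
            "iq": log.iq,
            "trial": trial[1:][keep],
            "stay": (choice1[1:] == choice1[:-1]).astype(int)[keep],
            "prev_reward": np.where(reward[:-1], 0.5, -0.5)[keep],
            "prev_transition": np.where(common[:-1], 0.5, -0.5)[keep],
        }
    )
    return frame[FEATURE_COLUMNS]


def features_from_logs(
    logs: list[SessionLog], *, drop_block_starts: bool = False
) -> pd.DataFrame:
    """Concatenate lagged features over sessions (lags never cross sessions)."""
    frames = [
        build_lagged_features(log, drop_block_starts=drop_block_starts) for log in logs
    ]
    if not frames:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def qc_invariant_responders(
    logs: list[SessionLog],
) -> tuple[list[SessionLog], pd.DataFrame]:
    """Exclude subjects who gave the same first-stage response all session.

    A subject is dropped entirely (all their sessions) if any one of their
    sessions has an invariant first-stage choice sequence. Returns the
    retained logs and a report of excluded subjects.
    """
    flagged: dict[str, str] = {}
    for log in logs:
        choices = {r.choice1 for r in log.records}
        if log.records and len(choices) == 1:
            flagged.setdefault(
                log.subject_id,
                f"invariant first-stage response (always {choices.pop()}) in "
                f"{log.condition}/visit {log.visit}",
            )
    retained = [log for log in logs if log.subject_id not in flagged]
    report = pd.DataFrame(
        sorted(flagged.items()), columns=["subject_id", "reason"]
    )
    return retained, report


def _bin_masks(features: pd.DataFrame):
    for r_label, r_code in (("rewarded", 0.5), ("unrewarded", -0.5)):
        for t_label, t_code in (("common", 0.5), ("rare", -0.5)):
            yield r_label, t_label, (
                (features["prev_reward"] == r_code)
                & (features["prev_transition"] == t_code)
            )


def stay_table(features: pd.DataFrame, **filters) -> StayTable:
    """Mean stay probability in each (previous reward) x (transition) bin.

    Keyword filters subset on feature columns first, e.g.
    ``stay_table(f, group="PTSD", condition="moderate")``.
    """
    sub = features
    for col, val in filters.items():
        sub = sub[sub[col] == val]
    if sub.empty:
        raise ValueError("no rows left after applying filters")
    idx = ["rewarded", "unrewarded"]
    cols = ["common", "rare"]
    probs = pd.DataFrame(np.nan, index=idx, columns=cols)
    counts = pd.DataFrame(0, index=idx, columns=cols, dtype=int)
    for r_label, t_label, mask in _bin_masks(sub):
        n = int(mask.sum())
        counts.loc[r_label, t_label] = n
        if n > 0:
            probs.loc[r_label, t_label] = float(sub.loc[mask, "stay"].mean())
    return StayTable(probs=probs, counts=counts)


def subject_stay_probs(
    features: pd.DataFrame, prev_reward: str, prev_transition: str, **filters
) -> pd.Series:
    """Per-subject stay probability in one bin (for between-sample effect sizes)."""
    sub = features
    for col, val in filters.items():
        sub = sub[sub[col] == val]
    r_code = 0.5 if prev_reward == "rewarded" else -0.5
    t_code = 0.5 if prev_transition == "common" else -0.5
    sub = sub[(sub["prev_reward"] == r_code) & (sub["prev_transition"] == t_code)]
    return sub.groupby("subject_id")["stay"].mean()


def cohens_d(sample_a, sample_b) -> EffectSize:
    """Standardized mean difference (mean_a - mean_b) / pooled SD.

    Pooled SD uses n-1 denominators weighted by (n_i - 1); no small-sample
    (Hedges) correction is applied.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var <= 0:
        raise DegenerateSampleError("pooled SD is zero; Cohen's d undefined")
    return EffectSize(
        cohens_d=float((a.mean() - b.mean()) / np.sqrt(pooled_var)), n1=n1, n2=n2
    )
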