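"""Trial-log CSV round-trip, config loading, and the run manifest."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .agents import CohortSpec
from .task import SessionLog, TaskConfig, TrialRecord

__all__ = [
    "LOG_COLUMNS",
    "logs_to_frame",
    "frame_to_logs",
    "write_logs",
    "read_logs",
    "load_config",
    "task_config_from_dict",
    "cohort_spec_from_dict",
    "RunManifest",
]

LOG_COLUMNS = [
    "subject_id", "group", "condition", "delay", "visit", "site", "age", "iq",
    "trial", "block", "choice1", "transition", "state2", "choice2", "reward",
]


class ConfigError(ValueError):
    """Malformed configuration file."""


def logs_to_frame(logs: list[SessionLog]) -> pd.DataFrame:
    rows = []
    for log in logs:
        for r in log.records:
            rows.append(
                (
                    log.subject_id, log.group, log.condition, log.delay, log.visit,
                    log.site, log.age, log.iq, r.trial, r.block, r.choice1,
                    r.transition, r.state2, r.choice2, r.reward,
                )
            )
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def frame_to_logs(frame: pd.DataFrame) -> list[SessionLog]:
    missing = [c for c in LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigError(f"trial-log frame missing columns: {missing}")
    logs = []
    keys = ["subject_id", "condition", "visit"]
    for (sid, cond, visit), g in frame.groupby(keys, sort=False):
        g = g.sort_values("trial")
        first = g.iloc[0]
        records = [
            TrialRecord(
                trial=int(r.trial),
                block=int(r.block),
                choice1=int(r.choice1),
                transition=str(r.transition),
                state2=int(r.state2),
                choice2=int(r.choice2),
                reward=int(r.reward),
                reward_probs_snapshot=(float("nan"),) * 4,
            )
            for r in g.itertuples()
        ]
        logs.append(
            SessionLog(
                subject_id=str(sid),
                group=str(first.group),
                condition=str(cond),
                delay=str(first.delay),
                visit=int(visit),
                site=str(first.site),
                age=float(first.age),
                iq=float(first.iq),
                records=records,
            )
        )
    return logs


def write_logs(logs: list[SessionLog], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    logs_to_frame(logs).to_csv(path, index=False)
    return path


def read_logs(path: str | Path) -> list[SessionLog]:
    return frame_to_logs(pd.read_csv(path))


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON, a YAML subset) config file into a dict."""
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def task_config_from_dict(cfg: dict) -> TaskConfig:
    section = cfg.get("task", {})
    try:
        return TaskConfig(**section)
    except TypeError as exc:
        raise ConfigError(f"task section: {exc}") from exc


def cohort_spec_from_dict(cfg: dict, seed: int | None = None) -> CohortSpec:
    section = dict(cfg.get("cohort", {}))
    if "w_mean" in section:
        raw = section["w_mean"]
        try:
            section["w_mean"] = {
                (g, c, d): float(raw[g][c][d])
                for g in raw
                for c in raw[g]
                for d in raw[g][c]
            }
        except (KeyError, TypeError) as exc:
            raise ConfigError(
                "cohort.w_mean must nest group -> condition -> delay -> value"
            ) from exc
    if seed is not None:
        section["seed"] = seed
    elif "seed" not in section:
        section["seed"] = int(cfg.get("seed", 0))
    try:
        return CohortSpec(**section)
    except TypeError as exc:
        raise ConfigError(f"cohort section: {exc}") from exc


@dataclass
class RunManifest:
    """What a pipeline stage did: resolved config, seeds, counts, outputs."""

    command: str
    config: dict
    seed: int
    version: str
    row_counts: dict[str, int] = field(default_factory=dict)
    exclusions: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = asdict(self)
        missing = [p for p in self.outputs if not Path(p).exists()]
        if missing:
            raise RuntimeError(f"manifest lists outputs that do not exist: {missing}")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, default=str)
        return path
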