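"""Plain-text I/O: sessions and covariates as CSV, reflections as JSON
lines, task/prior configuration as YAML. Synthetic cohorts are written to
the same files a real-data ingest would read, so the downstream pipeline is
path-identical for either source."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .cohort import Participant
from .hgf import BeliefTrajectory
from .metacog import Reflection
from .prl import SessionData, TaskConfig, TrialRecord

__all__ = [
    "sessions_to_frame",
    "write_sessions_csv",
    "read_sessions_csv",
    "write_reflections_jsonl",
    "read_reflections_jsonl",
    "write_task_config",
    "read_task_config",
    "trajectory_to_frame",
    "write_cohort",
]


def sessions_to_frame(sessions: list[SessionData]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for r in s.records:
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "trial": r.t,
                    "choice": r.choice,
                    "outcome": r.outcome,
                    "p1": r.assigned_probs[0],
                    "p2": r.assigned_probs[1],
                    "p3": r.assigned_probs[2],
                    "reversal_event": r.reversal_event,
                }
            )
    return pd.DataFrame(rows)


def write_sessions_csv(sessions: list[SessionData], path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def read_sessions_csv(path) -> list[SessionData]:
    df = pd.read_csv(path)
    sessions = []
    for pid, grp in df.groupby("participant_id", sort=False):
        records = [
            TrialRecord(
                t=int(row.trial),
                choice=int(row.choice),
                outcome=int(row.outcome),
                assigned_probs=(float(row.p1), float(row.p2), float(row.p3)),
                reversal_event=str(row.reversal_event),
            )
            for row in grp.sort_values("trial").itertuples()
        ]
        sessions.append(SessionData(participant_id=str(pid), records=records))
    return sessions


def write_reflections_jsonl(reflections: list[Reflection], path) -> None:
    with open(path, "w") as fh:
        for r in reflections:
            fh.write(json.dumps({"participant_id": r.participant_id, "text": r.text}) + "\n")


def read_reflections_jsonl(path) -> list[Reflection]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                out.append(Reflection(participant_id=d["participant_id"], text=d["text"]))
    return out


def write_task_config(config: TaskConfig, path) -> None:
    payload = {
        "n_trials": config.n_trials,
        "n_options": config.n_options,
        "probs_pre": list(config.probs_pre),
        "probs_post": list(config.probs_post),
        "shift_trial": config.shift_trial,
        "scheduled_period": config.scheduled_period,
        "perf_window": config.perf_window,
        "perf_criterion": config.perf_criterion,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_task_config(path) -> TaskConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["probs_pre"] = tuple(raw["probs_pre"])
    raw["probs_post"] = tuple(raw["probs_post"])
    return TaskConfig(**raw)


def trajectory_to_frame(traj: BeliefTrajectory) -> pd.DataFrame:
    n_opts = traj.xhat2.shape[1]
    data = {"trial": range(1, traj.n_trials + 1)}
    for j in range(n_opts):
        data[f"xhat2_{j + 1}"] = traj.xhat2[:, j]
        data[f"mu2_{j + 1}"] = traj.mu2[:, j]
        data[f"mhat_{j + 1}"] = traj.mhat[:, j]
        data[f"sigma2_{j + 1}"] = traj.sigma2[:, j]
    data["xhat3"] = traj.xhat3
    data["mu3"] = traj.mu3
    data["sigma3"] = traj.sigma3
    data["delta1"] = traj.delta1
    data["delta2"] = traj.delta2
    return pd.DataFrame(data)


def write_cohort(participants: list[Participant], outdir) -> dict[str, Path]:
    """Write a generated cohort as trials.csv, reflections.jsonl and
    covariates.csv under ``outdir`` (created if missing)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": outdir / "trials.csv",
        "reflections": outdir / "reflections.jsonl",
        "covariates": outdir / "covariates.csv",
    }
    sessions = [p.session for p in participants if p.session is not None]
    write_sessions_csv(sessions, paths["trials"])
    write_reflections_jsonl([p.reflection for p in participants], paths["reflections"])
    cov = pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in participants],
            "rgpts_persecution": [p.rgpts_persecution for p in participants],
            "group": [p.group for p in participants],
            "education": [p.education for p in participants],
            "crt1": [p.crt_answers[0] for p in participants],
            "crt2": [p.crt_answers[1] for p in participants],
            "crt3": [p.crt_answers[2] for p in participants],
            "age": [p.age for p in participants],
            "gender": [p.gender for p in participants],
            "true_mu3_0": [p.params.mu3_0 for p in participants],
        }
    )
    cov.to_csv(paths["covariates"], index=False)
    return paths
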