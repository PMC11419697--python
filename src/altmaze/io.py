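"""Reading and writing the delimited visit-log dialect and YAML configs.

The visit-log file is a CSV with header
``rat_id,group,phase,day,session,trial_index,location,rewarded`` (one row per
reward-location visit) plus an optional trailing ``task`` column naming the
maze the session ran on.  Logs are validated on read; malformed rows are
reported with their line numbers.
"""

from __future__ import annotations

import pandas as pd
import yaml

from .codec import Visit, VisitDataError, VisitLog

VISIT_COLUMNS = [
    "rat_id", "group", "phase", "day", "session", "trial_index", "location", "rewarded",
]


def write_visit_logs(logs, path) -> None:
    """Write a collection of :class:`VisitLog` to one CSV file."""
    rows = []
    any_task = any(log.task for log in logs)
    for log in logs:
        for v in log.visits:
            row = {
                "rat_id": log.rat_id,
                "group": log.group,
                "phase": log.phase,
                "day": log.day,
                "session": log.session,
                "trial_index": v.trial_index,
                "location": v.location,
                "rewarded": int(v.rewarded),
            }
            if any_task:
                row["task"] = log.task or ""
            rows.append(row)
    cols = VISIT_COLUMNS + (["task"] if any_task else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_visit_logs(path) -> list:
    """Read and validate visit logs; returns one :class:`VisitLog` per
    (rat, phase, day, session)."""
    df = pd.read_csv(path)
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise VisitDataError(f"{path}: missing columns {missing}")
    has_task = "task" in df.columns
    logs = []
    keys = ["rat_id", "phase", "day", "session"]
    for key, sub in df.groupby(keys, sort=True):
        rat_id, phase, day, session = key
        sub = sub.sort_values("trial_index")
        visits = []
        for line, row in zip(sub.index, sub.itertuples(index=False)):
            loc = int(row.location)
            if not 1 <= loc <= 4:
                raise VisitDataError(f"{path}: impossible location {loc} at row {line + 2}")
            visits.append(Visit(int(row.trial_index), loc, bool(int(row.rewarded))))
        task = None
        if has_task:
            tasks = set(sub["task"].dropna().astype(str)) - {""}
            if len(tasks) > 1:
                raise VisitDataError(f"{path}: conflicting tasks {tasks} for {key}")
            task = tasks.pop() if tasks else None
        try:
            logs.append(
                VisitLog(
                    str(rat_id), str(sub["group"].iloc[0]), int(phase), int(day),
                    int(session), visits, task,
                )
            )
        except VisitDataError as e:
            first = sub.index[0] + 2
            raise VisitDataError(f"{path}: near row {first}: {e}") from e
    return logs


def read_config(path) -> dict:
    """Load a YAML (or JSON, a YAML subset) pipeline configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
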