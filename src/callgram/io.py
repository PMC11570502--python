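"""Delimited-text formats and validation.

All tables are comma-separated UTF-8 with a mandatory header row and "."
decimals.  ``calls.csv`` columns: trial_id, call_index, onset_s, duration_s,
max_freq_khz, true_type (optional), assigned_type (optional).  ``trials.csv``
columns: trial_id, dataset, stimulus, mode, elevation, group_location.
Readers return typed records, enforce onset order within trials, and report
rejected rows instead of silently dropping them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segment import CallSequence
from .synth import CallRecord, Trial

log = logging.getLogger("callgram")

CALL_COLUMNS = ["trial_id", "call_index", "onset_s", "duration_s",
                "max_freq_khz"]
TRIAL_COLUMNS = ["trial_id", "dataset", "stimulus", "mode", "elevation",
                 "group_location"]


class SchemaError(ValueError):
    pass


@dataclass
class ValidationReport:
    n_rows: int = 0
    n_accepted: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_calls(path) -> tuple[list[CallRecord], ValidationReport]:
    """Read a calls table; rows with unparseable numerics are rejected and
    logged, and calls are sorted by onset within each trial."""
    df = pd.read_csv(path, dtype=str)
    _require(df, CALL_COLUMNS, path)
    report = ValidationReport(n_rows=len(df))
    records: list[CallRecord] = []
    for i, row in df.iterrows():
        try:
            onset = float(row["onset_s"])
            dur = float(row["duration_s"])
            freq = float(row["max_freq_khz"])
            idx = int(row["call_index"])
        except (TypeError, ValueError) as exc:
            report.rejected.append((int(i), str(exc)))
            log.warning("calls row %d rejected: %s", i, exc)
            continue
        if not (np.isfinite(onset) and dur > 0 and freq > 0):
            report.rejected.append((int(i), "non-positive duration/frequency"))
            continue
        records.append(CallRecord(
            trial_id=str(row["trial_id"]), call_index=idx, onset=onset,
            duration=dur, max_frequency=freq,
            true_type=(str(row["true_type"])
                       if "true_type" in df.columns
                       and pd.notna(row.get("true_type")) else None),
            assigned_type=(str(row["assigned_type"])
                           if "assigned_type" in df.columns
                           and pd.notna(row.get("assigned_type"))
                           else "unassigned")))
    records.sort(key=lambda c: (c.trial_id, c.onset))
    report.n_accepted = len(records)
    return records, report


def read_trials(path) -> tuple[list[Trial], ValidationReport]:
    df = pd.read_csv(path, dtype=str)
    _require(df, TRIAL_COLUMNS, path)
    report = ValidationReport(n_rows=len(df), n_accepted=len(df))
    trials = [Trial(trial_id=str(r["trial_id"]), dataset=str(r["dataset"]),
                    stimulus=str(r["stimulus"]), mode=str(r["mode"]),
                    elevation=str(r["elevation"]),
                    group_location=str(r["group_location"]),
                    responded=bool(int(r["responded"]))
                    if "responded" in df.columns else True)
              for _, r in df.iterrows()]
    return trials, report


def calls_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame([{
        "trial_id": c.trial_id, "call_index": c.call_index,
        "onset_s": c.onset, "duration_s": c.duration,
        "max_freq_khz": c.max_frequency,
        "true_type": c.true_type if c.true_type else "",
        "assigned_type": c.assigned_type,
    } for c in calls])


def trials_to_frame(trials) -> pd.DataFrame:
    return pd.DataFrame([{
        "trial_id": t.trial_id, "dataset": t.dataset, "stimulus": t.stimulus,
        "mode": t.mode, "elevation": t.elevation,
        "group_location": t.group_location, "responded": int(t.responded),
    } for t in trials])


def sequences_to_frame(sequences) -> pd.DataFrame:
    from .grammar import classify_pattern, initiation, termination_bigram

    return pd.DataFrame([{
        "trial_id": s.trial_id, "symbols": s.symbols,
        "pattern": s.pattern or classify_pattern(s.symbols),
        "initiation": initiation(s.symbols),
        "termination": termination_bigram(s.symbols),
        "n": s.n, "start_s": s.start_s, "end_s": s.end_s,
    } for s in sequences])


def read_sequences(path) -> list[CallSequence]:
    df = pd.read_csv(path, dtype={"trial_id": str, "symbols": str})
    _require(df, ["trial_id", "symbols", "start_s", "end_s"], path)
    return [CallSequence(trial_id=str(r["trial_id"]), symbols=str(r["symbols"]),
                         start_s=float(r["start_s"]), end_s=float(r["end_s"]),
                         pattern=(str(r["pattern"])
                                  if "pattern" in df.columns else None))
            for _, r in df.iterrows()]


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
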