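"""Context-specificity analysis of sequence production.

Builds the per-trial count tables behind the sequence-initiation, overall
sequence-pattern and sequence-termination models (one row per trial x
category level, with explicit zeros and an exposure offset
``log(total sequences in the trial + 1)``), fits the Poisson
random-intercept GLMM of :mod:`callgram.glmm`, and computes per-stimulus
vocal response rates.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .glmm import PoissonRandomInterceptModel
from .grammar import classify_pattern, initiation, termination_bigram
from .segment import CallSequence
from .synth import CallRecord, Trial

CATEGORY_LEVELS = {
    "initiation": ["A", "B"],
    "pattern": ["A_repeat", "BA", "A_BA", "BA_A"],
    "termination": ["AA_gram", "BA_gram"],
}

#: treatment-coding reference levels of the count models
REFERENCES = {
    "initiation": "A",
    "pattern": "A_repeat",
    "termination": "AA_gram",
    "stimulus": "eagle",
    "group_location": "north",
    "elevation": "ground",
}


def _categorize(symbols: str, category: str) -> str:
    if category == "initiation":
        return initiation(symbols)
    if category == "pattern":
        return classify_pattern(symbols)
    if category == "termination":
        return termination_bigram(symbols)
    raise ValueError(f"unknown category {category!r}")


def build_count_table(sequences: Sequence[CallSequence],
                      trials: Sequence[Trial], category: str,
                      window: float = 160.0,
                      include_other_in_offset: bool = True) -> pd.DataFrame:
    """Per-trial counts of sequences in each category level.

    Only responding trials (>= 1 sequence starting inside the analysis
    window) contribute; unobserved levels appear as explicit zeros.  The
    offset is ``log(N_total_sequences_in_trial + 1)`` where the total counts
    every sequence in the window (including ones outside the modeled levels,
    e.g. "other" patterns) unless ``include_other_in_offset`` is False.
    """
    if category not in CATEGORY_LEVELS:
        raise ValueError(f"unknown category {category!r}")
    levels = CATEGORY_LEVELS[category]
    tr = {t.trial_id: t for t in trials}
    per_trial: dict[str, list[str]] = {}
    for s in sequences:
        if s.start_s >= window:
            continue
        if s.trial_id not in tr:
            raise ValueError(f"sequence references unknown trial {s.trial_id!r}")
        per_trial.setdefault(s.trial_id, []).append(s.symbols)
    rows = []
    for tid, seqs in per_trial.items():
        cats = [_categorize(s, category) for s in seqs]
        n_tot = len(seqs) if include_other_in_offset else sum(
            c in levels for c in cats)
        t = tr[tid]
        for lev in levels:
            rows.append({
                "trial_id": tid,
                "level": lev,
                "count": sum(c == lev for c in cats),
                "stimulus": t.stimulus,
                "mode": t.mode,
                "elevation": t.elevation,
                "group_location": t.group_location,
                "offset_log": math.log(n_tot + 1.0),
            })
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(["trial_id", "level"]).reset_index(drop=True)
    return table


def fit_category_model(table: pd.DataFrame, category: str,
                       ridge_sd: float | None = None,
                       include_location: bool = True,
                       stimuli: Iterable[str] = ("eagle", "leopard", "tree")):
    """Fit ``count ~ level * stimulus (+ group_location)`` with the trial
    random intercept and exposure offset; returns (model, results)."""
    sub = table[table["stimulus"].isin(list(stimuli))].copy()
    factors = {"level": REFERENCES[category], "stimulus": REFERENCES["stimulus"]}
    if include_location:
        factors["group_location"] = REFERENCES["group_location"]
    model = PoissonRandomInterceptModel.from_dataframe(
        sub, "count", factors, interactions=[("level", "stimulus")],
        groups="trial_id", offset="offset_log")
    return model, model.fit(ridge_sd=ridge_sd)


def response_rate(trials: Sequence[Trial], calls: Sequence[CallRecord],
                  window: float = 160.0) -> pd.DataFrame:
    """Percentage of trials with >= 1 call before ``window``, per
    (stimulus, mode)."""
    responded: set[str] = {c.trial_id for c in calls if c.onset < window}
    rows = []
    groups: dict[tuple[str, str], list[Trial]] = {}
    for t in trials:
        groups.setdefault((t.stimulus, t.mode), []).append(t)
    for (stim, mode), ts in sorted(groups.items()):
        n = len(ts)
        k = sum(t.trial_id in responded for t in ts)
        rows.append({"stimulus": stim, "mode": mode, "n_trials": n,
                     "n_responded": k, "rate_pct": 100.0 * k / n})
    return pd.DataFrame(rows)
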