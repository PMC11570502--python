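"""Synthetic corpus generator for two-call-type alarm sequences.

Emulates the statistical structure of an Olive colobus playback/visual-model
study corpus: two acoustic call classes ("A": short, low frequency; "B": long,
high frequency), call sequences built from a small set of grammar-conforming
patterns, within-sequence inter-call gaps far shorter than between-sequence
gaps, and stimulus-dependent pattern frequencies.  Every downstream stage of
the pipeline (clustering, segmentation, grammar induction, count models) is
testable against corpora drawn here, with known ground truth.

Units: seconds for all times and durations, kHz for maximum frequency.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

PATTERNS = ("A_repeat", "BA", "A_BA", "BA_A")
STIMULI = ("leopard", "eagle", "tree", "chimpanzee")
MODES = ("playback", "visual_model")

#: duration (s) and maximum frequency (kHz) of the two call classes,
#: mean +/- SD as measured on the field corpus (N=921 "A", N=325 "B").
DEFAULT_ACOUSTICS = {
    "A": {"dur_mean": 0.12, "dur_sd": 0.12, "freq_mean": 1.00, "freq_sd": 0.16,
          "truncation": 3.0},
    "B": {"dur_mean": 0.58, "dur_sd": 0.28, "freq_mean": 7.72, "freq_sd": 1.73,
          "truncation": 3.0},
}

#: within-sequence and between-sequence inter-call interval distributions,
#: arithmetic mean/SD in seconds (log-normal via moment matching).
DEFAULT_INTERVALS = {
    "within_mean": 0.12, "within_sd": 0.14,
    "between_mean": 22.8, "between_sd": 21.3,
}


def _remainder(major: str, p: float) -> dict[str, float]:
    rest = (1.0 - p) / 3.0
    return {pat: (p if pat == major else rest) for pat in PATTERNS}


#: stimulus-conditioned sequence-pattern probabilities; the dominant class and
#: its share follow the field percentages (leopard -> "BA" grams, eagle ->
#: "A + BA", falling tree -> "BA + A"); the remaining mass is spread uniformly
#: over the classes whose shares were not reported.
DEFAULT_PATTERN_PROBS = {
    "leopard": _remainder("BA", 0.72),
    "eagle": _remainder("A_BA", 0.36),
    "tree": _remainder("BA_A", 0.60),
    "chimpanzee": {pat: 0.25 for pat in PATTERNS},
}

#: per-stimulus probability that a playback trial draws any vocal response
#: (from the reported response rates); visual-model trials have their own map.
DEFAULT_RESPONSE_PROBS = {
    "leopard": 0.614, "eagle": 0.367, "tree": 0.506, "chimpanzee": 0.0,
}
DEFAULT_VISUAL_RESPONSE_PROBS = {"leopard": 0.667, "eagle": 0.0}

#: trial layout mirroring the playback dataset (leopard 44, eagle 60,
#: falling tree 83, chimpanzee 14 trials).
DEFAULT_N_TRIALS = {"leopard": 44, "eagle": 60, "tree": 83, "chimpanzee": 14}


class ConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic corpus.

    ``repeat_geom_p`` is the success probability of the (1-shifted) geometric
    law for gram repetitions per segment; the default gives a mean of ~1.9
    repetitions so that mean sequence length lands near 4 calls.
    ``n_sequences_lambda`` is the Poisson rate of the (1-shifted) law for
    sequences per responding trial (default mean 1 + 1.4 = 2.4, matching
    ~284 sequences over ~119 responding trials).
    """

    acoustic_params: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_ACOUSTICS.items()})
    interval_params: dict = field(default_factory=lambda: dict(DEFAULT_INTERVALS))
    pattern_probs: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_PATTERN_PROBS.items()})
    response_probs: dict = field(default_factory=lambda: dict(DEFAULT_RESPONSE_PROBS))
    visual_response_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_VISUAL_RESPONSE_PROBS))
    repeat_geom_p: float = 1.0 / 1.9
    n_sequences_lambda: float = 1.4
    window: float = 160.0
    within_trunc_upper: float = 1.0   # within gaps resampled until < this (s)
    between_trunc_lower: float = 2.0  # between gaps resampled until > this (s)
    seed: int = 0

    def validate(self) -> None:
        for ct, p in self.acoustic_params.items():
            if p["dur_sd"] <= 0 or p["freq_sd"] <= 0:
                raise ConfigError(f"acoustic SDs must be > 0 for type {ct!r}")
            if p["truncation"] <= 0:
                raise ConfigError(f"truncation must be > 0 for type {ct!r}")
        ip = self.interval_params
        if ip["within_sd"] <= 0 or ip["between_sd"] <= 0:
            raise ConfigError("interval SDs must be > 0")
        if ip["within_mean"] <= 0 or ip["between_mean"] <= 0:
            raise ConfigError("interval means must be > 0")
        for stim, probs in self.pattern_probs.items():
            tot = sum(probs.values())
            if abs(tot - 1.0) > 1e-9:
                raise ConfigError(
                    f"pattern_probs[{stim!r}] sums to {tot}, expected 1")
            if any(p < 0 for p in probs.values()):
                raise ConfigError(f"pattern_probs[{stim!r}] has negative mass")
        for m in (self.response_probs, self.visual_response_probs):
            for stim, p in m.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"response prob for {stim!r} not in [0,1]")
        if self.window <= 0:
            raise ConfigError("window must be > 0")
        if not 0.0 < self.repeat_geom_p <= 1.0:
            raise ConfigError("repeat_geom_p must be in (0, 1]")


@dataclass
class Trial:
    trial_id: str
    dataset: str
    stimulus: str
    mode: str
    elevation: str  # "ground" | "tree" | "none"
    group_location: str  # "north" | "south"
    responded: bool


@dataclass
class CallRecord:
    trial_id: str
    call_index: int
    onset: float
    duration: float
    max_frequency: float
    true_type: str | None = None  # "A" | "B" ground truth
    assigned_type: str = "unassigned"


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with given arithmetic mean and SD."""
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def sample_call_features(call_type: str, config: GeneratorConfig,
                         rng: np.random.Generator,
                         size: int | None = None):
    """Draw (duration, max_frequency) for one call type.

    Per-type normals truncated at +/- ``truncation`` SDs and floored at a
    small positive epsilon; with the default +/-3 SD truncation the A and B
    maximum-frequency supports are disjoint (A <= 1.48 kHz, B >= 2.53 kHz).
    """
    p = config.acoustic_params[call_type]
    t = p["truncation"]
    n = 1 if size is None else size
    dur = sps.truncnorm.rvs(-t, t, loc=p["dur_mean"], scale=p["dur_sd"],
                            size=n, random_state=rng)
    freq = sps.truncnorm.rvs(-t, t, loc=p["freq_mean"], scale=p["freq_sd"],
                             size=n, random_state=rng)
    dur = np.maximum(dur, 1e-3)
    freq = np.maximum(freq, 1e-3)
    if size is None:
        return float(dur[0]), float(freq[0])
    return dur, freq


def _draw_repeats(rng: np.random.Generator, p: float) -> int:
    # 1-shifted geometric: support {1, 2, ...}, mean 1/p
    return int(rng.geometric(p))


def generate_sequence_string(pattern: str, rng: np.random.Generator,
                             repeat_geom_p: float = 1.0 / 1.9,
                             repeats: int | None = None,
                             n_solo: int | None = None) -> str:
    """Build one grammar-conforming symbol string for a pattern class.

    ``repeats`` pins the gram-repetition count (tests); otherwise it is drawn
    from the 1-shifted geometric law.  ``A_repeat`` strings get one extra
    repetition so the minimum length-2 "AA" is respected.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}")
    r = repeats if repeats is not None else _draw_repeats(rng, repeat_geom_p)
    if pattern == "A_repeat":
        return "A" * max(2, r if repeats is not None else r + 1)
    if pattern == "BA":
        return "BA" * r
    a = n_solo if n_solo is not None else _draw_repeats(rng, repeat_geom_p)
    if pattern == "A_BA":
        return "A" * a + "BA" * r
    return "BA" * r + "A" * a  # BA_A


def _truncated_lognormal(rng, mu, sigma, lower=None, upper=None, max_tries=1000):
    for _ in range(max_tries):
        x = float(rng.lognormal(mu, sigma))
        if (lower is None or x > lower) and (upper is None or x < upper):
            return x
    raise RuntimeError("truncated log-normal rejection sampling failed")


def default_trial_layout() -> list[tuple[str, str, int]]:
    """(stimulus, mode, n_trials) triples of the default study layout."""
    layout = [(s, "playback", n) for s, n in DEFAULT_N_TRIALS.items()]
    layout += [("leopard", "visual_model", 15), ("eagle", "visual_model", 10)]
    return layout


def generate_corpus(
    config: GeneratorConfig,
    n_trials_per_stimulus: Mapping[str, int] | Sequence[tuple[str, str, int]] | None = None,
) -> tuple[list[Trial], list[CallRecord]]:
    """Generate a full synthetic corpus of trials and call records.

    Each responding trial carries >= 1 call sequence from a single caller.
    Symbol strings are grammar-conforming by construction; within-sequence
    gaps come from the within-interval law truncated below
    ``within_trunc_upper`` and between-sequence gaps from the between law
    truncated above ``between_trunc_lower``.  Trials whose layout exceeds the
    analysis window are regenerated (warned once, counted).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if n_trials_per_stimulus is None:
        layout = default_trial_layout()
    elif isinstance(n_trials_per_stimulus, Mapping):
        layout = [(s, "playback", int(n)) for s, n in n_trials_per_stimulus.items()]
    else:
        layout = [(s, m, int(n)) for s, m, n in n_trials_per_stimulus]
    for stim, mode, n in layout:
        if n < 0:
            raise ConfigError("trial counts must be >= 0")
        if stim not in STIMULI or mode not in MODES:
            raise ConfigError(f"unknown stimulus/mode ({stim!r}, {mode!r})")

    mu_w, sg_w = lognormal_params(config.interval_params["within_mean"],
                                  config.interval_params["within_sd"])
    mu_b, sg_b = lognormal_params(config.interval_params["between_mean"],
                                  config.interval_params["between_sd"])

    trials: list[Trial] = []
    calls: list[CallRecord] = []
    n_regenerated = 0
    tid = 0
    for stim, mode, n in layout:
        resp_map = (config.response_probs if mode == "playback"
                    else config.visual_response_probs)
        p_resp = resp_map.get(stim, 0.0)
        for _ in range(n):
            tid += 1
            trial_id = f"T{tid:04d}"
            if stim == "tree" or mode == "visual_model":
                elevation = "none"
            else:
                elevation = "ground" if rng.random() < 0.5 else "tree"
            group_location = "north" if rng.random() < 0.5 else "south"
            responded = bool(rng.random() < p_resp)
            trials.append(Trial(trial_id, "synthetic", stim, mode, elevation,
                                group_location, responded))
            if not responded:
                continue
            for attempt in range(100):
                trial_calls = _layout_trial(
                    trial_id, stim, config, rng, mu_w, sg_w, mu_b, sg_b)
                if trial_calls is not None:
                    break
                n_regenerated += 1
            else:
                raise RuntimeError(
                    f"could not place a response inside the {config.window}s "
                    f"window for trial {trial_id}")
            calls.extend(trial_calls)
    if n_regenerated:
        warnings.warn(f"{n_regenerated} trial layout(s) exceeded the "
                      f"{config.window}s window and were regenerated",
                      stacklevel=2)
    return trials, calls


def _layout_trial(trial_id, stimulus, config, rng, mu_w, sg_w, mu_b, sg_b):
    """Place one responding trial's calls on the time axis, or None if the
    drawn layout does not fit in the window."""
    probs = config.pattern_probs[stimulus]
    pats = list(PATTERNS)
    pvec = np.array([probs[p] for p in pats])
    n_seq = 1 + int(rng.poisson(config.n_sequences_lambda))
    strings = [
        generate_sequence_string(pats[rng.choice(len(pats), p=pvec)], rng,
                                 config.repeat_geom_p)
        for _ in range(n_seq)
    ]
    t = float(rng.uniform(0.0, 5.0))
    records: list[CallRecord] = []
    idx = 0
    for k, s in enumerate(strings):
        if k > 0:
            t += _truncated_lognormal(rng, mu_b, sg_b,
                                      lower=config.between_trunc_lower)
        for j, sym in enumerate(s):
            if j > 0:
                t += _truncated_lognormal(rng, mu_w, sg_w,
                                          upper=config.within_trunc_upper)
            dur, freq = sample_call_features(sym, config, rng)
            if t + dur > config.window:
                return None
            records.append(CallRecord(trial_id, idx, round(t, 6), dur, freq,
                                      true_type=sym))
            idx += 1
            t += dur
    return records


# ---------------------------------------------------------------------------
# negative-control fixtures

RULES = ("A_dominance", "A_suffixation", "B_singularity")


def inject_rule_violations(calls: Iterable[CallRecord], rule: str, rate: float,
                           rng: np.random.Generator,
                           threshold_s: float = 1.0):
    """Corrupt ~``rate`` of sequences so they violate the named grammar rule.

    Operates on the ground-truth symbols of a generated corpus: calls are
    grouped into sequences by the gap threshold, a Bernoulli(rate) subset of
    sequences is selected, and their ``true_type`` symbols are rewritten to a
    violating string of the same length.  Returns (modified calls, log); the
    log records each touched sequence and any collateral rule breaks (a pure
    A-dominance violation is impossible without also breaking suffixation or
    B-singularity: a string with no "BB" that ends in "A" always has
    #A >= #B).
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}")
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    calls = [dataclasses.replace(c) for c in calls]
    by_trial: dict[str, list[CallRecord]] = {}
    for c in calls:
        by_trial.setdefault(c.trial_id, []).append(c)
    log = []
    for trial_id, recs in by_trial.items():
        recs.sort(key=lambda c: c.onset)
        runs: list[list[CallRecord]] = [[recs[0]]]
        for prev, cur in zip(recs, recs[1:]):
            gap = cur.onset - (prev.onset + prev.duration)
            if gap < threshold_s:
                runs[-1].append(cur)
            else:
                runs.append([cur])
        for run in runs:
            if len(run) < 2 or rng.random() >= rate:
                continue
            n = len(run)
            new, collateral = _violating_string(rule, n)
            for c, sym in zip(run, new):
                c.true_type = sym
            log.append({"trial_id": trial_id, "n": n, "rule": rule,
                        "string": new, "collateral": collateral})
    return calls, log


def _violating_string(rule: str, n: int) -> tuple[str, list[str]]:
    from . import grammar

    if rule == "B_singularity":
        s = "BB" + "A" * (n - 2)  # dominance/suffixation survive for n >= 4
    elif rule == "A_suffixation":
        s = "A" * (n - 1) + "B"
    else:
        # A_dominance: give B the majority; a pure violation is impossible
        # (no "BB" + terminal "A" imply #A >= #B), so suffixation breaks too
        k = n // 2 + 1
        s = "BA" * (n - k) + "B" * (2 * k - n)
    preds = grammar.rule_predicates(s)
    collateral = [r for r, ok in preds.items() if not ok and r != rule]
    assert not preds[rule]
    return s, collateral
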