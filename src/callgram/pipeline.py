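"""Pipeline driver: simulate -> classify -> segment -> grammar -> stats.

A single TOML configuration drives all stages; every run writes a manifest
(seed, configuration hash, artifact checksums) so that reruns with the same
configuration and seed are bit-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import calltype, grammar, io, segment, stats, synth

log = logging.getLogger("callgram")


@dataclass
class PipelineConfig:
    out_dir: str = "callgram_out"
    seed: int = 0
    window_s: float = 160.0
    threshold_s: float = 1.0  # or "auto" via threshold_auto
    threshold_auto: bool = False
    k_range: tuple[int, int] = (2, 10)
    n_boot: int = 199
    ridge_sd: float | None = 1.0
    stages: tuple[str, ...] = ("simulate", "classify", "segment", "grammar",
                               "stats")
    calls_path: str | None = None
    trials_path: str | None = None

    def validate(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        if not self.threshold_auto and self.threshold_s <= 0:
            raise ValueError("threshold_s must be > 0")
        if self.n_boot < 99:
            raise ValueError("n_boot must be >= 99")
        if self.k_range[0] < 2 or self.k_range[1] < self.k_range[0]:
            raise ValueError("invalid k_range")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                if f.name in ("k_range", "stages"):
                    v = tuple(v)
                kwargs[f.name] = v
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the report bundle.

    Artifacts land under ``config.out_dir``; a failing stage raises a
    :class:`StageError` naming the stage, leaving earlier artifacts intact.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"seed": config.seed}
    artifacts: dict[str, str] = {}

    trials = calls = None
    try:
        if "simulate" in config.stages:
            gen = synth.GeneratorConfig(seed=config.seed, window=config.window_s)
            trials, calls = synth.generate_corpus(gen)
            io.write_csv(io.calls_to_frame(calls), out / "calls.csv")
            io.write_csv(io.trials_to_frame(trials), out / "trials.csv")
            artifacts["calls.csv"] = _sha256(out / "calls.csv")
            artifacts["trials.csv"] = _sha256(out / "trials.csv")
        else:
            if not (config.calls_path and config.trials_path):
                raise ValueError("calls_path/trials_path required when the "
                                 "simulate stage is disabled")
            calls, _ = io.read_calls(config.calls_path)
            trials, _ = io.read_trials(config.trials_path)
    except Exception as exc:
        raise StageError(f"stage 'simulate' failed: {exc}") from exc

    try:
        if "classify" in config.stages and calls:
            feats = np.array([[c.duration, c.max_frequency] for c in calls])
            z, _ = calltype.standardize_features(feats)
            lo, hi = config.k_range
            best_k, curve = calltype.select_k(z, range(lo, hi + 1))
            result = calltype.pam_cluster(z, best_k)
            if best_k == 2:
                labels = calltype.label_clusters(
                    result, [c.max_frequency for c in calls])
                for c, lab in zip(calls, labels):
                    c.assigned_type = str(lab)
            io.write_csv(io.calls_to_frame(calls), out / "calls_labeled.csv")
            import pandas as pd

            io.write_csv(pd.DataFrame({"k": list(curve),
                                       "mean_silhouette": list(curve.values())}),
                         out / "silhouette_curve.csv")
            artifacts["calls_labeled.csv"] = _sha256(out / "calls_labeled.csv")
            bundle["classify"] = {"best_k": best_k, "curve": curve}
    except Exception as exc:
        raise StageError(f"stage 'classify' failed: {exc}") from exc

    sequences = []
    try:
        if "segment" in config.stages and calls:
            intervals = segment.compute_intervals(calls)
            pooled = segment.pooled_intervals(intervals)
            threshold = config.threshold_s
            seg_info = {"threshold_s": threshold}
            if pooled.size > 10:
                fit = segment.fit_log_mixture(pooled, K=2)
                seg_info["mixture"] = {
                    "means_log": fit.means.tolist(),
                    "sds_log": fit.sds.tolist(),
                    "weights": fit.weights.tolist(),
                    "boundary_s": fit.boundary_s,
                }
                if config.threshold_auto and fit.boundary_s:
                    threshold = fit.boundary_s
                    seg_info["threshold_s"] = threshold
            sequences, n_singletons = segment.segment_sequences(
                calls, threshold_s=threshold)
            seg_info["n_sequences"] = len(sequences)
            seg_info["n_singletons"] = n_singletons
            io.write_csv(io.sequences_to_frame(sequences), out / "sequences.csv")
            artifacts["sequences.csv"] = _sha256(out / "sequences.csv")
            bundle["segment"] = seg_info
    except Exception as exc:
        raise StageError(f"stage 'segment' failed: {exc}") from exc

    try:
        if "grammar" in config.stages and sequences:
            strings = [s.symbols for s in sequences]
            summary = grammar.repertoire_summary(strings)
            rules = grammar.check_rules(strings)
            summary["rules"] = {r: {"holds": rules.holds[r],
                                    "violation_fraction":
                                        rules.violation_fraction[r]}
                                for r in grammar.RULES}
            trie = grammar.build_trie(strings)
            grammar.export_trie_dot(trie, out / "trie.dot")
            with open(out / "summary.json", "w", encoding="utf-8") as fh:
                json.dump(summary, fh, indent=2)
            artifacts["summary.json"] = _sha256(out / "summary.json")
            artifacts["trie.dot"] = _sha256(out / "trie.dot")
            bundle["grammar"] = summary
    except Exception as exc:
        raise StageError(f"stage 'grammar' failed: {exc}") from exc

    try:
        if "stats" in config.stages and sequences:
            rates = stats.response_rate(trials, calls, window=config.window_s)
            io.write_csv(rates, out / "rates.csv")
            models = {}
            for category in ("initiation", "pattern", "termination"):
                table = stats.build_count_table(sequences, trials, category,
                                                window=config.window_s)
                playback = table[table["mode"] == "playback"]
                if playback["trial_id"].nunique() < 5:
                    continue
                io.write_csv(playback, out / f"counts_{category}.csv")
                _, res = stats.fit_category_model(playback, category,
                                                  ridge_sd=config.ridge_sd)
                tab = res.summary()
                models[category] = {
                    "estimates": dict(zip(tab.index, tab["estimate"])),
                    "se": dict(zip(tab.index, tab["se"])),
                    "random_intercept_sd": res.random_intercept_sd,
                    "log_likelihood": res.llf,
                    "converged": res.converged,
                }
            with open(out / "model_summary.json", "w", encoding="utf-8") as fh:
                json.dump(models, fh, indent=2)
            artifacts["model_summary.json"] = _sha256(out / "model_summary.json")
            bundle["stats"] = {"rates": rates.to_dict("records"),
                               "models": list(models)}
    except Exception as exc:
        raise StageError(f"stage 'stats' failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config": {f.name: getattr(config, f.name)
                   for f in dataclasses.fields(config)},
        "artifacts": artifacts,
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True, default=str).encode()
    ).hexdigest()
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    bundle["manifest"] = manifest
    return bundle
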