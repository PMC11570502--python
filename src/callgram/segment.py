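"""Sequence segmentation from call timing.

The distribution of inter-call intervals (silent gap from one call's offset
to the next call's onset, within a trial) is strongly bimodal on a log axis:
short gaps inside call sequences versus long gaps between sequences.  This
module fits a K-component Gaussian mixture to natural-log intervals by EM,
tests the number of components with a parametric bootstrap likelihood-ratio
test, and segments calls into sequences with a within/between gap threshold
(default 1 s, the operative field definition; the fitted posterior boundary
is exposed as a data-derived alternative).

A sequence is a maximal run of >= 2 calls whose consecutive gaps are all
strictly below the threshold; isolated calls are counted as singletons and
excluded from grammar analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence
import warnings

import numpy as np
from scipy import optimize
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .synth import CallRecord

_GAP_FLOOR = 1e-4  # s; overlapping calls are floored here with a warning
_SD_FLOOR = 1e-4   # log-s


def compute_intervals(calls: Iterable[CallRecord]) -> dict[str, np.ndarray]:
    """Inter-call intervals per trial, offset -> next onset, floored at 1e-4 s.

    Intervals never span trials.  Calls must be sorted by onset within each
    trial (the readers enforce this); overlapping calls produce a warning and
    a floored gap rather than a negative interval.
    """
    by_trial: dict[str, list[CallRecord]] = {}
    for c in calls:
        by_trial.setdefault(c.trial_id, []).append(c)
    out: dict[str, np.ndarray] = {}
    n_overlap = 0
    for tid, recs in by_trial.items():
        recs = sorted(recs, key=lambda c: c.onset)
        gaps = np.array([b.onset - (a.onset + a.duration)
                         for a, b in zip(recs, recs[1:])])
        n_overlap += int((gaps < -_GAP_FLOOR).sum())
        out[tid] = np.maximum(gaps, _GAP_FLOOR)
    if n_overlap:
        warnings.warn(f"{n_overlap} overlapping call pair(s); gaps floored at "
                      f"{_GAP_FLOOR} s", stacklevel=2)
    return out


def pooled_intervals(intervals: dict[str, np.ndarray]) -> np.ndarray:
    return np.concatenate([v for v in intervals.values() if v.size]) \
        if intervals else np.empty(0)


# ---------------------------------------------------------------------------
# log-interval Gaussian mixture (EM)


@dataclass
class MixtureResult:
    """Fitted K-component Gaussian mixture on natural-log intervals."""

    K: int
    weights: np.ndarray
    means: np.ndarray      # log-seconds, sorted ascending
    sds: np.ndarray        # log-seconds
    log_likelihood: float
    responsibilities: np.ndarray  # (n, K)
    converged: bool
    n_iter: int
    boundary_s: float | None = None  # posterior-0.5 crossing, K=2 only

    def component_mean_s(self, j: int) -> float:
        """Arithmetic mean on the seconds scale of component j."""
        return float(np.exp(self.means[j] + self.sds[j] ** 2 / 2.0))

    def density(self, x_s: np.ndarray) -> np.ndarray:
        """Mixture density of the interval in seconds (log-normal mixture)."""
        x = np.asarray(x_s, dtype=float)
        z = np.log(x)
        comp = [w * norm.pdf(z, m, s) / x
                for w, m, s in zip(self.weights, self.means, self.sds)]
        return np.sum(comp, axis=0)


class LogIntervalMixture:
    """Model object holding one interval sample (seconds, all > 0)."""

    def __init__(self, intervals_s):
        x = np.asarray(intervals_s, dtype=float).ravel()
        if x.size == 0 or (x <= 0).any():
            raise ValueError("intervals must be positive and nonempty")
        self.intervals_s = x
        self.z = np.log(x)

    def fit(self, K: int, tol: float = 1e-8, max_iter: int = 1000,
            n_init: int = 10) -> MixtureResult:
        """EM with unequal variances; best of ``n_init`` quantile spreads.

        The log-likelihood is asserted non-decreasing at every EM step (up
        to round-off); convergence when the gain drops below ``tol``.
        """
        z = self.z
        n = z.size
        if K < 1:
            raise ValueError("K must be >= 1")
        if n <= 3 * K:
            raise ValueError(f"need more than {3 * K} intervals for K={K}")
        if K == 1:
            mu, sd = float(z.mean()), max(float(z.std(ddof=0)), _SD_FLOOR)
            ll = float(norm.logpdf(z, mu, sd).sum())
            return MixtureResult(1, np.array([1.0]), np.array([mu]),
                                 np.array([sd]), ll, np.ones((n, 1)),
                                 True, 0)
        best: MixtureResult | None = None
        for m in range(n_init):
            res = self._fit_once(K, tol, max_iter, init_index=m,
                                 n_init=n_init)
            if best is None or res.log_likelihood > best.log_likelihood:
                best = res
        if K == 2:
            best.boundary_s = _posterior_boundary(best)
        return best

    def _fit_once(self, K, tol, max_iter, init_index, n_init):
        z = self.z
        n = z.size
        shift = (init_index + 1.0) / (n_init + 1.0)
        qs = (np.arange(K) + shift) / K
        means = np.quantile(z, qs)
        sds = np.full(K, max(z.std(ddof=0) / K, 10 * _SD_FLOOR))
        weights = np.full(K, 1.0 / K)
        prev_ll = -np.inf
        converged = False
        it = 0
        log_2pi = np.log(2.0 * np.pi)
        for it in range(1, max_iter + 1):
            dev = (z[:, None] - means[None, :]) / sds[None, :]
            logp = (np.log(weights)[None, :] - np.log(sds)[None, :]
                    - 0.5 * (dev * dev + log_2pi))
            mx = logp.max(axis=1)
            w = np.exp(logp - mx[:, None])
            sw = w.sum(axis=1)
            ll = float((mx + np.log(sw)).sum())
            assert ll >= prev_ll - 1e-6 * max(1.0, abs(prev_ll)), \
                "EM log-likelihood decreased"
            resp = w / sw[:, None]
            if ll - prev_ll < tol and it > 1:
                converged = True
                prev_ll = ll
                break
            prev_ll = ll
            nk = resp.sum(axis=0)
            nk = np.maximum(nk, 1e-12)
            weights = nk / n
            means = (resp * z[:, None]).sum(axis=0) / nk
            var = (resp * (z[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
            sds = np.maximum(np.sqrt(var), _SD_FLOOR)
        order = np.argsort(means)
        return MixtureResult(K, weights[order], means[order], sds[order],
                             prev_ll, resp[:, order], converged, it)

    def simulate(self, res: MixtureResult, n: int,
                 rng: np.random.Generator) -> np.ndarray:
        """Draw n intervals (seconds) from a fitted mixture."""
        comp = rng.choice(res.K, size=n, p=res.weights / res.weights.sum())
        z = rng.normal(res.means[comp], res.sds[comp])
        return np.exp(z)


def fit_log_mixture(intervals_s, K: int, tol: float = 1e-8,
                    max_iter: int = 1000, n_init: int = 10) -> MixtureResult:
    """Functional wrapper around :class:`LogIntervalMixture`."""
    return LogIntervalMixture(intervals_s).fit(K, tol, max_iter, n_init)


def _posterior_boundary(res: MixtureResult) -> float | None:
    """Seconds value where the two lowest-mean components have equal
    posterior mass (0.5 crossing), searched between the component means."""
    (w1, w2), (m1, m2), (s1, s2) = res.weights[:2], res.means[:2], res.sds[:2]

    def g(zv):
        return (np.log(w1) + norm.logpdf(zv, m1, s1)
                - np.log(w2) - norm.logpdf(zv, m2, s2))

    lo, hi = m1, m2
    if g(lo) * g(hi) > 0:
        return None
    z = optimize.brentq(g, lo, hi, xtol=1e-10)
    return float(np.exp(z))


# ---------------------------------------------------------------------------
# bootstrap likelihood-ratio test for the number of components


def bootstrap_lrt(intervals_s, K0: int, K1: int, n_boot: int = 999,
                  seed: int | None = None, n_init: int = 10,
                  boot_n_init: int = 3, boot_max_iter: int = 300,
                  max_degenerate: float = 0.2):
    """Parametric bootstrap LRT of K0 vs K1 = K0+1 components.

    chi2_obs = 2 (ll_K1 - ll_K0) on the observed sample; the null reference
    distribution comes from refitting both models on ``n_boot`` samples of
    equal size simulated from the fitted K0 model.  p uses the +1 convention
    so it can never be exactly 0.  Degenerate bootstrap refits (non-finite
    or negative likelihood-ratio beyond round-off) are dropped and counted;
    more than ``max_degenerate`` of them is an error.

    Bootstrap refits use lighter EM settings (``boot_n_init`` starts,
    ``boot_max_iter`` iterations) than the observed-data fits: refits under
    the null wander slowly and their tail statistic is insensitive to the
    final convergence digits.
    """
    if K1 != K0 + 1:
        raise ValueError("K1 must equal K0 + 1")
    if n_boot < 99:
        raise ValueError("n_boot must be >= 99")
    model = LogIntervalMixture(intervals_s)
    fit0 = model.fit(K0, n_init=n_init)
    fit1 = model.fit(K1, n_init=n_init)
    chi2_obs = 2.0 * (fit1.log_likelihood - fit0.log_likelihood)
    rng = np.random.default_rng(seed)
    n = model.z.size
    stats = []
    n_degenerate = 0
    for _ in range(n_boot):
        sim = model.simulate(fit0, n, rng)
        try:
            b0 = LogIntervalMixture(sim).fit(K0, max_iter=boot_max_iter,
                                             n_init=boot_n_init)
            b1 = LogIntervalMixture(sim).fit(K1, max_iter=boot_max_iter,
                                             n_init=boot_n_init)
            stat = 2.0 * (b1.log_likelihood - b0.log_likelihood)
        except (ValueError, AssertionError):
            n_degenerate += 1
            continue
        if not np.isfinite(stat) or stat < -1e-6:
            n_degenerate += 1
            continue
        stats.append(max(stat, 0.0))
    if n_degenerate > max_degenerate * n_boot:
        raise RuntimeError(f"{n_degenerate}/{n_boot} degenerate bootstrap refits")
    stats = np.array(stats)
    p = (1.0 + float((stats >= chi2_obs).sum())) / (stats.size + 1.0)
    return float(chi2_obs), float(p)


def select_modes(intervals_s, K_max: int = 5, n_boot: int = 999,
                 seed: int | None = None, alpha: float = 0.05,
                 n_init: int = 10, boot_n_init: int = 3,
                 boot_max_iter: int = 300) -> int:
    """Sequential bootstrap LRTs K vs K+1 from K=1; stop at the first
    non-rejection and return the last accepted K."""
    if K_max < 2:
        raise ValueError("K_max must be >= 2")
    rng = np.random.default_rng(seed)
    K = 1
    while K < K_max:
        sub = int(rng.integers(0, 2**31 - 1))
        _, p = bootstrap_lrt(intervals_s, K, K + 1, n_boot=n_boot, seed=sub,
                             n_init=n_init, boot_n_init=boot_n_init,
                             boot_max_iter=boot_max_iter)
        if p >= alpha:
            return K
        K += 1
    return K


# ---------------------------------------------------------------------------
# segmentation


@dataclass
class CallSequence:
    trial_id: str
    symbols: str
    start_s: float
    end_s: float
    call_indices: list[int] = field(default_factory=list)
    pattern: str | None = None

    @property
    def n(self) -> int:
        return len(self.symbols)


def segment_sequences(calls: Sequence[CallRecord], threshold_s: float = 1.0,
                      use_true_type: bool = False):
    """Split labeled calls into sequences at gaps >= ``threshold_s``.

    Maximal runs of calls with consecutive gaps strictly below the threshold
    become sequences if they contain >= 2 calls; length-1 runs are counted as
    singletons.  Every call lands in exactly one run.  Returns
    (list of CallSequence, singleton count).
    """
    by_trial: dict[str, list[CallRecord]] = {}
    for c in calls:
        by_trial.setdefault(c.trial_id, []).append(c)
    sequences: list[CallSequence] = []
    n_singletons = 0

    def label(c: CallRecord) -> str:
        t = c.true_type if use_true_type else c.assigned_type
        if t not in ("A", "B"):
            raise ValueError(
                f"call {c.trial_id}/{c.call_index} is not labeled A/B")
        return t

    for tid in sorted(by_trial):
        recs = sorted(by_trial[tid], key=lambda c: c.onset)
        run: list[CallRecord] = [recs[0]]
        for prev, cur in zip(recs, recs[1:]):
            gap = cur.onset - (prev.onset + prev.duration)
            if gap < threshold_s:
                run.append(cur)
            else:
                n_singletons += _flush(run, tid, sequences, label)
                run = [cur]
        n_singletons += _flush(run, tid, sequences, label)
    return sequences, n_singletons


def _flush(run, tid, sequences, label) -> int:
    if len(run) < 2:
        # still validate the label so unlabeled corpora fail loudly
        label(run[0])
        return 1
    sequences.append(CallSequence(
        trial_id=tid,
        symbols="".join(label(c) for c in run),
        start_s=run[0].onset,
        end_s=run[-1].onset + run[-1].duration,
        call_indices=[c.call_index for c in run],
    ))
    return 0
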