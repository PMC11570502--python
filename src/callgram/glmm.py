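"""Poisson random-intercept count model, fitted by Laplace-approximate ML.

The context-specificity analyses model per-trial sequence counts

    y_{g,l} ~ Poisson( exp( x_{g,l}' beta + offset_g + u_g ) ),
    u_g ~ Normal(0, sigma^2)  (one random intercept per trial),

with a log link and a fixed exposure offset (log of the trial's total
sequence count + 1).  The marginal likelihood integrates the random
intercept by a Laplace approximation: with a scalar intercept and log link
the group contribution reduces to sufficient statistics T_g = sum y and
S_g = sum exp(x'beta + offset), so the inner mode solve is a scalar Newton
iteration per group and the outer problem is a smooth optimization over
(beta, log sigma).

Complete separation (a cell with zero response variance) sends ML estimates
to infinity; an optional zero-mean Gaussian ridge on the fixed effects
(``ridge_sd``, typically 1.0 on the log scale) keeps them finite, mirroring
the weakly-informative-prior fix used for such designs.

The Model/Results split follows statsmodels: build a
:class:`PoissonRandomInterceptModel` from a DataFrame, call ``fit()``, and
read estimates, standard errors and diagnostics off the results object.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

__all__ = [
    "PoissonRandomInterceptModel",
    "PoissonRandomInterceptResults",
    "lr_test",
    "drop1_interactions",
    "pairwise_contrasts",
]


class ConvergenceWarning(UserWarning):
    pass


def _build_design(data: pd.DataFrame, factors: dict[str, str],
                  interactions: list[tuple[str, str]]):
    """Treatment-coded design matrix with explicit reference levels.

    ``factors`` maps factor column -> reference level; ``interactions`` lists
    factor pairs whose dummy products enter the model.  Column order:
    intercept, main effects in ``factors`` order, then interactions.
    Returns (X, names, column_specs, levels) where ``column_specs`` keeps
    enough structure to build marginal-mean rows later.
    """
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]
    specs: list[tuple] = [("intercept",)]
    levels: dict[str, list[str]] = {}
    for fac, ref in factors.items():
        obs = sorted(map(str, data[fac].astype(str).unique()))
        if str(ref) not in obs:
            raise ValueError(f"reference level {ref!r} not observed in {fac!r}")
        levels[fac] = [str(ref)] + [l for l in obs if l != str(ref)]
        for lev in levels[fac][1:]:
            cols.append((data[fac].astype(str) == lev).to_numpy(float))
            names.append(f"{fac}[{lev}]")
            specs.append(("main", fac, lev))
    for f1, f2 in interactions:
        for l1 in levels[f1][1:]:
            d1 = (data[f1].astype(str) == l1).to_numpy(float)
            for l2 in levels[f2][1:]:
                d2 = (data[f2].astype(str) == l2).to_numpy(float)
                cols.append(d1 * d2)
                names.append(f"{f1}[{l1}]:{f2}[{l2}]")
                specs.append(("inter", (f1, l1), (f2, l2)))
    return np.column_stack(cols), names, specs, levels


@dataclass
class _TermInfo:
    factors: dict[str, str]
    interactions: list[tuple[str, str]]


class PoissonRandomInterceptModel:
    """Poisson GLMM with a single Gaussian random intercept per group."""

    def __init__(self, endog, exog, groups, offset=None, exog_names=None,
                 column_specs=None, factor_levels=None, term_info=None,
                 data=None, response=None, group_col=None, offset_col=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.size:
            raise ValueError("exog must be (n, p) aligned with endog")
        codes, uniq = pd.factorize(np.asarray(groups), sort=True)
        self.group_codes = codes
        self.group_labels = uniq
        self.n_groups = len(uniq)
        self.offset = (np.zeros_like(self.endog) if offset is None
                       else np.asarray(offset, dtype=float))
        p = self.exog.shape[1]
        self.exog_names = list(exog_names) if exog_names else [
            f"x{j}" for j in range(p)]
        self.column_specs = column_specs
        self.factor_levels = factor_levels
        self.term_info = term_info
        self.data = data
        self.response = response
        self.group_col = group_col
        self.offset_col = offset_col
        self._gammaln_y = float(gammaln(self.endog + 1.0).sum())
        self._Ty = np.bincount(self.group_codes, weights=self.endog,
                               minlength=self.n_groups)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       factors: dict[str, str],
                       interactions: list[tuple[str, str]] | None = None,
                       groups: str = "trial_id",
                       offset: str | None = None):
        """Build the model from a tidy count table.

        ``factors`` maps categorical column -> reference level (treatment
        coding); ``interactions`` lists factor pairs; ``offset`` names a
        column already on the log scale.
        """
        interactions = list(interactions or [])
        X, names, specs, levels = _build_design(data, factors, interactions)
        off = data[offset].to_numpy(float) if offset else None
        return cls(data[response].to_numpy(float), X, data[groups],
                   offset=off, exog_names=names, column_specs=specs,
                   factor_levels=levels,
                   term_info=_TermInfo(dict(factors), interactions),
                   data=data.reset_index(drop=True), response=response,
                   group_col=groups, offset_col=offset)

    def refit_without_terms(self, drop: list[tuple[str, str] | str]):
        """New model with the named interaction pairs / factors removed."""
        if self.term_info is None or self.data is None:
            raise ValueError("term structure unavailable (raw-matrix model)")
        facs = dict(self.term_info.factors)
        inters = list(self.term_info.interactions)
        for d in drop:
            if isinstance(d, tuple):
                inters = [i for i in inters if i != d]
            else:
                if any(d in pair for pair in inters):
                    raise ValueError(
                        f"cannot drop main effect {d!r} while an interaction "
                        "containing it remains")
                facs.pop(d)
        return PoissonRandomInterceptModel.from_dataframe(
            self.data, self.response, facs, inters, groups=self.group_col,
            offset=self.offset_col)

    # -- likelihood ---------------------------------------------------------

    def _group_stats(self, beta):
        xi = self.exog @ beta + self.offset
        S = np.bincount(self.group_codes, weights=np.exp(xi),
                        minlength=self.n_groups)
        ysum_xi = float(self.endog @ xi)
        return S, ysum_xi

    @staticmethod
    def _solve_modes(T, S, sigma2, u0=None):
        """Scalar Newton for the conditional mode per group, vectorized.

        Solves T - S e^u - u/sigma2 = 0; the left side is strictly
        decreasing in u, so damped Newton converges for every group.
        """
        u = np.zeros_like(T) if u0 is None else u0.copy()
        for _ in range(100):
            eu = np.exp(u)
            h = T - S * eu - u / sigma2
            hp = -S * eu - 1.0 / sigma2
            step = np.clip(-h / hp, -4.0, 4.0)
            u = u + step
            if np.max(np.abs(h)) < 1e-10 * (1.0 + np.max(np.abs(T))):
                break
        return u

    def loglike(self, params, ridge_sd=None, penalize_intercept=False):
        """Laplace-approximate marginal log-likelihood at
        params = (beta, log sigma); optionally ridge-penalized."""
        beta = params[:-1]
        sigma = np.exp(params[-1])
        sigma2 = sigma**2
        S, ysum_xi = self._group_stats(beta)
        u = self._solve_modes(self._Ty, S, sigma2)
        eu = np.exp(u)
        ll = (ysum_xi - self._gammaln_y
              + float(self._Ty @ u - S @ eu)
              - float((u**2).sum()) / (2.0 * sigma2)
              - self.n_groups * np.log(sigma)
              - 0.5 * float(np.log(S * eu + 1.0 / sigma2).sum()))
        if ridge_sd is not None:
            b = beta if penalize_intercept else beta[1:]
            ll -= float(b @ b) / (2.0 * ridge_sd**2)
        return ll

    # -- fitting ------------------------------------------------------------

    def fit(self, ridge_sd: float | None = None,
            penalize_intercept: bool = False, maxiter: int = 500,
            start_params=None,
            fix_log_sigma: float | None = None
            ) -> "PoissonRandomInterceptResults":
        p = self.exog.shape[1]
        if start_params is None:
            x0 = np.zeros(p + 1)
            mean_y = max(self.endog.mean(), 1e-3)
            x0[0] = np.log(mean_y) - self.offset.mean()
            x0[-1] = np.log(0.5)
        else:
            x0 = np.asarray(start_params, dtype=float)

        def nll(th):
            return -self.loglike(th, ridge_sd, penalize_intercept)

        sig_bound = ((-8.0, 5.0) if fix_log_sigma is None
                     else (fix_log_sigma, fix_log_sigma))
        if fix_log_sigma is not None:
            x0[-1] = fix_log_sigma
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B",
            bounds=[(None, None)] * p + [sig_bound],
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7})
        params = res.x
        converged = bool(res.success)
        if not converged:
            warnings.warn("GLMM optimizer did not report convergence",
                          ConvergenceWarning, stacklevel=2)
        beta = params[:-1]
        if ridge_sd is None and np.any(np.abs(beta) > 10.0):
            warnings.warn(
                "fixed effect |estimate| > 10 on the log scale: likely "
                "complete separation; refit with ridge_sd=1",
                ConvergenceWarning, stacklevel=2)
        if fix_log_sigma is None:
            hess = _num_hessian(
                lambda th: -self.loglike(th, ridge_sd, penalize_intercept),
                params)
            cov = _safe_inv(hess)
        else:
            hb = _num_hessian(
                lambda b: -self.loglike(np.append(b, fix_log_sigma),
                                        ridge_sd, penalize_intercept),
                params[:-1])
            cov = np.full((p + 1, p + 1), np.nan)
            cov[:p, :p] = _safe_inv(hb)
        llf = self.loglike(params)  # unpenalized, for LRTs/ICs
        return PoissonRandomInterceptResults(
            self, params, cov, llf, converged, ridge_sd,
            penalized_llf=self.loglike(params, ridge_sd, penalize_intercept),
            penalize_intercept=penalize_intercept)

    # -- simulation ---------------------------------------------------------

    def simulate(self, params, rng: np.random.Generator):
        """Draw a response vector from the fitted model (new random
        intercepts + Poisson noise)."""
        beta = params[:-1]
        sigma = np.exp(params[-1])
        u = rng.normal(0.0, sigma, size=self.n_groups)
        mu = np.exp(self.exog @ beta + self.offset + u[self.group_codes])
        return rng.poisson(mu)

    def fitted_means(self, params, conditional=True):
        beta = params[:-1]
        sigma2 = np.exp(params[-1])**2
        xi = self.exog @ beta + self.offset
        if not conditional:
            return np.exp(xi)
        S = np.bincount(self.group_codes, weights=np.exp(xi),
                        minlength=self.n_groups)
        u = self._solve_modes(self._Ty, S, sigma2)
        return np.exp(xi + u[self.group_codes])


def _num_hessian(f, x, rel_step=1e-4):
    n = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i]**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)) / (4 * h[i] * h[j])
    return H


def _safe_inv(H):
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    d = np.diag(cov).copy()
    d[d < 0] = np.nan
    cov[np.diag_indices_from(cov)] = d
    return cov


class PoissonRandomInterceptResults:
    """Fit results: estimates, SEs, diagnostics, bootstrap and stability."""

    def __init__(self, model, params, cov_all, llf, converged, ridge_sd,
                 penalized_llf=None, penalize_intercept=False):
        self.model = model
        self.params_all = params
        self.params = params[:-1]
        self.log_sigma = params[-1]
        self.random_intercept_sd = float(np.exp(params[-1]))
        self.cov_all = cov_all
        self.cov_params = cov_all[:-1, :-1]
        self.bse = np.sqrt(np.diag(self.cov_params))
        self.llf = float(llf)
        self.penalized_llf = (float(penalized_llf) if penalized_llf is not None
                              else float(llf))
        self.converged = converged
        self.ridge_sd = ridge_sd
        self.penalize_intercept = penalize_intercept
        self.exog_names = model.exog_names
        self.nobs = model.endog.size
        self.n_groups = model.n_groups
        self.df_model = len(self.params)

    def conf_int(self, alpha=0.05):
        """Wald confidence intervals for the fixed effects."""
        z = norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse,
                                self.params + z * self.bse])

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        tab = pd.DataFrame({
            "estimate": self.params,
            "se": self.bse,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
        }, index=self.exog_names)
        tab.attrs["random_intercept_sd"] = self.random_intercept_sd
        tab.attrs["log_likelihood"] = self.llf
        tab.attrs["ridge_sd"] = self.ridge_sd
        tab.attrs["n_obs"] = self.nobs
        tab.attrs["n_groups"] = self.n_groups
        tab.attrs["converged"] = self.converged
        return tab

    def __str__(self):
        head = (f"Poisson random-intercept GLMM  "
                f"(n={self.nobs}, groups={self.n_groups}, "
                f"sigma_u={self.random_intercept_sd:.3f}, "
                f"ll={self.llf:.3f}"
                + (f", ridge_sd={self.ridge_sd}" if self.ridge_sd else "")
                + ")\n")
        return head + self.summary().to_string(float_format="%.3f")

    # -- diagnostics --------------------------------------------------------

    def bootstrap_ci(self, n_boot: int = 1000, seed: int | None = None,
                     alpha: float = 0.05, max_failed: float = 0.2):
        """Parametric-bootstrap percentile CIs for the fixed effects."""
        rng = np.random.default_rng(seed)
        draws = []
        n_failed = 0
        m = self.model
        for _ in range(n_boot):
            y = m.simulate(self.params_all, rng)
            bm = PoissonRandomInterceptModel(
                y, m.exog, m.group_labels[m.group_codes], offset=m.offset,
                exog_names=m.exog_names)
            try:
                r = bm.fit(ridge_sd=self.ridge_sd,
                           penalize_intercept=self.penalize_intercept,
                           start_params=self.params_all)
            except Exception:
                n_failed += 1
                continue
            if not np.isfinite(r.params).all():
                n_failed += 1
                continue
            draws.append(r.params)
        if n_failed > max_failed * n_boot:
            raise RuntimeError(f"{n_failed}/{n_boot} bootstrap refits failed")
        draws = np.array(draws)
        lo = np.percentile(draws, 100 * alpha / 2, axis=0)
        hi = np.percentile(draws, 100 * (1 - alpha / 2), axis=0)
        return pd.DataFrame({"ci_low": lo, "ci_high": hi,
                             "n_boot_used": draws.shape[0]},
                            index=self.exog_names)

    def stability_analysis(self):
        """Leave-one-group-out refits; per-coefficient min/max."""
        m = self.model
        if m.n_groups < 3:
            raise ValueError("need at least 3 groups")
        est = []
        for g in range(m.n_groups):
            keep = m.group_codes != g
            bm = PoissonRandomInterceptModel(
                m.endog[keep], m.exog[keep],
                m.group_labels[m.group_codes[keep]], offset=m.offset[keep],
                exog_names=m.exog_names)
            r = bm.fit(ridge_sd=self.ridge_sd,
                       penalize_intercept=self.penalize_intercept,
                       start_params=self.params_all)
            est.append(r.params)
        est = np.array(est)
        return pd.DataFrame({"min": est.min(axis=0), "max": est.max(axis=0),
                             "estimate": self.params},
                            index=self.exog_names)

    def dispersion_check(self, n_sim: int = 250, seed: int | None = None):
        """Simulation dispersion test: SD of observed Pearson residuals
        against the same statistic on model simulations; two-sided p.

        Residuals are taken against the unconditional fitted means (random
        intercept integrated out at its zero mean) for both the observed
        and the simulated responses, so the random-effect variance enters
        both sides of the comparison symmetrically.
        """
        rng = np.random.default_rng(seed)
        m = self.model
        mu = self.model.fitted_means(self.params_all, conditional=False)
        mu = np.maximum(mu, 1e-12)

        def stat(y):
            r = (y - mu) / np.sqrt(mu)
            return float(r.std(ddof=0)) if r.size > 1 else 0.0

        obs = stat(m.endog)
        sims = np.array([stat(m.simulate(self.params_all, rng))
                         for _ in range(n_sim)])
        denom = sims.mean() if sims.mean() > 0 else 1.0
        ratio = obs / denom
        n_ge = int((sims >= obs).sum())
        n_le = int((sims <= obs).sum())
        p = min(1.0, 2.0 * min(n_ge + 1, n_le + 1) / (n_sim + 1))
        return float(ratio), float(p)


# ---------------------------------------------------------------------------
# inference helpers


def lr_test(fit_full: PoissonRandomInterceptResults,
            fit_reduced: PoissonRandomInterceptResults):
    """Chi-squared likelihood-ratio test of nested fits on the same data."""
    if fit_full.nobs != fit_reduced.nobs:
        raise ValueError("fits are not on the same data")
    names_f, names_r = set(fit_full.exog_names), set(fit_reduced.exog_names)
    if not names_r.issubset(names_f):
        raise ValueError("reduced model is not nested in the full model")
    df = fit_full.df_model - fit_reduced.df_model
    if df < 0:
        raise ValueError("reduced model has more parameters than the full")
    chi2 = max(2.0 * (fit_full.llf - fit_reduced.llf), 0.0)
    p = float(chi2_dist.sf(chi2, df)) if df > 0 else 1.0
    return float(chi2), int(df), p


def drop1_interactions(fit: PoissonRandomInterceptResults,
                       alpha: float = 0.05):
    """Per-term LRTs respecting marginality.

    Interactions are tested first (each dropped from the full model); if any
    are non-significant at ``alpha`` the model is refitted without them and
    the main effects are then tested in the refitted model (rows flagged
    ``refitted``).  Returns (table, refitted results or None).
    """
    model = fit.model
    if model.term_info is None:
        raise ValueError("term structure unavailable")
    rows = []
    ns_inter = []
    for pair in model.term_info.interactions:
        red = model.refit_without_terms([pair]).fit(
            ridge_sd=fit.ridge_sd, penalize_intercept=fit.penalize_intercept)
        chi2, df, p = lr_test(fit, red)
        rows.append({"term": f"{pair[0]}:{pair[1]}", "chi2": chi2, "df": df,
                     "p": p, "stage": "full"})
        if p >= alpha:
            ns_inter.append(pair)
    refit = None
    if ns_inter:
        refit = model.refit_without_terms(ns_inter).fit(
            ridge_sd=fit.ridge_sd, penalize_intercept=fit.penalize_intercept)
        base = refit
    else:
        base = fit
    kept_inter = [p for p in base.model.term_info.interactions]
    for fac in base.model.term_info.factors:
        if any(fac in pair for pair in kept_inter):
            continue  # marginality: main effect shielded by its interaction
        red = base.model.refit_without_terms([fac]).fit(
            ridge_sd=fit.ridge_sd, penalize_intercept=fit.penalize_intercept)
        chi2, df, p = lr_test(base, red)
        rows.append({"term": fac, "chi2": chi2, "df": df, "p": p,
                     "stage": "refitted" if ns_inter else "full"})
    return pd.DataFrame(rows), refit


def _emm_row(specs, levels, fixed: dict[str, str]):
    """Design row of an estimated marginal mean: target factors pinned to
    ``fixed`` levels, nuisance factors averaged uniformly over levels."""
    row = []
    for spec in specs:
        if spec[0] == "intercept":
            row.append(1.0)
        elif spec[0] == "main":
            _, fac, lev = spec
            if fac in fixed:
                row.append(1.0 if fixed[fac] == lev else 0.0)
            else:
                row.append(1.0 / len(levels[fac]))
        else:
            _, (f1, l1), (f2, l2) = spec
            v1 = (1.0 if fixed.get(f1) == l1 else
                  (1.0 / len(levels[f1]) if f1 not in fixed else 0.0))
            v2 = (1.0 if fixed.get(f2) == l2 else
                  (1.0 / len(levels[f2]) if f2 not in fixed else 0.0))
            row.append(v1 * v2)
    return np.array(row)


def pairwise_contrasts(fit: PoissonRandomInterceptResults,
                       factors: str | tuple[str, ...],
                       adjust: str = "mvt", n_mc: int = 20000,
                       seed: int = 0) -> pd.DataFrame:
    """All pairwise contrasts of estimated marginal means on the link scale.

    Cells are the level combinations of ``factors``; every other factor is
    averaged uniformly over its levels.  SEs come from the delta method
    (here the contrasts are linear, so exactly c'Vc).  ``adjust="mvt"``
    calibrates p-values against the Monte-Carlo distribution of the maximum
    absolute standardized contrast under the joint normal (Tukey-style);
    ``adjust="holm"`` applies the Holm step-down correction; ``"none"``
    leaves them raw.
    """
    model = fit.model
    if model.column_specs is None:
        raise ValueError("term structure unavailable")
    if isinstance(factors, str):
        factors = (factors,)
    levels = model.factor_levels
    cells = list(itertools.product(*[levels[f] for f in factors]))
    rows = {cell: _emm_row(model.column_specs, levels,
                           dict(zip(factors, cell)))
            for cell in cells}
    recs = []
    cvecs = []
    for c1, c2 in itertools.combinations(cells, 2):
        c = rows[c1] - rows[c2]
        var = float(c @ fit.cov_params @ c)
        est = float(c @ fit.params)
        if var <= 0 or not np.isfinite(var):
            recs.append({"contrast": f"{'/'.join(c1)} - {'/'.join(c2)}",
                         "estimate": est, "se": np.nan, "z": np.nan,
                         "p": np.nan, "estimable": False})
            cvecs.append(None)
            continue
        se = float(np.sqrt(var))
        z = est / se
        recs.append({"contrast": f"{'/'.join(c1)} - {'/'.join(c2)}",
                     "estimate": est, "se": se, "z": z,
                     "p": float(2 * norm.sf(abs(z))), "estimable": True})
        cvecs.append(c)
    tab = pd.DataFrame(recs)
    ok = tab["estimable"].to_numpy()
    if adjust == "none" or ok.sum() == 0:
        tab["p_adj"] = tab["p"]
        return tab
    if adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        adj = np.full(len(tab), np.nan)
        adj[ok] = multipletests(tab.loc[ok, "p"], method="holm")[1]
        tab["p_adj"] = adj
        return tab
    if adjust != "mvt":
        raise ValueError(f"unknown adjustment {adjust!r}")
    C = np.array([c for c in cvecs if c is not None])
    V = C @ fit.cov_params @ C.T
    sd = np.sqrt(np.diag(V))
    R = V / np.outer(sd, sd)
    R = (R + R.T) / 2 + 1e-10 * np.eye(len(sd))
    rng = np.random.default_rng(seed)
    zs = rng.multivariate_normal(np.zeros(len(sd)), R, size=n_mc,
                                 method="cholesky")
    maxabs = np.abs(zs).max(axis=1)
    zobs = tab.loc[ok, "z"].to_numpy()
    adj = np.full(len(tab), np.nan)
    if ok.sum() == 1:
        adj[ok] = tab.loc[ok, "p"]
    else:
        adj[ok] = [(1.0 + float((maxabs >= abs(z)).sum())) / (n_mc + 1.0)
                   for z in zobs]
    tab["p_adj"] = adj
    return tab
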