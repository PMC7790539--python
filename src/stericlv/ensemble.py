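"""Replicate sweeps and ensemble survival statistics.

Replicate survivor counts are summarized by a modified (zero-truncated)
binomial: conditional on at least one of N species surviving, the number of
survivors n follows

    p_n(N, α) = C(N, n) αⁿ (1−α)^(N−n) / (1 − (1−α)^N),   1 ≤ n ≤ N,

where α is the ensemble-average single-species survival probability.  α is
fitted by maximum likelihood with 95% profile-likelihood confidence
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import dynamics, environment, interactions, observables

_CHI2_95_HALF = stats.chi2.ppf(0.95, df=1) / 2.0  # profile-CI drop


@dataclass
class SurvivalDistribution:
    """Histogram of survivor counts over replicates (n = 1 … N)."""

    N_initial: int
    counts: np.ndarray  # length N, counts[n-1] = replicates with n survivors
    replicate_metadata: list = field(default_factory=list)

    @classmethod
    def from_survivor_counts(cls, survivors, N: int,
                             metadata=None) -> "SurvivalDistribution":
        counts = np.zeros(N, dtype=int)
        for s in survivors:
            if s == 0:
                # all-extinct replicates fall outside the truncated model
                continue
            counts[int(s) - 1] += 1
        return cls(N_initial=N, counts=counts,
                   replicate_metadata=list(metadata or []))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MLEFit:
    """Maximum-likelihood estimate of the survival probability α."""

    alpha_hat: float
    ci_low: float
    ci_high: float
    loglik: float
    n_replicates: int
    upper_open: bool = False  # likelihood maximized at the α→1 boundary


def modified_binomial_pmf(n, N: int, alpha: float):
    """Zero-truncated binomial pmf p_n(N, α) for 1 ≤ n ≤ N."""
    n = np.asarray(n)
    if np.any(n < 1) or np.any(n > N):
        raise ValueError("n must lie in 1..N (zero survivors is excluded)")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    p = stats.binom.pmf(n, N, alpha) / (1.0 - (1.0 - alpha) ** N)
    return float(p) if p.ndim == 0 else p


def _loglik(alpha: float, counts: np.ndarray, N: int) -> float:
    ns = np.arange(1, N + 1)
    logp = (stats.binom.logpmf(ns, N, alpha)
            - np.log1p(-(1.0 - alpha) ** N))
    return float(np.dot(counts, logp))


def fit_alpha_mle(counts, N: int, ci_level: float = 0.95,
                  bootstrap: int = 0, rng=None) -> MLEFit:
    """Fit α to a survivor-count histogram by maximum likelihood.

    ``counts`` is the histogram over n = 1 … N (length N) or a
    :class:`SurvivalDistribution`.  Confidence bounds come from the profile
    likelihood at the χ²(1) cutoff; pass ``bootstrap > 0`` to use a
    parametric bootstrap instead.  If all replicates ended with n = N the
    likelihood increases toward α → 1 and the fit is reported at the
    boundary with an open upper interval.
    """
    if isinstance(counts, SurvivalDistribution):
        N = counts.N_initial
        counts = counts.counts
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (N,):
        raise ValueError("counts must have length N (n = 1 .. N)")
    total = counts.sum()
    if total < 10:
        raise ValueError("need at least 10 replicates for a stable fit")

    eps = 1e-9
    res = optimize.minimize_scalar(lambda a: -_loglik(a, counts, N),
                                   bounds=(eps, 1 - eps), method="bounded",
                                   options={"xatol": 1e-10})
    alpha_hat = float(res.x)
    llmax = -float(res.fun)
    upper_open = bool(counts[-1] == total)

    drop = stats.chi2.ppf(ci_level, df=1) / 2.0

    def g(a):
        return _loglik(a, counts, N) - (llmax - drop)

    if bootstrap:
        rng = np.random.default_rng(rng)
        boot = np.empty(bootstrap)
        ns = np.arange(1, N + 1)
        pmf = modified_binomial_pmf(ns, N, min(alpha_hat, 1 - eps))
        for b in range(bootstrap):
            draws = rng.choice(ns, size=int(total), p=pmf / pmf.sum())
            c = np.bincount(draws, minlength=N + 1)[1:]
            r = optimize.minimize_scalar(lambda a: -_loglik(a, c, N),
                                         bounds=(eps, 1 - eps),
                                         method="bounded")
            boot[b] = r.x
        lo, hi = np.quantile(boot, [(1 - ci_level) / 2,
                                    (1 + ci_level) / 2])
    else:
        lo = (optimize.brentq(g, eps, alpha_hat)
              if g(eps) < 0 else eps)
        if upper_open or g(1 - eps) >= 0:
            hi = 1.0
        else:
            hi = optimize.brentq(g, alpha_hat, 1 - eps)
    return MLEFit(alpha_hat=alpha_hat, ci_low=float(lo), ci_high=float(hi),
                  loglik=llmax, n_replicates=int(total),
                  upper_open=upper_open)


def _replicate_seeds(base_seed: int, row_index: int) -> dict:
    """Deterministic, order-independent seed triplet for one replicate."""
    ss = np.random.SeedSequence([int(base_seed), int(row_index)])
    env_s, mat_s, init_s = ss.spawn(3)
    return {
        "seed_env": int(env_s.generate_state(1)[0] % (2 ** 31)),
        "seed_matrix": int(mat_s.generate_state(1)[0] % (2 ** 31)),
        "seed_init": int(init_s.generate_state(1)[0] % (2 ** 31)),
    }


def run_replicate(params: dict, seeds: dict) -> dict:
    """Simulate one replicate from a flat parameter dict and summarize it.

    Expected keys (with standard defaults): N, L, R, dx_over_R, delta,
    mean_p, delta_p_over_mean_p, dt, max_time, equilibrium_tol,
    seeding_fraction, record_interval.
    """
    N = int(params.get("N", 8))
    L = float(params.get("L", 150.0))
    R = float(params.get("R", 3.0))
    dx = float(params.get("dx_over_R", 3.5)) * R
    delta = float(params.get("delta", 0.0))
    mean_p = float(params.get("mean_p", 0.25))
    delta_p = float(params.get("delta_p_over_mean_p", 0.0)) * mean_p
    env = environment.make_environment(L, dx, R, delta,
                                       seed=seeds["seed_env"])
    mat = interactions.sample_matrix(N, mean_p, delta_p,
                                     seed=seeds["seed_matrix"])
    cfg = dynamics.SimulationConfig(
        n_species=N,
        dt=float(params.get("dt", 0.01)),
        max_time=float(params.get("max_time", 5000.0)),
        equilibrium_tol=float(params.get("equilibrium_tol", 0.001)),
        seeding_fraction=float(params.get("seeding_fraction", 0.002)),
        record_interval=int(params.get("record_interval", 100)),
    )
    traj = dynamics.run(cfg, env, mat.P,
                        rng=np.random.default_rng(seeds["seed_init"]))
    return observables.summarize_run(traj, env)


def run_sweep(grid_spec: dict, replicates: int, base_seed: int,
              fixed: dict | None = None, progress: bool = False,
              ) -> pd.DataFrame:
    """Replicate sweep over a parameter grid; one tidy row per replicate.

    ``grid_spec`` maps parameter names (any of N, L, delta, dx_over_R,
    delta_p_over_mean_p, ...) to value lists; the grid is their Cartesian
    product.  Seeds derive from ``base_seed`` and the global row index, so
    results are reproducible and independent of execution order.  A crashed
    replicate is recorded as a failed row and the sweep continues.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    from itertools import product

    names = list(grid_spec)
    combos = list(product(*(grid_spec[k] for k in names)))
    rows = []
    row_index = 0
    for combo in combos:
        params = dict(fixed or {})
        params.update(dict(zip(names, combo)))
        for rep in range(replicates):
            seeds = _replicate_seeds(base_seed, row_index)
            row = {**{k: params.get(k) for k in params},
                   "replicate": rep, "row_index": row_index, **seeds}
            try:
                summary = run_replicate(params, seeds)
                row.update(
                    survivor_count=summary["survivor_count"],
                    nsd=summary["nsd"],
                    connection_density=summary.get("connection_density",
                                                   np.nan),
                    terminated_by=summary["terminated_by"],
                    clamp_events=summary["clamp_events"],
                    failed=False,
                )
            except Exception as exc:  # record and continue
                row.update(survivor_count=np.nan, nsd=np.nan,
                           connection_density=np.nan,
                           terminated_by="failed", clamp_events=np.nan,
                           failed=True, error=str(exc))
            rows.append(row)
            row_index += 1
            if progress:
                print(f"  sweep {row_index}/{len(combos) * replicates}: "
                      f"{row.get('terminated_by')}", flush=True)
    return pd.DataFrame(rows)


def mean_survivors_map(table: pd.DataFrame, R: float = 3.0,
                       mean_p: float = 0.25, lam: float = 1.0) -> dict:
    """Mean survivor count over the (ΔP/⟨P⟩, dx/R) grid plus the
    theoretical critical-scale overlay curve."""
    ok = table[~table["failed"]] if "failed" in table else table
    pivot = ok.pivot_table(index="delta_p_over_mean_p", columns="dx_over_R",
                           values="survivor_count", aggfunc="mean")
    asym = np.asarray(pivot.index, dtype=float)
    overlay = np.array([
        interactions.critical_structural_scale(mean_p, a * mean_p, R, lam)
        if a > 0 else np.inf
        for a in asym])
    full = table.pivot_table(index="delta_p_over_mean_p",
                             columns="dx_over_R", values="survivor_count",
                             aggfunc="count")
    return {"mean_survivors": pivot, "overlay_dx_over_R": overlay,
            "asymmetry": asym, "missing_cells": full.isna()}


def disorder_correlation(table: pd.DataFrame) -> dict:
    """Pairwise Pearson correlations between per-disorder curves of mean
    survivors vs competitive asymmetry."""
    ok = table[~table["failed"]] if "failed" in table else table
    pivot = ok.pivot_table(index="delta", columns="delta_p_over_mean_p",
                           values="survivor_count", aggfunc="mean")
    if pivot.shape[0] < 2 or pivot.shape[1] < 3:
        raise ValueError("need >= 2 disorder values and >= 3 asymmetries")
    deltas = list(pivot.index)
    corrs = {}
    flagged = []
    for a in range(len(deltas)):
        for b in range(a + 1, len(deltas)):
            x, y = pivot.iloc[a].values, pivot.iloc[b].values
            if np.std(x) == 0 or np.std(y) == 0:
                flagged.append((deltas[a], deltas[b]))
                continue
            corrs[(deltas[a], deltas[b])] = float(np.corrcoef(x, y)[0, 1])
    vals = np.array(list(corrs.values()))
    return {"pairwise": corrs,
            "mean": float(vals.mean()) if vals.size else np.nan,
            "min": float(vals.min()) if vals.size else np.nan,
            "undefined_pairs": flagged}


def alpha_vs_N(table: pd.DataFrame,
               condition_cols: tuple = ("delta_p_over_mean_p", "L"),
               ) -> pd.DataFrame:
    """MLE survival-probability fits per (N, condition) group."""
    ok = table[~table["failed"]] if "failed" in table else table
    cols = [c for c in condition_cols if c in ok.columns]
    rows = []
    for key, grp in ok.groupby(["N", *cols]):
        key = key if isinstance(key, tuple) else (key,)
        N = int(key[0])
        dist = SurvivalDistribution.from_survivor_counts(
            grp["survivor_count"].astype(int), N)
        fit = fit_alpha_mle(dist.counts, N)
        row = {"N": N, **dict(zip(cols, key[1:])),
               "alpha": fit.alpha_hat, "ci_low": fit.ci_low,
               "ci_high": fit.ci_high, "n_replicates": fit.n_replicates,
               "upper_open": fit.upper_open}
        rows.append(row)
    return pd.DataFrame(rows)
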