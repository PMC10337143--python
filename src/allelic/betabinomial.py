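"""Beta-binomial comparator test on point estimates only.

Fits, per feature, an intercept-only beta-binomial GLM to the allelic
counts (a2 successes out of a1+a2 trials across samples) by maximum
likelihood, with a free overdispersion parameter, and tests the allelic log
odds (logit-mean intercept) against zero with a Wald statistic.  Unlike the
bootstrap-averaged tests, this uses only the point estimates and therefore
ignores inferential uncertainty — it serves as the uncertainty-blind
baseline.  Multiple testing is controlled with Benjamini-Hochberg.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .matrix import AllelicMatrix

__all__ = ["beta_binomial_fit", "beta_binomial_test"]

# log-precision bounds: exp(15) ~ 3.3e6 is effectively binomial
_TAU_BOUNDS = (-5.0, 15.0)


def _negll(params: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    beta, tau = params
    p = special.expit(beta)
    theta = np.exp(tau)
    a = max(p * theta, 1e-12)
    b = max((1.0 - p) * theta, 1e-12)
    return -float(stats.betabinom.logpmf(k, n, a, b).sum())


def _wald_se(params, k, n, which: int = 0) -> float:
    """SE from a finite-difference Hessian of the negative log-likelihood."""
    h = 1e-4
    d = len(params)
    H = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            e_i = np.zeros(d)
            e_j = np.zeros(d)
            e_i[i] = h
            e_j[j] = h
            H[i, j] = H[j, i] = (
                _negll(params + e_i + e_j, k, n)
                - _negll(params + e_i - e_j, k, n)
                - _negll(params - e_i + e_j, k, n)
                + _negll(params - e_i - e_j, k, n)
            ) / (4 * h * h)
    v = np.nan
    try:
        cov = np.linalg.inv(H)
        v = cov[which, which]
    except np.linalg.LinAlgError:
        pass
    if not np.isfinite(v) or v <= 0:
        # precision parameter at its bound flattens the likelihood; fall
        # back to the conditional SE with the nuisance parameter fixed
        if H[which, which] > 0:
            v = 1.0 / H[which, which]
        else:
            return np.nan
    return float(np.sqrt(v))


def beta_binomial_fit(
    k: np.ndarray,
    n: np.ndarray,
    fixed_log_precision: Optional[float] = None,
) -> dict:
    """MLE of an intercept-only beta-binomial model.

    Parameters are the logit mean ``beta`` and the log precision ``tau``
    (overdispersion vanishes as tau -> +inf, recovering the binomial).
    Returns dict with beta, tau, se (Wald SE of beta), pvalue, converged.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    use = n > 0
    k, n = k[use], n[use]
    if k.size < 3:
        raise ValueError("need >= 3 samples with positive totals")
    phat = np.clip(k.sum() / n.sum(), 1e-6, 1 - 1e-6)
    beta0 = special.logit(phat)
    if fixed_log_precision is not None:
        tau = float(fixed_log_precision)
        res = optimize.minimize_scalar(
            lambda b: _negll(np.array([b, tau]), k, n),
            bracket=(beta0 - 1, beta0, beta0 + 1),
            method="brent",
        )
        beta = float(res.x)
        se = _wald_se(np.array([beta, tau]), k, n, which=0)
        converged = bool(res.success if res.success is not None else True)
    else:
        best = None
        for tau0 in (1.0, 4.0, 8.0):
            res = optimize.minimize(
                _negll,
                x0=np.array([beta0, tau0]),
                args=(k, n),
                method="L-BFGS-B",
                bounds=[(-30, 30), _TAU_BOUNDS],
            )
            if best is None or res.fun < best.fun:
                best = res
        beta, tau = best.x
        se = _wald_se(best.x, k, n, which=0)
        converged = bool(best.success)
    if not np.isfinite(se) or se <= 0:
        return {
            "beta": beta,
            "tau": tau,
            "se": np.nan,
            "pvalue": np.nan,
            "converged": False,
        }
    z = beta / se
    return {
        "beta": float(beta),
        "tau": float(tau),
        "se": float(se),
        "pvalue": float(2 * stats.norm.sf(abs(z))),
        "converged": converged,
    }


def beta_binomial_test(m: AllelicMatrix, min_samples: int = 3) -> pd.DataFrame:
    """Per-feature beta-binomial Wald test of allelic log odds = 0.

    Counts are rounded to integers; features with fewer than ``min_samples``
    samples of positive total are assigned NA.  Returns a frame with
    feature_id, stat (Wald z), log_odds, pvalue, qvalue (BH), converged.
    """
    a1 = np.round(m.counts[..., 0]).astype(int)
    a2 = np.round(m.counts[..., 1]).astype(int)
    rows = []
    for i, fid in enumerate(m.feature_ids):
        k, n = a2[i], a1[i] + a2[i]
        if (n > 0).sum() < min_samples:
            rows.append((fid, np.nan, np.nan, np.nan, False))
            continue
        try:
            fit = beta_binomial_fit(k, n)
        except (ValueError, FloatingPointError):
            rows.append((fid, np.nan, np.nan, np.nan, False))
            continue
        z = fit["beta"] / fit["se"] if fit["se"] and np.isfinite(fit["se"]) else np.nan
        rows.append((fid, z, fit["beta"], fit["pvalue"], fit["converged"]))
    out = pd.DataFrame(
        rows, columns=["feature_id", "stat", "log_odds", "pvalue", "converged"]
    )
    q = np.full(len(out), np.nan)
    ok = out["pvalue"].notna().to_numpy()
    if ok.any():
        q[ok] = multipletests(out.loc[ok, "pvalue"], method="fdr_bh")[1]
    out["qvalue"] = q
    return out
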